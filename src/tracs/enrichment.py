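"""Hypergeometric pathway enrichment: cluster filtering and edge annotation.

A cluster of size ``C_i`` drawn from a universe of ``N`` genes containing
``N_p`` pathway genes is scored by the upper tail of the hypergeometric
distribution, ``P(X >= C_ip)`` where ``C_ip`` pathway genes landed in the
cluster.

Two uses:

* *Cluster filtering*: keep only clusters enriched (tail <= threshold) for
  a user-supplied pathway of interest.
* *Edge annotation* (two-group test): a pathway is shared across an edge
  between clusters i and j when the union of their genes is enriched
  (``P(X >= C_ijp) <= 0.05``) while neither cluster alone is
  (``0.05 < min(P(X >= C_ip), P(X >= C_jp))``), considering only pathways
  with more than 10 genes in the universe.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable

from scipy.stats import hypergeom

from .datamodel import ClusterAssignment, GeneSetCollection
from .network import EdgeAnnotation

__all__ = [
    "EnrichmentResult",
    "hypergeom_tail",
    "filter_clusters",
    "edge_annotations",
    "EDGE_P_THRESHOLD",
    "MIN_PATHWAY_SIZE",
]

logger = logging.getLogger(__name__)

EDGE_P_THRESHOLD = 0.05
MIN_PATHWAY_SIZE = 10  # pathways with N_p <= 10 are excluded from edge tests


@dataclass(frozen=True)
class EnrichmentResult:
    pathway_id: str
    N: int
    N_p: int
    C_i: int
    C_ip: int
    p_value: float


def hypergeom_tail(N: int, N_p: int, C_i: int, C_ip: int) -> float:
    """Upper-tail probability ``P(X >= C_ip)`` of the hypergeometric PMF."""
    for name, v in (("N", N), ("N_p", N_p), ("C_i", C_i), ("C_ip", C_ip)):
        if int(v) != v or v < 0:
            raise ValueError(f"{name} must be a non-negative integer, got {v}")
    if not (C_ip <= C_i <= N and N_p <= N and C_ip <= N_p):
        raise ValueError(
            f"invalid counts: need C_ip <= min(C_i, N_p) and C_i, N_p <= N "
            f"(N={N}, N_p={N_p}, C_i={C_i}, C_ip={C_ip})"
        )
    # survival function is P(X > k); shift by one for the inclusive tail
    return float(min(1.0, hypergeom.sf(C_ip - 1, N, N_p, C_i)))


def _universe(assignment: ClusterAssignment, universe: Iterable[str] | None) -> frozenset[str]:
    return frozenset(universe) if universe is not None else frozenset(assignment.labels)


def filter_clusters(
    assignment: ClusterAssignment,
    sets: GeneSetCollection,
    pathway_id: str,
    threshold: float = 0.1,
    universe: Iterable[str] | None = None,
) -> ClusterAssignment:
    """Keep only clusters enriched for a pathway of interest.

    The universe defaults to the clustered genes; pathway genes outside the
    universe do not count toward ``N_p``. Removed clusters are logged with
    their p-values. Cluster indices are renumbered consecutively while
    preserving their relative order.
    """
    if pathway_id not in sets:
        raise ValueError(f"unknown pathway id {pathway_id!r}")
    uni = _universe(assignment, universe)
    pathway = sets.genes(pathway_id) & uni
    n, n_p = len(uni), len(pathway)
    kept: list[int] = []
    for r in range(assignment.k):
        members = set(assignment.members(r))
        p = hypergeom_tail(n, n_p, len(members), len(members & pathway))
        if p <= threshold:
            kept.append(r)
        else:
            logger.info(
                "filtering cluster %d: %s tail p=%.4g > %.3g", r, pathway_id, p, threshold
            )
    if not kept:
        raise ValueError(
            f"no cluster enriched for {pathway_id!r} at threshold {threshold}"
        )
    remap = {old: new for new, old in enumerate(kept)}
    labels = {
        g: remap[c] for g, c in assignment.labels.items() if c in remap
    }
    return ClusterAssignment(
        labels=labels, k=len(kept), method=assignment.method, seed=assignment.seed
    )


def edge_annotations(
    cluster_i: Iterable[str],
    cluster_j: Iterable[str],
    sets: GeneSetCollection,
    universe: Iterable[str],
) -> list[EdgeAnnotation]:
    """Pathways satisfying the two-group criterion for one candidate edge.

    For each pathway with more than :data:`MIN_PATHWAY_SIZE` genes in the
    universe, computes tails for cluster i, cluster j and their union and
    annotates iff ``p_union <= 0.05 < min(p_i, p_j)``.
    """
    gi, gj = set(cluster_i), set(cluster_j)
    if gi & gj:
        raise ValueError(f"clusters overlap: {sorted(gi & gj)[:5]}")
    uni = frozenset(universe)
    if not (gi <= uni and gj <= uni):
        raise ValueError("cluster genes must be contained in the universe")
    n = len(uni)
    out: list[EdgeAnnotation] = []
    for pid in sets.ids():
        pathway = sets.genes(pid) & uni
        n_p = len(pathway)
        if n_p <= MIN_PATHWAY_SIZE:
            continue
        p_i = hypergeom_tail(n, n_p, len(gi), len(gi & pathway))
        p_j = hypergeom_tail(n, n_p, len(gj), len(gj & pathway))
        p_union = hypergeom_tail(n, n_p, len(gi) + len(gj), len((gi | gj) & pathway))
        if p_union <= EDGE_P_THRESHOLD < min(p_i, p_j):
            out.append(
                EdgeAnnotation(
                    pathway_id=pid,
                    name=sets.name(pid),
                    p_union=p_union,
                    p_source=p_i,
                    p_target=p_j,
                )
            )
    return out
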