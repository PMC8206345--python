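"""Ordering clusters into a directed cell-state transition network.

Shape-based distance (SBD) compares two cluster GP mean curves over every
integer shift ``w`` of the interpolation grid:

    SBD(a, b) = 1 - max_w CC_w(mu_a, mu_b) / sqrt(CC_0(mu_a, mu_a) * CC_0(mu_b, mu_b))

with ``CC_w(a, b) = sum_t a[t + w] * b[t]`` (out-of-range positions
zero-padded). The optimal shift's sign gives temporal precedence: if
``w < 0`` the second curve is a delayed copy of the first, so cluster *a*
is followed by cluster *b*. Pairwise precedences are merged into a total
order with the ranked-pairs (Tideman) algorithm — lock the strongest
victories first, skipping any that would create a cycle — and the final
network is a simple path over the ordered clusters (k - 1 edges).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Mapping, Sequence

import networkx as nx
import numpy as np

from .datamodel import ClusterAssignment
from .gp import GPFit

__all__ = [
    "SBDResult",
    "EdgeAnnotation",
    "ClusterNode",
    "NetworkEdge",
    "ClusterNetwork",
    "shape_based_distance",
    "pairwise_orders",
    "ranked_pairs_order",
    "build_network",
]

CI_Z = 1.96  # 95% confidence band half-width in posterior s.d. units


@dataclass(frozen=True)
class SBDResult:
    """SBD between one unordered pair of clusters and the implied direction."""

    a: int
    b: int
    sbd: float
    w_opt: int
    direction: str  # "a_before_b" | "b_before_a" | "tie"

    def swapped(self) -> "SBDResult":
        direction = {
            "a_before_b": "b_before_a",
            "b_before_a": "a_before_b",
            "tie": "tie",
        }[self.direction]
        return SBDResult(self.b, self.a, self.sbd, -self.w_opt, direction)


def _cross_correlation(a: np.ndarray, b: np.ndarray, w: int) -> float:
    """CC_w(a, b) = sum_t a[t + w] * b[t], zero-padded outside [0, m)."""
    m = a.size
    lo = max(0, -w)
    hi = min(m, m - w)
    if lo >= hi:
        return 0.0
    return float(np.dot(a[lo + w : hi + w], b[lo:hi]))


def shape_based_distance(mu_a: np.ndarray, mu_b: np.ndarray, a: int = 0, b: int = 1) -> SBDResult:
    """SBD and optimal shift between two equal-length series.

    Ties in the maximal cross-correlation are broken toward the smallest
    ``|w|``, then toward negative ``w``.
    """
    mu_a = np.asarray(mu_a, dtype=float).ravel()
    mu_b = np.asarray(mu_b, dtype=float).ravel()
    if mu_a.shape != mu_b.shape:
        raise ValueError("series must have equal length")
    m = mu_a.size
    if m < 2:
        raise ValueError("series must have length >= 2")
    if not (np.isfinite(mu_a).all() and np.isfinite(mu_b).all()):
        raise ValueError("series must be finite")
    norm = np.sqrt(np.dot(mu_a, mu_a) * np.dot(mu_b, mu_b))
    if norm == 0:
        raise ValueError("degenerate cluster mean (zero norm)")
    best_cc, best_w = -np.inf, 0
    for w in range(1 - m, m):
        cc = _cross_correlation(mu_a, mu_b, w) / norm
        better = cc > best_cc + 1e-12
        tie = abs(cc - best_cc) <= 1e-12
        if better or (tie and (abs(w) < abs(best_w) or (abs(w) == abs(best_w) and w < best_w))):
            best_cc, best_w = max(cc, best_cc), w
    if best_w < 0:
        direction = "a_before_b"
    elif best_w > 0:
        direction = "b_before_a"
    else:
        direction = "tie"
    return SBDResult(a=a, b=b, sbd=1.0 - best_cc, w_opt=best_w, direction=direction)


def pairwise_orders(fits: Mapping[int, GPFit] | Sequence[GPFit], k: int | None = None) -> list[SBDResult]:
    """SBD for every unordered pair of cluster GP means on the dense grid."""
    if not isinstance(fits, Mapping):
        fits = dict(enumerate(fits))
    ids = sorted(fits)
    if k is not None and len(ids) != k:
        raise ValueError(f"expected {k} fits, got {len(ids)}")
    if len(ids) < 2:
        raise ValueError("need at least 2 clusters to order")
    return [
        shape_based_distance(fits[a].mean, fits[b].mean, a=a, b=b)
        for a, b in combinations(ids, 2)
    ]


def ranked_pairs_order(pairs: Sequence[SBDResult]) -> list[int]:
    """Total order of clusters by the ranked-pairs (Tideman) algorithm.

    Each decisive pair (``w_opt != 0``) is a victory of the earlier cluster
    over the later one with strength ``1 - SBD``; zero-shift pairs abstain.
    Victories are locked in decreasing strength (ties: larger ``|w_opt|``
    first, then lexicographic cluster ids), skipping any that would create
    a cycle; the result is the lexicographic topological order of the
    locked graph.
    """
    if not pairs:
        raise ValueError("need at least one pair")
    nodes = sorted({p.a for p in pairs} | {p.b for p in pairs})
    decisive = [p for p in pairs if p.w_opt != 0]
    if not decisive:
        raise ValueError("no ordering signal: all pairs tied (zero optimal shift)")

    def sort_key(p: SBDResult):
        return (-(1.0 - p.sbd), -abs(p.w_opt), min(p.a, p.b), max(p.a, p.b))

    g = nx.DiGraph()
    g.add_nodes_from(nodes)
    for p in sorted(decisive, key=sort_key):
        winner, loser = (p.a, p.b) if p.direction == "a_before_b" else (p.b, p.a)
        if g.has_node(loser) and g.has_node(winner) and nx.has_path(g, loser, winner):
            continue  # would create a cycle
        g.add_edge(winner, loser)
    return list(nx.lexicographical_topological_sort(g))


@dataclass
class EdgeAnnotation:
    """A pathway shared by two adjacent clusters, with the three tail p-values."""

    pathway_id: str
    name: str
    p_union: float
    p_source: float
    p_target: float


@dataclass
class ClusterNode:
    cluster: int
    genes: list[str]
    grid: list[float]
    mean: list[float]
    sd: list[float]

    @property
    def ci_lower(self) -> list[float]:
        return [m - CI_Z * s for m, s in zip(self.mean, self.sd)]

    @property
    def ci_upper(self) -> list[float]:
        return [m + CI_Z * s for m, s in zip(self.mean, self.sd)]


@dataclass
class NetworkEdge:
    source: int
    target: int
    annotations: list[EdgeAnnotation] = field(default_factory=list)


@dataclass
class ClusterNetwork:
    """A directed path over ordered clusters with annotated transitions."""

    order: list[int]
    nodes: list[ClusterNode]
    edges: list[NetworkEdge]
    seed: int | None = None

    def validate(self) -> None:
        node_ids = {n.cluster for n in self.nodes}
        if set(self.order) != node_ids:
            raise ValueError("order and node set disagree")
        if len(self.edges) != max(len(self.order) - 1, 0):
            raise ValueError("network must be a path with k-1 edges")
        for e, (a, b) in zip(self.edges, zip(self.order, self.order[1:])):
            if (e.source, e.target) != (a, b):
                raise ValueError("edges do not follow the cluster order")

    def to_dict(self) -> dict:
        return {
            "order": list(self.order),
            "seed": self.seed,
            "nodes": [
                {
                    "cluster": n.cluster,
                    "genes": list(n.genes),
                    "grid": list(map(float, n.grid)),
                    "mean": list(map(float, n.mean)),
                    "sd": list(map(float, n.sd)),
                }
                for n in self.nodes
            ],
            "edges": [
                {
                    "source": e.source,
                    "target": e.target,
                    "annotations": [
                        {
                            "pathway_id": a.pathway_id,
                            "name": a.name,
                            "p_union": a.p_union,
                            "p_source": a.p_source,
                            "p_target": a.p_target,
                        }
                        for a in e.annotations
                    ],
                }
                for e in self.edges
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ClusterNetwork":
        return cls(
            order=list(d["order"]),
            seed=d.get("seed"),
            nodes=[
                ClusterNode(
                    cluster=n["cluster"],
                    genes=list(n["genes"]),
                    grid=list(n["grid"]),
                    mean=list(n["mean"]),
                    sd=list(n["sd"]),
                )
                for n in d["nodes"]
            ],
            edges=[
                NetworkEdge(
                    source=e["source"],
                    target=e["target"],
                    annotations=[
                        EdgeAnnotation(**a) for a in e.get("annotations", [])
                    ],
                )
                for e in d["edges"]
            ],
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ClusterNetwork):
            return NotImplemented
        return self.to_dict() == other.to_dict()


def build_network(
    assignment: ClusterAssignment,
    fits: Mapping[int, GPFit],
    order: Sequence[int],
    annotations: Mapping[tuple[int, int], Sequence[EdgeAnnotation]] | None = None,
    seed: int | None = None,
) -> ClusterNetwork:
    """Assemble the path network: ordered nodes with GP summaries, k-1 edges."""
    if sorted(order) != sorted(range(assignment.k)):
        raise ValueError("order must cover every cluster exactly once")
    annotations = annotations or {}
    nodes = [
        ClusterNode(
            cluster=c,
            genes=sorted(assignment.members(c)),
            grid=list(map(float, fits[c].grid_times)),
            mean=list(map(float, fits[c].mean)),
            sd=list(map(float, fits[c].sd)),
        )
        for c in order
    ]
    edges = [
        NetworkEdge(a, b, list(annotations.get((a, b), [])))
        for a, b in zip(order, order[1:])
    ]
    net = ClusterNetwork(order=list(order), nodes=nodes, edges=edges, seed=seed)
    net.validate()
    return net
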