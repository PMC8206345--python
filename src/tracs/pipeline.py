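"""High-level orchestration: normalize -> gap scan -> network.

These wrappers compose the module-level operations the way the command
line does; library users can equally call the pieces directly.
"""

from __future__ import annotations

from typing import Iterable

from .datamodel import ClusterAssignment, GeneSetCollection, TimeSeriesMatrix
from .enrichment import edge_annotations, filter_clusters
from .gap import GapScan, fit_cluster_gps, gap_scan
from .network import ClusterNetwork, build_network, pairwise_orders, ranked_pairs_order
from .preprocessing import average_replicates, log_z_normalize

__all__ = ["cluster_timeseries", "infer_network"]


def cluster_timeseries(
    m: TimeSeriesMatrix,
    k_range: tuple[int, int] = (1, 20),
    method: str = "kmeans",
    B: int = 10,
    mode: str = "gp",
    seed: int = 0,
    *,
    normalize: bool = True,
    log_offset: float = 1.0,
    already_log: bool = False,
    criterion: str = "argmax",
) -> tuple[GapScan, ClusterAssignment, TimeSeriesMatrix]:
    """Normalize, scan k by the gap statistic, return the chosen partition.

    Returns the scan, the assignment at ``k_opt`` and the normalized,
    replicate-averaged matrix the assignment was computed on.
    """
    if normalize:
        m, _ = log_z_normalize(m, log_offset, already_log=already_log)
    avg = average_replicates(m)
    scan = gap_scan(avg, k_range, method, B, mode, seed, criterion=criterion)
    return scan, scan.assignments[scan.k_opt], avg


def infer_network(
    m: TimeSeriesMatrix,
    assignment: ClusterAssignment,
    gene_sets: GeneSetCollection | None = None,
    *,
    pathway_filter: str | None = None,
    filter_threshold: float = 0.1,
    universe: Iterable[str] | None = None,
    seed: int = 0,
) -> ClusterNetwork:
    """Order clusters by SBD + ranked pairs and annotate edges.

    ``m`` must already be normalized and averaged (the matrix returned by
    :func:`cluster_timeseries`). If a ``pathway_filter`` id is given,
    clusters not enriched for it are removed before ordering.
    """
    if pathway_filter is not None:
        if gene_sets is None:
            raise ValueError("pathway_filter requires gene sets")
        assignment = filter_clusters(
            assignment, gene_sets, pathway_filter, filter_threshold, universe=universe
        )
    m = m.subset([g for g in m.gene_ids if g in assignment.labels])
    fits = fit_cluster_gps(m, assignment, seed=seed)
    if assignment.k == 1:
        return build_network(assignment, fits, [0], seed=seed)
    pairs = pairwise_orders(fits, assignment.k)
    order = ranked_pairs_order(pairs)

    annotations = {}
    if gene_sets is not None and len(gene_sets):
        uni = frozenset(universe) if universe is not None else frozenset(m.gene_ids)
        for a, b in zip(order, order[1:]):
            annotations[(a, b)] = edge_annotations(
                assignment.members(a), assignment.members(b), gene_sets, uni
            )
    return build_network(assignment, fits, order, annotations, seed=seed)
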