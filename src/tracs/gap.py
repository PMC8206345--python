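"""Choosing the number of clusters with the gap statistic.

Two dispersion measures are supported for the gap between observed data and
a structureless uniform reference:

* *Euclidean*: the classic within-cluster sum of squared pairwise distances
  ``W_k = sum_r D_r / (2 n_r)``; the gap is
  ``E*[log W_k(ref)] - log W_k(obs)``.
* *GP*: each cluster is summarized by one Gaussian process and
  ``W_k^GP = sum_r L_r`` is the summed log marginal likelihood of member
  profiles under their cluster's GP. A larger likelihood means a tighter
  cluster, so the gap is ``W_k^GP(obs) - E*[W_k^GP(ref)]``. (``W_k^GP`` is
  a sum of log densities and is typically negative, so no outer log is
  applied; the selection is monotone-equivalent where both are defined.)

``k_opt`` is the argmax of the selected gap over the scanned range, ties
broken toward the smallest k; the Tibshirani one-standard-error rule is
available as an alternative criterion.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import cho_factor, cho_solve
from sklearn.cluster import AgglomerativeClustering, KMeans

from .datamodel import ClusterAssignment, TimeGrid, TimeSeriesMatrix
from .gp import GPFit, fit_cluster_gp
from .preprocessing import average_replicates

__all__ = [
    "GapScan",
    "cluster_matrix",
    "euclidean_dispersion",
    "fit_cluster_gps",
    "gp_dispersion",
    "sample_reference",
    "gap_scan",
]


def cluster_matrix(
    m: TimeSeriesMatrix, k: int, method: str = "kmeans", seed: int = 0
) -> ClusterAssignment:
    """Partition genes into ``k`` clusters on their averaged profiles."""
    x = m.averaged_values()
    if not np.isfinite(x).all():
        raise ValueError("averaged profiles contain non-finite values")
    if k > m.n_genes:
        raise ValueError(f"k={k} exceeds the number of genes ({m.n_genes})")
    if method == "kmeans":
        km = KMeans(n_clusters=k, n_init=10, random_state=int(seed) % (2**31))
        labels = km.fit_predict(x)
    elif method == "agglomerative":
        if k == 1:
            labels = np.zeros(m.n_genes, dtype=int)
        else:
            labels = AgglomerativeClustering(n_clusters=k, linkage="ward").fit_predict(x)
    else:
        raise ValueError(f"unknown clustering method {method!r}")
    return ClusterAssignment(
        labels=dict(zip(m.gene_ids, (int(c) for c in labels))),
        k=k,
        method=method,
        seed=int(seed),
    )


def euclidean_dispersion(
    m: TimeSeriesMatrix, assignment: ClusterAssignment, route: str = "centroid"
) -> float:
    """Within-cluster dispersion ``W_k = sum_r D_r / (2 n_r)``.

    ``D_r`` is the sum of squared Euclidean distances over all ordered
    pairs in cluster r, identically ``2 n_r`` times the within-cluster sum
    of squares about the centroid. Both routes are exposed so they can be
    cross-checked.
    """
    x = m.averaged_values()
    idx = m.gene_index()
    w = 0.0
    for r in range(assignment.k):
        members = assignment.members(r)
        if not members:
            raise ValueError(f"cluster {r} is empty")
        xr = x[[idx[g] for g in members]]
        n_r = len(members)
        if route == "centroid":
            mu = xr.mean(axis=0)
            w += float(np.sum((xr - mu) ** 2))
        elif route == "pairs":
            d_r = 0.0
            for i in range(n_r):
                d_r += float(np.sum((xr - xr[i]) ** 2))
            w += d_r / (2.0 * n_r)
        else:
            raise ValueError(f"unknown route {route!r}")
    return w


def fit_cluster_gps(
    m: TimeSeriesMatrix,
    assignment: ClusterAssignment,
    grid: TimeGrid | None = None,
    *,
    seed: int = 0,
    **gp_kwargs,
) -> dict[int, GPFit]:
    """Fit one GP per cluster to all member (time, value) points."""
    grid = grid or m.grid
    idx = m.gene_index()
    times = np.asarray(m.grid.points, dtype=float)
    fits: dict[int, GPFit] = {}
    for r in range(assignment.k):
        members = assignment.members(r)
        rows = m.values[[idx[g] for g in members]]  # (n_r, N_t, N_r)
        t_flat = np.broadcast_to(times[None, :, None], rows.shape).ravel()
        fits[r] = fit_cluster_gp(
            t_flat, rows.ravel(), grid, seed=seed + r, **gp_kwargs
        )
    return fits


def gp_dispersion(
    m: TimeSeriesMatrix,
    assignment: ClusterAssignment,
    grid: TimeGrid | None = None,
    *,
    seed: int = 0,
    fits: dict[int, GPFit] | None = None,
    **gp_kwargs,
) -> float:
    """GP dispersion ``W_k^GP``: summed log likelihood of every member
    profile (one vector per gene and replicate) under its cluster's GP."""
    grid = grid or m.grid
    if fits is None:
        fits = fit_cluster_gps(m, assignment, grid, seed=seed, **gp_kwargs)
    idx = m.gene_index()
    times = np.asarray(m.grid.points, dtype=float)
    total = 0.0
    for r in range(assignment.k):
        fit = fits[r]
        rows = m.values[[idx[g] for g in assignment.members(r)]]
        profiles = rows.transpose(0, 2, 1).reshape(-1, m.n_timepoints)
        complete = np.isfinite(profiles).all(axis=1)
        if complete.any():
            # shared mean/covariance across complete profiles: one solve
            mu, _ = fit.posterior(times)
            cov = np.exp(
                -((times[:, None] - times[None, :]) ** 2)
                / (2.0 * fit.params.length_scale**2)
            )
            cov[np.diag_indices_from(cov)] += fit.params.noise_sd**2 + 1e-10
            cf = cho_factor(cov, lower=True)
            resid = profiles[complete] - mu
            quad = np.sum(resid * cho_solve(cf, resid.T).T, axis=1)
            logdet = 2.0 * np.sum(np.log(np.diag(cf[0])))
            total += float(
                np.sum(-0.5 * (quad + logdet + times.size * np.log(2.0 * np.pi)))
            )
        for p in profiles[~complete]:
            if np.isfinite(p).any():
                total += fit.profile_log_likelihood(p, times)
    return total


def sample_reference(m: TimeSeriesMatrix, seed: int = 0) -> TimeSeriesMatrix:
    """Structureless reference: each time-point feature is drawn i.i.d.
    uniform over the observed [min, max] of that feature."""
    x = average_replicates(m).averaged_values()
    lo = np.nanmin(x, axis=0)
    hi = np.nanmax(x, axis=0)
    rng = np.random.default_rng(seed)
    ref = rng.uniform(lo, hi, size=x.shape)
    gene_ids = [f"ref{i:05d}" for i in range(x.shape[0])]
    return TimeSeriesMatrix(gene_ids, ref[:, :, None], m.grid)


@dataclass
class GapScan:
    """Full record of a gap-statistic scan over a range of k."""

    ks: list[int]
    mode: str                      # "gp" or "euclidean"
    method: str
    B: int
    seed: int
    log_w: list[float]             # log W_k (Euclidean), observed
    w_gp: list[float | None]       # W_k^GP, observed (None in euclidean mode)
    ref_log_w: list[float]         # E*[log W_k] over reference draws
    ref_w_gp: list[float | None]
    se_log_w: list[float]          # Tibshirani s_k = sd * sqrt(1 + 1/B)
    se_w_gp: list[float | None]
    gap: list[float]               # gap of the selected mode, per k
    k_opt: int = 0
    assignments: dict[int, ClusterAssignment] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "ks": self.ks,
            "mode": self.mode,
            "method": self.method,
            "B": self.B,
            "seed": self.seed,
            "log_w": self.log_w,
            "w_gp": self.w_gp,
            "ref_log_w": self.ref_log_w,
            "ref_w_gp": self.ref_w_gp,
            "se_log_w": self.se_log_w,
            "se_w_gp": self.se_w_gp,
            "gap": self.gap,
            "k_opt": self.k_opt,
        }


def _select_k(ks: list[int], gaps: list[float], ses: list[float], criterion: str) -> int:
    finite = [(k, g) for k, g, in zip(ks, gaps) if np.isfinite(g)]
    if not finite:
        raise ValueError("no k had a finite gap value")
    if criterion == "argmax":
        best = max(g for _, g in finite)
        return min(k for k, g in finite if g == best)
    if criterion == "tibshirani-se":
        # smallest k with Gap(k) >= Gap(k+1) - s_{k+1}
        for i in range(len(ks) - 1):
            if not (np.isfinite(gaps[i]) and np.isfinite(gaps[i + 1])):
                continue
            if gaps[i] >= gaps[i + 1] - ses[i + 1]:
                return ks[i]
        return ks[-1]
    raise ValueError(f"unknown gap criterion {criterion!r}")


def gap_scan(
    m: TimeSeriesMatrix,
    k_range: tuple[int, int] = (1, 20),
    method: str = "kmeans",
    B: int = 10,
    mode: str = "gp",
    seed: int = 0,
    *,
    criterion: str = "argmax",
    **gp_kwargs,
) -> GapScan:
    """Scan k over ``k_range`` and select ``k_opt`` by the gap statistic.

    The matrix is replicate-averaged up front; observed data and each of B
    uniform reference draws are clustered with the same method, and the
    reference draws are shared across all k. In GP mode a GP is fitted per
    cluster on both observed and reference data. Deterministic given
    (data, seed, B, method).
    """
    if mode not in ("gp", "euclidean"):
        raise ValueError(f"unknown mode {mode!r}")
    if B < 1:
        raise ValueError("B must be >= 1")
    k_min, k_max = k_range
    if k_min < 1:
        raise ValueError("k_min must be >= 1")
    avg = average_replicates(m)
    rng = np.random.default_rng(seed)
    ref_seeds = rng.integers(0, 2**31 - 1, size=B)
    refs = [sample_reference(avg, int(s)) for s in ref_seeds]

    scan = GapScan(
        ks=[], mode=mode, method=method, B=B, seed=seed,
        log_w=[], w_gp=[], ref_log_w=[], ref_w_gp=[],
        se_log_w=[], se_w_gp=[], gap=[],
    )

    for k in range(k_min, k_max + 1):
        if k > avg.n_genes:
            warnings.warn(f"k={k} exceeds number of genes; skipped", stacklevel=2)
            continue
        k_seed = int(rng.integers(0, 2**31 - 1))
        assignment = cluster_matrix(avg, k, method, seed=k_seed)
        w_obs = euclidean_dispersion(avg, assignment)
        log_w_obs = float(np.log(w_obs)) if w_obs > 0 else -np.inf
        if mode == "gp":
            wgp_obs = gp_dispersion(avg, assignment, seed=k_seed, **gp_kwargs)
        else:
            wgp_obs = None

        ref_log, ref_gp = [], []
        for b, ref in enumerate(refs):
            r_seed = int(rng.integers(0, 2**31 - 1))
            a_ref = cluster_matrix(ref, k, method, seed=r_seed)
            w_ref = euclidean_dispersion(ref, a_ref)
            ref_log.append(float(np.log(w_ref)) if w_ref > 0 else -np.inf)
            if mode == "gp":
                ref_gp.append(gp_dispersion(ref, a_ref, seed=r_seed, **gp_kwargs))

        if np.isfinite(ref_log).all():
            e_log = float(np.mean(ref_log))
            se_log = float(np.std(ref_log) * np.sqrt(1.0 + 1.0 / B))
        else:  # a reference draw hit zero dispersion (k near n_genes)
            e_log, se_log = -np.inf, 0.0
        scan.ks.append(k)
        scan.log_w.append(log_w_obs)
        scan.ref_log_w.append(e_log)
        scan.se_log_w.append(se_log)
        scan.assignments[k] = assignment
        if mode == "gp":
            e_gp = float(np.mean(ref_gp))
            se_gp = float(np.std(ref_gp) * np.sqrt(1.0 + 1.0 / B))
            scan.w_gp.append(wgp_obs)
            scan.ref_w_gp.append(e_gp)
            scan.se_w_gp.append(se_gp)
            scan.gap.append(wgp_obs - e_gp)
        else:
            scan.w_gp.append(None)
            scan.ref_w_gp.append(None)
            scan.se_w_gp.append(None)
            gap_k = e_log - log_w_obs
            # a zero observed or reference dispersion makes the log-gap
            # undefined; mark that k as unusable rather than +/- infinite
            scan.gap.append(gap_k if np.isfinite(gap_k) else -np.inf)

    ses = scan.se_w_gp if mode == "gp" else scan.se_log_w
    scan.k_opt = _select_k(scan.ks, scan.gap, [s or 0.0 for s in ses], criterion)
    return scan
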