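"""Normalization and optional functional-PCA feature extraction.

Expression values are log-transformed (``log(x + offset)``, default
offset 1) and then z-scored per gene across all time points and replicates
jointly, so that clustering compares temporal shapes rather than absolute
levels. Zero-variance genes are kept as all-zero rows and flagged.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .datamodel import TimeSeriesMatrix

__all__ = [
    "NormalizationRecord",
    "log_z_normalize",
    "inverse_normalize",
    "average_replicates",
    "functional_pca",
    "FPCAResult",
    "drop_sparse_genes",
]


@dataclass
class NormalizationRecord:
    """Per-gene statistics needed to invert a log + z-score transform."""

    gene_ids: list[str]
    mean: np.ndarray            # per-gene mean of log-scale values
    sd: np.ndarray              # per-gene s.d. of log-scale values (1 for constant genes)
    log_offset: float
    already_log: bool
    constant_genes: frozenset[str] = field(default_factory=frozenset)


def log_z_normalize(
    m: TimeSeriesMatrix,
    log_offset: float = 1.0,
    *,
    already_log: bool = False,
) -> tuple[TimeSeriesMatrix, NormalizationRecord]:
    """Log-transform then z-score each gene across all entries.

    Returns the transformed matrix and a record sufficient to invert the
    transform. Genes with zero variance become all-zero rows and are listed
    in ``record.constant_genes``.
    """
    v = m.values
    if already_log:
        logged = v.copy()
    else:
        if np.nanmin(v) < 0:
            raise ValueError(
                "negative expression values; pass already_log=True for "
                "log-scale input"
            )
        logged = np.log(v + log_offset)

    flat = logged.reshape(m.n_genes, -1)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mu = np.nanmean(flat, axis=1)
        sd = np.nanstd(flat, axis=1, ddof=0)
    constant = sd <= 1e-12
    safe_sd = np.where(constant, 1.0, sd)
    z = (logged - mu[:, None, None]) / safe_sd[:, None, None]
    z[constant] = np.where(np.isnan(logged[constant]), np.nan, 0.0)

    record = NormalizationRecord(
        gene_ids=list(m.gene_ids),
        mean=mu,
        sd=safe_sd,
        log_offset=float(log_offset),
        already_log=already_log,
        constant_genes=frozenset(np.array(m.gene_ids)[constant].tolist()),
    )
    return TimeSeriesMatrix(list(m.gene_ids), z, m.grid), record


def inverse_normalize(m: TimeSeriesMatrix, record: NormalizationRecord) -> TimeSeriesMatrix:
    """Undo :func:`log_z_normalize` to recover the original values."""
    if list(m.gene_ids) != record.gene_ids:
        raise ValueError("gene ids do not match the normalization record")
    logged = m.values * record.sd[:, None, None] + record.mean[:, None, None]
    if record.already_log:
        out = logged
    else:
        out = np.exp(logged) - record.log_offset
    return TimeSeriesMatrix(list(m.gene_ids), out, m.grid)


def average_replicates(m: TimeSeriesMatrix) -> TimeSeriesMatrix:
    """Collapse replicates to per-time-point means (missing entries ignored)."""
    if m.n_replicates == 1:
        return TimeSeriesMatrix(list(m.gene_ids), m.values.copy(), m.grid)
    counts = np.sum(np.isfinite(m.values), axis=2)
    empty = np.argwhere(counts == 0)
    if empty.size:
        g, t = empty[0]
        raise ValueError(
            f"gene {m.gene_ids[g]!r} has no finite replicate at time "
            f"{m.grid.points[t]}"
        )
    return TimeSeriesMatrix(list(m.gene_ids), m.averaged_values()[:, :, None], m.grid)


def drop_sparse_genes(
    m: TimeSeriesMatrix, max_missing_timepoints: int = 4
) -> TimeSeriesMatrix:
    """Drop genes missing *all* replicates at more than ``max_missing_timepoints``
    time points; dropped genes are reported via a warning."""
    counts = np.sum(np.isfinite(m.values), axis=2)
    n_missing = np.sum(counts == 0, axis=1)
    keep = n_missing <= max_missing_timepoints
    if keep.all():
        return m
    dropped = [g for g, k in zip(m.gene_ids, keep) if not k]
    warnings.warn(
        f"dropping {len(dropped)} gene(s) missing more than "
        f"{max_missing_timepoints} time points: {dropped[:10]}",
        stacklevel=2,
    )
    kept = [g for g, k in zip(m.gene_ids, keep) if k]
    return TimeSeriesMatrix(kept, m.values[keep].copy(), m.grid)


@dataclass
class FPCAResult:
    """Scores and eigenfunctions of discretized functional PCA."""

    scores: np.ndarray                    # genes x n_components
    components: np.ndarray                # n_components x N_t eigenfunctions
    explained_variance_ratio: np.ndarray  # non-increasing
    mean_curve: np.ndarray                # N_t


def functional_pca(m: TimeSeriesMatrix, n_components: int) -> FPCAResult:
    """Project each gene's curve onto the leading modes of variation.

    Implemented as PCA of the N_t x N_t sample covariance on the observed
    grid (a discretized eigenfunction basis); the matrix must already be
    replicate-averaged.
    """
    if n_components < 1:
        raise ValueError("n_components must be >= 1")
    if n_components > m.n_timepoints:
        raise ValueError(
            f"n_components={n_components} exceeds N_t={m.n_timepoints}"
        )
    if m.n_replicates != 1:
        raise ValueError("functional_pca expects a replicate-averaged matrix")
    x = m.averaged_values()
    if not np.isfinite(x).all():
        raise ValueError("non-finite values; normalize/average first")
    mean_curve = x.mean(axis=0)
    xc = x - mean_curve
    denom = max(m.n_genes - 1, 1)
    cov = xc.T @ xc / denom
    eigval, eigvec = np.linalg.eigh(cov)
    order = np.argsort(eigval)[::-1]
    eigval = np.clip(eigval[order], 0.0, None)
    eigvec = eigvec[:, order]
    # deterministic sign: largest-magnitude loading positive
    for j in range(eigvec.shape[1]):
        i = np.argmax(np.abs(eigvec[:, j]))
        if eigvec[i, j] < 0:
            eigvec[:, j] = -eigvec[:, j]
    total = eigval.sum()
    ratio = eigval / total if total > 0 else np.zeros_like(eigval)
    comps = eigvec[:, :n_components].T
    return FPCAResult(
        scores=xc @ comps.T,
        components=comps,
        explained_variance_ratio=ratio[:n_components],
        mean_curve=mean_curve,
    )
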