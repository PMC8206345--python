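"""Core domain types for time-series expression clustering.

The universal input is a genes x (time points x replicates) tensor with an
explicit numeric time grid. Clustering, Gaussian-process summaries and the
cluster network all hang off these containers.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "TimeGrid",
    "TimeSeriesMatrix",
    "ClusterAssignment",
    "GeneSetCollection",
]

_ROUND = 9  # decimals used to merge near-identical grid points


@dataclass(frozen=True)
class TimeGrid:
    """An ordered set of observation times plus an interpolation step.

    Parameters
    ----------
    points
        Strictly increasing observation times, length >= 2 for any
        clustering run (a single point is allowed for degenerate fixtures).
    interpolation_step
        Spacing of the dense grid used for GP interpolation; the dense grid
        is every multiple of the step inside ``[min, max]``, union the
        observed points.
    """

    points: tuple[float, ...]
    interpolation_step: float = 1.0

    def __init__(self, points: Iterable[float], interpolation_step: float = 1.0):
        pts = tuple(float(p) for p in points)
        if len(pts) < 1:
            raise ValueError("TimeGrid needs at least one time point")
        if any(b <= a for a, b in zip(pts, pts[1:])):
            raise ValueError(f"time points must be strictly increasing, got {pts}")
        if interpolation_step <= 0:
            raise ValueError("interpolation_step must be positive")
        object.__setattr__(self, "points", pts)
        object.__setattr__(self, "interpolation_step", float(interpolation_step))

    @property
    def n_timepoints(self) -> int:
        return len(self.points)

    @property
    def span(self) -> float:
        return self.points[-1] - self.points[0]

    def interpolation_grid(self) -> np.ndarray:
        """Dense grid: multiples of the step spanning [min, max], union observed."""
        lo, hi = self.points[0], self.points[-1]
        step = self.interpolation_step
        start = np.ceil(np.round(lo / step, _ROUND)) * step
        multiples = np.arange(start, hi + step / 2, step)
        multiples = multiples[(multiples >= lo - 10**-_ROUND) & (multiples <= hi + 10**-_ROUND)]
        merged = np.union1d(np.round(multiples, _ROUND), np.round(self.points, _ROUND))
        return merged.astype(float)


@dataclass
class TimeSeriesMatrix:
    """Expression values for ``genes x time points x replicates``.

    ``values`` has shape ``(n_genes, N_t, N_r)``; missing replicate
    measurements are NaN. The per-gene replicate-averaged profile must be
    finite after preprocessing.
    """

    gene_ids: list[str]
    values: np.ndarray
    grid: TimeGrid

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim == 2:
            self.values = self.values[:, :, None]
        if self.values.ndim != 3:
            raise ValueError("values must be a genes x time x replicate tensor")
        n_genes, n_t, _ = self.values.shape
        if len(self.gene_ids) != n_genes:
            raise ValueError(
                f"{len(self.gene_ids)} gene ids for {n_genes} rows of values"
            )
        if n_t != self.grid.n_timepoints:
            raise ValueError(
                f"values have {n_t} time points but grid has {self.grid.n_timepoints}"
            )
        seen: set[str] = set()
        dupes = {g for g in self.gene_ids if g in seen or seen.add(g)}
        if dupes:
            raise ValueError(f"duplicate gene ids: {sorted(dupes)}")

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_timepoints(self) -> int:
        return self.values.shape[1]

    @property
    def n_replicates(self) -> int:
        return self.values.shape[2]

    def averaged_values(self) -> np.ndarray:
        """Per-time-point replicate means (NaN-aware), shape (genes, N_t)."""
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            return np.nanmean(self.values, axis=2)

    def gene_index(self) -> dict[str, int]:
        return {g: i for i, g in enumerate(self.gene_ids)}

    def subset(self, gene_ids: Sequence[str]) -> "TimeSeriesMatrix":
        idx = self.gene_index()
        rows = [idx[g] for g in gene_ids]
        return TimeSeriesMatrix(list(gene_ids), self.values[rows].copy(), self.grid)


@dataclass
class ClusterAssignment:
    """A hard partition of genes into ``k`` clusters.

    Cluster indices live in ``[0, k)`` and every cluster is non-empty.
    """

    labels: dict[str, int]
    k: int
    method: str = "kmeans"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.method not in ("kmeans", "agglomerative", "truth", "manual"):
            raise ValueError(f"unknown clustering method {self.method!r}")
        present = set(self.labels.values())
        if not self.labels:
            raise ValueError("empty assignment")
        if not present <= set(range(self.k)):
            raise ValueError(f"labels outside [0, {self.k}): {sorted(present)}")
        if present != set(range(self.k)):
            missing = sorted(set(range(self.k)) - present)
            raise ValueError(f"empty clusters: {missing}")

    def members(self, cluster: int) -> list[str]:
        return [g for g, c in self.labels.items() if c == cluster]

    def cluster_sizes(self) -> list[int]:
        sizes = [0] * self.k
        for c in self.labels.values():
            sizes[c] += 1
        return sizes

    def labels_for(self, gene_ids: Sequence[str]) -> np.ndarray:
        return np.array([self.labels[g] for g in gene_ids], dtype=int)


@dataclass
class GeneSetCollection:
    """Named gene sets (pathways), e.g. parsed from a GMT file."""

    sets: dict[str, tuple[str, frozenset[str]]] = field(default_factory=dict)

    def __contains__(self, pathway_id: str) -> bool:
        return pathway_id in self.sets

    def __len__(self) -> int:
        return len(self.sets)

    def genes(self, pathway_id: str) -> frozenset[str]:
        return self.sets[pathway_id][1]

    def name(self, pathway_id: str) -> str:
        return self.sets[pathway_id][0]

    def ids(self) -> list[str]:
        return list(self.sets)

    @classmethod
    def from_mapping(cls, mapping: Mapping[str, Iterable[str]]) -> "GeneSetCollection":
        return cls({pid: (pid, frozenset(genes)) for pid, genes in mapping.items()})
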