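import numpy as np
import pytest

from tracs import SimulationSpec, TimeGrid, TimeSeriesMatrix


@pytest.fixture
def unit_grid8() -> TimeGrid:
    return TimeGrid(np.arange(8.0))


@pytest.fixture
def small_matrix(unit_grid8) -> TimeSeriesMatrix:
    """12 genes x 8 time points, two planted sinusoid clusters, seeded."""
    rng = np.random.default_rng(42)
    t = np.arange(8.0)
    rows = []
    for c in range(2):
        curve = np.sin(2 * np.pi * (t - 2.5 * c) / 7.0)
        for _ in range(6):
            rows.append(curve + rng.normal(0, 0.1, t.size))
    return TimeSeriesMatrix([f"g{i}" for i in range(12)], np.stack(rows)[:, :, None], TimeGrid(t))


def planted_spec(k: int, seed: int, *, genes: int = 20, noise: float = 0.1,
                 base: str = "sinusoid", shift_step: int = 2) -> SimulationSpec:
    """Low-noise planted-cluster fixture on the 8-point unit grid."""
    return SimulationSpec(
        k_true=k,
        genes_per_cluster=[genes] * k,
        grid=TimeGrid(np.arange(8.0)),
        base_curve=base,
        shift_per_cluster=[shift_step * i for i in range(k)],
        noise_sd=noise,
        seed=seed,
    )
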