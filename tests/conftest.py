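import numpy as np
import pytest

from acclimate.core import AcclimationDataset, NormalizedSeries, Record


def make_series(times, d, z0=1.0, z_inf=0.0, **kw) -> NormalizedSeries:
    times = np.asarray(times, float)
    return NormalizedSeries(times=times, d=np.asarray(d, float), z0=z0,
                            z_inf=z_inf, n_per_point=np.ones(len(times), int),
                            **kw)


def make_dataset(shifted: dict[float, list[float]],
                 initial: list[float] | None = None,
                 new: list[float] | None = None,
                 time_unit="h") -> AcclimationDataset:
    """Build a dataset from {time: [replicate phenotypes]} plus control values."""
    records = []
    for t, vals in shifted.items():
        for j, z in enumerate(vals):
            records.append(Record("shifted", float(t), float(z), f"s{t}r{j}"))
    for group, vals in (("initial_control", initial or []),
                        ("new_control", new or [])):
        for j, z in enumerate(vals):
            records.append(Record(group, 0.0, float(z), f"{group}{j}"))
    return AcclimationDataset(records=records, time_unit=time_unit)


def grid_search_lambda(shape: str, times, d, lo=1e-4, hi=10.0, n=100_000):
    """Independent brute-force SSE minimizer over a log-spaced rate grid.

    Returns (lam_at_min, grid) so callers can assert agreement within one
    grid step.  Deliberately shares no code with the fitters.
    """
    times = np.asarray(times, float)
    d = np.asarray(d, float)
    grid = np.logspace(np.log10(lo), np.log10(hi), n)
    if shape == "exponential":
        pred = np.exp(-np.outer(grid, times))
    elif shape == "linear":
        pred = np.maximum(1.0 - np.outer(grid, times), 0.0)
    else:
        raise ValueError(shape)
    sse = ((pred - d) ** 2).sum(axis=1)
    return float(grid[np.argmin(sse)]), grid


@pytest.fixture
def noiseless_exponential_series():
    t = np.arange(0.0, 21.0, 2.0)
    return make_series(t, np.exp(-0.1 * t))


@pytest.fixture
def noiseless_linear_series():
    t = np.arange(0.0, 41.0, 5.0)
    return make_series(t, np.maximum(1.0 - 0.05 * t, 0.0))
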