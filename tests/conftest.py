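import numpy as np
import pytest

from gcfmri import RoiTimeSeries


def ar1(n: int, phi: float, rng: np.random.Generator, sd: float = 1.0) -> np.ndarray:
    """Stationary-start AR(1) sample path."""
    x = np.empty(n)
    x[0] = rng.standard_normal() * sd / np.sqrt(1 - phi ** 2)
    e = rng.standard_normal(n) * sd
    for t in range(1, n):
        x[t] = phi * x[t - 1] + e[t]
    return x


def coupled_pair(n: int, rng: np.random.Generator, a_y: float = 0.5,
                 a_x: float = 0.5, c: float = 0.4) -> tuple[np.ndarray, np.ndarray]:
    """x drives y with one-sample lag: y(t) = a_y y(t-1) + c x(t-1) + e."""
    x = np.zeros(n)
    y = np.zeros(n)
    ex = rng.standard_normal(n)
    ey = rng.standard_normal(n)
    for t in range(1, n):
        x[t] = a_x * x[t - 1] + ex[t]
        y[t] = a_y * y[t - 1] + c * x[t - 1] + ey[t]
    return x, y


def series(values, dt: float = 0.1, roi: str = "roi", **kw) -> RoiTimeSeries:
    return RoiTimeSeries(values=np.asarray(values, dtype=float), dt=dt,
                         roi=roi, **kw)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def tiny_cohort():
    """A 3-subject, 1-run, default-network cohort shared by slow tests."""
    from gcfmri import CohortSpec, simulate_cohort

    return simulate_cohort(spec=CohortSpec(n_subjects=3, n_runs=1,
                                           master_seed=77))
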