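import numpy as np
import pytest

from retivel.timebase import CardiacTiming, build_time_grid


@pytest.fixture(scope="session")
def timing_307() -> CardiacTiming:
    """Three cardiac cycles of 102/102/103 frames, the acquisition layout."""
    return CardiacTiming(cycle_boundaries=(0, 102, 204, 307), cycle_time_s=0.852743)


@pytest.fixture(scope="session")
def t_307(timing_307) -> np.ndarray:
    return build_time_grid(timing_307).t


@pytest.fixture(scope="session")
def t_300() -> np.ndarray:
    """Three even cycles of 100 frames."""
    timing = CardiacTiming(cycle_boundaries=(0, 100, 200, 300), cycle_time_s=0.9)
    return build_time_grid(timing).t


def make_ar1(rng: np.random.Generator, n: int, rho: float, sigma_u: float) -> np.ndarray:
    """Stationary AR(1) noise series (independent generation path from the
    image simulator, used to build test series)."""
    eps = np.empty(n)
    eps[0] = rng.normal(0.0, sigma_u / np.sqrt(1.0 - rho**2)) if sigma_u else 0.0
    for k in range(1, n):
        eps[k] = rho * eps[k - 1] + rng.normal(0.0, sigma_u)
    return eps


def model_series(t, a0=5.0, harmonics=((1.2, -0.4), (0.3, 0.1)),
                 drift=(0.0, 0.0, 0.0)):
    """Noiseless two-harmonic + spline-drift signal on grid t."""
    y = np.full_like(t, a0, dtype=float)
    for n, (a, b) in enumerate(harmonics, start=1):
        y += a * np.cos(2 * np.pi * n * t) + b * np.sin(2 * np.pi * n * t)
    b1, b2, b3 = drift
    y += b1 * t + b2 * np.maximum(t - 1, 0.0) + b3 * np.maximum(t - 2, 0.0)
    return y
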