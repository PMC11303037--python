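import numpy as np
import pytest

from otolunar import simulate as sim
from otolunar.lunar import LunarCalendar
from otolunar.residuals import fit_age_detrend


@pytest.fixture(scope="session")
def cal():
    return LunarCalendar()


@pytest.fixture(scope="session")
def small_cohort():
    """240 fish, uniform spawn phase (all quarters populated), default signal."""
    params = sim.default_params(n_spawned=240, seed=5, spawn_concentration=0.0)
    series, truth = sim.simulate(params)
    return params, series, truth


@pytest.fixture(scope="session")
def small_detrend(small_cohort):
    _, series, _ = small_cohort
    return fit_age_detrend(series)


def make_clean_series(birth_angles, n_days=60, amp=0.5, cal=None, base=7.0):
    """Noise-free increment series with a pure lunar sine of known amplitude.

    Birth angles should be balanced over the cycle so that the pooled
    per-age mean contains no net lunar signal.
    """
    from otolunar.lunar import theta
    from otolunar.simulate import IncrementSeries

    cal = cal or LunarCalendar()
    ages = np.arange(1, n_days + 1, dtype=float)
    out = []
    for i, ang in enumerate(birth_angles):
        incr = base + amp * np.sin(np.radians(theta(ages, ang, cal)))
        out.append(
            IncrementSeries(
                fish_id=i, radii=np.cumsum(incr), settlement_index=46,
                stage="settler", capture_day=float(n_days),
            )
        )
    return out
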