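import numpy as np
import pytest

from rdlg.synth import SleepConfig, TaskConfig, SpatialUnitSpec, \
    simulate_sleep_session, simulate_task_session


@pytest.fixture(scope="session")
def sleep_session():
    """One full-size synthetic sleep session shared across detector tests."""
    return simulate_sleep_session(SleepConfig(), seed=11)


@pytest.fixture(scope="session")
def task_session():
    units = (
        SpatialUnitSpec(3.0, (0.0, 25.0), 5.0, 5.0, gain_left=1.0,
                        gain_right=0.2),             # splitter
        SpatialUnitSpec(3.0, (0.0, 15.0), 5.0, 4.0),  # location-related
        SpatialUnitSpec(4.0),                         # untuned
        SpatialUnitSpec(1.0, speed_slope=0.2),        # speed cell
    )
    return simulate_task_session(TaskConfig(n_trials=40, units=units), seed=7)


def poisson_train(rate_hz, duration_s, rng, unit_id="u", region="RSC"):
    from rdlg.core import SpikeTrain
    n = rng.poisson(rate_hz * duration_s)
    return SpikeTrain(unit_id, region, np.sort(rng.uniform(0, duration_s, n)))


def bump_train(anchors, rate_hz, duration_s, rng, gain=2.0, center=-0.06,
               sd=0.06, unit_id="u", region="RSC"):
    """Poisson baseline plus per-event Gaussian rate bump (superposition)."""
    from rdlg.core import SpikeTrain
    base = rng.uniform(0, duration_s, rng.poisson(rate_hz * duration_s))
    extra_per_event = rate_hz * (gain - 1.0) * sd * np.sqrt(2 * np.pi)
    extras = []
    for a in anchors:
        k = rng.poisson(extra_per_event)
        extras.append(a + center + sd * rng.standard_normal(k))
    times = np.concatenate([base] + extras)
    times = times[(times >= 0) & (times < duration_s)]
    return SpikeTrain(unit_id, region, np.sort(times))
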