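import numpy as np
import pytest

from hypoburden import MapSeries, default_trial_profiles, generate_cohort


def make_series(t, m, patient_id="p", **channels):
    return MapSeries(patient_id, np.asarray(t, float), np.asarray(m, float), channels=dict(channels))


def triangle_trace(baseline=70.0, nadir=60.0, dip_start_s=120.0, dip_len_s=240.0,
                   total_s=900.0, dt=20.0):
    """Piecewise-linear dip baseline -> nadir -> baseline, symmetric."""
    t = np.arange(0.0, total_s + dt / 2, dt)
    m = np.full_like(t, baseline)
    half = dip_len_s / 2.0
    down = (t >= dip_start_s) & (t <= dip_start_s + half)
    up = (t > dip_start_s + half) & (t <= dip_start_s + dip_len_s)
    m[down] = baseline - (baseline - nadir) * (t[down] - dip_start_s) / half
    m[up] = nadir + (baseline - nadir) * (t[up] - dip_start_s - half) / half
    return t, m


@pytest.fixture
def triangle_series():
    """MAP dips linearly 70 -> 60 -> 70 over 4 min inside a 15-min trace."""
    t, m = triangle_trace()
    return make_series(t, m)


@pytest.fixture(scope="session")
def trial_cohort():
    """One default trial-like cohort (30 + 30), shared across tests."""
    return generate_cohort(default_trial_profiles(seed=1))


def random_trace(rng, n=None, around=65.0, spread=12.0, dt=20.0):
    """A random-walk trace that repeatedly crosses the threshold region."""
    if n is None:
        n = int(rng.integers(5, 101))
    steps = rng.normal(0.0, 4.0, n)
    m = np.clip(around + spread * np.tanh(np.cumsum(steps) / 20.0) + rng.normal(0, 2, n),
                20.0, 240.0)
    t = np.arange(n) * dt
    return t, m
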