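import numpy as np
import pytest

from glucotriad import GlucoseTrace


def make_random_trace(rng, days=2, interval=5.0, mu=120.0, subject_id="S"):
    """A wiggly, positive, uniform CGM-like trace for oracle comparisons."""
    n = int(days * 1440 / interval)
    t = np.arange(n) * interval
    drift = rng.normal(0, 2.0, size=n).cumsum()
    drift -= np.linspace(0, drift[-1], n)  # keep it range-bound
    meals = sum(rng.uniform(20, 60) * np.exp(-0.5 * ((t - c) / 40.0) ** 2)
                for c in rng.uniform(0, t[-1], size=3 * days))
    g = np.maximum(mu + drift + meals + rng.normal(0, 4.0, size=n), 45.0)
    return GlucoseTrace(subject_id, t, g, sampling_interval=interval)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def random_traces(rng):
    """20 random short traces mixing 5- and 15-min sampling over 2-3 days."""
    out = []
    for i in range(20):
        interval = 5.0 if i % 2 == 0 else 15.0
        days = 2 + (i % 2)
        out.append(make_random_trace(rng, days=days, interval=interval,
                                     mu=rng.uniform(90, 180),
                                     subject_id=f"T{i}"))
    return out
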