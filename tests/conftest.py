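import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=40,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def rng():
    return np.random.default_rng(20231115)


def make_train(times, amplitudes=None, prominences=None, channel="1-2", params=None,
               n_samples=None):
    """Build a SpikeTrain directly from peak times (test plumbing)."""
    from mycolingua.spike_detection import SpikeEvent, SpikeTrain

    times = list(int(t) for t in times)
    if amplitudes is None:
        amplitudes = [1.0] * len(times)
    if prominences is None:
        prominences = [1.0] * len(times)
    events = [
        SpikeEvent(peak_index=t, amplitude=float(a), prominence=float(p))
        for t, a, p in zip(times, amplitudes, prominences)
    ]
    if n_samples is None:
        n_samples = (times[-1] + 1) if times else 0
    return SpikeTrain(channel=channel, events=events, params=params, n_samples=n_samples)
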