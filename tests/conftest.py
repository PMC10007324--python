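import numpy as np
import pytest

import stressprofile as sp


@pytest.fixture(scope="session")
def protocol256():
    return sp.default_protocol(256.0)


@pytest.fixture(scope="session")
def protocol32():
    """Reduced-rate protocol used for simulation-heavy tests; stage-mean
    geometry (hence RSI) does not depend on the sampling rate."""
    return sp.default_protocol(32.0)


@pytest.fixture(scope="session")
def reference_cohort():
    return sp.load_reference_cohort()


@pytest.fixture
def low_noise_config():
    """Subject config with noise small enough that centroid geometry is
    essentially the configured stage-level geometry."""
    return sp.SubjectSimConfig(
        noise_sd=(0.1, 0.08, 0.01),
        osc_amplitude=(0.3, 0.25, 0.0),
        ar_sd=0.004,
        artifact_rate_per_min=0.0,
        seed=7,
    )


def brute_force_median_filter(x, w):
    """Independent oracle: per-window median with symmetric truncated edges,
    computed with Python's statistics module."""
    import statistics

    k = (w - 1) // 2
    n = len(x)
    out = []
    for i in range(n):
        r = min(k, i, n - 1 - i)
        out.append(statistics.median(list(x[i - r : i + r + 1])))
    return np.array(out)
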