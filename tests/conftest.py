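import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("suite", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("suite")


@pytest.fixture
def exp_curve_factory():
    """Exponential survival curves sampled exactly on a uniform grid."""
    from idasurv import KMCurve

    def make(lam, t_max=60.0, step=0.5, label=""):
        t = np.arange(0.0, t_max + 1e-9, step)
        return KMCurve(t, np.exp(-lam * t), step, arm_label=label)

    return make


@pytest.fixture
def simulated_arm_300():
    """300 subjects, exponential events (0.06/month), uniform censoring."""
    from idasurv import IPDDataset

    rng = np.random.default_rng(7)
    n = 300
    ev = rng.exponential(1 / 0.06, n)
    cn = rng.uniform(0, 60, n)
    time = np.minimum(ev, cn)
    status = (ev <= cn).astype(int)
    return IPDDataset.from_arrays(time, status, "sim")
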