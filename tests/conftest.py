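import numpy as np
import pytest
from scipy.special import logit

from bspquant.bsp import BSPTrajectory, EpochCounts


def make_traj(p, sd_logit=0.05, epoch_len=1.0, with_counts=True):
    """Trajectory with given per-epoch probabilities and logit-scale posterior sd."""
    p = np.asarray(p, dtype=float)
    x = logit(np.clip(p, 1e-9, 1 - 1e-9))
    var = np.full_like(x, float(sd_logit) ** 2)
    counts = None
    if with_counts:
        N = np.full(len(p), 256, dtype=int)
        counts = EpochCounts(np.round(p * 256).astype(int), N, epoch_len)
    return BSPTrajectory(x, var, 1e-6, epoch_len, counts, kind="smoothed")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
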