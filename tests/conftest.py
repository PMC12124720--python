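import numpy as np
import pytest

from gktransport.correlation import caf
from gktransport.series import split_series
from gktransport.synthetic import ionic_toy_system, ou_series

#: simulation durations (ns) for the uncertainty scaling scan
SCALING_DURATIONS_NS = (1, 2, 5, 10, 20)


@pytest.fixture(scope="session")
def ou_scaling_cafs():
    """CAFs of a unit OU current (tau=1 ps, sigma^2=1, dt=1 fs) for a
    range of total simulation durations, split into 100 ps intervals.

    Shared between the uncertainty-scaling checks; the expensive
    fixture is computed once per session.
    """
    out = {}
    for t_ns in SCALING_DURATIONS_NS:
        series = ou_series(tau=1.0, sigma2=1.0, dt=1.0, n_steps=t_ns * 10**6,
                           n_components=1, seed=42 + t_ns)
        out[t_ns] = caf(split_series(series, 100e3))
    return out


@pytest.fixture()
def toy_ions():
    """Small neutral two-species system with ballistic frames."""
    return ionic_toy_system(n_pairs=4, temperature=300.0, box=4.0,
                            n_frames=5, dt=1.0, seed=7)


def direct_correlate(x, y, max_lag):
    """O(N^2) double-sum oracle for the lag correlation."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = x.size
    return np.array(
        [np.dot(x[k:], y[: n - k]) / (n - k) for k in range(max_lag + 1)]
    )


def direct_msd(vectors):
    """O(N^2) origin-averaged MSD oracle; vectors (T, P, 3)."""
    v = np.asarray(vectors, float)
    if v.ndim == 2:
        v = v[:, None, :]
    n = v.shape[0]
    out = np.zeros(n)
    for k in range(1, n):
        d = v[k:] - v[: n - k]
        out[k] = (d**2).sum(axis=2).mean()
    return out
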