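import sys
from pathlib import Path

import numpy as np
import pytest
from scipy import signal

sys.path.insert(0, str(Path(__file__).parent))

from _signals import narrowband, slow_driver  # noqa: E402


@pytest.fixture
def rng():
    return np.random.default_rng(20260924)


@pytest.fixture
def coupled_analytic_pair():
    """Factory: two analytic signals with envelope coupling ``kappa``."""

    def make(seed, kappa, n=42000, fs=250.0, band=(8.0, 12.0)):
        r = np.random.default_rng(seed)
        g = slow_driver(r, n, fs)
        envs = []
        for _ in range(2):
            e = slow_driver(r, n, fs)
            envs.append(np.logaddexp(0, 1.4 * (np.sqrt(1 - kappa) * e + np.sqrt(kappa) * g)))
        out = []
        for a in envs:
            c = narrowband(r, n, fs, *band)
            out.append(signal.hilbert(a * c))
        return out[0], out[1]

    return make
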