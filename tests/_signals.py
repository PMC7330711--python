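"""Shared signal builders for the test suite."""

import numpy as np
from scipy import signal


def narrowband(rng, n, fs, f_low, f_high):
    """Unit-variance band-limited Gaussian noise."""
    sos = signal.butter(4, [f_low, f_high], btype="bandpass", fs=fs, output="sos")
    x = signal.sosfiltfilt(sos, rng.standard_normal(n))
    return x / x.std()


def slow_driver(rng, n, fs, cutoff=0.9):
    """Standardized low-pass Gaussian envelope driver."""
    sos = signal.butter(2, cutoff, btype="low", fs=fs, output="sos")
    x = signal.sosfiltfilt(sos, rng.standard_normal(n))
    return x / x.std()
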