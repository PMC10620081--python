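"""Shared independent oracles for the test suite."""

import numpy as np
from scipy.signal import hilbert


def envelope_oracle(a, b, f1=2000.0, f2=2005.0, fs=200_000.0):
    """Time-domain oracle: simulate one beat of ``a sin(2 pi f1 t) +
    b sin(2 pi f2 t)``, extract the Hilbert envelope, and return
    ``(max - min, max)``.  Independent of the algebraic projection
    formulas it is used to check."""
    T = 1.0 / abs(f1 - f2)
    n = int(round(fs * T))
    t = np.arange(n) / fs
    s = a * np.sin(2 * np.pi * f1 * t) + b * np.sin(2 * np.pi * f2 * t)
    env = np.abs(hilbert(s))
    return env.max() - env.min(), env.max()
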