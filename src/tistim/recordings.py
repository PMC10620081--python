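"""Synthetic depth-electrode recordings.

Emulates what a multi-contact sEEG electrode sees during temporal
interference stimulation: at each contact the potential is a sum of two
kHz sinusoids (one per stimulation pair) whose amplitudes vary with
contact depth, plus additive white Gaussian noise.  Real recordings
additionally contain electrode drift, line noise and biological signal;
none of that is modeled here.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["Recording", "synth_recording", "gaussian_profile"]


@dataclass
class Recording:
    """Multichannel time series in mV.

    Attributes
    ----------
    data : (n_contacts, n_samples) float array, mV
    fs : float
        Sampling rate, samples per second.
    contact_depths_mm : (n_contacts,) float array
        Depth of each contact along the electrode shaft, strictly
        increasing (deeper contacts later).
    meta : dict
        Provenance (generator parameters, seed).
    """

    data: np.ndarray
    fs: float
    contact_depths_mm: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.atleast_2d(np.asarray(self.data, dtype=float))
        self.contact_depths_mm = np.asarray(self.contact_depths_mm, dtype=float)
        if self.data.shape[0] != self.contact_depths_mm.shape[0]:
            raise ValueError("one depth per contact required")
        if np.any(np.diff(self.contact_depths_mm) <= 0):
            raise ValueError("contact depths must be strictly increasing")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")

    @property
    def n_contacts(self) -> int:
        return self.data.shape[0]

    @property
    def duration_s(self) -> float:
        return self.data.shape[1] / self.fs

    @property
    def inter_contact_spacing_mm(self) -> float:
        d = np.diff(self.contact_depths_mm)
        return float(d.mean())


def synth_recording(
    contact_depths_mm,
    A1_profile_mV,
    A2_profile_mV,
    f1_hz: float,
    f2_hz: float,
    fs: float = 30_000.0,
    duration_s: float = 25.0,
    noise_sd_mV: float = 0.0,
    seed: int | None = None,
) -> Recording:
    """Generate a two-tone multichannel recording.

    Per contact ``k``::

        data[k](t) = A1_k sin(2 pi f1 t) + A2_k sin(2 pi f2 t) + N(0, noise_sd)

    With ``noise_sd_mV = 0`` the signal is exactly periodic over the beat
    period ``1/|f1-f2|`` and its sample maximum converges to ``A1 + A2``
    with duration.  Reproducible under a fixed seed.

    Raises
    ------
    ValueError
        If ``fs <= 2 max(f1, f2)`` (aliasing) or profile lengths mismatch.
    """
    depths = np.asarray(contact_depths_mm, dtype=float)
    a1 = np.broadcast_to(np.asarray(A1_profile_mV, dtype=float), depths.shape).copy()
    a2 = np.broadcast_to(np.asarray(A2_profile_mV, dtype=float), depths.shape).copy()
    if a1.shape != depths.shape or a2.shape != depths.shape:
        raise ValueError("amplitude profiles must match the number of contacts")
    if fs <= 2.0 * max(f1_hz, f2_hz):
        raise ValueError("sampling rate must exceed twice the highest carrier frequency")
    if duration_s <= 0:
        raise ValueError("duration must be positive")
    if noise_sd_mV < 0:
        raise ValueError("noise standard deviation must be non-negative")

    n = int(round(duration_s * fs))
    t = np.arange(n) / fs
    data = a1[:, None] * np.sin(2 * np.pi * f1_hz * t) + a2[:, None] * np.sin(
        2 * np.pi * f2_hz * t
    )
    if noise_sd_mV > 0:
        rng = np.random.default_rng(seed)
        data = data + rng.normal(0.0, noise_sd_mV, size=data.shape)
    return Recording(
        data=data,
        fs=float(fs),
        contact_depths_mm=depths,
        meta={
            "f1_hz": f1_hz,
            "f2_hz": f2_hz,
            "noise_sd_mV": noise_sd_mV,
            "seed": seed,
            "A1_profile_mV": a1.tolist(),
            "A2_profile_mV": a2.tolist(),
        },
    )


def gaussian_profile(depths_mm, center_mm: float, width_mm: float, amplitude_mV: float):
    """Gaussian amplitude-vs-depth profile, handy for recovery tests whose
    analytic spatial derivative is known."""
    d = np.asarray(depths_mm, dtype=float)
    return amplitude_mV * np.exp(-0.5 * ((d - center_mm) / width_mm) ** 2)
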