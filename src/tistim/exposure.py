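"""Temporal-interference exposure metrics, steering sweeps and ROI summaries.

Two fields E1, E2 oscillating at nearby kHz frequencies superpose to a
waveform whose amplitude envelope is modulated at the difference
frequency.  Projected on the local structure orientation ``n``, the
envelope-modulation amplitude (peak minus trough of the beat envelope) is

    E_AM(n, r) = | |(E1 + E2) . n| - |(E1 - E2) . n| |
              = 2 min(|E1 . n|, |E2 . n|)

and the absolute amplitude (peak of the summed projection over a beat
cycle) is ``|E1 . n| + |E2 . n|``.  Because the solutions are linear in
the applied current, exposure maps for any current pair (I1, I2) are
obtained by scaling 1 mA-normalized solutions; the stimulation locus is
steered by changing the current ratio at a fixed current sum, moving
toward the pair with the smaller current.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .phantom import PARCEL_NAMES, Phantom, target_arc_coordinate
from .solver import FieldSolution

__all__ = [
    "TIExposure",
    "projected_envelope_amplitude",
    "projected_absolute_amplitude",
    "exposure_maps",
    "roi_summary",
    "steering_sweep",
    "peak_voxel",
    "parcel_masks",
]


def _check_unit(n: np.ndarray, tol: float = 1e-6) -> None:
    norms = np.linalg.norm(n, axis=-1)
    finite = np.isfinite(norms)
    if finite.any() and not np.allclose(norms[finite], 1.0, atol=tol):
        raise ValueError("orientation vectors must be unit norm")


def projected_envelope_amplitude(E1, E2, n) -> np.ndarray | float:
    """Envelope-modulation amplitude of the projected TI field (V/m).

    ``||(E1+E2).n| - |(E1-E2).n||``, algebraically equal to
    ``2 min(|E1.n|, |E2.n|)``.  Broadcasts over leading axes; the last
    axis holds the 3 vector components.
    """
    E1 = np.asarray(E1, dtype=float)
    E2 = np.asarray(E2, dtype=float)
    n = np.asarray(n, dtype=float)
    _check_unit(n)
    p1 = np.sum(E1 * n, axis=-1)
    p2 = np.sum(E2 * n, axis=-1)
    out = np.abs(np.abs(p1 + p2) - np.abs(p1 - p2))
    return float(out) if out.ndim == 0 else out


def projected_absolute_amplitude(E1, E2, n) -> np.ndarray | float:
    """Peak amplitude of the summed projected two-tone field over a beat
    cycle: ``|E1.n| + |E2.n|`` (V/m)."""
    E1 = np.asarray(E1, dtype=float)
    E2 = np.asarray(E2, dtype=float)
    n = np.asarray(n, dtype=float)
    _check_unit(n)
    out = np.abs(np.sum(E1 * n, axis=-1)) + np.abs(np.sum(E2 * n, axis=-1))
    return float(out) if out.ndim == 0 else out


@dataclass
class TIExposure:
    """Per-voxel TI exposure maps.

    ``eam`` is the projected envelope-modulation amplitude and ``eabs``
    the projected absolute amplitude, both V/m and NaN where undefined.
    Invariants: ``0 <= eam <= eabs`` everywhere; both scale linearly
    under joint scaling of the pair currents.
    """

    eam: np.ndarray
    eabs: np.ndarray
    currents_mA: tuple[float, float]
    mask: np.ndarray


def exposure_maps(
    sol1: FieldSolution,
    sol2: FieldSolution,
    I1_mA: float,
    I2_mA: float,
    phantom: Phantom,
) -> TIExposure:
    """Combine two 1 mA-normalized pair solutions into TI exposure maps.

    Raises
    ------
    ValueError
        Mismatched grids, missing orientation field, or negative currents.
    """
    if sol1.E.shape != sol2.E.shape or sol1.E.shape[:-1] != phantom.shape:
        raise ValueError("solutions and phantom are on different grids")
    if phantom.orientation is None:
        raise ValueError("phantom has no orientation field")
    if I1_mA < 0 or I2_mA < 0:
        raise ValueError("currents must be non-negative")

    n = phantom.orientation
    mask = (
        phantom.brain_mask()
        & np.isfinite(n).all(axis=-1)
        & np.isfinite(sol1.E).all(axis=-1)
        & np.isfinite(sol2.E).all(axis=-1)
    )
    eam = np.full(phantom.shape, np.nan)
    eabs = np.full(phantom.shape, np.nan)
    E1 = I1_mA * sol1.E[mask]
    E2 = I2_mA * sol2.E[mask]
    nv = n[mask]
    eam[mask] = projected_envelope_amplitude(E1, E2, nv)
    eabs[mask] = projected_absolute_amplitude(E1, E2, nv)
    return TIExposure(eam=eam, eabs=eabs, currents_mA=(I1_mA, I2_mA), mask=mask)


def peak_voxel(values: np.ndarray) -> tuple[int, int, int]:
    """Voxel index of the map maximum; ties break to the lowest linear
    index (deterministic)."""
    filled = np.where(np.isfinite(values), values, -np.inf)
    return tuple(np.unravel_index(int(np.argmax(filled)), values.shape))


def roi_summary(
    values: np.ndarray,
    roi_masks: Mapping[str, np.ndarray],
    normalization: str = "none",
    target_roi: str | None = None,
    subregion_rois: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Per-ROI voxel count, median and s.d. of a map, with normalization.

    Parameters
    ----------
    normalization : {"none", "to_target_median", "fraction_of_subregion_sum"}
        ``to_target_median`` divides every median by the target ROI median
        (the target then reports exactly 1); ``fraction_of_subregion_sum``
        divides each subregion median by the sum of subregion medians
        (fractions over the subregions sum to 1).
    """
    rows = []
    for name, mask in roi_masks.items():
        mask = np.asarray(mask, dtype=bool)
        vals = values[mask]
        vals = vals[np.isfinite(vals)]
        if vals.size == 0:
            raise ValueError(f"ROI {name!r} is empty on the map")
        rows.append(
            {
                "roi": name,
                "nvox": int(vals.size),
                "median": float(np.median(vals)),
                "sd": float(np.std(vals)),
            }
        )
    df = pd.DataFrame(rows)

    if normalization == "none":
        df["normalized"] = df["median"]
    elif normalization == "to_target_median":
        if target_roi is None or target_roi not in set(df["roi"]):
            raise ValueError("to_target_median requires a target_roi present in roi_masks")
        ref = float(df.loc[df["roi"] == target_roi, "median"].iloc[0])
        if ref == 0:
            raise ValueError("target ROI median is zero; cannot normalize")
        df["normalized"] = df["median"] / ref
    elif normalization == "fraction_of_subregion_sum":
        subs = list(subregion_rois) if subregion_rois is not None else list(df["roi"])
        total = float(df.loc[df["roi"].isin(subs), "median"].sum())
        if total == 0:
            raise ValueError("subregion medians sum to zero; cannot normalize")
        df["normalized"] = df["median"] / total
    else:
        raise ValueError(f"unknown normalization mode: {normalization!r}")
    df["normalization"] = normalization
    return df


def parcel_masks(phantom: Phantom) -> dict[str, np.ndarray]:
    """Ant/Mid/Post masks from the phantom's target parcellation."""
    if phantom.target_parcels is None:
        raise ValueError("phantom target is not parcellated")
    return {name: phantom.target_parcels == pid for pid, name in PARCEL_NAMES.items()}


def steering_sweep(
    sol1: FieldSolution,
    sol2: FieldSolution,
    ratios: Sequence[tuple[float, float]],
    phantom: Phantom,
    rois: Mapping[str, np.ndarray] | None = None,
) -> pd.DataFrame:
    """Current-ratio steering sweep over the target.

    For each current pair (I1, I2) — typically at fixed I1 + I2 — computes
    the target-subregion fractions of the envelope-modulation amplitude
    (``fraction_of_subregion_sum`` normalization) and the eam-weighted
    centroid along the target axis, expressed as arc length in mm from
    the anterior end.  Reducing one pair's current moves the centroid
    toward that pair's side of the target.
    """
    if rois is None:
        rois = parcel_masks(phantom)
    arc = target_arc_coordinate(phantom)
    tmask = phantom.target_mask()

    rows = []
    for I1, I2 in ratios:
        if I1 < 0 or I2 < 0:
            raise ValueError("steering ratios require non-negative currents")
        exp = exposure_maps(sol1, sol2, I1, I2, phantom)
        summary = roi_summary(exp.eam, rois, normalization="fraction_of_subregion_sum")
        row = {"I1_mA": I1, "I2_mA": I2}
        for _, r in summary.iterrows():
            row[f"frac_{r['roi']}"] = r["normalized"]
        sel = tmask & np.isfinite(exp.eam) & np.isfinite(arc)
        w = exp.eam[sel]
        if w.sum() > 0:
            row["centroid_mm"] = float(np.sum(w * arc[sel]) / w.sum())
        else:
            row["centroid_mm"] = np.nan
        rows.append(row)
    return pd.DataFrame(rows)
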