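"""Scalp electrode montages and rule-based placement.

Two electrically isolated electrode pairs carry sinusoidal currents at
nearby kHz frequencies f1 and f2; their interference produces an envelope
modulated at df = f1 - f2.  Electrode centers are placed on the scalp
surface by fractional-circumference rules: on a given axial plane the
half circumference H is measured from the nasion (the anterior point)
around the chosen hemisphere, and an electrode sits at
``fraction * H + offset`` of arc length.

The default rules reproduce the experimental layout: e1/e3 on the target
hemisphere at the nasion plane at 0.5H -/+ 2.5 cm (5 cm between centers)
paired with e2/e4 on the opposite hemisphere at an eyebrow-level plane at
0.2H - 1 cm and 0.7H + 1 cm (~16 cm between centers); pairs are (e1, e2)
and (e3, e4).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np

from .phantom import Phantom

__all__ = [
    "Electrode",
    "Montage",
    "place_electrode_pairs",
    "default_rule_spec",
    "symmetric_rule_spec",
    "arc_distance",
    "electrode_mask",
]


@dataclass(frozen=True)
class Electrode:
    """A scalp contact: center on the scalp surface, modeled as a
    spherical-cap patch of the given area."""

    label: str
    center: tuple[float, float, float]  # mm, world
    area_cm2: float = 2.25
    shape: str = "cap"

    @property
    def patch_radius_mm(self) -> float:
        return float(np.sqrt(self.area_cm2 / np.pi) * 10.0)


@dataclass
class Montage:
    """Two electrode pairs with per-pair currents (mA) and frequencies (kHz)."""

    electrodes: dict[str, Electrode]
    pairs: tuple[tuple[str, str], tuple[str, str]]
    currents_mA: tuple[float, float] = (1.0, 1.0)
    frequencies_khz: tuple[float, float] = (2.005, 2.0)

    def __post_init__(self) -> None:
        self.validate()

    @property
    def delta_f_khz(self) -> float:
        return self.frequencies_khz[0] - self.frequencies_khz[1]

    def validate(self) -> None:
        if len(self.pairs) != 2:
            raise ValueError("a montage has exactly two electrode pairs")
        for anode, cathode in self.pairs:
            for lbl in (anode, cathode):
                if lbl not in self.electrodes:
                    raise ValueError(f"pair references unknown electrode {lbl!r}")
        if any(i < 0 for i in self.currents_mA):
            raise ValueError("currents must be non-negative")
        if self.frequencies_khz[0] == self.frequencies_khz[1]:
            raise ValueError("the two carrier frequencies must differ")


def default_rule_spec(
    area_cm2: float = 2.25,
    nasion_plane_mm: float = 0.0,
    eyebrow_plane_mm: float = 20.0,
    target_side: str = "left",
) -> dict:
    """The experimental placement rules as a serializable rule spec."""
    other = "right" if target_side == "left" else "left"
    return {
        "planes": {"nasion": nasion_plane_mm, "eyebrow": eyebrow_plane_mm},
        "electrodes": {
            "e1": {"plane": "nasion", "side": target_side, "fraction": 0.5, "offset_cm": -2.5},
            "e3": {"plane": "nasion", "side": target_side, "fraction": 0.5, "offset_cm": 2.5},
            "e2": {"plane": "eyebrow", "side": other, "fraction": 0.2, "offset_cm": -1.0},
            "e4": {"plane": "eyebrow", "side": other, "fraction": 0.7, "offset_cm": 1.0},
        },
        "pairs": [["e1", "e2"], ["e3", "e4"]],
        "area_cm2": area_cm2,
    }


def symmetric_rule_spec(
    area_cm2: float = 2.25,
    near_offset_cm: float = 2.5,
    far_offset_cm: float = 6.0,
    target_side: str = "left",
) -> dict:
    """A montage mirror-symmetric about the anterior-posterior midplane.

    Both planes coincide with the nasion plane and the contralateral
    electrodes sit at 0.5H -/+ ``far_offset_cm``, so reflecting y -> -y
    maps pair 1 onto pair 2.  Used for steering experiments where the 1:1
    current ratio must land the envelope-modulation locus at the target
    midpoint by symmetry.
    """
    other = "right" if target_side == "left" else "left"
    return {
        "planes": {"nasion": 0.0},
        "electrodes": {
            "e1": {"plane": "nasion", "side": target_side, "fraction": 0.5, "offset_cm": -near_offset_cm},
            "e3": {"plane": "nasion", "side": target_side, "fraction": 0.5, "offset_cm": near_offset_cm},
            "e2": {"plane": "nasion", "side": other, "fraction": 0.5, "offset_cm": -far_offset_cm},
            "e4": {"plane": "nasion", "side": other, "fraction": 0.5, "offset_cm": far_offset_cm},
        },
        "pairs": [["e1", "e2"], ["e3", "e4"]],
        "area_cm2": area_cm2,
    }


def _plane_radius(phantom: Phantom, z_mm: float) -> float:
    R = phantom.outer_radius()
    if abs(z_mm) >= R:
        raise ValueError(f"plane z={z_mm} mm does not intersect the scalp (R={R:.1f} mm)")
    return float(np.sqrt(R**2 - z_mm**2))


def place_electrode_pairs(
    phantom: Phantom,
    rule_spec: Mapping | None = None,
    currents_mA: tuple[float, float] = (1.0, 1.0),
    frequencies_khz: tuple[float, float] = (2.005, 2.0),
) -> Montage:
    """Place four electrodes on the scalp by fractional-circumference rules.

    For each electrode the rule gives the cutting plane, the hemisphere,
    and the arc position ``fraction * H + offset_cm`` measured from the
    nasion along that hemisphere, where H is the half circumference of the
    scalp cross-section in that plane.

    Raises
    ------
    ValueError
        If an arc position falls outside [0, H] or a plane misses the scalp.
    """
    if rule_spec is None:
        rule_spec = default_rule_spec()
    planes = rule_spec["planes"]
    area = float(rule_spec.get("area_cm2", 2.25))

    electrodes: dict[str, Electrode] = {}
    for label, rule in rule_spec["electrodes"].items():
        z = float(planes[rule["plane"]])
        rho = _plane_radius(phantom, z)
        H = np.pi * rho  # half circumference of the cross-section circle
        s = float(rule["fraction"]) * H + float(rule["offset_cm"]) * 10.0
        if not 0.0 <= s <= H:
            raise ValueError(
                f"electrode {label!r}: arc position {s:.1f} mm outside [0, {H:.1f}] mm"
            )
        theta = s / rho  # angle from the nasion direction (+y)
        sign = -1.0 if rule["side"] == "left" else 1.0
        center = (sign * rho * np.sin(theta), rho * np.cos(theta), z)
        electrodes[label] = Electrode(label=label, center=center, area_cm2=area)

    pairs = tuple(tuple(p) for p in rule_spec["pairs"])
    return Montage(
        electrodes=electrodes,
        pairs=pairs,  # type: ignore[arg-type]
        currents_mA=tuple(currents_mA),
        frequencies_khz=tuple(frequencies_khz),
    )


def arc_distance(phantom: Phantom, montage: Montage, a: str, b: str) -> float:
    """Geodesic distance (mm) between two electrode centers.

    Electrodes in the same axial plane are measured along the plane's
    cross-section circle (the tape-measure arc used by the placement
    rules); otherwise along the great circle of the scalp sphere.
    """
    pa = np.asarray(montage.electrodes[a].center, dtype=float)
    pb = np.asarray(montage.electrodes[b].center, dtype=float)
    if np.isclose(pa[2], pb[2]):
        rho = _plane_radius(phantom, pa[2])
        ua, ub = pa[:2] / np.linalg.norm(pa[:2]), pb[:2] / np.linalg.norm(pb[:2])
        ang = np.arccos(np.clip(ua @ ub, -1.0, 1.0))
        return float(rho * ang)
    R = phantom.outer_radius()
    ua, ub = pa / np.linalg.norm(pa), pb / np.linalg.norm(pb)
    ang = np.arccos(np.clip(ua @ ub, -1.0, 1.0))
    return float(R * ang)


def electrode_mask(phantom: Phantom, electrode: Electrode) -> np.ndarray:
    """Voxels covered by an electrode patch: outer-surface scalp voxels
    within the spherical-cap radius of the electrode center."""
    labels = phantom.labels
    scalp_label = min(phantom.tissue_table)  # outermost shell has the lowest id
    scalp = labels == scalp_label

    # surface voxels: scalp voxels with a 6-neighbor in the background
    surface = np.zeros_like(scalp)
    bg = labels == 0
    for axis in range(3):
        for shift in (1, -1):
            surface |= scalp & np.roll(bg, shift, axis=axis)
    # voxels on the array boundary also face outward
    for axis in range(3):
        sl = [slice(None)] * 3
        for edge in (0, -1):
            sl[axis] = edge
            surface[tuple(sl)] |= scalp[tuple(sl)]

    centers = phantom.voxel_centers()
    d = np.linalg.norm(centers - np.asarray(electrode.center), axis=-1)
    mask = surface & (d <= electrode.patch_radius_mm)
    if not mask.any():
        raise ValueError(f"electrode {electrode.label!r} covers no scalp surface voxel")
    return mask
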