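"""Run configuration: the study conditions as serializable defaults.

The default configuration reproduces the study setup at desk scale: a
five-shell spherical head phantom with a curved deep target in the left
hemisphere, the fractional-circumference electrode montage, carrier
frequencies 2.005 / 2.000 kHz (5 Hz difference), and the named
stimulation conditions TI 1:1 (2 + 2 mA), TI 1:3 (1 + 3 mA) and sham
(0 + 0 mA).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import yaml

from .montage import default_rule_spec
from .phantom import DEFAULT_TISSUES

__all__ = [
    "TargetSpec",
    "PhantomConfig",
    "SolverConfig",
    "EphysConfig",
    "Condition",
    "RunConfig",
    "default_run_config",
]

#: Default shell outer radii (mm): scalp, skull, CSF, gray, white.
DEFAULT_RADII_MM = [80.0, 74.0, 68.0, 63.0, 56.0]

#: Default curved target centerline (mm, world; anterior end first) —
#: a banana-shaped deep structure in the left hemisphere with its long
#: axis along y.
DEFAULT_CENTERLINE_MM = [[-18.0, 24.0, 0.0], [-30.0, 0.0, 0.0], [-18.0, -24.0, 0.0]]


@dataclass
class TargetSpec:
    centerline_mm: list = field(default_factory=lambda: [list(p) for p in DEFAULT_CENTERLINE_MM])
    radius_mm: float = 6.0
    label: int = 6
    name: str = "target"


@dataclass
class PhantomConfig:
    radii_mm: list = field(default_factory=lambda: list(DEFAULT_RADII_MM))
    conductivities_S_per_m: list = field(
        default_factory=lambda: list(DEFAULT_TISSUES.values())
    )
    tissue_names: list = field(default_factory=lambda: list(DEFAULT_TISSUES))
    resolution_mm: float = 2.5
    target: TargetSpec = field(default_factory=TargetSpec)
    # projection direction n: radial is the proxy for the dominant cellular
    # axis (cortical pyramidal cells point radially; the deep target's
    # pyramidal axis is transverse to its long axis, i.e. close to radial
    # at its lateral position)
    brain_orientation_mode: str = "radial"
    target_orientation_mode: str = "radial"


@dataclass
class SolverConfig:
    tolerance: float = 1e-8
    max_iter: int = 50_000
    applied_voltage_V: float = 1.0
    # optional white-matter anisotropy; off by default on the sphere phantom
    anisotropic_tissues: list = field(default_factory=list)
    sigma_long_S_per_m: float | None = None
    sigma_trans_S_per_m: float | None = None


@dataclass
class EphysConfig:
    band: str = "ti"
    n_epochs: int = 25
    epoch_len_s: float = 1.0
    zero_phase: bool = True
    lp_cutoff_hz: float = 500.0
    ratio_mode: str = "depth"
    stat_mode: str = "half_difference"
    fs: float = 30_000.0
    noise_sd_mV: float = 0.0


@dataclass
class Condition:
    """A named stimulation condition: two pair currents and frequencies."""

    name: str
    currents_mA: list
    frequencies_khz: list = field(default_factory=lambda: [2.005, 2.0])

    def validate(self) -> None:
        if len(self.currents_mA) != 2 or any(i < 0 for i in self.currents_mA):
            raise ValueError(f"condition {self.name!r}: needs two non-negative currents")
        if len(self.frequencies_khz) != 2 or self.frequencies_khz[0] == self.frequencies_khz[1]:
            raise ValueError(f"condition {self.name!r}: needs two distinct frequencies")


@dataclass
class RunConfig:
    phantom: PhantomConfig = field(default_factory=PhantomConfig)
    montage_rules: dict = field(default_factory=default_rule_spec)
    conditions: list = field(
        default_factory=lambda: [
            Condition("TI_1to1", [2.0, 2.0]),
            Condition("TI_1to3", [1.0, 3.0]),
            Condition("sham", [0.0, 0.0]),
        ]
    )
    steering_ratios: list = field(
        default_factory=lambda: [
            [3.0, 1.0],
            [8.0 / 3.0, 4.0 / 3.0],
            [2.0, 2.0],
            [4.0 / 3.0, 8.0 / 3.0],
            [1.0, 3.0],
        ]
    )
    solver: SolverConfig = field(default_factory=SolverConfig)
    ephys: EphysConfig = field(default_factory=EphysConfig)
    seed: int = 0

    # -- validation ------------------------------------------------------
    def validate(self) -> None:
        """Reject invalid conditions and montage rules before any compute."""
        p = self.phantom
        if p.resolution_mm <= 0:
            raise ValueError("resolution must be positive")
        if len(p.radii_mm) != len(p.conductivities_S_per_m):
            raise ValueError("radii and conductivities must have equal length")
        for c in self.conditions:
            c.validate()
        R = float(p.radii_mm[0])
        for label, rule in self.montage_rules["electrodes"].items():
            z = float(self.montage_rules["planes"][rule["plane"]])
            if abs(z) >= R:
                raise ValueError(f"electrode {label!r}: plane misses the scalp")
            rho = np.sqrt(R**2 - z**2)
            H = np.pi * rho
            s = rule["fraction"] * H + rule["offset_cm"] * 10.0
            if not 0 <= s <= H:
                raise ValueError(
                    f"electrode {label!r}: offset exceeds the half circumference"
                )

    # -- serialization ---------------------------------------------------
    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, doc: dict) -> "RunConfig":
        doc = dict(doc)
        phantom = doc.get("phantom", {})
        if isinstance(phantom, dict):
            phantom = dict(phantom)
            target = phantom.get("target", {})
            if isinstance(target, dict):
                phantom["target"] = TargetSpec(**target)
            doc["phantom"] = PhantomConfig(**phantom)
        if isinstance(doc.get("solver"), dict):
            doc["solver"] = SolverConfig(**doc["solver"])
        if isinstance(doc.get("ephys"), dict):
            doc["ephys"] = EphysConfig(**doc["ephys"])
        doc["conditions"] = [
            Condition(**c) if isinstance(c, dict) else c for c in doc.get("conditions", [])
        ]
        return cls(**doc)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def default_run_config(**overrides) -> RunConfig:
    cfg = RunConfig()
    for k, v in overrides.items():
        setattr(cfg, k, v)
    return cfg
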