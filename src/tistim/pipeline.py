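"""End-to-end pipeline driver.

Ties together phantom generation, per-pair field solving, TI exposure /
steering analysis, and the synthetic-recording envelope analysis.  Each
electrode pair is solved once at 1 V, normalized to 1 mA, and rescaled
per condition (exact by linearity of the quasistatic problem), so no
re-solve is needed across conditions or steering ratios.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .config import RunConfig
from .envelope import analyze_recording
from .exposure import exposure_maps, parcel_masks, roi_summary, steering_sweep
from .io import save_montage, save_phantom, save_recording, save_solution
from .montage import Montage, place_electrode_pairs
from .phantom import (
    Phantom,
    embed_target,
    make_layered_sphere_phantom,
    make_orientation_field,
    parcellate_target,
)
from .recordings import synth_recording
from .solver import (
    build_conductivity_tensors,
    normalize_to_current,
    solve_montage_pair,
)

__all__ = [
    "build_phantom",
    "build_montage",
    "cortical_rois",
    "depth_electrode_track",
    "current_density",
    "run_pipeline",
]

log = logging.getLogger("tistim")


def current_density(current_mA: float, contact_area_cm2: float) -> float:
    """Electrode current density, mA/cm^2 (e.g. 1 mA on a 2.25 cm^2 pad
    gives ~0.45 mA/cm^2; 2 mA gives ~0.9)."""
    if contact_area_cm2 <= 0:
        raise ValueError("contact area must be positive")
    return current_mA / contact_area_cm2


def build_phantom(config: RunConfig) -> Phantom:
    """Default study phantom: layered sphere, embedded parcellated target,
    radial brain orientation with tangential target orientation."""
    p = config.phantom
    phantom = make_layered_sphere_phantom(
        p.radii_mm, p.conductivities_S_per_m, p.resolution_mm, names=p.tissue_names
    )
    phantom = embed_target(
        phantom,
        p.target.centerline_mm,
        p.target.radius_mm,
        p.target.label,
        name=p.target.name,
    )
    phantom = parcellate_target(phantom)
    phantom = make_orientation_field(phantom, p.brain_orientation_mode, vector=(0, 1, 0))
    if p.target_orientation_mode != p.brain_orientation_mode:
        phantom = make_orientation_field(phantom, p.target_orientation_mode, where="target")
    phantom.validate()
    return phantom


def build_montage(phantom: Phantom, config: RunConfig) -> Montage:
    cond = config.conditions[0] if config.conditions else None
    freqs = tuple(cond.frequencies_khz) if cond else (2.005, 2.0)
    return place_electrode_pairs(phantom, config.montage_rules, frequencies_khz=freqs)


def cortical_rois(
    phantom: Phantom, montage: Montage, radius_mm: float = 10.0
) -> dict[str, np.ndarray]:
    """Spherical gray-matter ROIs in the cortex overlying the target.

    Centers sit at mid-gray depth beneath the two target-side electrodes
    (anterior/posterior) and beneath the scalp point midway between them,
    mirroring the Crtx Ant / Crtx Mid / Crtx Post regions.
    """
    by_name = phantom.labels_by_name()
    if "gray" not in by_name:
        raise ValueError("phantom has no gray-matter shell")
    gray = phantom.labels == by_name["gray"]
    radii = phantom.meta.get("radii")
    if radii is None or len(radii) < 2:
        raise ValueError("cortical ROIs require a layered-sphere phantom")
    gray_outer = radii[by_name["gray"] - 1]
    gray_inner = radii[by_name["gray"]] if len(radii) > by_name["gray"] else 0.0
    r_mid = 0.5 * (gray_outer + gray_inner)

    (a1, _), (a3, _) = montage.pairs
    e1 = np.asarray(montage.electrodes[a1].center, dtype=float)
    e3 = np.asarray(montage.electrodes[a3].center, dtype=float)
    mid = e1 + e3
    dirs = {
        "Crtx_Ant": e1 / np.linalg.norm(e1),
        "Crtx_Mid": mid / np.linalg.norm(mid),
        "Crtx_Post": e3 / np.linalg.norm(e3),
    }
    centers = phantom.voxel_centers()
    rois = {}
    for name, u in dirs.items():
        c = u * r_mid
        d = np.linalg.norm(centers - c, axis=-1)
        mask = gray & (d <= radius_mm)
        if not mask.any():
            raise ValueError(f"cortical ROI {name} is empty; check montage geometry")
        rois[name] = mask
    return rois


def depth_electrode_track(
    phantom: Phantom,
    n_contacts: int = 15,
    spacing_mm: float = 3.5,
    first_depth_mm: float = 2.0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """A simulated sEEG shaft: entry at the left scalp surface aimed at the
    target centerline midpoint, perpendicular to the target long axis.

    Returns ``(positions_mm, depths_mm, shaft_direction)``.
    """
    if phantom.target_centerline is None:
        raise ValueError("phantom has no target centerline")
    cl = np.asarray(phantom.target_centerline, dtype=float)
    aim = cl[len(cl) // 2]
    R = phantom.outer_radius()
    entry = np.array([-R, aim[1], aim[2]])
    direction = aim - entry
    direction = direction / np.linalg.norm(direction)
    depths = first_depth_mm + spacing_mm * np.arange(n_contacts)
    positions = entry[None, :] + depths[:, None] * direction[None, :]
    return positions, depths, direction


def _sample_at(values: np.ndarray, phantom: Phantom, points: np.ndarray) -> np.ndarray:
    idx = phantom.world_to_index(points)
    idx = np.clip(idx, 0, np.asarray(phantom.shape) - 1)
    return values[idx[:, 0], idx[:, 1], idx[:, 2]]


def run_pipeline(config: RunConfig, out_dir) -> dict:
    """Run the full analysis and write all artifacts plus a manifest.

    Stages: phantom build -> montage -> two 1 mA pair solves -> exposure
    maps and ROI summaries per condition -> steering sweep -> synthetic
    depth-electrode recording and its envelope analysis.  All randomness
    flows from ``config.seed``; a re-run writes byte-identical CSV/JSON.
    """
    config.validate()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "stages": {},
        "files": {},
    }

    def stage(name):
        log.info("stage %s", name)
        manifest["stages"][name] = "ok"

    try:
        stage("phantom")
        phantom = build_phantom(config)
        manifest["files"]["phantom"] = save_phantom(phantom, out / "phantom")
        manifest["phantom_voxels"] = int(phantom.conducting_mask().sum())
        manifest["target_voxels"] = int(phantom.target_mask().sum())

        stage("montage")
        montage = build_montage(phantom, config)
        save_montage(montage, out / "montage.yaml")
        manifest["files"]["montage"] = "montage.yaml"

        stage("solve")
        tensors = build_conductivity_tensors(
            phantom,
            sigma_long=config.solver.sigma_long_S_per_m,
            sigma_trans=config.solver.sigma_trans_S_per_m,
            anisotropic_labels=[
                phantom.labels_by_name()[n] for n in config.solver.anisotropic_tissues
            ]
            or None,
        )
        solutions = []
        for k in range(2):
            sol = solve_montage_pair(
                phantom,
                tensors,
                montage,
                k,
                applied_voltage=config.solver.applied_voltage_V,
                tolerance=config.solver.tolerance,
                max_iter=config.solver.max_iter,
            )
            sol = normalize_to_current(sol, 1.0)  # 1 mA reference per pair
            solutions.append(sol)
            manifest["files"][f"solution_pair{k + 1}"] = save_solution(
                sol, out / "fields", phantom, f"pair{k + 1}_1mA"
            )

        stage("exposure")
        rois = {"Target": phantom.target_mask(), **cortical_rois(phantom, montage)}
        parcels = parcel_masks(phantom)
        from .io import save_nifti  # local import to keep module deps one-way

        for cond in config.conditions:
            I1, I2 = cond.currents_mA
            exp = exposure_maps(solutions[0], solutions[1], I1, I2, phantom)
            save_nifti(out / f"eam_{cond.name}.nii.gz", exp.eam.astype(np.float32), phantom)
            save_nifti(out / f"eabs_{cond.name}.nii.gz", exp.eabs.astype(np.float32), phantom)
            if I1 > 0 or I2 > 0:
                df = roi_summary(
                    exp.eam, rois, normalization="to_target_median", target_roi="Target"
                )
                df_abs = roi_summary(
                    exp.eabs, rois, normalization="to_target_median", target_roi="Target"
                )
                dfp = roi_summary(
                    exp.eam, parcels, normalization="fraction_of_subregion_sum"
                )
                df.to_csv(out / f"roi_eam_{cond.name}.csv", index=False)
                df_abs.to_csv(out / f"roi_eabs_{cond.name}.csv", index=False)
                dfp.to_csv(out / f"parcel_eam_{cond.name}.csv", index=False)
                target_med = float(df.loc[df["roi"] == "Target", "median"].iloc[0])
                crtx_med = float(
                    df.loc[df["roi"] != "Target", "median"].max()
                )
                if target_med <= crtx_med:
                    log.warning(
                        "condition %s: target eam median does not exceed cortex",
                        cond.name,
                    )
            manifest["files"][f"eam_{cond.name}"] = f"eam_{cond.name}.nii.gz"
            manifest["files"][f"eabs_{cond.name}"] = f"eabs_{cond.name}.nii.gz"

        stage("steering")
        sweep = steering_sweep(
            solutions[0], solutions[1], [tuple(r) for r in config.steering_ratios], phantom
        )
        sweep.to_csv(out / "steering.csv", index=False)
        manifest["files"]["steering"] = "steering.csv"

        stage("recording")
        positions, depths, shaft = depth_electrode_track(phantom)
        f1 = config.conditions[0].frequencies_khz[0] * 1e3
        f2 = config.conditions[0].frequencies_khz[1] * 1e3
        I1, I2 = config.conditions[0].currents_mA
        # the contacts record the local potential of each pair's field (mV)
        a1 = _sample_at(solutions[0].phi, phantom, positions) * I1 * 1e3
        a2 = _sample_at(solutions[1].phi, phantom, positions) * I2 * 1e3
        a1 = np.nan_to_num(a1)
        a2 = np.nan_to_num(a2)
        rec = synth_recording(
            depths,
            a1,
            a2,
            f1_hz=f1,
            f2_hz=f2,
            fs=config.ephys.fs,
            duration_s=config.ephys.n_epochs * config.ephys.epoch_len_s,
            noise_sd_mV=config.ephys.noise_sd_mV,
            seed=config.seed,
        )
        save_recording(rec, out / "recording.h5")
        metrics, mod_prof, abs_prof = analyze_recording(
            rec,
            band=config.ephys.band,
            zero_phase=config.ephys.zero_phase,
            lp_cutoff_hz=config.ephys.lp_cutoff_hz,
            epoch_len_s=config.ephys.epoch_len_s,
            n_epochs=config.ephys.n_epochs,
            ratio_mode=config.ephys.ratio_mode,
            stat_mode=config.ephys.stat_mode,
        )
        metrics.to_frame().to_csv(out / "contacts.csv", index=False)
        mod_prof.to_csv(out / "field_profile_modulation.csv", index=False)
        abs_prof.to_csv(out / "field_profile_absolute.csv", index=False)
        manifest["files"]["recording"] = "recording.h5"
        manifest["files"]["contacts"] = "contacts.csv"

        manifest["residuals"] = [s.residual for s in solutions]
        manifest["injected_current_mA"] = [s.injected_current_mA for s in solutions]
    except Exception as err:  # annotate failures with the failing stage
        last = list(manifest["stages"])[-1] if manifest["stages"] else "setup"
        manifest["stages"][last] = f"failed: {err}"
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
        raise RuntimeError(f"pipeline stage {last!r} failed: {err}") from err

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
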