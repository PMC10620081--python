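"""File formats: NIfTI volumes, YAML configs/montages, HDF5/CSV recordings.

Label volumes, parcellations, orientation fields (4D, 3 components),
potentials and exposure maps travel as NIfTI with a diagonal mm affine.
Phantom metadata that NIfTI cannot hold (tissue table, centerline) goes
in a YAML sidecar.  Recordings are HDF5 (contacts x samples, attributes
for fs) or CSV with a header comment.
"""

from __future__ import annotations

import os
from pathlib import Path

import h5py
import nibabel as nib
import numpy as np
import yaml

from .montage import Electrode, Montage
from .phantom import Phantom, Tissue
from .recordings import Recording
from .solver import FieldSolution

__all__ = [
    "save_nifti",
    "load_nifti",
    "save_phantom",
    "load_phantom",
    "save_montage",
    "load_montage",
    "save_recording",
    "load_recording",
    "save_solution",
]


def _affine(phantom_or_spacing, origin=None) -> np.ndarray:
    if isinstance(phantom_or_spacing, Phantom):
        spacing = phantom_or_spacing.spacing
        origin = phantom_or_spacing.origin
    else:
        spacing = phantom_or_spacing
        origin = np.zeros(3) if origin is None else origin
    aff = np.eye(4)
    aff[:3, :3] = np.diag(spacing)
    aff[:3, 3] = origin
    return aff


def save_nifti(path, data: np.ndarray, phantom: Phantom | None = None, spacing=None):
    aff = _affine(phantom) if phantom is not None else _affine(spacing or (1, 1, 1))
    img = nib.Nifti1Image(np.asarray(data), aff)
    nib.save(img, os.fspath(path))


def load_nifti(path) -> tuple[np.ndarray, np.ndarray]:
    img = nib.load(os.fspath(path))
    return np.asarray(img.dataobj), img.affine


def save_phantom(phantom: Phantom, out_dir) -> dict[str, str]:
    """Write labels / parcels / orientation NIfTIs plus a YAML sidecar.
    Returns the file manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    files = {}
    save_nifti(out / "labels.nii.gz", phantom.labels.astype(np.int16), phantom)
    files["labels"] = "labels.nii.gz"
    if phantom.target_parcels is not None:
        save_nifti(out / "parcels.nii.gz", phantom.target_parcels.astype(np.int16), phantom)
        files["parcels"] = "parcels.nii.gz"
    if phantom.orientation is not None:
        save_nifti(out / "orientation.nii.gz", phantom.orientation.astype(np.float32), phantom)
        files["orientation"] = "orientation.nii.gz"
    sidecar = {
        "spacing_mm": list(map(float, phantom.spacing)),
        "origin_mm": [float(v) for v in phantom.origin],
        "tissue_table": {
            int(k): {"name": t.name, "sigma_S_per_m": float(t.sigma)}
            for k, t in phantom.tissue_table.items()
        },
        "target_label": phantom.target_label,
        "target_centerline_mm": None
        if phantom.target_centerline is None
        else np.asarray(phantom.target_centerline).tolist(),
        "meta": phantom.meta,
    }
    with open(out / "phantom.yaml", "w") as fh:
        yaml.safe_dump(sidecar, fh, sort_keys=True)
    files["sidecar"] = "phantom.yaml"
    return files


def load_phantom(out_dir) -> Phantom:
    out = Path(out_dir)
    with open(out / "phantom.yaml") as fh:
        sidecar = yaml.safe_load(fh)
    labels, _ = load_nifti(out / "labels.nii.gz")
    table = {
        int(k): Tissue(v["name"], float(v["sigma_S_per_m"]))
        for k, v in sidecar["tissue_table"].items()
    }
    phantom = Phantom(
        labels=np.asarray(labels, dtype=np.int16),
        spacing=tuple(sidecar["spacing_mm"]),
        tissue_table=table,
        origin=np.asarray(sidecar["origin_mm"], dtype=float),
        target_label=sidecar.get("target_label"),
        target_centerline=None
        if sidecar.get("target_centerline_mm") is None
        else np.asarray(sidecar["target_centerline_mm"], dtype=float),
        meta=sidecar.get("meta", {}),
    )
    if (out / "parcels.nii.gz").exists():
        parcels, _ = load_nifti(out / "parcels.nii.gz")
        phantom.target_parcels = np.asarray(parcels, dtype=np.int8)
    if (out / "orientation.nii.gz").exists():
        orient, _ = load_nifti(out / "orientation.nii.gz")
        phantom.orientation = np.asarray(orient, dtype=float)
    return phantom


def save_montage(montage: Montage, path) -> None:
    doc = {
        "electrodes": {
            lbl: {
                "center_mm": [float(c) for c in e.center],
                "area_cm2": float(e.area_cm2),
            }
            for lbl, e in montage.electrodes.items()
        },
        "pairs": [list(p) for p in montage.pairs],
        "currents_mA": [float(i) for i in montage.currents_mA],
        "frequencies_khz": [float(f) for f in montage.frequencies_khz],
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=True)


def load_montage(path) -> Montage:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    electrodes = {
        lbl: Electrode(label=lbl, center=tuple(e["center_mm"]), area_cm2=e["area_cm2"])
        for lbl, e in doc["electrodes"].items()
    }
    return Montage(
        electrodes=electrodes,
        pairs=tuple(tuple(p) for p in doc["pairs"]),
        currents_mA=tuple(doc["currents_mA"]),
        frequencies_khz=tuple(doc["frequencies_khz"]),
    )


def save_recording(recording: Recording, path) -> None:
    """HDF5 when the suffix is .h5/.hdf5, else CSV (contacts x samples)."""
    path = Path(path)
    if path.suffix in {".h5", ".hdf5"}:
        with h5py.File(path, "w") as fh:
            fh.create_dataset("data_mV", data=recording.data)
            fh.create_dataset("contact_depths_mm", data=recording.contact_depths_mm)
            fh.attrs["fs"] = recording.fs
            for k, v in recording.meta.items():
                if v is not None and not isinstance(v, (list, dict)):
                    fh.attrs[k] = v
    else:
        header = f"fs={recording.fs}"
        depths = ",".join(repr(float(d)) for d in recording.contact_depths_mm)
        with open(path, "w") as fh:
            fh.write(f"# {header}\n# depths_mm={depths}\n")
            np.savetxt(fh, recording.data, delimiter=",")


def load_recording(path) -> Recording:
    path = Path(path)
    if path.suffix in {".h5", ".hdf5"}:
        with h5py.File(path, "r") as fh:
            return Recording(
                data=fh["data_mV"][()],
                fs=float(fh.attrs["fs"]),
                contact_depths_mm=fh["contact_depths_mm"][()],
            )
    with open(path) as fh:
        line1 = fh.readline().strip()
        line2 = fh.readline().strip()
        fs = float(line1.split("fs=")[1])
        depths = np.asarray(
            [float(v) for v in line2.split("depths_mm=")[1].split(",")]
        )
        data = np.loadtxt(fh, delimiter=",")
    return Recording(data=np.atleast_2d(data), fs=fs, contact_depths_mm=depths)


def save_solution(solution: FieldSolution, out_dir, phantom: Phantom, stem: str) -> dict:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    save_nifti(out / f"{stem}_phi.nii.gz", solution.phi.astype(np.float32), phantom)
    save_nifti(out / f"{stem}_E.nii.gz", solution.E.astype(np.float32), phantom)
    return {
        "phi": f"{stem}_phi.nii.gz",
        "E": f"{stem}_E.nii.gz",
        "pair_id": solution.pair_id,
        "residual": solution.residual,
        "injected_current_mA": solution.injected_current_mA,
    }
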