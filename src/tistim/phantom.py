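"""Synthetic voxel head phantoms.

A :class:`Phantom` is a labeled voxel volume with a tissue conductivity
table, an optional per-voxel unit orientation field (the local principal
structure direction ``n`` along which fields are projected), and an
optional parcellation of an embedded deep target into anterior / middle /
posterior thirds.

The stand-in anatomy is a set of concentric spherical shells
(scalp / skull / CSF / gray / white from the outside in) with a curved
tubular deep target embedded in the brain compartment.  World coordinates
are in mm, right-handed, with the sphere centered at the origin; by
convention the target's long axis runs along y and its anterior end is
the +y end (the first centerline vertex).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

__all__ = [
    "Tissue",
    "Phantom",
    "PARCEL_NAMES",
    "DEFAULT_TISSUES",
    "make_layered_sphere_phantom",
    "embed_target",
    "parcellate_target",
    "make_orientation_field",
    "target_arc_coordinate",
    "connected_components",
]

#: Parcel ids for the target thirds along its long axis.
PARCEL_NAMES = {1: "Ant", 2: "Mid", 3: "Post"}

#: Default five-tissue conductivity table, S/m (configuration defaults from
#: a meta-analysis of reported human head conductivities; the target is
#: assigned the gray-matter value).
DEFAULT_TISSUES = {
    "scalp": 0.4,
    "skull": 0.008,
    "csf": 1.79,
    "gray": 0.28,
    "white": 0.13,
}


@dataclass(frozen=True)
class Tissue:
    """Tissue class: display name and scalar conductivity in S/m."""

    name: str
    sigma: float


@dataclass
class Phantom:
    """Voxel label volume plus tissue table and optional derived fields.

    Attributes
    ----------
    labels : (nx, ny, nz) int array
        Tissue id per voxel; 0 is non-conducting background.
    spacing : (3,) float
        Voxel edge length per axis, mm.
    tissue_table : dict[int, Tissue]
        Tissue id -> name + conductivity (S/m).  Every nonzero label must
        have an entry with positive conductivity.
    origin : (3,) float
        World coordinate (mm) of the center of voxel (0, 0, 0).
    orientation : (nx, ny, nz, 3) float array or None
        Unit direction per voxel, NaN where undefined.
    target_parcels : int array or None
        Parcel id per voxel (0 none, 1 Ant, 2 Mid, 3 Post).
    target_label : int or None
        Label of the embedded deep target.
    target_centerline : (k, 3) float array or None
        Control polyline (mm, world) used to embed the target; the first
        vertex is the anterior end.
    meta : dict
        Free-form provenance (e.g. shell radii for sphere phantoms).
    """

    labels: np.ndarray
    spacing: tuple[float, float, float]
    tissue_table: dict[int, Tissue]
    origin: np.ndarray
    orientation: np.ndarray | None = None
    target_parcels: np.ndarray | None = None
    target_label: int | None = None
    target_centerline: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    # -- basic geometry --------------------------------------------------
    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape

    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    def voxel_centers(self) -> np.ndarray:
        """World coordinates (mm) of every voxel center, shape (*shape, 3)."""
        axes = [
            self.origin[a] + np.arange(self.shape[a]) * self.spacing[a]
            for a in range(3)
        ]
        grid = np.meshgrid(*axes, indexing="ij")
        return np.stack(grid, axis=-1)

    def world_to_index(self, points: np.ndarray) -> np.ndarray:
        """Nearest voxel index for world points (mm)."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        idx = np.rint((pts - self.origin) / np.asarray(self.spacing)).astype(int)
        return idx

    # -- masks -----------------------------------------------------------
    def conducting_mask(self) -> np.ndarray:
        return self.labels > 0

    def labels_by_name(self) -> dict[str, int]:
        return {t.name: lid for lid, t in self.tissue_table.items()}

    def brain_labels(self) -> set[int]:
        """Labels counted as brain: gray, white and the target if present."""
        by_name = self.labels_by_name()
        out = {by_name[n] for n in ("gray", "white") if n in by_name}
        if not out:
            # single-compartment phantoms: treat the innermost label as brain
            out = {max(self.tissue_table)}
        if self.target_label is not None:
            out.add(self.target_label)
        return out

    def brain_mask(self) -> np.ndarray:
        return np.isin(self.labels, sorted(self.brain_labels()))

    def target_mask(self) -> np.ndarray:
        if self.target_label is None:
            raise ValueError("phantom has no embedded target")
        return self.labels == self.target_label

    def sigma_map(self) -> np.ndarray:
        """Scalar conductivity per voxel (S/m), 0 in background."""
        sig = np.zeros(self.shape, dtype=float)
        for lid, tissue in self.tissue_table.items():
            sig[self.labels == lid] = tissue.sigma
        return sig

    def outer_radius(self) -> float:
        """Radius (mm) of the outer (scalp) surface about the world origin."""
        if "radii" in self.meta:
            return float(self.meta["radii"][0])
        centers = self.voxel_centers()[self.conducting_mask()]
        return float(np.linalg.norm(centers, axis=1).max())

    # -- validation ------------------------------------------------------
    def validate(self) -> None:
        """Check the structural invariants; raise ``ValueError`` on failure."""
        present = set(np.unique(self.labels)) - {0}
        missing = present - set(self.tissue_table)
        if missing:
            raise ValueError(f"labels without tissue table entry: {missing}")
        for lid, tissue in self.tissue_table.items():
            if not tissue.sigma > 0:
                raise ValueError(f"non-positive conductivity for label {lid}")
        if self.orientation is not None:
            norms = np.linalg.norm(self.orientation, axis=-1)
            defined = np.isfinite(norms)
            if defined.any() and not np.allclose(norms[defined], 1.0, atol=1e-9):
                raise ValueError("orientation vectors are not unit norm")
        if self.target_parcels is not None:
            tmask = self.target_mask()
            pmask = self.target_parcels > 0
            if not np.array_equal(tmask, pmask):
                raise ValueError("target parcels do not partition the target")


def _sample_polyline(points: np.ndarray, step: float) -> tuple[np.ndarray, np.ndarray]:
    """Densely resample a polyline; returns (samples, arc-length per sample)."""
    pts = np.asarray(points, dtype=float)
    seg = np.diff(pts, axis=0)
    seg_len = np.linalg.norm(seg, axis=1)
    if np.any(seg_len == 0):
        raise ValueError("centerline has coincident consecutive points")
    cum = np.concatenate([[0.0], np.cumsum(seg_len)])
    total = cum[-1]
    n = max(int(np.ceil(total / step)) + 1, 2)
    s = np.linspace(0.0, total, n)
    samples = np.empty((n, 3))
    for a in range(3):
        samples[:, a] = np.interp(s, cum, pts[:, a])
    return samples, s


def make_layered_sphere_phantom(
    radii: Sequence[float],
    conductivities: Sequence[float],
    resolution: float,
    names: Sequence[str] | None = None,
) -> Phantom:
    """Build a phantom of concentric spherical shells.

    Parameters
    ----------
    radii : sequence of float
        Outer radius of each shell in mm, strictly decreasing (outermost
        first).  Voxels outside ``radii[0]`` are background (label 0).
    conductivities : sequence of float
        Conductivity (S/m) per shell, same length/order as ``radii``.
    resolution : float
        Isotropic voxel size, mm.
    names : sequence of str, optional
        Tissue names per shell.  Defaults to the five standard head
        tissues when five shells are given, else ``shell1..shellN``.
    """
    radii = [float(r) for r in radii]
    conductivities = [float(s) for s in conductivities]
    if resolution <= 0:
        raise ValueError("resolution must be positive")
    if len(radii) != len(conductivities):
        raise ValueError("radii and conductivities must have equal length")
    if any(r <= 0 for r in radii):
        raise ValueError("radii must be positive")
    if any(b >= a for a, b in zip(radii, radii[1:])):
        raise ValueError("radii must be strictly decreasing (outer to inner)")
    if any(s <= 0 for s in conductivities):
        raise ValueError("conductivities must be positive")

    if names is None:
        if len(radii) == len(DEFAULT_TISSUES):
            names = list(DEFAULT_TISSUES)
        else:
            names = [f"shell{i + 1}" for i in range(len(radii))]

    half = int(np.ceil(radii[0] / resolution)) + 1
    n = 2 * half + 1  # odd: the sphere center falls on a voxel center
    spacing = (resolution,) * 3
    origin = -np.array([half, half, half]) * resolution

    ax = origin[0] + np.arange(n) * resolution
    xx, yy, zz = np.meshgrid(ax, ax, ax, indexing="ij")
    r = np.sqrt(xx**2 + yy**2 + zz**2)

    labels = np.zeros((n, n, n), dtype=np.int16)
    for k, radius in enumerate(radii, start=1):  # outer -> inner overwrites
        labels[r <= radius] = k
    table = {
        k: Tissue(name, sigma)
        for k, (name, sigma) in enumerate(zip(names, conductivities), start=1)
    }
    return Phantom(
        labels=labels,
        spacing=spacing,
        tissue_table=table,
        origin=origin,
        meta={"radii": radii},
    )


def embed_target(
    phantom: Phantom,
    centerline: Sequence[Sequence[float]],
    radius: float,
    label: int,
    name: str = "target",
    sigma: float | None = None,
    brain_labels: set[int] | None = None,
) -> Phantom:
    """Embed a tubular deep target around a centerline polyline.

    The tube (no spherical end caps: voxels whose nearest centerline point
    is an endpoint are excluded, so the voxel count tracks the analytic
    cylinder volume) overwrites brain labels only.  The first centerline
    vertex is taken as the anterior end.

    Raises
    ------
    ValueError
        If the centerline has fewer than two points, exits the brain
        compartment, or the label already exists.
    """
    pts = np.asarray(centerline, dtype=float)
    if pts.ndim != 2 or pts.shape[0] < 2 or pts.shape[1] != 3:
        raise ValueError("centerline must contain at least two 3D points")
    if radius <= 0:
        raise ValueError("target radius must be positive")
    if label in phantom.tissue_table:
        raise ValueError(f"label {label} already present in tissue table")

    if brain_labels is None:
        brain_labels = phantom.brain_labels()
    brain = np.isin(phantom.labels, sorted(brain_labels))

    step = min(phantom.spacing) / 2.0
    samples, _ = _sample_polyline(pts, step)

    # bounds + brain membership for every densified centerline point
    idx = phantom.world_to_index(samples)
    if np.any(idx < 0) or np.any(idx >= np.array(phantom.shape)):
        raise ValueError("centerline exits the phantom volume")
    if not brain[idx[:, 0], idx[:, 1], idx[:, 2]].all():
        raise ValueError("centerline exits the brain compartment")

    centers = phantom.voxel_centers()
    lo = samples.min(axis=0) - radius - max(phantom.spacing)
    hi = samples.max(axis=0) + radius + max(phantom.spacing)
    box = np.all((centers >= lo) & (centers <= hi), axis=-1)
    box_idx = np.argwhere(box)
    box_pts = centers[box]

    tree = cKDTree(samples)
    dist, nearest = tree.query(box_pts, workers=-1)
    interior = (nearest > 0) & (nearest < len(samples) - 1)
    hit = (dist <= radius) & interior

    labels = phantom.labels.copy()
    sel = box_idx[hit]
    in_brain = brain[sel[:, 0], sel[:, 1], sel[:, 2]]
    sel = sel[in_brain]
    labels[sel[:, 0], sel[:, 1], sel[:, 2]] = label

    if sigma is None:
        by_name = phantom.labels_by_name()
        sigma = (
            phantom.tissue_table[by_name["gray"]].sigma
            if "gray" in by_name
            else next(iter(phantom.tissue_table.values())).sigma
        )
    table = dict(phantom.tissue_table)
    table[label] = Tissue(name, float(sigma))
    return replace(
        phantom,
        labels=labels,
        tissue_table=table,
        target_label=label,
        target_centerline=pts,
        target_parcels=None,
    )


def parcellate_target(phantom: Phantom, label: int | None = None) -> Phantom:
    """Split the target into Ant/Mid/Post arc-length thirds.

    Each target voxel is assigned the third of the centerline (by arc
    length from the anterior end) containing its nearest centerline point.
    Parcels are disjoint and cover the target exactly.
    """
    if label is None:
        label = phantom.target_label
    if label is None or not np.any(phantom.labels == label):
        raise ValueError("target label absent from phantom")
    if phantom.target_centerline is None:
        raise ValueError("phantom does not record a target centerline")

    step = min(phantom.spacing) / 2.0
    samples, s = _sample_polyline(phantom.target_centerline, step)
    total = s[-1]

    tmask = phantom.labels == label
    centers = phantom.voxel_centers()[tmask]
    tree = cKDTree(samples)
    _, nearest = tree.query(centers, workers=-1)
    arc = s[nearest]
    parcel = np.where(arc < total / 3.0, 1, np.where(arc < 2.0 * total / 3.0, 2, 3))

    parcels = np.zeros(phantom.shape, dtype=np.int8)
    parcels[tmask] = parcel
    return replace(phantom, target_parcels=parcels)


def target_arc_coordinate(phantom: Phantom) -> np.ndarray:
    """Arc-length coordinate (mm from the anterior end) of each target voxel,
    as a full-grid array (NaN outside the target)."""
    if phantom.target_label is None or phantom.target_centerline is None:
        raise ValueError("phantom has no target/centerline")
    step = min(phantom.spacing) / 2.0
    samples, s = _sample_polyline(phantom.target_centerline, step)
    tmask = phantom.target_mask()
    centers = phantom.voxel_centers()[tmask]
    tree = cKDTree(samples)
    _, nearest = tree.query(centers, workers=-1)
    out = np.full(phantom.shape, np.nan)
    out[tmask] = s[nearest]
    return out


def make_orientation_field(
    phantom: Phantom,
    mode: str,
    vector: Sequence[float] | None = None,
    where: str = "brain",
) -> Phantom:
    """Attach a unit orientation field to the phantom.

    Parameters
    ----------
    mode : {"uniform", "radial", "along_target_axis"}
        ``uniform`` uses ``vector`` everywhere; ``radial`` points away
        from the sphere center (the cortical-column direction on a
        spherical brain); ``along_target_axis`` uses the tangent of the
        nearest target-centerline point.
    where : {"brain", "target"}
        Voxels to assign.  ``target`` overrides only target voxels and
        keeps any existing orientation elsewhere, so a radial brain field
        can be composed with a tangential target field.
    """
    if where == "brain":
        mask = phantom.brain_mask()
    elif where == "target":
        mask = phantom.target_mask()
    else:
        raise ValueError(f"unknown 'where' selector: {where!r}")

    n_vox = int(mask.sum())
    if mode == "uniform":
        if vector is None:
            raise ValueError("mode 'uniform' requires a vector")
        v = np.asarray(vector, dtype=float)
        norm = np.linalg.norm(v)
        if norm == 0:
            raise ValueError("uniform orientation vector must be nonzero")
        vecs = np.tile(v / norm, (n_vox, 1))
    elif mode == "radial":
        centers = phantom.voxel_centers()[mask]
        norms = np.linalg.norm(centers, axis=1)
        vecs = np.empty_like(centers)
        ok = norms > 0
        vecs[ok] = centers[ok] / norms[ok, None]
        vecs[~ok] = (1.0, 0.0, 0.0)  # the center voxel has no radial direction
    elif mode == "along_target_axis":
        if phantom.target_centerline is None:
            raise ValueError("mode 'along_target_axis' requires an embedded target")
        step = min(phantom.spacing) / 2.0
        samples, _ = _sample_polyline(phantom.target_centerline, step)
        tangents = np.gradient(samples, axis=0)
        tangents /= np.linalg.norm(tangents, axis=1, keepdims=True)
        centers = phantom.voxel_centers()[mask]
        tree = cKDTree(samples)
        _, nearest = tree.query(centers, workers=-1)
        vecs = tangents[nearest]
    else:
        raise ValueError(f"unknown orientation mode: {mode!r}")

    if phantom.orientation is not None and where == "target":
        orientation = phantom.orientation.copy()
    else:
        orientation = np.full(phantom.shape + (3,), np.nan)
    orientation[mask] = vecs
    return replace(phantom, orientation=orientation)


def connected_components(mask: np.ndarray) -> int:
    """Number of 26-connected components in a boolean mask."""
    _, n = ndimage.label(mask, structure=np.ones((3, 3, 3), dtype=bool))
    return int(n)
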