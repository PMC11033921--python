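"""Volume and coordinate geometry for tractogram--DES comparisons.

Tractograms, stimulation spheres, lesions and brain masks are all handled as
binary masks on a voxel grid with a 4x4 voxel-to-world affine (world units mm).
All distances are Euclidean distances in world space between a stimulation
coordinate and the *centers* of nonzero voxels, computed on each patient's
1 mm working grid and rounded **up** to integer millimetres (sub-voxel
increments are not meaningful at 1 mm resolution).

Conventions
-----------
* Voxel indices are 0-based; only the affine is trusted for orientation
  (RAS is typical but never assumed).
* Sphere membership is inclusive: a voxel belongs to a sphere ROI when its
  world-space center lies within ``radius_mm`` of the sphere center.
* An empty tractogram mask is an error, never an "infinite distance" — it
  signals an upstream reconstruction failure that must surface.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import nibabel as nib
import numpy as np
import pandas as pd

__all__ = [
    "METHODS",
    "DTI_METHODS",
    "CSD_METHODS",
    "BUNDLES",
    "RESPONSES",
    "DEPTHS",
    "HEMISPHERES",
    "LabeledVolume",
    "StimulationPoint",
    "DistanceRecord",
    "read_volume",
    "write_volume",
    "make_sphere",
    "center_of_mass",
    "collapse_and_recreate",
    "min_distance",
    "min_distance_mm",
    "volume_ml",
    "ratio_to",
    "dice",
    "jaccard",
    "compute_distance_table",
    "read_points_tsv",
    "write_points_tsv",
    "read_manifest_tsv",
    "records_to_frame",
    "write_distances_tsv",
    "read_distances_tsv",
]

#: Tractography method factor levels; FACT (the manual clinical standard) is
#: the reference level everywhere.
METHODS = ("FACT", "TP", "ATP", "iFOD2", "AiFOD2")
DTI_METHODS = ("FACT", "TP", "ATP")
CSD_METHODS = ("iFOD2", "AiFOD2")
BUNDLES = ("CST", "AF")
RESPONSES = ("positive", "negative")
DEPTHS = ("cortical", "subcortical")
HEMISPHERES = ("L", "R")

_DIST_TOL = 1e-6  # absorb float noise before the ceiling / boundary tests


@dataclass
class LabeledVolume:
    """A 3-D binary mask plus its voxel-index-to-world-mm affine.

    Parameters
    ----------
    mask : (i, j, k) array of {0, 1}
    affine : (4, 4) array
        Maps homogeneous voxel indices to world coordinates in mm.
    label : str
        Free-text role tag (``tractogram`` | ``sphere`` | ``lesion`` |
        ``brain``), carried through for bookkeeping only.
    """

    mask: np.ndarray
    affine: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        mask = np.asarray(self.mask)
        if mask.ndim != 3:
            raise ValueError(f"mask must be 3-D, got ndim={mask.ndim}")
        if not np.isin(mask, (0, 1)).all():
            raise ValueError("mask must contain only 0/1")
        affine = np.asarray(self.affine, dtype=float)
        if affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if abs(np.linalg.det(affine[:3, :3])) <= 1e-12:
            raise ValueError("singular affine: zero voxel volume")
        self.mask = mask.astype(np.uint8)
        self.affine = affine

    # -- geometry helpers -------------------------------------------------
    @property
    def shape(self) -> tuple[int, int, int]:
        return self.mask.shape  # type: ignore[return-value]

    @property
    def voxel_volume_mm3(self) -> float:
        return float(abs(np.linalg.det(self.affine[:3, :3])))

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())

    def voxel_to_world(self, ijk: np.ndarray) -> np.ndarray:
        """World-mm coordinates of (possibly fractional) voxel indices."""
        ijk = np.atleast_2d(np.asarray(ijk, dtype=float))
        return ijk @ self.affine[:3, :3].T + self.affine[:3, 3]

    def world_to_voxel(self, xyz: Sequence[float]) -> np.ndarray:
        inv = np.linalg.inv(self.affine)
        xyz = np.asarray(xyz, dtype=float)
        return xyz @ inv[:3, :3].T + inv[:3, 3]

    def nonzero_world(self) -> np.ndarray:
        """(n, 3) world-mm centers of all nonzero voxels."""
        idx = np.argwhere(self.mask > 0)
        return self.voxel_to_world(idx)

    def same_grid(self, other: "LabeledVolume", atol: float = 1e-6) -> bool:
        return self.shape == other.shape and np.allclose(
            self.affine, other.affine, atol=atol
        )


@dataclass(frozen=True)
class StimulationPoint:
    """One DES test site in world mm.

    ``response`` is ``positive`` (stimulation interfered with task
    performance / elicited an effect) or ``negative`` (no response up to the
    maximum stimulation amplitude). ``bundle``/``hemisphere`` name the
    white-matter bundle the site was probing.
    """

    patient_id: str
    point_id: str
    xyz_mm: tuple[float, float, float]
    response: str
    depth: str
    bundle: str
    hemisphere: str

    def __post_init__(self) -> None:
        if self.response not in RESPONSES:
            raise ValueError(f"response must be one of {RESPONSES}")
        if self.depth not in DEPTHS:
            raise ValueError(f"depth must be one of {DEPTHS}")
        if self.bundle not in BUNDLES:
            raise ValueError(f"bundle must be one of {BUNDLES}")
        if self.hemisphere not in HEMISPHERES:
            raise ValueError(f"hemisphere must be one of {HEMISPHERES}")
        xyz = tuple(float(c) for c in self.xyz_mm)
        if not np.isfinite(xyz).all():
            raise ValueError("xyz_mm must be finite")
        object.__setattr__(self, "xyz_mm", xyz)


@dataclass(frozen=True)
class DistanceRecord:
    """One tractogram--coordinate pairing and its integer distance (mm)."""

    patient_id: str
    bundle: str
    hemisphere: str
    method: str
    point_id: str
    response: str
    depth: str
    distance_mm: int

    def __post_init__(self) -> None:
        if self.method not in METHODS:
            raise ValueError(f"method must be one of {METHODS}")
        if self.distance_mm < 0:
            raise ValueError("distance_mm must be >= 0")


# ---------------------------------------------------------------------------
# NIfTI and TSV I/O
# ---------------------------------------------------------------------------

def read_volume(path: str | Path, label: str = "") -> LabeledVolume:
    """Read a NIfTI-1 file as a binary mask (values > 0 map to 1)."""
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 3-D image, got ndim={data.ndim}")
    return LabeledVolume((data > 0).astype(np.uint8), np.asarray(img.affine), label)


def write_volume(vol: LabeledVolume, path: str | Path) -> Path:
    path = Path(path)
    nib.save(nib.Nifti1Image(vol.mask.astype(np.uint8), vol.affine), str(path))
    return path


POINTS_COLUMNS = [
    "patient_id", "point_id", "x_mm", "y_mm", "z_mm",
    "response", "depth", "bundle", "hemisphere",
]
MANIFEST_COLUMNS = ["patient_id", "bundle", "hemisphere", "method", "nifti_path"]
DISTANCES_COLUMNS = [
    "patient_id", "bundle", "hemisphere", "method",
    "point_id", "response", "depth", "distance_mm",
]


def read_points_tsv(path: str | Path) -> list[StimulationPoint]:
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"patient_id": str, "point_id": str})
    missing = set(POINTS_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"points table missing columns: {sorted(missing)}")
    return [
        StimulationPoint(
            patient_id=row.patient_id,
            point_id=row.point_id,
            xyz_mm=(row.x_mm, row.y_mm, row.z_mm),
            response=row.response,
            depth=row.depth,
            bundle=row.bundle,
            hemisphere=row.hemisphere,
        )
        for row in df.itertuples()
    ]


def write_points_tsv(points: Iterable[StimulationPoint], path: str | Path) -> Path:
    rows = [
        {
            "patient_id": p.patient_id,
            "point_id": p.point_id,
            "x_mm": p.xyz_mm[0],
            "y_mm": p.xyz_mm[1],
            "z_mm": p.xyz_mm[2],
            "response": p.response,
            "depth": p.depth,
            "bundle": p.bundle,
            "hemisphere": p.hemisphere,
        }
        for p in points
    ]
    pd.DataFrame(rows, columns=POINTS_COLUMNS).to_csv(path, sep="\t", index=False)
    return Path(path)


def read_manifest_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"patient_id": str})
    missing = set(MANIFEST_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"manifest missing columns: {sorted(missing)}")
    return df[MANIFEST_COLUMNS]


def records_to_frame(records: Iterable[DistanceRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {c: getattr(r, c) for c in DISTANCES_COLUMNS}
            for r in records
        ],
        columns=DISTANCES_COLUMNS,
    )


def write_distances_tsv(records, path: str | Path) -> Path:
    frame = records if isinstance(records, pd.DataFrame) else records_to_frame(records)
    frame.to_csv(path, sep="\t", index=False)
    return Path(path)


def read_distances_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", dtype={"patient_id": str, "point_id": str})


# ---------------------------------------------------------------------------
# Sphere ROIs and center-of-mass collapse
# ---------------------------------------------------------------------------

def _check_in_fov(vol: LabeledVolume, xyz_mm: Sequence[float]) -> np.ndarray:
    vox = vol.world_to_voxel(xyz_mm)
    lo, hi = -0.5, np.asarray(vol.shape) - 0.5
    if np.any(vox < lo) or np.any(vox >= hi):
        raise ValueError(
            f"coordinate {tuple(np.round(xyz_mm, 2))} outside the reference field of view"
        )
    return vox


def make_sphere(
    center_xyz_mm: Sequence[float],
    radius_mm: float = 5.0,
    reference: LabeledVolume | None = None,
) -> LabeledVolume:
    """Sphere ROI: voxels whose world-space centers lie within ``radius_mm``
    (inclusive) of ``center_xyz_mm``, on the reference grid.

    The 5 mm default radius matches the DES sphere convention used for
    intraoperative coordinates.
    """
    if reference is None:
        raise ValueError("a reference volume defining the grid is required")
    if radius_mm < 0:
        raise ValueError("radius_mm must be >= 0")
    center = np.asarray(center_xyz_mm, dtype=float)
    _check_in_fov(reference, center)

    # bounding box in voxel space: |dvox_i| <= ||row_i(A^-1)|| * radius
    inv3 = np.linalg.inv(reference.affine)[:3, :3]
    center_vox = reference.world_to_voxel(center)
    pad = np.linalg.norm(inv3, axis=1) * radius_mm + 1.0
    lo = np.maximum(np.floor(center_vox - pad).astype(int), 0)
    hi = np.minimum(np.ceil(center_vox + pad).astype(int) + 1, reference.shape)

    mask = np.zeros(reference.shape, dtype=np.uint8)
    if np.all(lo < hi):
        ii, jj, kk = np.meshgrid(
            np.arange(lo[0], hi[0]),
            np.arange(lo[1], hi[1]),
            np.arange(lo[2], hi[2]),
            indexing="ij",
        )
        idx = np.stack([ii.ravel(), jj.ravel(), kk.ravel()], axis=1)
        world = reference.voxel_to_world(idx)
        d2 = np.sum((world - center) ** 2, axis=1)
        inside = d2 <= radius_mm**2 + _DIST_TOL
        sel = idx[inside]
        mask[sel[:, 0], sel[:, 1], sel[:, 2]] = 1
    return LabeledVolume(mask, reference.affine, label="sphere")


def center_of_mass(vol: LabeledVolume) -> np.ndarray:
    """Unweighted mean of world coordinates of nonzero voxel centers (mm)."""
    if vol.n_voxels == 0:
        raise ValueError("center_of_mass of an empty mask")
    return vol.nonzero_world().mean(axis=0)


def _snap_to_voxel_center(vol: LabeledVolume, xyz_mm: np.ndarray) -> np.ndarray:
    """Round a world coordinate to the center of the voxel containing it."""
    vox = np.rint(vol.world_to_voxel(xyz_mm))
    return vol.voxel_to_world(vox)[0]


def collapse_and_recreate(
    sphere: LabeledVolume,
    radius_mm: float = 5.0,
    reference: LabeledVolume | None = None,
) -> LabeledVolume:
    """Collapse a (possibly warp-deformed) sphere ROI to its center of mass and
    recreate an undeformed sphere of the same radius there.

    The COM is snapped to the nearest voxel center (a sub-voxel adjustment,
    below the integer-mm rounding granularity) so the recreated sphere is
    lattice-symmetric and the operation is exactly idempotent.
    """
    ref = reference if reference is not None else sphere
    return make_sphere(_snap_to_voxel_center(ref, center_of_mass(sphere)), radius_mm, ref)


# ---------------------------------------------------------------------------
# Distances, volumes, overlap metrics
# ---------------------------------------------------------------------------

def min_distance_mm(xyz_mm: Sequence[float], tract: LabeledVolume) -> float:
    """Raw (unrounded) minimum Euclidean distance in mm from a world-space
    point to the nearest nonzero voxel center of ``tract``."""
    if tract.n_voxels == 0:
        raise ValueError("empty tractogram mask: cannot compute a distance")
    xyz = np.asarray(xyz_mm, dtype=float)
    d = np.linalg.norm(tract.nonzero_world() - xyz, axis=1)
    return float(d.min())


def min_distance(point, tract: LabeledVolume) -> int:
    """Integer minimum distance (mm) from a DES coordinate to a tractogram.

    The distance is 0 when the voxel containing the point belongs to the mask;
    otherwise it is the minimum point-to-voxel-center Euclidean distance,
    rounded up to an integer millimetre.
    """
    xyz = point.xyz_mm if isinstance(point, StimulationPoint) else point
    if tract.n_voxels == 0:
        raise ValueError("empty tractogram mask: cannot compute a distance")
    vox = np.rint(tract.world_to_voxel(xyz)).astype(int)
    if np.all(vox >= 0) and np.all(vox < tract.shape) and tract.mask[tuple(vox)]:
        return 0
    d = min_distance_mm(xyz, tract)
    return int(math.ceil(d - _DIST_TOL))


def volume_ml(vol: LabeledVolume) -> float:
    """Mask volume in millilitres (voxel count x voxel volume / 1000)."""
    return vol.n_voxels * vol.voxel_volume_mm3 / 1000.0


def ratio_to(vol: LabeledVolume, brain: LabeledVolume) -> float:
    """Unitless volume ratio, e.g. bundle-to-TIV or lesion-to-TIV."""
    if brain.n_voxels == 0:
        raise ValueError("empty brain mask in ratio_to")
    return volume_ml(vol) / volume_ml(brain)


def _overlap_counts(a: LabeledVolume, b: LabeledVolume) -> tuple[int, int, int]:
    if not a.same_grid(b):
        raise ValueError("dice/jaccard require identical grids and affines")
    inter = int(np.logical_and(a.mask, b.mask).sum())
    return inter, a.n_voxels, b.n_voxels


def dice(a: LabeledVolume, b: LabeledVolume) -> float:
    """Dice similarity coefficient 2|A∩B|/(|A|+|B|); 0 when both empty."""
    inter, na, nb = _overlap_counts(a, b)
    if na + nb == 0:
        return 0.0
    return 2.0 * inter / (na + nb)


def jaccard(a: LabeledVolume, b: LabeledVolume) -> float:
    """Jaccard index |A∩B|/|A∪B|; 0 when both empty."""
    inter, na, nb = _overlap_counts(a, b)
    union = na + nb - inter
    if union == 0:
        return 0.0
    return inter / union


# ---------------------------------------------------------------------------
# Pairing: the distance table
# ---------------------------------------------------------------------------

def _as_volume_mapping(tractograms) -> Mapping[tuple, LabeledVolume]:
    """Accept either a mapping {(patient, bundle, hemi, method): LabeledVolume}
    or a manifest DataFrame with a nifti_path column."""
    if isinstance(tractograms, Mapping):
        return tractograms
    if isinstance(tractograms, pd.DataFrame):
        out = {}
        for row in tractograms.itertuples():
            key = (row.patient_id, row.bundle, row.hemisphere, row.method)
            out[key] = read_volume(row.nifti_path, label="tractogram")
        return out
    raise TypeError("tractograms must be a mapping or a manifest DataFrame")


def measurement_point(
    point: StimulationPoint,
    reference: LabeledVolume,
    sphere_radius_mm: float = 5.0,
    collapse: bool = True,
) -> np.ndarray:
    """The world coordinate distances are measured from.

    With ``collapse`` (the default) the DES coordinate is first turned into a
    sphere ROI on the reference grid, collapsed to its center of mass and the
    COM used as the measuring point — mirroring the sphere COM-collapse step
    that mitigates registration deformations. Otherwise the raw coordinate is
    used.
    """
    xyz = np.asarray(point.xyz_mm, dtype=float)
    if not collapse:
        return xyz
    sphere = make_sphere(xyz, sphere_radius_mm, reference)
    return _snap_to_voxel_center(reference, center_of_mass(sphere))


def compute_distance_table(
    points: Sequence[StimulationPoint],
    tractograms,
    *,
    collapse: bool = True,
    sphere_radius_mm: float = 5.0,
) -> list[DistanceRecord]:
    """One DistanceRecord per eligible (tractogram, point) pair.

    Pairing is restricted within patient: positive DES points pair only with
    tractograms of their designated bundle (and hemisphere); negative DES
    points pair with *all* of the patient's tractograms. A missing tractogram
    (failed reconstruction) simply yields no records.
    """
    volumes = _as_volume_mapping(tractograms)
    patients = {key[0] for key in volumes}
    records: list[DistanceRecord] = []
    for point in points:
        if point.patient_id not in patients:
            raise KeyError(f"point {point.point_id}: unknown patient {point.patient_id}")
        for (pid, bundle, hemi, method), vol in volumes.items():
            if pid != point.patient_id:
                continue
            if point.response == "positive" and (
                bundle != point.bundle or hemi != point.hemisphere
            ):
                continue
            xyz = measurement_point(point, vol, sphere_radius_mm, collapse)
            records.append(
                DistanceRecord(
                    patient_id=pid,
                    bundle=bundle,
                    hemisphere=hemi,
                    method=method,
                    point_id=point.point_id,
                    response=point.response,
                    depth=point.depth,
                    distance_mm=min_distance(xyz, vol),
                )
            )
    return records
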