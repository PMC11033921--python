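"""Synthetic cohorts with known ground truth.

Two generators, serving different purposes:

* :func:`generate_cohort` builds a voxel-level cohort (bundle masks per
  tractography method, lesions, brain masks, stimulation points) that
  exercises the full geometry pipeline. Bundle geometry is deliberately
  simple — a parametric tube with an apical fan for CST-like bundles, an arc
  for AF-like bundles — because the *statistical* structure is the contract:
  CSD-like methods (iFOD2, AiFOD2) yield spatially larger masks that strictly
  contain the DTI-like ones (FACT, TP, ATP); positive DES points cluster near
  bundles while negative points sit farther away with a heavier tail; and an
  occasional reconstruction fails outright.

* :func:`generate_semicontinuous` draws tabular data *exactly* from the
  correlated two-part model, for parameter-recovery and calibration tests
  with full distributional control.

All randomness flows through one seeded generator per call, and the realized
ground truth is returned alongside the data.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage, special

from .spatial import (
    BUNDLES,
    CSD_METHODS,
    DTI_METHODS,
    METHODS,
    LabeledVolume,
    StimulationPoint,
    min_distance_mm,
    ratio_to,
    volume_ml,
    write_points_tsv,
    write_volume,
)
from .twopart import TwoPartParams, build_design

__all__ = [
    "CohortParams",
    "SyntheticCohort",
    "SyntheticTruth",
    "generate_cohort",
    "generate_semicontinuous",
    "DEFAULT_TWOPART_ALPHA",
    "DEFAULT_TWOPART_BETA",
    "DEFAULT_TWOPART_PARAMS",
]


# ---------------------------------------------------------------------------
# Voxel-level cohort
# ---------------------------------------------------------------------------

@dataclass
class CohortParams:
    """Generative parameters of a voxel-level synthetic cohort.

    Defaults emulate a realistic DES-validation cohort: ~20 patients, a CST
    per patient and an AF with probability ``p_af`` (language mapping is the
    rarer indication), on average 51:123 positive:negative DES points across
    20 patients with ~90% cortical sites, and a ~1/135 chance that any
    automated reconstruction fails outright.
    ``method_offsets_mm`` encode that CSD-like masks are dilations of the
    base bundle while DTI-like masks are erosions of it.
    """

    n_patients: int = 20
    shape: tuple[int, int, int] = (64, 64, 64)
    voxel_mm: float = 1.0
    p_af: float = 0.35
    method_offsets_mm: Mapping[str, int] = field(
        default_factory=lambda: {"FACT": -2, "TP": -2, "ATP": -1, "iFOD2": 1, "AiFOD2": 2}
    )
    mean_n_pdes: float = 51.0 / 20.0
    mean_n_ndes: float = 123.0 / 20.0
    p_cortical: float = 0.9
    pdes_scale_mm: float = 10.0      # truncated-exponential offset of pDES from the bundle
    pdes_max_mm: float = 30.0
    ndes_offset_mm: float = 4.0     # nDES offset = ndes_offset + Exp(ndes_scale)
    ndes_scale_mm: float = 16.0
    lesion_radius_range_mm: tuple[float, float] = (5.0, 14.0)
    failure_prob: float = 1.0 / 135.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        if not 0.0 <= self.p_af <= 1.0:
            raise ValueError("p_af must be in [0, 1]")
        if not 0.0 <= self.failure_prob <= 1.0:
            raise ValueError("failure_prob must be in [0, 1]")
        if min(self.shape) < 32:
            raise ValueError("grid too small for the bundle geometry (need >= 32 per axis)")
        if self.seed is None:
            raise ValueError("seed is mandatory")


@dataclass
class SyntheticTruth:
    """Everything needed to recompute the generated observables."""

    params: dict
    seed: int
    random_effects: dict = field(default_factory=dict)
    true_distances: list = field(default_factory=list)
    failed_reconstructions: list = field(default_factory=list)

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(json.dumps(asdict(self), indent=2, default=_json_default))
        return path


def _json_default(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")


@dataclass
class SyntheticCohort:
    volumes: dict          # (patient_id, bundle, hemisphere, method) -> LabeledVolume
    base_bundles: dict     # (patient_id, bundle, hemisphere) -> LabeledVolume
    brains: dict           # patient_id -> LabeledVolume
    lesions: dict          # patient_id -> LabeledVolume
    points: list           # list[StimulationPoint]
    manifest: pd.DataFrame
    covariates: pd.DataFrame  # per-tractogram bundle_tiv_ratio + lesion_tiv_ratio
    truth: SyntheticTruth

    def write(self, out_dir: str | Path) -> Path:
        """Persist the cohort in the pipeline's on-disk dialect (NIfTI + TSV)."""
        out = Path(out_dir)
        (out / "masks").mkdir(parents=True, exist_ok=True)
        rows = []
        for (pid, bundle, hemi, method), vol in self.volumes.items():
            path = out / "masks" / f"{pid}_{bundle}_{hemi}_{method}.nii.gz"
            write_volume(vol, path)
            rows.append({"patient_id": pid, "bundle": bundle, "hemisphere": hemi,
                         "method": method, "nifti_path": str(path)})
        for pid, vol in self.brains.items():
            write_volume(vol, out / "masks" / f"{pid}_brain.nii.gz")
        for pid, vol in self.lesions.items():
            write_volume(vol, out / "masks" / f"{pid}_lesion.nii.gz")
        pd.DataFrame(rows).to_csv(out / "manifest.tsv", sep="\t", index=False)
        write_points_tsv(self.points, out / "points.tsv")
        self.covariates.to_csv(out / "covariates.tsv", sep="\t", index=False)
        self.truth.to_json(out / "truth.json")
        return out


def _ball(radius: int) -> np.ndarray:
    if radius <= 0:
        return np.ones((1, 1, 1), dtype=bool)
    r = int(radius)
    g = np.mgrid[-r : r + 1, -r : r + 1, -r : r + 1]
    return (g**2).sum(axis=0) <= r**2


def _world_grid(shape, affine):
    ii, jj, kk = np.meshgrid(*(np.arange(s) for s in shape), indexing="ij")
    idx = np.stack([ii, jj, kk], axis=-1).astype(float)
    return idx @ affine[:3, :3].T + affine[:3, 3]


def _cst_mask(world, cx, jitter, rng) -> np.ndarray:
    """Tube along z with an apical fan (the hallmark CST shape)."""
    x, y, z = world[..., 0], world[..., 1], world[..., 2]
    r_base = 4.5 + jitter
    z_lo, z_hi = -24.0, 22.0
    fan_start = 8.0
    fan = np.clip((z - fan_start) / (z_hi - fan_start), 0.0, 1.0)
    radius = r_base + 5.0 * fan
    in_z = (z >= z_lo) & (z <= z_hi)
    d2 = (x - cx) ** 2 + (y - rng.uniform(-2.0, 2.0)) ** 2
    return (in_z & (d2 <= radius**2)).astype(np.uint8)


def _af_mask(world, cx, jitter, rng) -> np.ndarray:
    """C-shaped arc in the sagittal plane (fronto-temporal hook)."""
    x, y, z = world[..., 0], world[..., 1], world[..., 2]
    arc_r = 13.0 + jitter
    tube_r = 4.0 + 0.5 * jitter
    yc, zc = rng.uniform(-2.0, 2.0), 2.0
    rad = np.sqrt((y - yc) ** 2 + (z - zc) ** 2)
    ang = np.arctan2(z - zc, y - yc)  # arc opens downward/forward
    in_arc = (np.abs(rad - arc_r) <= tube_r) & (ang > -0.3) & (np.abs(x - cx) <= tube_r)
    return in_arc.astype(np.uint8)


def _surface_voxels(mask: np.ndarray) -> np.ndarray:
    eroded = ndimage.binary_erosion(mask.astype(bool))
    return np.argwhere(mask.astype(bool) & ~eroded)


def generate_cohort(params: CohortParams | None = None, out_dir: str | Path | None = None) -> SyntheticCohort:
    """Generate a voxel-level synthetic cohort; fully reproducible from seed."""
    params = params if params is not None else CohortParams()
    rng = np.random.default_rng(params.seed)
    shape = params.shape
    affine = np.diag([params.voxel_mm] * 3 + [1.0])
    affine[:3, 3] = -np.asarray(shape) * params.voxel_mm / 2.0
    world = _world_grid(shape, affine)

    # shared brain ellipsoid (per-grid, not per-patient: registration-space fiction)
    half = np.asarray(shape) * params.voxel_mm / 2.0
    semi = half * np.array([0.92, 0.92, 0.9])
    brain_mask = (np.sum(((world - 0.0) / semi) ** 2, axis=-1) <= 1.0).astype(np.uint8)

    volumes: dict = {}
    base_bundles: dict = {}
    brains: dict = {}
    lesions: dict = {}
    points: list[StimulationPoint] = []
    manifest_rows = []
    cov_rows = []
    failed = []
    true_distances = []

    for i in range(params.n_patients):
        pid = f"PT{i + 1:03d}"
        brains[pid] = LabeledVolume(brain_mask, affine, "brain")

        # lesion: random ball inside the brain
        lr = rng.uniform(*params.lesion_radius_range_mm)
        lcenter = rng.uniform(-12.0, 12.0, size=3)
        lesion = (np.linalg.norm(world - lcenter, axis=-1) <= lr).astype(np.uint8)
        lesions[pid] = LabeledVolume(lesion, affine, "lesion")
        lesion_ratio = ratio_to(lesions[pid], brains[pid])

        hemi = "L" if rng.random() < 0.5 else "R"
        cx = -14.0 if hemi == "L" else 14.0
        bundles = [("CST", hemi)]
        if rng.random() < params.p_af:
            bundles.append(("AF", hemi))

        for bundle, bh in bundles:
            jitter = rng.uniform(-0.5, 0.5)
            base = _cst_mask(world, cx, jitter, rng) if bundle == "CST" else _af_mask(world, cx, jitter, rng)
            base_vol = LabeledVolume(base, affine, "tractogram")
            base_bundles[(pid, bundle, bh)] = base_vol
            for method in METHODS:
                off = int(params.method_offsets_mm[method])
                if off >= 0:
                    mask = ndimage.binary_dilation(base.astype(bool), _ball(off))
                else:
                    # FACT and TP share the erosion radius but not the element,
                    # so the two DTI-like masks differ slightly
                    elem = _ball(-off) if method != "TP" else ndimage.generate_binary_structure(3, 1)
                    it = 1 if method != "TP" else -off
                    mask = ndimage.binary_erosion(base.astype(bool), elem, iterations=it)
                if method != "FACT" and rng.random() < params.failure_prob:
                    failed.append({"patient_id": pid, "bundle": bundle,
                                   "hemisphere": bh, "method": method})
                    continue
                if not mask.any():
                    raise ValueError("grid too small: an eroded bundle mask vanished")
                vol = LabeledVolume(mask.astype(np.uint8), affine, "tractogram")
                volumes[(pid, bundle, bh, method)] = vol
                manifest_rows.append({"patient_id": pid, "bundle": bundle,
                                      "hemisphere": bh, "method": method})
                cov_rows.append({
                    "patient_id": pid, "bundle": bundle, "hemisphere": bh,
                    "method": method,
                    "bundle_tiv_ratio": ratio_to(vol, brains[pid]),
                    "lesion_tiv_ratio": lesion_ratio,
                })

        # stimulation points
        n_p = int(rng.poisson(params.mean_n_pdes))
        n_n = int(rng.poisson(params.mean_n_ndes))
        pt_counter = 0
        for response, count in (("positive", n_p), ("negative", n_n)):
            for _ in range(count):
                bundle, bh = bundles[int(rng.integers(len(bundles)))]
                base_vol = base_bundles[(pid, bundle, bh)]
                depth = "cortical" if rng.random() < params.p_cortical else "subcortical"
                surf = _surface_voxels(base_vol.mask)
                zs = base_vol.voxel_to_world(surf)[:, 2]
                cut = np.quantile(zs, 0.6)
                pool = surf[zs >= cut] if depth == "cortical" else surf[zs < cut]
                if len(pool) == 0:
                    pool = surf
                anchor = base_vol.voxel_to_world(pool[int(rng.integers(len(pool)))])[0]
                if response == "positive":
                    d = min(rng.exponential(params.pdes_scale_mm), params.pdes_max_mm)
                else:
                    d = params.ndes_offset_mm + rng.exponential(params.ndes_scale_mm)
                # mostly-outward direction so the offset translates into distance
                centroid = base_vol.nonzero_world().mean(axis=0)
                outward = anchor - centroid
                nrm = np.linalg.norm(outward)
                outward = outward / nrm if nrm > 1e-9 else rng.normal(size=3)
                direction = outward + 0.3 * rng.normal(size=3)
                direction /= np.linalg.norm(direction)
                xyz = anchor + d * direction
                lim = half - 2.0 * params.voxel_mm
                xyz = np.clip(xyz, -lim, lim)
                pt_counter += 1
                point = StimulationPoint(
                    patient_id=pid,
                    point_id=f"{pid}_{response[0]}{pt_counter:03d}",
                    xyz_mm=tuple(xyz),
                    response=response,
                    depth=depth,
                    bundle=bundle,
                    hemisphere=bh,
                )
                points.append(point)
                true_distances.append({
                    "point_id": point.point_id,
                    "bundle": bundle,
                    "hemisphere": bh,
                    "true_distance_mm": min_distance_mm(xyz, base_vol),
                })

    truth = SyntheticTruth(
        params={k: (list(v) if isinstance(v, tuple) else (dict(v) if isinstance(v, Mapping) else v))
                for k, v in asdict(params).items()},
        seed=params.seed,
        true_distances=true_distances,
        failed_reconstructions=failed,
    )
    cohort = SyntheticCohort(
        volumes=volumes,
        base_bundles=base_bundles,
        brains=brains,
        lesions=lesions,
        points=points,
        manifest=pd.DataFrame(manifest_rows,
                              columns=["patient_id", "bundle", "hemisphere", "method"]),
        covariates=pd.DataFrame(cov_rows),
        truth=truth,
    )
    if out_dir is not None:
        cohort.write(out_dir)
    return cohort


# ---------------------------------------------------------------------------
# Tabular two-part data
# ---------------------------------------------------------------------------

#: Default generative fixed effects, on the model's own scales (part A:
#: logit of overlap probability; part B: log mm). They mirror the expected
#: clinical structure: positive DES sites overlap far more often and sit
#: closer; CSD-like methods carry an overlap advantage of ~1.8 logits.
DEFAULT_TWOPART_ALPHA = {
    "Intercept": -1.5,
    "response[positive]": 2.0,
    "method[TP]": 0.0,
    "method[ATP]": 0.3,
    "method[iFOD2]": 1.8,
    "method[AiFOD2]": 1.8,
    "bundle_tiv_ratio": 0.5,
    "lesion_tiv_ratio": 0.0,
}
DEFAULT_TWOPART_BETA = {
    "Intercept": 3.2,
    "response[positive]": -0.35,
    "method[TP]": 0.0,
    "method[ATP]": -0.05,
    "method[iFOD2]": -0.30,
    "method[AiFOD2]": -0.35,
    "bundle_tiv_ratio": -0.10,
    "lesion_tiv_ratio": 0.0,
}
DEFAULT_TWOPART_PARAMS = dict(tau_u=1.0, tau_v=0.4, rho=0.5, sigma=0.45)


def _coef_vector(coefs: Mapping[str, float], names: Sequence[str]) -> np.ndarray:
    missing = [n for n in names if n not in coefs]
    if missing:
        raise ValueError(f"no coefficient given for design columns: {missing}")
    return np.array([coefs[n] for n in names], dtype=float)


def generate_semicontinuous(
    *,
    n_subjects: int,
    n_obs_per_subject: int,
    seed: int,
    alpha: Mapping[str, float] | None = None,
    beta: Mapping[str, float] | None = None,
    tau_u: float = DEFAULT_TWOPART_PARAMS["tau_u"],
    tau_v: float = DEFAULT_TWOPART_PARAMS["tau_v"],
    rho: float = DEFAULT_TWOPART_PARAMS["rho"],
    sigma: float = DEFAULT_TWOPART_PARAMS["sigma"],
    p_positive: float = 51.0 / 174.0,
    include_method: bool = True,
    covariates: Sequence[str] = ("bundle_tiv_ratio", "lesion_tiv_ratio"),
    cutoff: float = 0.0,
) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Draw a tabular semicontinuous dataset exactly from the two-part model.

    Per subject: correlated random intercepts ``(u, v)``; per observation a
    Bernoulli overlap through the logistic part and, if not overlapping,
    ``y = cutoff + exp(z' beta + v + sigma * eps)``. With the default
    ``cutoff = 0`` the draw matches the fitted density exactly; a positive
    cutoff produces the shifted thresholding variant and should be fit with
    the model's matching ``shift_cutoff``.

    Covariates are subject-level standard normals (the standardized-ratio
    scale the model fits on). Response and method assignments are balanced
    within subject as in the real pairing design.
    """
    if not (tau_u > 0 and tau_v > 0 and sigma > 0 and -1 < rho < 1):
        raise ValueError("inadmissible variance/correlation parameters")
    rng = np.random.default_rng(seed)
    alpha = dict(DEFAULT_TWOPART_ALPHA if alpha is None else alpha)
    beta = dict(DEFAULT_TWOPART_BETA if beta is None else beta)

    rows = []
    for i in range(n_subjects):
        pid = f"S{i + 1:04d}"
        cov_vals = {c: rng.normal() for c in covariates}
        for j in range(n_obs_per_subject):
            method = METHODS[j % len(METHODS)] if include_method else "FACT"
            response = "positive" if rng.random() < p_positive else "negative"
            rows.append({"patient_id": pid, "method": method, "response": response,
                         **cov_vals})
    frame = pd.DataFrame(rows)

    design = build_design(
        frame,
        include_method=include_method,
        covariates=covariates,
        standardize_covariates=False,  # covariates are drawn standardized already
    )
    a_vec = _coef_vector(alpha, design.names)
    b_vec = _coef_vector(beta, design.names)

    cov = np.array([[tau_u**2, rho * tau_u * tau_v], [rho * tau_u * tau_v, tau_v**2]])
    re = rng.multivariate_normal(np.zeros(2), cov, size=n_subjects)
    sidx = np.repeat(np.arange(n_subjects), n_obs_per_subject)
    eta_a = design.matrix @ a_vec + re[sidx, 0]
    eta_b = design.matrix @ b_vec + re[sidx, 1]
    p_overlap = special.expit(eta_a)
    o = rng.random(len(frame)) < p_overlap
    y = np.where(o, 0.0, cutoff + np.exp(eta_b + sigma * rng.normal(size=len(frame))))
    frame["y"] = y
    frame["overlap"] = o.astype(int)

    truth = SyntheticTruth(
        params={
            "alpha": alpha, "beta": beta,
            "tau_u": tau_u, "tau_v": tau_v, "rho": rho, "sigma": sigma,
            "cutoff": cutoff, "n_subjects": n_subjects,
            "n_obs_per_subject": n_obs_per_subject, "design_names": design.names,
        },
        seed=seed,
        random_effects={"u": re[:, 0], "v": re[:, 1]},
    )
    return frame, truth
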