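"""End-to-end orchestration: distances -> agreement -> two-part model -> report.

Each stage is a plain function taking a :class:`PipelineConfig` plus in-memory
inputs and writing its TSV/JSON outputs (every file carries a schema-version
marker). Stages compose: ``run_agreement(config, run_distances(config))``
equals the monolithic :func:`run_all`. With a fixed seed and fixed inputs the
whole pipeline is byte-deterministic.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import agreement as agr
from . import spatial, twopart

SCHEMA_VERSION = 1
log = logging.getLogger("tractval")

__all__ = [
    "PipelineConfig",
    "run_distances",
    "run_agreement",
    "run_twopart",
    "report",
    "run_all",
    "POOLING_GROUPS",
]

#: ROC pooling groups: everything, the CSD-like family, the DTI-like family.
POOLING_GROUPS: dict[str, tuple[str, ...]] = {
    "all": spatial.METHODS,
    "CSD": spatial.CSD_METHODS,
    "DTI": spatial.DTI_METHODS,
}


@dataclass
class TwoPartConfig:
    #: distance threshold defining "overlap"; ``None`` means "use the pooled
    #: patient-averaged Youden cutoff computed by the agreement stage"
    cutoff_mm: float | None = 12.5
    covariates: tuple[str, ...] = ("bundle_tiv_ratio", "lesion_tiv_ratio")
    quadrature: int = 7
    adaptive_fwe: bool = True
    random_slope: bool = False
    bundle: str | None = "CST"


@dataclass
class PipelineConfig:
    """Configuration of the full analysis.

    Defaults follow the usual working conventions for DES validation: 5 mm
    DES spheres, COM-collapse on, agreement cutoffs at 5.5/12.5/13.5 mm
    (Youden cutoffs of pooled CSD, all-methods and pooled DTI data), and the
    two-part model at the 12.5 mm pooled cutoff.
    """

    manifest: str | None = None
    points: str | None = None
    out_dir: str = "tractval_out"
    sphere_radius_mm: float = 5.0
    collapse: bool = True
    cutoffs_mm: tuple[float, ...] = (5.5, 12.5, 13.5)
    averaging: str = "patient_response"  # or "raw"
    twopart: TwoPartConfig = field(default_factory=TwoPartConfig)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sphere_radius_mm < 0:
            raise ValueError("sphere_radius_mm must be >= 0")
        if any(c <= 0 for c in self.cutoffs_mm):
            raise ValueError("cutoffs must be > 0")
        if isinstance(self.twopart, Mapping):
            self.twopart = TwoPartConfig(**self.twopart)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        data.pop("schema_version", None)
        if "cutoffs_mm" in data:
            data["cutoffs_mm"] = tuple(data["cutoffs_mm"])
        return cls(**data)

    def to_yaml(self, path: str | Path) -> Path:
        data = asdict(self)
        data["schema_version"] = SCHEMA_VERSION
        Path(path).write_text(yaml.safe_dump(data, sort_keys=False))
        return Path(path)


def _write_tsv(frame: pd.DataFrame, path: Path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# tractval schema_version={SCHEMA_VERSION}\n")
        frame.to_csv(fh, sep="\t", index=False)


def _write_json(obj: dict, path: Path) -> None:
    obj = {"schema_version": SCHEMA_VERSION, **obj}
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True))


def _stage(name: str):
    def deco(fn):
        def wrapper(*args, **kwargs):
            t0 = time.perf_counter()
            out = fn(*args, **kwargs)
            log.info("stage %s finished in %.2fs", name, time.perf_counter() - t0)
            return out
        wrapper.__name__ = fn.__name__
        wrapper.__doc__ = fn.__doc__
        return wrapper
    return deco


# ---------------------------------------------------------------------------
# Stages
# ---------------------------------------------------------------------------

@_stage("distances")
def run_distances(
    config: PipelineConfig,
    points: Sequence[spatial.StimulationPoint] | None = None,
    tractograms=None,
) -> pd.DataFrame:
    """Minimum-distance table for every eligible tractogram--point pair.

    Inputs may be given in memory (points + volume mapping) or resolved from
    the configured points.tsv / manifest.tsv paths. Pairs whose tractogram is
    missing from the manifest (failed reconstructions) yield no records and
    are logged.
    """
    if points is None:
        if config.points is None:
            raise ValueError("no points given and config.points unset")
        points = spatial.read_points_tsv(config.points)
    if tractograms is None:
        if config.manifest is None:
            raise ValueError("no tractograms given and config.manifest unset")
        tractograms = spatial.read_manifest_tsv(config.manifest)
    records = spatial.compute_distance_table(
        points, tractograms,
        collapse=config.collapse,
        sphere_radius_mm=config.sphere_radius_mm,
    )
    frame = spatial.records_to_frame(records)
    volumes = spatial._as_volume_mapping(tractograms)
    expected = {(p.patient_id, p.bundle, p.hemisphere, m) for p in points
                if p.response == "positive" for m in spatial.METHODS}
    missing = sorted(k for k in expected if k not in volumes)
    for key in missing:
        log.warning("no tractogram for %s; pairs skipped", key)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    _write_tsv(frame, out / "distances.tsv")
    return frame


def _group_roc_inputs(distances: pd.DataFrame, methods: Sequence[str], averaging: str):
    sub = distances[distances["method"].isin(methods)]
    if averaging == "patient_response":
        cells = agr.average_per_patient(sub, by=("patient_id", "response"))
        return cells["distance_mm"].to_numpy(), cells["response"].to_numpy(), cells
    return sub["distance_mm"].to_numpy(float), sub["response"].to_numpy(), sub


@_stage("agreement")
def run_agreement(config: PipelineConfig, distances: pd.DataFrame) -> dict:
    """ROC curves, Youden cutoffs, pairwise DeLong tests and the confusion
    grid at the configured cutoffs.

    ROC pooling groups are: all methods, the CSD-like family (iFOD2, AiFOD2),
    the DTI-like family (FACT, TP, ATP), and each method alone; the headline
    pathway averages distances per patient per DES response type first.
    The confusion grid uses all raw tractogram--DES pairs.
    """
    if len(distances) == 0:
        raise ValueError("empty distance table")
    if distances["response"].nunique() < 2:
        raise ValueError("agreement stage needs both DES response types")
    groups = dict(POOLING_GROUPS)
    for m in spatial.METHODS:
        if (distances["method"] == m).any():
            groups[m] = (m,)

    rocs: dict[str, agr.ROCCurve] = {}
    youden: dict[str, float] = {}
    for name, methods in groups.items():
        d, labels, _ = _group_roc_inputs(distances, methods, config.averaging)
        if len(np.unique(labels)) < 2:
            log.warning("group %s has a single response class; skipped", name)
            continue
        roc = agr.roc_curve(d, labels)
        rocs[name] = roc
        try:
            youden[name] = agr.youden_cutoff(roc)
        except ValueError:
            youden[name] = float("nan")

    # paired DeLong between methods on patient-averaged cells
    delong: list[dict] = []
    present = [m for m in spatial.METHODS if m in rocs]
    cells = agr.average_per_patient(
        distances, by=("patient_id", "response", "method")
    ).pivot_table(index=["patient_id", "response"], columns="method",
                  values="distance_mm", aggfunc="mean")
    for i, m1 in enumerate(present):
        for m2 in present[i + 1:]:
            labels = cells.index.get_level_values("response").to_numpy()
            res = agr.delong_test(
                cells[m1].to_numpy(), cells[m2].to_numpy(), labels, paired=True
            )
            if res.n_dropped:
                log.info("DeLong %s vs %s dropped %d incomplete cells", m1, m2, res.n_dropped)
            delong.append({"pair": f"{m1} versus {m2}", "auc_a": res.auc_a,
                           "auc_b": res.auc_b, "z": res.z, "p": res.p,
                           "n_dropped": res.n_dropped})

    confusion_rows = []
    for m in present:
        sub = distances[distances["method"] == m]
        for cutoff in config.cutoffs_mm:
            summ = agr.confusion_at_cutoff(
                sub["distance_mm"].to_numpy(float), sub["response"].to_numpy(), cutoff
            )
            confusion_rows.append({"method": m, "cutoff_mm": cutoff, **summ.summary_row()})
    confusion = pd.DataFrame(confusion_rows)

    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    _write_json(
        {
            "rocs": {k: r.to_dict() for k, r in rocs.items()},
            "youden_cutoffs_mm": youden,
            "delong": delong,
            "averaging": config.averaging,
        },
        out / "roc.json",
    )
    _write_tsv(confusion, out / "confusion.tsv")
    return {"rocs": rocs, "youden": youden, "delong": delong, "confusion": confusion}


@_stage("twopart")
def run_twopart(
    config: PipelineConfig,
    distances: pd.DataFrame,
    covariates: pd.DataFrame | None = None,
    cutoff_mm: float | None = None,
) -> dict:
    """Threshold distances at the configured cutoff, fit the correlated
    two-part model and run the pairwise method post-hocs.

    The cutoff is, in order of precedence: the ``cutoff_mm`` argument (e.g.
    the pooled Youden cutoff from the agreement stage), the configured
    ``twopart.cutoff_mm``, else an error.
    """
    tp = config.twopart
    cutoff = cutoff_mm if cutoff_mm is not None else tp.cutoff_mm
    if cutoff is None:
        raise ValueError("no two-part cutoff configured; pass cutoff_mm")
    sub = distances
    if tp.bundle is not None:
        sub = sub[sub["bundle"] == tp.bundle]
        if len(sub) == 0:
            raise ValueError(f"no records for bundle {tp.bundle}")
    use_cov = tuple(tp.covariates) if covariates is not None else ()
    frame = twopart.threshold_distances(sub, cutoff, covariates)
    model = twopart.TwoPartModel(
        frame,
        covariates=use_cov,
        quadrature=tp.quadrature,
        random_slope=tp.random_slope,
    )
    fit = model.fit()
    if not fit.converged:
        log.warning("two-part model did not converge: %s", fit.message)
    contrasts = twopart.pairwise_contrasts(fit, adaptive=tp.adaptive_fwe)
    cframe = twopart.contrasts_to_frame(contrasts)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    _write_json({"fit": fit.to_dict(), "cutoff_mm": cutoff}, out / "twopart_fit.json")
    _write_tsv(cframe, out / "contrasts.tsv")
    return {"fit": fit, "contrasts": contrasts, "contrast_frame": cframe}


@_stage("report")
def report(config: PipelineConfig) -> Path:
    """Assemble a human-readable markdown report from whatever stage outputs
    exist in the output directory; missing stages are noted, never fatal."""
    out = Path(config.out_dir)
    lines = ["# tractval report", "",
             f"schema_version: {SCHEMA_VERSION}", ""]
    lines += ["## Configuration", "", "```yaml",
              yaml.safe_dump(asdict(config), sort_keys=False).strip(), "```", ""]

    dist_path = out / "distances.tsv"
    if dist_path.exists():
        d = pd.read_csv(dist_path, sep="\t", comment="#")
        lines += ["## Distance summaries (mm) per method x response", ""]
        summ = (
            d.groupby(["method", "response"])["distance_mm"]
            .describe()[["count", "mean", "50%", "min", "max"]]
            .rename(columns={"50%": "median"})
            .round(2)
        )
        lines += ["```", summ.to_string(), "```", ""]
    else:
        lines += ["## Distance summaries", "", "_distances.tsv not found; stage skipped_", ""]

    roc_path = out / "roc.json"
    if roc_path.exists():
        data = json.loads(roc_path.read_text())
        lines += ["## ROC / Youden cutoffs", ""]
        rows = [
            {"group": k, "auc": round(v["auc"], 3),
             "youden_cutoff_mm": data["youden_cutoffs_mm"].get(k)}
            for k, v in data["rocs"].items()
        ]
        lines += ["```", pd.DataFrame(rows).to_string(index=False), "```", ""]
    else:
        lines += ["## ROC / Youden cutoffs", "", "_roc.json not found; stage skipped_", ""]

    conf_path = out / "confusion.tsv"
    if conf_path.exists():
        c = pd.read_csv(conf_path, sep="\t", comment="#")
        lines += ["## Binary agreement at distance cutoffs", "",
                  "```", c.to_string(index=False), "```", ""]

    fit_path = out / "twopart_fit.json"
    if fit_path.exists():
        data = json.loads(fit_path.read_text())["fit"]
        lines += ["## Two-part model", "",
                  f"log-likelihood: {data['loglik']:.2f}; "
                  f"df: {data['df']}; converged: {data['converged']}", ""]
        fit_frame = pd.DataFrame({"name": data["names"],
                                  "estimate": np.round(data["estimates"], 3),
                                  "se": np.round(data["se"], 3) if data["se"] else None})
        lines += ["```", fit_frame.to_string(index=False), "```", ""]
        cpath = out / "contrasts.tsv"
        if cpath.exists():
            cc = pd.read_csv(cpath, sep="\t", comment="#").round(3)
            lines += ["### Post-hoc method contrasts", "",
                      "```", cc.to_string(index=False), "```", ""]
    else:
        lines += ["## Two-part model", "", "_twopart_fit.json not found; stage skipped_", ""]

    path = out / "report.md"
    path.write_text("\n".join(lines))
    return path


def run_all(
    config: PipelineConfig,
    points=None,
    tractograms=None,
    covariates: pd.DataFrame | None = None,
) -> dict:
    """Distances, agreement, two-part model and report in one call."""
    distances = run_distances(config, points, tractograms)
    agreement_out = run_agreement(config, distances)
    cutoff = config.twopart.cutoff_mm
    if cutoff is None:
        cutoff = agreement_out["youden"]["all"]
    twopart_out = run_twopart(config, distances, covariates, cutoff_mm=cutoff)
    report_path = report(config)
    return {
        "distances": distances,
        "agreement": agreement_out,
        "twopart": twopart_out,
        "report": report_path,
    }
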