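"""The full validation pipeline on a simulated cohort.

Simulates a 20-patient voxel-level cohort (5 tractography methods per bundle,
DES-style stimulation points), writes it to disk in the NIfTI/TSV dialect,
and runs distances -> agreement -> two-part model -> report, exactly as the
`tractval run-all` command would.
"""

import tempfile
from pathlib import Path

import tractval as tv
from tractval.synthetic import CohortParams

with tempfile.TemporaryDirectory() as tmp:
    cohort_dir = Path(tmp) / "cohort"
    out_dir = Path(tmp) / "out"
    cohort = tv.generate_cohort(CohortParams(n_patients=20, seed=7),
                                out_dir=cohort_dir)
    print(f"simulated {len(cohort.points)} DES points, "
          f"{len(cohort.volumes)} tractograms "
          f"({len(cohort.truth.failed_reconstructions)} failed reconstructions)")

    cfg = tv.PipelineConfig(
        manifest=str(cohort_dir / "manifest.tsv"),
        points=str(cohort_dir / "points.tsv"),
        out_dir=str(out_dir),
        seed=7,
    )
    res = tv.run_all(cfg, covariates=cohort.covariates)

    print("\nYouden distance cutoffs (patient-averaged, mm):")
    for group in ("all", "CSD", "DTI"):
        roc = res["agreement"]["rocs"][group]
        print(f"  {group:4s} AUC = {roc.auc:.3f}  cutoff = "
              f"{res['agreement']['youden'][group]:.2f} mm")
    # the CSD family reaches its best sensitivity/specificity trade-off at a
    # shorter distance than the DTI family: its masks lie closer to DES sites

    fit = res["twopart"]["fit"]
    i = fit.names.index("A:response[positive]")
    print(f"\ntwo-part model (df = {fit.df}): positive DES sites are more "
          f"likely to overlap the CST, T = {fit.estimates[i] / fit.se[i]:.2f}")
    sig = [(c.label, c.part) for c in res["twopart"]["contrasts"] if c.p_fwe < 0.05]
    print(f"FWE-significant method contrasts (volume-adjusted): {sig or 'none'}")
    # with bundle/lesion volume covariates the dilation-driven CSD advantage
    # of this simulator is absorbed by the volume term, as it should be

    print(f"\nreport written to {res['report']}")
    print((Path(out_dir) / "report.md").read_text().splitlines()[0])
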