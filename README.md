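# tractval

Validation of presurgical white-matter tractography against intraoperative
direct electrical stimulation (DES).

## The problem

During function-preserving neurosurgery, DES is the gold standard for
locating eloquent tissue: a stimulation site that disrupts motor, sensory or
language performance is *positive* (pDES), one with no elicitable response is
*negative* (nDES). Presurgical diffusion-MRI tractography — deterministic or
probabilistic tensor-based methods (FACT, TP, ATP) and constrained spherical
deconvolution methods (iFOD2, AiFOD2) — promises the same map non-invasively,
but different reconstruction methods produce bundles of very different
spatial extent. `tractval` implements the statistical machinery for judging
tractograms against DES ground truth:

1. **Distance scoring** (`tractval.spatial`). Each DES coordinate is handled
   as a 5 mm sphere ROI, collapsed to its center of mass (to undo
   registration deformation) on the patient's 1 mm T1 grid. For every
   eligible tractogram–coordinate pair the minimum Euclidean distance from
   the coordinate to the nearest mask-voxel center is computed and rounded
   up to integer mm (`d = ⌈min_v ‖x − c_v‖⌉`, 0 if the coordinate's voxel is
   in the mask). Positive points pair only with their designated bundle;
   negative points pair with every tractogram of the patient. Bundle and
   lesion volumes, volume-to-TIV ratios, and Dice/Jaccard mask similarity
   round out the geometry layer.

2. **Binary agreement** (`tractval.agreement`). Distance is treated as a
   screening score (`distance ≤ cutoff ⇒ predicted eloquent`): ROC curves on
   patient-averaged distances, Youden-index cutoffs
   (argmax of `sens + spec − 1`, half-integer thresholds on integer
   distances), DeLong tests for paired AUC differences, and confusion-matrix
   summaries (accuracy/sensitivity/specificity/PPV/NPV) at fixed cutoffs.

3. **Correlated two-part mixed model** (`tractval.twopart`). After
   thresholding at the ROC cutoff, distances are semicontinuous — a point
   mass at zero plus right-skewed positive values — with patients
   contributing many correlated pairs. The model couples a logistic part for
   overlap, `logit P(y_ij = 0) = x_ij'α + u_i`, with a lognormal part for
   positive distances, `log y_ij = z_ij'β + v_i + σε_ij`, through correlated
   subject random intercepts `(u_i, v_i) ~ N₂(0, Σ(τ_u, τ_v, ρ))`. The
   marginal likelihood is maximized by adaptive Gauss–Hermite quadrature;
   Wald post-hoc method contrasts use `df = n_subjects − 2` and adaptive
   Hochberg step-up FWE correction.

4. **Synthetic cohorts** (`tractval.synthetic`). A voxel-level generator
   (parametric CST/AF-like bundles in which CSD-like masks strictly contain
   DTI-like ones, pDES points near bundles, nDES points farther with a
   heavier tail, occasional failed reconstructions) and a tabular generator
   that draws *exactly* from the two-part model — both with saved ground
   truth for recovery testing.

5. **Pipeline + CLI** (`tractval.pipeline`, `tractval` command). NIfTI/TSV
   in, TSV/JSON/markdown out, deterministic given inputs and seed.

## Worked example

```python
import tractval as tv
from tractval.synthetic import CohortParams

cohort = tv.generate_cohort(CohortParams(n_patients=20, seed=7))
cfg = tv.PipelineConfig(out_dir="out", seed=7)
res = tv.run_all(cfg, points=cohort.points, tractograms=cohort.volumes,
                 covariates=cohort.covariates)
```

prints (via `examples/04_full_pipeline.py`):

```
Youden distance cutoffs (patient-averaged, mm):
  all  AUC = 0.916  cutoff = 7.70 mm
  CSD  AUC = 0.905  cutoff = 5.60 mm
  DTI  AUC = 0.921  cutoff = 8.93 mm

two-part model (df = 18): positive DES sites are more likely to overlap the CST, T = 6.63
FWE-significant method contrasts (volume-adjusted): none
```

Reading the numbers: the CSD-like family reaches its optimal
sensitivity/specificity trade-off at a markedly shorter distance cutoff than
the DTI-like family (its larger masks lie closer to stimulation sites), the
two-part model confirms that pDES sites overlap the corticospinal tract far
more often than nDES sites, and — in this simulator, where the CSD advantage
is carried entirely by mask volume — the method contrasts correctly vanish
once bundle-to-TIV ratio is adjusted for. On exact tabular draws with a
genuine (volume-independent) method effect, the same contrasts are
recovered as strongly significant (`examples/03_two_part_model.py`).

The same analysis runs from a shell:

```bash
tractval simulate  --out cohort --seed 7
tractval run-all   --config config.yaml --seed 7 --out results
```

Other narrative walk-throughs: `examples/01_spheres_and_distances.py`
(geometry and integer rounding), `examples/02_roc_youden_agreement.py`
(ROC/Youden/DeLong/confusion).

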