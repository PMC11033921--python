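# Methods

This note records the models, conventions and numerical choices behind
`tractval`, and what its synthetic benchmarks do and do not establish.

## Geometry

**Grids and coordinates.** Every volume is a binary mask plus a 4×4
voxel-to-world affine in mm. Voxel indices are 0-based; only the affine is
trusted (RAS is typical but never assumed or enforced). All comparisons run
in each patient's 1 mm working space; the spatial module *rejects*
mismatched grids for overlap metrics rather than resampling silently —
resampling belongs upstream, where interpolation choices are visible.

**Sphere ROIs.** A DES coordinate becomes the set of voxels whose centers
lie within `radius` (default 5 mm, the usual DES sphere convention) of the
coordinate, inclusive of the boundary, evaluated through the affine so
sheared/anisotropic grids are handled exactly.

**COM collapse.** Registration can deform sphere ROIs, so spheres are
collapsed to their center of mass (unweighted mean of nonzero voxel-center
world coordinates) and recreated with the same radius. The recreated sphere
is centered on the voxel center nearest the COM. This half-voxel snap —
below the 1 mm rounding granularity of the distances — is what makes the
operation exactly idempotent: a voxelized sphere at an off-lattice center
has a slightly displaced COM, and without the snap repeated
collapse/recreate cycles drift by a voxel at a time.

**Distances.** The score for a tractogram–coordinate pair is the minimum
Euclidean distance from the (COM-collapsed, by default) coordinate to any
nonzero voxel *center*, rounded **up** to an integer mm; it is 0 whenever
the voxel containing the coordinate belongs to the mask. Rounding up encodes
that sub-voxel increments are not meaningful at 1 mm resolution; a 1e-6
tolerance absorbs float noise before the ceiling so exact integers are not
inflated. An empty tractogram mask raises an error — a failed reconstruction
must surface, never masquerade as "infinitely far".

**Pairing.** Positive DES points pair only with tractograms of their
designated bundle and hemisphere (a motor response says nothing about the
language pathway); negative points pair with all of the patient's
tractograms, since "no response" argues against connectivity to any nearby
bundle. Missing tractograms simply contribute no records.

## Agreement statistics

Distance is a screening score with polarity "small ⇒ eloquent", so the
decision rule is `distance ≤ t ⇒ predicted positive`. Candidate thresholds
are −∞, midpoints of consecutive unique distances, and +∞; on integer
distances this yields half-integer cutoffs, so the ≤ / < distinction never
matters. Sensitivity at `t` is the fraction of pDES cases at or below `t`,
specificity the fraction of nDES cases above it; AUC is the trapezoidal
area, which equals the tie-corrected Mann–Whitney `U/(n₁n₂)`.

The headline ROC pathway first averages distances per patient per response
type, so a patient contributing thirty stimulation sites does not dominate
one contributing three; raw-pair analyses are available alongside.
Confusion-grid summaries at fixed cutoffs always use raw pairs.

The Youden cutoff maximizes `sens + spec − 1` over finite thresholds; ties
(within 1e-9, absorbing float summation noise) break toward the **smaller**
cutoff — the conservative direction for a surgical margin.

DeLong's placement-value estimator provides the variance of AUC differences:
paired mode uses the covariance of per-case placements and drops (and
counts) cases missing under either method; unpaired mode reduces to the sum
of the two single-curve variances. Self-comparison yields exactly z = 0,
p = 1.

## The correlated two-part model

After thresholding at the ROC cutoff (values ≤ cutoff become 0, larger
values pass through unshifted — they are actual distances, not excesses;
a shifted variant is available via `shift_cutoff`), the outcome is
semicontinuous. The model:

* part A: `logit P(y_ij = 0) = x_ij'α + u_i` (probability of overlap),
* part B: `log y_ij = z_ij'β + v_i + σ ε_ij` for `y_ij > 0`,
* `(u_i, v_i) ~ N₂(0, [[τ_u², ρτ_uτ_v], [·, τ_v²]])`, `ε_ij ~ N(0,1)`.

Both parts share the same fixed-effect terms: DES response, tractography
method (reference FACT), and optional continuous nuisance covariates
(bundle-to-TIV and lesion-to-TIV ratios, z-scored by default for
conditioning). The part-B scale is log-mm: distances are strictly positive
and right-skewed, and the lognormal positive part is the standard
semicontinuous formulation. Part A is parameterized as the probability of
*overlap*; some treatments model the probability of a nonzero response
instead, which flips every part-A sign but no magnitude.

**Estimation.** The marginal likelihood integrates `(u, v)` out per subject.
The integral is approximated by adaptive Gauss–Hermite quadrature: per
subject the joint log-density is maximized over the random effects (damped
Newton; the objective is strictly concave), the quadrature grid (default
7 nodes per dimension) is centered at the mode and scaled by the Cholesky
inverse of the curvature, and accumulation is in log space. Benchmarks in
the test suite show 7-node AGH agrees with dense trapezoidal integration to
better than 1e-4 and with 21-node AGH to 1e-3.

The outer optimization is L-BFGS-B on transformed parameters
(log τ_u, log τ_v, atanh ρ, log σ; bounds keep the transforms in a sane
numerical range), with starting values from separate fixed-effects fits — a
GLM logistic for part A, OLS of log y on positives for part B — plus
τ = 0.3, ρ = 0. Convergence is declared at projected-gradient < 1e-5;
non-convergence is reported on the fit object and warned about, never
silent. Estimation is fully deterministic given data.

**Inference.** Standard errors come from the inverse observed information
(central finite-difference Hessian in the natural parameterization, relative
step 5e-4). Wald tests and intervals use a t reference with
`df = n_subjects − n_random_effects` (18 at 20 subjects with two random
intercepts) — the subject-based convention appropriate when random effects
carry the replication structure. Pairwise method contrasts
("FACT versus TP" tests coef(FACT) − coef(TP)) are corrected within each
model part across the 10 pairs by Hochberg's step-up procedure; the default
*adaptive* variant replaces the family size with the Hochberg–Benjamini
lowest-slope estimate of the number of true nulls,
`m̂₀ = min(m, ⌊1/s_j + 1⌋)` at the first decrease of
`s_j = (1 − p_(j))/(m + 1 − j)`. Plain Hochberg (exactly the brute-force
step-up definition, and never below the input nor above Holm) is available
and is the oracle-tested mode.

An optional subject-level response slope in part B (a third, independent
random effect, integrated by 3-D AGH) is provided but off by default:
identifiability is marginal at cohort sizes around 20.

## Synthetic data

**Voxel-level cohort** (`generate_cohort`). Defaults encode the cohort
conditions this package targets: 20 patients on a 64³ 1 mm grid; every
patient contributes a CST-like bundle and, with probability 0.35, an
AF-like bundle; Poisson(2.55) positive and Poisson(6.15) negative points per
patient (51:123 in expectation across 20 patients), 90% cortical; one
reconstruction in ~135 fails. Bundles are parametric tubes with an apical
fan (CST) or sagittal arcs (AF); per-method masks are morphological erosions
(FACT −2, TP −2 with a different structuring element, ATP −1 mm) or
dilations (iFOD2 +1, AiFOD2 +2 mm) of the base bundle, so DTI-like masks are
strict subsets of CSD-like masks. Positive points sit an Exp(10 mm)
(truncated at 30 mm) outward offset from the bundle surface, negative points
4 + Exp(16) mm — scales chosen so that operating characteristics at the
working cutoffs (sensitivity in the 60–95% range, specificity 30–90%
across methods at 12.5 mm) resemble a realistic DES validation cohort.
Anatomical realism is an explicit non-goal: the statistical structure
(nesting, excess zeros after thresholding, right skew, volume-graded method
differences, failure missingness) is the contract.

A consequence worth stating: in this generator the CSD advantage is carried
*entirely* by mask volume, so the volume-adjusted method contrasts correctly
come out null on voxel cohorts. Genuine (volume-independent) method effects
are exercised through the tabular generator.

**Tabular generator** (`generate_semicontinuous`). Draws exactly from the
two-part model: per subject correlated `(u, v)`, per observation a Bernoulli
overlap and, if positive, `y = cutoff + exp(z'β + v + σε)`. With the default
`cutoff = 0` the draw matches the fitted density exactly (the configuration
used for recovery and calibration tests); a positive cutoff produces the
shifted thresholding variant and pairs with the model's `shift_cutoff`.
Default truth: part A intercept −1.5, response +2.0, CSD methods +1.8
logits, τ_u = 1.0; part B intercept 3.2 (≈25 mm), response −0.35,
CSD ≈ −0.3 on log-mm, τ_v = 0.4, σ = 0.45, ρ = +0.5 (with p parameterized
as overlap, patients who overlap more also measure *larger* positive
distances when ρ > 0; the sign is a convention, and recovery tests confirm
it round-trips).

What passing these benchmarks shows — and does not. Parameter recovery and
interval calibration on exact draws validate the estimator, not the model's
fit to any real cohort; the voxel cohorts validate the plumbing and the
qualitative CSD-vs-DTI ordering under a known mechanism, not anatomical
fidelity, registration error, or brain shift beyond the thresholding
rationale.

## Benchmark problem sizes

Chosen as the package's own benchmark design: geometry oracles run 1000
random grids (≤ 10³ voxels, sheared affines); the DeLong check uses 10,000
bootstrap replicates at n = 12 + 12; parameter recovery fits one
200-subject × 40-observation draw and 100 replicates at 100 × 20 for
interval calibration; familywise type-I control uses 200 null cohorts of
20 subjects × 25 observations; the directional end-to-end check uses 8 voxel
cohorts of 10 patients plus 25 power replicates at a 1.5-logit generating
effect.

## Known limitations

* Wald/observed-information inference is mildly optimistic in very small
  cohorts (the df = subjects − 2 t reference compensates only partly);
  profile-likelihood or parametric-bootstrap intervals are out of scope.
* The likelihood treats the part-B density on the log scale without the
  1/y Jacobian; the term is parameter-free, so estimates, SEs and tests are
  unaffected — only the absolute log-likelihood value shifts.
* Integer-rounded distances are modeled as continuous in part B; at 1 mm
  resolution and distances of 13–40 mm the discretization is negligible.
* No spatial uncertainty model for DES coordinates beyond the cutoff
  thresholding rationale; no brain-shift correction.
* The adaptive-Hochberg m̂₀ estimator has no closed-form oracle; only the
  plain step-up mode is oracle-tested, and simulations show the adaptive
  variant keeps the familywise error within its nominal bound under the
  complete null.
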