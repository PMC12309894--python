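# Methods

## The harmonization model

Diffusion MRI signals measured on one b-shell are antipodally symmetric
functions on the sphere, so each voxel's shell signal is represented with
real even-order spherical harmonics (SH) up to order 6 (28 coefficients).
For each even order *l*, the rotational-invariant energy

    L_l = sum_{m=-l..l} c_{l,m}^2

is insensitive to head orientation because a rotation mixes coefficients
orthogonally within an order. Scanner differences in a co-registered
cohort are modeled as voxel-wise multiplicative effects on these
energies: the scaling map

    theta_l(x) = sigma_{l,R}(x) / sigma_{l,T}(x)

maps the target site T onto the reference site R, where sigma is the
expected RISH feature at that voxel. A subject is harmonized by fitting
SH, multiplying each order's coefficients by sqrt(theta_l) (so the energy
is scaled by theta_l exactly), and reconstructing the signal at the
subject's own gradient directions. Shells of a multi-shell acquisition
are treated independently; b=0 volumes pass through unchanged (see
Limitations).

Two estimators of sigma are provided:

* **means** — the conventional estimator: voxel-wise arithmetic mean of
  the training subjects' L_l per site. Valid only when the training
  groups are biologically matched, because any systematic group
  difference (e.g. a 20-year age gap) is absorbed into theta.
* **glm** — per voxel and order, ordinary least squares of L_l on one
  0/1 indicator column per site (no global intercept) plus mean-centered
  covariates. The site coefficients are covariate-adjusted site means, so
  theta_l = beta_{l,R} / beta_{l,T} isolates the scanner effect from the
  modeled biology. Any number of sites is handled in one fit by adding
  indicator columns, and all target-site maps are produced in one step.

With indicators only, OLS returns the group means exactly, so the GLM
estimator nests the conventional one; this algebraic identity is asserted
to 1e-10 in the acceptance suite.

The GLM assumes (i) an approximately linear relation between covariates
and RISH energies within the training range, and (ii) limited
collinearity between site membership and covariates. Both are assumptions
about the training cohort, not the applied subjects. Note that linearity
in L_l does not require linearity between covariates and derived metrics
such as FA.

## Parameters that matter

| parameter | default | meaning / rationale |
|---|---|---|
| `max_order` | 6 | even SH order; 60 directions at b=1000 support 28 coefficients |
| `lambda_reg` | 5e-3 | L2 weight of the SH fit; Laplace–Beltrami penalty `l^2(l+1)^2`, leaving l=0 (the mean signal) untouched — conventional smoothness prior for shell fits. An `identity` penalty is available. |
| `b0_threshold` | 50 s/mm² | vendor-rounding-robust b=0 classification |
| shell tolerance | 100 s/mm² | nominal-b matching window |
| `clip_bounds` | (0.1, 10) | theta clipping; clip counts reported |
| `eps_rel` | 1e-6 | a voxel is valid only where the denominator exceeds `eps_rel x` its mask mean (per order); invalid voxels get theta=1 and pass through |
| covariate centering | pooled mean | site betas become adjusted means at the cohort-average covariate; an uncentered age axis would evaluate the ratio at age 0, a wild extrapolation. The centering record is stored in the model. |

The experiment scripts and acceptance suite fit with `lambda_reg = 0`:
60 well-spread directions over-determine the 28 coefficients (normal
matrix condition number ≈ 1.06), the phantom's injected site effect is
exactly invertible only under the unregularized projection, and shrinkage
cancels in the theta ratio anyway. The nonzero default is for real,
artifact-prone data.

Numerical guards: the fit warns when the normal-matrix condition number
exceeds 1e8 and raises on degenerate direction sets; negative
reconstructed signals are clipped to zero at output (coefficients
untouched) with counts reported; zero-variance voxels in group tests are
excluded and counted.

## The phantom

`rishglm.synthetic` generates the study conditions end to end. Defaults:
16³ voxel grid split into slabs of 70% "white matter" (prolate tensor,
diffusivities 1.7/0.2/0.2 × 10⁻³ mm²/s, FA ≈ 0.87), 20% isotropic "gray
matter" (0.8 × 10⁻³) and 10% "CSF" (3.0 × 10⁻³); S0 = 1; one b=0 plus 60
directions (a fixed electrostatically-optimized set shipped with the
package, minimum separation 18.3°) at b = 1000 s/mm²; two sites of 18
subjects with mean ages 35.4 ± 6.1 vs 56.4 ± 8.5 years and female
fractions 0.44/0.39 — a deliberately age-unmatched design. Biology: WM
radial diffusivity rises 0.3%/year around age 46 (FA falls ≈ 0.2%/year,
in the range reported for adult aging) plus a 2% female offset. Scanner
effect: each non-reference site multiplies the order-l SH energy by a
smooth random field g_l(x) in [0.7, 1.3] (Gaussian-smoothed white noise,
sigma 2 voxels), injected exactly in the SH domain on the noiseless
signal, so the ground-truth scaling map is theta_l = 1/g_l in closed
form. Noise: Rician at b0-referenced SNR 30 (Gaussian and noise-free
modes for linear-theory and exactness tests). The noise/demographics seed
and the effect-field seed are separate, so noise realizations can be
varied while holding the scanner effect fixed.

What the phantom does **not** emulate: real anatomy and partial-volume
ramps (tissue blocks are crisp by design, for exact oracles), crossing
fibers, spatially varying fiber orientation (irrelevant to RISH by
rotation invariance), TE/relaxation-mediated site effects, motion, eddy
currents, ghosting, or registration error. Passing tests therefore
demonstrate correctness of the estimation machinery under the model's own
assumptions, not robustness to acquisition artifacts.

## Evaluation

The diffusion tensor is fitted per voxel by log-linear least squares
(`log(S/S0) = -b g'Dg`, signals floored at 1e-6·S0), FA and MD follow
from the eigenvalues. Cross-site differences are quantified by voxel-wise
t-tests on FA with linear age/sex adjustment — a parametric, deterministic
stand-in for permutation/TFCE inference; the before/after comparison of
significant-voxel fractions is the quantity of interest, not the exact
inference machinery. Whole-WM-block means play the role of skeleton
averages. Recovery against ground truth is summarized as median and 90th
percentile of |theta_hat − theta_true| / theta_true over valid WM voxels.

Experiment sizes (chosen to keep every experiment at desk scale): 16³
grids, 2–3 sites with 15–18 subjects each, order-6 fits — each experiment
in `scripts/acceptance.py` runs in seconds.

## Design choices where the design was open

* **Feature convention**: L_l is the *energy* (sum of squares), not its
  square root; the coefficient multiplier is therefore sqrt(theta_l).
  Consequence: multiplying all target training signals by k scales theta
  by k² (asserted in tests). Site means average L, not sqrt(L); a
  config flag is not exposed because every internal consistency result
  (nesting, equivariance, exact injection) is stated in the energy
  convention.
* **Degenerate voxels**: ratios are formed only where the denominator
  clears the eps guard; elsewhere theta = 1 (identity) and the voxel is
  flagged, never NaN-propagated. Negative site betas survive to the ratio
  and are caught by clipping; they are a symptom of noise-floor orders
  (below).
* **No spatial smoothing of theta maps by default**: the estimator is
  purely voxel-wise; an optional Gaussian smoothing method exists on
  `ScalingMaps` but is never applied implicitly.
* **Reference-site subjects are returned unmodified**, not re-projected
  through the SH basis, so a reference cohort is bit-identical before and
  after harmonization.

## Known limitations

* **High-order energies sit at the noise floor.** A b = 1000 tensor
  signal concentrates its energy at orders 0–2 (for the phantom's WM:
  L0 ≈ 3.7, L2 ≈ 0.52, L4 ≈ 0.017, L6 ≈ 2.6e-4 at S0 = 1), while the
  SNR-30 coefficient noise contributes an energy bias of ≈ 2e-3 to 3e-3
  per order. Per-voxel theta estimates for orders 4 and 6 from ~15
  subjects per site therefore carry double-digit-percent sampling error
  regardless of estimator; order-6 scaling maps are effectively
  noise-dominated at this b-value and SNR. The acceptance suite states
  the 5%-per-order recovery check as specified and the orders-4/6 cases
  fail it for this physical reason.
* **Site–age collinearity inflates GLM variance.** With a 21-year group
  age gap the site indicator and age are strongly correlated (VIF ≈ 3),
  so GLM theta estimates are noisier than mean-ratio estimates at the
  noise-floor orders even though they are ~3× more accurate at orders
  0–2 where the biological confound actually lives. Whether the pooled
  median error of the GLM beats the mean-ratio estimator can therefore
  depend on the noise realization.
* **b=0 volumes are not harmonized**; only diffusion-weighted shells are
  scaled. Metrics normalized by S0 (e.g. MD) are harmonized through the
  shell scaling alone.
* Covariate effects are linear, site-shared, and additive: no
  interactions, nonlinear trends, or site-by-covariate terms; no
  empirical-Bayes shrinkage across voxels.
* The package assumes all inputs are already co-registered on a common
  grid; it performs no registration or resampling, and bvecs are taken
  in the image frame without gradient rotation.
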