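# Methods

This note documents the statistical procedures implemented in `voxdose`,
their assumptions, the parameters that matter, and the design choices made
where more than one reasonable convention exists.

## Setting and data model

All analyses assume a cohort of 3D dose distributions already deformably
registered onto one template geometry; registration itself is out of scope.
A `VoxelGrid` is a scalar field indexed `[x, y, z]` with spacing and origin
in mm; grids are *compatible* when dims match and spacing/origin agree
within 1e-6 mm (registered exports carry float jitter; anything larger is a
real geometry mismatch and is rejected rather than resampled). The
canonical voxel ordering is x-fastest, fixed so that statistic vectors
scatter back into maps bit-stably. NIfTI-1 files are reoriented to
canonical RAS+ axes on read; masks are stored as uint8, everything else as
float32.

## EQD2

Dose grids from different fractionation schemes are made comparable through
the linear-quadratic isoeffective dose in 2 Gy fractions,

    EQD2(v) = D(v) · (d(v) + α/β) / (2 + α/β),   d(v) = D(v) / n_fractions,

with a spatially invariant α/β = 3 Gy (the conventional late-responding
normal-tissue value), exposed as a parameter for sensitivity analyses.
Dose per fraction is computed **per voxel** from the voxel's own total dose,
not from the prescription: that is the standard convention for spatial EQD2
maps and the only one that is self-consistent when phases are summed
voxel-wise. Phases are converted individually and added, giving one
distribution per patient.

## Endpoint derivation

Follow-up is a per-endpoint series of graded visits (grades 0–4). An event
is the first visit strictly later than 3 months with grade ≥ threshold
(threshold 2 by default; 1 for haematuria, where grade ≥ 2 events are too
rare to analyse). "Strictly later" is deliberate: a crossing at exactly
month 3 is baseline-adjacent, not late. Non-events are censored at the last
visit. Exclusions, applied in order and logged per patient: non-EBRT
treatment, baseline grade ≥ 1 for the endpoint, no usable post-window
follow-up. Missing single visits are simply skipped — no imputation — and a
patient is only lost when no post-window visit exists. The time origin is
end of radiotherapy; a cohort whose clock starts at the beginning of
radiotherapy carries that flag through for provenance, since the derivation
itself is clock-agnostic.

## Dose-difference permutation test

At every masked voxel the "locally normalized dose difference" is the
pooled-variance two-sample t statistic (the normalization is pluggable;
pooled-t is the default because it is the canonical max-T construction).
Group labels are permuted uniformly at random with group sizes preserved,
sampled with replacement from the relabeling space; n_perm = 1,000 by
default. The max statistic over the mask — |t| for the default two-sided
test, signed t for the one-sided option — forms the null distribution;
T_α is its (1−α) percentile by the ceiling-rank convention
(k = ⌈(1−α)·n_perm⌉-th order statistic, conservative and reproducible), and
a voxel is significant at α when its observed statistic strictly exceeds
T_α. The observed-max p uses the add-one estimator (1 + b)/(n_perm + 1), so
it is never zero. The α ladder {0.05, 0.1, 0.2, 0.3} reflects how
conservative a global max-statistic threshold is.

Degenerate voxels: zero pooled variance with zero difference gives
statistic 0 (no contrast); zero pooled variance with a non-zero difference
gives ±∞ (fully separated groups — the most extreme evidence, which makes
the small-sample exact example work out). An exhaustive mode enumerates all
C(n, n₁) relabelings (capped, default 10,000) and serves as the exact
oracle for the Monte-Carlo test.

The permutation computation is vectorized: group sums and sums of squares
for all permutations are two matrix products (n_perm × n) @ (n × V), which
makes full FWER calibration studies (hundreds of replicate cohorts)
practical on one CPU.

## Per-voxel Cox maps

At each voxel, patients split at the median of the cohort's dose there;
ties go to the low group (a deterministic rule the data do not dictate).
The Cox model contains the high-dose indicator plus the endpoint's selected
baseline covariates, fit by partial-likelihood maximization with the Efron
tie approximation — visit-grid follow-up guarantees heavily tied event
times, where Efron is the accurate standard. Outputs are an HR map, a
two-sided Wald p map, and overlays of p < 0.05 voxels split by HR
direction. Voxels with constant dose, non-convergent fits, or monotone
likelihood (all events in one group) are flagged non-informative and
excluded rather than aborting the map.

Covariate selection screens the six candidates (age, prescribed dose group,
disease risk, cancer stage, baseline PSA, number of beams) with univariable
Cox fits, retaining Wald p < 0.157 — the AIC-equivalent level. The screen,
its threshold, and an explicit covariate list are all configurable, and the
retained set is logged per run.

No multiplicity correction is applied to the per-voxel p map: it is a
display of raw Wald p-values, and family-wise error control is the
permutation test's job. Consequently, in spatially correlated dose fields
the p < 0.05 overlay flags not only the causal region but also voxels whose
dose co-varies with it (beam paths, shared field edges); the package's own
recovery tests quantify this by checking that detections are enriched in
dose-correlated voxels while FWER-controlled detections stay inside the
true region.

## Multi-voxel LASSO–Cox

All voxel indicators (same median-split rule; constant columns dropped and
logged) enter one Cox model with an L1 penalty. Binary indicator columns
share a scale and are not standardized; the optional continuous-dose design
is standardized. The penalty path has 100 values, equally spaced on a
linear scale from λ_max — computed in closed form as max_j |U_j(0)|/n with
U the Breslow null score, which matches the coordinate-descent solver's
convention exactly — down to λ_max × 1e-3. "Selects every voxel" is not
attainable when voxels outnumber events, so the small-fraction floor stands
in for the all-selected end; both the floor and a log-scale grid are
configurable.

Ten-fold cross-validation with event-stratified, seeded folds scores each
penalty by the Verweij–van Houwelingen deviance: each fold contributes
−2·[ℓ(all data) − ℓ(training data)] at the fold-trained coefficients, with
ℓ the Breslow partial log-likelihood (evaluated by this package's own
stable `logaddexp` implementation, independent of the fitting library).
Both the deviance-minimizing penalty and the largest penalty within one
standard error of that minimum are reported. **Selection defaults to the
one-standard-error convention.** The reasons are empirical and documented:
the CV-minimum's deviance curve is flat near its argmin and the argmin is
noise-driven, so it systematically selects spurious voxels (R's
`cv.glmnet lambda.min` reproduces the identical behaviour on exported
data), whereas the 1-SE rule yields the very sparse selections — frequently
empty — that voxel-level LASSO maps of this kind actually produce. The
CV-minimum remains available via `selection_rule="min"`. An empty selection
is a legitimate outcome, not an error. Path fitting uses scikit-survival's
Coxnet (coordinate descent with warm starts) at tolerance 1e-5; selected
sets were unchanged versus the 1e-7 default in the cases checked, at an
order-of-magnitude less compute.

Baseline covariates are excluded from the penalized model by default (the
voxel-selection model contains only voxel variables); forcing them in
unpenalized is a planned extension, not a default.

## Exemplar selection

Pairwise similarity is the Pearson correlation of voxel values (optionally
within a crop mask); externally computed similarity matrices can be
supplied instead, so registration-quality-based similarities plug in.
Affinity propagation (damping 0.9, max 1000 iterations, convergence window
50, preference = median off-diagonal similarity) clusters the matrix; when
several exemplars emerge, the one with the largest net similarity to all
items is returned. The anti-exemplar is the item least similar to the
exemplar, ties to the lowest index. On matrices with a dominant medoid the
exemplar coincides with the brute-force medoid (argmax of column sums),
which is the test oracle.

## Synthetic cohorts

The generator emulates the structure of registered conformal prostate EBRT
cohorts, not any particular patient set:

- **Dose fields.** 3–7 beams (weights favouring 4-field plans) rotate about
  the cranio-caudal axis through an isocenter in the CTV, each an
  erf-penumbra rectangular profile sized to cover the CTV plus a margin
  (12 mm, jittered up to 8 mm per beam; angles jittered ±30°). The summed
  field is calibrated so the CTV mean equals the arm's prescribed dose
  (66/70/74 Gy at 2 Gy per fraction by default; hypofractionated 57/60 Gy
  arms available), then perturbed by u·∇D with u a smooth random
  displacement field (σ = 4 mm, correlation ≈ 2 voxels) — a proxy for
  residual registration/anatomy variability that vanishes on the flat CTV
  plateau and peaks at field edges, which is where real registered cohorts
  show their inter-patient variance — and finally by 4% lognormal voxel
  noise. The cohort-variance structure (minimal inside the CTV, maximal
  outside) is asserted by test.
- **Covariates.** Age ~ N(68.5, 6²) years, PSA lognormal with median
  14 ng/ml, binary risk/stage with prevalences 0.52/0.31, plus the arm and
  beam count; values chosen to resemble published trial summaries.
- **Outcomes.** Latent event times are Weibull (shape 1.1, scale 300
  months) scaled by exp(β·(d̄ − ref)/10 + γᵀz) where d̄ is the mean EQD2 in
  a planted effect region (default: a small tube inferior to the CTV,
  echoing the extraprostatic-urethra finding purely as a fixture choice),
  β defaults to log 2 per 10 Gy, and γ defaults to a single age effect of
  0.25 per SD. With ref = cohort mean (the default), the marginal event
  fraction stays near the baseline Weibull value (≈ 20% by 84 months)
  regardless of geometry. Latent times are interval-censored to the first
  visit at or after them on the follow-up schedule (3-monthly to 18 months,
  6-monthly to 5 years, then annual; configurable per trial flavour);
  events landing within the 3-month window become baseline-toxicity flags,
  and an independent 5% baseline prevalence is added. Patients outliving
  the schedule are censored at the last visit.
- **Reproducibility.** Every random draw comes from a per-patient stream
  spawned from the master seed, so cohorts are byte-identical under any
  execution order; on-disk cohorts carry a SHA-256 manifest.

What the generator does **not** emulate: treatment-plan optimization,
anatomical imaging, grade trajectories (only the first threshold crossing
and baseline flags are emitted), competing risks, and inter-patient
variation in visit adherence. Passing tests therefore demonstrate that the
statistics behave correctly on proportional-hazards data with localized
dose variability — they do not validate registration accuracy or dosimetric
realism on real cohorts.

## Numerical choices and test scales

- Permutation null distributions are computed by blocked matrix products;
  ±∞ statistics propagate correctly through max and percentile operations.
- The Breslow partial log-likelihood uses a running `logaddexp`
  accumulation, stable for the saturated coefficients that arise at the
  smallest penalties of a linear λ grid.
- Calibration studies in the test suite use sizes chosen to give stable
  rates at desk scale: 200 null cohorts (n = 60, 20×20×10 voxels,
  500 permutations) for the family-wise error band, 200 replicates for
  hazard-ratio recovery, 1,000 single-voxel fits for the type-I rate, and
  50 replicates (n = 300, 501 voxel columns, ~99 events) for LASSO
  selection recovery with a planted log 6 single-voxel effect — a
  deliberately strong effect, as appropriate for a selection power study.
  The acceptance script re-runs the same experiments at reduced replicate
  counts and reports the rates.

## Known limitations

- Inputs must be pre-registered; there is no resampling between
  incompatible geometries, by design.
- The covariate screen stands in for a selection procedure whose original
  specification is not public; it is logged and configurable.
- Proportional hazards is assumed throughout; only a warning hook exists
  for proportionality diagnostics.
- Pooled multi-cohort analyses are naive concatenations (optionally
  balanced by subsampling); no stratification by cohort is applied by
  default.
- Threshold-free cluster enhancement and other local-maximum-sensitive
  alternatives to the global max-statistic test are not implemented.
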