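# Methods

This note documents the models, numerical choices and limitations of
`mcisvm`: what each stage assumes, which parameters matter, what the
synthetic generator does and does not emulate, and where the design was
genuinely open.

## Study design being emulated

A single-site prognostic cohort: N = 55 adults with amnestic MCI at
baseline, of whom 41 remained diagnostically stable and 14 declined to
dementia at follow-up. Baseline data per subject: a T1-weighted volume on
a common grid, a resting-state BOLD time series summarized as 51 atlas
parcels grouped into 7 large-scale networks, an aMCI subtype
(single-domain N = 23 / multi-domain N = 32), and a six-measure
neuropsychological battery in which 27 subjects miss one or two scores at
random. The pipeline predicts the binary outcome from baseline data alone
and maps which brain regions drive the prediction.

## Synthetic cohort generator

Real cohorts of this kind are access-restricted, so the generator
produces data with the statistical structure the analysis assumes, plus
controllable planted effects for parameter-recovery testing.

**Atlas.** An ellipsoid inscribed in the grid forms the "brain" mask
(≈ 4.2k of 8k voxels at the default 20³ grid — small enough that a full
nested cross-validation runs in minutes, while preserving the
voxels ≫ subjects regime of the real analysis). The mask is tiled into
parcels by nearest-centroid (Voronoi) assignment around seeded random
centroids, so every parcel is non-empty and roughly convex; parcels are
dealt to networks so each network receives at least one parcel.

**T1 volumes.** Uniform tissue intensity (100) plus iid Gaussian voxel
noise (`noise_sd`, default 1). A planted structural effect lowers the
decline class's mean intensity in designated parcels by
`t1_effect_size × noise_sd` — so the effect size is a standardized mean
difference per voxel. Note the direction: decliners lose signal, so
*preserved* intensity predicts stability and the recovered SVM weights in
planted parcels are positive (stability side); ranking operates on
contribution magnitudes and is unaffected.

**Time series.** T × R Gaussian mixtures of latent signals: every parcel
loads (a = 0.3) on its network's latent series, giving weak within-network
correlation (~0.09); parcels in a designated effect pair additionally
share a pair latent with correlation `conn_base_corr` (default 0.2) in
the stable class and `conn_base_corr + conn_effect_size` in the decline
class. No BOLD autocorrelation, drift or motion structure is simulated —
only the cross-correlation structure matters downstream, because features
are correlations. Consequently, passing tests demonstrate correctness of
the machinery under exchangeable Gaussian noise, not robustness to the
artifacts of real fMRI.

**Determinism.** Each subject's data comes from its own random
sub-stream keyed to (seed, subject index); cohort size and generation
order cannot alter any subject's data, and fixtures are byte-stable.

**Neuropsychological battery.** Six standard-normal scores; the decline
class's column means are shifted by `group_shift`. Exactly
`n_incomplete` subjects (chosen uniformly, independent of label — i.e.
MAR by construction) receive 1 or 2 missing cells. Subtype is Bernoulli
per class with the single-domain rates of the emulated cohort
(51.2% stable / 14.3% decline).

## Feature construction

T1 features are all in-mask voxel intensities in a fixed scan order
(first grid axis fastest, i.e. Fortran flattening), documented so weight
maps round-trip bit-for-bit. Connectivity features are Fisher
z-transformed Pearson correlations (sample correlation, denominator
T−1) of all R(R−1)/2 unordered pairs in row-major upper-triangle order;
|r| is clipped at 1 − 1e−7 before atanh so perfectly correlated inputs
stay finite. With 51 parcels this yields 1,275 connections.

## Selection, standardization, classifier

**t-test filter.** Pooled-variance Student's t per column (Welch
available via `variant="welch"`), two-sided p, keep p < α = 0.01, no
multiple-testing correction — the filter is deliberately liberal because
the SVM, not the filter, is the classifier. Zero-variance columns have an
undefined statistic and are dropped rather than producing NaNs; a column
with zero within-class variance but distinct class means gets p = 0 and
is kept.

**Standardization.** Column z-scores with mean/SD (ddof = 1) from the
training rows only, applied after selection. Constant training columns
are centered with divisor 1 instead of producing NaN.

**Class costs.** cost(class) = N/(2·N_class). This reproduces
"proportional" minority up-weighting, is invariant to total N, and gives
(1, 1) for balanced samples. At 40/14 training counts the decline
multiplier is 1.93 vs 0.68 for stable.

**SVM.** The primal objective is ½‖w‖² + Σ C·cost(y_i)·max(1 − y_i(wᵀx_i
+ b), 0)² — the squared hinge is the model; an unsquared-hinge mode
(`loss="hinge"`, solved as a constrained QP in the representer form,
small instances only) exists purely for sensitivity analysis and is
cross-checked against an independent kernel-SVM reference in the tests.
The squared-hinge solver is a
damped Newton method on the representer parametrization w = Xᵀβ (the
optimum lies in the span of the training rows, so the problem is
(N+1)-dimensional whatever the feature count), with backtracking line
search and a convergence criterion of relative objective decrease
< 1e−8. Warm starts across a C grid only change speed — the objective is
strictly convex in (w, b) on the active set and the minimizer is unique.
`qp_oracle` solves the identical objective with scipy's L-BFGS-B
(analytic gradient, tight tolerances) and is used in tests only;
agreement is enforced to 1e−6 in objective value. Because the squared
hinge is C¹ but not C², the oracle judges convergence by final gradient
norm rather than the library's status flag.

**Ties.** A decision value of exactly 0 is reported as +1 (stable) and
logged; under continuous features this is a measure-zero event and the
convention only matters for degenerate inputs.

## Nested cross-validation

Outer loop: leave-one-out (deterministic, identical across repetitions).
Inner loop: stratified 10-fold over the N−1 training subjects (per-class
shuffled round-robin assignment, fold sizes within ±1). For each inner
split the full pipeline — filter, standardizer, class costs, SVM — is
refit on the inner training rows; C is chosen to maximize mean balanced
accuracy over inner folds (balanced accuracy because the design is
unbalanced), ties toward the smallest C. The chosen C then drives a refit
on all N−1 training subjects, which predicts the held-out subject. Ten
repetitions re-randomize only the inner assignments; headline metrics
are means over repetitions, with pooled-prediction metrics also emitted
(the two aggregations are both reported because either convention is
defensible). Default C grid: 2⁻⁵ … 2¹⁵ in powers of two (21 points).

Inner splits whose training side has fewer than two members of either
class are skipped in the C score — with very small subgroups
(e.g. two decliners) leave-one-out plus a two-sample test is simply not
well-defined, and the stratification error is raised rather than silently
degraded.

Leakage guards are structural, not incidental: masks, standardizers,
costs and C are functions of training rows only, and tests assert that
arbitrarily perturbing any held-out subject changes nothing fitted.

## Metrics

Decline (y = −1) is the event class everywhere: sensitivity is the
detection rate of decliners, precision/F1 follow, and the
precision-recall curve scores the negated decision value (more negative =
more decline-like). MCC uses the standard formula with the convention
MCC = 0 when a marginal is zero. The PR curve groups tied scores into one
threshold and integrates precision over recall steps (average
precision); for constant scores the curve degenerates to one point and
the area equals the event prevalence.

## Weight mapping

A final model is trained on all subjects (mask and standardizer fitted on
the full sample; C chosen by the same inner procedure applied to the
full sample, since no outer criterion exists for a deployment model).
Positive and negative weights are normalized separately to percent
contributions summing to 100% per sign class. Parcels are ranked by
**average voxel percent contribution over all voxels of the parcel** —
selected voxels carry their contribution magnitude, unselected voxels
carry zero. Averaging only over selected voxels was considered and
rejected: a parcel containing a single spuriously selected voxel then
routinely outranks a parcel whose genuine signal spans many voxels
(measured 0/20 planted-parcel recovery versus 20/20 with the all-voxel
denominator), which defeats the purpose of the ranking as a localization
tool. A secondary column reports each parcel's share of selected voxels
by count, and the small-strong vs large-weak dissociation (high mean
contribution, low volume share) remains expressible. Connectivity
weights have no unique voxel embedding and are reported in a separate
parcel-pair table rather than painted into the volume. The display
volume keeps the top `ceil(top_fraction × n_selected)` voxels by
contribution magnitude (default 50%).

## Neuropsychological data

Class-mean filling imputes a training subject's missing score from the
observed mean of that subject's diagnostic class; a held-out subject's
class is precisely what the classifier must predict, so held-out cells
are filled with the overall training mean instead. A `paper_faithful`
flag reproduces the full-sample class-mean variant — which leaks outcome
information into the features — for comparison only. List-wise deletion
drops incomplete subjects and recomputes the class costs from the
survivors. The combined model appends the six battery columns to the
imaging matrix untransformed; they are z-scored by the fold-internal
standardizer along with every other selected feature, because any global
pre-standardization would use all-subject statistics.

## Contingency statistics

The subtype-by-outcome table is reconstructed from the group sizes and
printed single-domain percentages (41 × 51.2% → 21, 14 × 14.3% → 2,
nearest integer), giving [[21, 20], [2, 12]]. Pearson chi-square without
continuity correction (df = 1) on this table is 5.85, p = 0.016. The odds
ratio is reported as computed, ad/bc = 6.3, without Haldane correction
(no zero cells).

## Problem sizes

Defaults mirror the study design (55 subjects, 51 parcels, 7 networks,
α = 0.01, inner k = 10, 10 repetitions, 21-point C grid). The test suite
and acceptance script use the package's own smaller Monte-Carlo scales
where a check does not depend on the full design: nested CV checks run
with 1–2 repetitions and an 11-point grid (every second power of two),
null-calibration checks use a 10³ grid with 8 parcels, and the
permutation-null check uses 24–32 permutations because the
per-permutation MCC of a 21-subject cohort has a standard deviation near
0.35 and a smaller sample cannot localize the mean. A full 10-repeat
multimodal nested cross-validation at study scale completes in roughly a
minute on one CPU.

## Known limitations

- The generator produces exchangeable Gaussian data; no scanner
  artifacts, motion, autocorrelated BOLD, site effects, or realistic
  intensity inhomogeneity. Passing parameter-recovery tests validates
  the machinery, not clinical performance.
- The real cohort's headline accuracies are not reproducible from
  synthetic data and are not targets of any test.
- Subgroup re-evaluation requires both classes with ≥ 2 members in every
  training split; subgroups with a near-empty class raise a
  stratification error instead of returning unstable numbers.
- No nonlinear kernels, no probability calibration, no surface
  rendering or anatomical naming beyond the atlas table.
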