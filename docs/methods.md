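# Methods

## Scope and data model

The unit of analysis is the patient record: clinical covariates, right-censored
progression-free survival in weeks (time counted from the preoperative MEG;
patients without observed progression are censored at last contact), a
cohort-based z-score of global broadband (0.5–48 Hz) oscillatory power, and an
ordinal NLGN3 expression grade (low / moderate / high) from tumor
immunohistochemistry, missing for patients without usable tissue. The packaged
cohort has 24 such records; 17 progressions; NLGN3 graded in 21 (12/6/3).

The imaging front end operates on one shared voxel grid: an integer atlas
volume (0 background, 1..78 parcels) and a binary tumor mask per patient. All
volumes are voxel-indexed and 0-based; co-registration of the atlas and mask
onto individual anatomy happens upstream and is out of scope, as are sensor-
level MEG processing and beamforming.

## Activity scores

Per-region broadband power is the Welch PSD integrated over the band
(trapezoid rule). Welch parameters — 4 s Hann segments, 50% overlap — are
conventional resting-state choices; any consistent estimator works because all
downstream statistics are invariant to positive rescaling after z-scoring.
"Absolute power" means the band-integrated PSD in squared signal units, not
relative power.

The peritumor set of a patient is every atlas parcel with at least one voxel
inside the tumor mask dilated twice by the 3×3×3 box structuring element (the
standard default dilation neighborhood in FSL-style mask tooling; both the
iteration count and an optional minimum-overlap voxel threshold are
parameters). Parcels fully inside the tumor core are included: the peritumor
measure covers the tumor and its surround. The three raw scores are arithmetic
means of parcel powers (peritumor set, all parcels, complement), so the exact
identity `R·global = |S|·peritumor + (R−|S|)·nontumor` holds and is asserted
per patient. An empty peritumor set (mask over background only) is an error at
scoring time.

Z-scoring uses the cohort's own mean and SD (divisor n−1). A reference variant
`(x − μ_ref)/σ_ref` supports normalization against an external control cohort;
because it is affine, hazard ratios transform by the SD ratio only. The
packaged table carries only cohort-based z-scores (control raw values are not
available), so the reference variant is exercised on synthetic data.

## Rank tests

Mann–Whitney U is reported as `min(U₁, U₂)` — the convention of mainstream
clinical statistics packages, and the only convention consistent with the
reference values reproduced here. For pooled samples of ≤ 25 untied
observations the two-sided p is exact: the null distribution of U is built by
the integer counting recurrence `f(n₁,n₂,u) = f(n₁−1,n₂,u−n₂) + f(n₁,n₂−1,u)`,
and p = min(1, 2·P(U ≤ u)). Doubling the lower tail is the standard two-sided
rule and is what resolves the 3-vs-6 comparison (p = 2·2/84 ≈ 0.048) that a
normal approximation misses. With ties or larger samples, the tie-corrected
normal approximation is used and flagged in the result. Kruskal–Wallis uses
midranks with the `1 − Σ(t³−t)/(N³−N)` tie correction and a χ²(k−1) p-value.
No multiplicity correction is applied to the pairwise post hocs, matching the
analysis being reproduced. The two-sample t-test (pooled by default, Welch
optional) exists for patient-vs-control comparisons on synthetic data.

## Survival analysis

The Cox model is fit by safeguarded Newton–Raphson on the partial likelihood
with analytic gradient and Hessian. Ties: Breslow by default — the packaged
cohort has two events at 54 weeks, and Breslow is what SPSS/SAS-style software
applies, which the reproduced hazard ratios require — with Efron optional; the
two coincide exactly on untied data (tested). Convergence: gradient norm
< 1e−8, at most 50 iterations, step-halving whenever a Newton step would
increase the negative log partial likelihood (acceptance tolerance relative,
1e−9·max(1,|ℓ|), since near the optimum the objective moves only at rounding
level). A post-fit guard flags monotone likelihoods: |β|·SD(x) > 10 (a hazard
ratio beyond e¹⁰ per SD means risk ordering follows the covariate perfectly)
raises a convergence error rather than reporting a meaningless Wald SE.
Inference is Wald (SE from the inverse Hessian, 95% CI `exp(β ± 1.96·SE)`),
matching the convention of the reproduced tables. Missing covariates are
dropped listwise per model and the count is carried on the fit. Bivariate
confounder models are the same engine at p = 2 with a rank check.

Kaplan–Meier is the product-limit estimator over distinct observed times; the
curve median is the first time survival reaches ≤ 0.5 (undefined if never).
The median-split utility dichotomizes at the sample median with ties assigned
to the low group. "Median PFS 87 ± 86" is the median and SD of observed event
times with censored records excluded — this convention, not the KM median,
reproduces the packaged cohort's value exactly and is the one adopted.

## Validation machinery

Leave-one-out refits the univariate model n times, excluding one patient each;
the spread of Wald p-values shows whether any single patient carries the
result. The permutation null shuffles the predictor across patients while
keeping each (time, event) pair intact — censoring stays attached to its time
— refits per shuffle, and summarizes with the add-one empirical p-value
`(1 + #{p_perm ≤ p_obs})/(B+1)`, which is never exactly zero and is valid at
any B. Non-convergent permuted fits are redrawn and counted. The permutation
RNG is seeded and the seed recorded; under an exchangeable predictor the
empirical p is uniform, which is tested by KS on replicate synthetic nulls.

## Synthetic cohorts

The generator emulates the study conditions end to end. Geometry: an
ellipsoidal "brain" foreground on a 32³ grid partitioned into 78 contiguous
parcels by seeded breadth-first flood fill (contiguity and nonemptiness hold
by construction); tumors are random ellipsoids rejected unless they overlap
the atlas. Signals: per region, unit-variance 1/f (pink) noise plus a 10 Hz
alpha oscillation — the minimal resting-state-like spectrum; nothing
downstream depends on the exact shape, only on band power being controllable —
with per-patient amplitude `exp(g·z)` (gain g = 0.15 by default) so that
broadband power is monotone in the latent activity z. Survival: Weibull
proportional hazards, `T = λ(E/e^{βz})^{1/k}`, default shape k = 1
(exponential; the Weibull form is kept so shape misspecification can be
probed), scale λ = 125 weeks so the z = 0 median is ≈ 87 weeks, and default
β = ln 2.10 per SD. Censoring is an independent uniform administrative horizon
U(0, h) with h calibrated by bisection against the analytic marginal survival
so the overall censoring probability equals the configured rate; the default
0.3 matches the cohort's 7/24 censored. NLGN3 tiers cut `z + ε`,
ε ~ N(0, 0.5²), at thresholds (0.20, 1.19) — the latent-scale quantiles at
cumulative shares 12/21 and 18/21 — giving expected tier counts ≈ 12/6/3 at
n = 21; a helper computes thresholds for any prevalence/noise combination.
Identical config and seed reproduce a cohort bit for bit.

What the generator does not emulate: spatial correlation of power between
parcels, non-proportional hazards, informative censoring, covariate-dependent
NLGN3 grading error, and realistic tumor shapes. Passing tests therefore show
the pipeline's correctness and calibration under the assumed model, not
robustness to violations of it.

## Calibration studies and problem sizes

Monte-Carlo checks run at desk scale, chosen to keep the full suite in a few
minutes while leaving tolerances meaningful: Wald 95% CI coverage of the
generating log-HR is measured over 1000 cohorts of n = 200 at default (30%)
censoring and must land in 93–97% (measured: 94.5%); recovery of the
generating hazard ratio within [1.9, 2.3] must hold in ≥ 90% of 200 cohorts of
n = 500 and is run with complete follow-up — with ~350 events under 30%
censoring the SE of the log-HR is ≈ 0.061, the band is only ±1.5–1.6 SE wide,
and the expected pass rate falls to ≈ 88%, so the censored setting cannot meet
the band and the study isolates estimator recovery from follow-up truncation
(measured at n = 500 complete follow-up: 92%). The exact-U null is checked
against full enumeration for every group-size pair with n₁+n₂ ≤ 12.

## Encodings and known quirks of the packaged cohort

Confounder encodings follow the source definitions: age ≤ 40, KPS ≤ 80, WHO
grade II vs III–IV, histology ordinal (O=1, OA=2, A/GBM=3), adjuvant treatment
ordinal by intensity, tumor volume in cm³. 1p/19q codeletion combines the nine
assessed statuses with the retrospective rule that IDH1-mutant astrocytomas
without assessment count as non-codeleted; the resulting WHO-2016 molecular
3-group variable (mutant-codeleted / mutant-non-codeleted / wildtype) is
defined for exactly 18 of the 24 patients — which matches the N reported for
the molecular confounder model even though IDH1 status alone is known for 21
(mutant status without codeletion information and non-astrocytoma histology
leaves the group undefined for three patients). Event status is an explicit
boolean column (the source table encodes it typographically, which does not
survive CSV). The NLGN3 Cox model over the low/moderate subset is available
through the generic engine with either tier as indicator, but no reference
value is attached to it because the original coding is not stated.

## Limitations

Small cohort: all reproduced inferences inherit the width of 24-patient
confidence intervals; the permutation and leave-one-out machinery quantify but
cannot remove that. The peritumor/non-tumor hazard ratios and the
control-referenced fit require per-region or control raw data that are not
printed in any recoverable form, so they are validated structurally on
synthetic cohorts rather than numerically. The Cox engine covers time-fixed
covariates only — no stratification, time-varying effects, frailty, or
proportionality diagnostics.
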