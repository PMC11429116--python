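# Methods

## The screening problem

Quiet-standing posturography records the center of pressure (CoP) under a
subject on a force platform as two displacement series, medio-lateral (ML)
and antero-posterior (AP), in millimetres at a fixed sampling rate
(100 Hz, 60 s by default). Subjects aged 60+ are labelled *Fall Risk* if
they reported at least one fall in the previous 12 months and/or high
concern about falling on the Short FES-I questionnaire, and *Non-Fall
Risk* otherwise. The package builds a trial-level feature table — 40 CoP
indices plus 7 descriptive variables (sex, age, height, weight, BMI, foot
length, polypharmacy) — and trains a Gaussian Bayes classifier whose
feature subset is chosen by a simulated-annealing wrapper.

## CoP indices

Both axes are mean-centred; the resultant distance is
RD[i] = √(AP[i]² + ML[i]²), duration T = N/fs with 0-based indexing.
Time-domain measures follow the classical definitions: mean distance
(mean RD; mean |axis| per axis), RMS distance, standard deviations
(sample N−1 per axis; for RD, s_RD = √(RMS² − MDIST²), the population SD
of RD, so RMS² = MDIST² + s_RD² holds by construction), total excursion
(Σ√(ΔAP²+ΔML²); Σ|Δ| per axis), mean velocity (excursion / T), range (the
exact planar diameter of the path, computed on the convex hull with a
principal-axis fallback for collinear paths; max − min per axis), the
AP–ML cross-covariance s_APML = (1/N) Σ AP·ML, the 95% confidence circle
area π(MDIST + 1.645 s_RD)², the 95% confidence ellipse area
2πF√(s_AP² s_ML² − s_APML²) with F fixed at 3.00 (its large-sample value;
the exact F(0.05; 2, N−2) differs by <0.3% for N in the thousands), and
the sway area (1/2T) Σ|AP_{i+1}ML_i − AP_iML_{i+1}|. Hybrid mean
frequencies are MVELO/(2π·MDIST) for RD and MVELO/(4·MDIST) per axis —
the rotation/oscillation rate of a point travelling the measured path at
the measured mean distance. The mixed SD conventions (sample per axis,
population for RD and the cross-covariance) are deliberate and asserted
in tests.

Frequency-domain measures use spectral moments μ_k = Σ f^k G(f) Δf over
the analysis band, 0.15–5.0 Hz by default (configurable): total power μ₀,
50%/95% power frequencies (smallest band frequency whose cumulative power
reaches that fraction of μ₀), centroidal frequency √(μ₂/μ₀), and
frequency dispersion √(1 − μ₁²/(μ₀μ₂)), a unitless quantity bounded in
[0, 1] by the Cauchy–Schwarz inequality (0 for a pure tone, 0.5 for an
ideal flat spectrum). The default estimator is a Welch averaged
periodogram (Hann window, 2048-sample segments at 100 Hz, 50% overlap),
which stabilizes moment estimates; a raw-periodogram mode exists for
closed-form oracle tests. Degenerate inputs (flat trials, zero in-band
power) yield NaN for the affected shape indices with a warning rather
than an exception.

## Dataset assembly

Records are trial-level: repeated trials of one subject are separate rows
sharing the subject's label. To balance the classes by record count,
at-risk subjects contribute their 3 earliest trials and non-risk subjects
their earliest trial (`nfr_keep=1`) by default; `nfr_keep=2` yields the
balanced 181-record composition (87 at-risk + 94 non-risk from a
29/47-subject cohort) used by the acceptance script. Subjects with fewer
trials than requested keep all they have, with a warning. Rows with
missing feature values are rejected rather than imputed. Splitting is
stratified at the record level; a subject-level grouping option exists
because repeated trials of one subject otherwise span splits.

## Classifier

Features are z-scored with mean/SD fitted on the training rows only and
applied unchanged to the held-out rows (a whole-table mode exists for
strict-reproduction comparisons). Only the at-risk class is
parameterized: μ and the sample covariance S over the selected features
come from the at-risk training rows; the score PFR = 0.5 · N(x; μ, S) is
a prior-weighted density, *not* a normalized posterior — it can exceed 1
— but the decision rule PFR > 1 − PFR reduces to thresholding at 0.5 and
ROC analysis only uses its ordering. A consequence worth knowing: with
k ≥ 2 and a near-unit covariance the density never reaches 0.5, so the
rule only produces positive predictions when the at-risk class is
*compact* in the selected subspace (small |S|). AUC is therefore the
primary metric; a normalized two-Gaussian posterior mode is available as
an option. Evaluation is in the log domain via Cholesky factorization; a
ridge of 1e−6 (escalated tenfold until the smallest eigenvalue clears
1e−8) is added when S is near-singular or when there are fewer than k+2
at-risk rows, and every application is logged. Ties in the decision
(PFR = 0.5 exactly) go to the non-risk class. The AUC uses the rank
(Mann–Whitney) formulation with ties counted ½, identical to trapezoidal
ROC integration.

## Feature selection

The cost of a subset is mean − sample-SD of the three AUCs on the
stratified 60/20/20 train/test/validation split (largest-remainder
per-class allocation, shuffled by seed), penalized to exactly 0 when any
of the six sensitivity/specificity values falls below 0.6. Subtracting
the spread rewards subsets that generalize consistently. The split is
frozen across the whole sweep for comparability.

The annealer draws fresh uniform n-subsets (a global neighbourhood; a
single-swap local mode exists but is off by default), accepts
improvements always and deteriorations with probability exp(ΔE/T), cools
geometrically (T ← 0.82·T) from T₀ = 0.5979 until T ≤ 0.0232 — 17
temperature levels — and performs round(Lk) evaluations per level with
Lk growing from 30 by the factor 2 − e⁻¹ ≈ 1.632 per level (≈196k
evaluations per dimension at the defaults). Every evaluated cost is
recorded and the returned optimum is the maximum of the whole history,
independent of the acceptance trajectory. An `as_printed` mode reproduces
a literal single-loop variant in which the temperature cools every
iteration and the candidate cost is replaced by the running maximum
before the acceptance test (making the downhill branch unreachable); it
is retained for comparison only. The dimension sweep starts at n = 11
from a fixed evidence-based solution (sex, BMI, age, polypharmacy, total
length ML/AP, 95% confidence ellipse area, mean velocity RD/AP, mean
frequency, RMS distance), warm-starts each next dimension with the
previous optimum plus one random unused feature, and stops after three
consecutive dimensions without best-cost improvement. Search-space sizes
are exact binomial coefficients C(m, n) in arbitrary precision.

## Validation statistics

Bagging fits B = 150 members by default, each on a with-replacement
resample of the training rows (resamples with no at-risk row are redrawn
and logged), and aggregates by mean PFR (soft voting) so the ensemble AUC
is well defined; a majority-vote mode exists for sensitivity/specificity
comparisons. Member-set metrics are computed on the original hold-out
sets, not out-of-bag. Univariate logistic regressions are fitted by IRLS
(tolerance 1e−8, ≤100 iterations); perfect separation is flagged and the
coefficients capped at ±25 on the z-scale, with the AUC still reported.
The Hosmer–Lemeshow test groups rows into g = 10 near-equal risk groups
by fitted probability (ties share the lower group; groups with zero
expected counts merge with a neighbour) and refers the statistic to
χ²(g−2). Two-group comparisons route continuous variables by a
Kolmogorov–Smirnov normality check of the z-scored values against the
standard normal (p < 0.05 → Mann–Whitney, else t-test; note that because
the location and scale are estimated from the same data, this routing is
anti-conservative for borderline cases — a known limitation);
categorical variables use χ² without continuity correction by default.

## Synthetic cohorts

Each trial is second-order Butterworth low-pass-filtered Gaussian white
noise per axis (cutoff 1 Hz baseline), rescaled to a target RMS (4 mm AP,
3 mm ML) and multiplied by an independent unit-mean lognormal amplitude
per axis with coefficient of variation 0.4 — the dominant feature of real
cohorts the generator reproduces is this large inter-subject overlap in
sway magnitude; the amplitudes are drawn independently per axis so that
no noise-free axis-ratio signature separates the classes. At-risk
subjects apply multiplicative `effect_map` shifts to per-axis gain and/or
cutoff. Descriptive variables are drawn independently per subject from
normal marginals (age 71.3 ± 6.4 y, height 157.2 ± 8.1 cm, weight
63.1 ± 8.4 kg, foot length 22.6 ± 1.3 cm, polypharmacy 2.3 ± 1.6,
women with probability 0.789); BMI is derived from weight and height;
fall history and the concern flag are generated consistently with the
labelling rule. Trials are i.i.d. given the subject's class, and the
realized at-risk count is exactly round(n·p).

What the generator does *not* emulate: inverted-pendulum biomechanics,
within-subject trial correlation, correlated descriptive variables
(marginals only), eyes-closed/soft-surface conditions, and the heavy
right tails of real power distributions. Passing tests therefore
demonstrate the correctness and internal consistency of the pipeline and
the detectability of planted effects of known size — not clinical
performance on real cohorts.

## Problem sizes and numerical choices

The test suite and the acceptance script choose sizes that exercise every
code path at full fidelity while completing comfortably on one CPU:
full-schedule annealing is exercised on a cheap planted-oracle cost
(100 seeded runs over a 10-feature pool); classifier-in-the-loop sweeps
use a reduced schedule (Lk₀ = 10, T_min = 0.1, ≈2100 evaluations per
dimension) on 180-record tables; cohort-level Monte-Carlo checks use 20
replicate cohorts of 60 subjects (10-s trials) for the null case and 200
records (60-s trials) for planted-signal detection; Hosmer–Lemeshow
calibration uses 500 replicates of n = 500. Tolerances: spectral oracles
to one frequency bin; sinusoid velocity to 1%; Parseval to 5%; algebraic
identities to 1e−10 relative; AUC-formulation equivalence to 1e−12.
Ridge, capping and tie-break conventions are stated above where they
arise.
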