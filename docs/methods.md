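# Methods

This note documents the models and procedures implemented in `strideboard`,
the parameters that matter, and the choices made where the design was
genuinely open.

## Scores and board aggregation

The SMS is the sum of six ordinal subscores (trunk, leg, arm, speed,
fluency, stability), each rated 0–3 by five raters. The board value of a
subscore is the mode of the five recommendations. With five raters over four
levels, the only ambiguous count pattern is 2-2-1; the singleton value `t`
then decides: if `t` lies strictly between the tied values it is returned
(compromise), otherwise the tied value nearer to `t` wins (weight). Because
the tied values are distinct integers and `t` lies outside their interval in
the weight case, "nearer" is always well defined; the exhaustive
enumeration over all 4⁵ panels in the test suite verifies that the tie
branch fires exactly when no unique mode exists. Panels of any size other
than five are rejected: the rule is only fully determined for five raters.

## Synthetic cohort generator

The generator emulates a hemiparetic stroke cohort measured on an
instrumented walkway. It exists so that every downstream stage can be tested
against a known ground truth; it is a statistical stand-in, not a
biomechanical simulation.

**Latent severities.** Each patient draws θ_k ∈ [0, 3] for the six subscores
from a Gaussian copula with uniform marginals and inter-subscore correlation
ρ = 0.5 (default), reflecting that globally impaired patients tend to score
high on several criteria. No published severity distribution exists for this
setting; the uniform-marginal copula is the package's own choice.

**Kinematics.** Each of the 18 joint angles per side has a normative
template: an analytic gait shape (sinusoids and periodic bumps, e.g. the
knee's small stance flexion bump and large swing peak) projected onto at
most five Fourier harmonics. Severities modulate the templates linearly:

| coupling | default | effect at θ = 3 |
|---|---|---|
| `leg_amplitude` | 0.50 | −50 % ROM of pelvis/foot/hip/knee/ankle angles (ipsilateral) |
| `arm_amplitude` | 0.60 | −60 % ROM of shoulder/elbow angles (ipsilateral) |
| `trunk_lean_deg` | 8.0 | +8° thorax/spine offset, −30 % axial ROM |
| `fluency_wobble_deg` | 3.0 | 3° seventh-harmonic wobble on all angles |
| `stability_sway` | 0.8 | +80 % trunk-sway / pelvis-obliquity amplitude |
| `speed_stride_time_s` | 0.50 | +0.50 s stride time |
| `speed_stride_length_m` | 0.60 | −0.60 m stride length |
| `stability_stance` | 0.08 | +8 percentage points stance fraction |
| `leg_asymmetry` | 0.06 | contralateral foot strike at 56 % instead of 50 % |

The contralateral side receives 35 % of the ipsilateral modulation
(bilateral involvement is attenuated, not absent). Per-sample Gaussian
jitter (σ_kin, default 1°) is added; the last sample repeats the first so
traces are exactly periodic. Walking-cane and AFO use are Bernoulli with
logistic probability in θ_stability (midpoints 1.7 and 2.3, slope 2.2).
Rater recommendations are `clip(round(θ_k + ε), 0, 3)` with
ε ~ N(0, σ_rater), σ_rater = 0.25 by default, five i.i.d. draws per
subscore.

The fluency wobble amplitude (3°) was set so that the seventh-harmonic
signature remains detectable in NAV statistics above the 1° sample jitter;
at 1.5° the jitter dominates the NAV features and the fluency subscore
carries almost no recoverable signal.

**What the generator does not emulate:** marker artefacts, soft-tissue and
filtering effects, trial structure and fatigue, inter-stride correlation
beyond patient-level parameters, non-linear or interacting severity effects,
and rater identity/bias. Passing the recovery tests therefore shows the
pipeline recovers planted monotone couplings at realistic noise levels — not
that it reaches any particular accuracy on real patients.

**Default sizes.** 100 patients, 4–12 strides per patient and side (pairs
form from consecutive strides, so each patient yields at least 2 usable
stride pairs), one continuous stride sequence per patient.

## Feature extraction

NAV is computed by central differences on the 101-point normalized cycle
grid (one-sided at the endpoints) — second order and exact on linear traces.
The stance window is [0 %, stance_fraction·100 %], the swing window the
remainder; the boundary sample belongs to both windows (closed windows).
Medians are sample medians (mean of the two central values for even
counts).

The 15 per-side gait parameters are gait speed, cadence, stride time, step
time, single/double support times and percentages, height-normalized step
width, leg-length-normalized step and stride lengths, limp index, start of
swing, and stance/swing durations. The limp index is defined here as the
side's stance time divided by the other side's stance time (configurable in
concept; 1 = symmetric). Double support uses the periodic-gait identity
stance_ipsi + stance_contra − stride time; single support of a side is the
other side's swing time. Speed and cadence are computed per side from that
side's own stride, so the two-side duplication of each parameter is
well-defined even when values nearly coincide.

## Dataset assembly

A stride pair couples an ipsilateral stride with the contralateral stride
that starts within it; contralateral strides are not reused. Pairs inherit
the patient's board labels. The 70/30 split is patient-grouped and
stratified by SMS with largest-remainder allocation of test patients across
strata; single-patient strata stay in training. Per-pair, per-target weights
follow `w_i = (max_s N_s / N_{s(i)}) / M_{p(i)}` computed on the training
partition. Note that the class-balancing factor alone equalizes label-class
mass (Σ_{i∈s} w_i · M_{p(i)} = max_s N_s for every class); the patient
divisor then redistributes mass inside each class, so the raw per-class
weight sums coincide exactly only when every patient contributes one pair.

## Feature selection

Step 1 applies fixed per-subscore masks (680/356/330/32/680/680 features for
trunk/leg/arm/speed/fluency/stability). Step 2 selects one representative
stride pair per training patient — the pair minimizing Euclidean distance,
in training-set z-score space over the step-1 features, to the patient's
component-wise median vector (ties to the lowest pair index) — groups the
representatives by board subscore, and keeps features whose Alexander–Govern
p-value is below α = 0.05. No multiple-testing correction is applied.

The AG test weighs groups by inverse squared standard error, forms per-group
t statistics against the variance-weighted grand mean, normalizes them with
Hill's transformation, and refers A = Σ z² to χ²(k−1). Label levels with
fewer than two representative pairs cannot form a group and are dropped from
the grouping; a feature with zero variance inside a remaining group is
flagged and excluded from testing (and hence not retained). If fewer than
two usable groups remain, the filter is skipped and the mask passes through
unchanged.

## Model training

Hyperparameter grids: DT — max-features rule {√n, n, log₂ n}, split strategy
{best, random}, minimum weight fraction {0.00 … 0.05 step 0.01}, max depth
{3, 4, 5} (108 cells); MLP — hidden architecture {[16, 8], [32, 16, 8]}
(ReLU hidden units), output activation {linear, ReLU}, Adam learning rate
{1e−3, 1e−4, 1e−5}, plus a conditional refinement {7.5e−5 … 2.5e−6} scanned
when 1e−5 wins the base grid with architecture and activation fixed.

Trees are CART regression trees (scikit-learn) fitted with per-pair weights;
the minimum weight fraction is enforced at leaves, the closest available
per-node realization. The MLP is a compact in-package implementation (Adam
on weighted squared error, seeded initialization and batching, inputs
z-scored by training statistics; the tree receives raw features). Defaults:
300 epochs, batch 32 at the API level; the pipeline default budget is 120
epochs, chosen as the package's reproducible single-CPU problem size — the
networks on these cohorts converge well before that.

Cross-validation uses 10 folds stratified by label at stride-pair level
(patients may straddle folds, matching the pair-level training design); a
`group_by_patient_cv` option switches to stratified group folds for stricter
validation. Representative pairs assigned to a held-out fold are moved back
to that fold's training side, so they are never scored; validation R² is
unweighted. All seeds (fold shuffling, random splits, network
initialization) derive from one pipeline master seed via
`SeedSequence.spawn`.

## Evaluation

Model outputs are averaged over each test patient's stride pairs and cut to
[0, 3]; the SMS prediction is the sum of the six range-adjusted subscore
predictions (∈ [0, 18]). Patient-level R² is unweighted (the weights correct
training biases; the test metric assesses patients). ICC(1,1) =
(MSB − MSW)/(MSB + (k−1)·MSW) is computed per subscore from the five-rater
panels and, for the total, from rater-level SMS sums (rater identity is
positional).

## Explanation

Tree importance is the per-feature sum of weighted squared-error reductions
over all splits, normalized to 1, ties broken by canonical feature order.
Permutation importance is the mean drop in pair-level test R² over repeated
global shuffles of one column (500 repetitions at the API default; the
pipeline default is 100, a problem-size choice — the rankings stabilize well
below that on these cohorts). Features never consumed by a model have
exactly zero importance. Rankings carry ipsi-/contralateral annotations so
side shares can be reported; the shares are dataset-dependent and are
reported, not asserted.

## Numerical choices and degenerate inputs

- Exact gait-cycle periodicity is enforced by repeating sample 0 at sample
  100 (jitter included).
- Cohort CSVs are written with `%.17g` and read with round-trip float
  parsing, so the cohort directory round-trips bit-exactly.
- R² is reported as NaN with a warning when the observed values have zero
  variance; CV folds whose validation side empties after representative
  reinsertion are skipped with a warning; patients without a valid stride
  pair are excluded with a warning.
- Grid-search ties resolve to the first cell in enumeration order;
  representative-pair ties to the lowest pair index.

## Known limitations

- The generator's couplings are linear and monotone; real poststroke gait
  exhibits non-monotone compensation patterns the pipeline is never tested
  against here.
- Walking-aid flags are patient-constant and may be excluded by the AG
  filter when a label group shows zero variance for them.
- The MLP is CPU-oriented and intentionally small; no early stopping is
  used, favouring bit-reproducibility over speed.
- ICC inputs for the total score (rater-level SMS sums) are one defensible
  choice among several; alternatives (e.g. per-rater board-vs-rater
  agreement) are not implemented.
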