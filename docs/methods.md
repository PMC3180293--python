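# Methods

This note records the models, estimators, numerical choices and known
limitations behind `scpremo`. Times are milliseconds on a single session
clock; every interval is half-open `[start, end)`, so a spike exactly at cue
onset belongs to the evoked epoch, not the baseline.

## Synthetic sessions

The generator (`scpremo.simulate`) emulates the statistical structure the
analysis assumes; it is a measurement model for the pipeline, not a
biophysical claim about the superior colliculus.

**Behavior.** Each trial draws: catch status (probability 0.167; catch trials
have no cue and a 1000-ms hold), modality uniformly from {V, A, AV}, side
uniformly from {left, right}, a foreperiod uniform on [400, 800) ms, and an RT
from a shifted log-normal (shift 100 ms) moment-matched to the configured
mean/SD — right-skewed and strictly positive, the usual shape of rodent RT
distributions. Defaults are V 386.3 ± 98.7, A 394.9 ± 101.6, AV
322.4 ± 86.5 ms, so audiovisual facilitation of ~64 ms is built in. Errors
occur with probability 0.19 (matching a ~81 % success rate) and place the
choice on the wrong side; the following trial repeats the same stimulus and is
flagged as a correction trial. Correction-procedure reassignment happens
*before* RTs are drawn so RTs always follow the labelled modality.

**Spike trains.** Each unit's trial rate is

    rate(t) = baseline
            + Σ_modality amp · exp(−(t − cue_on − latency)² / 2σ_w²)
            + ramp(t) ,

where the premovement ramp rises linearly from `premove_onset` (default
−200 ms) to its amplitude at withdrawal and decays over the following 100 ms.
The per-trial amplitude is

    gain(direction) · (premove_amp + β · (RT − median RT)) · (AV factor if AV),

clamped so the total rate is ≥ 0. The sign of `premove_amp` makes the unit an
activation or suppression unit; the sign of β sets the direction of the
RT–rate correlation; `av_modulation_factor` > 1 (< 1) produces multisensory
enhancement (depression) of premovement activity independently of the evoked
bumps. Separate evoked latencies are used for the auditory (20 ms) and visual
(70 ms) bumps so the analysis-side evoked windows ([0, 40) and [50, 100) ms)
are meaningful. Spikes are sampled per trial by Poisson thinning under an
analytic rate bound, over the window [poke-in − 300, withdrawal + 400) ms;
no spikes are generated between trials, which only matters for analyses that
would look outside trial windows (none here do).

For typed populations the default coupling is |β| = 0.06 sp/s per ms: with a
±8 sp/s ramp on a 10 sp/s baseline and 200 trials, premovement-epoch counts
are ~Poisson with mean ≈ 1.6 in 100 ms (rate SD ≈ 12.6 sp/s), the ramp
contributes 0.75 of its amplitude to the epoch mean, and RT SD ≈ 90 ms, giving
|r| ≈ 0.75·β·90 / √((0.75·β·90)² + 12.6²) ≈ 0.3.

One caveat discovered while validating the generator: a nonzero β interacts
with the AV modulation factor, because AV trials are faster and the β term
then shifts AV premovement amplitudes on its own (+2.4 sp/s at β = −0.06),
enough to cancel a 0.6 depression factor. MSI-recovery experiments therefore
use β = 0 so the audiovisual factor is isolated.

**Wideband synthesis.** A 32-sample biphasic template is added at each spike
time onto Gaussian noise, replicated over 4 channels with amplitude scales
(1.0 … 0.4); coincident spikes sum. Sampling rate 25 kHz, raw little-endian
int16 with a JSON sidecar (µV/bit).

**Seeding.** One master seed; per-unit streams are spawned from a
`SeedSequence`, so fixed-seed output is bit-identical across runs.

## Spike density functions and epoch rates

SDFs convolve 1-ms spike-count histograms with a Gaussian kernel (σ = 15 ms
for movement analyses, σ = 4 ms for sensory analyses), truncated at ±4σ and
**renormalised to exact unit mass on the grid**. The renormalisation is the
reason the SDF integral equals the spike count to ~1e-16 relative error for
spikes ≥ 4σ inside the window (a plain truncated Gaussian would lose 6e-5 of
its mass). Binning to the 1-ms grid displaces each spike by at most 0.5 ms,
far below either kernel width. Epoch rates (baseline [−100, 0) before cue;
evoked [0, 100) after cue; premovement [−100, 0) before withdrawal) are exact
count-based estimates, not SDF integrals.

Trial filtering for neural analyses keeps correct, non-catch trials with
RT ≥ 150 ms (excluding trials where the evoked response would bleed into the
premovement epoch) and by default drops correction-procedure repeats, whose
post-error state is not what the analysis models; both choices are
configurable.

## ROC indices and permutation inference

The ROC area is computed from pooled ranks (ties halved), so the index is
invariant under any strictly monotone transform and antisymmetric under group
swap — both identities hold to machine precision and are asserted in the
tests against a brute-force pair-counting oracle. Permutation p-values shuffle
group labels preserving sizes (the pooled ranks are permutation-invariant, so
each of the 500 null indices costs one rank-subset sum), are two-sided on
|index|, and use the add-one correction `p = (1 + k)/(n_perm + 1)`, making
1/501 the smallest attainable p and the null distribution conservative.
Time courses slide a 100-ms window in 20-ms steps over per-trial SDF means;
only fully contained windows are evaluated, with centers at
`grid_start + width/2 + k·step`. The center of mass of significant positive
windows summarises when a unit's preference lives.

Direction preference groups trials by movement (choice) side relative to the
recorded hemisphere (configurable, default left ⇒ contraversive = rightward).
The correct-vs-error comparison groups *error* trials by movement direction
too, so a movement-coding unit produces same-sign preferences on both trial
sets; it requires at least 4 false-hit errors.

## Neuron typing and MSI

Eligibility for the four-type classification is a significant premovement
index (permutation p < 0.05 vs baseline). Labels follow the quadrant of
(sign of index, sign of r); exact zeros (measure-zero ties) are left
unclassified. The representative flag demands |index| > 0.1 **and**
|r| > 0.1. The MSI uses the bounded normalised contrast
`(AV − UNIave)/(AV + UNIave)` — chosen over the classic percentage form
because it is bounded in [−1, 1], scale-invariant, and matches the ±0.2 scale
on which premovement modulation is typically reported; `0/0` is defined as 0
and flagged degenerate. This normalisation is the package's one substantive
interpretive choice and is isolated in `scpremo.neurontype.msi`.

## Evoked-response detection

The σ = 4 ms trial-mean SDF must exceed baseline mean + 2 SD (SD taken across
time points of [−100, 0), matching a threshold applied to a mean trace) for
**more than** 15 ms (≥ 16 contiguous 1-ms samples), in runs starting within
100 ms of stimulus onset or offset (offset = onset + 100 ms); a run already
above threshold when the window opens counts with latency 0. A zero baseline
SD falls back to a 1 sp/s floor and is flagged. Classification: both
unisensory responses ⇒ multisensory; one ⇒ that modality; a response only
under AV ⇒ multisensory (an AV response in a unit with one unisensory
response is expected and does not by itself make it multisensory).

These thresholds have designed error rates, not negligible ones: the 2-SD /
15-ms rule admits roughly a 5 % false positive per condition (it was tuned to
that significance level), and a bump of 4 baseline-SDs clears the threshold by
only 2 SDs, giving ~88 % single-condition detection. Consequently a truly
unresponsive unit keeps the "none" label only ~0.95³ ≈ 86 % of the time when
examined under three conditions. The classification property test asserts
exactly these operating characteristics (8-SD bumps, ≥ 85 % unisensory,
≥ 90 % multisensory, ≥ 70 % none); perfect per-label accuracy is not a
property this criterion can have.

## Detection front-end

Zero-phase 3rd-order Butterworth band-pass (0.8–5 kHz, applied forward and
backward), RMS power in a centered 0.2-ms (5-sample) window, per-channel
threshold mean + 5 SD of the power trace ("SD of the mean power" is read as
the temporal SD of the windowed RMS signal), events merged within one
32-sample waveform span and reported at the power peak. Waveforms are cut
with the trough at sample 10 of 32 (keeping pre-trough context); edge events
are dropped and counted. Quality: refractory violations are ISIs < 1.5 ms
(the period is configurable; only the 1 % criterion is fixed), and the
isolation distance is the squared Mahalanobis distance — under the cluster's
own covariance — of the n-th closest non-cluster spike (n = cluster size),
capped and flagged when fewer non-cluster spikes exist. Units pass with
violations < 1 % and isolation distance > 20. Sorting itself (KlustaKwik /
MClust) is out of scope; the synthetic path uses ground-truth identities.

## Behavioral statistics

The modality comparison is a one-way repeated-measures ANOVA (statsmodels
`AnovaRM`) on per-session modality mean RTs with sessions as subjects,
followed by Tukey's HSD across modalities; the degenerate all-equal input
returns F = 0 by definition. Injection comparisons are within-animal paired
t-tests of each injection condition against control per modality, Bonferroni
corrected over the (conditions × modalities) family (family size
configurable — the appropriate family is a judgement call). The per-animal
facilitation test compares AV RTs against the unisensory modality with the
smaller mean, one-sided (AV faster). Selecting the faster modality by sample
mean makes this test slightly conservative when the two unisensory
distributions coincide; its calibration test therefore separates the
unisensory means.

## Problem sizes and study conditions used in validation

The acceptance script and tests run: the exhaustive ROC check over all size
pairs up to 8×8 (complete enumeration up to 3×3 on {0,1,2}); permutation
calibration with 1000 replicates of Poisson(10) 20+20 groups; type recovery
with 40 units and exactly 200 neural-filtered trials per direction; MSI sign
recovery with 40 units and ~200 neural trials per modality within each
direction (the trial count entering each rate estimate); detection fidelity
with 500 spikes at SNR 10; ANOVA power with 100 replicates of 43
186-trial sessions and type-I calibration with 1000 such null replicates.
These sizes make every stochastic check's expected margin several binomial
SDs wide while keeping the full run to a few minutes on one core.

## Limitations

* The generator's rate model (linear ramp, Gaussian bumps, Poisson spiking)
  reproduces the first-order statistics the pipeline measures — epoch rates,
  RT coupling, direction gain, AV modulation — but not refractoriness,
  bursting, slow drifts, cross-trial rate correlations or electrode
  instabilities; passing tests demonstrate correctness of the estimators
  under the assumed model, not robustness to every property of real data.
* The RT ← rate link in the generator is a convenient parameterisation of the
  correlation the analysis measures, not a causal model.
* Tukey post hoc tests are computed on the pooled session means (no
  subject-level error term); with 43 sessions and the effect sizes involved
  this is immaterial, but it is not a fully repeated-measures post hoc.
* The evoked-response criterion inherits its ~5 % per-condition false-positive
  rate by design; population counts of sensory classes should be interpreted
  with that base rate in mind.
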