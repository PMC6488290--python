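# Methods

This note documents the models, parameter choices and numerical decisions
behind `accmirror`, in the spirit of a package methods appendix. It states
no empirical result that the test suite or `scripts/acceptance.py` does
not itself compute.

## Analysis windows

Every channel- and cell-level statistic integrates over 1 s windows so no
condition is favored by a longer window: baseline always (−1.2, −0.2) s
relative to stimulus onset; response (0, 1) s for ShockObs and CS and
(0.3, 1.3) s for Laser, because laser-evoked nociception rides on
slow-conducting unmyelinated fibers and the 200 ms pulse needs time to
reach painful skin temperature. Spike-count windows are half-open
[start, end) — the edge convention is a package choice; the source
protocol does not state one.

## Multiunit activity

The MUA envelope is pairwise re-referenced (contactᵢ − contactᵢ₊₁ within
each shaft, 25 channels from a 5×6 probe), high-pass filtered at 1000 Hz,
full-wave rectified, and low-pass filtered at 200 Hz. Filters are
4th-order Butterworth applied forward-backward (`sosfiltfilt`): the
protocol names cutoffs but not a design, and zero-phase filtering
preserves response latencies, which matter for the 1 s windows.
Epochs span (−2, +3) s; z-scoring uses each trial's own 3 s pre-onset
mean/SD, so the reference window has mean 0 / SD 1 exactly by
construction. Zero-SD (constant) reference windows are flagged, never
divided by.

Artifact trials are those where any sample exceeds z > 8 or z < −5 on at
least a fraction of channels; "many or all channels" is not quantified at
the source, so the default fraction is 0.5 and configurable. The
synthetic generator gives injected artifacts a per-contact gain spread
(uniform 0.5–1.5×) because a perfectly common-mode artifact would be
cancelled exactly by pairwise re-referencing — real artifacts are not
common-mode.

Activation statistics are one-tailed t tests on the area under the
z-MUA (trapezoidal, units z·s): paired against the immediately preceding
baseline, two-sample across conditions, α = 0.01. Zero-variance inputs
yield "no test" (t = 0, p = 1, flag false). AUC is computed per trial and
then averaged where population tests need per-channel values; the
average-then-integrate order is also exposed.

The baseline window is (−1.2, −0.2) s; a variant reading "(−1.2 to
0.2 s)" appears in one place at the source but is inconsistent with the
required 1 s window length and with the results text, so it is not used.

Habituation compares each channel's mean response AUC over the first and
last 5 trials of a condition (paired t, two-tailed by default since both
decreases and increases are of interest; the tail is configurable) and a
two-way repeated-measures ANOVA (3 conditions × 2 epochs, via pingouin)
for the interaction. Evidence *for* no habituation uses a Bayesian
one-sample t test: BF₀₊ = p(t | δ=0) / ∫₀^∞ p(t | δ) 2·Cauchy(δ; 0.707) dδ,
integrating the noncentral-t likelihood over a positives-truncated Cauchy
prior by adaptive quadrature. The integrand wraps `scipy.stats.nct.pdf`,
which underflows to NaN at large noncentrality; NaNs are mapped to 0
(they occur only where the likelihood is vanishingly small) and the
quadrature is split at δ = 1 for stability.

## Cross-session unit tracking

The ShockObs session defines each unit's reference mean waveform. Filters
run in a fixed order: (1) remove spikes with waveform-Pearson r < 0.85;
(2) remove spikes with peak |amplitude| outside ±15% of the reference
peak; (3) remove whole sessions whose baseline-rate ratio against the
reference session exceeds 8 — computed from the spikes that survived
steps 1–2, which matters and is tested; finally sessions below 0.06 Hz
are dropped. All boundary values are kept (the removal rules are strict
inequalities). Two readings were open: the rate ratio is made symmetric
(max of ratio and inverse) because only that reading excludes drift in
both directions, and the 0.06 Hz floor applies to the whole session (the
source wording says simply "a spike firing rate"). Peak amplitude is
max |v| — polarity is not assumed. An audit trail records every removal
with its stage and reason, so input = kept + removals always reconciles.

## Single-cell statistics

Counts are compared with one-tailed nonparametric tests at p < 0.05:
signed-rank against each condition's own baseline, rank-sum across
conditions. The signed-rank test uses the exact null distribution for
n < 25 (ties handled by mid-ranks inside the exact distribution, as in
modern scipy); this reproduces the closed-form p = 2⁻¹⁰ when all ten
differences are positive. Note that an exact discrete test cannot have
size exactly 0.05: at n = 10 its largest achievable one-sided level is
0.0420, and the calibration tests check against that discrete nominal
(plus validity: never above 0.05). The rank-sum test is computed as the
tie-corrected Mann–Whitney U — spike counts tie heavily and the plain
normal approximation without tie correction is slightly mis-sized.

The taxonomy follows the Venn logic: responsive = any of the three
vs-baseline tests significant; among responsive cells, social =
HighShockObs > CtrlShockObs, laser = HighLaser > CtrlLaser (the control
contrasts exclude delivery-sound confounds), cs = CS > baseline (kept
lenient on purpose, to catch any salient-sound response); mirror =
social ∧ (laser ∨ cs); pain/fear/unselective partition the mirror set;
selective pain mirrors additionally require HighLaser > CS by rank-sum.

Binomial over-representation tails are summed in log space
(logsumexp of the tail log-pmf) so values below 10⁻¹⁴ stay accurate. The
channel-vs-cell Venn comparison is a Pearson χ² on the 2×7 region table
(df = 6), with regions empty in both groups dropped and df reduced.

Spike-density functions bin spikes at 1 ms, average over trials, and
convolve with a causal exponential (τ = 200 ms) then a Gaussian
(σ = 50 ms), both unit-area so spike count is conserved; convolution
commutes, so kernel order is immaterial. Each condition's trace is
baseline-subtracted (−2.2 to −1.2 s) and all conditions are divided by
the one cross-condition maximum inside the experimental windows, so 1
marks the cell's maximum rate; a cell that fired nowhere is flagged and
left unnormalized.

## Cross-modal decoding

Intensity is treated as ordinal-numeric (0/1/2) with squared-error loss —
the performance metric is a Pearson correlation between decoded and
actual intensity, which presumes continuous predictions. The decoder is a
lasso (elastic-net mixing available); columns are standardized to unit
variance inside the solver and the scaler is stored with the model so the
transfer to the other modality applies the identical affine map. The
penalty grid descends 100 log-spaced values over 4 decades from the
smallest penalty that zeroes all weights; the chosen penalty minimizes
leave-one-out CV squared error in the training modality, and the final
model is refit on all 30 training trials.

Within-modality LOO re-selects the penalty inside every fold by default
(nested selection, so the held-out trial can never influence model
selection — verified by a poisoning test); a fixed-penalty mode exists
because the source protocol is one sentence and agnostic on this point.
Cross-modal evaluation applies the trained model verbatim. Pairwise
intensity comparisons are one-tailed two-sample t tests with
Benjamini–Hochberg FDR.

A caveat worth knowing: under a pure-noise null, within-LOO predictions
are *negatively* correlated with the held-out labels, because each fold's
near-zero-weight model predicts its training-label mean, which excludes
the held-out trial (the standard LOO fold-mean artifact). The two-sided
r-test is therefore anticonservative within-modality under the null; the
meaningful null checks are one-sided (significant positive decoding,
bounded at nominal) and the cross-modal label-shuffle null, which has no
such artifact and is calibrated.

## Behavior

The attention score interpolates linearly between the stated anchors
(1 at α ≤ 30°, 0 at α ≥ 150°), which reproduces the worked value 0.66 at
70°. Freezing percentage is summed bout∩epoch time over epoch length,
with bouts clipped at the edges; the muscimol epochs are the first 720 s
(baseline) and next 720 s (test). Trial- and spike-triggered
spectrograms operate on a time–frequency energy matrix; pixel statistics
are matched-pair t tests with one value per animal (random effects),
thresholded at p < 0.001 uncorrected as in the source analysis (an
optional cluster correction exists but is off by default). The
spike-triggered spectrogram takes moments in the top 5% of instantaneous
rate (1/ISI), skips a configurable initial baseline, and subtracts the
per-frequency session mean, so a stationary track averages to exactly
zero.

The muscimol design (2 groups between × 2 sessions × 2 epochs within) is
evaluated with the exact 2-level contrast decomposition: each within
effect reduces to a t test on a per-subject contrast score with
F = t² on (1, n₁+n₂−2) df, the between effect to a two-sample t on
subject means, and within-effect marginal means are unweighted (Type-III
style) under unequal group sizes (defaults 6 muscimol vs 8 saline). No
installed package offers a 3-way mixed ANOVA, and for all-2-level designs
the contrast decomposition is exact rather than approximate; collapsing a
factor reproduces the corresponding paired t (tested).

Sample-size arithmetic uses the two-sample normal approximation
n = 2((z₁₋α + z_power)/d)², rounded up with a floor of 2; the yield
calculation is ceil(target/cells-per-animal) inflated by the loss rate.

## Synthetic experiments

The generator is first-class, tested code; its defaults are the study
conditions. Schedules: ShockObs 10 High + 10 Low + 20 Ctrl 1 s shocks at
60/90 s inter-onset gaps; Laser 10/10/20 200 ms pulses at 24/36 s; CS ten
20 s tones at 60/90 s. Spiking is inhomogeneous Poisson: baseline rate
(log-normally jittered around 5 Hz) plus, per trial of a responded-to
condition, an expected `gain` spikes (default 8, "Low" conditions at half
gain) spread over the response window by a unimodal
difference-of-exponentials kernel (rise 50 ms, decay 300 ms, unit area,
truncated to the window) — the source shows only empirical PSTHs, so any
unimodal kernel on the window is equally defensible and the shape is
configurable. Profiles fix which gains are nonzero: pain mirrors respond
to ShockObs (graded) and HighLaser; fear mirrors to ShockObs and CS;
unselective mirrors to all three; plus social-only, laser-only, cs-only
and nonresponsive units. LowLaser carries no gain in any profile — it is
calibrated below the nociceptive threshold by design. Habituation
multiplies gains by 0.93 per trial within condition, applied to ShockObs
and CS only (no laser habituation is modeled, matching the empirical
pattern the Bayesian null test quantifies).

Continuous rendering inserts each unit's 1 ms biphasic template (scaled
copies at 0.4× on vertical neighbors) into a 5×6-contact matrix with
white plus 1/f noise; the default sampling rate is 8 kHz — enough for
the 1 kHz high-pass at a quarter of the acquisition-rate cost — with the
rate configurable up to the hardware's 32 kHz. Audio is synthesized
directly as a time–frequency energy matrix (50 ms bins, 0–80 kHz in 41
bands): broadband bursts at squeak/jump times (within 0–1 s after High
shocks always, Low shocks with probability 0.5, never Ctrl), non-locked
22 kHz vocalization events, and a configurable squeak duration (0.3 s
default; the source does not report durations). A WAV renderer exists
for format round-trips only. All randomness derives from one master seed
through named substreams (schedule/units/spikes/noise/behavior/drift), so
a fixed seed reproduces everything bit-for-bit.

What the generator does *not* emulate — and what passing tests therefore
do not show about real data: biophysical spike shapes and electrode
drift dynamics (drift is a per-session amplitude scale + shape noise,
chosen to straddle the cleanup thresholds), cross-unit correlations and
oscillatory structure in the noise, behavioral dynamics beyond interval
labels and a piecewise head-angle trace, and acoustic call structure
beyond band-limited energy bursts.

## Problem sizes in the statistical tests

Calibration and recovery properties are checked at sizes the package
treats as its standard verification conditions: 2000-unit null
simulations for test calibration; 10 replicate experiments of the
25/11/3/20/14 composition for taxonomy recovery; 40 replicates for
cross-modal transfer power; 200 label-shuffle refits for the cross-modal
null; 12 replicates for the planted transfer asymmetry; 17 synthetic
animals for the pixel-test calibration.

## Known limitations

- The strict per-class recovery of a planted composition is bounded for
  *social-only* units by test multiplicity, not power: a true social-only
  cell picks up a spurious laser or cs flag with probability
  ≈ 1 − (1 − 0.05)² ≈ 0.0975 at α = 0.05, capping expected per-class
  accuracy near 0.90 regardless of gain strength.
- The within-modality LOO r-test is anticonservative under the null (see
  the decoding caveat above); cross-modal inferences are the calibrated
  ones.
- The Bayes factor quadrature is accurate to ~3 significant figures;
  prior scale and tail are configurable but results are only validated
  for the default one-tailed Cauchy(0.707).
- The mixed-ANOVA decomposition is exact only because every factor has 2
  levels; it does not generalize to more levels.
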