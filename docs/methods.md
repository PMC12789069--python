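# Methods

`beattag` implements a frequency-tagging analysis of beat and meter
representation for rhythmic sequences whose degree of pattern
repetition is manipulated, together with the stimulus-design machinery
the analysis presumes and a synthetic-data generator that makes every
stage testable end to end. This note records the models, the defaults
and why they were chosen, the numerical decisions, and what the
synthetic validation does and does not establish.

## The measurement model

The central quantity is the **beat-related z-score**. Given a magnitude
spectrum A(f) of one epoch and a set F of frequencies of interest (FOI)
partitioned into beat-related frequencies B = {1.25, 2.5, 3.75} Hz and
beat-unrelated control frequencies F \ B,

    z(f) = (A(f) − mean_{g∈F} A(g)) / sd_{g∈F} A(g),
    beat_z = mean_{f∈B} z(f).

`beat_z > 0` means beat periodicities stand out relative to the other
periodicities the signal contains; applied to a stimulus envelope it
quantifies (the lack of) acoustic beat cues, i.e. syncopation; applied
to EEG it quantifies the neural emphasis of the beat. The contrast
between a negative stimulus-level value and a positive EEG value is the
input–output "periodization" the analysis is designed to detect.

The beat frequencies are fixed by behaviour: participants' median
intertap intervals converge on 800 and 400 ms (1.25 and 2.5 Hz, four
and two grid intervals), and 3.75 Hz is the prominent harmonic of
those rates.

## Stimuli

Seed rhythms occupy a 12-slot grid of 200 ms time points (2.4 s per
rhythm), 8 slots carrying a 200 ms pure tone (10/20 ms linear ramps,
carriers geometrically spaced from 150 to 200 Hz across trials) and 4
silent. The library is built by rejection sampling over the 12-choose-4
silent-slot placements, keeping patterns whose beat-related z-score over
the first 12 modulation-spectrum bins (Hilbert envelope, bins 1/2.4 Hz
… 5 Hz, sample-SD z-scores) is strictly negative — the syncopation
criterion. The search is deterministic given its seed and touches at
most the 495 possible placements.

Sequences last 67.2 s (28 seeds): a 2-seed 4.8 s pattern looped 14
times (repetition rate 0.208 Hz), a 4-seed 9.6 s pattern looped 7 times
(0.104 Hz), or 28 constrained random draws (no identical adjacent
seeds; no contiguous reproduction of the looped patterns). Because the
published seed set is only available graphically, the library here is
searched rather than transcribed, and the looped patterns are then
*chosen by the same control the original design states*: each candidate
2-seed pattern (and 4-seed extension of the chosen pair) is scored by
the beat-related z-score of its full-sequence Hilbert modulation
spectrum, and the pattern whose (negative) score is closest to the
no-repetition sequence's score is selected. Scoring runs at a reduced
audio rate (2205 Hz); the amplitude-envelope spectrum below 30 Hz is
unaffected as long as the carrier stays below Nyquist. A manifest format
lets users supply an explicit seed order (e.g. the published patterns,
if transcribed).

Audio defaults: 44.1 kHz sampling, unit-peak normalisation with a
per-carrier scale hook; loudness (dB A) equalisation belongs to
playback hardware and is metadata only. Tempo-change snippets warp
event onsets so the grid interval follows half a cosine cycle
(baseline → extremum → baseline over 4.8 s; fixed extrema 188.7/217.4
ms); audio is placed at remapped onsets rather than resampled, so
carrier pitch is untouched. The two-down one-up staircase moves the
extremum 8 ms toward the 200 ms baseline after two consecutive correct
responses and 8 ms away after each error, converging on the ~70.7 %
point of the psychometric function.

## Envelope front-ends

Two envelope extractors feed the spectral analysis. The Hilbert
envelope is the magnitude of the analytic signal. The cochlear
front-end stands in for an auditory-nerve model: 128 gammatone channels
with centre frequencies ERB-spaced from 130 Hz to 16 kHz (Glasberg &
Moore ERB-rate scale), each implemented as the classic cascade of four
second-order sections (numerically stable where a single 8th-order
transfer function is not, and unit passband gain at CF), half-wave
rectified, averaged across channels, and smoothed with a zero-phase
50 Hz low-pass. Rectified channels are averaged before the (linear)
smoothing, which equals smoothing each channel first. Channels at or
above Nyquist are dropped with a warning. No adaptation or compression
is modelled: the analysis consumes only the channel-averaged modulation
spectrum, for which this linear-filterbank front-end is an adequate
stand-in.

Envelopes are resampled to the 512 Hz EEG rate and cut to the trial
length of round(67.2 s × 512 Hz) = 34406 samples, so stimulus and EEG
spectra share one frequency-bin grid (bin width 1/67.199 s ≈ 0.0149
Hz). 67.2 s is not an integer sample count at 512 Hz; the beat
frequencies land within 10⁻³ of a bin of their nominal values and all
nominal-frequency lookups tolerate half a bin.

## EEG reduction

Cleaned trials (artifact rejection, ICA and channel interpolation are
accepted as already applied; the module validates finiteness only) are
high-pass filtered at 0.1 Hz with a 4th-order Butterworth, applied
forward-backward — the zero-phase choice is ours, the original reports
only the filter — re-referenced to the mastoid average, averaged over
trials in the time domain, and averaged over the 9 frontocentral
channels F1, Fz, F2, FC1, FCz, FC2, C1, Cz, C2. The whole chain is
linear, so it preserves the stimulus-locked component exactly up to the
filter's passband ripple (< 10⁻⁸ amplitude error at 1.25 Hz) and its
edge transients (the 0.1 Hz filter rings for tens of seconds; on a
finite epoch this perturbs FOI amplitudes at the ~10⁻⁴ level, which is
why exact-recovery tests split the filter from the rest of the chain).

Spectra are computed by FFT of the entire epoch, no window, no
padding; a unit-amplitude bin-aligned sinusoid yields amplitude 1. The
local noise correction subtracts from each bin the mean of its
neighbours at offsets ±2…±5 (edge bins use the available offsets
only). The correction is linear, zeroes constant and linear
backgrounds at interior bins, and preserves isolated peaks exactly.

## Data-driven FOI selection

Per condition: prominent peaks of each group's (noise-corrected,
group-averaged) EEG spectrum — local maxima with topographic prominence
≥ mean + 2·SD of the spectrum in (0, 30] Hz — are intersected across
groups, then merged with the prominent peaks of the condition's
stimulus modulation spectrum (taken before noise correction; both
sides configurable). Candidates below 1.25 Hz are dropped (pattern
rates 0.104/0.208 Hz would leave no controls; 0.625 Hz is behaviourally
unclassifiable; low bins are 1/f-contaminated), as are 5 Hz and its
integer multiples up to the 30 Hz search ceiling (event-rate response
shape). Counts are equalised at the smallest per-condition candidate
count m by keeping the m candidates with the largest amplitude in that
condition's stimulus spectrum, with the beat frequencies always forced
in; ties keep the lower frequency. z-scores use the sample SD (n−1);
the spread estimator is configurable since the original does not state
it.

The default beat set {1.25, 2.5, 3.75} Hz treats 5 Hz as the grid rate
rather than a beat harmonic (it is excluded outright); the set is
configurable.

## Tapping

Intertap intervals are first differences of debounced tap onsets
(onsets closer than 100 ms merge; configurable). The predicted beat
period is the integer multiple k·200 ms, k = 1…12, nearest the median
ITI, ties toward the smaller period. Stability is the mean resultant
length |mean exp(i·φ)| of tap phases φ = 2π(onset mod period)/period —
in [0, 1], invariant to global time shifts, so referencing phases to
trial onset rather than to stimulus pulse positions changes nothing.

## Synthetic data and what it validates

A synthetic subject's trial is

    response = unit-peak(envelope ⊗ ERP kernel)
             + beat_gain · Σ_f cos(2πft),  f ∈ {1.25, 2.5, 3.75} Hz
             + noise_scale · 1/f^α noise,

with the ERP kernel a 300 ms damped 10 Hz sinusoid, zero-phase beat
cosines (so time-domain trial averaging preserves them — the measure
assumes stimulus-locked responses), α = 1 by default, and fresh noise
per trial on each of 9 frontocentral clone channels (mastoids are
zeros, making re-referencing the identity). `beat_gain` is the known
ground truth; `noise_scale` is in units of the unit-peak response, and
its default of 1 makes the single-trial, single-channel SNR of order
one — deliberately pessimistic per trial, with the realistic SNR gain
recovered by trial/channel averaging. Synthetic taps sit at k·period
plus wrapped-Gaussian jitter with circular SD σ, for which the expected
stability is exp(−σ²/2) in closed form.

Validation simulations use a scaled-down design chosen to exercise
every stage while keeping the whole suite re-runnable on one CPU:
cohorts of 6 subjects × 2 trials for calibration checks, 20 seeds × 5
gains for recovery, 500 replicate cohorts for the type-I rate, and 100
seeds × 80 taps for stability recovery.

Two points deserve emphasis. First, beat-gain recovery is assessed as
*ordinal* (Spearman correlation of beat_z with gain), because z-scoring
is a relative measure and saturates at high gain. Second, the
calibration (type-I error) of the one-sample enhancement test is
assessed against the generator's **null expectation** — the Monte-Carlo
mean beat_z of zero-gain subjects from an independent seed stream — not
against the cochlear or noiseless beat_z. Measurement noise biases
spectrum magnitudes upward (Rician bias of |FFT| bins, strongest where
signal amplitude is small), so even at zero gain the noisy pipeline's
expected beat_z sits above the noiseless value; a test against the
noiseless reference would reject almost always and would say nothing
about calibration. The cohort-level enhancement test itself still uses
the cochlear beat_z as its baseline, exactly as in the headline
analysis — the distinction is between *using* the test (sensory
baseline) and *validating its calibration* (null-matched baseline).

What passing these simulations does **not** show: the generator has no
head-model mixing, no artifacts, no inter-subject amplitude or latency
variability, clone channels share one response, and the injected beat
is exactly sinusoidal and exactly stimulus-locked. Results on recorded
EEG depend on preprocessing quality and response topography in ways the
synthetic cohort cannot probe.

## Orchestration defaults

`run_pipeline` simulates a full study replica: 2 groups × 2 condition
orders × 3 conditions, 4 subjects per cell and 2 trials each by
default (a desk-scale cohort; the recorded study used 26 subjects per
group and 10 trials). The demo injects beat_gain = 0.1 — enough to turn
EEG beat_z positive in every condition against the negative stimulus
baseline, mirroring the observed periodization — and synthesises taps
with group-specific jitter (σ = 0.3 musicians, 0.7 non-musicians) to
reproduce the behavioural stability contrast. Enhancement tests are
FDR-corrected (Benjamini–Hochberg) across the group × order × condition
family; the family is configurable. Runs are reproducible from config +
seed, and every output row carries group, order, condition and seed
provenance.

## Known limitations

- The seed library and looped patterns are searched, not the published
  ones; all structural constraints and the syncopation criterion are
  enforced, but the exact audio differs from the OSF deposit.
- The cochlear stand-in is linear; auditory-nerve adaptation could
  shift the relative prominence of modulation peaks.
- FOI selection on small synthetic cohorts is noisier than on the
  recorded 26-subject group averages; the cross-group intersection is
  the main guard, and the toy-spectrum tests pin the selection rules
  themselves.
- The supplementary counterevidence-C-score syncopation measure and the
  autocorrelation variant of frequency tagging are out of scope.
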