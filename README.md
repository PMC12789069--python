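# beattag

Frequency-tagging analysis of the neural and behavioural representation
of musical beat under graded rhythmic-pattern repetition.

When people listen to syncopated rhythms — sequences whose acoustics
only weakly cue the periodic pulse — their EEG nevertheless shows a
selective enhancement of activity at the perceived beat frequencies: the
brain *periodizes* its input. `beattag` implements the full measurement
chain for studying how this periodization depends on the slow,
supra-second recurrence created by looping rhythmic patterns: stimulus
construction under syncopation constraints, amplitude-envelope
front-ends (Hilbert and a gammatone cochlear model), EEG reduction to a
pooled frontocentral waveform, data-driven selection of frequencies of
interest, beat-related z-scoring with a sensory-baseline test, circular
statistics for finger tapping, and a synthetic EEG/tapping generator
with known ground truth so that every stage is testable without any
recorded data.

It is aimed at auditory-cognitive-neuroscience researchers who use
frequency tagging / steady-state evoked potentials for rhythm and who
want a tested, scriptable reference implementation of this analysis.

## The core statistic

Amplitudes of a magnitude spectrum at a set F of frequencies of
interest are standardised and averaged over the beat frequencies
B = {1.25, 2.5, 3.75} Hz (the tapped beat rates, 1/800 ms and
1/400 ms, and their prominent harmonic):

```
z(f)   = (A(f) − mean_{g∈F} A(g)) / sd_{g∈F} A(g)
beat_z = mean_{f∈B} z(f)
```

F is chosen data-driven per condition: spectral peaks with prominence ≥
mean + 2 SD of the 0–30 Hz spectrum, intersected across participant
groups, merged with the stimulus-spectrum peaks, pruned of
frequencies < 1.25 Hz and of 5 Hz and its multiples, and equalised in
count across conditions (keeping the largest-stimulus-amplitude
candidates, with B always forced in). A negative `beat_z` of the
stimulus envelope certifies syncopation; a positive EEG `beat_z`
against the negative cochlear baseline is the periodization effect,
tested per cohort with a one-tailed one-sample t-test and
Benjamini–Hochberg FDR correction.

## Worked example

```python
import beattag as bt

# 14 syncopated seed rhythms (8 sound / 4 silent slots on a 200 ms grid)
lib = bt.generate_seed_library(14, rng_seed=1)
print([round(bt.seed_syncopation_zscore(p), 3) for p in lib][:4])
# [-0.145, -0.131, -0.131, -0.145]   all 14 scores fall in [-1.158, -0.013]

print(bt.carrier_frequencies(5, 150, 200))
# [150.0, 161.19, 173.21, 186.12, 200.0]

# a tapping trial: 80 taps on an 800 ms beat with phase jitter sd 0.5 rad
train = bt.synth_taps(bt.SyntheticTapSpec(
    beat_period_s=0.8, phase_jitter_sd_rad=0.5, n_taps=80, rng_seed=1))
r = bt.analyze_tap_train(train)
print(r.median_iti_s, r.beat_period_s, r.stability)
# 0.796 0.8 0.916   (expected stability exp(-0.5**2/2) = 0.882)

# the full synthetic study replica
bundle = bt.run_pipeline(bt.RunConfig(out_dir="demo_run", rng_seed=1))
print(bundle["stimulus_beat_z"][["condition", "beat_z"]])
#            condition    beat_z
# 0  medium_repetition -1.268063
# 1    long_repetition -1.247112
# 2      no_repetition -1.242779
```

The run builds the three 67.2 s sequences (a 4.8 s pattern looped 14
times at 0.208 Hz, a 9.6 s pattern looped 7 times at 0.104 Hz, and a
non-repeating draw), and the negative `beat_z` values confirm that all
three carry weak acoustic beat cues. The synthetic cohort in the same
bundle, which injects a stimulus-locked beat component (gain 0.1),
comes out positive — e.g. mean EEG `beat_z` of 1.52 (medium), 1.24
(long) and 2.59 (no repetition) for the musicians group — so every
group × order × condition enhancement test rejects its cochlear
baseline after FDR correction, reproducing the input–output
periodization contrast. `demo_run/` then contains `beat_z.csv`,
`stimulus_beat_z.csv`, `enhancement_tests.csv`,
`tapping_stability.csv`, `foi.json`, the per-condition sequence
manifests and a JSON-lines run log; identical configs give
byte-identical tables.

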