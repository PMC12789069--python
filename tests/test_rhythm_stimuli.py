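"""Stimulus construction: carriers, tones, seed search, sequence
assembly, tempo warps, and the adaptive staircase."""

import numpy as np
import pytest

import beattag as bt
from beattag.rhythm_stimuli import (
    GRID_INTERVAL_S,
    InvalidParameterError,
    SequenceSpec,
    StaircaseState,
    TempoModulation,
    modulated_grid_intervals,
    resolve_order,
    staircase_update,
    synthesize_tone,
)

AUDIO_FS = 44_100.0


class TestCarrierFrequencies:
    @pytest.mark.parametrize(
        "args, expected",
        [
            ((5, 150, 200), [150.00, 161.19, 173.21, 186.12, 200.00]),
            ((1, 150, 200), [150.00]),
            ((2, 100, 400), [100.00, 400.00]),
        ],
    )
    def test_geometric_series(self, args, expected):
        assert bt.carrier_frequencies(*args) == expected

    def test_rejects_nonpositive_frequency(self):
        with pytest.raises(InvalidParameterError):
            bt.carrier_frequencies(3, -10, 200)


class TestToneAndRhythmSynthesis:
    def test_all_silent_pattern_is_zero(self):
        p = bt.GridPattern([False] * 12)
        audio = bt.synthesize_rhythm(p, bt.ToneSpec(), AUDIO_FS)
        assert len(audio) == round(2.4 * AUDIO_FS)
        assert np.all(audio == 0)

    def test_single_event_support_and_ramp(self):
        p = bt.GridPattern([True] + [False] * 11)
        tone = bt.ToneSpec(carrier_hz=150.0)
        audio = bt.synthesize_rhythm(p, tone, AUDIO_FS)
        n_slot = round(0.2 * AUDIO_FS)
        assert np.any(audio[:n_slot] != 0)
        assert np.all(audio[n_slot:] == 0)
        # envelope reaches full scale only after the 10 ms onset ramp
        n_up = round(0.010 * AUDIO_FS)
        assert np.max(np.abs(audio[:n_up])) < 1.0
        assert np.max(np.abs(audio)) == pytest.approx(1.0, abs=1e-3)

    def test_sound_slots_peak_at_carrier(self, seed_library):
        """FFT oracle: the spectral peak of a sound slot sits at the carrier."""
        tone = bt.ToneSpec(carrier_hz=173.21)
        audio = bt.synthesize_rhythm(seed_library[0], tone, AUDIO_FS)
        n_slot = round(0.2 * AUDIO_FS)
        k = next(i for i, s in enumerate(seed_library[0].slots) if s)
        slot = audio[k * n_slot : (k + 1) * n_slot]
        freqs = np.fft.rfftfreq(n_slot, 1 / AUDIO_FS)
        peak = freqs[np.argmax(np.abs(np.fft.rfft(slot)))]
        assert peak == pytest.approx(tone.carrier_hz, abs=1 / 0.2)
        silent = [i for i, s in enumerate(seed_library[0].slots) if not s]
        for i in silent:
            assert np.all(audio[i * n_slot : (i + 1) * n_slot] == 0)

    def test_rejects_sub_nyquist_rate(self):
        with pytest.raises(InvalidParameterError):
            synthesize_tone(bt.ToneSpec(carrier_hz=200.0), fs=300.0)


class TestSeedLibrary:
    def test_constraints_and_determinism(self, seed_library):
        assert len(seed_library) == 14
        assert len({p.slots for p in seed_library}) == 14
        for p in seed_library:
            assert p.n_sound == 8 and len(p.slots) == 12
            assert bt.seed_syncopation_zscore(p) < 0
        again = bt.generate_seed_library(14, rng_seed=0)
        assert [p.slots for p in again] == [p.slots for p in seed_library]


class TestSequenceAssembly:
    def test_looped_conditions_rates_and_cycles(self, sequences):
        audio_m, man_m = sequences["medium_repetition"]
        audio_l, man_l = sequences["long_repetition"]
        assert man_m["pattern_repetition_hz"] == pytest.approx(0.208, abs=5e-4)
        assert man_l["pattern_repetition_hz"] == pytest.approx(0.104, abs=5e-4)
        # identical cycles, sample-exact
        n_cycle = round(4.8 * AUDIO_FS)
        cycles = audio_m.reshape(14, n_cycle)
        assert np.array_equal(cycles, np.tile(cycles[0], (14, 1)))
        n_cycle = round(9.6 * AUDIO_FS)
        cycles = audio_l.reshape(7, n_cycle)
        assert np.array_equal(cycles, np.tile(cycles[0], (7, 1)))

    def test_duration_and_seed_count(self, sequences):
        for audio, manifest in sequences.values():
            assert len(audio) == round(67.2 * AUDIO_FS)
            assert len(manifest["seed_ids"]) == 28

    def test_no_repetition_constraints(self, sequences, condition_patterns):
        medium, long_ = condition_patterns
        ids = sequences["no_repetition"][1]["seed_ids"]
        assert all(a != b for a, b in zip(ids, ids[1:]))
        for i in range(len(ids) - 1):
            assert tuple(ids[i : i + 2]) != tuple(medium)
        for i in range(len(ids) - 3):
            assert tuple(ids[i : i + 4]) != tuple(long_)

    def test_determinism_of_random_order(self, seed_library):
        spec = SequenceSpec(
            condition="no_repetition", seed_library=tuple(seed_library), rng_seed=7
        )
        assert resolve_order(spec) == resolve_order(spec)

    def test_selected_patterns_are_admissible(self, condition_patterns):
        medium, long_ = condition_patterns
        assert len(medium) == 2 and medium[0] != medium[1]
        assert len(long_) == 4
        assert long_[:2] == medium
        assert all(a != b for a, b in zip(long_, long_[1:]))
        assert long_[-1] != long_[0]  # seamless loop keeps neighbours distinct
        assert long_[2:] != medium  # must not collapse to the medium loop


class TestTempoModulation:
    def test_none_is_identity(self, seed_library):
        tail = seed_library[:2]
        mod = TempoModulation(direction="none")
        warped, onsets = bt.apply_tempo_modulation(tail, mod, bt.ToneSpec(), AUDIO_FS)
        plain = np.concatenate(
            [bt.synthesize_rhythm(p, bt.ToneSpec(), AUDIO_FS) for p in tail]
        )
        assert np.allclose(warped, plain)
        assert np.allclose(np.diff(onsets), GRID_INTERVAL_S)

    def test_deceleration_reaches_maximum_interval(self, seed_library):
        mod = TempoModulation(direction="decelerate")
        _, onsets = bt.apply_tempo_modulation(
            seed_library[:2], mod, bt.ToneSpec(), AUDIO_FS
        )
        intervals = modulated_grid_intervals(mod, 24)
        assert np.max(intervals) == pytest.approx(0.2174, abs=1 / AUDIO_FS)
        assert np.max(np.diff(onsets)) == pytest.approx(0.2174, abs=1 / AUDIO_FS)
        # returns to baseline at the snippet edges
        assert intervals[0] == pytest.approx(GRID_INTERVAL_S, abs=1e-12)

    def test_acceleration_shortens_snippet(self, seed_library):
        mod = TempoModulation(direction="accelerate")
        warped, _ = bt.apply_tempo_modulation(
            seed_library[:2], mod, bt.ToneSpec(), AUDIO_FS
        )
        assert len(warped) < round(4.8 * AUDIO_FS)

    def test_rejects_inverted_bounds(self):
        with pytest.raises(InvalidParameterError):
            TempoModulation(
                direction="accelerate",
                min_grid_interval_s=0.25,
                max_grid_interval_s=0.2,
            )


class TestStaircase:
    def test_two_down_one_up_arithmetic(self):
        s = StaircaseState(current_value_s=0.2381, direction="decelerate")
        s = staircase_update(s, True)
        assert s.current_value_s == pytest.approx(0.2381)  # one correct: no move
        s = staircase_update(s, True)
        assert s.current_value_s == pytest.approx(0.2301)  # second correct: harder
        s = staircase_update(s, False)
        assert s.current_value_s == pytest.approx(0.2381)  # incorrect: easier

    def test_converges_near_70_7_percent_point(self):
        """Monte-Carlo oracle: 2-down-1-up tracks the 70.7 % point of the
        psychometric function."""
        rng = np.random.default_rng(42)

        def p_correct(value_s):
            # sigmoid in the tempo-change magnitude |value - 200 ms|
            depth = abs(value_s - 0.2)
            return 1 / (1 + np.exp(-(depth - 0.020) / 0.004))

        s = StaircaseState(current_value_s=0.2381, direction="decelerate")
        for _ in range(2000):
            s = staircase_update(s, rng.random() < p_correct(s.current_value_s))
        tail = [v for v, _ in s.history[-1000:]]
        converged_depth = abs(np.mean(tail) - 0.2)
        # invert the sigmoid at 70.7 %
        target_depth = 0.020 + 0.004 * np.log(0.707 / (1 - 0.707))
        assert converged_depth == pytest.approx(target_depth, abs=0.004)
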