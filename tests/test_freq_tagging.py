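"""Spectra, noise correction, FOI selection, and z-scoring."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import beattag as bt
from beattag.freq_tagging import (
    BEAT_FREQS,
    DegenerateSelectionError,
    FrequencySet,
    InvalidInputError,
    MagnitudeSpectrum,
    UndefinedZScoreError,
    noise_correct,
    select_frequencies_of_interest,
    stimulus_frequency_sets,
)


class TestMagnitudeSpectrum:
    def test_bin_width_is_reciprocal_duration(self):
        fs = 512.0
        spec = bt.magnitude_spectrum(np.zeros(round(67.2 * fs)) + 1.0, fs)
        assert spec.df == pytest.approx(1 / 67.2, rel=1e-4)

    def test_unit_sinusoid_at_bin_frequency(self):
        fs, n = 256.0, 2560  # 10 s -> 0.1 Hz bins
        t = np.arange(n) / fs
        spec = bt.magnitude_spectrum(np.sin(2 * np.pi * 2.0 * t), fs)
        assert spec.amplitude_at(2.0) == pytest.approx(1.0, abs=1e-9)
        others = np.delete(spec.amplitudes, spec.bin_index(2.0))
        assert np.max(np.abs(others)) < 1e-9

    def test_bin_aligned_sinusoids_superpose(self):
        fs, n = 256.0, 2560
        t = np.arange(n) / fs
        x = 0.5 * np.sin(2 * np.pi * 2.0 * t) + 2.0 * np.cos(2 * np.pi * 7.3 * t)
        spec = bt.magnitude_spectrum(x, fs)
        assert spec.amplitude_at(2.0) == pytest.approx(0.5, abs=1e-9)
        assert spec.amplitude_at(7.3) == pytest.approx(2.0, abs=1e-9)

    def test_rejects_empty_signal(self):
        with pytest.raises(InvalidInputError):
            bt.magnitude_spectrum(np.array([]), 512.0)


def _spec(amps, df=0.1):
    amps = np.asarray(amps, dtype=float)
    freqs = np.arange(1, len(amps) + 1) * df
    return MagnitudeSpectrum(freqs, amps, duration_s=1 / df)


class TestNoiseCorrection:
    def test_flat_spectrum_corrects_to_zero(self):
        out = noise_correct(_spec(np.full(50, 3.7)))
        assert np.allclose(out.amplitudes, 0.0, atol=1e-12)

    def test_isolated_peak_preserved_neighbors_dip(self):
        a = np.zeros(41)
        a[20] = 2.0
        out = noise_correct(_spec(a))
        assert out.amplitudes[20] == pytest.approx(2.0)
        for off in (2, 3, 4, 5):
            assert out.amplitudes[20 + off] == pytest.approx(-2.0 / 8)
            assert out.amplitudes[20 - off] == pytest.approx(-2.0 / 8)
        assert out.amplitudes[19] == pytest.approx(0.0)
        assert out.amplitudes[21] == pytest.approx(0.0)

    def test_linear_ramp_zero_at_interior_bins(self):
        out = noise_correct(_spec(np.linspace(1, 5, 60)))
        assert np.allclose(out.amplitudes[5:-5], 0.0, atol=1e-12)

    @settings(derandomize=True, max_examples=25)
    @given(st.integers(0, 2**31 - 1))
    def test_correction_is_linear(self, seed):
        rng = np.random.default_rng(seed)
        a, b = rng.normal(size=(2, 40))
        lhs = noise_correct(_spec(a + b)).amplitudes
        rhs = noise_correct(_spec(a)).amplitudes + noise_correct(_spec(b)).amplitudes
        assert np.allclose(lhs, rhs, atol=1e-12)

    def test_rejects_short_spectrum(self):
        with pytest.raises(InvalidInputError):
            noise_correct(_spec(np.ones(8)))


class TestSeedSyncopationScore:
    def test_isochronous_pattern_has_nonpositive_beat_z(self):
        """FFT oracle: a tone in every slot modulates only at the 5 Hz
        grid rate, so beat bins hold no excess energy."""
        iso = bt.GridPattern([True] * 12)
        assert bt.seed_syncopation_zscore(iso) <= 0

    def test_rotation_invariance(self, seed_library):
        p = seed_library[0]
        z0 = bt.seed_syncopation_zscore(p)
        for k in (3, 7):
            assert bt.seed_syncopation_zscore(p.rotate(k)) == pytest.approx(
                z0, abs=5e-2
            )

    def test_rejects_off_grid_beat_frequency(self):
        with pytest.raises(Exception):
            bt.seed_syncopation_zscore(
                bt.GridPattern([True, False] * 6), beat_freqs=(1.3,)
            )


class TestProminentPeaks:
    def test_three_isolated_spikes_found(self):
        a = np.zeros(400)
        a[[50, 120, 260]] = 5.0
        peaks = bt.find_prominent_peaks(_spec(a, df=0.05))
        assert peaks == pytest.approx([51 * 0.05, 121 * 0.05, 261 * 0.05])

    def test_flat_spectrum_yields_no_peaks(self):
        assert bt.find_prominent_peaks(_spec(np.ones(300), df=0.05)) == []

    @pytest.mark.parametrize("height", [0.3, 0.8, 1.5, 3.0, 6.0])
    def test_threshold_decision_matches_oracle(self, height):
        """Accept/reject agrees with an independently computed
        mean + 2 SD prominence threshold."""
        rng = np.random.default_rng(99)
        a = rng.uniform(0, 0.1, size=500)
        a[250] = height
        spec = _spec(a, df=0.05)
        mask = (spec.frequencies > 0) & (spec.frequencies <= 30)
        thr = a[mask].mean() + 2 * a[mask].std(ddof=1)
        found = any(abs(f - 251 * 0.05) < 1e-9 for f in bt.find_prominent_peaks(spec))
        base = max(a[248:250].max(), a[251:253].max())
        assert found == (height - base >= thr) or abs(height - base - thr) < 0.12


from conftest import toy_selection_inputs as _toy_selection_inputs


class TestFOISelection:
    def test_equalizes_to_smallest_candidate_count(self):
        stim, eeg, _ = _toy_selection_inputs()
        sets = select_frequencies_of_interest(stim, eeg)
        assert {len(s) for s in sets.values()} == {27}
        for s in sets.values():
            assert s.beat_related == (1.25, 2.5, 3.75)
            assert len(s.beat_unrelated) == 24

    def test_exclusions_and_forced_beat(self):
        stim, eeg, _ = _toy_selection_inputs()
        sets = select_frequencies_of_interest(stim, eeg)
        for s in sets.values():
            assert 0.625 not in s.all_frequencies
            assert all(abs(f - 5.0) > 1e-9 and abs(f - 10.0) > 1e-9
                       for f in s.all_frequencies)
            assert all(f >= 1.25 for f in s.all_frequencies)

    def test_equalization_keeps_largest_stimulus_amplitudes(self):
        stim, eeg, pools = _toy_selection_inputs()
        sets = select_frequencies_of_interest(stim, eeg)
        # condition A: 27 candidates survive of 30 -> the 24 largest-amplitude
        # non-beat candidates are exactly the first 24 of its descending pool
        expected = set(np.round(pools["A"][:24], 9))
        assert set(np.round(sets["A"].beat_unrelated, 9)) == expected

    def test_group_unique_eeg_peaks_are_dropped(self):
        stim, eeg, _ = _toy_selection_inputs()
        sets = select_frequencies_of_interest(stim, eeg)
        for s in sets.values():
            assert all(abs(f - 20.5) > 1e-9 and abs(f - 25.25) > 1e-9
                       for f in s.all_frequencies)

    def test_degenerate_selection_raises(self):
        df = 1 / 64
        grid = np.arange(1, 2049) * df
        a = np.zeros(2048)
        for f in (1.25, 2.5, 3.75):
            a[int(round(f / df)) - 1] = 5.0
        spec = MagnitudeSpectrum(grid, a, duration_s=64.0)
        with pytest.raises(DegenerateSelectionError):
            select_frequencies_of_interest(
                {"A": spec}, {"A": {"g1": spec, "g2": spec}}
            )

    def test_stimulus_only_variant_matches_rules(self, stimulus_foi):
        sizes = {len(s) for s in stimulus_foi.values()}
        assert len(sizes) == 1  # equalized across conditions
        for s in stimulus_foi.values():
            # beat frequencies land on the nearest bins of the 512 Hz
            # trial grid (34406 samples), within a small fraction of a bin
            assert s.beat_related == pytest.approx((1.25, 2.5, 3.75), abs=1e-3)


class TestZScoring:
    def test_hand_computed_example(self):
        foi = FrequencySet(beat_related=(1.0,), beat_unrelated=(2.0, 3.0, 4.0))
        spec = _spec(np.array([3.0, 1.0, 1.0, 1.0, 0, 0, 0, 0, 0, 0, 0]), df=1.0)
        r = bt.zscore_frequency_set(spec, foi)
        assert r.beat_z == pytest.approx(1.5)

    def test_equal_amplitudes_are_degenerate(self):
        foi = FrequencySet(beat_related=(1.0,), beat_unrelated=(2.0, 3.0))
        spec = _spec(np.full(12, 2.0), df=1.0)
        with pytest.raises(UndefinedZScoreError):
            bt.zscore_frequency_set(spec, foi)

    @settings(derandomize=True, max_examples=25)
    @given(st.integers(0, 2**31 - 1))
    def test_zscores_have_zero_mean_unit_sd(self, seed):
        rng = np.random.default_rng(seed)
        amps = rng.uniform(0.1, 5.0, size=16)
        amps[0] += 1.0  # guarantee spread
        foi = FrequencySet(
            beat_related=(1.0, 2.0, 3.0),
            beat_unrelated=tuple(float(f) for f in range(4, 17)),
        )
        r = bt.zscore_frequency_set(_spec(amps, df=1.0), foi)
        z = np.array(list(r.z_per_frequency.values()))
        assert np.mean(z) == pytest.approx(0.0, abs=1e-10)
        assert np.std(z, ddof=1) == pytest.approx(1.0, abs=1e-10)

    def test_below_mean_beat_amplitudes_give_negative_z(self):
        foi = FrequencySet(beat_related=(1.0,), beat_unrelated=(2.0, 3.0, 4.0))
        spec = _spec(np.array([0.5, 2.0, 2.5, 3.0, 0, 0, 0, 0, 0, 0, 0]), df=1.0)
        assert bt.zscore_frequency_set(spec, foi).beat_z < 0


class TestEnhancementTest:
    def test_no_enhancement_gives_t_zero_p_half(self):
        t, p = bt.beat_enhancement_test([0.4, 0.4, 0.4, 0.4], 0.4)
        assert t == pytest.approx(0.0)
        assert p == pytest.approx(0.5)

    def test_one_tailed_symmetry(self):
        zs = np.array([0.5, 0.8, 0.3, 0.9, 0.6])
        _, p = bt.beat_enhancement_test(zs, 0.2)
        _, p_flip = bt.beat_enhancement_test(-zs, -0.2)
        assert p_flip == pytest.approx(1 - p)

    def test_power_at_strong_effect(self):
        """Simulation oracle: n=26 cohorts with a strong shift reject in
        >= 95 % of replicates."""
        rng = np.random.default_rng(7)
        rejections = 0
        for _ in range(200):
            zs = rng.normal(loc=0.8, scale=0.5, size=26)
            _, p = bt.beat_enhancement_test(zs, 0.0)
            rejections += p < 0.05
        assert rejections / 200 >= 0.95

    def test_requires_two_subjects(self):
        with pytest.raises(Exception):
            bt.beat_enhancement_test([0.5], 0.0)

    def test_fdr_is_monotone_and_bounded(self):
        p = [0.001, 0.01, 0.02, 0.2, 0.8]
        adj = bt.fdr_correct(p)
        assert np.all(adj >= np.asarray(p) - 1e-12)
        assert np.all(adj <= 1.0)
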