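"""Shared fixtures: a deterministic seed library, condition sequences,
and their envelopes at the common analysis rate.

Everything is generated programmatically (no stored data); session
scope keeps the expensive stimulus synthesis to one pass.
"""

import numpy as np
import pytest

import beattag as bt
from beattag.envelope_frontend import ANALYSIS_FS, hilbert_envelope, resample_envelope
from beattag.eeg_pipeline import TRIAL_SAMPLES
from beattag.freq_tagging import magnitude_spectrum, stimulus_frequency_sets

CONDITIONS = ("medium_repetition", "long_repetition", "no_repetition")
AUDIO_FS = 44_100.0


@pytest.fixture(scope="session")
def seed_library():
    return bt.generate_seed_library(14, rng_seed=0)


@pytest.fixture(scope="session")
def condition_patterns(seed_library):
    return bt.select_condition_patterns(seed_library, rng_seed=0)


@pytest.fixture(scope="session")
def sequences(seed_library, condition_patterns):
    """condition -> (audio at 44.1 kHz, manifest)."""
    medium, long_ = condition_patterns
    out = {}
    for cond in CONDITIONS:
        spec = bt.SequenceSpec(
            condition=cond,
            seed_library=tuple(seed_library),
            rng_seed=0,
            medium_pattern=medium,
            long_pattern=long_,
        )
        out[cond] = bt.assemble_sequence(spec, bt.ToneSpec(), AUDIO_FS)
    return out


@pytest.fixture(scope="session")
def hilbert_envelopes_512(sequences):
    """condition -> Hilbert envelope resampled to the 512 Hz trial grid."""
    return {
        cond: resample_envelope(
            hilbert_envelope(audio, AUDIO_FS), ANALYSIS_FS, n_samples=TRIAL_SAMPLES
        )
        for cond, (audio, _) in sequences.items()
    }


@pytest.fixture(scope="session")
def stimulus_foi(hilbert_envelopes_512):
    """Equalised stimulus-only FOI sets from the Hilbert spectra."""
    spectra = {
        cond: magnitude_spectrum(env.samples, ANALYSIS_FS)
        for cond, env in hilbert_envelopes_512.items()
    }
    return stimulus_frequency_sets(spectra)


def toy_selection_inputs():
    """Constructed FOI-selection inputs with candidate sets of sizes
    30/27/29 on a shared fine bin grid (0.625, 1.25, 5 and 10 Hz all
    bin-exact)."""
    from beattag.freq_tagging import MagnitudeSpectrum

    df = 1 / 64
    n = 2048  # covers up to 32 Hz
    grid = np.arange(1, n + 1) * df

    def make(amp_pairs):
        a = np.zeros(n)
        for f, h in amp_pairs:
            a[int(round(f / df)) - 1] = h
        return MagnitudeSpectrum(grid, a, duration_s=1 / df)

    beat = [1.25, 2.5, 3.75]
    excluded = [0.625, 5.0, 10.0]  # below-beat and 5 Hz-harmonic exclusions
    pools = {}
    sizes = {"A": 30, "B": 27, "C": 29}
    for name, size in sizes.items():
        k = np.arange(size - 3)
        pool = grid[89 + 60 * k + {"A": 0, "B": 1, "C": 2}[name]]
        assert all(
            f >= 1.25 and min(abs(f - 5 * m) for m in range(1, 7)) > df for f in pool
        )
        pools[name] = list(pool)
    stim, eeg = {}, {}
    for name in sizes:
        # descending stimulus amplitudes make the equalisation ranking explicit
        spikes = [(f, 10.0) for f in beat]
        spikes += [(f, 9.0 - 0.1 * i) for i, f in enumerate(pools[name])]
        spikes += [(f, 8.0) for f in excluded]
        stim[name] = make(spikes)
        shared = [(f, 6.0) for f in beat + pools[name] + excluded]
        eeg[name] = {
            "musicians": make(shared + [(20.5, 7.0)]),
            "nonmusicians": make(shared + [(25.25, 7.0)]),
        }
    return stim, eeg, pools


@pytest.fixture(scope="session")
def medium_envelope_512(hilbert_envelopes_512):
    return hilbert_envelopes_512["medium_repetition"]


@pytest.fixture(scope="session")
def medium_foi(stimulus_foi):
    return stimulus_foi["medium_repetition"]
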