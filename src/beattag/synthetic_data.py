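"""Synthetic EEG trials and tap trains with known ground truth.

Every pipeline stage is exercisable without recorded data: synthetic
EEG trials contain a stimulus-locked response (the stimulus envelope
convolved with a damped-oscillation ERP kernel), an injected
beat-periodic component of known gain (sum of zero-phase cosines at the
beat frequencies 1.25/2.5/3.75 Hz — the ground truth for parameter
recovery), and fresh 1/f noise per trial and channel.  Synthetic tap
trains place taps on a chosen metric period with wrapped-Gaussian phase
jitter, for which the expected circular stability has the closed form
exp(-sigma^2/2).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import signal as sps

from .eeg_pipeline import (
    EEG_FS,
    FRONTOCENTRAL_CHANNELS,
    MASTOID_CHANNELS,
    TRIAL_SAMPLES,
    EEGTrialSet,
)
from .envelope_frontend import EnvelopeSignal
from .freq_tagging import BEAT_FREQS
from .tapping import TRIAL_DURATION_S, TapTrain

__all__ = [
    "SyntheticEEGSpec",
    "SyntheticTapSpec",
    "default_erp_kernel",
    "beat_component",
    "one_over_f_noise",
    "stimulus_locked_component",
    "pipeline_beat_z",
    "null_beat_z_baseline",
    "synth_eeg",
    "synth_cohort",
    "synth_taps",
]


class InvalidParameterError(ValueError):
    pass


def default_erp_kernel(fs: float = EEG_FS, duration_s: float = 0.3) -> np.ndarray:
    """Damped 10 Hz sinusoid, ``duration_s`` long, unit peak.

    A minimal stand-in for the evoked response to one sound event; its
    low-pass character shapes the stimulus-locked spectrum the way a
    real ERP would.
    """
    t = np.arange(int(round(duration_s * fs))) / fs
    k = np.sin(2 * np.pi * 10.0 * t) * np.exp(-t / 0.05)
    return k / np.max(np.abs(k))


def beat_component(
    n_samples: int, fs: float, freqs: Sequence[float] = BEAT_FREQS
) -> np.ndarray:
    """Unit-amplitude zero-phase cosines at the beat frequencies, summed.

    Zero phase keeps the component stimulus-locked, so time-domain trial
    averaging preserves it exactly.
    """
    t = np.arange(n_samples) / fs
    return np.sum([np.cos(2 * np.pi * f * t) for f in freqs], axis=0)


def one_over_f_noise(
    n_samples: int, alpha: float, rng: np.random.Generator, size: int | tuple = 1
) -> np.ndarray:
    """Unit-SD 1/f^alpha noise via spectral shaping of white noise.

    Returns shape ``(*size, n_samples)``.
    """
    if np.isscalar(size):
        size = (int(size),)
    white = rng.standard_normal((*size, n_samples))
    spec = np.fft.rfft(white, axis=-1)
    f = np.fft.rfftfreq(n_samples)
    shape = np.zeros_like(f)
    shape[1:] = f[1:] ** (-alpha / 2.0)
    out = np.fft.irfft(spec * shape, n=n_samples, axis=-1)
    sd = out.std(axis=-1, keepdims=True)
    sd[sd == 0] = 1.0
    return out / sd


@dataclass(frozen=True)
class SyntheticEEGSpec:
    """Recipe for one synthetic subject's EEG trials.

    ``beat_gain`` multiplies the injected beat-periodic component in
    units of the (unit-peak) stimulus-locked response; ``noise_scale``
    is the per-channel 1/f noise SD in the same units.
    """

    stimulus_envelope: EnvelopeSignal
    erp_kernel: np.ndarray | None = None
    beat_gain: float = 0.0
    noise_exponent: float = 1.0
    noise_scale: float = 1.0
    n_trials: int = 10
    n_subjects: int = 1
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.beat_gain < 0:
            raise InvalidParameterError("beat_gain must be nonnegative")
        if self.stimulus_envelope.fs != EEG_FS:
            raise InvalidParameterError(
                f"envelope must be at the {EEG_FS:.0f} Hz analysis rate"
            )
        if len(self.stimulus_envelope.samples) != TRIAL_SAMPLES:
            raise InvalidParameterError(
                f"envelope must span one trial ({TRIAL_SAMPLES} samples)"
            )


def stimulus_locked_component(spec: SyntheticEEGSpec) -> np.ndarray:
    """The deterministic part of every trial (response + injected beat).

    The envelope is convolved with the ERP kernel, normalised to unit
    peak, and the beat component added with amplitude ``beat_gain``.
    """
    kernel = spec.erp_kernel if spec.erp_kernel is not None else default_erp_kernel()
    n = TRIAL_SAMPLES
    resp = sps.fftconvolve(spec.stimulus_envelope.samples, kernel)[:n]
    peak = np.max(np.abs(resp))
    if peak > 0:
        resp = resp / peak
    return resp + spec.beat_gain * beat_component(n, EEG_FS)


def synth_eeg(spec: SyntheticEEGSpec, subject_index: int = 0) -> EEGTrialSet:
    """Generate one synthetic subject's trials.

    Channels are the 9 frontocentral labels (shared stimulus-locked
    signal, independent 1/f noise per trial and channel) plus two
    all-zero mastoids, so mastoid re-referencing is the identity.
    Deterministic given ``rng_seed`` and ``subject_index``.
    """
    rng = np.random.default_rng(
        np.random.SeedSequence(spec.rng_seed).spawn(subject_index + 1)[-1]
    )
    component = stimulus_locked_component(spec)
    n_fc = len(FRONTOCENTRAL_CHANNELS)
    n = TRIAL_SAMPLES
    trials = np.zeros((spec.n_trials, n_fc + len(MASTOID_CHANNELS), n))
    if spec.noise_scale > 0:
        noise = spec.noise_scale * one_over_f_noise(
            n, spec.noise_exponent, rng, size=(spec.n_trials, n_fc)
        )
    else:
        noise = np.zeros((spec.n_trials, n_fc, n))
    trials[:, :n_fc, :] = component[None, None, :] + noise
    labels = FRONTOCENTRAL_CHANNELS + MASTOID_CHANNELS
    return EEGTrialSet(
        trials, fs=EEG_FS, channel_labels=labels, subject=f"S{subject_index:02d}"
    )


def synth_cohort(spec: SyntheticEEGSpec) -> list[EEGTrialSet]:
    """All ``n_subjects`` subjects of the spec (independent noise each)."""
    return [synth_eeg(spec, i) for i in range(spec.n_subjects)]


# ---------------------------------------------------------------------------
# End-to-end validation helpers
# ---------------------------------------------------------------------------


def pipeline_beat_z(
    spec: SyntheticEEGSpec,
    foi,
    subject_index: int = 0,
    first_n_trials: int | None = None,
) -> float:
    """Full-pipeline beat-related z-score of one synthetic subject.

    Runs the exact analysis chain a recorded subject would get:
    synthetic trials -> high-pass -> mastoid re-reference -> trial and
    frontocentral averaging -> magnitude spectrum -> local noise
    correction -> z-scoring over ``foi``.
    """
    from .eeg_pipeline import preprocess
    from .freq_tagging import magnitude_spectrum, noise_correct, zscore_frequency_set

    trialset = synth_eeg(spec, subject_index)
    waveform = preprocess(trialset, first_n_trials=first_n_trials)
    spectrum = noise_correct(magnitude_spectrum(waveform, EEG_FS))
    return zscore_frequency_set(spectrum, foi).beat_z


def null_beat_z_baseline(
    spec: SyntheticEEGSpec, foi, n_calibration: int = 200
) -> float:
    """Expected beat_z of the generator at zero injected beat gain.

    Monte-Carlo mean over ``n_calibration`` independent gain-0 subjects
    (a seed stream disjoint from any cohort drawn from ``spec``).  This
    is the correct H0 reference for calibration checks of the
    enhancement test: measurement noise biases spectrum magnitudes
    upward (Rician magnitude bias), so the noiseless — or cochlear —
    beat_z is not the null mean of the noisy pipeline output.
    """
    import dataclasses

    null_spec = dataclasses.replace(
        spec, beat_gain=0.0, rng_seed=int((spec.rng_seed + 987_654_321) % 2**31)
    )
    zs = [pipeline_beat_z(null_spec, foi, i) for i in range(n_calibration)]
    return float(np.mean(zs))


@dataclass(frozen=True)
class SyntheticTapSpec:
    """Recipe for one synthetic tap train."""

    beat_period_s: float = 0.8
    phase_jitter_sd_rad: float = 0.0
    miss_probability: float = 0.0
    n_taps: int = 80
    start_s: float = 0.4
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.beat_period_s <= 0:
            raise InvalidParameterError("beat period must be positive")
        if not 0 <= self.miss_probability < 1:
            raise InvalidParameterError("miss probability must be in [0, 1)")


def synth_taps(spec: SyntheticTapSpec, **labels) -> TapTrain:
    """Taps at k*period with wrapped-Gaussian phase jitter and misses.

    Onset jitter (s) is ``phase_jitter_sd_rad * period / 2 pi``; with
    jitter sigma the expected circular stability is exp(-sigma^2/2).
    Taps falling outside the trial, or collapsing onto an earlier tap,
    are dropped.
    """
    rng = np.random.default_rng(spec.rng_seed)
    k = np.arange(spec.n_taps)
    onsets = spec.start_s + k * spec.beat_period_s
    if spec.phase_jitter_sd_rad > 0:
        onsets = onsets + rng.normal(
            0.0,
            spec.phase_jitter_sd_rad * spec.beat_period_s / (2 * np.pi),
            size=spec.n_taps,
        )
    if spec.miss_probability > 0:
        onsets = onsets[rng.random(spec.n_taps) >= spec.miss_probability]
    onsets = np.sort(onsets)
    onsets = onsets[(onsets >= 0) & (onsets <= TRIAL_DURATION_S)]
    # enforce strict monotonicity after jitter (drop collided taps)
    keep = np.concatenate([[True], np.diff(onsets) > 0])
    return TapTrain(onsets[keep], **labels)
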