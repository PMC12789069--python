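"""Amplitude-envelope extraction from stimulus audio.

Two front-ends feed the modulation-spectrum analysis: the magnitude of
the analytic (Hilbert) signal, and a cochlear stand-in — an ERB-spaced
gammatone filterbank followed by half-wave rectification, channel
averaging and 50 Hz low-pass smoothing — approximating the
auditory-nerve representation whose modulation spectrum serves as the
sensory baseline for the beat-related z-score.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import signal

__all__ = [
    "EnvelopeSignal",
    "hilbert_envelope",
    "cochlear_envelope",
    "erb_space",
    "resample_envelope",
    "write_envelope_csv",
    "read_envelope_csv",
]

#: Common analysis rate (Hz) shared with the EEG, so stimulus and EEG
#: spectra live on the same frequency-bin grid.
ANALYSIS_FS = 512.0
#: Samples per 67.2 s trial at the analysis rate.
TRIAL_SAMPLES = round(67.2 * ANALYSIS_FS)


class InvalidInputError(ValueError):
    pass


@dataclass(frozen=True)
class EnvelopeSignal:
    """A nonnegative amplitude envelope at sampling rate ``fs``."""

    samples: np.ndarray
    fs: float
    source: str  # "hilbert" | "cochlear"

    def __post_init__(self) -> None:
        object.__setattr__(self, "samples", np.asarray(self.samples, dtype=float))
        if self.samples.ndim != 1 or self.samples.size == 0:
            raise InvalidInputError("envelope must be a nonempty 1-D series")

    @property
    def duration_s(self) -> float:
        return len(self.samples) / self.fs


def hilbert_envelope(audio: np.ndarray, fs: float) -> EnvelopeSignal:
    """Magnitude of the analytic signal of ``audio``."""
    audio = np.asarray(audio, dtype=float)
    if audio.size == 0:
        raise InvalidInputError("empty audio")
    if not np.all(np.isfinite(audio)):
        raise InvalidInputError("audio contains non-finite samples")
    env = np.abs(signal.hilbert(audio))
    return EnvelopeSignal(env, fs, "hilbert")


def erb_space(f_low: float, f_high: float, n: int) -> np.ndarray:
    """``n`` centre frequencies equally spaced on the ERB-rate scale.

    Uses the Glasberg & Moore ERB-rate mapping
    ``ERBS(f) = 21.4 log10(1 + 0.00437 f)``.
    """
    if n < 1:
        raise InvalidInputError("need at least one channel")
    c = 0.00437
    erb_lo = 21.4 * np.log10(1 + c * f_low)
    erb_hi = 21.4 * np.log10(1 + c * f_high)
    erbs = np.linspace(erb_lo, erb_hi, n)
    return (10 ** (erbs / 21.4) - 1) / c


def gammatone_sos(cf: float, fs: float) -> np.ndarray:
    """4th-order gammatone filter at centre frequency ``cf`` as 4 biquads.

    Classic ERB-gammatone digital design (Slaney's all-pole cascade):
    four second-order sections sharing the pole pair of a resonator with
    bandwidth 1.019 ERB(cf), with the four distinct zeros distributed
    one per section and the passband gain normalised to 1 at ``cf``.
    The cascade form is numerically stable at low cf/fs ratios where a
    single 8th-order transfer function is not.
    """
    T = 1.0 / fs
    erb = 24.7 * (4.37e-3 * cf + 1.0)
    B = 1.019 * 2 * np.pi * erb
    arg = 2 * cf * np.pi * T
    ebt = np.exp(B * T)
    rt_pos = np.sqrt(3 + 2**1.5)
    rt_neg = np.sqrt(3 - 2**1.5)

    a = np.array([1.0, -2 * np.cos(arg) / ebt, np.exp(-2 * B * T)])
    a1 = -(2 * T * np.cos(arg) / ebt + 2 * rt_pos * T * np.sin(arg) / ebt) / 2
    a2 = -(2 * T * np.cos(arg) / ebt - 2 * rt_pos * T * np.sin(arg) / ebt) / 2
    a3 = -(2 * T * np.cos(arg) / ebt + 2 * rt_neg * T * np.sin(arg) / ebt) / 2
    a4 = -(2 * T * np.cos(arg) / ebt - 2 * rt_neg * T * np.sin(arg) / ebt) / 2

    e2 = np.exp(4j * cf * np.pi * T)
    eb2 = np.exp(-(B * T) + 2j * cf * np.pi * T)
    gain = np.abs(
        (-2 * e2 * T + 2 * eb2 * T * (np.cos(arg) - rt_neg * np.sin(arg)))
        * (-2 * e2 * T + 2 * eb2 * T * (np.cos(arg) + rt_neg * np.sin(arg)))
        * (-2 * e2 * T + 2 * eb2 * T * (np.cos(arg) - rt_pos * np.sin(arg)))
        * (-2 * e2 * T + 2 * eb2 * T * (np.cos(arg) + rt_pos * np.sin(arg)))
        / (-2 / np.exp(2 * B * T) - 2 * e2 + 2 * (1 + e2) / ebt) ** 4
    )
    sos = np.array(
        [
            [T / gain, a1 / gain, 0.0, *a],
            [T, a2, 0.0, *a],
            [T, a3, 0.0, *a],
            [T, a4, 0.0, *a],
        ]
    )
    return sos


def cochlear_envelope(
    audio: np.ndarray,
    fs: float,
    n_channels: int = 128,
    cf_low: float = 130.0,
    cf_high: float = 16_000.0,
    smooth_hz: float = 50.0,
) -> EnvelopeSignal:
    """Channel-averaged output of a gammatone filterbank.

    Each of ``n_channels`` ERB-spaced gammatone channels is half-wave
    rectified; the channel average is then low-pass smoothed at
    ``smooth_hz`` (zero phase).  Channels with centre frequency at or
    above Nyquist are dropped with a warning.  Smoothing after the
    (linear) channel average equals averaging per-channel smoothed
    envelopes.
    """
    audio = np.asarray(audio, dtype=float)
    if audio.size == 0:
        raise InvalidInputError("empty audio")
    if n_channels < 1:
        raise InvalidInputError("n_channels must be >= 1")
    cfs = erb_space(cf_low, cf_high, n_channels)
    usable = cfs < 0.5 * fs
    if not np.all(usable):
        warnings.warn(
            f"dropping {int(np.sum(~usable))} gammatone channels at/above "
            f"Nyquist ({fs / 2:.0f} Hz)",
            stacklevel=2,
        )
        cfs = cfs[usable]
    if cfs.size == 0:
        raise InvalidInputError("no gammatone channel below Nyquist")
    acc = np.zeros_like(audio)
    for cf in cfs:
        acc += np.maximum(signal.sosfilt(gammatone_sos(cf, fs), audio), 0.0)
    env = acc / len(cfs)
    if smooth_hz and smooth_hz < 0.5 * fs:
        sos = signal.butter(4, smooth_hz, btype="low", fs=fs, output="sos")
        env = np.maximum(signal.sosfiltfilt(sos, env), 0.0)
    return EnvelopeSignal(env, fs, "cochlear")


def resample_envelope(
    env: EnvelopeSignal,
    target_fs: float = ANALYSIS_FS,
    n_samples: int | None = None,
) -> EnvelopeSignal:
    """Resample an envelope to the common analysis rate.

    ``n_samples`` trims/zero-pads the result to a fixed trial length so
    stimulus and EEG spectra share one bin grid (default: leave as is).
    """
    if env.fs == target_fs:
        out = env.samples.copy()
    else:
        from fractions import Fraction

        frac = Fraction(target_fs / env.fs).limit_denominator(10_000)
        out = signal.resample_poly(env.samples, frac.numerator, frac.denominator)
    out = np.maximum(out, 0.0)
    if n_samples is not None:
        if len(out) >= n_samples:
            out = out[:n_samples]
        else:
            out = np.pad(out, (0, n_samples - len(out)))
    return EnvelopeSignal(out, target_fs, env.source)


def write_envelope_csv(path: str | Path, env: EnvelopeSignal) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow([f"envelope fs={env.fs} source={env.source}"])
        for s in env.samples:
            w.writerow([repr(float(s))])


def read_envelope_csv(path: str | Path) -> EnvelopeSignal:
    with open(path, newline="") as fh:
        r = csv.reader(fh)
        header = next(r)[0].split()
        meta = dict(kv.split("=") for kv in header[1:])
        samples = np.array([float(row[0]) for row in r])
    return EnvelopeSignal(samples, float(meta["fs"]), meta["source"])
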