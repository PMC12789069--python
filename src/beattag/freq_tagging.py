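"""Frequency-tagging analysis: spectra, noise correction, frequency-of-
interest selection, and beat-related z-scores.

The central quantity is the *beat-related z-score*: amplitudes of a
magnitude spectrum at a data-driven set of frequencies of interest (FOI)
are standardised to z-scores, and the mean z over the beat frequencies
(1.25, 2.5 and 3.75 Hz — the tapped beat rates and their prominent
harmonic) indexes how much beat periodicities stand out relative to the
other periodicities present in the signal.  Applied to the stimulus
envelope it quantifies syncopation (negative values = weak acoustic beat
cues); applied to EEG spectra it quantifies the neural emphasis of the
beat; their difference is the input-output "periodization" the
enhancement test evaluates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from .rhythm_stimuli import (
    DEFAULT_AUDIO_FS,
    GridPattern,
    ToneSpec,
    synthesize_rhythm,
)

__all__ = [
    "MagnitudeSpectrum",
    "FrequencySet",
    "ZScoreResult",
    "magnitude_spectrum",
    "noise_correct",
    "seed_syncopation_zscore",
    "find_prominent_peaks",
    "select_frequencies_of_interest",
    "stimulus_frequency_sets",
    "zscore_frequency_set",
    "beat_enhancement_test",
    "fdr_correct",
]

#: Beat-related frequencies (Hz): the convergent tapped rates 1.25 and
#: 2.5 Hz plus the prominent 3.75 Hz harmonic.
BEAT_FREQS: tuple[float, ...] = (1.25, 2.5, 3.75)
#: Upper edge (Hz) of the peak search and of the 5 Hz-harmonic exclusion.
PEAK_SEARCH_F_MAX = 30.0


class InvalidInputError(ValueError):
    pass


class InvalidParameterError(ValueError):
    pass


class DegenerateSelectionError(RuntimeError):
    """FOI selection would leave no beat-unrelated control frequencies."""


class UndefinedZScoreError(ZeroDivisionError):
    """Zero spread across FOI amplitudes; z-scores are undefined."""


class InsufficientDataError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Magnitude spectra
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MagnitudeSpectrum:
    """Single-sided amplitude spectrum of one full epoch.

    Frequencies start at the bin resolution ``1/duration_s`` (DC is
    dropped); amplitudes may be signed after noise correction.
    """

    frequencies: np.ndarray
    amplitudes: np.ndarray
    duration_s: float

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "frequencies", np.asarray(self.frequencies, dtype=float)
        )
        object.__setattr__(self, "amplitudes", np.asarray(self.amplitudes, dtype=float))
        if self.frequencies.shape != self.amplitudes.shape:
            raise InvalidInputError("frequency/amplitude length mismatch")

    @property
    def df(self) -> float:
        """Frequency-bin width (Hz)."""
        return 1.0 / self.duration_s

    def bin_index(self, freq: float, tol: float | None = None) -> int:
        """Index of the bin nearest ``freq`` (within ``tol``, default half a bin)."""
        if tol is None:
            tol = 0.5 * self.df
        i = int(np.argmin(np.abs(self.frequencies - freq)))
        if abs(self.frequencies[i] - freq) > tol + 1e-12:
            raise InvalidParameterError(
                f"{freq} Hz is {abs(self.frequencies[i] - freq):.4g} Hz off the "
                f"bin grid (bin width {self.df:.4g} Hz)"
            )
        return i

    def amplitude_at(self, freq: float, tol: float | None = None) -> float:
        return float(self.amplitudes[self.bin_index(freq, tol)])


def magnitude_spectrum(x: np.ndarray, fs: float) -> MagnitudeSpectrum:
    """FFT amplitude spectrum of the full epoch (no window, no padding).

    A unit-amplitude sinusoid at an exact bin frequency yields amplitude
    1.0 at that bin.
    """
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        raise InvalidInputError("empty signal")
    if not np.all(np.isfinite(x)):
        raise InvalidInputError("signal contains non-finite samples")
    n = len(x)
    spec = np.abs(np.fft.rfft(x)) * 2.0 / n
    if n % 2 == 0:
        spec[-1] /= 2.0  # Nyquist bin is not doubled
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    return MagnitudeSpectrum(freqs[1:], spec[1:], duration_s=n / fs)


def noise_correct(spectrum: MagnitudeSpectrum) -> MagnitudeSpectrum:
    """Subtract the local noise baseline from every bin.

    The baseline at each bin is the mean amplitude of the bins at
    offsets +/-2..+/-5; at spectrum edges the neighbour set shrinks to the
    available offsets.  The operation is linear, zeroes flat and linear
    backgrounds at interior bins, and leaves an isolated peak intact.
    """
    a = spectrum.amplitudes
    n = len(a)
    if n < 11:
        raise InvalidInputError("need at least 11 bins for +/-2..+/-5 correction")
    acc = np.zeros(n)
    cnt = np.zeros(n)
    for off in (-5, -4, -3, -2, 2, 3, 4, 5):
        if off > 0:
            acc[: n - off] += a[off:]
            cnt[: n - off] += 1
        else:
            acc[-off:] += a[: n + off]
            cnt[-off:] += 1
    return MagnitudeSpectrum(
        spectrum.frequencies, a - acc / cnt, spectrum.duration_s
    )


# ---------------------------------------------------------------------------
# Seed syncopation score
# ---------------------------------------------------------------------------


def seed_syncopation_zscore(
    pattern: GridPattern,
    beat_freqs: Sequence[float] = BEAT_FREQS,
    tone: ToneSpec | None = None,
    fs: float = DEFAULT_AUDIO_FS,
    ddof: int = 1,
) -> float:
    """Beat-related z-score of one 2.4 s seed rhythm.

    The rhythm is synthesised, its Hilbert envelope taken, and the first
    12 modulation-spectrum bins (1/2.4 Hz up to the 5 Hz grid rate)
    standardised; the mean z over ``beat_freqs`` is returned.  Negative
    values mean the rhythm's amplitude modulation carries weak beat cues
    (the syncopation criterion for admitting a seed).
    """
    from .envelope_frontend import hilbert_envelope  # avoid import cycle

    if tone is None:
        tone = ToneSpec()
    audio = synthesize_rhythm(pattern, tone, fs)
    env = hilbert_envelope(audio, fs)
    spec = magnitude_spectrum(env.samples, fs)
    n_bins = 12
    amps = spec.amplitudes[:n_bins]
    tol = 1e-6  # the 12-bin grid is exact; off-grid beat frequencies are errors
    idx = []
    for f in beat_freqs:
        i = spec.bin_index(f, tol)
        if i >= n_bins:
            raise InvalidParameterError(
                f"beat frequency {f} Hz lies outside the first {n_bins} bins"
            )
        idx.append(i)
    sd = np.std(amps, ddof=ddof)
    if sd == 0:
        raise UndefinedZScoreError("zero spread over the 12 modulation bins")
    z = (amps - np.mean(amps)) / sd
    return float(np.mean(z[idx]))


# ---------------------------------------------------------------------------
# Peak detection and FOI selection
# ---------------------------------------------------------------------------


def find_prominent_peaks(
    spectrum: MagnitudeSpectrum, f_max: float = PEAK_SEARCH_F_MAX
) -> list[float]:
    """Local maxima with topographic prominence >= mean + 2 SD of (0, f_max].

    Mirrors a findpeaks call with a data-driven minimum prominence;
    returns the peak frequencies (possibly empty).
    """
    from scipy.signal import find_peaks

    mask = (spectrum.frequencies > 0) & (spectrum.frequencies <= f_max)
    if not np.any(mask):
        raise InvalidInputError(f"spectrum does not cover (0, {f_max}] Hz")
    amps = spectrum.amplitudes[mask]
    freqs = spectrum.frequencies[mask]
    threshold = float(np.mean(amps) + 2.0 * np.std(amps, ddof=1))
    peaks, _ = find_peaks(amps, prominence=threshold)
    return [float(f) for f in freqs[peaks]]


@dataclass(frozen=True)
class FrequencySet:
    """Condition-specific beat-related and beat-unrelated FOIs (Hz)."""

    beat_related: tuple[float, ...]
    beat_unrelated: tuple[float, ...]
    condition: str = ""

    def __post_init__(self) -> None:
        if set(self.beat_related) & set(self.beat_unrelated):
            raise InvalidParameterError("beat-related/unrelated sets overlap")

    @property
    def all_frequencies(self) -> tuple[float, ...]:
        return tuple(sorted(self.beat_related + self.beat_unrelated))

    def __len__(self) -> int:
        return len(self.beat_related) + len(self.beat_unrelated)


def _snap(freqs: Iterable[float], grid: np.ndarray, tol: float) -> set[int]:
    """Map frequencies to indices of the shared bin grid (within tol)."""
    out = set()
    for f in freqs:
        i = int(np.argmin(np.abs(grid - f)))
        if abs(grid[i] - f) <= tol:
            out.add(i)
    return out


def _candidate_indices(
    spectrum: MagnitudeSpectrum,
    grid: np.ndarray,
    tol: float,
    min_freq: float,
    harmonic_base: float,
    f_max: float,
) -> set[int]:
    """Prominent-peak bins of one spectrum after the exclusion rules.

    Peaks below ``min_freq`` (slow pattern-rate region) and at integer
    multiples of ``harmonic_base`` (event-rate response shape) are
    dropped.
    """
    cand = _snap(find_prominent_peaks(spectrum, f_max), grid, tol)
    cand = {i for i in cand if grid[i] >= min_freq - tol}
    return {
        i
        for i in cand
        if not any(
            abs(grid[i] - k * harmonic_base) <= tol
            for k in range(1, int(f_max / harmonic_base) + 1)
        )
    }


def stimulus_frequency_sets(
    stim_spectra: Mapping[str, MagnitudeSpectrum],
    beat_freqs: Sequence[float] = BEAT_FREQS,
    min_freq: float = 1.25,
    harmonic_base: float = 5.0,
    f_max: float = PEAK_SEARCH_F_MAX,
    equalize: bool = True,
) -> dict[str, FrequencySet]:
    """Stimulus-only FOI selection (no EEG merge).

    Same prominence, exclusion, forcing and (optionally) equalisation
    rules as :func:`select_frequencies_of_interest`, but taking
    candidates from each condition's modulation spectrum alone — the
    form used to verify stimulus syncopation at sequence level before
    any EEG exists.
    """
    conditions = list(stim_spectra)
    grid = stim_spectra[conditions[0]].frequencies
    tol = 0.5 * float(grid[0])
    beat_idx = _snap(beat_freqs, grid, tol)
    if len(beat_idx) != len(beat_freqs):
        raise InvalidParameterError("a beat frequency is off the bin grid")
    candidates = {
        cond: _candidate_indices(
            stim_spectra[cond], grid, tol, min_freq, harmonic_base, f_max
        )
        | beat_idx
        for cond in conditions
    }
    m = min(len(c) for c in candidates.values()) if equalize else None
    if m is not None and m < len(beat_idx) + 1:
        raise DegenerateSelectionError("no beat-unrelated control frequencies")
    out = {}
    for cond in conditions:
        others = sorted(candidates[cond] - beat_idx)
        amps = stim_spectra[cond].amplitudes
        others.sort(key=lambda i: (-amps[i], grid[i]))
        if m is not None:
            others = others[: m - len(beat_idx)]
        out[cond] = FrequencySet(
            beat_related=tuple(sorted(float(grid[i]) for i in beat_idx)),
            beat_unrelated=tuple(sorted(float(grid[i]) for i in others)),
            condition=cond,
        )
    return out


def select_frequencies_of_interest(
    stim_spectra: Mapping[str, MagnitudeSpectrum],
    eeg_spectra: Mapping[str, Mapping[str, MagnitudeSpectrum]],
    beat_freqs: Sequence[float] = BEAT_FREQS,
    min_freq: float = 1.25,
    harmonic_base: float = 5.0,
    f_max: float = PEAK_SEARCH_F_MAX,
) -> dict[str, FrequencySet]:
    """Data-driven per-condition FOI selection.

    Per condition: (1) prominent peaks of each group's EEG spectrum,
    intersected across groups; (2) union with the stimulus-spectrum
    peaks; (3) drop frequencies below ``min_freq`` (slow pattern-rate
    region, unclassifiable 0.625 Hz, 1/f-contaminated bins); (4) drop
    ``harmonic_base`` (5 Hz) and its integer multiples (event-rate
    response shape); (5) equalise counts by keeping, in every condition,
    the m = min-over-conditions candidates with the largest stimulus
    amplitude, always forcing ``beat_freqs`` in; (6) classify
    ``beat_freqs`` as beat-related and the rest as beat-unrelated.

    All spectra must share one bin grid; nominal frequencies are matched
    to bins within half a bin width.  Ties on stimulus amplitude keep
    the lower frequency.
    """
    conditions = list(stim_spectra)
    grids = [stim_spectra[c].frequencies for c in conditions] + [
        g.frequencies for c in conditions for g in eeg_spectra[c].values()
    ]
    for g in grids[1:]:
        if len(g) != len(grids[0]) or not np.allclose(g, grids[0], rtol=1e-9):
            raise InvalidInputError("all spectra must share one frequency-bin grid")
    grid = grids[0]
    df = float(grid[0])
    tol = 0.5 * df

    beat_idx = _snap(beat_freqs, grid, tol)
    if len(beat_idx) != len(beat_freqs):
        raise InvalidParameterError("a beat frequency is off the shared bin grid")

    candidates: dict[str, set[int]] = {}
    for cond in conditions:
        groups = eeg_spectra[cond]
        if not groups:
            raise InvalidInputError(f"no EEG spectra for condition {cond!r}")
        eeg_sets = [
            _candidate_indices(spec, grid, tol, min_freq, harmonic_base, f_max)
            for spec in groups.values()
        ]
        eeg_common = set.intersection(*eeg_sets)
        stim_set = _candidate_indices(
            stim_spectra[cond], grid, tol, min_freq, harmonic_base, f_max
        )
        candidates[cond] = eeg_common | stim_set | beat_idx

    m = min(len(c) for c in candidates.values())
    if m < len(beat_idx) + 1:
        raise DegenerateSelectionError(
            f"only {m} candidate FOIs; no beat-unrelated control frequencies remain"
        )

    out: dict[str, FrequencySet] = {}
    for cond in conditions:
        others = sorted(candidates[cond] - beat_idx)
        amps = stim_spectra[cond].amplitudes
        # largest stimulus amplitude first; ties keep the lower frequency
        others.sort(key=lambda i: (-amps[i], grid[i]))
        keep = others[: m - len(beat_idx)]
        out[cond] = FrequencySet(
            beat_related=tuple(sorted(float(grid[i]) for i in beat_idx)),
            beat_unrelated=tuple(sorted(float(grid[i]) for i in keep)),
            condition=cond,
        )
    return out


# ---------------------------------------------------------------------------
# z-scoring and group statistics
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ZScoreResult:
    """Standardised FOI amplitudes and the mean beat-related z."""

    z_per_frequency: dict[float, float]
    beat_z: float
    condition: str = ""
    subject: str = ""
    group: str = ""


def zscore_frequency_set(
    spectrum: MagnitudeSpectrum,
    foi: FrequencySet,
    ddof: int = 1,
    **labels: str,
) -> ZScoreResult:
    """z-score amplitudes over the FOI set; mean z at beat frequencies.

    ``ddof=1`` (sample SD) is the default spread estimator; pass
    ``ddof=0`` for the population SD.
    """
    freqs = foi.all_frequencies
    amps = np.array([spectrum.amplitude_at(f) for f in freqs])
    sd = np.std(amps, ddof=ddof)
    if sd == 0:
        raise UndefinedZScoreError("zero spread across FOI amplitudes")
    z = (amps - np.mean(amps)) / sd
    z_map = {f: float(v) for f, v in zip(freqs, z)}
    beat_z = float(np.mean([z_map[f] for f in foi.beat_related]))
    return ZScoreResult(z_per_frequency=z_map, beat_z=beat_z, **labels)


def beat_enhancement_test(
    subject_beat_zs: Sequence[float], baseline: float
) -> tuple[float, float]:
    """One-sample, one-tailed t-test of beat_z against a sensory baseline.

    Tests whether the cohort's beat-related z-scores exceed the value
    predicted by the cochlear front-end (upper tail).  Returns
    ``(t, p_one_tailed)``; multiple-comparison (FDR) correction across a
    family of such tests is the caller's responsibility.
    """
    zs = np.asarray(subject_beat_zs, dtype=float)
    if zs.size < 2:
        raise InsufficientDataError("need at least 2 subjects")
    if np.ptp(zs) == 0:  # degenerate cohort: t is 0/0 or +/-inf
        if zs[0] == baseline:
            return 0.0, 0.5
        return (np.inf, 0.0) if zs[0] > baseline else (-np.inf, 1.0)
    res = stats.ttest_1samp(zs, popmean=baseline, alternative="greater")
    return float(res.statistic), float(res.pvalue)


def fdr_correct(pvalues: Sequence[float], alpha: float = 0.05) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values for a test family."""
    from statsmodels.stats.multitest import multipletests

    _, p_adj, _, _ = multipletests(pvalues, alpha=alpha, method="fdr_bh")
    return p_adj
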