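"""Grid-rhythm stimulus construction.

Seed rhythms live on a 12-slot grid of 200 ms time points (2.4 s per
rhythm): 8 slots carry a short pure tone, 4 are silent, and the
arrangement is constrained so that beat periodicities (1.25 Hz and
harmonics) are *not* prominent in the rhythm's amplitude-modulation
spectrum — i.e. the rhythms are syncopated.  Seed rhythms are
concatenated into 67.2 s sequences whose degree of pattern repetition is
the experimental manipulation: a 4.8 s two-seed pattern looped 14 times
(medium repetition), a 9.6 s four-seed pattern looped 7 times (long
repetition), or 28 draws from the library with no looping (no
repetition).

Tempo-change snippets (a cosine warp of the grid interval over 4.8 s)
and the two-down one-up staircase that titrates their magnitude are also
implemented here; they belong to the vigilance task appended after the
steady-tempo part of each trial.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Literal, Sequence

import numpy as np
from scipy.io import wavfile

__all__ = [
    "GridPattern",
    "ToneSpec",
    "SequenceSpec",
    "TempoModulation",
    "StaircaseState",
    "carrier_frequencies",
    "synthesize_tone",
    "synthesize_rhythm",
    "generate_seed_library",
    "select_condition_patterns",
    "assemble_sequence",
    "apply_tempo_modulation",
    "staircase_update",
    "write_wav",
    "write_manifest",
]

#: Default grid interval (s): 12 slots of 200 ms make one 2.4 s rhythm.
GRID_INTERVAL_S = 0.2
#: Slots per seed rhythm.
N_SLOTS = 12
#: Sound / silent slot counts for conformant seeds.
N_SOUND = 8
N_SILENT = 4
#: Default audio sampling rate (Hz).
DEFAULT_AUDIO_FS = 44_100
#: Seeds per 67.2 s sequence (28 x 2.4 s).
SEEDS_PER_SEQUENCE = 28


class InvalidParameterError(ValueError):
    """A stimulus parameter is outside its valid range."""


class SearchFailureError(RuntimeError):
    """A constrained random search exhausted its iteration budget."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GridPattern:
    """Boolean occupancy of a 12-slot, 200 ms rhythm grid.

    ``slots[k]`` is True when slot ``k`` (time ``[k*grid_interval,
    (k+1)*grid_interval)``, 0-based) carries a sound event.
    """

    slots: tuple[bool, ...]
    grid_interval_s: float = GRID_INTERVAL_S

    def __post_init__(self) -> None:
        object.__setattr__(self, "slots", tuple(bool(s) for s in self.slots))
        if len(self.slots) != N_SLOTS:
            raise InvalidParameterError(
                f"a grid pattern has exactly {N_SLOTS} slots, got {len(self.slots)}"
            )
        if self.grid_interval_s <= 0:
            raise InvalidParameterError("grid interval must be positive")

    @property
    def duration_s(self) -> float:
        return len(self.slots) * self.grid_interval_s

    @property
    def n_sound(self) -> int:
        return sum(self.slots)

    def is_conformant(self) -> bool:
        """True when the pattern has the canonical 8 sound / 4 silent split."""
        return self.n_sound == N_SOUND

    def rotate(self, k: int) -> "GridPattern":
        """Circularly rotate the slot occupancy by ``k`` slots."""
        k %= N_SLOTS
        return replace(self, slots=self.slots[k:] + self.slots[:k])


@dataclass(frozen=True)
class ToneSpec:
    """A short pure tone with linear onset/offset ramps.

    The nominal presentation level (dB A) is retained as metadata only;
    digital amplitude is normalised to ``peak_amplitude`` and loudspeaker
    calibration is left to the playback chain.
    """

    carrier_hz: float = 150.0
    duration_s: float = 0.2
    ramp_up_s: float = 0.010
    ramp_down_s: float = 0.020
    level_dba: float = 70.0
    peak_amplitude: float = 1.0

    def __post_init__(self) -> None:
        if self.carrier_hz <= 0:
            raise InvalidParameterError("carrier frequency must be positive")
        if self.ramp_up_s + self.ramp_down_s >= self.duration_s:
            raise InvalidParameterError("ramps must fit inside the tone duration")


Condition = Literal["medium_repetition", "long_repetition", "no_repetition"]

#: 1-based library IDs making up the looped patterns, mirroring the
#: two-seed (4.8 s) and four-seed (9.6 s) published arrangements.
DEFAULT_MEDIUM_PATTERN: tuple[int, ...] = (5, 10)
DEFAULT_LONG_PATTERN: tuple[int, ...] = (5, 10, 8, 9)


@dataclass(frozen=True)
class SequenceSpec:
    """Recipe for one 67.2 s stimulus sequence.

    ``order`` is resolved lazily by :func:`resolve_order` /
    :func:`assemble_sequence`; for looped conditions it is the loop of
    ``medium_pattern`` or ``long_pattern``, for the no-repetition
    condition it is a constrained random draw.
    """

    condition: Condition
    seed_library: tuple[GridPattern, ...]
    rng_seed: int = 0
    medium_pattern: tuple[int, ...] = DEFAULT_MEDIUM_PATTERN
    long_pattern: tuple[int, ...] = DEFAULT_LONG_PATTERN
    order: tuple[int, ...] | None = None

    def library_pattern(self, seed_id: int) -> GridPattern:
        """Look up a pattern by its 1-based library ID."""
        return self.seed_library[seed_id - 1]


@dataclass(frozen=True)
class TempoModulation:
    """Cosine warp of the grid interval over a 4.8 s snippet.

    The instantaneous grid interval starts at the baseline, follows half
    a cosine cycle out to the extremum (``max`` for decelerations,
    ``min`` for accelerations) and returns to baseline at the snippet
    end.  The fixed-magnitude values 188.7 / 217.4 ms are those used for
    musicians; for non-musicians the extremum is set per trial by the
    staircase.
    """

    direction: Literal["accelerate", "decelerate", "none"] = "none"
    span_s: float = 4.8
    min_grid_interval_s: float = 0.1887
    max_grid_interval_s: float = 0.2174
    baseline_grid_interval_s: float = GRID_INTERVAL_S

    def __post_init__(self) -> None:
        if self.min_grid_interval_s >= self.max_grid_interval_s:
            raise InvalidParameterError("min grid interval must be below max")
        if self.span_s <= 0:
            raise InvalidParameterError("modulation span must be positive")


@dataclass(frozen=True)
class StaircaseState:
    """State of a two-down one-up adaptive staircase on the grid interval.

    Difficulty increases (the extremum interval moves 8 ms toward the
    200 ms baseline, shrinking the tempo change) after two consecutive
    correct responses, and decreases (8 ms away from baseline) after
    every incorrect response.  The procedure converges on the ~70.7 %
    correct point of the underlying psychometric function.
    """

    current_value_s: float
    direction: Literal["accelerate", "decelerate"]
    step_s: float = 0.008
    baseline_s: float = GRID_INTERVAL_S
    consecutive_correct: int = 0
    history: tuple[tuple[float, bool], ...] = ()


# ---------------------------------------------------------------------------
# Tone and rhythm synthesis
# ---------------------------------------------------------------------------


def carrier_frequencies(n: int, f_low: float, f_high: float) -> list[float]:
    """Geometrically spaced carrier frequencies from ``f_low`` to ``f_high``.

    The 5-point series from 150 to 200 Hz reproduces the published
    carriers [150.00, 161.19, 173.21, 186.12, 200.00] Hz, one per
    successive trial.  Values are rounded to 2 decimals for reporting.
    """
    if n < 1:
        raise InvalidParameterError("need at least one carrier")
    if f_low <= 0 or f_high <= 0 or f_low > f_high:
        raise InvalidParameterError("need 0 < f_low <= f_high")
    if n == 1:
        return [round(float(f_low), 2)]
    freqs = f_low * (f_high / f_low) ** (np.arange(n) / (n - 1))
    return [round(float(f), 2) for f in freqs]


def synthesize_tone(tone: ToneSpec, fs: float) -> np.ndarray:
    """Render one ramped pure tone at sampling rate ``fs``."""
    if fs < 2 * tone.carrier_hz:
        raise InvalidParameterError(
            f"fs={fs} is below Nyquist for a {tone.carrier_hz} Hz carrier"
        )
    n = int(round(tone.duration_s * fs))
    t = np.arange(n) / fs
    wave = np.sin(2 * np.pi * tone.carrier_hz * t)
    env = np.ones(n)
    n_up = int(round(tone.ramp_up_s * fs))
    n_down = int(round(tone.ramp_down_s * fs))
    if n_up:
        env[:n_up] = np.linspace(0.0, 1.0, n_up, endpoint=False)
    if n_down:
        env[n - n_down :] = np.linspace(1.0, 0.0, n_down + 1)[1:]
    return tone.peak_amplitude * wave * env


def synthesize_rhythm(
    pattern: GridPattern, tone: ToneSpec, fs: float = DEFAULT_AUDIO_FS
) -> np.ndarray:
    """Render one grid pattern as audio; silent slots are exact zeros."""
    slot_n = int(round(pattern.grid_interval_s * fs))
    out = np.zeros(slot_n * N_SLOTS)
    burst = synthesize_tone(tone, fs)
    m = min(len(burst), slot_n)
    for k, occupied in enumerate(pattern.slots):
        if occupied:
            out[k * slot_n : k * slot_n + m] = burst[:m]
    return out


# ---------------------------------------------------------------------------
# Seed-library search
# ---------------------------------------------------------------------------


def _default_score_fn() -> Callable[[GridPattern], float]:
    # deferred import: the syncopation score lives with the spectral code
    from .freq_tagging import seed_syncopation_zscore

    return seed_syncopation_zscore


def generate_seed_library(
    n_seeds: int = 14,
    rng_seed: int = 0,
    score_fn: Callable[[GridPattern], float] | None = None,
    max_iter: int = 2000,
) -> list[GridPattern]:
    """Rejection-sample syncopated seed rhythms.

    Draws 8-sound/4-silent arrangements from the 12-choose-4 silent-slot
    placements and keeps those whose beat-related z-score (mean
    standardised modulation-spectrum amplitude at 1.25/2.5/3.75 Hz) is
    strictly negative, i.e. rhythms that do not acoustically emphasise
    the beat.  Deterministic for a given ``rng_seed``.
    """
    if score_fn is None:
        score_fn = _default_score_fn()
    rng = np.random.default_rng(rng_seed)
    # enumerate all silent-slot placements once, shuffle, then scan:
    # bounded and deterministic, and cheap relative to scoring
    placements = list(itertools.combinations(range(N_SLOTS), N_SILENT))
    rng.shuffle(placements)
    library: list[GridPattern] = []
    seen: set[tuple[bool, ...]] = set()
    tried = 0
    for silent in placements:
        if len(library) >= n_seeds:
            break
        if tried >= max_iter:
            break
        tried += 1
        slots = tuple(k not in silent for k in range(N_SLOTS))
        if slots in seen:
            continue
        seen.add(slots)
        pattern = GridPattern(slots)
        if score_fn(pattern) < 0:
            library.append(pattern)
    if len(library) < n_seeds:
        raise SearchFailureError(
            f"found only {len(library)}/{n_seeds} syncopated seeds "
            f"after {tried} candidates (budget {max_iter})"
        )
    return library


def select_condition_patterns(
    seed_library: Sequence[GridPattern],
    rng_seed: int = 0,
    fs: float = 2205.0,
    tone: ToneSpec | None = None,
) -> tuple[tuple[int, ...], tuple[int, ...]]:
    """Choose the looped medium (2-seed) and long (4-seed) patterns.

    Assembled sequences are controlled to carry similarly weak beat
    cues: each candidate loop is scored by the beat-related z-score of
    its full-sequence Hilbert-envelope modulation spectrum (prominent
    peaks, <1.25 Hz and 5 Hz-multiple exclusions, beat frequencies
    forced), and the medium pair is the one with negative score closest
    to the no-repetition sequence's score; the long pattern extends the
    medium pair by two more seeds under the same criterion, with no
    identical adjacent seeds within the looped cycle.  Scoring runs at a
    reduced audio rate — the magnitude spectrum of the envelope is
    rate-invariant well above the carrier's Nyquist — and is
    deterministic given ``rng_seed``.
    """
    from .envelope_frontend import hilbert_envelope
    from .freq_tagging import (
        magnitude_spectrum,
        stimulus_frequency_sets,
        zscore_frequency_set,
    )

    if tone is None:
        tone = ToneSpec()
    rendered = [synthesize_rhythm(p, tone, fs) for p in seed_library]

    def order_z(order: Sequence[int]) -> float:
        audio = np.concatenate([rendered[i - 1] for i in order])
        spec = magnitude_spectrum(hilbert_envelope(audio, fs).samples, fs)
        foi = stimulus_frequency_sets({"c": spec}, equalize=False)["c"]
        return zscore_frequency_set(spec, foi).beat_z

    def loop_z(cycle: Sequence[int]) -> float:
        return order_z(tuple(cycle) * (SEEDS_PER_SEQUENCE // len(cycle)))

    # reference: the no-repetition draw this rng_seed produces
    ref_spec = SequenceSpec(
        condition="no_repetition",
        seed_library=tuple(seed_library),
        rng_seed=rng_seed,
    )
    z_ref = order_z(resolve_order(ref_spec))

    n = len(seed_library)
    best_pair, best_d = None, np.inf
    for i in range(1, n + 1):
        for j in range(i + 1, n + 1):
            z = loop_z((i, j))
            if z < 0 and abs(z - z_ref) < best_d:
                best_pair, best_d = (i, j), abs(z - z_ref)
    if best_pair is None:
        raise SearchFailureError("no seed pair yields a negative sequence z-score")
    z_medium = loop_z(best_pair)

    best_quad, best_d = None, np.inf
    a, b = best_pair
    rest = [k for k in range(1, n + 1)]
    for c in rest:
        if c == b:
            continue
        for d in rest:
            if d in (c, a):
                continue
            if (c, d) == (a, b):  # would collapse to the medium loop
                continue
            z = loop_z((a, b, c, d))
            if z < 0 and abs(z - z_medium) < best_d:
                best_quad, best_d = (a, b, c, d), abs(z - z_medium)
    if best_quad is None:
        raise SearchFailureError("no seed quad yields a negative sequence z-score")
    return best_pair, best_quad


# ---------------------------------------------------------------------------
# Sequence assembly
# ---------------------------------------------------------------------------


def _contains_contiguous(order: Sequence[int], sub: Sequence[int]) -> bool:
    sub = tuple(sub)
    n = len(sub)
    return any(tuple(order[i : i + n]) == sub for i in range(len(order) - n + 1))


def resolve_order(spec: SequenceSpec, max_iter: int = 10_000) -> tuple[int, ...]:
    """Resolve the 28-seed order for a sequence spec.

    Looped conditions tile their pattern; the no-repetition condition
    draws 28 seeds such that no two adjacent seeds are identical and no
    contiguous subsequence reproduces the medium (2-seed) or long
    (4-seed) looped patterns.
    """
    if spec.order is not None:
        if len(spec.order) != SEEDS_PER_SEQUENCE:
            raise InvalidParameterError(
                f"an explicit order must list {SEEDS_PER_SEQUENCE} seeds"
            )
        return tuple(spec.order)
    if spec.condition == "medium_repetition":
        return spec.medium_pattern * (SEEDS_PER_SEQUENCE // len(spec.medium_pattern))
    if spec.condition == "long_repetition":
        return spec.long_pattern * (SEEDS_PER_SEQUENCE // len(spec.long_pattern))

    rng = np.random.default_rng(spec.rng_seed)
    ids = np.arange(1, len(spec.seed_library) + 1)
    for _ in range(max_iter):
        order = [int(rng.choice(ids))]
        ok = True
        for _ in range(SEEDS_PER_SEQUENCE - 1):
            # grow left-to-right, re-drawing until local constraints hold
            for _attempt in range(200):
                cand = int(rng.choice(ids))
                if cand == order[-1]:
                    continue
                trial = order + [cand]
                tail2 = tuple(trial[-len(spec.medium_pattern) :])
                tail4 = tuple(trial[-len(spec.long_pattern) :])
                if tail2 == tuple(spec.medium_pattern):
                    continue
                if len(trial) >= len(spec.long_pattern) and tail4 == tuple(
                    spec.long_pattern
                ):
                    continue
                order.append(cand)
                break
            else:
                ok = False
                break
        if ok and not _contains_contiguous(order, spec.medium_pattern):
            return tuple(order)
    raise SearchFailureError(
        f"no admissible no-repetition order found in {max_iter} restarts"
    )


def assemble_sequence(
    spec: SequenceSpec,
    tone: ToneSpec | None = None,
    fs: float = DEFAULT_AUDIO_FS,
) -> tuple[np.ndarray, dict]:
    """Assemble one 67.2 s sequence; returns (waveform, manifest).

    The manifest records the condition, rng seed, resolved seed IDs, the
    looped pattern cycle (empty for no-repetition) and the grid interval,
    and is JSON-serialisable as-is.
    """
    if tone is None:
        tone = ToneSpec()
    order = resolve_order(spec)
    rendered: dict[int, np.ndarray] = {}
    chunks = []
    for seed_id in order:
        if seed_id not in rendered:
            rendered[seed_id] = synthesize_rhythm(
                spec.library_pattern(seed_id), tone, fs
            )
        chunks.append(rendered[seed_id])
    audio = np.concatenate(chunks)
    cycle = {
        "medium_repetition": list(spec.medium_pattern),
        "long_repetition": list(spec.long_pattern),
        "no_repetition": [],
    }[spec.condition]
    grid = spec.seed_library[0].grid_interval_s
    pattern_duration = len(cycle) * N_SLOTS * grid if cycle else None
    manifest = {
        "condition": spec.condition,
        "rng_seed": spec.rng_seed,
        "seed_ids": list(order),
        "pattern_cycle": cycle,
        "pattern_duration_s": pattern_duration,
        "pattern_repetition_hz": (
            round(1.0 / pattern_duration, 3) if pattern_duration else None
        ),
        "grid_interval_s": grid,
        "fs": fs,
        "duration_s": len(audio) / fs,
    }
    return audio, manifest


# ---------------------------------------------------------------------------
# Tempo modulation and staircase
# ---------------------------------------------------------------------------


def modulated_grid_intervals(mod: TempoModulation, n_slots: int) -> np.ndarray:
    """Instantaneous grid interval per slot under the cosine warp.

    The interval runs baseline -> extremum -> baseline over ``n_slots``
    slots following (1 - cos)/2 of one full cycle, so the extremum is
    reached exactly mid-snippet.
    """
    if mod.direction == "none":
        return np.full(n_slots, mod.baseline_grid_interval_s)
    extremum = (
        mod.max_grid_interval_s
        if mod.direction == "decelerate"
        else mod.min_grid_interval_s
    )
    phase = 2 * np.pi * np.arange(n_slots) / n_slots
    depth = (1 - np.cos(phase)) / 2.0
    return mod.baseline_grid_interval_s + depth * (
        extremum - mod.baseline_grid_interval_s
    )


def apply_tempo_modulation(
    base_sequence_tail: Sequence[GridPattern],
    mod: TempoModulation,
    tone: ToneSpec | None = None,
    fs: float = DEFAULT_AUDIO_FS,
) -> tuple[np.ndarray, np.ndarray]:
    """Render a snippet whose event grid is cosine-warped in time.

    Event onsets are remapped (audio is not resampled, so the carrier
    pitch is unchanged); returns ``(audio, slot_onsets_s)``.  With
    ``direction='none'`` the output equals the unwarped rendering of the
    tail.
    """
    if tone is None:
        tone = ToneSpec()
    slots = [s for p in base_sequence_tail for s in p.slots]
    n_slots = len(slots)
    expected = int(round(mod.span_s / mod.baseline_grid_interval_s))
    if mod.direction != "none" and n_slots != expected:
        raise InvalidParameterError(
            f"a {mod.span_s} s modulation covers {expected} slots, got {n_slots}"
        )
    intervals = modulated_grid_intervals(mod, n_slots)
    onsets = np.concatenate([[0.0], np.cumsum(intervals[:-1])])
    total = float(np.sum(intervals))
    audio = np.zeros(int(round(total * fs)))
    burst = synthesize_tone(tone, fs)
    for onset, occupied in zip(onsets, slots):
        if not occupied:
            continue
        i0 = int(round(onset * fs))
        m = min(len(burst), len(audio) - i0)
        audio[i0 : i0 + m] += burst[:m]
    return audio, onsets


def staircase_update(
    state: StaircaseState, correct: bool
) -> StaircaseState:
    """Advance a two-down one-up staircase by one response.

    Harder means the extremum grid interval moves ``step_s`` toward the
    200 ms baseline (a smaller tempo change); easier moves it away.
    """
    toward_baseline = np.sign(state.baseline_s - state.current_value_s)
    if toward_baseline == 0:
        toward_baseline = 1.0 if state.direction == "accelerate" else -1.0
    history = state.history + ((state.current_value_s, bool(correct)),)
    if correct:
        streak = state.consecutive_correct + 1
        if streak >= 2:
            return replace(
                state,
                current_value_s=state.current_value_s
                + float(toward_baseline) * state.step_s,
                consecutive_correct=0,
                history=history,
            )
        return replace(state, consecutive_correct=streak, history=history)
    return replace(
        state,
        current_value_s=state.current_value_s - float(toward_baseline) * state.step_s,
        consecutive_correct=0,
        history=history,
    )


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------


def write_wav(path: str | Path, audio: np.ndarray, fs: float) -> None:
    """Write float32 WAV (unit-peak convention)."""
    wavfile.write(str(path), int(fs), audio.astype(np.float32))


def write_manifest(path: str | Path, manifest: dict) -> None:
    Path(path).write_text(json.dumps(manifest, indent=2) + "\n")


def read_manifest(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())
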