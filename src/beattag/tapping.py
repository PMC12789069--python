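"""Tapping analysis: intertap intervals, perceived beat period, and
circular tapping stability.

Participants tap the pulse they perceive; the median intertap interval
(ITI) indexes the tapped beat period, the nearest integer multiple of
the 200 ms grid is the *predicted beat period*, and the length of the
mean resultant vector of tap phases relative to that period measures
how stably the taps lock to it (0 = phases uniform, 1 = perfectly
periodic).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .rhythm_stimuli import GRID_INTERVAL_S

__all__ = [
    "TapTrain",
    "StabilityResult",
    "intertap_intervals",
    "predicted_beat_period",
    "tapping_stability",
    "analyze_tap_train",
    "analyze_taps_csv",
]

#: Trial duration (s) taps must fall into.
TRIAL_DURATION_S = 67.2
#: Default debounce window (s): onsets closer than this are merged
#: (hardware double-trigger guard).
DEBOUNCE_S = 0.1


class InsufficientDataError(ValueError):
    pass


class InvalidParameterError(ValueError):
    pass


@dataclass(frozen=True)
class TapTrain:
    """Tap onset times (s from trial start) for one trial."""

    onsets: np.ndarray
    subject: str = ""
    condition: str = ""
    trial: int = 0

    def __post_init__(self) -> None:
        onsets = np.asarray(self.onsets, dtype=float)
        object.__setattr__(self, "onsets", onsets)
        if onsets.ndim != 1:
            raise InvalidParameterError("onsets must be 1-D")
        if onsets.size and (np.any(np.diff(onsets) <= 0)):
            raise InvalidParameterError("onsets must be strictly increasing")
        if onsets.size and (onsets[0] < 0 or onsets[-1] > TRIAL_DURATION_S):
            raise InvalidParameterError(
                f"onsets must lie in [0, {TRIAL_DURATION_S}] s"
            )

    def debounced(self, min_separation_s: float = DEBOUNCE_S) -> "TapTrain":
        """Merge onsets closer than ``min_separation_s`` (keep the first)."""
        if self.onsets.size == 0:
            return self
        keep = [self.onsets[0]]
        for t in self.onsets[1:]:
            if t - keep[-1] >= min_separation_s:
                keep.append(t)
        return TapTrain(
            np.array(keep), subject=self.subject, condition=self.condition,
            trial=self.trial,
        )


@dataclass(frozen=True)
class StabilityResult:
    median_iti_s: float
    beat_period_s: float
    stability: float
    subject: str = ""
    condition: str = ""
    trial: int = 0


def intertap_intervals(train: TapTrain) -> np.ndarray:
    """Durations between successive taps (n-1 values)."""
    if train.onsets.size < 2:
        raise InsufficientDataError("need at least 2 taps for ITIs")
    return np.diff(train.onsets)


def predicted_beat_period(
    median_iti_s: float,
    grid_interval_s: float = GRID_INTERVAL_S,
    max_multiple: int = 12,
) -> float:
    """Metric period (k x grid interval, k = 1..max_multiple) nearest the median ITI.

    Ties between two candidates are broken toward the smaller period.
    A median ITI of 0.8 s maps to k=4 (1.25 Hz); 0.41 s maps to k=2
    (2.5 Hz).
    """
    if median_iti_s <= 0:
        raise InvalidParameterError("median ITI must be positive")
    candidates = grid_interval_s * np.arange(1, max_multiple + 1)
    errors = np.abs(candidates - median_iti_s)
    # argmin returns the first (smaller-period) candidate on exact ties
    return float(candidates[int(np.argmin(errors))])


def tapping_stability(train: TapTrain, beat_period_s: float) -> float:
    """Mean resultant length of tap phases relative to the beat period.

    Phases are 2*pi*(onset mod period)/period; the result
    |mean(exp(i*phase))| lies in [0, 1] and is invariant to a global
    time shift of all taps.
    """
    if beat_period_s <= 0:
        raise InvalidParameterError("beat period must be positive")
    if train.onsets.size < 2:
        raise InsufficientDataError("need at least 2 taps")
    phases = 2 * np.pi * np.mod(train.onsets, beat_period_s) / beat_period_s
    return float(np.abs(np.mean(np.exp(1j * phases))))


def analyze_tap_train(
    train: TapTrain,
    grid_interval_s: float = GRID_INTERVAL_S,
    debounce_s: float = DEBOUNCE_S,
) -> StabilityResult:
    """Median ITI -> predicted beat period -> circular stability, one trial."""
    train = train.debounced(debounce_s)
    itis = intertap_intervals(train)
    median_iti = float(np.median(itis))
    period = predicted_beat_period(median_iti, grid_interval_s)
    return StabilityResult(
        median_iti_s=median_iti,
        beat_period_s=period,
        stability=tapping_stability(train, period),
        subject=train.subject,
        condition=train.condition,
        trial=train.trial,
    )


def analyze_taps_csv(
    in_path: str | Path, out_path: str | Path | None = None
) -> pd.DataFrame:
    """Analyze a taps CSV (subject, condition, trial, onset_s) per trial.

    Returns (and optionally writes) a table with columns subject,
    condition, trial, median_iti_s, beat_period_s, stability.
    """
    df = pd.read_csv(in_path)
    rows = []
    for (subject, condition, trial), g in df.groupby(
        ["subject", "condition", "trial"], sort=True
    ):
        train = TapTrain(
            np.sort(g["onset_s"].to_numpy()),
            subject=str(subject), condition=str(condition), trial=int(trial),
        )
        r = analyze_tap_train(train)
        rows.append(
            dict(
                subject=r.subject, condition=r.condition, trial=r.trial,
                median_iti_s=r.median_iti_s, beat_period_s=r.beat_period_s,
                stability=r.stability,
            )
        )
    out = pd.DataFrame(rows)
    if out_path is not None:
        out.to_csv(out_path, index=False)
    return out
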