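"""EEG preprocessing: filter, re-reference, average, pool.

Takes cleaned (artifact-free) multichannel trials for one subject and
condition and reduces them to the single frontocentral waveform whose
magnitude spectrum the frequency-tagging analysis consumes: 0.1 Hz
high-pass, mastoid re-reference, time-domain trial averaging, then
averaging over 9 frontocentral channels.  Artifact rejection, ICA and
bad-channel interpolation are assumed already applied upstream; the
only validation here is that samples are finite.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import signal

__all__ = [
    "EEGTrialSet",
    "FRONTOCENTRAL_CHANNELS",
    "MASTOID_CHANNELS",
    "highpass_filter",
    "rereference_mastoids",
    "average_and_pool",
    "preprocess",
    "read_trials_csv",
    "write_trials_csv",
    "read_raw_edf_trials",
]

#: The 9 pooled frontocentral channels (10-20 names).
FRONTOCENTRAL_CHANNELS: tuple[str, ...] = (
    "F1", "Fz", "F2", "FC1", "FCz", "FC2", "C1", "Cz", "C2",
)
#: Mastoid reference channels.
MASTOID_CHANNELS: tuple[str, ...] = ("M1", "M2")
#: EEG sampling rate (Hz) and trial length in samples (~67.2 s).
EEG_FS = 512.0
TRIAL_SAMPLES = round(67.2 * EEG_FS)


class InvalidParameterError(ValueError):
    pass


class MissingChannelError(KeyError):
    pass


class InsufficientDataError(ValueError):
    pass


@dataclass(frozen=True)
class EEGTrialSet:
    """Cleaned EEG trials for one subject and condition.

    ``trials`` has shape (n_trials, n_channels, n_samples); all trials
    share one length and channel ordering given by ``channel_labels``.
    """

    trials: np.ndarray
    fs: float
    channel_labels: tuple[str, ...]
    condition: str = ""
    subject: str = ""
    group: str = ""
    order: str = ""

    def __post_init__(self) -> None:
        t = np.asarray(self.trials, dtype=float)
        object.__setattr__(self, "trials", t)
        object.__setattr__(self, "channel_labels", tuple(self.channel_labels))
        if t.ndim != 3:
            raise InvalidParameterError("trials must be (n_trials, n_channels, n_samples)")
        if t.shape[1] != len(self.channel_labels):
            raise InvalidParameterError("channel label count mismatch")
        if not np.all(np.isfinite(t)):
            raise InvalidParameterError(
                "non-finite samples: artifact cleaning is assumed upstream"
            )

    @property
    def n_trials(self) -> int:
        return self.trials.shape[0]

    def channel_index(self, label: str) -> int:
        try:
            return self.channel_labels.index(label)
        except ValueError:
            raise MissingChannelError(label) from None


def highpass_filter(
    trialset: EEGTrialSet, cutoff: float = 0.1, order: int = 4
) -> EEGTrialSet:
    """Zero-phase Butterworth high-pass on every channel of every trial."""
    if cutoff >= trialset.fs / 2:
        raise InvalidParameterError("cutoff at/above Nyquist")
    sos = signal.butter(order, cutoff, btype="high", fs=trialset.fs, output="sos")
    filtered = signal.sosfiltfilt(sos, trialset.trials, axis=-1)
    return replace(trialset, trials=filtered)


def rereference_mastoids(
    trialset: EEGTrialSet, mastoid_labels: Sequence[str] = MASTOID_CHANNELS
) -> EEGTrialSet:
    """Subtract the mastoid average from every channel at every sample."""
    idx = [trialset.channel_index(m) for m in mastoid_labels]
    ref = trialset.trials[:, idx, :].mean(axis=1, keepdims=True)
    return replace(trialset, trials=trialset.trials - ref)


def average_and_pool(
    trialset: EEGTrialSet,
    pool_labels: Sequence[str] = FRONTOCENTRAL_CHANNELS,
    first_n_trials: int | None = None,
) -> np.ndarray:
    """Trial-mean then frontocentral channel-mean -> one waveform.

    ``first_n_trials`` subselects the leading trials before averaging
    (the exposure-equalisation control retains the first 5 of 10 trials
    of the medium-repetition condition).
    """
    trials = trialset.trials
    if first_n_trials is not None:
        trials = trials[:first_n_trials]
    if trials.shape[0] == 0:
        raise InsufficientDataError("no trials to average")
    idx = [trialset.channel_index(c) for c in pool_labels]
    return trials.mean(axis=0)[idx, :].mean(axis=0)


def preprocess(
    trialset: EEGTrialSet,
    cutoff: float = 0.1,
    order: int = 4,
    pool_labels: Sequence[str] = FRONTOCENTRAL_CHANNELS,
    first_n_trials: int | None = None,
) -> np.ndarray:
    """Full chain: high-pass -> mastoid re-reference -> average & pool."""
    ts = highpass_filter(trialset, cutoff=cutoff, order=order)
    ts = rereference_mastoids(ts)
    return average_and_pool(ts, pool_labels=pool_labels, first_n_trials=first_n_trials)


# ---------------------------------------------------------------------------
# I/O — binary-free CSV trials, plus BDF/EDF via MNE when available
# ---------------------------------------------------------------------------


def write_trials_csv(directory: str | Path, trialset: EEGTrialSet) -> list[Path]:
    """One CSV per trial (sample rows x channel columns, label header)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    header = ",".join(trialset.channel_labels)
    for i in range(trialset.n_trials):
        p = directory / f"trial_{i:03d}.csv"
        np.savetxt(
            p, trialset.trials[i].T, delimiter=",", header=header, comments=""
        )
        paths.append(p)
    return paths


def read_trials_csv(
    directory: str | Path, fs: float = EEG_FS, **labels: str
) -> EEGTrialSet:
    """Read a directory of per-trial CSVs written by :func:`write_trials_csv`."""
    directory = Path(directory)
    files = sorted(directory.glob("trial_*.csv"))
    if not files:
        raise InsufficientDataError(f"no trial_*.csv under {directory}")
    channel_labels: tuple[str, ...] | None = None
    trials = []
    for p in files:
        with open(p) as fh:
            labels_row = tuple(fh.readline().strip().split(","))
        if channel_labels is None:
            channel_labels = labels_row
        elif labels_row != channel_labels:
            raise InvalidParameterError(f"channel labels differ in {p}")
        trials.append(np.loadtxt(p, delimiter=",", skiprows=1).T)
    return EEGTrialSet(
        np.stack(trials), fs=fs, channel_labels=channel_labels, **labels
    )


def read_raw_edf_trials(
    path: str | Path,
    trial_onsets_s: Sequence[float],
    trial_duration_s: float = 67.2,
    **labels: str,
) -> EEGTrialSet:
    """Epoch a continuous BDF/EDF recording into an EEGTrialSet.

    Requires MNE; trials are cut [onset, onset + duration) at the file's
    sampling rate.
    """
    import mne  # optional dependency, imported lazily

    path = Path(path)
    reader = mne.io.read_raw_bdf if path.suffix.lower() == ".bdf" else mne.io.read_raw_edf
    raw = reader(path, preload=True, verbose="error")
    fs = float(raw.info["sfreq"])
    data = raw.get_data()
    n = int(round(trial_duration_s * fs))
    trials = []
    for onset in trial_onsets_s:
        i0 = int(round(onset * fs))
        if i0 + n > data.shape[1]:
            raise InvalidParameterError(f"trial at {onset} s overruns the recording")
        trials.append(data[:, i0 : i0 + n])
    return EEGTrialSet(
        np.stack(trials), fs=fs, channel_labels=tuple(raw.ch_names), **labels
    )
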