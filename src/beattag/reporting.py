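"""End-to-end study replica: stimuli -> envelopes -> (synthetic) EEG ->
FOI selection -> beat-related z-scores -> enhancement tests -> tables.

`run_pipeline` wires every stage together for a fully synthetic cohort:
it builds the seed library and the three 67.2 s sequences, extracts
Hilbert and cochlear envelopes, simulates per-subject EEG trials with a
configurable injected beat gain, runs the preprocessing and
frequency-tagging chain, and writes the per-subject beat_z table, the
FOI sets, the tapping-stability table, and the FDR-corrected
enhancement-test table, together with a JSON-lines run log.  A run is
reproducible from its config alone.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import sys
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .eeg_pipeline import TRIAL_SAMPLES, preprocess
from .envelope_frontend import (
    ANALYSIS_FS,
    cochlear_envelope,
    hilbert_envelope,
    resample_envelope,
)
from .freq_tagging import (
    BEAT_FREQS,
    FrequencySet,
    MagnitudeSpectrum,
    beat_enhancement_test,
    fdr_correct,
    magnitude_spectrum,
    noise_correct,
    select_frequencies_of_interest,
    zscore_frequency_set,
)
from .rhythm_stimuli import (
    DEFAULT_AUDIO_FS,
    SequenceSpec,
    ToneSpec,
    assemble_sequence,
    generate_seed_library,
    select_condition_patterns,
)
from .synthetic_data import (
    SyntheticEEGSpec,
    SyntheticTapSpec,
    synth_eeg,
    synth_taps,
)
from .tapping import analyze_tap_train

__all__ = ["RunConfig", "run_pipeline", "load_config", "pattern_exposure_counts"]


def pattern_exposure_counts(
    n_trials: int,
    equalize_exposure: bool,
    first_n_trials_medium: int = 5,
    sequence_duration_s: float = 67.2,
    medium_pattern_s: float = 4.8,
    long_pattern_s: float = 9.6,
) -> dict[str, int]:
    """Total looped-pattern presentations per repetition condition.

    Each medium trial presents 14 pattern cycles (67.2/4.8) and each
    long trial 7 (67.2/9.6); the exposure-equalisation control retains
    only the first ``first_n_trials_medium`` medium trials so that both
    conditions present the same number of patterns (70 at the full 10/5
    trial counts).
    """
    medium_trials = (
        min(first_n_trials_medium, n_trials) if equalize_exposure else n_trials
    )
    return {
        "medium_repetition": round(sequence_duration_s / medium_pattern_s)
        * medium_trials,
        "long_repetition": round(sequence_duration_s / long_pattern_s) * n_trials,
    }

logger = logging.getLogger("beattag")

CONDITIONS: tuple[str, ...] = (
    "medium_repetition",
    "long_repetition",
    "no_repetition",
)
GROUPS: tuple[str, ...] = ("musicians", "nonmusicians")
#: Condition orders: maximum prior context starts with the most
#: repetitive sequence; no prior context starts with the non-repeating one.
ORDERS: tuple[str, ...] = ("maximum_context", "no_context")


@dataclass(frozen=True)
class RunConfig:
    """Fully serialisable recipe for one pipeline run."""

    out_dir: str = "beattag_run"
    rng_seed: int = 0
    n_subjects_per_cell: int = 4
    n_trials: int = 2
    beat_gain: float = 0.1
    noise_scale: float = 0.5
    noise_exponent: float = 1.0
    equalize_exposure: bool = False
    first_n_trials_medium: int = 5
    conditions: tuple[str, ...] = CONDITIONS
    groups: tuple[str, ...] = GROUPS
    orders: tuple[str, ...] = ORDERS
    audio_fs: float = DEFAULT_AUDIO_FS
    cochlear_n_channels: int = 128
    n_seeds: int = 14
    beat_freqs: tuple[float, ...] = BEAT_FREQS
    zscore_ddof: int = 1

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2)


def load_config(path: str | Path) -> RunConfig:
    """Load a RunConfig from JSON or YAML."""
    text = Path(path).read_text()
    if str(path).endswith((".yml", ".yaml")):
        import yaml

        data = yaml.safe_load(text)
    else:
        data = json.loads(text)
    for key in ("conditions", "groups", "orders", "beat_freqs"):
        if key in data:
            data[key] = tuple(data[key])
    return RunConfig(**data)


def _setup_logging(out_dir: Path) -> logging.Handler:
    handler = logging.FileHandler(out_dir / "run_log.jsonl", mode="w")
    handler.setFormatter(logging.Formatter("%(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    if not any(isinstance(h, logging.StreamHandler) for h in logger.handlers):
        logger.addHandler(logging.StreamHandler(sys.stderr))
    return handler


def _log(stage: str, **fields) -> None:
    logger.info(json.dumps({"stage": stage, **fields}))


def _subject_seed(base: int, group: str, order: str, cond: str, subject: int) -> int:
    """Stable per-cell seed below 2**31, derived from the run seed."""
    from zlib import crc32

    tag = crc32(f"{group}|{order}|{cond}".encode())
    h = np.random.SeedSequence([base, tag, subject])
    return int(h.generate_state(1)[0] % 2**31)


def run_pipeline(config: RunConfig) -> dict:
    """Run the full study replica on a synthetic cohort.

    Returns a result bundle with the key tables (also written under
    ``config.out_dir``): ``beat_z`` (per subject/condition),
    ``foi`` (per condition), ``stability``, ``enhancement`` (with
    FDR-adjusted p), ``stimulus_beat_z`` and ``manifests``.
    """
    t0 = time.time()
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    handler = _setup_logging(out_dir)
    try:
        return _run(config, out_dir, t0)
    finally:
        logger.removeHandler(handler)
        handler.close()


def _run(config: RunConfig, out_dir: Path, t0: float) -> dict:
    (out_dir / "config.json").write_text(config.to_json() + "\n")
    _log("start", version=__version__, rng_seed=config.rng_seed)

    # --- stimuli -----------------------------------------------------------
    try:
        library = generate_seed_library(config.n_seeds, rng_seed=config.rng_seed)
    except Exception as exc:  # pragma: no cover - stage tagging only
        raise RuntimeError(f"stage rhythm_stimuli failed: {exc}") from exc
    tone = ToneSpec()
    medium_pattern, long_pattern = select_condition_patterns(
        library, rng_seed=config.rng_seed
    )
    audio: dict[str, np.ndarray] = {}
    manifests: dict[str, dict] = {}
    for cond in config.conditions:
        spec = SequenceSpec(
            condition=cond,
            seed_library=tuple(library),
            rng_seed=config.rng_seed,
            medium_pattern=medium_pattern,
            long_pattern=long_pattern,
        )
        audio[cond], manifests[cond] = assemble_sequence(spec, tone, config.audio_fs)
    _log(
        "stimuli",
        conditions=list(config.conditions),
        medium_pattern=list(medium_pattern),
        long_pattern=list(long_pattern),
    )

    # --- envelopes and stimulus spectra -----------------------------------
    stim_spectra: dict[str, MagnitudeSpectrum] = {}
    hilbert_env_512 = {}
    stim_beat_rows = []
    for cond in config.conditions:
        h = resample_envelope(
            hilbert_envelope(audio[cond], config.audio_fs),
            ANALYSIS_FS,
            n_samples=TRIAL_SAMPLES,
        )
        c = resample_envelope(
            cochlear_envelope(
                audio[cond], config.audio_fs, n_channels=config.cochlear_n_channels
            ),
            ANALYSIS_FS,
            n_samples=TRIAL_SAMPLES,
        )
        hilbert_env_512[cond] = h
        stim_spectra[cond] = magnitude_spectrum(c.samples, ANALYSIS_FS)
    _log("envelopes", analysis_fs=ANALYSIS_FS)

    # --- synthetic EEG cohort ---------------------------------------------
    pooled: dict[tuple, np.ndarray] = {}  # (group, order, cond, subj) -> waveform
    for group in config.groups:
        for order in config.orders:
            for cond in config.conditions:
                first_n = None
                if config.equalize_exposure and cond == "medium_repetition":
                    first_n = config.first_n_trials_medium
                for subj in range(config.n_subjects_per_cell):
                    seed = _subject_seed(
                        config.rng_seed, group, order, cond, subj
                    )
                    eeg_spec = SyntheticEEGSpec(
                        stimulus_envelope=hilbert_env_512[cond],
                        beat_gain=config.beat_gain,
                        noise_exponent=config.noise_exponent,
                        noise_scale=config.noise_scale,
                        n_trials=config.n_trials,
                        rng_seed=seed,
                    )
                    trialset = synth_eeg(eeg_spec)
                    trialset = dataclasses.replace(
                        trialset,
                        condition=cond,
                        group=group,
                        order=order,
                        subject=f"{group[:3]}_{order[:3]}_{subj:02d}",
                    )
                    pooled[(group, order, cond, subj)] = preprocess(
                        trialset, first_n_trials=first_n
                    )
    _log(
        "synthetic_eeg",
        n_subjects_per_cell=config.n_subjects_per_cell,
        n_trials=config.n_trials,
        beat_gain=config.beat_gain,
    )

    # --- subject spectra and group averages --------------------------------
    subj_spectra = {
        key: noise_correct(magnitude_spectrum(w, ANALYSIS_FS))
        for key, w in pooled.items()
    }
    eeg_group_spectra: dict[str, dict[str, MagnitudeSpectrum]] = {}
    template = next(iter(subj_spectra.values()))
    for cond in config.conditions:
        eeg_group_spectra[cond] = {}
        for group in config.groups:
            amps = np.mean(
                [
                    s.amplitudes
                    for key, s in subj_spectra.items()
                    if key[0] == group and key[2] == cond
                ],
                axis=0,
            )
            eeg_group_spectra[cond][group] = MagnitudeSpectrum(
                template.frequencies, amps, template.duration_s
            )

    # --- FOI selection ------------------------------------------------------
    foi = select_frequencies_of_interest(
        stim_spectra, eeg_group_spectra, beat_freqs=config.beat_freqs
    )
    _log("foi", sizes={c: len(foi[c]) for c in foi})

    # --- z-scores -----------------------------------------------------------
    beat_rows = []
    for (group, order, cond, subj), spec in subj_spectra.items():
        r = zscore_frequency_set(spec, foi[cond], ddof=config.zscore_ddof)
        beat_rows.append(
            dict(
                group=group,
                order=order,
                condition=cond,
                subject=subj,
                beat_z=r.beat_z,
                rng_seed=config.rng_seed,
            )
        )
    beat_df = pd.DataFrame(beat_rows).sort_values(
        ["group", "order", "condition", "subject"], ignore_index=True
    )

    stim_rows = []
    for cond in config.conditions:
        r = zscore_frequency_set(
            stim_spectra[cond], foi[cond], ddof=config.zscore_ddof
        )
        stim_rows.append(
            dict(condition=cond, source="cochlear", beat_z=r.beat_z,
                 rng_seed=config.rng_seed)
        )
    stim_df = pd.DataFrame(stim_rows)

    # --- enhancement tests (family-wise FDR) --------------------------------
    test_rows = []
    for group in config.groups:
        for order in config.orders:
            for cond in config.conditions:
                zs = beat_df.query(
                    "group == @group and order == @order and condition == @cond"
                )["beat_z"].to_numpy()
                baseline = float(
                    stim_df.loc[stim_df.condition == cond, "beat_z"].iloc[0]
                )
                t, p = beat_enhancement_test(zs, baseline)
                test_rows.append(
                    dict(
                        group=group, order=order, condition=cond,
                        mean_beat_z=float(np.mean(zs)),
                        sem=float(np.std(zs, ddof=1) / np.sqrt(len(zs))),
                        cochlear_beat_z=baseline, t=t, p=p,
                        rng_seed=config.rng_seed,
                    )
                )
    test_df = pd.DataFrame(test_rows)
    test_df["p_fdr"] = fdr_correct(test_df["p"].to_numpy())
    _log("enhancement", n_tests=len(test_df))

    # --- tapping ------------------------------------------------------------
    tap_rows = []
    for group in config.groups:
        jitter = 0.3 if group == "musicians" else 0.7
        for order in config.orders:
            for cond in config.conditions:
                for subj in range(config.n_subjects_per_cell):
                    seed = _subject_seed(
                        config.rng_seed + 10_007, group, order, cond, subj
                    )
                    train = synth_taps(
                        SyntheticTapSpec(
                            beat_period_s=0.8,
                            phase_jitter_sd_rad=jitter,
                            miss_probability=0.05,
                            rng_seed=seed,
                        ),
                        subject=f"{group[:3]}_{order[:3]}_{subj:02d}",
                        condition=cond,
                    )
                    r = analyze_tap_train(train)
                    tap_rows.append(
                        dict(
                            group=group, order=order, condition=cond,
                            subject=r.subject, median_iti_s=r.median_iti_s,
                            beat_period_s=r.beat_period_s, stability=r.stability,
                            rng_seed=config.rng_seed,
                        )
                    )
    tap_df = pd.DataFrame(tap_rows)

    # --- outputs ------------------------------------------------------------
    beat_df.to_csv(out_dir / "beat_z.csv", index=False)
    stim_df.to_csv(out_dir / "stimulus_beat_z.csv", index=False)
    test_df.to_csv(out_dir / "enhancement_tests.csv", index=False)
    tap_df.to_csv(out_dir / "tapping_stability.csv", index=False)
    foi_json = {
        cond: {
            "beat_related": list(foi[cond].beat_related),
            "beat_unrelated": list(foi[cond].beat_unrelated),
        }
        for cond in foi
    }
    (out_dir / "foi.json").write_text(json.dumps(foi_json, indent=2) + "\n")
    for cond, manifest in manifests.items():
        (out_dir / f"manifest_{cond}.json").write_text(
            json.dumps(manifest, indent=2) + "\n"
        )
    _log("done", seconds=round(time.time() - t0, 1))
    return {
        "beat_z": beat_df,
        "stimulus_beat_z": stim_df,
        "enhancement": test_df,
        "stability": tap_df,
        "foi": foi,
        "manifests": manifests,
        "stim_spectra": stim_spectra,
        "out_dir": out_dir,
    }
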