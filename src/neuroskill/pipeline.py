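"""End-to-end assembly: cohort -> labeled segments -> modality batches.

Bridges the stage modules: derives per-segment majority-vote labels from the
rater table, runs the preprocessing chain once per trial on the full usable
montage, slices the fused 136-feature segments into the four modality
configurations (32-channel EEG, 116-channel EEG, eye tracking, combined),
windows them, and balances classes by seeded downsampling.  The same window
identities are retained across modalities so paired comparisons contrast
inputs, not sampling noise.
"""

from __future__ import annotations

from dataclasses import replace as _dc_replace

import numpy as np

from .montage import EEG32_CHANNELS
from .preprocess import preprocess_recording
from .ratings import DEFAULT_THRESHOLDS, derive_labels
from .types import GAZE_SIGNALS, AlignedSegment, Cohort
from .windows import (Window, WindowBatch, WindowConfig, balance_downsample,
                      slide_windows, tensorize)

MODALITIES = ("eeg32", "eeg116", "gaze", "combined")


def label_segments(cohort: Cohort,
                   thresholds: tuple[float, float] = DEFAULT_THRESHOLDS
                   ) -> dict[str, int]:
    """segment_id -> majority-vote skill class, both subtasks."""
    out: dict[str, int] = {}
    for subtask in (1, 2):
        for lab in derive_labels(cohort.ratings, subtask, thresholds):
            out[lab.segment_id] = lab.skill_class
    return out


def build_segments(cohort: Cohort,
                   thresholds: tuple[float, float] = DEFAULT_THRESHOLDS,
                   artifact_mode: str = "pca") -> list[AlignedSegment]:
    """Preprocess and fuse every trial; attach majority-vote labels."""
    labels = label_segments(cohort, thresholds)
    segments = []
    for rec in cohort.trials:
        for seg in preprocess_recording(rec, artifact_mode=artifact_mode):
            seg.label = labels.get(seg.segment_id)
            segments.append(seg)
    return segments


def _feature_rows(feature_names: list[str], modality: str) -> list[int]:
    n_gaze = len(GAZE_SIGNALS)
    eeg_names = feature_names[:-n_gaze]
    if modality == "combined":
        return list(range(len(feature_names)))
    if modality == "eeg116":
        return list(range(len(eeg_names)))
    if modality == "gaze":
        return list(range(len(eeg_names), len(feature_names)))
    if modality == "eeg32":
        missing = [n for n in EEG32_CHANNELS if n not in eeg_names]
        if missing:
            raise ValueError(f"32-channel subset missing channels: {missing}")
        return [eeg_names.index(n) for n in EEG32_CHANNELS]
    raise ValueError(f"unknown modality {modality!r}")


def build_modality_batches(segments: list[AlignedSegment], subtask: int,
                           window_cfg: WindowConfig,
                           modalities: tuple[str, ...] = MODALITIES,
                           balance_seed: int = 0,
                           balance: bool = True
                           ) -> tuple[dict[str, WindowBatch], dict]:
    """Window one subtask's segments and emit one batch per modality.

    Balancing (majority-class downsampling) is decided once on the combined
    window list and the same windows are retained in every modality batch.
    """
    segs = [s for s in segments if s.subtask == subtask and s.label is not None]
    if not segs:
        raise ValueError(f"no labeled segments for subtask {subtask}")
    windows: list[Window] = []
    for seg in segs:
        windows.extend(slide_windows(seg, window_cfg))
    log: dict = {"n_windows": len(windows)}
    if balance:
        windows, bal_log = balance_downsample(windows, balance_seed)
        log["balance"] = bal_log
    feature_names = segs[0].feature_names
    batches = {}
    for mod in modalities:
        rows = _feature_rows(feature_names, mod)
        mod_windows = [_dc_replace(w, data=w.data[rows]) for w in windows]
        batches[mod] = tensorize(mod_windows, window_cfg,
                                 [feature_names[i] for i in rows])
    return batches, log


def true_class_accuracy_labels(cohort: Cohort) -> dict[str, int]:
    """Generator-truth classes per participant (diagnostics only)."""
    return dict(cohort.participants)


def label_agreement_with_truth(cohort: Cohort,
                               thresholds=DEFAULT_THRESHOLDS) -> float:
    """Fraction of segments whose majority-vote label matches the
    generator's latent class (sanity diagnostic for synthetic cohorts)."""
    labels = label_segments(cohort, thresholds)
    truth = dict(cohort.participants)
    hits = [int(labels[f"{t.trial_id}_s{s}"] == truth[t.participant_id])
            for t in cohort.trials for s in (1, 2)
            if f"{t.trial_id}_s{s}" in labels]
    return float(np.mean(hits)) if hits else np.nan
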