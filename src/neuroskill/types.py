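"""Shared data containers for the pipeline."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: The 20 eye-tracking signals exported per sample (Tobii-style layout).
GAZE_SIGNALS = [
    "gaze_point_x", "gaze_point_y",
    "gaze_point_3d_x", "gaze_point_3d_y", "gaze_point_3d_z",
    "gaze_dir_left_x", "gaze_dir_left_y", "gaze_dir_left_z",
    "gaze_dir_right_x", "gaze_dir_right_y", "gaze_dir_right_z",
    "pupil_pos_left_x", "pupil_pos_left_y", "pupil_pos_left_z",
    "pupil_pos_right_x", "pupil_pos_right_y", "pupil_pos_right_z",
    "pupil_diam_left", "pupil_diam_right",
    "eye_movement_type",
]

#: Index (into GAZE_SIGNALS) of the categorical eye-movement-type channel
#: (1 = fixation, 2 = saccade, 3 = unclassified / eyes not detected).
EYE_MOVEMENT_TYPE_IDX = GAZE_SIGNALS.index("eye_movement_type")


@dataclass
class Recording:
    """One participant-trial's synchronized raw streams.

    EEG is channels x samples in microvolts at ``eeg_rate`` Hz; gaze is the 20
    exported signals x samples at ``gaze_rate`` Hz.  Timestamps are in
    milliseconds on a shared clock; ``events`` are (label, time_ms) markers
    delimiting the two subtask segments.
    """

    participant_id: str
    trial_id: str
    eeg: np.ndarray
    eeg_channels: list[str]
    eeg_times: np.ndarray
    gaze: np.ndarray
    gaze_signals: list[str]
    gaze_times: np.ndarray
    events: list[tuple[str, float]]
    eeg_rate: float = 512.0
    gaze_rate: float = 50.0
    true_class: int | None = None

    def __post_init__(self) -> None:
        if self.eeg.shape[0] != len(self.eeg_channels):
            raise ValueError("EEG row count does not match channel names")
        if self.gaze.shape[0] != len(self.gaze_signals):
            raise ValueError("gaze row count does not match signal names")
        for t in (self.eeg_times, self.gaze_times):
            if len(t) > 1 and not np.all(np.diff(t) > 0):
                raise ValueError("timestamps must be strictly increasing")

    def segment_bounds(self, subtask: int) -> tuple[float, float]:
        """Start/end time (ms) of a subtask segment from the event markers."""
        ev = dict(self.events)
        try:
            return ev[f"subtask{subtask}_start"], ev[f"subtask{subtask}_end"]
        except KeyError as e:
            raise KeyError(f"missing segment marker for subtask {subtask}") from e


@dataclass
class AlignedSegment:
    """A preprocessed, fused segment: (116 EEG + 20 gaze) rows at 512 Hz."""

    data: np.ndarray            # (n_features, n_samples)
    feature_names: list[str]
    subtask: int
    participant_id: str
    segment_id: str
    rate: float = 512.0
    label: int | None = None    # majority-vote skill class, attached later

    @property
    def duration(self) -> float:
        return self.data.shape[1] / self.rate

    def __post_init__(self) -> None:
        if self.data.shape[0] != len(self.feature_names):
            raise ValueError("feature row count does not match names")
        if np.isnan(self.data).any():
            raise ValueError("aligned segment contains missing values")


@dataclass
class Cohort:
    """A synthetic study cohort: participants, raw trials, rater table."""

    participants: list[tuple[str, int]]
    trials: list[Recording]
    ratings: pd.DataFrame = field(default_factory=pd.DataFrame)

    def trials_for(self, participant_id: str) -> list[Recording]:
        return [t for t in self.trials if t.participant_id == participant_id]
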