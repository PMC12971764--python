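"""Readers and writers for the raw-stream and report formats.

EEG is exchanged as delimited text (one column per channel plus a
millisecond timestamp column) or read from EDF when ``mne`` is available;
gaze uses a Tobii-export-like tab-delimited layout with named signal
columns; events are a two-column delimited file; ratings travel as CSV.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .types import GAZE_SIGNALS, Cohort, Recording


def write_recording(rec: Recording, out_dir: Path) -> dict[str, str]:
    """Write one trial's streams as text files; returns the file map."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    base = rec.trial_id
    eeg_path = out_dir / f"{base}_eeg.tsv"
    gaze_path = out_dir / f"{base}_gaze.tsv"
    events_path = out_dir / f"{base}_events.tsv"

    eeg_df = pd.DataFrame(rec.eeg.T, columns=rec.eeg_channels)
    eeg_df.insert(0, "time_ms", rec.eeg_times)
    eeg_df.to_csv(eeg_path, sep="\t", index=False, float_format="%.4f")

    gaze_df = pd.DataFrame(rec.gaze.T, columns=rec.gaze_signals)
    gaze_df.insert(0, "time_ms", rec.gaze_times)
    gaze_df.to_csv(gaze_path, sep="\t", index=False, float_format="%.6f")

    pd.DataFrame(rec.events, columns=["label", "time_ms"]).to_csv(
        events_path, sep="\t", index=False)
    return {"eeg": str(eeg_path), "gaze": str(gaze_path),
            "events": str(events_path)}


def read_recording(eeg_path: str | Path, gaze_path: str | Path,
                   events_path: str | Path, participant_id: str,
                   trial_id: str, eeg_rate: float = 512.0,
                   gaze_rate: float = 50.0) -> Recording:
    """Load one trial from text files (or EDF for the EEG stream)."""
    eeg_path = Path(eeg_path)
    if eeg_path.suffix.lower() == ".edf":
        eeg, channels, times = _read_edf(eeg_path)
    else:
        df = pd.read_csv(eeg_path, sep="\t")
        times = df.pop("time_ms").to_numpy()
        channels = list(df.columns)
        eeg = df.to_numpy().T
    gdf = pd.read_csv(gaze_path, sep="\t")
    gtimes = gdf.pop("time_ms").to_numpy()
    signals = list(gdf.columns)
    if signals != GAZE_SIGNALS:
        raise ValueError("gaze file does not carry the 20 expected signals")
    edf_events = pd.read_csv(events_path, sep="\t")
    events = [(str(r.label), float(r.time_ms)) for r in edf_events.itertuples()]
    return Recording(participant_id=participant_id, trial_id=trial_id,
                     eeg=eeg, eeg_channels=channels, eeg_times=times,
                     gaze=gdf.to_numpy().T, gaze_signals=signals,
                     gaze_times=gtimes, events=events,
                     eeg_rate=eeg_rate, gaze_rate=gaze_rate)


def _read_edf(path: Path):
    try:
        import mne
    except ImportError as e:  # pragma: no cover - optional dependency
        raise ImportError("reading EDF requires the optional mne dependency") from e
    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    data = raw.get_data() * 1e6  # volts -> microvolts
    times = raw.times * 1000.0
    return data, list(raw.ch_names), times


def write_cohort(cohort: Cohort, out_dir: str | Path) -> dict:
    """Write every trial plus ratings and a participants manifest."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"participants": [
        {"participant_id": pid, "true_class": c}
        for pid, c in cohort.participants], "trials": []}
    for rec in cohort.trials:
        files = write_recording(rec, out_dir / "trials")
        manifest["trials"].append({
            "participant_id": rec.participant_id,
            "trial_id": rec.trial_id, **files})
    cohort.ratings.to_csv(out_dir / "ratings.csv", index=False)
    manifest["ratings"] = str(out_dir / "ratings.csv")
    with open(out_dir / "manifest.json", "w") as f:
        json.dump(manifest, f, indent=2)
    return manifest


def read_cohort(in_dir: str | Path) -> Cohort:
    in_dir = Path(in_dir)
    with open(in_dir / "manifest.json") as f:
        manifest = json.load(f)
    participants = [(p["participant_id"], int(p["true_class"]))
                    for p in manifest["participants"]]
    classes = dict(participants)
    trials = []
    for t in manifest["trials"]:
        rec = read_recording(t["eeg"], t["gaze"], t["events"],
                             t["participant_id"], t["trial_id"])
        rec.true_class = classes.get(t["participant_id"])
        trials.append(rec)
    ratings = pd.read_csv(manifest["ratings"])
    return Cohort(participants=participants, trials=trials, ratings=ratings)


def save_json(obj, path: str | Path) -> None:
    def _default(o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        raise TypeError(f"not JSON serializable: {type(o)}")

    with open(path, "w") as f:
        json.dump(obj, f, indent=2, default=_default)
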