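"""Preprocessing chain for EEG and eye-tracking, and modality alignment.

The EEG chain, applied identically to every subject, is: channel exclusion
(8 poor-quality electrodes incl. mastoids) -> 60 Hz notch -> 0.2–250 Hz
band-pass (24 dB/octave) -> common average reference -> PCA artifact
removal (a transparent stand-in for interactive review software, with a
no-op mode) -> surface (Hjorth) Laplacian.  All filters are zero-phase
(forward-backward) IIR realizations, so the chain is linear and introduces
no phase distortion.

Gaze is mean-imputed, smoothed with a 3-point moving average (categorical
eye-movement-type channel via majority-of-3 instead), then resampled from
50 Hz to the 512 Hz EEG timeline with an interpolating cubic spline
(previous-value hold for the categorical channel).  The output of
``align_modalities`` stacks 116 EEG rows over 20 gaze rows: the fused
136-feature series.  Channel-wise z-scoring deliberately does NOT happen
here — normalization statistics belong to the training split (see
``neuroskill.windows``).
"""

from __future__ import annotations

import warnings
from dataclasses import replace as _dc_replace

import numpy as np
from scipy import signal as sp_signal
from scipy.interpolate import CubicSpline

from .montage import EXCLUDED_CHANNELS, default_montage, neighbor_map
from .types import EYE_MOVEMENT_TYPE_IDX, AlignedSegment, Recording


def exclude_channels(recording: Recording,
                     names: list[str] | None = None) -> Recording:
    """Drop named EEG channels (default: the 8 poor-quality electrodes)."""
    if names is None:
        names = EXCLUDED_CHANNELS
    seen = set()
    uniq = []
    for n in names:
        if n in seen:
            warnings.warn(f"duplicate channel {n} in exclusion list")
            continue
        seen.add(n)
        uniq.append(n)
    unknown = [n for n in uniq if n not in recording.eeg_channels]
    if unknown:
        raise ValueError(f"unknown channel name(s): {unknown}")
    keep = [i for i, n in enumerate(recording.eeg_channels) if n not in seen]
    rec = _dc_replace(
        recording,
        eeg=recording.eeg[keep],
        eeg_channels=[recording.eeg_channels[i] for i in keep],
    )
    return rec


def notch_filter(series: np.ndarray, rate: float = 512.0,
                 f0: float = 60.0, q: float = 30.0) -> np.ndarray:
    """Zero-phase second-order IIR notch at ``f0`` Hz (quality factor 30)."""
    if f0 >= rate / 2:
        raise ValueError("notch frequency must be below Nyquist")
    b, a = sp_signal.iirnotch(f0, q, fs=rate)
    return sp_signal.filtfilt(b, a, series, axis=-1)


def bandpass_filter(series: np.ndarray, rate: float = 512.0,
                    low: float = 0.2, high: float = 250.0) -> np.ndarray:
    """Zero-phase 4th-order Butterworth band-pass (24 dB/octave roll-off)."""
    nyq = rate / 2
    if not (0 < low < high < nyq):
        raise ValueError("band edges must satisfy 0 < low < high < Nyquist")
    sos = sp_signal.butter(4, [low, high], btype="bandpass", fs=rate,
                           output="sos")
    return sp_signal.sosfiltfilt(sos, series, axis=-1)


def common_average_reference(eeg: np.ndarray) -> np.ndarray:
    """Subtract the per-sample mean over channels from every channel."""
    if eeg.shape[0] < 2:
        raise ValueError("common average reference needs >= 2 channels")
    return eeg - eeg.mean(axis=0, keepdims=True)


def spatial_laplacian(eeg: np.ndarray, channels: list[str],
                      neighbors: dict[str, list[str]] | None = None,
                      ) -> np.ndarray:
    """Hjorth nearest-neighbour Laplacian: channel minus mean of neighbours.

    Mitigates volume conduction.  The neighbour graph defaults to 4 nearest
    channels on the schematic montage.  Not idempotent: applying it twice is
    a different (sharper) spatial filter.
    """
    if neighbors is None:
        neighbors = neighbor_map(channels, k=4)
    idx = {n: i for i, n in enumerate(channels)}
    out = np.empty_like(eeg)
    for i, ch in enumerate(channels):
        if ch not in neighbors:
            raise KeyError(f"channel {ch} missing from neighbor map")
        nb = neighbors[ch]
        if not nb:
            raise ValueError(f"channel {ch} has no neighbors")
        out[i] = eeg[i] - eeg[[idx[n] for n in nb]].mean(axis=0)
    return out


def _ocular_template(channels: list[str]) -> np.ndarray:
    """Synthetic frontal scalp pattern approximating a blink topography."""
    mont = default_montage().set_index("name")
    y = mont.loc[channels, "y"].to_numpy()
    w = np.clip(y, 0, None) ** 2
    n = np.linalg.norm(w)
    return w / n if n > 0 else w


def clean_artifacts(eeg: np.ndarray, channels: list[str],
                    variance_fraction: float = 0.15,
                    template_corr: float = 0.9,
                    mode: str = "pca") -> np.ndarray:
    """Simplified PCA artifact removal (stand-in for interactive review).

    Principal components whose scalp projection correlates with a synthetic
    ocular (frontal) template above ``template_corr``, or that individually
    carry more than ``variance_fraction`` of total variance, are removed and
    the signal reconstructed from the remaining components.
    ``mode='none'`` is an exact no-op.
    """
    if mode == "none":
        return eeg
    if mode != "pca":
        raise ValueError(f"unknown mode {mode!r}")
    x = eeg - eeg.mean(axis=1, keepdims=True)
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    var = s**2 / max((s**2).sum(), 1e-30)
    template = _ocular_template(channels)
    drop = np.zeros(len(s), dtype=bool)
    for j in range(len(s)):
        topo = u[:, j]
        denom = np.linalg.norm(topo) * np.linalg.norm(template)
        corr = abs(topo @ template) / denom if denom > 0 else 0.0
        if corr > template_corr or var[j] > variance_fraction:
            drop[j] = True
    keep = ~drop
    cleaned = (u[:, keep] * s[keep]) @ vt[keep]
    return cleaned + eeg.mean(axis=1, keepdims=True)


def moving_average_3(x: np.ndarray) -> np.ndarray:
    """Centered 3-point moving average; edges use a shrinking window."""
    x = np.asarray(x, dtype=float)
    out = np.empty_like(x)
    out[..., 1:-1] = (x[..., :-2] + x[..., 1:-1] + x[..., 2:]) / 3.0
    if x.shape[-1] >= 2:
        out[..., 0] = (x[..., 0] + x[..., 1]) / 2.0
        out[..., -1] = (x[..., -2] + x[..., -1]) / 2.0
    else:
        out[..., 0] = x[..., 0]
    return out


def _majority_of_3(x: np.ndarray) -> np.ndarray:
    """Mode over a centered 3-sample window for the categorical channel."""
    n = len(x)
    out = x.copy()
    for i in range(n):
        lo, hi = max(0, i - 1), min(n, i + 2)
        vals, counts = np.unique(x[lo:hi], return_counts=True)
        # ties resolve to the current sample's value when it is among the modes
        modes = vals[counts == counts.max()]
        out[i] = x[i] if x[i] in modes else modes[0]
    return out


def smooth_and_impute_gaze(gaze: np.ndarray) -> np.ndarray:
    """Mean-impute missing gaze samples, then smooth.

    Continuous signals: per-signal mean imputation of NaNs followed by the
    3-point moving average.  The categorical eye-movement-type channel is
    never averaged: missing samples become type 3 (eyes not detected) and a
    majority-of-3 smoother is applied instead.
    """
    out = np.array(gaze, dtype=float, copy=True)
    n_sig = out.shape[0]
    for i in range(n_sig):
        if i == EYE_MOVEMENT_TYPE_IDX:
            row = out[i]
            row[np.isnan(row)] = 3
            out[i] = _majority_of_3(row.astype(np.int64)).astype(float)
            continue
        row = out[i]
        miss = np.isnan(row)
        if miss.all():
            raise ValueError(f"gaze signal index {i} is entirely missing")
        if miss.any():
            row[miss] = row[~miss].mean()
        out[i] = moving_average_3(row)
    return out


def preprocess_eeg(recording: Recording,
                   artifact_mode: str = "pca") -> Recording:
    """Full EEG chain on a raw recording; returns a new Recording."""
    rec = exclude_channels(recording)
    x = rec.eeg.astype(np.float64)
    x = notch_filter(x, rec.eeg_rate)
    x = bandpass_filter(x, rec.eeg_rate)
    x = common_average_reference(x)
    x = clean_artifacts(x, rec.eeg_channels, mode=artifact_mode)
    x = spatial_laplacian(x, rec.eeg_channels)
    return _dc_replace(rec, eeg=x)


def align_modalities(recording: Recording, subtask: int,
                     segment_id: str | None = None) -> AlignedSegment:
    """Fuse both streams into one 512 Hz matrix for a subtask segment.

    Gaze (already smoothed/imputed) is resampled from 50 Hz onto the EEG
    timeline with an interpolating cubic spline; the categorical channel uses
    previous-value hold.  Output rows are EEG channels then gaze signals.
    """
    t0, t1 = recording.segment_bounds(subtask)
    et, gt = recording.eeg_times, recording.gaze_times
    if t0 < et[0] or t1 > et[-1] or t0 < gt[0] or t1 > gt[-1]:
        raise ValueError("segment extends outside stream coverage")
    if np.any(np.diff(et) <= 0) or np.any(np.diff(gt) <= 0):
        raise ValueError("timestamps must be strictly increasing")

    emask = (et >= t0) & (et < t1)
    seg_times = et[emask]
    eeg_seg = recording.eeg[:, emask]

    gaze = recording.gaze
    if np.isnan(gaze).any():
        raise ValueError("gaze must be imputed before alignment")
    n_sig = gaze.shape[0]
    gaze_up = np.empty((n_sig, seg_times.size))
    for i in range(n_sig):
        if i == EYE_MOVEMENT_TYPE_IDX:
            idx = np.searchsorted(gt, seg_times, side="right") - 1
            gaze_up[i] = gaze[i, np.clip(idx, 0, len(gt) - 1)]
        else:
            cs = CubicSpline(gt, gaze[i])
            gaze_up[i] = cs(seg_times)

    data = np.vstack([eeg_seg, gaze_up])
    names = list(recording.eeg_channels) + list(recording.gaze_signals)
    seg_id = segment_id or f"{recording.trial_id}_s{subtask}"
    return AlignedSegment(data=data, feature_names=names, subtask=subtask,
                          participant_id=recording.participant_id,
                          segment_id=seg_id, rate=recording.eeg_rate)


def preprocess_recording(recording: Recording,
                         artifact_mode: str = "pca",
                         eeg_subset: list[str] | None = None,
                         ) -> list[AlignedSegment]:
    """Raw recording -> one aligned, fused segment per subtask.

    ``eeg_subset`` restricts the EEG block to a named channel subset (e.g.
    the 32-channel low-density configuration) after preprocessing on the full
    usable montage.
    """
    rec = preprocess_eeg(recording, artifact_mode=artifact_mode)
    gaze = smooth_and_impute_gaze(rec.gaze)
    rec = _dc_replace(rec, gaze=gaze)
    if eeg_subset is not None:
        missing = [n for n in eeg_subset if n not in rec.eeg_channels]
        if missing:
            raise ValueError(f"subset channels not available: {missing}")
        keep = [rec.eeg_channels.index(n) for n in eeg_subset]
        rec = _dc_replace(rec, eeg=rec.eeg[keep],
                          eeg_channels=list(eeg_subset))
    return [align_modalities(rec, st) for st in (1, 2)]
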