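"""Sliding-window augmentation, padding/masking, tensorization, balancing.

Aligned segments become model-ready batches of shape (N, T, S, F):

* label-preserving sliding windows of L seconds with 50% overlap — every
  window inherits its parent segment's majority-vote label;
* segments shorter than L yield a single window, zero-padded at the end;
* each window is subdivided into T = 10 temporal steps.  At 512 Hz the
  nominal step length is L x 51.2 samples (256 for L = 5, 512 for L = 10);
  for L = 3 that is the non-integer 153.6, so step boundaries are placed at
  round(i * L * 512 / 10) — steps of 153/154 samples padded to the maximal
  step length S so the tensor stays rectangular;
* a step is masked False iff it contains only padded samples; partially
  padded steps stay True (the attention layer later excludes False steps);
* channel-wise z-scoring uses statistics from the *training* windows' real
  (unpadded) samples only, and padded samples remain exactly zero after
  normalization (normalize-then-pad semantics), preventing leakage across
  subject-independent splits;
* majority-class windows are randomly downsampled (seeded, without
  replacement) to equalize class counts — synthetic oversampling is avoided
  because it can introduce non-physiological temporal/spectral structure.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .types import AlignedSegment


@dataclass
class WindowConfig:
    L: float = 5.0            # window length, s (3, 5 or 10 in the study grid)
    overlap: float = 0.5      # fractional overlap between successive windows
    T: int = 10               # temporal steps per window
    rate: float = 512.0       # Hz

    def __post_init__(self) -> None:
        if self.L <= 0:
            raise ValueError("window length must be positive")
        if not (0 <= self.overlap < 1):
            raise ValueError("overlap must be in [0, 1)")

    @property
    def win_samples(self) -> int:
        return int(round(self.L * self.rate))

    @property
    def hop_samples(self) -> int:
        return max(1, int(round(self.win_samples * (1 - self.overlap))))

    @property
    def step_bounds(self) -> np.ndarray:
        return np.round(np.arange(self.T + 1) * self.win_samples / self.T
                        ).astype(int)

    @property
    def step_samples(self) -> int:
        """Maximal (nominal) step length S."""
        return int(np.diff(self.step_bounds).max())


@dataclass
class Window:
    """One raw (unpadded) window: features x valid samples."""

    data: np.ndarray
    label: int
    participant_id: str
    segment_id: str
    subtask: int
    start_sample: int


@dataclass
class WindowBatch:
    """Tensorized windows: data (N, T, S, F), step mask (N, T)."""

    data: np.ndarray
    mask: np.ndarray
    step_valid: np.ndarray      # real samples per step, (N, T)
    labels: np.ndarray          # class in {1, 2, 3}, (N,)
    participant_ids: np.ndarray
    subtask: int
    feature_names: list[str] = field(default_factory=list)

    @property
    def n(self) -> int:
        return self.data.shape[0]

    def sample_mask(self) -> np.ndarray:
        """Boolean (N, T, S): True where a sample holds real data."""
        s = self.data.shape[2]
        return np.arange(s)[None, None, :] < self.step_valid[:, :, None]

    def select(self, idx: np.ndarray) -> "WindowBatch":
        return WindowBatch(self.data[idx], self.mask[idx],
                           self.step_valid[idx], self.labels[idx],
                           self.participant_ids[idx], self.subtask,
                           self.feature_names)

    @staticmethod
    def concatenate(batches: list["WindowBatch"]) -> "WindowBatch":
        first = batches[0]
        for b in batches[1:]:
            if b.data.shape[1:] != first.data.shape[1:]:
                raise ValueError("batches have incompatible window shapes")
        return WindowBatch(
            np.concatenate([b.data for b in batches]),
            np.concatenate([b.mask for b in batches]),
            np.concatenate([b.step_valid for b in batches]),
            np.concatenate([b.labels for b in batches]),
            np.concatenate([b.participant_ids for b in batches]),
            first.subtask, first.feature_names)


def expected_window_count(duration: float, cfg: WindowConfig) -> int:
    """Closed-form window count: floor((dur-L)/(L(1-ov))) + 1, min 1."""
    if duration <= 0:
        return 0
    if duration < cfg.L:
        return 1
    hop = cfg.L * (1 - cfg.overlap)
    return int(np.floor((duration - cfg.L) / hop + 1e-9)) + 1


def slide_windows(segment: AlignedSegment, cfg: WindowConfig) -> list[Window]:
    """Cut a labeled segment into overlapping windows (label-preserving)."""
    n = segment.data.shape[1]
    if n == 0:
        raise ValueError("empty segment")
    if segment.label is None:
        raise ValueError(f"segment {segment.segment_id} has no label")
    win, hop = cfg.win_samples, cfg.hop_samples
    out = []
    if n < win:
        starts = [0]
    else:
        starts = list(range(0, n - win + 1, hop))
    for s in starts:
        out.append(Window(
            data=segment.data[:, s:min(s + win, n)],
            label=int(segment.label),
            participant_id=segment.participant_id,
            segment_id=segment.segment_id,
            subtask=segment.subtask,
            start_sample=s,
        ))
    return out


def pad_and_mask(window: Window, cfg: WindowConfig
                 ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """One window -> ((T, S, F) array, (T,) step mask, (T,) valid counts).

    Zeros are appended at the end of the signals to reach L x rate samples;
    a step is masked False iff every one of its samples is padding.
    """
    n_valid = window.data.shape[1]
    if n_valid == 0:
        raise ValueError("zero-length window")
    if n_valid > cfg.win_samples:
        raise ValueError("window longer than the configured length")
    bounds = cfg.step_bounds
    s_max = cfg.step_samples
    f = window.data.shape[0]
    out = np.zeros((cfg.T, s_max, f), dtype=np.float32)
    valid = np.zeros(cfg.T, dtype=np.int64)
    x = window.data.T  # samples x features
    for t in range(cfg.T):
        b0, b1 = bounds[t], bounds[t + 1]
        v = int(np.clip(n_valid - b0, 0, b1 - b0))
        valid[t] = v
        if v > 0:
            out[t, :v, :] = x[b0:b0 + v, :]
    mask = valid > 0
    return out, mask, valid


def tensorize(windows: list[Window], cfg: WindowConfig,
              feature_names: list[str] | None = None) -> WindowBatch:
    """Stack windows into a (N, T, S, F) batch with step masks."""
    if not windows:
        raise ValueError("no windows to tensorize")
    f = windows[0].data.shape[0]
    subtask = windows[0].subtask
    if any(w.data.shape[0] != f for w in windows):
        raise ValueError("windows have mixed feature counts")
    data = np.empty((len(windows), cfg.T, cfg.step_samples, f),
                    dtype=np.float32)
    mask = np.empty((len(windows), cfg.T), dtype=bool)
    valid = np.empty((len(windows), cfg.T), dtype=np.int64)
    for i, w in enumerate(windows):
        data[i], mask[i], valid[i] = pad_and_mask(w, cfg)
    return WindowBatch(
        data=data, mask=mask, step_valid=valid,
        labels=np.array([w.label for w in windows], dtype=np.int64),
        participant_ids=np.array([w.participant_id for w in windows]),
        subtask=subtask, feature_names=feature_names or [])


@dataclass
class Normalizer:
    """Per-channel z-score statistics fitted on training data only."""

    mean: np.ndarray
    std: np.ndarray

    def apply(self, batch: WindowBatch) -> WindowBatch:
        sm = batch.sample_mask()[..., None]
        z = (batch.data - self.mean) / self.std
        data = np.where(sm, z, 0.0).astype(np.float32)
        return WindowBatch(data, batch.mask, batch.step_valid, batch.labels,
                           batch.participant_ids, batch.subtask,
                           batch.feature_names)


def fit_normalizer(train_batch: WindowBatch, sd_floor: float = 1e-8
                   ) -> Normalizer:
    """Channel stats over the training batch's real (unpadded) samples."""
    if train_batch.n == 0:
        raise ValueError("empty training batch")
    sm = train_batch.sample_mask()
    x = train_batch.data[sm].astype(np.float64)   # (n_real_samples, F)
    mean = x.mean(axis=0)
    std = x.std(axis=0)
    if (std < sd_floor).any():
        warnings.warn("zero-variance channel(s); standard deviation floored")
    std = np.maximum(std, sd_floor)
    return Normalizer(mean=mean.astype(np.float32), std=std.astype(np.float32))


def fit_apply_normalizer(train_batch: WindowBatch,
                         *other_batches: WindowBatch
                         ) -> tuple[list[WindowBatch], Normalizer]:
    """Fit on the training batch, apply to it and every other batch."""
    norm = fit_normalizer(train_batch)
    out = [norm.apply(train_batch)] + [norm.apply(b) for b in other_batches]
    return out, norm


def balance_downsample(windows: list[Window], seed: int
                       ) -> tuple[list[Window], dict]:
    """Randomly downsample majority classes to the minority class count.

    Seeded, without replacement; preserves original relative order of the
    retained windows.  Returns the balanced list and a removal log.
    """
    labels = np.array([w.label for w in windows])
    classes, counts = np.unique(labels, return_counts=True)
    if len(classes) == 0 or counts.min() == 0:
        raise ValueError("every class needs at least one window")
    n_min = counts.min()
    rng = np.random.default_rng(seed)
    keep_idx: list[int] = []
    for c in classes:
        idx = np.flatnonzero(labels == c)
        if len(idx) > n_min:
            idx = rng.choice(idx, size=n_min, replace=False)
        keep_idx.extend(idx.tolist())
    keep_idx.sort()
    log = {
        "counts_before": {int(c): int(n) for c, n in zip(classes, counts)},
        "counts_after": {int(c): int(n_min) for c in classes},
        "removed": int(counts.sum() - n_min * len(classes)),
    }
    return [windows[i] for i in keep_idx], log


def save_batch(path, batch: WindowBatch) -> None:
    """Persist a batch to HDF5 (datasets: data/mask/step_valid/labels/ids)."""
    import h5py

    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=batch.data, compression="gzip")
        f.create_dataset("mask", data=batch.mask)
        f.create_dataset("step_valid", data=batch.step_valid)
        f.create_dataset("labels", data=batch.labels)
        f.create_dataset("participant_ids",
                         data=np.array(batch.participant_ids, dtype="S"))
        f.attrs["subtask"] = batch.subtask
        f.attrs["feature_names"] = [str(n) for n in batch.feature_names]


def load_batch(path) -> WindowBatch:
    import h5py

    with h5py.File(path, "r") as f:
        return WindowBatch(
            data=f["data"][()], mask=f["mask"][()],
            step_valid=f["step_valid"][()], labels=f["labels"][()],
            participant_ids=f["participant_ids"][()].astype(str),
            subtask=int(f.attrs["subtask"]),
            feature_names=list(f.attrs["feature_names"]))
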