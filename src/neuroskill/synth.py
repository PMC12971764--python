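"""Seeded synthetic cohorts with the statistical structure the pipeline assumes.

No public recording of the study setup exists, so this module emulates it:
two modalities at different sampling rates (EEG 512 Hz, gaze 50 Hz) on a
shared millisecond clock, 60 Hz line contamination, missing gaze samples,
trial durations that shrink with expertise (experienced trials can be shorter
than the analysis window, exercising the zero-padding path), and noisy
ordinal ratings from three raters.

Class-discriminative structure is placed in two places, each independently
switchable so unimodal-vs-multimodal comparisons are meaningful:

* EEG band power — frontal theta (4–8 Hz) rises and occipital alpha
  (8–13 Hz) falls with expertise, the pattern reported for efficient
  cognitive control and visuospatial processing;
* gaze dynamics — mean fixation duration rises (and saccade rate falls)
  with expertise.

``effect_size`` scales both; ``effect_size = 0`` produces class-exchangeable
signals.  All randomness flows from a single integer seed through
``numpy.random.Generator`` so cohorts are bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .montage import EXCLUDED_CHANNELS, channel_names
from .types import EYE_MOVEMENT_TYPE_IDX, GAZE_SIGNALS, Cohort, Recording

#: Ideal latent RACE score per skill class (Likert 1–5 scale).
CLASS_IDEAL_SCORE = {1: 1.5, 2: 3.0, 3: 4.5}

#: Domains used to score each subtask (needle positioning + entry for
#: subtask 1; driving/trauma, suture placement, tissue approximation for 2).
SUBTASK_DOMAINS = {1: (1, 2), 2: (3, 4, 5)}


@dataclass
class GeneratorConfig:
    """Study-condition knobs for the synthetic cohort generator.

    Defaults mirror the recording setup: 23 participants skewed toward
    inexperienced (11 inexperienced / 7 competent / 5 experienced expected),
    116 usable EEG channels at 512 Hz, 20 gaze signals at 50 Hz, 60 Hz mains
    contamination.  Per-class segment-duration ranges are free parameters of
    the generator (no published distribution exists); experienced segments
    may be shorter than the 5 s analysis window.
    """

    n_participants: int = 23
    class_proportions: tuple[float, float, float] = (11 / 23, 7 / 23, 5 / 23)
    eeg_channels: int = 116
    gaze_signals: int = 20
    eeg_rate: float = 512.0
    gaze_rate: float = 50.0
    trial_duration_range_per_class: dict[int, tuple[float, float]] = field(
        default_factory=lambda: {1: (20.0, 45.0), 2: (10.0, 25.0), 3: (4.0, 14.0)}
    )
    effect_size: float = 1.0
    eeg_effect: bool = True
    gaze_effect: bool = True
    line_noise_amp: float = 5.0          # µV
    line_freq: float = 60.0              # Hz
    gaze_dropout_prob: float = 0.02
    rater_noise_sd: float = 0.5          # Likert units
    blink_rate: float = 0.08             # blinks / s, frontal artifact
    trials_per_participant: int = 2
    #: explicit per-participant classes (overrides the multinomial draw);
    #: useful for small cohorts where every class must be represented
    fixed_classes: tuple[int, ...] | None = None
    seed: int = 0

    def validate(self) -> None:
        p = np.asarray(self.class_proportions, dtype=float)
        if p.shape != (3,) or (p < 0).any() or abs(p.sum() - 1.0) > 1e-9:
            raise ValueError("class_proportions must be a 3-simplex")
        for c, (lo, hi) in self.trial_duration_range_per_class.items():
            if not (0 < lo <= hi):
                raise ValueError(f"non-positive duration range for class {c}")
        if self.effect_size < 0:
            raise ValueError("effect_size must be >= 0")
        if not (0 <= self.gaze_dropout_prob <= 1):
            raise ValueError("gaze_dropout_prob must be a probability")
        if self.gaze_signals != 20:
            raise ValueError("the gaze export always carries 20 signals")
        if self.fixed_classes is not None:
            if len(self.fixed_classes) != self.n_participants:
                raise ValueError("fixed_classes length must equal n_participants")
            if any(c not in (1, 2, 3) for c in self.fixed_classes):
                raise ValueError("fixed_classes entries must be in {1, 2, 3}")


def _class_gain(true_class: int, effect_size: float, sign: float = 1.0) -> float:
    """Multiplicative band-power gain: 1 + 0.35*es*(class-2), floored at 0.1."""
    return max(0.1, 1.0 + sign * 0.35 * effect_size * (true_class - 2))


def _band_noise(rng: np.random.Generator, n_ch: int, n: int, rate: float,
                lo: float, hi: float) -> np.ndarray:
    """Unit-RMS Gaussian noise band-limited to [lo, hi] Hz via FFT masking."""
    white = rng.standard_normal((n_ch, n))
    spec = np.fft.rfft(white, axis=1)
    f = np.fft.rfftfreq(n, d=1.0 / rate)
    spec[:, (f < lo) | (f > hi)] = 0.0
    sig = np.fft.irfft(spec, n=n, axis=1)
    rms = np.sqrt(np.mean(sig**2, axis=1, keepdims=True))
    rms[rms == 0] = 1.0
    return sig / rms


def _pink_noise(rng: np.random.Generator, n_ch: int, n: int, rate: float) -> np.ndarray:
    """Unit-RMS 1/f background (flat below 1 Hz to keep variance finite)."""
    white = rng.standard_normal((n_ch, n))
    spec = np.fft.rfft(white, axis=1)
    f = np.fft.rfftfreq(n, d=1.0 / rate)
    spec /= np.sqrt(np.maximum(f, 1.0))
    sig = np.fft.irfft(spec, n=n, axis=1)
    rms = np.sqrt(np.mean(sig**2, axis=1, keepdims=True))
    return sig / rms


def synthesize_eeg(duration: float, true_class: int, config: GeneratorConfig,
                   rng: np.random.Generator,
                   channels: list[str] | None = None) -> np.ndarray:
    """Generate a channels x samples EEG matrix (µV) at ``config.eeg_rate``.

    1/f background plus class-dependent frontal theta and occipital alpha
    oscillations, a common-phase mains sinusoid, and sporadic frontal blink
    transients.  With ``channels=None`` the usable (post-exclusion) montage
    truncated to ``config.eeg_channels`` names is used.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    if channels is None:
        channels = channel_names(include_excluded=False)[: config.eeg_channels]
    from .montage import default_montage

    mont = default_montage().set_index("name")
    n = int(round(duration * config.eeg_rate))
    t = np.arange(n) / config.eeg_rate
    n_ch = len(channels)
    region = mont.loc[channels, "region"].to_numpy()
    y = mont.loc[channels, "y"].to_numpy()

    eeg = 5.0 * _pink_noise(rng, n_ch, n, config.eeg_rate)

    es = config.effect_size if config.eeg_effect else 0.0
    theta_amp = 4.0 * _class_gain(true_class, es, sign=+1.0)
    alpha_amp = 6.0 * _class_gain(true_class, es, sign=-1.0)
    frontal = region == "frontal"
    occipital = region == "occipital"
    if frontal.any():
        eeg[frontal] += theta_amp * _band_noise(
            rng, frontal.sum(), n, config.eeg_rate, 4.0, 8.0)
    if occipital.any():
        eeg[occipital] += alpha_amp * _band_noise(
            rng, occipital.sum(), n, config.eeg_rate, 8.0, 13.0)
    # weak class-independent oscillations elsewhere, for realism
    rest = ~(frontal | occipital)
    if rest.any():
        eeg[rest] += 1.5 * _band_noise(rng, rest.sum(), n, config.eeg_rate, 8.0, 13.0)

    if config.line_noise_amp > 0:
        phase = rng.uniform(0, 2 * np.pi)
        gains = 1.0 + 0.1 * rng.standard_normal(n_ch)
        eeg += config.line_noise_amp * gains[:, None] * np.sin(
            2 * np.pi * config.line_freq * t + phase)[None, :]

    if config.blink_rate > 0:
        n_blinks = rng.poisson(config.blink_rate * duration)
        width = int(0.3 * config.eeg_rate)
        blink = np.hanning(width)
        # frontal-dominant spatial pattern decaying toward the back of the head
        pattern = np.clip(y, 0, None) ** 2 * 40.0
        for _ in range(n_blinks):
            start = rng.integers(0, max(1, n - width))
            eeg[:, start:start + width] += pattern[:, None] * blink[None, :len(eeg[0, start:start + width])]

    return eeg.astype(np.float32)


def synthesize_gaze(duration: float, true_class: int, config: GeneratorConfig,
                    rng: np.random.Generator) -> np.ndarray:
    """Generate the 20-signal x samples gaze matrix at ``config.gaze_rate``.

    An alternating fixation/saccade regime drives all geometric signals; the
    class-dependent mean fixation duration (longer fixations, fewer saccades
    with expertise) carries the skill signal.  Dropped samples are NaN with
    eye-movement-type 3.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    rate = config.gaze_rate
    n = int(round(duration * rate))
    es = config.effect_size if config.gaze_effect else 0.0
    mu_fix = max(0.06, 0.25 * (1.0 + 0.4 * es * (true_class - 2)))

    # build fixation/saccade state sequence and fixation targets
    state = np.empty(n, dtype=np.int64)      # 1 fixation, 2 saccade
    gx = np.empty(n)
    gy = np.empty(n)
    pos = np.array([960.0, 540.0])
    prev_pos = pos.copy()
    i = 0
    in_fix = True
    seg_left = max(1, int(round(rng.gamma(4.0, mu_fix / 4.0) * rate)))
    sacc_len = 0
    while i < n:
        if in_fix:
            state[i] = 1
            gx[i], gy[i] = pos + rng.standard_normal(2) * 3.0
        else:
            state[i] = 2
            frac = 1.0 - seg_left / max(1, sacc_len)
            p = prev_pos + frac * (pos - prev_pos)
            gx[i], gy[i] = p + rng.standard_normal(2) * 5.0
        seg_left -= 1
        i += 1
        if seg_left == 0:
            if in_fix:
                in_fix = False
                prev_pos = pos.copy()
                pos = np.clip(pos + rng.standard_normal(2) * 200.0,
                              [0.0, 0.0], [1920.0, 1080.0])
                sacc_len = max(1, int(round(rng.uniform(0.02, 0.06) * rate)))
                seg_left = sacc_len
            else:
                in_fix = True
                seg_left = max(1, int(round(rng.gamma(4.0, mu_fix / 4.0) * rate)))

    g = np.empty((20, n))
    g[0], g[1] = gx, gy
    # schematic 3-D gaze point in metres, camera-centred
    g[2] = (gx - 960.0) / 1000.0
    g[3] = (gy - 540.0) / 1000.0
    g[4] = 0.60 + 0.01 * rng.standard_normal(n)
    # gaze directions: unit vectors from each eye toward the 3-D point
    for k, ex in ((5, -0.03), (8, +0.03)):
        vx, vy, vz = g[2] - ex, g[3].copy(), g[4].copy()
        norm = np.sqrt(vx**2 + vy**2 + vz**2)
        g[k] = vx / norm + 0.005 * rng.standard_normal(n)
        g[k + 1] = vy / norm + 0.005 * rng.standard_normal(n)
        g[k + 2] = vz / norm + 0.005 * rng.standard_normal(n)
    # pupil positions (mm, eye-tracker frame): slow drift around nominal
    for k, ex in ((11, -30.0), (14, +30.0)):
        drift = np.cumsum(rng.standard_normal((3, n)) * 0.02, axis=1)
        g[k] = ex + drift[0]
        g[k + 1] = 0.0 + drift[1]
        g[k + 2] = 40.0 + drift[2]
    # pupil diameters (mm)
    t = np.arange(n) / rate
    slow = 0.3 * np.sin(2 * np.pi * 0.05 * t + rng.uniform(0, 2 * np.pi))
    g[17] = 3.0 + slow + 0.05 * rng.standard_normal(n)
    g[18] = 3.0 + slow + 0.05 * rng.standard_normal(n)
    g[EYE_MOVEMENT_TYPE_IDX] = state

    if config.gaze_dropout_prob > 0:
        drop = rng.random(n) < config.gaze_dropout_prob
        g[:EYE_MOVEMENT_TYPE_IDX, drop] = np.nan
        g[EYE_MOVEMENT_TYPE_IDX, drop] = 3
    return g


def synthesize_ratings(cohort: Cohort, rater_noise_sd: float,
                       seed: int) -> pd.DataFrame:
    """Three raters score five RACE domains per segmented subtask.

    Each rater's Likert score is the class-mapped ideal score plus Gaussian
    noise, rounded and clipped to [1, 5].
    """
    rng = np.random.default_rng(seed)
    classes = dict(cohort.participants)
    rows = []
    for trial in cohort.trials:
        c = classes[trial.participant_id]
        ideal = CLASS_IDEAL_SCORE[c]
        for subtask in (1, 2):
            seg_id = f"{trial.trial_id}_s{subtask}"
            for rater in (1, 2, 3):
                for domain in range(1, 6):
                    score = int(np.clip(round(ideal + rng.normal(0, rater_noise_sd)), 1, 5))
                    rows.append((seg_id, trial.participant_id, subtask, rater, domain, score))
    return pd.DataFrame(
        rows, columns=["segment_id", "participant_id", "subtask",
                       "rater_id", "domain", "score"])


def generate_cohort(config: GeneratorConfig) -> Cohort:
    """Generate a full seeded cohort: participants, trials, rater table.

    Each participant performs ``trials_per_participant`` anastomoses; each
    trial contains both subtask segments with event markers at the segment
    boundaries and a short lead-in / inter-segment gap / tail.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    if config.fixed_classes is not None:
        classes = np.asarray(config.fixed_classes)
    else:
        classes = rng.choice([1, 2, 3], size=config.n_participants,
                             p=np.asarray(config.class_proportions, dtype=float))
    participants = [(f"P{i + 1:02d}", int(c)) for i, c in enumerate(classes)]

    raw_channels = channel_names(include_excluded=False)[: config.eeg_channels]
    raw_channels = raw_channels + EXCLUDED_CHANNELS

    trials = []
    for pid, c in participants:
        lo, hi = config.trial_duration_range_per_class[c]
        for k in range(config.trials_per_participant):
            d1 = rng.uniform(lo, hi)
            d2 = rng.uniform(lo, hi)
            lead, gap, tail = 1.0, 1.0, 1.0
            total = lead + d1 + gap + d2 + tail
            eeg = synthesize_eeg(total, c, config, rng, channels=raw_channels)
            gaze = synthesize_gaze(total, c, config, rng)
            events = [
                ("subtask1_start", lead * 1000.0),
                ("subtask1_end", (lead + d1) * 1000.0),
                ("subtask2_start", (lead + d1 + gap) * 1000.0),
                ("subtask2_end", (lead + d1 + gap + d2) * 1000.0),
            ]
            trials.append(Recording(
                participant_id=pid,
                trial_id=f"{pid}_t{k + 1}",
                eeg=eeg,
                eeg_channels=list(raw_channels),
                eeg_times=np.arange(eeg.shape[1]) / config.eeg_rate * 1000.0,
                gaze=gaze,
                gaze_signals=list(GAZE_SIGNALS),
                gaze_times=np.arange(gaze.shape[1]) / config.gaze_rate * 1000.0,
                events=events,
                eeg_rate=config.eeg_rate,
                gaze_rate=config.gaze_rate,
                true_class=c,
            ))

    cohort = Cohort(participants=participants, trials=trials)
    cohort.ratings = synthesize_ratings(cohort, config.rater_noise_sd,
                                        seed=config.seed + 1)
    return cohort
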