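"""Desk-scale experiment profiles.

The full study design (23 participants, 10 repeats, the complete
hyperparameter grid) is expressible with the library directly; these presets
define two reduced, fixed profiles used by the test suite and the
reproduction script:

* ``smoke``  — a strongly separable synthetic cohort (effect size 8, 15
  participants, 5 trials each) with a small single-configuration model and
  2 repeated 10/5 subject-independent splits.  Exercises every pipeline
  stage, including zero-padding (experienced segments can be shorter than
  the 5 s window).
* ``null``   — the same pipeline at effect size 0 with class-independent
  segment durations, so held-out accuracy has no signal to find and should
  sit at chance (1/3).

Profile sizes are the package's choice of a tractable demonstration scale;
the scientific structure (two subtasks, class-skewed durations, grouped
splits, balanced windows) matches the full design.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .evaluation import ExperimentResult, make_split_plan, run_experiment
from .model import ModelConfig
from .pipeline import build_modality_batches, build_segments
from .synth import GeneratorConfig, generate_cohort
from .windows import WindowConfig


@dataclass
class Profile:
    generator: GeneratorConfig
    window: WindowConfig
    model: ModelConfig
    n_train: int
    n_test: int
    k_folds: int
    repeats: int
    patience: int
    subtask: int = 1
    modalities: tuple[str, ...] = ("combined",)


def smoke_profile(seed: int = 0) -> Profile:
    """Strong-effect reduced profile (held-out accuracy should be high)."""
    return Profile(
        generator=GeneratorConfig(
            n_participants=15,
            fixed_classes=tuple([1, 2, 3] * 5),
            trials_per_participant=6,
            effect_size=8.0,
            trial_duration_range_per_class={
                1: (12.0, 20.0), 2: (9.0, 16.0), 3: (4.0, 14.0)},
            seed=seed,
        ),
        window=WindowConfig(L=5.0),
        model=ModelConfig(conv_filters=8, kernel_size=5, pool_size=8,
                          lstm_units=16, dense_units=16, dropout=0.2,
                          l2=1e-3, epochs=200, batch_size=16,
                          learning_rate=2e-3, seed=seed + 1),
        n_train=10, n_test=5, k_folds=2, repeats=2, patience=40,
    )


def null_profile(seed: int = 0) -> Profile:
    """Effect-free profile: exchangeable classes, equal duration ranges."""
    return Profile(
        generator=GeneratorConfig(
            n_participants=9,
            fixed_classes=tuple([1, 2, 3] * 3),
            trials_per_participant=4,
            effect_size=0.0,
            trial_duration_range_per_class={
                1: (6.0, 12.0), 2: (6.0, 12.0), 3: (6.0, 12.0)},
            seed=seed,
        ),
        window=WindowConfig(L=5.0),
        model=ModelConfig(conv_filters=8, kernel_size=5, pool_size=8,
                          lstm_units=16, dense_units=16, dropout=0.2,
                          l2=1e-3, epochs=60, batch_size=16,
                          learning_rate=3e-3, seed=seed + 1),
        n_train=6, n_test=3, k_folds=2, repeats=2, patience=15,
    )


def run_profile(profile: Profile, split_seed: int = 7,
                balance_seed: int = 5) -> ExperimentResult:
    """Generate, preprocess, window and evaluate one profile end to end."""
    cohort = generate_cohort(profile.generator)
    segments = build_segments(cohort)
    batches, _ = build_modality_batches(
        segments, profile.subtask, profile.window,
        modalities=profile.modalities, balance_seed=balance_seed)
    classes = dict(cohort.participants)
    plan = make_split_plan(
        [p for p, _ in cohort.participants],
        n_train=profile.n_train, n_test=profile.n_test,
        k=profile.k_folds, repeats=profile.repeats,
        seed=split_seed, classes=classes)
    return run_experiment(plan, [profile.model], batches,
                          patience=profile.patience)


def binomial_ci_contains(p_hat: float, n: int, p0: float = 1 / 3,
                         z: float = 1.96) -> bool:
    """Is ``p0`` inside the normal-approximation CI around ``p_hat``?"""
    half = z * np.sqrt(p_hat * (1 - p_hat) / n + 1e-12)
    return bool(abs(p_hat - p0) <= max(half, z * np.sqrt(p0 * (1 - p0) / n)))
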