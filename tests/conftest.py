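import numpy as np
import pytest

from neuroskill.synth import GeneratorConfig, generate_cohort
from neuroskill.windows import WindowBatch


def small_generator_config(**overrides) -> GeneratorConfig:
    """A fast, fully featured cohort config for unit tests."""
    base = dict(
        n_participants=6,
        fixed_classes=(1, 1, 2, 2, 3, 3),
        trials_per_participant=2,
        trial_duration_range_per_class={1: (8.0, 12.0), 2: (6.0, 10.0),
                                        3: (3.0, 6.0)},
        effect_size=2.0,
        seed=123,
    )
    base.update(overrides)
    return GeneratorConfig(**base)


@pytest.fixture(scope="session")
def small_cohort():
    return generate_cohort(small_generator_config())


@pytest.fixture(scope="session")
def small_segments(small_cohort):
    from neuroskill.pipeline import build_segments

    return build_segments(small_cohort)


def toy_batch(n=12, t=10, s=64, f=8, seed=0, masked_from=None) -> WindowBatch:
    """A random, well-formed batch for model-level tests."""
    rng = np.random.default_rng(seed)
    data = rng.standard_normal((n, t, s, f)).astype(np.float32)
    mask = np.ones((n, t), dtype=bool)
    step_valid = np.full((n, t), s, dtype=np.int64)
    if masked_from is not None:
        mask[:, masked_from:] = False
        step_valid[:, masked_from:] = 0
        data[:, masked_from:] = 0.0
    labels = rng.integers(1, 4, size=n)
    labels[:3] = [1, 2, 3]
    pids = np.array([f"p{i % 4}" for i in range(n)])
    return WindowBatch(data, mask, step_valid, labels, pids, subtask=1)


@pytest.fixture(scope="session")
def smoke_result():
    """The strong-effect reduced pipeline, shared across heavy tests."""
    from neuroskill.presets import run_profile, smoke_profile

    return run_profile(smoke_profile(seed=11), split_seed=7, balance_seed=5)


@pytest.fixture(scope="session")
def null_result():
    """The effect-free pipeline (classes exchangeable in the signals)."""
    from neuroskill.presets import null_profile, run_profile

    return run_profile(null_profile(seed=11), split_seed=7, balance_seed=5)
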