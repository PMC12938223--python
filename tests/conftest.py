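import numpy as np
import pytest

from msfs import FeatureBatch, SynthSpec, generate_synthetic_subjects


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def two_cluster_batch():
    """Four samples, one feature: the worked relocation example."""
    return FeatureBatch(np.array([[0.0], [0.1], [5.0], [0.9]]),
                        np.array([1, 1, 2, 2]))


def random_eligible_batch(rng, max_n_per_class=6, max_F=4, max_K=3,
                          quantize_prob=0.3):
    """Random eligible batch; sometimes quantized to force value ties."""
    K = int(rng.integers(2, max_K + 1))
    npc = int(rng.integers(2, max_n_per_class + 1))
    F = int(rng.integers(1, max_F + 1))
    y = rng.permutation(np.repeat(np.arange(1, K + 1), npc))
    Z = rng.normal(size=(len(y), F))
    if rng.random() < quantize_prob:
        Z = np.round(Z, 1)
    return FeatureBatch(Z, y)


@pytest.fixture(scope="session")
def tiny_subjects():
    """Two tiny synthetic subjects for fast training smoke tests."""
    return generate_synthetic_subjects(
        SynthSpec(n_subjects=2, trials_per_class=8, n_samples=64,
                  cue_sample=16, seed=7))
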