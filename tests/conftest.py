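import numpy as np
import pytest

from hprnet import (ModelConfig, SynthConfig, TrainConfig, build_model,
                    synth_dataset, train_fold)


@pytest.fixture(scope="session")
def small_cfg():
    """A narrow two-ResLayer config used for fast unit tests."""
    return ModelConfig(
        front_channels=4,
        layer_channels=((4, 8), (8, 8)),
        layer_strides=(1, 2),
        reb_counts=(2, 1),
        num_classes=3,
        dropout_p=0.0,
    )


@pytest.fixture()
def small_model(small_cfg):
    return build_model(small_cfg, seed=7)


@pytest.fixture(scope="session")
def clean_synth():
    """Noiseless synthetic dataset (template recovery is exact)."""
    return synth_dataset(
        SynthConfig(n_per_class=10, noise_sd=0.0, wander_amp=0.0, seed=0))


@pytest.fixture(scope="session")
def noisy_synth():
    """1000 beats at noise_sd=0.1, seed 0 (the seeded oracle fixture)."""
    return synth_dataset(SynthConfig(n_per_class=250, noise_sd=0.1, seed=0))


@pytest.fixture(scope="session")
def tiny_trained():
    """Full-width single-REB-per-layer model trained on the separable
    synthetic 4-class task (the scaled-down training condition).

    Trained once per session; returns (model, history, held-out config).
    """
    ds = synth_dataset(SynthConfig(n_per_class=200, noise_sd=0.05, seed=0))
    rng = np.random.default_rng(0)
    perm = rng.permutation(len(ds))
    n_val = len(ds) // 4
    val, train = ds.subset(perm[:n_val]), ds.subset(perm[n_val:])
    cfg = ModelConfig(reb_counts=(1,) * 9, num_classes=4)
    model = build_model(cfg, seed=0)
    model, history = train_fold(
        model, train, val,
        TrainConfig(max_epochs=10, seed=0, early_stop_val_acc=0.95))
    return model, history
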