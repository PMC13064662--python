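import numpy as np
import pytest

from molmm import (FixtureSpec, ModelConfig, TrainConfig, fit_layout,
                   generate_signal_molecules, init_params, render_batch)


@pytest.fixture(scope="session")
def tiny_model_config():
    """A minimal CNN config: 6x6 grid, one conv block, tiny latent."""
    return ModelConfig(encoder="cnn", grid_shape=(6, 6), conv_channels=(3,),
                       latent_dim=4, head_hidden=3, activation="tanh", seed=0)


@pytest.fixture(scope="session")
def tiny_trained_model(tiny_model_config):
    """A small model fine-tuned on a separable planted-signal set."""
    from molmm.training import train_supervised

    spec = FixtureSpec(n_compounds=120, n_descriptors=36, signal_dims=6,
                       effect_size=2.0, block_size=6, seed=5)
    x, y, _ = generate_signal_molecules(spec)
    layout = fit_layout(x[:60], (6, 6), seed=0, method="cmds")
    fmaps = render_batch(x, layout)
    cfg = TrainConfig(seed=0, stage2_epochs=15, batch_size=16)
    params = train_supervised(fmaps, y, tiny_model_config, cfg)
    return params, fmaps, y


@pytest.fixture(scope="session")
def planted_descriptor_set():
    spec = FixtureSpec(n_compounds=400, n_descriptors=64, signal_dims=8,
                       effect_size=1.5, noisy_flip_rate=0.2, seed=11)
    x, y, y_noisy = generate_signal_molecules(spec)
    return spec, x, y, y_noisy
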