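import numpy as np
import pytest

from bbrex import (
    EmbeddingConfig,
    EncoderConfig,
    SynthConfig,
    TrainConfig,
    generate_dataset,
)


@pytest.fixture(scope="session")
def tiny_dataset():
    """60 train / 30 test instances from the planted-rule generator."""
    cfg = SynthConfig(seed=11)
    return generate_dataset(60, 30, cfg)


def small_configs(train_instances, seed=0, **train_overrides):
    """Reduced-dimension model configs for fast unit tests."""
    emb = EmbeddingConfig.from_instances(
        train_instances, word_dim=16, pos_dim=4, dist_dim_per_entity=4, seed=seed
    )
    enc = EncoderConfig(blstm_hidden=8, max_sdp_len=8, cnn_filters=8, cnn_windows=(3, 5))
    defaults = dict(seed=seed, max_epochs=3, use_sentence_embedding=False)
    defaults.update(train_overrides)
    tc = TrainConfig(**defaults)
    return emb, enc, tc


@pytest.fixture
def rng():
    return np.random.default_rng(123)
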