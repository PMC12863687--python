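import numpy as np
import pytest

from bioseqlm.encoder import Encoder, EncoderConfig
from bioseqlm.tokenization import Modality, train_vocabulary_pair


@pytest.fixture(scope="session")
def single_char_vocabs():
    """Single-character nucleic/protein vocabulary pair with disjoint ids."""
    nuc, prot = train_vocabulary_pair(
        ["ACGTU", "ACGT"], ["ACDEFGHIKLMNPQRSTVWY"], algorithm="single_char")
    return nuc, prot


@pytest.fixture(scope="session")
def tiny_encoder(single_char_vocabs):
    nuc, prot = single_char_vocabs
    cfg = EncoderConfig(d=32, n_layers=2, n_heads=4,
                        vocab_size=max(nuc.max_id, prot.max_id) + 1,
                        context_length=64)
    return Encoder(cfg, np.random.default_rng(0))
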