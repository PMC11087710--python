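import pytest

from rxnbind import (
    BPETokenizer,
    MixtureSpec,
    ModelConfig,
    ReactionEncoder,
    train_model,
)
from rxnbind.synthetic import SynthSpec, generate_corpus


@pytest.fixture(scope="session")
def tiny_spec():
    return SynthSpec(n_enzymatic=300, n_organic=60, seed=7)


@pytest.fixture(scope="session")
def tiny_corpus(tiny_spec):
    return generate_corpus(tiny_spec)


@pytest.fixture(scope="session")
def tiny_sequences(tiny_corpus):
    records, _ = tiny_corpus
    return [r.reaction.enzyme.value for r in records]


@pytest.fixture(scope="session")
def char_tokenizer(tiny_sequences):
    # vocab_size == alphabet size -> zero merges, pure character tokenization
    return BPETokenizer.train(tiny_sequences, vocab_size=21)


@pytest.fixture(scope="session")
def small_tokenizer(tiny_sequences):
    return BPETokenizer.train(tiny_sequences, vocab_size=80)


@pytest.fixture(scope="session")
def tiny_encoder(tiny_corpus, small_tokenizer):
    records, organic = tiny_corpus
    return ReactionEncoder.build([r.reaction for r in records] + organic, small_tokenizer)


@pytest.fixture(scope="session")
def tiny_encoded(tiny_corpus, tiny_encoder):
    records, organic = tiny_corpus
    enz = [tiny_encoder.encode_reaction(r.reaction) for r in records]
    org = [tiny_encoder.encode_reaction(r) for r in organic]
    return enz, org


@pytest.fixture(scope="session")
def untrained_model(tiny_encoder, tiny_encoded):
    enz, org = tiny_encoded
    mix = MixtureSpec(enzymatic=enz, organic=org)
    config = ModelConfig(
        vocab_size=tiny_encoder.vocab_size, layers=2, heads=4, hidden_dim=32, seed=3
    )
    return train_model(mix, config, steps=0)
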