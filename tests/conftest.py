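from dataclasses import replace

import pytest

from pgntag.synth import SynthConfig, gen_background, gen_corpus, gen_lexicon


@pytest.fixture(scope="session")
def small_config():
    return SynthConfig(
        seed=11, n_docs=30, sentences_per_doc=2, mentions_per_doc_mean=4.0,
        lexicon_size=150, background_vocab=800,
    )


@pytest.fixture(scope="session")
def small_world(small_config):
    """Lexicon + background + one generated corpus, shared across tests."""
    lex = gen_lexicon(small_config)
    bg = gen_background(small_config, lex)
    gen = gen_corpus(small_config, lex, bg)
    return small_config, lex, bg, gen
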