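import matplotlib
import numpy as np
import pandas as pd
import pytest
from hypothesis import settings as hyp_settings

matplotlib.use("Agg")

hyp_settings.register_profile("deterministic", derandomize=True)
hyp_settings.load_profile("deterministic")

from infodur import (
    SynthConfig,
    attach_predictors,
    compute_bigram_stats,
    generate_corpus,
)


@pytest.fixture
def hand_tokens() -> pd.DataFrame:
    """Four-token corpus {A->w1, A->w1, A->w2, B->w1} with known statistics."""
    return pd.DataFrame(
        {"word": ["w1", "w1", "w2", "w1"], "context": ["A", "A", "A", "B"]}
    )


@pytest.fixture(scope="session")
def synth_corpus():
    """Default synthetic Zipfian corpus (2000 tokens, 500 contexts), shared."""
    tokens, truth = generate_corpus(SynthConfig(seed=20260101))
    return tokens, truth


@pytest.fixture(scope="session")
def synth_data(synth_corpus):
    """The synthetic corpus with estimated predictors attached."""
    tokens, truth = synth_corpus
    stats = compute_bigram_stats(tokens)
    return attach_predictors(tokens, stats), stats, truth


def random_token_table(rng: np.random.Generator, n: int = 60,
                       n_words: int = 12, n_contexts: int = 6) -> pd.DataFrame:
    words = rng.integers(0, n_words, n)
    contexts = rng.integers(0, n_contexts, n)
    out = pd.DataFrame(
        {
            "word": [f"w{i}" for i in words],
            "context": [f"c{i}" for i in contexts],
            "duration_log": rng.normal(-2.0, 0.5, n),
        }
    )
    out.index.name = "token_id"
    return out
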