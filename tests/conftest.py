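"""Shared fixtures: fixture corpora and trained policies reused across tests.

The expensive artifacts (the desk-scale pre-trained generator and the toy RL
fine-tuning run) are session-scoped so every test that needs them shares one
computation.
"""

import warnings

import numpy as np
import pytest

from molrl import fixtures as fx
from molrl.chemio import Vocabulary
from molrl.generator import GeneratorConfig, build_policy, train_supervised
from molrl.rl_engine import RLConfig, ScalarizationScheme, run_finetuning

warnings.filterwarnings("ignore", module="sklearn")

# Desk-scale study conditions: 3000-molecule corpus, 2x64-unit LSTM trained
# 25 epochs with batch 16, lr 1e-3, gradient norm clip 3.
CORPUS_N = 3000
CORPUS_SEED = 7
GEN_UNITS = 64


@pytest.fixture(scope="session")
def fixture_corpus():
    return fx.make_corpus(fx.FixtureSpec(CORPUS_N, seed=CORPUS_SEED))


@pytest.fixture(scope="session")
def fixture_vocab(fixture_corpus):
    return Vocabulary.from_corpus(fixture_corpus)


@pytest.fixture(scope="session")
def pretrained_policy(fixture_corpus, fixture_vocab):
    """Generator pre-trained on the fixture corpus (session-wide)."""
    cfg = GeneratorConfig(recurrent_units=GEN_UNITS, epochs=25)
    policy = build_policy(cfg, fixture_vocab, seed=1)
    losses = train_supervised(policy, fixture_corpus, cfg,
                              rng=np.random.default_rng(2))
    policy.pretrain_losses = losses
    return policy


@pytest.fixture(scope="session")
def toy_rl_run(pretrained_policy):
    """200-episode Chebyshev (0.5, 0.5) fine-tuning against the mock oracles."""
    cfg = RLConfig(episodes=200, batch_size=10)
    scheme = ScalarizationScheme("chebyshev", (0.5, 0.5))
    unbiased = pretrained_policy
    before = {k: v.copy() for k, v in unbiased.model.params.items()}
    biased, logs = run_finetuning(unbiased, fx.mock_affinity_oracle,
                                  fx.mock_bbb_oracle, scheme, cfg, seed=11)
    return {"unbiased": unbiased, "biased": biased, "logs": logs,
            "cfg": cfg, "unbiased_params_before": before}


@pytest.fixture(scope="session")
def tiny_vocab():
    from molrl.chemio import PAD, START, END
    return Vocabulary((PAD, START, END, "C", "O"))
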