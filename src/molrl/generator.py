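"""Recurrent SMILES language model: pre-training and tempered sampling.

The generator is the RL agent.  It is pre-trained by teacher forcing on a
corpus of valid SMILES (maximum-likelihood next-token prediction) and then
sampled autoregressively: at each step the logits are divided by a softmax
temperature before sampling, which controls how adventurous the model is
when proposing new molecules.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from collections.abc import Sequence

import numpy as np

from ._nn import Adam, SequenceModel, softmax
from .chemio import Vocabulary, detokenize, tokenize

__all__ = [
    "GeneratorConfig", "PolicyNetwork", "SampleBatch", "build_policy",
    "train_supervised", "sample", "clone_policy", "save_policy", "load_policy",
]


@dataclass
class GeneratorConfig:
    """Architecture and training settings for the SMILES generator.

    Defaults follow the reference setup: two 256-unit LSTM layers, dropout
    between them, batches of 16 SMILES, 25 epochs of Adam at 1e-3 with the
    gradient norm clipped at 3, at most 65 tokens per molecule and a sampling
    temperature of 0.9.
    """

    recurrent_layers: int = 2
    recurrent_units: int = 256
    cell: str = "lstm"
    dropout_rate: float = 0.3
    batch_size: int = 16
    epochs: int = 25
    learning_rate: float = 1e-3
    grad_clip_norm: float = 3.0
    max_tokens: int = 65
    temperature: float = 0.9

    def __post_init__(self):
        if self.temperature <= 0:
            raise ValueError("temperature must be > 0")
        if not 0 <= self.dropout_rate < 1:
            raise ValueError("dropout_rate must be in [0, 1)")


@dataclass
class SampleBatch:
    """Sampled action sequences with their stepwise log-probabilities.

    ``sequences[i]`` holds the emitted token ids (END included when reached);
    ``logprobs[i]`` the log-probability of each emitted token under the
    tempered distribution it was sampled from; ``terminated[i]`` whether END
    arrived within the token budget.  ``emitted_by_biased`` is filled by the
    dual-generator sampler and marks which tokens the trainable policy chose.
    """

    sequences: list[np.ndarray]
    logprobs: list[np.ndarray]
    terminated: list[bool]
    vocab: Vocabulary
    emitted_by_biased: list[np.ndarray] | None = None

    def __len__(self) -> int:
        return len(self.sequences)

    def smiles(self) -> list[str]:
        return [
            detokenize(self.vocab.decode(seq.tolist()))
            for seq in self.sequences
        ]


class PolicyNetwork:
    """The generator's parameters theta plus its vocabulary and config."""

    def __init__(self, config: GeneratorConfig, vocab: Vocabulary,
                 seed: int = 0):
        self.config = config
        self.vocab = vocab
        self.model = SequenceModel(
            vocab_size=len(vocab), layers=config.recurrent_layers,
            units=config.recurrent_units, cell=config.cell,
            rng=np.random.default_rng(seed))

    def next_token_distribution(self, prefix: Sequence[str],
                                temperature: float = 1.0) -> np.ndarray:
        """Probability vector over the next token given a token prefix."""
        ids = [self.vocab.start_id] + list(self.vocab.encode(list(prefix)))
        state = self.model.zero_state(1)
        logits = None
        for tid in ids:
            logits, state = self.model.step(np.array([tid]), state)
        return softmax(logits[0] / temperature)

    def parameters_equal(self, other: "PolicyNetwork") -> bool:
        return all(
            np.array_equal(v, other.model.params[k])
            for k, v in self.model.params.items()
        )


def build_policy(config: GeneratorConfig, vocab: Vocabulary,
                 seed: int = 0) -> PolicyNetwork:
    return PolicyNetwork(config, vocab, seed=seed)


def clone_policy(policy: PolicyNetwork) -> PolicyNetwork:
    """Deep, independent copy: updating one leaves the other bit-identical."""
    out = PolicyNetwork.__new__(PolicyNetwork)
    out.config = policy.config
    out.vocab = policy.vocab
    out.model = policy.model.clone()
    return out


def _encode_corpus(corpus: Sequence[str] | Sequence[Sequence[str]],
                   vocab: Vocabulary) -> list[np.ndarray]:
    encoded = []
    for item in corpus:
        toks = tokenize(item, vocab) if isinstance(item, str) else list(item)
        encoded.append(vocab.encode(toks))
    return encoded


def _pad_batch(seqs: list[np.ndarray], vocab: Vocabulary):
    """Teacher-forcing arrays: X = START+tokens, Y = tokens+END, PAD-filled."""
    B = len(seqs)
    T = max(len(s) for s in seqs) + 1
    X = np.full((B, T), vocab.pad_id, dtype=np.int64)
    Y = np.full((B, T), vocab.pad_id, dtype=np.int64)
    C = np.zeros((B, T))
    for i, s in enumerate(seqs):
        n = len(s) + 1
        X[i, 0] = vocab.start_id
        X[i, 1:n] = s
        Y[i, :n - 1] = s
        Y[i, n - 1] = vocab.end_id
        C[i, :n] = 1.0
    return X, Y, C


def train_supervised(policy: PolicyNetwork, corpus: Sequence,
                     config: GeneratorConfig | None = None,
                     rng: np.random.Generator | None = None,
                     verbose: bool = False) -> list[float]:
    """Teacher-forcing maximum-likelihood training; returns per-epoch NLL.

    Each step conditions on the ground-truth prefix; the loss is the mean
    per-token categorical negative log-likelihood.  Adam with global-norm
    gradient clipping.
    """
    config = config or policy.config
    if len(corpus) == 0:
        raise ValueError("empty training corpus")
    rng = rng or np.random.default_rng(0)
    encoded = _encode_corpus(corpus, policy.vocab)
    too_long = [i for i, s in enumerate(encoded) if len(s) + 1 > config.max_tokens]
    if too_long:
        raise ValueError(
            f"{len(too_long)} sequences exceed max_tokens={config.max_tokens}")
    opt = Adam(policy.model.params, lr=config.learning_rate,
               clip=config.grad_clip_norm, clip_mode="norm")
    losses: list[float] = []
    n = len(encoded)
    for epoch in range(config.epochs):
        order = rng.permutation(n)
        total_nll = 0.0
        total_tokens = 0
        for lo in range(0, n, config.batch_size):
            batch = [encoded[i] for i in order[lo:lo + config.batch_size]]
            X, Y, C = _pad_batch(batch, policy.vocab)
            ntok = C.sum()
            loss, grads = policy.model.loss_and_grads(
                X, Y, C / ntok, temperature=1.0,
                dropout_rate=config.dropout_rate, dropout_rng=rng)
            opt.step(policy.model.params, grads)
            total_nll += loss * ntok
            total_tokens += ntok
        losses.append(total_nll / total_tokens)
        if verbose:
            print(f"epoch {epoch + 1}/{config.epochs}: "
                  f"per-token NLL {losses[-1]:.4f}")
    return losses


def sample(policy: PolicyNetwork, n: int, temperature: float | None = None,
           rng: np.random.Generator | None = None) -> SampleBatch:
    """Autoregressive tempered sampling of ``n`` token sequences.

    Each step conditions on the tokens sampled so far; logits are divided by
    the temperature before the softmax; generation stops at END or at the
    max_tokens budget.  Log-probabilities are recorded under the tempered
    distribution actually sampled from.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    temp = policy.config.temperature if temperature is None else temperature
    if temp <= 0:
        raise ValueError("temperature must be > 0")
    rng = rng or np.random.default_rng(0)
    vocab = policy.vocab
    model = policy.model

    cur = np.full(n, vocab.start_id, dtype=np.int64)
    state = model.zero_state(n)
    active = np.ones(n, dtype=bool)
    seqs: list[list[int]] = [[] for _ in range(n)]
    lps: list[list[float]] = [[] for _ in range(n)]
    for _ in range(policy.config.max_tokens):
        logits, state = model.step(cur, state)
        logp = logits / temp
        logp = logp - logp.max(axis=1, keepdims=True)
        logp = logp - np.log(np.exp(logp).sum(axis=1, keepdims=True))
        # Gumbel-max draw keeps sampling vectorized and seed-reproducible
        gumbel = -np.log(-np.log(rng.random(logp.shape)))
        nxt = np.argmax(logp + gumbel, axis=1)
        for i in np.flatnonzero(active):
            seqs[i].append(int(nxt[i]))
            lps[i].append(float(logp[i, nxt[i]]))
        active &= nxt != vocab.end_id
        if not active.any():
            break
        cur = np.where(active, nxt, vocab.pad_id)
    terminated = [len(s) > 0 and s[-1] == vocab.end_id for s in seqs]
    return SampleBatch(
        sequences=[np.array(s, dtype=np.int64) for s in seqs],
        logprobs=[np.array(l) for l in lps],
        terminated=terminated, vocab=vocab)


def save_policy(policy: PolicyNetwork, path: str) -> None:
    """Single-file checkpoint: weights + config + vocabulary."""
    meta = {
        "config": asdict(policy.config),
        "vocab": list(policy.vocab.tokens),
    }
    np.savez(path, __meta__=json.dumps(meta),
             **{k: v for k, v in policy.model.params.items()})


def load_policy(path: str, expected_vocab: Vocabulary | None = None
                ) -> PolicyNetwork:
    with np.load(path, allow_pickle=False) as data:
        meta = json.loads(str(data["__meta__"]))
        vocab = Vocabulary(tuple(meta["vocab"]))
        if expected_vocab is not None and vocab.tokens != expected_vocab.tokens:
            raise ValueError(
                "checkpoint vocabulary does not match the expected vocabulary")
        config = GeneratorConfig(**meta["config"])
        policy = PolicyNetwork(config, vocab, seed=0)
        for k in policy.model.params:
            policy.model.params[k] = np.array(data[k])
    return policy
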