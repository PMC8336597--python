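"""REINFORCE fine-tuning of the generator against two property objectives.

The pre-trained generator is duplicated: the *unbiased* copy stays frozen and
keeps proposing tokens the way the training corpus taught it (exploration),
while the *biased* copy receives policy-gradient updates (exploitation).  At
every token of every molecule a uniform draw decides which of the two acts;
the threshold depends on whether the recent reward trend is increasing
(0.01), decreasing (0.05) or undefined (0.1), so the biased generator acts
with probability 0.99 / 0.95 / 0.90.  Only tokens the biased generator
emitted contribute to its gradient.

Each finished molecule receives a terminal reward vector (affinity, BBB),
both components in [0, 1]; invalid molecules get (0, 0).  A scalarization
scheme (linear weighted sum, or Chebyshev: optimize the objective farthest
from the utopian point (1, 1)) collapses the vector to the scalar R used in
the surrogate loss

    L(theta) = -(1/n) sum_i sum_j R_i * gamma^j * ln p(t_ij | prefix, theta),

whose gradient is the REINFORCE estimate.  A bounded FIFO memory of recent
fingerprints penalizes the reward whenever a batch's average Tanimoto
distance to the memory falls below a threshold, pushing the policy out of
mode collapse.
"""

from __future__ import annotations

import math
from collections import deque
from dataclasses import dataclass, field

import numpy as np

from ._nn import Adam
from .chemio import fingerprints, is_valid, set_diversity
from .generator import PolicyNetwork, SampleBatch, clone_policy

__all__ = [
    "RLConfig", "ScalarizationScheme", "ExplorationController",
    "DiversityMemory", "EpisodeLog", "ParetoPoint", "affinity_reward",
    "bbb_reward", "scalarize", "discounted_return", "diversity_penalty",
    "select_policy", "sample_dual", "reinforce_loss", "run_finetuning",
    "pareto_front", "weight_sweep",
]

INCREASING, DECREASING, UNDEFINED = "increasing", "decreasing", "undefined"
BIASED, UNBIASED = "biased", "unbiased"


@dataclass
class RLConfig:
    """Fine-tuning settings.

    The pIC50-to-reward rule is raw = exp(pIC50/4 - 1), min-max normalized
    over the pIC50 range [pic50_low, pic50_high] and clamped to [0, 1];
    gradients are clamped elementwise to [-grad_clip, grad_clip].
    """

    episodes: int = 400
    batch_size: int = 10
    gamma: float = 1.0
    learning_rate: float = 1e-3
    grad_clip: float = 3.0
    temperature: float = 0.9
    pic50_low: float = 3.0
    pic50_high: float = 11.0
    desirable_pic50: float = 6.5
    trend_window: int = 10
    trend_slope_tol: float = 1e-3
    thresholds: dict = field(default_factory=lambda: {
        INCREASING: 0.01, DECREASING: 0.05, UNDEFINED: 0.1})
    memory_capacity: int = 30
    diversity_threshold: float = 0.75
    penalty_factor: float = 0.7
    fingerprint_bits: int = 2048
    fingerprint_radius: int = 2
    final_window: int = 20

    def __post_init__(self):
        if not 0.0 <= self.gamma <= 1.0:
            raise ValueError("gamma must be in [0, 1]")
        if self.pic50_low >= self.pic50_high:
            raise ValueError("pic50_low must be < pic50_high")


@dataclass(frozen=True)
class ScalarizationScheme:
    """Reward scalarization: 'lws' or 'chebyshev', weights summing to 1."""

    kind: str
    weights: tuple[float, float] = (0.5, 0.5)
    utopia: tuple[float, float] = (1.0, 1.0)

    def __post_init__(self):
        if self.kind not in ("lws", "chebyshev"):
            raise ValueError("kind must be 'lws' or 'chebyshev'")
        w = self.weights
        if len(w) != 2 or min(w) < 0 or abs(sum(w) - 1.0) > 1e-9:
            raise ValueError("weights must be two non-negatives summing to 1")


# -------------------------------------------------------------------- rewards
def affinity_reward(pic50: float, cfg: RLConfig) -> float:
    """Map a predicted pIC50 to [0, 1]: exp(pIC50/4 - 1), min-max normalized."""
    raw = math.exp(pic50 / 4.0 - 1.0)
    lo = math.exp(cfg.pic50_low / 4.0 - 1.0)
    hi = math.exp(cfg.pic50_high / 4.0 - 1.0)
    return float(np.clip((raw - lo) / (hi - lo), 0.0, 1.0))


def bbb_reward(p_bbb: float) -> float:
    """Classifier probability of BBB+ is already a [0, 1] reward."""
    if not 0.0 <= p_bbb <= 1.0:
        raise ValueError(f"BBB probability {p_bbb} outside [0, 1]")
    return float(p_bbb)


def scalarize(r: tuple[float, float], scheme: ScalarizationScheme) -> float:
    """Collapse a reward vector to one scalar.

    LWS returns the weighted sum.  Chebyshev finds the objective with the
    largest weighted distance to the utopian point and returns *that
    objective's* reward — the farthest-behind objective is the one optimized
    this step.  Ties break toward the affinity objective (index 0).
    """
    w = scheme.weights
    if scheme.kind == "lws":
        return float(w[0] * r[0] + w[1] * r[1])
    d = [w[j] * (scheme.utopia[j] - r[j]) for j in range(2)]
    j_star = 0 if d[0] >= d[1] else 1
    return float(r[j_star])


def discounted_return(rewards, gamma: float) -> float:
    """sum_k gamma^k * r_{k+1}."""
    rewards = np.asarray(rewards, dtype=np.float64)
    return float(np.sum(rewards * gamma ** np.arange(len(rewards))))


# ----------------------------------------------------------- diversity memory
class DiversityMemory:
    """Bounded FIFO of recent fingerprints driving the repeat penalty."""

    def __init__(self, capacity: int = 30, threshold: float = 0.75,
                 penalty_factor: float = 0.7):
        if not 0 < penalty_factor <= 1:
            raise ValueError("penalty_factor must be in (0, 1]")
        self.capacity = capacity
        self.threshold = threshold
        self.penalty_factor = penalty_factor
        self.buffer: deque[np.ndarray] = deque(maxlen=capacity)

    def __len__(self) -> int:
        return len(self.buffer)

    def update(self, batch: list[np.ndarray] | np.ndarray) -> None:
        for fp in batch:
            self.buffer.append(np.asarray(fp))


def diversity_penalty(batch, memory: DiversityMemory, reward: float
                      ) -> tuple[float, bool]:
    """Penalize ``reward`` if the batch sits too close to recent molecules.

    d = delta(batch, memory); if d < threshold the reward is multiplied by
    the penalty factor (once — never compounded within a batch).  The memory
    is then updated FIFO with the batch.  An empty memory never penalizes.
    """
    if reward < 0:
        raise ValueError("reward must be >= 0")
    penalized = False
    if len(memory) > 0 and len(batch) > 0:
        d = set_diversity(np.asarray(batch), np.asarray(memory.buffer))
        penalized = d < memory.threshold
    memory.update(batch)
    return (reward * memory.penalty_factor if penalized else reward), penalized


# -------------------------------------------------------- exploration control
class ExplorationController:
    """Trend-dependent choice between the biased and unbiased generator."""

    def __init__(self, thresholds: dict | None = None, trend_window: int = 10,
                 slope_tol: float = 1e-3,
                 rng: np.random.Generator | None = None):
        self.thresholds = thresholds or {
            INCREASING: 0.01, DECREASING: 0.05, UNDEFINED: 0.1}
        self.trend_window = trend_window
        self.slope_tol = slope_tol
        self.rng = rng or np.random.default_rng(0)

    def classify_trend(self, reward_means) -> str:
        """Linear-regression slope over the recent episode means."""
        recent = np.asarray(reward_means, dtype=np.float64)[-self.trend_window:]
        if len(recent) < 2:
            return UNDEFINED
        slope = np.polyfit(np.arange(len(recent)), recent, 1)[0]
        if abs(slope) < self.slope_tol:
            return UNDEFINED
        return INCREASING if slope > 0 else DECREASING

    def threshold(self, trend: str) -> float:
        return self.thresholds[trend]


def select_policy(ctrl: ExplorationController, trend: str) -> str:
    """Draw u ~ U(0,1); the biased generator acts iff u > threshold(trend)."""
    u = ctrl.rng.random()
    return BIASED if u > ctrl.threshold(trend) else UNBIASED


# ---------------------------------------------------------------- RL sampling
def sample_dual(biased: PolicyNetwork, unbiased: PolicyNetwork, n: int,
                ctrl: ExplorationController, trend: str,
                temperature: float, rng: np.random.Generator) -> SampleBatch:
    """Autoregressive sampling with per-token policy selection.

    Both generators track the realized token sequence; at each step each
    still-active molecule draws which policy emits its next token.  Tokens
    emitted by the frozen unbiased policy are excluded from the gradient via
    the ``emitted_by_biased`` mask.
    """
    vocab = biased.vocab
    if vocab.tokens != unbiased.vocab.tokens:
        raise ValueError("generators must share a vocabulary")
    thr = ctrl.threshold(trend)
    max_tokens = biased.config.max_tokens

    cur = np.full(n, vocab.start_id, dtype=np.int64)
    st_b = biased.model.zero_state(n)
    st_u = unbiased.model.zero_state(n)
    active = np.ones(n, dtype=bool)
    seqs: list[list[int]] = [[] for _ in range(n)]
    lps: list[list[float]] = [[] for _ in range(n)]
    by_biased: list[list[bool]] = [[] for _ in range(n)]

    def log_softmax(z):
        z = z / temperature
        z = z - z.max(axis=1, keepdims=True)
        return z - np.log(np.exp(z).sum(axis=1, keepdims=True))

    for _ in range(max_tokens):
        logits_b, st_b = biased.model.step(cur, st_b)
        logits_u, st_u = unbiased.model.step(cur, st_u)
        use_biased = ctrl.rng.random(n) > thr
        logp = np.where(use_biased[:, None], log_softmax(logits_b),
                        log_softmax(logits_u))
        gumbel = -np.log(-np.log(rng.random(logp.shape)))
        nxt = np.argmax(logp + gumbel, axis=1)
        for i in np.flatnonzero(active):
            seqs[i].append(int(nxt[i]))
            lps[i].append(float(logp[i, nxt[i]]))
            by_biased[i].append(bool(use_biased[i]))
        active &= nxt != vocab.end_id
        if not active.any():
            break
        cur = np.where(active, nxt, vocab.pad_id)
    terminated = [len(s) > 0 and s[-1] == vocab.end_id for s in seqs]
    return SampleBatch(
        sequences=[np.array(s, dtype=np.int64) for s in seqs],
        logprobs=[np.array(l) for l in lps],
        terminated=terminated, vocab=vocab,
        emitted_by_biased=[np.array(b, dtype=bool) for b in by_biased])


# ------------------------------------------------------------- surrogate loss
def reinforce_loss(policy: PolicyNetwork, batch: SampleBatch,
                   scalar_rewards, gamma: float,
                   temperature: float | None = None):
    """Surrogate loss -(1/n) sum_i sum_j R_i gamma^j ln p(t_ij) and gradient.

    The log-probabilities are those of the tempered distribution the tokens
    were sampled from.  When the batch carries an ``emitted_by_biased`` mask,
    only those tokens contribute (the unbiased policy is frozen).  Returns
    ``(loss, grads)`` with grads over the policy's parameter dict.
    """
    rewards = np.asarray(scalar_rewards, dtype=np.float64)
    if len(rewards) != len(batch):
        raise ValueError("one scalar reward per sampled sequence required")
    temp = policy.config.temperature if temperature is None else temperature
    vocab = policy.vocab
    n = len(batch)
    seqs = batch.sequences
    T = max((len(s) for s in seqs), default=0)
    if T == 0 or not np.any(rewards):
        zero = {k: np.zeros_like(v) for k, v in policy.model.params.items()}
        return 0.0, zero
    X = np.full((n, T), vocab.pad_id, dtype=np.int64)
    Y = np.full((n, T), vocab.pad_id, dtype=np.int64)
    C = np.zeros((n, T))
    for i, s in enumerate(seqs):
        m = len(s)
        if m == 0:
            continue
        X[i, 0] = vocab.start_id
        X[i, 1:m] = s[:-1]
        Y[i, :m] = s
        C[i, :m] = rewards[i] * gamma ** np.arange(m)
        if batch.emitted_by_biased is not None:
            C[i, :m] *= batch.emitted_by_biased[i]
    return policy.model.loss_and_grads(X, Y, C / n, temperature=temp)


# -------------------------------------------------------------------- logging
@dataclass
class EpisodeLog:
    """Append-only record of one fine-tuning episode."""

    episode: int
    smiles: list[str]
    valid: list[bool]
    reward_vectors: list[tuple[float, float]]
    scalar_rewards: list[float]
    penalized: bool
    trend: str
    biased_fraction: float
    mean_scalar: float
    loss: float

    def as_dict(self) -> dict:
        return {
            "episode": self.episode, "smiles": self.smiles,
            "valid": self.valid,
            "reward_vectors": [list(r) for r in self.reward_vectors],
            "scalar_rewards": self.scalar_rewards,
            "penalized": self.penalized, "trend": self.trend,
            "biased_fraction": self.biased_fraction,
            "mean_scalar": self.mean_scalar, "loss": self.loss,
        }


def _as_predictor(obj):
    if callable(obj) and not hasattr(obj, "predict"):
        return obj
    return obj.predict


# ------------------------------------------------------------------- training
def run_finetuning(unbiased: PolicyNetwork, affinity, bbb,
                   scheme: ScalarizationScheme, cfg: RLConfig,
                   seed: int = 0, verbose: bool = False
                   ) -> tuple[PolicyNetwork, list[EpisodeLog]]:
    """Policy-gradient fine-tuning loop; returns the biased policy and logs.

    ``affinity`` and ``bbb`` are either trained models with ``.predict`` or
    plain callables SMILES -> pIC50 / SMILES -> P(BBB+).  A predictor failure
    on a valid molecule drops that molecule from the episode (zero reward and
    zero gradient) instead of crashing the run.
    """
    aff_fn = _as_predictor(affinity)
    bbb_fn = _as_predictor(bbb)
    rng = np.random.default_rng(seed)
    ctrl = ExplorationController(cfg.thresholds, cfg.trend_window,
                                 cfg.trend_slope_tol,
                                 rng=np.random.default_rng(seed + 1))
    memory = DiversityMemory(cfg.memory_capacity, cfg.diversity_threshold,
                             cfg.penalty_factor)
    biased = clone_policy(unbiased)
    opt = Adam(biased.model.params, lr=cfg.learning_rate,
               clip=cfg.grad_clip, clip_mode="value")
    mean_history: list[float] = []
    logs: list[EpisodeLog] = []

    for ep in range(cfg.episodes):
        trend = ctrl.classify_trend(mean_history)
        batch = sample_dual(biased, unbiased, cfg.batch_size, ctrl, trend,
                            cfg.temperature, rng)
        smiles = batch.smiles()
        valid = [is_valid(s) for s in smiles]
        vectors: list[tuple[float, float]] = []
        scalars: list[float] = []
        for s, ok in zip(smiles, valid):
            if not ok:
                vectors.append((0.0, 0.0))
                scalars.append(0.0)
                continue
            try:
                r_a = affinity_reward(float(aff_fn(s)), cfg)
                r_b = bbb_reward(float(bbb_fn(s)))
            except Exception:  # drop the molecule, never crash the episode
                import warnings
                warnings.warn(f"predictor failed on valid molecule {s!r}; "
                              "dropped from episode")
                vectors.append((0.0, 0.0))
                scalars.append(0.0)
                continue
            vectors.append((r_a, r_b))
            scalars.append(scalarize((r_a, r_b), scheme))

        valid_smiles = [s for s, ok in zip(smiles, valid) if ok]
        penalized = False
        if valid_smiles:
            fps = fingerprints(valid_smiles, n_bits=cfg.fingerprint_bits,
                               radius=cfg.fingerprint_radius)
            base = 1.0
            _, penalized = diversity_penalty(list(fps), memory, base)
            if penalized:
                scalars = [r * memory.penalty_factor for r in scalars]

        loss, grads = reinforce_loss(biased, batch, scalars, cfg.gamma,
                                     temperature=cfg.temperature)
        opt.step(biased.model.params, grads)

        n_tok = sum(len(m) for m in batch.emitted_by_biased)
        frac_biased = (
            sum(int(x.sum()) for x in batch.emitted_by_biased) / n_tok
            if n_tok else 1.0)
        mean_scalar = float(np.mean(scalars)) if scalars else 0.0
        mean_history.append(mean_scalar)
        logs.append(EpisodeLog(
            episode=ep, smiles=smiles, valid=valid, reward_vectors=vectors,
            scalar_rewards=scalars, penalized=bool(penalized), trend=trend,
            biased_fraction=frac_biased, mean_scalar=mean_scalar,
            loss=float(loss)))
        if verbose and (ep + 1) % 20 == 0:
            recent = np.mean(mean_history[-20:])
            print(f"episode {ep + 1}/{cfg.episodes}: "
                  f"mean reward (last 20) {recent:.3f}")
    return biased, logs


# ----------------------------------------------------------------- Pareto set
@dataclass
class ParetoPoint:
    """A fine-tuning outcome: weights and mean terminal reward coordinates."""

    weights: tuple[float, float]
    r_affinity: float
    r_bbb: float
    dominated: bool = False


def _dominates(a: tuple[float, float], b: tuple[float, float]) -> bool:
    return (a[0] >= b[0] and a[1] >= b[1]) and (a[0] > b[0] or a[1] > b[1])


def pareto_front(points: list[ParetoPoint]) -> list[ParetoPoint]:
    """Non-dominated subset, in stable input order; flags set on all points.

    A point dominates another if it is at least as good on both objectives
    and strictly better on one.
    """
    if not points:
        raise ValueError("pareto_front requires at least one point")
    coords = np.array([[p.r_affinity, p.r_bbb] for p in points])
    A = coords[:, None, :]  # i
    B = coords[None, :, :]  # j
    ge = (B >= A).all(axis=2)
    gt = (B > A).any(axis=2)
    dominated = (ge & gt).any(axis=1)
    for p, d in zip(points, dominated):
        p.dominated = bool(d)
    return [p for p, d in zip(points, dominated) if not d]


def weight_sweep(unbiased: PolicyNetwork, affinity, bbb, kind: str,
                 weights, cfg: RLConfig, seed: int = 0,
                 verbose: bool = False) -> list[ParetoPoint]:
    """One fine-tuning run per affinity weight; Pareto flags on the results.

    Each point's coordinates are the mean terminal reward vector over the
    final ``cfg.final_window`` episodes (all molecules, invalid ones
    contributing (0, 0)).
    """
    points: list[ParetoPoint] = []
    for i, w in enumerate(weights):
        scheme = ScalarizationScheme(kind, (float(w), 1.0 - float(w)))
        _, logs = run_finetuning(unbiased, affinity, bbb, scheme, cfg,
                                 seed=seed + 101 * i, verbose=verbose)
        tail = logs[-cfg.final_window:]
        vecs = np.array([v for log in tail for v in log.reward_vectors])
        points.append(ParetoPoint(
            weights=scheme.weights,
            r_affinity=float(vecs[:, 0].mean()),
            r_bbb=float(vecs[:, 1].mean())))
    pareto_front(points)
    return points
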