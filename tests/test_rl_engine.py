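"""Rewards, scalarization, exploration control and the REINFORCE gradient."""

import math

import numpy as np
import pytest

from molrl import fixtures as fx
from molrl.chemio import Vocabulary, fingerprint
from molrl.generator import GeneratorConfig, build_policy, clone_policy, sample
from molrl.rl_engine import (BIASED, DECREASING, INCREASING, UNBIASED,
                             UNDEFINED, DiversityMemory,
                             ExplorationController, ParetoPoint, RLConfig,
                             ScalarizationScheme, affinity_reward, bbb_reward,
                             diversity_penalty, discounted_return,
                             pareto_front, reinforce_loss, run_finetuning,
                             sample_dual, scalarize, select_policy)

CFG = RLConfig()


# ------------------------------------------------------------------- rewards
def test_affinity_reward_endpoints_and_monotonicity():
    assert affinity_reward(CFG.pic50_low, CFG) == 0.0
    assert affinity_reward(CFG.pic50_high, CFG) == 1.0
    assert affinity_reward(7.0, CFG) > affinity_reward(6.5, CFG)
    assert affinity_reward(2.0, CFG) == 0.0  # clamped below range
    assert affinity_reward(12.0, CFG) == 1.0


def test_affinity_reward_uses_exponential_rule():
    # raw(pIC50) = exp(pIC50/4 - 1); raw(4.0) = 1 before normalization
    lo = math.exp(CFG.pic50_low / 4 - 1)
    hi = math.exp(CFG.pic50_high / 4 - 1)
    assert affinity_reward(4.0, CFG) == pytest.approx((1.0 - lo) / (hi - lo))


def test_bbb_reward_identity_and_range():
    assert bbb_reward(0.0) == 0.0
    assert bbb_reward(1.0) == 1.0
    assert bbb_reward(0.37) == 0.37
    with pytest.raises(ValueError):
        bbb_reward(-0.1)
    with pytest.raises(ValueError):
        bbb_reward(1.2)


# -------------------------------------------------------------- scalarization
def test_lws_examples():
    s = ScalarizationScheme("lws", (0.5, 0.5))
    assert scalarize((0.6, 0.4), s) == pytest.approx(0.5)
    s10 = ScalarizationScheme("lws", (1.0, 0.0))
    rng = np.random.default_rng(0)
    for _ in range(50):
        r = tuple(rng.random(2))
        assert scalarize(r, s10) == pytest.approx(r[0])


def test_chebyshev_selects_farthest_objective():
    s = ScalarizationScheme("chebyshev", (0.5, 0.5))
    # distances (0.05, 0.40): BBB is farthest from utopia -> its reward
    assert scalarize((0.9, 0.2), s) == 0.2
    # tie breaks toward the affinity objective
    assert scalarize((0.3, 0.3), s) == 0.3


def test_scalarization_symmetric_under_objective_swap():
    rng = np.random.default_rng(1)
    for kind in ("lws", "chebyshev"):
        for _ in range(100):
            r = tuple(rng.random(2))
            w = rng.random()
            a = scalarize(r, ScalarizationScheme(kind, (w, 1 - w)))
            b = scalarize(r[::-1], ScalarizationScheme(kind, (1 - w, w)))
            assert a == pytest.approx(b)


def test_scalarization_validates_weights():
    with pytest.raises(ValueError):
        ScalarizationScheme("lws", (0.7, 0.7))
    with pytest.raises(ValueError):
        ScalarizationScheme("nope", (0.5, 0.5))


def test_discounted_return_matches_loop():
    assert discounted_return([1, 1, 1], 0.5) == pytest.approx(1.75)
    assert discounted_return([3.0, 9.9, -1], 0.0) == 3.0
    rng = np.random.default_rng(2)
    r = rng.standard_normal(6)
    expected = sum(0.9 ** k * r[k] for k in range(6))
    assert discounted_return(r, 0.9) == pytest.approx(expected)


# ---------------------------------------------------------- diversity memory
def test_diversity_penalty_on_repeats():
    mem = DiversityMemory(capacity=10, threshold=0.75, penalty_factor=0.7)
    fp = fingerprint("c1ccccc1", n_bits=256)
    mem.update([fp] * 3)
    adjusted, hit = diversity_penalty([fp, fp], mem, 1.0)
    assert hit
    assert adjusted == pytest.approx(0.7)


def test_diversity_penalty_skips_empty_memory_and_zero_threshold():
    mem = DiversityMemory(threshold=0.75)
    fp = fingerprint("CCO", n_bits=256)
    adjusted, hit = diversity_penalty([fp], mem, 0.8)
    assert not hit and adjusted == 0.8
    mem0 = DiversityMemory(threshold=0.0)
    mem0.update([fp] * 5)
    adjusted, hit = diversity_penalty([fp], mem0, 0.8)
    assert not hit and adjusted == 0.8  # d >= 0 is never < 0


def test_diversity_memory_fifo_eviction():
    mem = DiversityMemory(capacity=3)
    fps = [fingerprint(s, n_bits=128) for s in ("C", "CC", "CCC", "CCCC")]
    mem.update(fps)
    assert len(mem) == 3
    assert np.array_equal(mem.buffer[0], fps[1])  # oldest evicted


# -------------------------------------------------------- exploration control
def test_select_policy_rates_and_reproducibility():
    ctrl = ExplorationController(rng=np.random.default_rng(0))
    draws = [select_policy(ctrl, INCREASING) for _ in range(10_000)]
    rate = np.mean([d == BIASED for d in draws])
    assert rate == pytest.approx(0.99, abs=0.01)
    ctrl2 = ExplorationController(rng=np.random.default_rng(0))
    draws2 = [select_policy(ctrl2, INCREASING) for _ in range(10_000)]
    assert draws == draws2


def test_select_policy_degenerate_threshold():
    ctrl = ExplorationController(thresholds={INCREASING: 1.0},
                                 rng=np.random.default_rng(3))
    assert all(select_policy(ctrl, INCREASING) == UNBIASED
               for _ in range(100))


def test_trend_classification():
    ctrl = ExplorationController(trend_window=10)
    up = list(np.linspace(0.1, 0.9, 15))
    down = list(np.linspace(0.9, 0.1, 15))
    flat = [0.5 + 1e-5 * (-1) ** i for i in range(15)]
    assert ctrl.classify_trend(up) == INCREASING
    assert ctrl.classify_trend(down) == DECREASING
    assert ctrl.classify_trend(flat) == UNDEFINED
    assert ctrl.classify_trend([0.3]) == UNDEFINED


# ------------------------------------------------------------ surrogate loss
def _tiny_policy(tiny_vocab, cell="lstm", seed=0):
    cfg = GeneratorConfig(recurrent_units=8, dropout_rate=0.0, max_tokens=12,
                          cell=cell)
    return build_policy(cfg, tiny_vocab, seed=seed)


def test_zero_rewards_give_zero_loss_and_gradient(tiny_vocab):
    policy = _tiny_policy(tiny_vocab)
    batch = sample(policy, 4, rng=np.random.default_rng(1))
    loss, grads = reinforce_loss(policy, batch, [0.0] * 4, gamma=1.0)
    assert loss == 0.0
    assert all(np.all(g == 0) for g in grads.values())


def test_unit_reward_single_sequence_loss_is_sequence_nll(tiny_vocab):
    """With R=1, gamma=1, n=1 the surrogate reduces to the sequence NLL."""
    policy = _tiny_policy(tiny_vocab, seed=4)
    batch = sample(policy, 1, temperature=0.9, rng=np.random.default_rng(2))
    loss, _ = reinforce_loss(policy, batch, [1.0], gamma=1.0, temperature=0.9)
    # independent route: the log-probs recorded while sampling
    assert loss == pytest.approx(-batch.logprobs[0].sum(), rel=1e-9)


def test_gamma_weights_token_positions(tiny_vocab):
    policy = _tiny_policy(tiny_vocab, seed=5)
    batch = sample(policy, 1, temperature=1.0, rng=np.random.default_rng(3))
    gamma = 0.5
    loss, _ = reinforce_loss(policy, batch, [2.0], gamma=gamma,
                             temperature=1.0)
    lp = batch.logprobs[0]
    expected = -2.0 * sum(gamma ** j * lp[j] for j in range(len(lp)))
    assert loss == pytest.approx(expected, rel=1e-9)


@pytest.mark.parametrize("cell", ["lstm", "gru"])
def test_reinforce_gradient_matches_finite_differences(tiny_vocab, cell):
    """Central finite differences validate the analytic policy gradient."""
    policy = _tiny_policy(tiny_vocab, cell=cell, seed=7)
    batch = sample(policy, 3, temperature=0.9, rng=np.random.default_rng(5))
    rewards = [0.8, 0.3, 1.0]
    _, grads = reinforce_loss(policy, batch, rewards, gamma=0.9,
                              temperature=0.9)
    h = 1e-4
    worst = 0.0
    for name, arr in policy.model.params.items():
        flat = arr.reshape(-1)
        sel = np.random.default_rng(0).choice(
            flat.size, size=min(60, flat.size), replace=False)
        for i in sel:
            orig = flat[i]
            flat[i] = orig + h
            lp, _ = reinforce_loss(policy, batch, rewards, 0.9,
                                   temperature=0.9)
            flat[i] = orig - h
            lm, _ = reinforce_loss(policy, batch, rewards, 0.9,
                                   temperature=0.9)
            flat[i] = orig
            num = (lp - lm) / (2 * h)
            ana = grads[name].reshape(-1)[i]
            if max(abs(num), abs(ana)) < 1e-10:
                continue
            worst = max(worst, abs(num - ana) / max(abs(num), abs(ana)))
    assert worst < 1e-3


def test_reinforce_loss_length_mismatch(tiny_vocab):
    policy = _tiny_policy(tiny_vocab)
    batch = sample(policy, 3, rng=np.random.default_rng(0))
    with pytest.raises(ValueError):
        reinforce_loss(policy, batch, [1.0, 1.0], gamma=1.0)


# -------------------------------------------------------------- dual sampling
def test_dual_sampling_masks_and_reproducibility(tiny_vocab):
    biased = _tiny_policy(tiny_vocab, seed=1)
    unbiased = _tiny_policy(tiny_vocab, seed=2)
    ctrl = ExplorationController(rng=np.random.default_rng(0))
    batch = sample_dual(biased, unbiased, 8, ctrl, UNDEFINED, 0.9,
                        np.random.default_rng(4))
    assert batch.emitted_by_biased is not None
    for seq, mask in zip(batch.sequences, batch.emitted_by_biased):
        assert len(seq) == len(mask)
    ctrl2 = ExplorationController(rng=np.random.default_rng(0))
    batch2 = sample_dual(biased, unbiased, 8, ctrl2, UNDEFINED, 0.9,
                         np.random.default_rng(4))
    assert batch.smiles() == batch2.smiles()


# ------------------------------------------------------------------ training
def test_zero_reward_oracle_leaves_parameters_unchanged(tiny_vocab):
    policy = _tiny_policy(tiny_vocab, seed=3)
    before = {k: v.copy() for k, v in policy.model.params.items()}
    cfg = RLConfig(episodes=5, batch_size=4)
    biased, logs = run_finetuning(
        policy, lambda s: CFG.pic50_low, lambda s: 0.0,
        ScalarizationScheme("lws", (0.5, 0.5)), cfg, seed=0)
    assert all(np.array_equal(biased.model.params[k], before[k])
               for k in before)
    assert all(np.array_equal(policy.model.params[k], before[k])
               for k in before)


def test_predictor_failure_drops_molecule_without_crash(tiny_vocab):
    policy = _tiny_policy(tiny_vocab, seed=3)

    def flaky_affinity(s):
        raise RuntimeError("boom")

    cfg = RLConfig(episodes=3, batch_size=4)
    with pytest.warns(UserWarning, match="dropped"):
        biased, logs = run_finetuning(
            policy, flaky_affinity, lambda s: 1.0,
            ScalarizationScheme("lws", (0.5, 0.5)), cfg, seed=0)
    assert len(logs) == 3


# ----------------------------------------------------------------- Pareto set
def _brute_force_front(points):
    keep = []
    for i, p in enumerate(points):
        dominated = False
        for j, q in enumerate(points):
            if i == j:
                continue
            if (q.r_affinity >= p.r_affinity and q.r_bbb >= p.r_bbb and
                    (q.r_affinity > p.r_affinity or q.r_bbb > p.r_bbb)):
                dominated = True
                break
        if not dominated:
            keep.append(p)
    return keep


def test_pareto_front_example_and_single_point():
    pts = [ParetoPoint((0.5, 0.5), *c) for c in
           [(0.5, 0.5), (0.6, 0.4), (0.4, 0.6), (0.3, 0.3)]]
    front = pareto_front(pts)
    assert front == pts[:3]
    assert pts[3].dominated
    single = [ParetoPoint((1, 0), 0.2, 0.9)]
    assert pareto_front(single) == single
    with pytest.raises(ValueError):
        pareto_front([])


def test_pareto_front_matches_brute_force_on_random_points():
    rng = np.random.default_rng(8)
    pts = [ParetoPoint((0.5, 0.5), float(a), float(b))
           for a, b in rng.random((100, 2))]
    front = pareto_front(pts)
    expected = _brute_force_front(pts)
    assert front == expected


def test_equal_points_are_mutually_non_dominated():
    pts = [ParetoPoint((0.5, 0.5), 0.4, 0.4) for _ in range(5)]
    assert pareto_front(pts) == pts
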