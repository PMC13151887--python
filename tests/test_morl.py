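import numpy as np
import pytest

from paretodiff.morl import (BufferEntry, ReplayBuffer, RLConfig, assign_rewards,
                             buffer_priority, buffer_update, compose_batch,
                             compose_counts, crowding_distance, curriculum_phase,
                             gae_advantages, non_dominated_sort, normalize_advantages,
                             pareto_front_mask, ppo_loss)
from conftest import brute_force_ranks

CFG = RLConfig()


# ---------------------------------------------------------------------------
# Non-dominated sorting
# ---------------------------------------------------------------------------

def test_sort_trivia():
    assert non_dominated_sort([[1.0, 2.0, 3.0]]).tolist() == [1]
    # distinct points with equal coordinate sums cannot dominate each other
    pts = np.array([[0.2, 0.3, 0.5], [0.5, 0.2, 0.3], [0.1, 0.8, 0.1]])
    assert non_dominated_sort(pts).tolist() == [1, 1, 1]
    # equal points share a front
    pts = np.array([[1.0, 1.0], [1.0, 1.0], [0.5, 0.5]])
    assert non_dominated_sort(pts).tolist() == [1, 1, 2]
    with pytest.raises(ValueError):
        non_dominated_sort(np.zeros((0, 3)))


def test_sort_front_stripping_consistency():
    rng = np.random.default_rng(0)
    pts = rng.random((80, 3))
    ranks = non_dominated_sort(pts)
    # removing the rank-1 front must turn rank-2 into the new rank-1
    rest = pts[ranks > 1]
    assert np.array_equal(non_dominated_sort(rest), ranks[ranks > 1] - 1)


def test_sort_matches_brute_force_oracle_many_instances():
    """1,000 random instances (N ≤ 200, 2–4 objectives) against an
    independent pairwise-dominance oracle."""
    rng = np.random.default_rng(2024)
    for i in range(1000):
        n = int(rng.integers(2, 201))
        m = int(rng.integers(2, 5))
        if rng.random() < 0.3:  # include heavy-tie instances
            pts = rng.integers(0, 4, size=(n, m)).astype(float)
        else:
            pts = rng.random((n, m))
        assert np.array_equal(non_dominated_sort(pts), brute_force_ranks(pts)), i


def test_front_mask_equals_rank_one():
    rng = np.random.default_rng(5)
    pts = rng.random((300, 3))
    assert np.array_equal(pareto_front_mask(pts), non_dominated_sort(pts) == 1)


# ---------------------------------------------------------------------------
# Crowding distance
# ---------------------------------------------------------------------------

def test_crowding_small_fronts_uniform():
    assert crowding_distance([[0.0, 1.0], [1.0, 0.0]]).tolist() == [1.0, 1.0]
    assert crowding_distance([[0.5, 0.5]]).tolist() == [1.0]


def test_crowding_hand_computation():
    front = np.array([[0.0, 1.0], [0.5, 0.5], [1.0, 0.0]])
    cd = crowding_distance(front)
    assert cd[1] == pytest.approx(2.0)       # (1-0)/1 + (1-0)/1
    assert cd[0] == cd[2] == pytest.approx(4.0)  # boundaries: 2× max interior


def test_crowding_order_equivariance():
    rng = np.random.default_rng(3)
    front = rng.random((8, 3))
    front = front[pareto_front_mask(front)]
    perm = rng.permutation(len(front))
    assert np.allclose(crowding_distance(front[perm]), crowding_distance(front)[perm])


# ---------------------------------------------------------------------------
# Rewards
# ---------------------------------------------------------------------------

def _phase(n):
    return curriculum_phase({1: 5, 2: 30, 3: 60}[n])


def test_rank_reward_endpoints_and_midpoint():
    # strictly dominated chain: ranks 1..N
    pts = np.array([[float(i)] * 3 for i in range(5, 0, -1)])
    res = assign_rewards(pts, CFG, _phase(2))
    assert res.ranks.tolist() == [1, 2, 3, 4, 5]
    assert res.rewards[0] == pytest.approx(1.0)
    assert res.rewards[-1] == pytest.approx(0.0)
    assert res.rewards[2] == pytest.approx(0.5)  # N=5, r=3


def test_phase1_reward_is_qed():
    objs = np.array([[0.8, -3.0, 0.9], [0.3, -2.0, 0.5]])
    res = assign_rewards(objs, CFG, _phase(1))
    assert np.allclose(res.rewards, [0.8, 0.3])


def test_phase3_adds_normalized_crowding_bonus():
    pts = np.array([[0.0, 1.0, 0.0], [0.5, 0.5, 0.0], [1.0, 0.0, 0.0]])
    res2 = assign_rewards(pts, CFG, _phase(2))
    res3 = assign_rewards(pts, CFG, _phase(3))
    # all rank 1 -> rank rewards are all 1; the max-CD molecule gains exactly α
    assert np.allclose(res2.rewards, 1.0)
    max_cd = np.argmax(res3.crowding)
    assert res3.rewards[max_cd] == pytest.approx(1.0 + CFG.diversity_alpha)


def test_reward_bounds_and_rank_monotonicity_property():
    rng = np.random.default_rng(7)
    for _ in range(50):
        n = int(rng.integers(1, 40))
        objs = rng.random((n, 3))
        res = assign_rewards(objs, CFG, _phase(3))
        assert np.all(res.rewards >= 0.0) and np.all(res.rewards <= 1.1 + 1e-12)
        if n > 1:
            rank_reward = 1.0 - (res.ranks - 1) / (n - 1)
            assert rank_reward[res.ranks == 1].min() >= rank_reward.max() - 1e-12


def test_invalid_molecules_get_zero_reward():
    objs = np.array([[0.9, -2.0, 0.9], [0.8, -2.5, 0.8]])
    res = assign_rewards(objs, CFG, _phase(2), valid=np.array([True, False]))
    assert res.rewards[1] == 0.0


def test_singleton_batch_reward():
    res = assign_rewards(np.array([[0.5, -3.0, 0.4]]), CFG, _phase(2))
    assert res.rewards[0] == 1.0


# ---------------------------------------------------------------------------
# GAE
# ---------------------------------------------------------------------------

def test_gae_closed_forms():
    assert gae_advantages([1.0], [0.0]) == pytest.approx([1.0])
    adv = gae_advantages([0.0, 1.0], [0.0, 0.0])
    assert adv[1] == pytest.approx(1.0)
    assert adv[0] == pytest.approx(0.99 * 0.95 * 1.0)  # γλ·δ₁ = 0.9405
    assert np.allclose(gae_advantages(np.zeros(5), np.zeros(5)), 0.0)
    with pytest.raises(ValueError):
        gae_advantages([1.0, 2.0], [0.0])


def test_gae_lambda_zero_reduces_to_td_residuals():
    rng = np.random.default_rng(1)
    r, v = rng.random(6), rng.random(6)
    cfg = RLConfig(gae_lambda=1e-12)  # λ→0: A_t = δ_t
    adv = gae_advantages(r, v, cfg)
    v_next = np.append(v[1:], 0.0)
    assert np.allclose(adv, r + cfg.gamma * v_next - v, atol=1e-9)


def test_gae_gamma_lambda_one_reduces_to_discounted_sum_minus_baseline():
    rng = np.random.default_rng(2)
    r, v = rng.random(5), rng.random(5)
    cfg = RLConfig(gamma=1.0, gae_lambda=1.0)
    adv = gae_advantages(r, v, cfg)
    returns = np.cumsum(r[::-1])[::-1]  # undiscounted return-to-go
    assert np.allclose(adv, returns - v, atol=1e-12)


# ---------------------------------------------------------------------------
# PPO loss
# ---------------------------------------------------------------------------

def test_ppo_clip_arithmetic():
    # ratio 1, A=1 -> surrogate term 1
    total, comps = ppo_loss(np.zeros(1), np.zeros(1), np.ones(1), np.zeros(1),
                            np.zeros(1), np.zeros(1))
    assert comps["surrogate"] == pytest.approx(1.0)
    # ratio 2, A=1, ε=0.2 -> min(2, 1.2) = 1.2
    total, comps = ppo_loss(np.log(2) * np.ones(1), np.zeros(1), np.ones(1),
                            np.zeros(1), np.zeros(1), np.zeros(1))
    assert comps["surrogate"] == pytest.approx(1.2)
    # ratio 0.5, A=−1 -> min(−0.5, −0.8) = −0.8
    total, comps = ppo_loss(np.log(0.5) * np.ones(1), np.zeros(1),
                            -np.ones(1), np.zeros(1), np.zeros(1), np.zeros(1))
    assert comps["surrogate"] == pytest.approx(-0.8)


def test_ppo_buffer_samples_excluded_from_surrogate():
    logp = np.array([0.0, np.log(3.0)])
    adv = np.array([1.0, 5.0])
    is_buffer = np.array([False, True])
    total, comps = ppo_loss(logp, np.zeros(2), adv, np.zeros(2), np.zeros(2),
                            np.zeros(2), is_buffer=is_buffer)
    assert comps["surrogate"] == pytest.approx(1.0)  # only the fresh sample


def test_ppo_value_loss_uses_clipped_importance_weights():
    # buffer sample with huge ratio: IS weight clipped to 2.0
    logp_new = np.array([0.0, 5.0])
    values = np.array([0.0, 1.0])
    returns = np.array([0.0, 0.0])
    is_buffer = np.array([False, True])
    total, comps = ppo_loss(logp_new, np.zeros(2), np.zeros(2), values, returns,
                            np.zeros(2), is_buffer=is_buffer)
    assert comps["value_loss"] == pytest.approx((0.0 + 2.0 * 1.0) / 2)


def test_advantage_normalization():
    adv = normalize_advantages(np.array([1.0, 2.0, 3.0]))
    assert adv.mean() == pytest.approx(0.0, abs=1e-9)
    assert adv.std() == pytest.approx(1.0, rel=1e-6)


# ---------------------------------------------------------------------------
# Replay buffer
# ---------------------------------------------------------------------------

def _entry(priority, tag=None):
    return BufferEntry(molecule=tag, objectives=None, priority=priority,
                       logp_old=0.0, epoch=0)


def test_buffer_priority_formula():
    assert buffer_priority(2, 0.8) == pytest.approx(0.4)
    assert buffer_priority(1, 1.0) == 1.0


def test_buffer_capacity_eviction_keeps_priority_order():
    buf = ReplayBuffer(capacity=100)
    rng = np.random.default_rng(0)
    priorities = rng.uniform(0.01, 1.0, size=101)
    for p in priorities:
        buf.add(_entry(p))
    assert len(buf) == 100
    kept = sorted(e.priority for e in buf.entries)
    assert kept == sorted(priorities)[1:]  # exactly the minimum evicted
    with pytest.raises(ValueError):
        buf.add(_entry(0.0))


def test_buffer_sampling_distribution_chi_squared():
    """Uniform priorities: empirical first-draw frequencies pass a χ² test."""
    from scipy.stats import chisquare
    buf = ReplayBuffer(capacity=10)
    for i in range(8):
        buf.add(_entry(1.0, tag=i))
    rng = np.random.default_rng(123)
    counts = np.zeros(8)
    for _ in range(10_000):
        e = buf.sample(1, rng)[0]
        counts[e.molecule] += 1
    _, p = chisquare(counts)
    assert p > 0.01


def test_buffer_sampling_zero_weight_never_first():
    buf = ReplayBuffer(capacity=4)
    buf.add(_entry(1.0, tag="hi"))
    buf.add(_entry(1e-12, tag="lo"))
    rng = np.random.default_rng(0)
    for _ in range(200):
        assert buf.sample(1, rng)[0].molecule == "hi"


def test_buffer_sampling_reproducible_and_oversized_request(caplog):
    buf = ReplayBuffer(capacity=10)
    for i in range(5):
        buf.add(_entry(0.1 * (i + 1), tag=i))
    a = [e.molecule for e in buf.sample(3, np.random.default_rng(9))]
    b = [e.molecule for e in buf.sample(3, np.random.default_rng(9))]
    assert a == b
    import logging
    with caplog.at_level(logging.WARNING):
        out = buf.sample(99, np.random.default_rng(0))
    assert len(out) == 5 and "returning all" in caplog.text
    with pytest.raises(ValueError):
        ReplayBuffer().sample(1, np.random.default_rng(0))


# ---------------------------------------------------------------------------
# Batch composition and curriculum
# ---------------------------------------------------------------------------

def test_compose_counts_printed_examples():
    assert compose_counts(128) == (90, 26, 12)
    assert compose_counts(10) == (7, 2, 1)
    assert sum(compose_counts(77)) == 77


def test_compose_batch_backfills_from_new():
    buf = ReplayBuffer()
    rng = np.random.default_rng(0)
    comp = compose_batch(list(range(20)), buf, ["m"] * 5, 10, CFG, rng)
    n_new, n_buf, n_train = comp["counts"]
    assert n_buf == 0 and n_train == 1 and n_new == 9  # buffer share backfilled


def test_curriculum_phases():
    assert curriculum_phase(10).phase == 1
    assert curriculum_phase(20).phase == 1
    assert curriculum_phase(21).phase == 2
    assert curriculum_phase(50).phase == 2
    p3 = curriculum_phase(51)
    assert p3.phase == 3 and p3.diversity_bonus
    assert curriculum_phase(1).objectives == ("qed",)
    assert curriculum_phase(30).pareto_ranking
    with pytest.raises(ValueError):
        curriculum_phase(0)


def test_rl_config_validation():
    with pytest.raises(ValueError):
        RLConfig(batch_mix=(0.5, 0.2, 0.2))
    with pytest.raises(ValueError):
        RLConfig(gamma=-1.0)
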