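import autograd.numpy as anp
import numpy as np
import pytest
from scipy.stats import special_ortho_group

from paretodiff.diffusion import (DiffusionSchedule, LossWeights, bond_loss,
                                  composite_loss, cosine_beta_schedule,
                                  ddim_sample, ddim_step, ddim_timesteps,
                                  denoise_loss, forward_diffuse, valence_loss)
from paretodiff.molgraph import ATOM_TYPES, ValenceTable


# ---------------------------------------------------------------------------
# Schedule
# ---------------------------------------------------------------------------

def test_cosine_schedule_endpoints_and_monotonicity():
    sched = cosine_beta_schedule(1000)
    assert sched.betas[0] == pytest.approx(1e-4)
    assert sched.betas[-1] == pytest.approx(0.02)
    assert sched.betas.min() >= 1e-4 and sched.betas.max() <= 0.02
    assert sched.alpha_bars[0] == 1.0
    assert np.all(np.diff(sched.alpha_bars) < 0)


def test_schedule_rejects_tiny_T():
    with pytest.raises(ValueError):
        cosine_beta_schedule(1)


# ---------------------------------------------------------------------------
# Forward diffusion
# ---------------------------------------------------------------------------

def test_forward_diffuse_identity_at_t0():
    sched = cosine_beta_schedule(100, ddim_steps=10)
    x0 = np.random.default_rng(0).standard_normal((5, 3))
    eps = np.ones_like(x0)
    assert np.allclose(forward_diffuse(x0, 0, eps, sched), x0)


def test_forward_diffuse_variance_identity():
    """For standardized x0, Var(x_t) = ᾱ + (1−ᾱ) = 1 at every t."""
    sched = cosine_beta_schedule(100, ddim_steps=10)
    rng = np.random.default_rng(42)
    x0 = rng.standard_normal(10_000)[:, None] * np.ones((1, 1))
    x0 = (x0 - x0.mean()) / x0.std()
    for t in (10, 50, 100):
        eps = rng.standard_normal(x0.shape)
        xt = forward_diffuse(x0, t, eps, sched)
        assert xt.std() == pytest.approx(1.0, abs=0.05)


def test_forward_diffuse_decorrelates_at_terminal_time():
    """At t=T the sample is almost pure noise: corr(x_t, x0) = √ᾱ_T ≈ 0.

    (The β range is clipped to [1e-4, 0.02], so ᾱ_T is small but not exactly
    zero; the Monte-Carlo correlation must match √ᾱ_T.)"""
    sched = cosine_beta_schedule(1000)
    rng = np.random.default_rng(3)
    x0 = rng.standard_normal((10_000, 1))
    eps = rng.standard_normal(x0.shape)
    xt = forward_diffuse(x0, 1000, eps, sched)
    corr = np.corrcoef(x0[:, 0], xt[:, 0])[0, 1]
    assert sched.alpha_bars[-1] < 0.005
    assert corr == pytest.approx(np.sqrt(sched.alpha_bars[-1]), abs=0.03)


def test_forward_diffuse_validates_inputs():
    sched = cosine_beta_schedule(10, ddim_steps=5)
    x0 = np.zeros((2, 3))
    with pytest.raises(ValueError):
        forward_diffuse(x0, 11, np.zeros_like(x0), sched)
    with pytest.raises(ValueError):
        forward_diffuse(x0, 1, np.zeros((3, 3)), sched)


def test_forward_diffuse_categorical_corruption_rate():
    sched = cosine_beta_schedule(100, ddim_steps=10)
    rng = np.random.default_rng(0)
    cat = np.zeros(20_000, dtype=int)
    _, corrupted = forward_diffuse(np.zeros((20_000, 3)), 90,
                                   np.zeros((20_000, 3)), sched,
                                   categorical=cat, rng=rng)
    ab = sched.alpha_bars[90]
    # resampled uniformly w.p. 1−ᾱ; a resample keeps the old type 1/6 of the time
    expected_changed = (1 - ab) * (1 - 1 / len(ATOM_TYPES))
    assert (corrupted != cat).mean() == pytest.approx(expected_changed, abs=0.02)


# ---------------------------------------------------------------------------
# Losses: closed forms and loop-reference agreement
# ---------------------------------------------------------------------------

def _loop_bond_loss(probs, coords, tau):
    total, n = 0.0, coords.shape[0]
    for i in range(n):
        for j in range(i + 1, n):
            d = np.linalg.norm(coords[i] - coords[j])
            y = 1.0 if d < tau else 0.0
            p = min(max(probs[i, j], 1e-7), 1 - 1e-7)
            total += -(y * np.log(p) + (1 - y) * np.log(1 - p))
    return total


def test_bond_loss_closed_forms():
    coords = np.array([[0.0, 0, 0], [1.5, 0, 0]])
    perfect = np.array([[0.0, 1.0], [1.0, 0.0]])
    assert bond_loss(perfect, coords, 1.8) == pytest.approx(0.0, abs=1e-5)
    half = np.array([[0.0, 0.5], [0.5, 0.0]])
    assert bond_loss(half, coords, 1.8) == pytest.approx(np.log(2), abs=1e-9)
    far = np.array([[0.0, 0, 0], [2.5, 0, 0]])
    confident = np.array([[0.0, 0.9], [0.9, 0.0]])
    assert bond_loss(confident, far, 1.8) == pytest.approx(-np.log(0.1), abs=1e-9)


def test_bond_loss_matches_loop_reference():
    rng = np.random.default_rng(5)
    for _ in range(5):
        n = 7
        coords = rng.uniform(-3, 3, size=(n, 3))
        probs = rng.uniform(0, 1, size=(n, n))
        probs = (probs + probs.T) / 2
        np.fill_diagonal(probs, 0.0)
        assert bond_loss(probs, coords, 1.8) == pytest.approx(
            _loop_bond_loss(probs, coords, 1.8), abs=1e-10)


def test_valence_loss_hinge_examples():
    # carbon with predicted bond-order sum 5 -> (5-4)^2 = 1
    probs = np.zeros((6, 6))
    probs[0, 1:] = 1.0
    probs[1:, 0] = 1.0
    assert valence_loss(probs, ["C", "C", "C", "C", "C", "C"]) == pytest.approx(1.0)
    # inactive hinge
    probs = np.zeros((2, 2))
    probs[0, 1] = probs[1, 0] = 1.0
    assert valence_loss(probs, ["C", "C"]) == 0.0
    # nitrogen row-sum 4.5 -> 2.25
    probs = np.zeros((4, 4))
    probs[0, 1:] = 1.5
    probs[1:, 0] = 1.5
    out = valence_loss(probs, ["N", "C", "C", "C"])
    assert out == pytest.approx(2.25 + 0.0)  # only the nitrogen row is over


def test_valence_loss_matches_loop_reference():
    rng = np.random.default_rng(8)
    table = ValenceTable()
    for _ in range(5):
        n = 6
        types = [ATOM_TYPES[i] for i in rng.integers(0, len(ATOM_TYPES), n)]
        probs = rng.uniform(0, 1, size=(n, n))
        np.fill_diagonal(probs, 0.0)
        ref = sum(max(0.0, probs[i].sum() - table.max_valence[types[i]]) ** 2
                  for i in range(n))
        assert valence_loss(probs, types) == pytest.approx(ref, abs=1e-10)


def test_valence_loss_unknown_atom():
    with pytest.raises(ValueError, match="unknown atom"):
        valence_loss(np.zeros((1, 1)), ["Xx"])


def test_composite_loss_weighted_sum():
    assert composite_loss(1.0, 2.0, 3.0) == pytest.approx(2.7)
    assert composite_loss(0.0, 0.0, 0.0) == 0.0
    x = np.random.default_rng(0).standard_normal((4, 3))
    assert denoise_loss(x, x) == 0.0
    with pytest.raises(ValueError):
        LossWeights(lambda_bond=-0.1)


# ---------------------------------------------------------------------------
# Denoiser symmetry suite
# ---------------------------------------------------------------------------

def test_denoiser_equivariance_suite(small_denoiser):
    """Coordinate noise rotates with the input; invariant heads do not move.

    20 random molecules × 5 random rotations at 1e-5."""
    den, params = small_denoiser
    rng = np.random.default_rng(17)
    for m in range(20):
        n = int(rng.integers(4, 9))
        x = rng.standard_normal((n, 3))
        x -= x.mean(axis=0)
        onehot = np.eye(len(ATOM_TYPES))[rng.integers(0, len(ATOM_TYPES), n)]
        eps, logits, bonds, _ = den.forward(params, x, onehot, 0.37)
        eps, logits, bonds = np.array(eps), np.array(logits), np.array(bonds)
        for k in range(5):
            R = special_ortho_group.rvs(3, random_state=100 * m + k)
            epsR, logitsR, bondsR, _ = den.forward(params, x @ R.T, onehot, 0.37)
            assert np.abs(np.array(epsR) - eps @ R.T).max() < 1e-5
            assert np.abs(np.array(logitsR) - logits).max() < 1e-5
            assert np.abs(np.array(bondsR) - bonds).max() < 1e-5


def test_denoiser_translation_invariance(small_denoiser):
    den, params = small_denoiser
    rng = np.random.default_rng(23)
    x = rng.standard_normal((6, 3))
    onehot = np.eye(len(ATOM_TYPES))[rng.integers(0, len(ATOM_TYPES), 6)]
    eps, logits, _, _ = den.forward(params, x, onehot, 0.5)
    epsT, logitsT, _, _ = den.forward(params, x + np.array([5.0, -3.0, 2.0]), onehot, 0.5)
    assert np.abs(np.array(epsT) - np.array(eps)).max() < 1e-9
    assert np.abs(np.array(logitsT) - np.array(logits)).max() < 1e-9


def test_denoiser_permutation_equivariance(small_denoiser):
    den, params = small_denoiser
    rng = np.random.default_rng(31)
    n = 7
    x = rng.standard_normal((n, 3))
    onehot = np.eye(len(ATOM_TYPES))[rng.integers(0, len(ATOM_TYPES), n)]
    perm = rng.permutation(n)
    eps, logits, bonds, _ = den.forward(params, x, onehot, 0.2)
    epsP, logitsP, bondsP, _ = den.forward(params, x[perm], onehot[perm], 0.2)
    assert np.abs(np.array(epsP) - np.array(eps)[perm]).max() < 1e-9
    assert np.abs(np.array(logitsP) - np.array(logits)[perm]).max() < 1e-9
    assert np.abs(np.array(bondsP) - np.array(bonds)[np.ix_(perm, perm)]).max() < 1e-9


# ---------------------------------------------------------------------------
# DDIM
# ---------------------------------------------------------------------------

class _ZeroDenoiser:
    """ε̂ ≡ 0: DDIM reduces to x_{t_prev} = √(ᾱ_{t_prev}/ᾱ_t)·x_t."""

    def __init__(self, cfg):
        self.cfg = cfg

    def forward(self, params, x, onehot, t_frac, context=None):
        n = x.shape[0]
        return (np.zeros_like(x), np.zeros((n, len(ATOM_TYPES))),
                np.zeros((n, n)), np.zeros(4))


def test_ddim_zero_denoiser_closed_form(small_denoiser):
    den, params = small_denoiser
    zero = _ZeroDenoiser(den.cfg)
    sched = cosine_beta_schedule(40, ddim_steps=8)
    rng = np.random.default_rng(11)
    init = rng.standard_normal((5, 3))
    out = ddim_sample(init, rng.integers(0, 6, 5), sched, zero, params, steps=8)
    ts = ddim_timesteps(sched, 8)
    x = init - init.mean(axis=0, keepdims=True)
    for i, t in enumerate(ts):  # hand recursion of the closed form
        t_prev = ts[i + 1] if i + 1 < len(ts) else 0
        x = np.sqrt(sched.alpha_bars[t_prev] / sched.alpha_bars[t]) * x
    assert np.allclose(out.coords, x - x.mean(axis=0), atol=1e-12)


def test_ddim_subschedule_consistency():
    """Full- and sub-schedule trajectories agree at shared timesteps for ε̂=0
    (the ᾱ-ratio updates telescope)."""
    sched = cosine_beta_schedule(60, ddim_steps=6)
    rng = np.random.default_rng(2)
    x0 = rng.standard_normal((4, 3))

    def run(steps):
        ts = ddim_timesteps(sched, steps)
        x = x0.copy()
        trace = {}
        for i, t in enumerate(ts):
            t_prev = int(ts[i + 1]) if i + 1 < len(ts) else 0
            x = np.array(ddim_step(x, np.zeros_like(x), int(t), t_prev, sched))
            trace[t_prev] = x.copy()
        return trace

    full, sub = run(60), run(6)
    for t, x_sub in sub.items():
        assert np.allclose(full[t], x_sub, atol=1e-10)


def test_ddim_deterministic_and_validates_steps(small_denoiser):
    den, params = small_denoiser
    sched = cosine_beta_schedule(40, ddim_steps=8)
    rng = np.random.default_rng(0)
    init = rng.standard_normal((5, 3))
    types = np.array([0, 1, 2, 0, 0])
    a = ddim_sample(init, types, sched, den, params, steps=8)
    b = ddim_sample(init, types, sched, den, params, steps=8)
    assert np.array_equal(a.coords, b.coords)
    assert a.atom_types == b.atom_types
    assert np.array_equal(a.bond_probs, b.bond_probs)
    with pytest.raises(ValueError):
        ddim_sample(init, types, sched, den, params, steps=41)


def test_training_smoke_loss_decreases(toy_corpus):
    """A 200-step seeded run on fixture molecules: the composite loss falls
    (moving average) from start to finish."""
    from paretodiff.training import smoke_diffusion_training

    losses = np.array(smoke_diffusion_training(toy_corpus[:8], n_steps=200, seed=5))
    assert np.all(np.isfinite(losses))
    window = 40
    ma = np.convolve(losses, np.ones(window) / window, mode="valid")
    assert ma[-1] < ma[0]
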