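"""Forward diffusion, composite loss, the equivariant denoiser, DDIM sampling.

Coordinates follow the standard Gaussian corruption x_t = √ᾱ_t·x₀ + √(1−ᾱ_t)·ε
under a squared-cosine ᾱ schedule whose implied β_t are clipped to the stated
[1e-4, 0.02] range. Categorical state (atom types) is corrupted by uniform
resampling with probability 1−ᾱ_t — the simplest discrete process consistent
with gradual structural corruption. Training minimises

    L = L_denoise + λ_bond·L_bond + λ_valence·L_valence

with λ_bond = 0.1 and λ_valence = 0.5: a mean-squared denoising term, a
binary-cross-entropy consistency term tying predicted bond probabilities to a
distance threshold τ_bond = 1.8 Å, and a squared hinge on per-atom predicted
valence sums.

The denoiser is an EGNN-style message-passing network: invariant node features
are updated from distance-based messages, while the coordinate-noise head is a
sum of relative-position vectors scaled by learned invariant weights, so
rotation equivariance and translation invariance hold by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import autograd.numpy as anp
import numpy as np

from .conditioning import (ConditioningConfig, cross_attend, gated_fuse,
                           init_conditioning_params, init_cross_attention_params)
from .molgraph import ATOM_TYPES, MoleculeGraph, ValenceTable, DEFAULT_VALENCE_TABLE
from .nnops import (linear, linear_params, mlp, mlp_params, sigmoid,
                    sinusoidal_embedding)

BETA_MIN, BETA_MAX = 1e-4, 0.02


@dataclass(frozen=True)
class DiffusionSchedule:
    """β/α/ᾱ sequences over T steps plus the DDIM sub-schedule length.

    ``alpha_bars`` has length T+1 with ᾱ_0 = 1 so that t indexes it directly.
    """

    T: int
    betas: np.ndarray
    alphas: np.ndarray
    alpha_bars: np.ndarray
    ddim_steps: int = 100

    def __post_init__(self):
        if self.betas.min() < BETA_MIN - 1e-12 or self.betas.max() > BETA_MAX + 1e-12:
            raise ValueError("betas outside [1e-4, 0.02]")
        if self.alpha_bars[0] != 1.0:
            raise ValueError("alpha_bars must start at 1")
        if np.any(np.diff(self.alpha_bars) >= 0):
            raise ValueError("alpha_bars must be strictly decreasing")


def cosine_beta_schedule(T: int, ddim_steps: int = 100, s: float = 0.008) -> DiffusionSchedule:
    """Squared-cosine ᾱ curve with implied β_t clipped into [1e-4, 0.02].

    The clipping reconciles the cosine shape with the stated β range: for the
    default T = 1000 the first and last β equal exactly 1e-4 and 0.02.
    """
    if T < 2:
        raise ValueError("T must be at least 2")
    t = np.arange(T + 1)
    f = np.cos(((t / T) + s) / (1 + s) * np.pi / 2) ** 2
    abar = f / f[0]
    betas = 1.0 - abar[1:] / abar[:-1]
    betas = np.clip(betas, BETA_MIN, BETA_MAX)
    alphas = 1.0 - betas
    alpha_bars = np.concatenate([[1.0], np.cumprod(alphas)])
    return DiffusionSchedule(T=T, betas=betas, alphas=alphas,
                             alpha_bars=alpha_bars, ddim_steps=ddim_steps)


def forward_diffuse(x0: np.ndarray, t: int, eps: np.ndarray, sched: DiffusionSchedule,
                    categorical: np.ndarray | None = None,
                    rng: np.random.Generator | None = None):
    """Corrupt coordinates (and optionally categorical state) to step t.

    x_t = √ᾱ_t·x₀ + √(1−ᾱ_t)·ε; each categorical entry is resampled uniformly
    with probability 1−ᾱ_t. At t=0 the input is returned unchanged.
    """
    if not 0 <= t <= sched.T:
        raise ValueError(f"t={t} outside [0, {sched.T}]")
    if eps.shape != x0.shape:
        raise ValueError("eps shape must match x0")
    ab = sched.alpha_bars[t]
    xt = np.sqrt(ab) * x0 + np.sqrt(1.0 - ab) * eps
    if categorical is None:
        return xt
    if rng is None:
        raise ValueError("rng required for categorical corruption")
    cat = np.array(categorical)
    mask = rng.random(cat.shape[0]) < (1.0 - ab)
    resampled = rng.integers(0, len(ATOM_TYPES), size=cat.shape[0])
    cat = np.where(mask, resampled, cat)
    return xt, cat


# ---------------------------------------------------------------------------
# Losses (autograd-friendly)
# ---------------------------------------------------------------------------

_EPS = 1e-7


@dataclass(frozen=True)
class LossWeights:
    lambda_bond: float = 0.1
    lambda_valence: float = 0.5

    def __post_init__(self):
        if self.lambda_bond < 0 or self.lambda_valence < 0:
            raise ValueError("loss weights must be non-negative")


def bond_loss(bond_probs, coords, tau: float = DEFAULT_VALENCE_TABLE.bond_threshold):
    """Σ_{i<j} BCE(b̂_ij, 1[d_ij < τ]) with probability clamping at 1e-7."""
    if tau <= 0:
        raise ValueError("tau must be positive")
    probs_arr = np.asarray(bond_probs) if isinstance(bond_probs, np.ndarray) else bond_probs
    if isinstance(probs_arr, np.ndarray) and (probs_arr.min() < 0 or probs_arr.max() > 1):
        raise ValueError("bond probabilities outside [0, 1]")
    n = coords.shape[0]
    diff = coords[:, None, :] - coords[None, :, :]
    dist = anp.sqrt(anp.sum(diff**2, axis=-1) + 1e-12)
    target = (dist < tau).astype(float)
    p = anp.clip(bond_probs, _EPS, 1.0 - _EPS)
    bce = -(target * anp.log(p) + (1.0 - target) * anp.log(1.0 - p))
    mask = np.triu(np.ones((n, n)), k=1)
    return anp.sum(bce * mask)


def valence_loss(bond_probs, atom_types, table: ValenceTable = DEFAULT_VALENCE_TABLE):
    """Σ_i max(0, Σ_j b̂_ij − v_max(a_i))² — squared hinge on predicted valence sums."""
    vmax = np.array([table.max_valence[a] if a in table.max_valence
                     else _raise_unknown(a) for a in atom_types], dtype=float)
    row_sums = anp.sum(bond_probs, axis=1)
    excess = anp.maximum(0.0, row_sums - vmax)
    return anp.sum(excess**2)


def _raise_unknown(a):
    raise ValueError(f"unknown atom type {a!r}")


def denoise_loss(eps_true, eps_pred):
    """Mean squared error between true and predicted coordinate noise."""
    return anp.mean((eps_true - eps_pred) ** 2)


def composite_loss(l_denoise, l_bond, l_valence, w: LossWeights = LossWeights()):
    """L = L_denoise + λ_bond·L_bond + λ_valence·L_valence (defaults 0.1, 0.5)."""
    return l_denoise + w.lambda_bond * l_bond + w.lambda_valence * l_valence


# ---------------------------------------------------------------------------
# Equivariant denoiser
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DenoiserConfig:
    """Denoiser architecture. Defaults are the full-scale model (12 layers,
    hidden 256, conditioning at layers {3, 6, 9, 12}); tests and smoke training
    shrink these."""

    n_layers: int = 12
    hidden: int = 256
    t_embed_dim: int = 64
    n_atom_types: int = len(ATOM_TYPES)
    conditioning: ConditioningConfig = field(default_factory=ConditioningConfig)

    def __post_init__(self):
        bad = [l for l in self.conditioning.conditioned_gnn_layers if not 1 <= l <= self.n_layers]
        if bad:
            raise ValueError(f"conditioned layers {bad} outside [1, {self.n_layers}]")


def _sparse_bond_head(rng, h):
    head = mlp_params(rng, (2 * h + 1, h, 1))
    head[-1]["b"] = head[-1]["b"] - 2.0
    return head


class EquivariantDenoiser:
    """EGNN predicting coordinate noise, atom-type logits and bond probabilities.

    The coordinate head accumulates Σ_j (x_i − x_j)·φ_x(m_ij): rotation-
    equivariant and translation-invariant by construction. Node/bond heads are
    functions of invariant features only.
    """

    def __init__(self, cfg: DenoiserConfig):
        self.cfg = cfg

    def init_params(self, rng: np.random.Generator) -> dict:
        cfg = self.cfg
        h, a, te = cfg.hidden, cfg.n_atom_types, cfg.t_embed_dim
        m = cfg.conditioning.model_dim
        params = {
            "embed": linear_params(rng, a + te, h),
            "layers": [
                {
                    "msg": mlp_params(rng, (2 * h + 1, h, h)),
                    "coord": mlp_params(rng, (h, h, 1)),
                    "node": mlp_params(rng, (2 * h, h, h)),
                }
                for _ in range(cfg.n_layers)
            ],
            "atom_head": mlp_params(rng, (h, h, a)),
            # final bias < 0: start from sparse bond graphs (most atom pairs
            # in a molecule are non-bonded), which also keeps early decoded
            # samples chemically plausible
            "bond_head": _sparse_bond_head(rng, h),
            "cond_proj_in": linear_params(rng, h, m),
            "cond_proj_out": linear_params(rng, m, h),
            "cross": {
                str(l): init_cross_attention_params(rng, m)
                for l in cfg.conditioning.conditioned_gnn_layers
            },
            "conditioning": init_conditioning_params(cfg.conditioning, rng),
        }
        return params

    def forward(self, params: dict, coords, atom_onehot, t_frac: float, context=None):
        """Returns (eps_coords n×3, atom_logits n×A, bond_probs n×n, pooled h).

        ``t_frac`` is t/T in [0, 1]; ``context`` an optional k×256 property
        context from :func:`paretodiff.conditioning.encode_properties`.
        """
        cfg = self.cfg
        n = atom_onehot.shape[0]
        t_emb = sinusoidal_embedding(t_frac * 100.0, cfg.t_embed_dim)
        hfeat = anp.tanh(linear(params["embed"],
                                anp.concatenate([atom_onehot,
                                                 anp.tile(t_emb, (n, 1))], axis=1)))
        x = coords
        mask = 1.0 - np.eye(n)
        for idx, layer in enumerate(params["layers"], start=1):
            diff = x[:, None, :] - x[None, :, :]
            d2 = anp.sum(diff**2, axis=-1, keepdims=True)
            hi = anp.tile(hfeat[:, None, :], (1, n, 1))
            hj = anp.tile(hfeat[None, :, :], (n, 1, 1))
            msg = mlp(layer["msg"], anp.concatenate([hi, hj, d2], axis=-1))
            msg = msg * mask[:, :, None]
            coef = anp.tanh(mlp(layer["coord"], msg))  # bounded update weights
            x = x + anp.sum(diff * coef * mask[:, :, None], axis=1) / max(n - 1, 1)
            agg = anp.sum(msg, axis=1)
            hfeat = hfeat + mlp(layer["node"], anp.concatenate([hfeat, agg], axis=-1))
            if context is not None and idx in cfg.conditioning.conditioned_gnn_layers:
                hm = linear(params["cond_proj_in"], hfeat)
                attended = cross_attend(hm, context, params["cross"][str(idx)])
                fused = gated_fuse(hm, attended, params["cross"][str(idx)]["Wg"])
                hfeat = hfeat + linear(params["cond_proj_out"], fused)
        eps_coords = x - coords  # sum of relative-position updates: equivariant
        atom_logits = mlp(params["atom_head"], hfeat)
        hi = anp.tile(hfeat[:, None, :], (1, n, 1))
        hj = anp.tile(hfeat[None, :, :], (n, 1, 1))
        diff = x[:, None, :] - x[None, :, :]
        d2 = anp.sum(diff**2, axis=-1, keepdims=True)
        pair = anp.concatenate([hi + hj, hi * hj, d2], axis=-1)  # symmetric in (i, j)
        logits = mlp(params["bond_head"], pair)[:, :, 0]
        logits = 0.5 * (logits + logits.T)  # enforce symmetry
        bond_probs = sigmoid(logits) * mask
        pooled = anp.mean(hfeat, axis=0)
        return eps_coords, atom_logits, bond_probs, pooled


# ---------------------------------------------------------------------------
# DDIM sampling
# ---------------------------------------------------------------------------

def ddim_timesteps(sched: DiffusionSchedule, steps: int) -> np.ndarray:
    """Descending kept timesteps T, T−k, … with uniform stride k = T // steps."""
    if steps > sched.T:
        raise ValueError(f"steps={steps} exceeds T={sched.T}")
    stride = sched.T // steps
    return np.arange(sched.T, 0, -stride)


def ddim_step(x_t, eps_hat, t: int, t_prev: int, sched: DiffusionSchedule):
    """Deterministic (η = 0) DDIM update via the predicted clean sample.

    x̂₀ = (x_t − √(1−ᾱ_t)·ε̂)/√ᾱ_t, then x_{t_prev} = √ᾱ_{t_prev}·x̂₀ +
    √(1−ᾱ_{t_prev})·ε̂. The α in the printed update is read as cumulative ᾱ.
    """
    ab_t = sched.alpha_bars[t]
    ab_prev = sched.alpha_bars[t_prev]
    x0_hat = (x_t - anp.sqrt(1.0 - ab_t) * eps_hat) / anp.sqrt(ab_t)
    return anp.sqrt(ab_prev) * x0_hat + anp.sqrt(1.0 - ab_prev) * eps_hat


def ddim_sample(init_coords: np.ndarray, init_types: np.ndarray,
                sched: DiffusionSchedule, denoiser: EquivariantDenoiser,
                params: dict, steps: int | None = None, context=None) -> MoleculeGraph:
    """Deterministic DDIM rollout from noise to a decoded MoleculeGraph.

    ``init_coords`` is the n×3 standard-normal draw, ``init_types`` integer
    atom-type indices (uniform draw). Given the same inputs and weights the
    trajectory is bitwise reproducible. Atom types and bonds are decoded by
    argmax / 0.5-thresholding at the final step.
    """
    steps = steps or sched.ddim_steps
    ts = ddim_timesteps(sched, steps)
    x = init_coords - init_coords.mean(axis=0, keepdims=True)
    n = x.shape[0]
    onehot = np.eye(len(ATOM_TYPES))[np.asarray(init_types)]
    atom_logits = None
    bond_probs = np.zeros((n, n))
    for i, t in enumerate(ts):
        t_prev = ts[i + 1] if i + 1 < len(ts) else 0
        eps_hat, atom_logits, bond_probs, _ = denoiser.forward(
            params, x, onehot, t / sched.T, context=context)
        x = ddim_step(x, eps_hat, int(t), int(t_prev), sched)
        onehot = np.array(_softmax_np(atom_logits))  # soft categorical state
    type_idx = np.argmax(atom_logits, axis=1)
    atom_types = [ATOM_TYPES[i] for i in type_idx]
    bond_probs = np.array(bond_probs)
    np.fill_diagonal(bond_probs, 0.0)
    x = np.array(x) - np.array(x).mean(axis=0, keepdims=True)
    E = np.zeros((n, n, 8))
    bonded = (bond_probs >= 0.5).astype(float)
    np.fill_diagonal(bonded, 0.0)
    E[:, :, 0] = bonded  # decoded bonds enter as single bonds
    dist = np.linalg.norm(x[:, None, :] - x[None, :, :], axis=-1)
    np.fill_diagonal(dist, 0.0)
    E[:, :, 4] = dist
    return MoleculeGraph(coords=x, atom_types=atom_types,
                         edge_features=E, bond_probs=bond_probs)


def _softmax_np(z):
    z = np.asarray(z, dtype=float)
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)
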