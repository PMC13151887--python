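"""Joint training loop: DDIM policy rollouts, Pareto rewards, PPO, diffusion loss.

The policy view of the sampler: at each kept DDIM step the denoiser's predicted
noise ε̂ is the mean of a Gaussian action distribution with fixed σ = 1 (the
paper-level formulation never defines π(a|s) for the deterministic update, so
this package makes the standard Gaussian-over-ε choice; see docs/methods.md).
Exploration noise is injected only during RL rollouts — inference-time DDIM
remains deterministic. One molecule rollout is one episode whose reward is the
terminal Pareto reward; intermediate rewards are zero.

Buffer samples contribute to the value update only: the critic reads *detached*
trunk features, so the PPO gradient of buffer samples with respect to policy
parameters is exactly zero by construction, and importance weights (ratios
clipped to [0.5, 2.0]) are computed outside the differentiated loss.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import autograd.numpy as anp
import numpy as np
from autograd import grad as agrad
from rdkit import Chem

from . import morl
from .diffusion import (DenoiserConfig, DiffusionSchedule, EquivariantDenoiser,
                        bond_loss, composite_loss, cosine_beta_schedule,
                        ddim_step, ddim_timesteps, denoise_loss, valence_loss,
                        LossWeights)
from .molgraph import ATOM_TYPES, MoleculeGraph, DEFAULT_VALENCE_TABLE
from .morl import (CurriculumPhase, ReplayBuffer, RLConfig, assign_rewards,
                   buffer_update, compose_batch, curriculum_phase,
                   gae_advantages, normalize_advantages, ppo_loss)
from .nnops import Adam, mlp, mlp_params
from .objectives import (FingerprintIndex, novelty_score, objective_vector,
                         score_properties)

logger = logging.getLogger(__name__)

_GAUSS_CONST = 0.5 * np.log(2.0 * np.pi)


def gaussian_logp(action, mean, sigma: float = 1.0):
    """Log-density of the Gaussian policy over ε (diagonal, fixed σ)."""
    d = action.size if hasattr(action, "size") else np.asarray(action).size
    sq = anp.sum((action - mean) ** 2)
    return -0.5 * sq / sigma**2 - d * (np.log(sigma) + _GAUSS_CONST)


def gaussian_entropy(dim: int, sigma: float = 1.0) -> float:
    """Entropy of the fixed-σ Gaussian policy (constant w.r.t. parameters)."""
    return dim * (0.5 + np.log(sigma) + _GAUSS_CONST)


@dataclass
class RolloutStep:
    coords: np.ndarray      # x_t before the update
    onehot: np.ndarray      # categorical state at t
    t: int
    action: np.ndarray      # sampled ε action
    logp_old: float
    features: np.ndarray    # detached pooled trunk features (critic input)


@dataclass
class Episode:
    steps: list
    graph: MoleculeGraph
    mol: Chem.Mol | None = None   # RDKit form when decodable
    valid: bool = False
    is_buffer: bool = False
    terminal_reward: float = 0.0


def graph_to_rdkit(graph: MoleculeGraph) -> Chem.Mol | None:
    """Decode a generated graph into a sanitized RDKit mol, or None on failure."""
    try:
        rw = Chem.RWMol()
        for sym in graph.atom_types:
            rw.AddAtom(Chem.Atom(sym))
        bonded = graph.bond_probs >= 0.5
        n = graph.n
        for i in range(n):
            for j in range(i + 1, n):
                if bonded[i, j]:
                    rw.AddBond(i, j, Chem.BondType.SINGLE)
        mol = rw.GetMol()
        Chem.SanitizeMol(mol)
        if mol.GetNumBonds() == 0 and mol.GetNumAtoms() > 1:
            return None  # disconnected atom soup
        return mol
    except Exception:
        return None


def policy_rollout(denoiser: EquivariantDenoiser, params: dict,
                   sched: DiffusionSchedule, n_atoms: int, steps: int,
                   rng: np.random.Generator, sigma: float = 1.0,
                   context=None) -> Episode:
    """Stochastic DDIM rollout under the Gaussian policy; returns the episode."""
    ts = ddim_timesteps(sched, steps)
    x = rng.standard_normal((n_atoms, 3))
    x -= x.mean(axis=0, keepdims=True)
    onehot = np.eye(len(ATOM_TYPES))[rng.integers(0, len(ATOM_TYPES), size=n_atoms)]
    episode_steps = []
    atom_logits = None
    bond_probs = np.zeros((n_atoms, n_atoms))
    for i, t in enumerate(ts):
        t_prev = int(ts[i + 1]) if i + 1 < len(ts) else 0
        eps_hat, atom_logits, bond_probs, pooled = denoiser.forward(
            params, x, onehot, t / sched.T, context=context)
        eps_hat = np.array(eps_hat)
        action = eps_hat + sigma * rng.standard_normal(eps_hat.shape)
        lp = float(gaussian_logp(action, eps_hat, sigma))
        feats = np.concatenate([np.array(pooled), [t / sched.T]])
        episode_steps.append(RolloutStep(coords=x.copy(), onehot=onehot.copy(),
                                         t=int(t), action=action, logp_old=lp,
                                         features=feats))
        x = np.array(ddim_step(x, action, int(t), t_prev, sched))
        probs = np.array(atom_logits)
        probs = np.exp(probs - probs.max(axis=1, keepdims=True))
        onehot = probs / probs.sum(axis=1, keepdims=True)
    type_idx = np.argmax(np.array(atom_logits), axis=1)
    bond_probs = np.array(bond_probs)
    np.fill_diagonal(bond_probs, 0.0)
    x -= x.mean(axis=0, keepdims=True)
    E = np.zeros((n_atoms, n_atoms, 8))
    E[:, :, 0] = (bond_probs >= 0.5).astype(float)
    np.fill_diagonal(E[:, :, 0], 0.0)
    dist = np.linalg.norm(x[:, None, :] - x[None, :, :], axis=-1)
    np.fill_diagonal(dist, 0.0)
    E[:, :, 4] = dist
    graph = MoleculeGraph(coords=x, atom_types=[ATOM_TYPES[k] for k in type_idx],
                          edge_features=E, bond_probs=bond_probs)
    mol = graph_to_rdkit(graph)
    return Episode(steps=episode_steps, graph=graph, mol=mol, valid=mol is not None)


@dataclass
class TrainState:
    """Everything the epoch loop mutates: networks, optimizers, buffer, LR."""

    denoiser: EquivariantDenoiser
    params: dict
    sched: DiffusionSchedule
    buffer: ReplayBuffer
    corpus: list
    fp_index: FingerprintIndex
    opt_rl: Adam
    opt_diff: Adam
    lr_rl: float
    lr_diffusion: float
    last_phase: int = 1
    epoch: int = 0
    rng: np.random.Generator = field(default_factory=lambda: np.random.default_rng(0))


def init_train_state(denoiser_cfg: DenoiserConfig, rl_cfg: RLConfig,
                     sched: DiffusionSchedule, corpus: list,
                     seed: int) -> TrainState:
    rng = np.random.default_rng(seed)
    denoiser = EquivariantDenoiser(denoiser_cfg)
    params = denoiser.init_params(rng)
    params["value"] = mlp_params(rng, (denoiser_cfg.hidden + 1, denoiser_cfg.hidden, 1))
    return TrainState(
        denoiser=denoiser, params=params, sched=sched,
        buffer=ReplayBuffer(rl_cfg.buffer_capacity), corpus=list(corpus),
        fp_index=FingerprintIndex(corpus),
        opt_rl=Adam(params, rl_cfg.lr_rl, rl_cfg.grad_clip),
        opt_diff=Adam(params, rl_cfg.lr_diffusion, rl_cfg.grad_clip),
        lr_rl=rl_cfg.lr_rl, lr_diffusion=rl_cfg.lr_diffusion, rng=rng,
    )


def _episode_objectives(episodes, corpus_mols, fp_index, backend: str):
    """Objective vectors + validity + novelty for policy episodes and corpus mols."""
    objs, valid, novelties = [], [], []
    for ep in episodes:
        if ep.valid:
            try:
                rec = score_properties(ep.mol, backend=backend)
                nov = novelty_score(ep.mol, fp_index)
                objs.append(objective_vector(rec, nov))
                valid.append(True)
                novelties.append(nov)
                continue
            except ValueError:
                ep.valid = False
        objs.append(np.array([0.0, -10.0, 0.0]))
        valid.append(False)
        novelties.append(0.0)
    for mol in corpus_mols:
        rec = score_properties(mol, backend=backend)
        nov = novelty_score(mol, fp_index)
        objs.append(objective_vector(rec, nov))
        valid.append(True)
        novelties.append(nov)
    return np.array(objs), np.array(valid), np.array(novelties)


def _ppo_update(state: TrainState, fresh: list, buffer_eps: list,
                cfg: RLConfig, phase: CurriculumPhase) -> dict:
    """K epochs of clipped-surrogate updates over the episode steps."""
    steps_fresh = [(ep, s) for ep in fresh for s in ep.steps]
    steps_buf = [(ep, s) for ep in buffer_eps for s in ep.steps]
    if not steps_fresh:
        return {"ppo_loss": 0.0, "surrogate": 0.0, "value_loss": 0.0}

    # GAE per fresh episode from the current critic (detached features)
    adv_list, ret_list = [], []
    for ep in fresh:
        feats = np.stack([s.features for s in ep.steps])
        values = mlp(state.params["value"], feats)[:, 0]
        rewards = np.zeros(len(ep.steps))
        rewards[-1] = ep.terminal_reward
        adv = gae_advantages(rewards, values, cfg)
        adv_list.append(adv)
        ret_list.append(adv + values)
    advantages = normalize_advantages(np.concatenate(adv_list))
    returns_fresh = np.concatenate(ret_list)
    # buffer returns: discounted terminal reward
    ret_buf = np.concatenate([
        np.array([cfg.gamma ** (len(ep.steps) - 1 - i) * ep.terminal_reward
                  for i in range(len(ep.steps))])
        for ep in buffer_eps]) if steps_buf else np.zeros(0)

    all_feats = np.stack([s.features for _, s in steps_fresh + steps_buf])
    logp_old = np.array([s.logp_old for _, s in steps_fresh + steps_buf])
    returns = np.concatenate([returns_fresh, ret_buf])
    adv_all = np.concatenate([advantages, np.zeros(len(steps_buf))])
    is_buffer = np.array([False] * len(steps_fresh) + [True] * len(steps_buf))
    entropy = gaussian_entropy(steps_fresh[0][1].action.size)

    # importance weights for buffer samples, computed outside the autograd tape
    if steps_buf:
        lp_now = np.array([
            float(gaussian_logp(s.action, np.array(state.denoiser.forward(
                state.params, s.coords, s.onehot, s.t / state.sched.T)[0])))
            for _, s in steps_buf])
        is_w = np.clip(np.exp(lp_now - logp_old[len(steps_fresh):]),
                       cfg.is_clip_range[0], cfg.is_clip_range[1])
    else:
        is_w = np.zeros(0)
    is_weights = np.concatenate([np.ones(len(steps_fresh)), is_w])

    def loss_fn(params):
        lps = [gaussian_logp(s.action,
                             state.denoiser.forward(params, s.coords, s.onehot,
                                                    s.t / state.sched.T)[0])
               for _, s in steps_fresh]
        logp_new = anp.concatenate([anp.stack(lps),
                                    logp_old[len(steps_fresh):]])  # buffer: masked out
        values = mlp(params["value"], all_feats)[:, 0]
        total, _ = ppo_loss(logp_new, logp_old, adv_all, values, returns,
                            entropy, cfg, is_buffer, is_weights)
        return total

    gfun = agrad(loss_fn)
    last = 0.0
    for _ in range(cfg.ppo_epochs):
        g = gfun(state.params)
        state.opt_rl.lr = state.lr_rl
        state.params = state.opt_rl.step(state.params, g)
        last = float(loss_fn(state.params))
    if not np.isfinite(last):
        raise RuntimeError(f"non-finite PPO loss: {last}; advantages={advantages}")
    return {"ppo_loss": last}


def diffusion_loss_on_mols(params, denoiser: EquivariantDenoiser,
                           sched: DiffusionSchedule, graphs: list,
                           ts: list, epses: list,
                           weights: LossWeights = LossWeights()):
    """Composite diffusion loss on clean molecule graphs at given (t, ε) draws."""
    total = 0.0
    for graph, t, eps in zip(graphs, ts, epses):
        x0 = graph.coords
        xt = np.sqrt(sched.alpha_bars[t]) * x0 + np.sqrt(1 - sched.alpha_bars[t]) * eps
        onehot = np.eye(len(ATOM_TYPES))[[ATOM_TYPES.index(a) for a in graph.atom_types]]
        eps_hat, _, bond_probs, _ = denoiser.forward(params, xt, onehot, t / sched.T)
        l_d = denoise_loss(eps, eps_hat)
        l_b = bond_loss(bond_probs, x0, DEFAULT_VALENCE_TABLE.bond_threshold)
        l_v = valence_loss(bond_probs, graph.atom_types)
        total = total + composite_loss(l_d, l_b, l_v, weights)
    return total / max(len(graphs), 1)


def _diffusion_update(state: TrainState, mols: list, cfg: RLConfig) -> float:
    if not mols:
        return 0.0
    graphs = [MoleculeGraph.from_rdkit(m) for m in mols]
    ts = [int(state.rng.integers(1, state.sched.T + 1)) for _ in graphs]
    epses = [state.rng.standard_normal(g.coords.shape) for g in graphs]

    def loss_fn(params):
        return diffusion_loss_on_mols(params, state.denoiser, state.sched,
                                      graphs, ts, epses)

    g = agrad(loss_fn)(state.params)
    state.opt_diff.lr = state.lr_diffusion
    state.params = state.opt_diff.step(state.params, g)
    val = float(loss_fn(state.params))
    if not np.isfinite(val):
        raise RuntimeError("non-finite diffusion loss")
    return val


def train_epoch(state: TrainState, epoch: int, cfg: RLConfig,
                batch_size: int = 12, n_atoms_range=(5, 9),
                rollout_steps: int = 5, iterations: int = 1,
                property_backend: str = "surrogate") -> tuple:
    """One curriculum-aware training epoch; returns (state, epoch log).

    Per iteration: compose the 70/20/10 batch, roll out fresh molecules by
    stochastic DDIM under the Gaussian policy, evaluate objectives, assign
    phase-dependent Pareto rewards, run K PPO epochs, update the replay buffer,
    and take a diffusion step on the training-data share. The learning rates
    halve when the epoch crosses a phase boundary.
    """
    phase = curriculum_phase(epoch)
    if phase.phase != state.last_phase:
        state.lr_rl *= 0.5
        state.lr_diffusion *= 0.5
        state.last_phase = phase.phase
    log = {"epoch": epoch, "phase": phase.phase, "lr_rl": state.lr_rl,
           "lr_diffusion": state.lr_diffusion}
    reward_means, counts = [], None
    for _ in range(iterations):
        n_new, n_buf, n_train = morl.compose_counts(batch_size, cfg.batch_mix)
        fresh = [policy_rollout(state.denoiser, state.params, state.sched,
                                int(state.rng.integers(*n_atoms_range)),
                                rollout_steps, state.rng)
                 for _ in range(n_new + max(0, n_buf - len(state.buffer)))]
        comp = compose_batch(fresh, state.buffer, state.corpus, batch_size,
                             cfg, state.rng)
        counts = comp["counts"]
        buffer_eps = [e.trajectory for e in comp["buffer"] if e.trajectory is not None]
        objs, valid, novelties = _episode_objectives(
            comp["new"], comp["train"], state.fp_index, property_backend)
        result = assign_rewards(objs, cfg, phase, valid)
        for i, ep in enumerate(comp["new"]):
            ep.terminal_reward = float(result.rewards[i])
        ppo_log = _ppo_update(state, comp["new"], buffer_eps, cfg, phase)
        buffer_update(state.buffer, [ep.mol for ep in comp["new"]],
                      morl.ParetoResult(ranks=result.ranks[:len(comp["new"])],
                                        crowding=result.crowding[:len(comp["new"])],
                                        rewards=result.rewards[:len(comp["new"])]),
                      novelties[:len(comp["new"])],
                      [ep.steps[0].logp_old for ep in comp["new"]],
                      epoch, trajectories=comp["new"])
        diff_loss = _diffusion_update(state, comp["train"], cfg)
        reward_means.append(float(result.rewards.mean()))
        front_size = int((result.ranks == 1).sum())
        log.update(ppo_log)
        log.update({"diffusion_loss": diff_loss, "front_size": front_size})
    log.update({
        "batch_counts": list(counts) if counts else [],
        "reward_mean": float(np.mean(reward_means)) if reward_means else 0.0,
        "reward_max": float(np.max([r for r in reward_means])) if reward_means else 0.0,
        "buffer_size": len(state.buffer),
    })
    state.epoch = epoch
    return state, log


def smoke_diffusion_training(corpus: list, n_steps: int = 200, seed: int = 0,
                             hidden: int = 16, n_layers: int = 2,
                             T: int = 40, lr: float = 5e-3) -> list:
    """Seeded pure-diffusion training run on a fixture corpus; returns the loss trace.

    Used to demonstrate that the composite loss decreases (moving average) —
    the desk-scale counterpart of the full training curve.
    """
    rng = np.random.default_rng(seed)
    sched = cosine_beta_schedule(T, ddim_steps=min(10, T))
    from .conditioning import ConditioningConfig
    cfg = DenoiserConfig(n_layers=n_layers, hidden=hidden,
                         conditioning=ConditioningConfig(
                             conditioned_gnn_layers=(n_layers,), model_dim=hidden * 2,
                             heads=2, transformer_layers=1))
    denoiser = EquivariantDenoiser(cfg)
    params = denoiser.init_params(rng)
    opt = Adam(params, lr, grad_clip=1.0)
    graphs = [MoleculeGraph.from_rdkit(m) for m in corpus]
    losses = []
    for step in range(n_steps):
        idx = int(rng.integers(len(graphs)))
        g = graphs[idx]
        t = int(rng.integers(1, T + 1))
        eps = rng.standard_normal(g.coords.shape)

        def loss_fn(p):
            return diffusion_loss_on_mols(p, denoiser, sched, [g], [t], [eps])

        grads = agrad(loss_fn)(params)
        params = opt.step(params, grads)
        losses.append(float(loss_fn(params)))
        if not np.isfinite(losses[-1]):
            raise RuntimeError(f"non-finite loss at step {step}")
    return losses
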