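"""Pareto-based multi-objective RL: NSGA-II sorting, rewards, PPO, replay, curriculum.

Molecules in a batch are scored on the objective vector (QED, −SA, Novelty),
partitioned into successive Pareto fronts by non-dominated sorting, and given a
rank-based reward R_rank = 1 − (r − 1)/(N − 1) plus, in the final curriculum
phase, a crowding-distance diversity bonus α·CD/max(CD) with α = 0.1. Policy
updates use PPO with a clipped surrogate (ε = 0.2), generalized advantage
estimation (γ = 0.99, λ = 0.95), and a prioritized replay buffer (capacity
10 000, priority (1/rank)·novelty, sampling exponent 0.6) whose samples feed
only the value function, weighted by importance ratios clipped to [0.5, 2.0].
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import autograd.numpy as anp
import numpy as np

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RLConfig:
    """PPO and replay hyperparameters (the printed training configuration)."""

    clip_epsilon: float = 0.2
    value_coef: float = 0.5
    entropy_coef: float = 0.01
    ppo_epochs: int = 4
    minibatch: int = 64
    gae_lambda: float = 0.95
    gamma: float = 0.99
    lr_rl: float = 1e-4
    lr_diffusion: float = 5e-4
    grad_clip: float = 0.5
    buffer_capacity: int = 10_000
    priority_exponent: float = 0.6
    diversity_alpha: float = 0.1
    batch_mix: tuple = (0.70, 0.20, 0.10)  # new / buffer / training data
    is_clip_range: tuple = (0.5, 2.0)
    grad_accumulation: int = 4

    def __post_init__(self):
        if abs(sum(self.batch_mix) - 1.0) > 1e-9:
            raise ValueError("batch_mix must sum to 1")
        for name in ("clip_epsilon", "value_coef", "entropy_coef", "gae_lambda",
                     "gamma", "lr_rl", "lr_diffusion", "grad_clip",
                     "priority_exponent", "diversity_alpha"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class ParetoResult:
    """Per-molecule Pareto rank (1 = non-dominated), crowding distance, reward."""

    ranks: np.ndarray
    crowding: np.ndarray
    rewards: np.ndarray


# ---------------------------------------------------------------------------
# Non-dominated sorting and crowding distance
# ---------------------------------------------------------------------------

def _dominance_mask(points: np.ndarray, chunk: int = 512) -> np.ndarray:
    """Boolean mask of points not dominated by any other (maximization).

    Chunked over rows so 10k-point clouds stay within memory.
    """
    n = points.shape[0]
    nondom = np.ones(n, dtype=bool)
    for start in range(0, n, chunk):
        block = points[start:start + chunk]
        ge = (points[None, :, :] >= block[:, None, :]).all(axis=2)
        gt = (points[None, :, :] > block[:, None, :]).any(axis=2)
        dominated = (ge & gt).any(axis=1)
        nondom[start:start + chunk] = ~dominated
    return nondom


def pareto_front_mask(points: np.ndarray) -> np.ndarray:
    """Mask of the rank-1 (non-dominated) set of a point cloud."""
    points = np.asarray(points, dtype=float)
    if points.ndim != 2 or points.shape[0] == 0:
        raise ValueError("points must be a non-empty 2-D array")
    return _dominance_mask(points)


def non_dominated_sort(points) -> np.ndarray:
    """NSGA-II front ranks (1-based) in maximization orientation.

    Implemented by iterative peeling with a vectorised dominance test: rank-1
    is the non-dominated set; stripping it yields rank-2, and so on. Equal
    points never dominate each other and therefore share a front.
    """
    points = np.asarray(points, dtype=float)
    if points.ndim != 2 or points.shape[0] == 0:
        raise ValueError("points must be a non-empty 2-D array")
    n = points.shape[0]
    ranks = np.zeros(n, dtype=int)
    remaining = np.arange(n)
    rank = 1
    while remaining.size:
        mask = _dominance_mask(points[remaining])
        ranks[remaining[mask]] = rank
        remaining = remaining[~mask]
        rank += 1
    return ranks


def crowding_distance(front) -> np.ndarray:
    """NSGA-II crowding distance over one front, with bounded boundary values.

    Per objective, interior points accumulate the normalized gap between their
    sorted neighbours. Boundary points — infinite in stock NSGA-II — are
    assigned twice the maximum finite interior distance so the normalized
    diversity bonus CD/max(CD) stays bounded; fronts of size ≤ 2 get uniform
    distance 1.
    """
    front = np.asarray(front, dtype=float)
    n, m = front.shape
    if n <= 2:
        return np.ones(n)
    dist = np.zeros(n)
    boundary = np.zeros(n, dtype=bool)
    any_span = False
    for j in range(m):
        order = np.argsort(front[:, j], kind="stable")
        span = front[order[-1], j] - front[order[0], j]
        if span <= 0:
            continue  # a constant objective carries no density information
        any_span = True
        boundary[order[0]] = boundary[order[-1]] = True
        gaps = (front[order[2:], j] - front[order[:-2], j]) / span
        dist[order[1:-1]] += gaps
    if not any_span:
        return np.ones(n)  # all points coincide in objective space
    interior = dist[~boundary]
    cap = 2.0 * interior.max() if interior.size and interior.max() > 0 else 1.0
    dist[boundary] = cap
    return dist


def assign_rewards(objectives, cfg: RLConfig, phase: "CurriculumPhase",
                   valid: np.ndarray | None = None) -> ParetoResult:
    """Phase-dependent Pareto rewards for a batch of objective vectors.

    Phase 1 rewards QED directly (single objective, no ranking); phases 2–3 use
    the rank reward 1 − (r−1)/(N−1); phase 3 adds the normalized crowding bonus
    α·CD/max(CD). Invalid molecules always receive reward 0. A singleton batch
    has reward 1 by convention.
    """
    objectives = np.asarray(objectives, dtype=float)
    n = objectives.shape[0]
    if n == 0:
        raise ValueError("empty batch")
    if valid is None:
        valid = np.ones(n, dtype=bool)
    ranks = non_dominated_sort(objectives)
    crowding = np.zeros(n)
    for r in np.unique(ranks):
        idx = np.where(ranks == r)[0]
        crowding[idx] = crowding_distance(objectives[idx])
    if phase.phase == 1:
        rewards = np.clip(objectives[:, 0], 0.0, 1.0)  # QED slot
    elif n == 1:
        rewards = np.ones(1)
    else:
        rewards = 1.0 - (ranks - 1) / (n - 1)
    if phase.diversity_bonus and n > 1:
        cd_max = crowding.max()
        if cd_max > 0:
            rewards = rewards + cfg.diversity_alpha * crowding / cd_max
    rewards = np.where(valid, rewards, 0.0)
    return ParetoResult(ranks=ranks, crowding=crowding, rewards=rewards)


# ---------------------------------------------------------------------------
# Advantage estimation and the PPO objective
# ---------------------------------------------------------------------------

def gae_advantages(rewards, values, cfg: RLConfig = RLConfig()) -> np.ndarray:
    """Backward-recursion GAE: A_t = δ_t + γλ·A_{t+1}, δ_t = r_t + γV_{t+1} − V_t.

    The terminal value is 0 (episodes end when the molecule is decoded).
    """
    rewards = np.asarray(rewards, dtype=float)
    values = np.asarray(values, dtype=float)
    if rewards.shape != values.shape:
        raise ValueError("rewards and values must align")
    T = rewards.shape[0]
    adv = np.zeros(T)
    next_value = 0.0
    next_adv = 0.0
    for t in range(T - 1, -1, -1):
        delta = rewards[t] + cfg.gamma * next_value - values[t]
        next_adv = delta + cfg.gamma * cfg.gae_lambda * next_adv
        adv[t] = next_adv
        next_value = values[t]
    return adv


def ppo_loss(logp_new, logp_old, advantages, values, returns, entropy,
             cfg: RLConfig = RLConfig(), is_buffer=None, is_weights=None):
    """Clipped PPO objective with buffer samples feeding only the value loss.

    Returns (total, components). The surrogate L_CLIP = E[min(r·A, clip(r)·A)]
    is averaged over fresh samples only; the value loss (coef 0.5) runs over
    all samples, with buffer samples weighted by importance ratios clipped to
    [0.5, 2.0]; the entropy bonus (coef 0.01) encourages exploration. The total
    is a minimization objective: −surrogate + c_v·L_V − c_H·H.
    """
    n = len(advantages)
    if is_buffer is None:
        is_buffer = np.zeros(n, dtype=bool)
    is_buffer = np.asarray(is_buffer, dtype=bool)
    fresh = ~is_buffer
    ratio = anp.exp(logp_new - logp_old)
    lo, hi = 1.0 - cfg.clip_epsilon, 1.0 + cfg.clip_epsilon
    surr = anp.minimum(ratio * advantages, anp.clip(ratio, lo, hi) * advantages)
    surrogate = anp.sum(surr * fresh) / max(fresh.sum(), 1)
    if is_weights is None:
        is_weights = anp.clip(ratio, cfg.is_clip_range[0], cfg.is_clip_range[1])
    weights = anp.where(fresh, 1.0, is_weights)
    value_loss = anp.sum(weights * (values - returns) ** 2) / n
    entropy_mean = anp.mean(entropy)
    total = -surrogate + cfg.value_coef * value_loss - cfg.entropy_coef * entropy_mean
    components = {"surrogate": surrogate, "value_loss": value_loss,
                  "entropy": entropy_mean}
    return total, components


def normalize_advantages(adv: np.ndarray) -> np.ndarray:
    """Per-minibatch advantage normalization (documented choice)."""
    adv = np.asarray(adv, dtype=float)
    sd = adv.std()
    return (adv - adv.mean()) / (sd + 1e-8)


# ---------------------------------------------------------------------------
# Prioritized replay buffer
# ---------------------------------------------------------------------------

@dataclass
class BufferEntry:
    """One stored rollout: molecule, objectives, priority, behaviour log-prob."""

    molecule: object
    objectives: np.ndarray
    priority: float
    logp_old: float
    epoch: int
    trajectory: object = None
    _index: int = 0  # insertion order; stable tie-break for eviction


class ReplayBuffer:
    """Priority replay with capacity eviction of the lowest-priority entry."""

    def __init__(self, capacity: int = 10_000):
        self.capacity = capacity
        self.entries: list = []
        self._counter = 0

    def __len__(self) -> int:
        return len(self.entries)

    def add(self, entry: BufferEntry) -> None:
        if entry.priority <= 0:
            raise ValueError("priorities must be positive")
        entry._index = self._counter
        self._counter += 1
        self.entries.append(entry)
        if len(self.entries) > self.capacity:
            # evict the minimum-priority entry; ties broken by insertion order
            victim = min(range(len(self.entries)),
                         key=lambda i: (self.entries[i].priority, self.entries[i]._index))
            self.entries.pop(victim)

    def sample(self, k: int, rng: np.random.Generator,
               exponent: float = 0.6) -> list:
        """Sample without replacement with probability ∝ priority^exponent."""
        if not self.entries:
            raise ValueError("cannot sample from an empty buffer")
        if k > len(self.entries):
            logger.warning("requested %d > buffer size %d; returning all", k, len(self.entries))
            return list(self.entries)
        p = np.array([e.priority for e in self.entries]) ** exponent
        p = p / p.sum()
        idx = rng.choice(len(self.entries), size=k, replace=False, p=p)
        return [self.entries[i] for i in idx]


def buffer_priority(rank: int, novelty: float) -> float:
    """Priority(m) = (1/rank) × novelty, favouring novel frontier molecules."""
    return novelty / rank


def buffer_update(buffer: ReplayBuffer, molecules, result: ParetoResult,
                  novelties, logp_olds, epoch: int, trajectories=None) -> ReplayBuffer:
    """Insert a scored batch into the replay buffer with (1/rank)·novelty priority."""
    trajectories = trajectories or [None] * len(molecules)
    objectives = getattr(result, "objectives", None)
    for i, mol in enumerate(molecules):
        pr = buffer_priority(int(result.ranks[i]), float(novelties[i]))
        if pr <= 0:
            continue  # zero-novelty memorised molecules never enter the buffer
        buffer.add(BufferEntry(molecule=mol,
                               objectives=None if objectives is None else objectives[i],
                               priority=pr, logp_old=float(logp_olds[i]),
                               epoch=epoch, trajectory=trajectories[i]))
    return buffer


# ---------------------------------------------------------------------------
# Batch composition and curriculum
# ---------------------------------------------------------------------------

def compose_counts(batch_size: int, mix=(0.70, 0.20, 0.10)) -> tuple:
    """(new, buffer, train) counts: rounded shares for the policy and buffer
    pools, with the training-data share taking the residual.

    Reproduces the stated compositions (90, 26, 12) at 128 and (7, 2, 1) at 10.
    """
    if batch_size < 1:
        raise ValueError("batch_size must be >= 1")
    new = int(np.floor(mix[0] * batch_size + 0.5))
    buf = int(np.floor(mix[1] * batch_size + 0.5))
    new = min(new, batch_size)
    buf = min(buf, batch_size - new)
    return new, buf, batch_size - new - buf


def compose_batch(policy_samples: list, buffer: ReplayBuffer, train_corpus: list,
                  batch_size: int, cfg: RLConfig, rng: np.random.Generator) -> dict:
    """Mix 70% new / 20% buffer / 10% training data, backfilling shortfalls with
    new samples (logged). Returns the three sub-lists plus the realised counts."""
    n_new, n_buf, n_train = compose_counts(batch_size, cfg.batch_mix)
    buf_entries = (buffer.sample(min(n_buf, len(buffer)), rng, cfg.priority_exponent)
                   if len(buffer) and n_buf else [])
    shortfall_buf = n_buf - len(buf_entries)
    n_train_avail = min(n_train, len(train_corpus))
    train = ([train_corpus[i] for i in
              rng.choice(len(train_corpus), size=n_train_avail, replace=False)]
             if n_train_avail else [])
    shortfall = shortfall_buf + (n_train - len(train))
    if shortfall:
        logger.info("compose_batch: backfilling %d slots with new samples", shortfall)
    n_new_total = n_new + shortfall
    new = policy_samples[:n_new_total]
    return {"new": new, "buffer": buf_entries, "train": train,
            "counts": (len(new), len(buf_entries), len(train))}


@dataclass(frozen=True)
class CurriculumPhase:
    """One stage of the three-phase curriculum."""

    phase: int
    epoch_range: tuple
    objectives: tuple
    pareto_ranking: bool
    diversity_bonus: bool
    lr_multiplier: float


_PHASES = (
    CurriculumPhase(1, (1, 20), ("qed",), False, False, 1.0),
    CurriculumPhase(2, (21, 50), ("qed", "sa", "novelty"), True, False, 0.5),
    CurriculumPhase(3, (51, None), ("qed", "sa", "novelty"), True, True, 0.5),
)


def __getattr__(name):
    # the epoch-level training loop lives in paretodiff.training (it pulls in
    # the diffusion and objectives stacks); exposed here as part of the RL API
    if name in ("train_epoch", "TrainState", "init_train_state"):
        from . import training
        return getattr(training, name)
    raise AttributeError(f"module {__name__!r} has no attribute {name!r}")


def curriculum_phase(epoch: int) -> CurriculumPhase:
    """Phase 1 = epochs 1–20 (QED only), 2 = 21–50 (+SA, novelty, Pareto
    ranking), 3 = 51+ (+diversity bonus). LR multiplier 0.5 applies at entry
    into phases 2 and 3."""
    if epoch < 1:
        raise ValueError("epoch must be >= 1")
    for ph in _PHASES:
        lo, hi = ph.epoch_range
        if epoch >= lo and (hi is None or epoch <= hi):
            return ph
    raise AssertionError("unreachable")
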