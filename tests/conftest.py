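import numpy as np
import pytest

from paretodiff.conditioning import ConditioningConfig
from paretodiff.diffusion import DenoiserConfig, EquivariantDenoiser
from paretodiff.fixtures import gen_toy_molecules


@pytest.fixture(scope="session")
def toy_corpus():
    """Small deterministic molecule corpus with 3D coordinates."""
    return gen_toy_molecules(12, seed=1234)


@pytest.fixture(scope="session")
def toy_corpus_flat():
    """Larger corpus without coordinates (fast; for metric tests)."""
    return gen_toy_molecules(30, seed=77, with_coords=False)


@pytest.fixture(scope="session")
def small_denoiser():
    """A desk-scale equivariant denoiser with initialized parameters."""
    cfg = DenoiserConfig(
        n_layers=3, hidden=16,
        conditioning=ConditioningConfig(conditioned_gnn_layers=(3,),
                                        model_dim=32, heads=2,
                                        transformer_layers=1))
    den = EquivariantDenoiser(cfg)
    params = den.init_params(np.random.default_rng(99))
    return den, params


def brute_force_ranks(points: np.ndarray) -> np.ndarray:
    """Independent O(N²·M) dominance oracle: repeated peeling with explicit
    pairwise dominance checks (maximization orientation)."""
    points = np.asarray(points, dtype=float)
    n = points.shape[0]
    dominated_by = np.zeros((n, n), dtype=bool)
    for i in range(n):
        ge = (points >= points[i]).all(axis=1)
        gt = (points > points[i]).any(axis=1)
        dominated_by[i] = ge & gt  # j dominates i
    ranks = np.zeros(n, dtype=int)
    alive = np.ones(n, dtype=bool)
    rank = 1
    while alive.any():
        front = alive & ~(dominated_by[:, alive].any(axis=1))
        ranks[front] = rank
        alive &= ~front
        rank += 1
    return ranks
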