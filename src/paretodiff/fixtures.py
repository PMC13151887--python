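"""Deterministic desk-scale input generators.

Three generators stand in for the corpora and trained models the full-scale
system would consume: small valid molecules with 3D coordinates (a stand-in
for drug-like SMILES corpora), objective-vector clouds with an exactly known
Pareto frontier (a harness for the sorting/efficiency machinery), and
closed-form fronts with analytic hypervolume (an oracle for the hypervolume
sweep). Every generator is a pure function of its arguments and seed.
"""

from __future__ import annotations

import numpy as np
from rdkit import Chem
from rdkit.Chem import AllChem

from .molgraph import check_validity

#: Ring cores and small functional templates over {C, N, O, F, S, Cl}; chosen
#: for guaranteed sanitisation and 5–15 heavy-atom products after decoration.
_RING_CORES = ("C1CCCCC1", "c1ccccc1", "C1CCCC1", "c1ccncc1", "c1ccsc1",
               "c1ccoc1", "C1CCOCC1", "C1CCNCC1")
_CHAIN_CORES = ("CCC", "CCCC", "CCOCC", "CCNCC", "CC(C)C", "CCSC")
_SUBSTITUENTS = ("C", "CC", "O", "OC", "N", "NC", "F", "Cl", "C=O", "C(=O)O",
                 "CO", "CN", "S", "C#N")


def _decorate(core_smiles: str, rng: np.random.Generator, n_subs: int) -> Chem.Mol | None:
    """Attach substituents to random open-valence heavy atoms of a core."""
    mol = Chem.RWMol(Chem.MolFromSmiles(core_smiles))
    for _ in range(n_subs):
        Chem.SanitizeMol(mol)
        open_atoms = [a.GetIdx() for a in mol.GetAtoms() if a.GetTotalNumHs() > 0]
        if not open_atoms:
            break
        anchor = int(rng.choice(open_atoms))
        sub = Chem.MolFromSmiles(_SUBSTITUENTS[rng.integers(len(_SUBSTITUENTS))])
        amap = {}
        for atom in sub.GetAtoms():
            amap[atom.GetIdx()] = mol.AddAtom(Chem.Atom(atom.GetSymbol()))
        for bond in sub.GetBonds():
            mol.AddBond(amap[bond.GetBeginAtomIdx()], amap[bond.GetEndAtomIdx()],
                        bond.GetBondType())
        mol.AddBond(anchor, amap[0], Chem.BondType.SINGLE)
    try:
        out = mol.GetMol()
        Chem.SanitizeMol(out)
        return out
    except Exception:
        return None


def gen_toy_molecules(n: int, seed: int, with_coords: bool = True,
                      max_heavy: int = 15) -> list:
    """n small valid molecules (5–15 heavy atoms) with seeded 3D coordinates.

    Cores (rings or short chains) are decorated with random substituents until
    the heavy-atom budget is met; coordinates come from RDKit's seeded
    distance-geometry embedding plus jitter ≤ 0.05 Å. Deterministic in
    (n, seed): the same call twice yields identical SMILES lists, and every
    output passes :func:`paretodiff.molgraph.check_validity`.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    mols: list = []
    while len(mols) < n:
        use_ring = rng.random() < 0.6
        core = (_RING_CORES[rng.integers(len(_RING_CORES))] if use_ring
                else _CHAIN_CORES[rng.integers(len(_CHAIN_CORES))])
        mol = _decorate(core, rng, n_subs=int(rng.integers(1, 4)))
        if mol is None or not (5 <= mol.GetNumHeavyAtoms() <= max_heavy):
            continue
        if not check_validity(mol).valid:
            continue
        if with_coords:
            mol = Chem.AddHs(mol)
            embed_seed = int(rng.integers(1, 2**31 - 1))
            if AllChem.EmbedMolecule(mol, randomSeed=embed_seed) != 0:
                continue
            AllChem.MMFFOptimizeMolecule(mol, maxIters=50)
            mol = Chem.RemoveHs(mol)
            conf = mol.GetConformer()
            jitter = rng.uniform(-0.05, 0.05, size=(mol.GetNumAtoms(), 3))
            for i in range(mol.GetNumAtoms()):
                p = conf.GetAtomPosition(i)
                conf.SetAtomPosition(i, (p.x + jitter[i, 0], p.y + jitter[i, 1],
                                         p.z + jitter[i, 2]))
        mols.append(mol)
    return mols


def gen_objective_cloud(n_total: int, n_frontier: int, seed: int,
                        simplex_sum: float = 1.5) -> tuple:
    """Objective cloud with an exactly known Pareto frontier.

    Frontier points are distinct points on the simplex x+y+z = c with positive
    coordinates — equal coordinate sums make mutual dominance impossible, so
    all of them are rank-1. Every remaining point is a frontier point scaled by
    a factor in (0, 1), hence strictly dominated by its generator. The frontier
    size is therefore exactly ``n_frontier``. Returns (points, frontier_mask).
    """
    if not 1 <= n_frontier <= n_total:
        raise ValueError("need 1 <= n_frontier <= n_total")
    rng = np.random.default_rng(seed)
    w = rng.dirichlet(np.ones(3), size=n_frontier)
    # keep coordinates strictly positive and points distinct
    w = 0.05 + 0.9 * w
    w = w / w.sum(axis=1, keepdims=True)
    frontier = simplex_sum * w
    n_dom = n_total - n_frontier
    gen_idx = rng.integers(0, n_frontier, size=n_dom)
    factors = rng.uniform(0.05, 0.95, size=n_dom)
    dominated = frontier[gen_idx] * factors[:, None]
    points = np.vstack([frontier, dominated])
    mask = np.zeros(n_total, dtype=bool)
    mask[:n_frontier] = True
    perm = rng.permutation(n_total)
    return points[perm], mask[perm]


def gen_closed_form_front(kind: str, params: dict) -> tuple:
    """(points, analytic hypervolume) for closed-form test fronts, ref = 0.

    kind="box": a single point (a, b, c) with hypervolume a·b·c.
    kind="staircase": the symmetric 2-D k-step staircase with points
    (i/k, (k+1−i)/k), i = 1..k, whose union of boxes has measure (k+1)/(2k)
    (k=2 gives the {(1, 0.5), (0.5, 1)} front with hypervolume 0.75).
    """
    if kind == "box":
        point = np.asarray(params["point"], dtype=float)
        if np.any(point < 0):
            raise ValueError("box corner must be non-negative")
        return point[None, :], float(np.prod(point))
    if kind == "staircase":
        k = int(params["k"])
        if k < 1:
            raise ValueError("k must be >= 1")
        i = np.arange(1, k + 1)
        points = np.column_stack([i / k, (k + 1 - i) / k])
        return points, (k + 1) / (2.0 * k)
    raise ValueError(f"unknown front kind {kind!r}")
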