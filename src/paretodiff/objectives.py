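"""Molecular property scoring and the objective vector f(m) = (QED, −SA, Novelty).

Two property backends are provided. The default "rdkit" backend delegates QED,
logP, descriptors and the Ertl–Schuffenhauer synthetic-accessibility score to
RDKit. The "surrogate" backend is a dependency-light stand-in (exact molecular
weight from atomic masses, additive logP table, ring/branch SA proxy, bounded
QED proxy) used where speed matters more than chemical fidelity (RL smoke
loops, property tests). Both return the same :class:`PropertyRecord` shape.

Per-molecule novelty — the third objective — is 1 minus the maximum Tanimoto
similarity of the molecule's Morgan fingerprint (2048 bits, radius 2) to any
training-set fingerprint. This continuous value is distinct from the batch
novelty metric in :mod:`paretodiff.metrics`, which uses exact canonical-SMILES
set membership.
"""

from __future__ import annotations

import functools
import logging
import os
import sys
from dataclasses import dataclass

import numpy as np
from rdkit import Chem, DataStructs, RDConfig
from rdkit.Chem import Descriptors, QED, rdMolDescriptors
from rdkit.Chem import rdFingerprintGenerator

from .molgraph import check_validity

logger = logging.getLogger(__name__)

#: Fingerprint constants for novelty/similarity everywhere in the package.
FP_BITS = 2048
FP_RADIUS = 2

#: Discrete-property vocabularies (values clamped into these on scoring).
DISCRETE_VOCABS = {
    "ring_count": (0, 6),
    "aromatic_rings": (0, 4),
    "hbd": (0, 5),
    "hba": (0, 10),
}

_ATOMIC_MASS = {
    "H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999,
    "F": 18.998, "S": 32.067, "Cl": 35.453,
}
# Coarse additive logP contributions per heavy atom (surrogate backend only).
_LOGP_CONTRIB = {"C": 0.27, "N": -0.60, "O": -0.55, "F": 0.14, "S": 0.40, "Cl": 0.65}


@dataclass(frozen=True)
class PropertyRecord:
    """Scored molecular properties: continuous (qed, sa, logp, mw) + discrete counts."""

    qed: float
    sa: float
    logp: float
    mw: float
    hbd: int
    hba: int
    ring_count: int
    aromatic_rings: int

    def __post_init__(self):
        for name, value in (("qed", self.qed),):
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name}={value} outside [0, 1]")
        if not 1.0 <= self.sa <= 10.0:
            raise ValueError(f"sa={self.sa} outside [1, 10]")

    def as_dict(self) -> dict:
        return {k: getattr(self, k) for k in
                ("qed", "sa", "logp", "mw", "hbd", "hba", "ring_count", "aromatic_rings")}


def _clamp_discrete(name: str, value: int) -> int:
    lo, hi = DISCRETE_VOCABS[name]
    clamped = int(min(max(value, lo), hi))
    if clamped != value:
        logger.warning("%s=%d outside vocabulary [%d, %d]; clamped", name, value, lo, hi)
    return clamped


@functools.lru_cache(maxsize=1)
def _sascorer():
    sys.path.append(os.path.join(RDConfig.RDContribDir, "SA_Score"))
    import sascorer  # type: ignore

    return sascorer


def _surrogate_counts(mol: Chem.Mol) -> dict:
    counts = {"H": 0}
    for a in mol.GetAtoms():
        counts[a.GetSymbol()] = counts.get(a.GetSymbol(), 0) + 1
        counts["H"] += a.GetTotalNumHs()
    return counts


def _surrogate_record(mol: Chem.Mol) -> PropertyRecord:
    counts = _surrogate_counts(mol)
    mw = sum(_ATOMIC_MASS[s] * n for s, n in counts.items())
    logp = sum(_LOGP_CONTRIB.get(s, 0.0) * n for s, n in counts.items())
    ring_count = rdMolDescriptors.CalcNumRings(mol)
    aromatic_rings = rdMolDescriptors.CalcNumAromaticRings(mol)
    hbd = sum(1 for a in mol.GetAtoms()
              if a.GetSymbol() in ("N", "O") and a.GetTotalNumHs() > 0)
    hba = sum(1 for a in mol.GetAtoms() if a.GetSymbol() in ("N", "O"))
    n_heavy = mol.GetNumHeavyAtoms()
    n_branch = sum(1 for a in mol.GetAtoms() if a.GetDegree() >= 3)
    sa = float(np.clip(1.0 + 0.12 * n_heavy + 0.35 * ring_count + 0.30 * n_branch, 1.0, 10.0))
    # Bounded drug-likeness proxy: product of smooth desirability bumps around
    # MW≈300 Da and logP≈2.5, with soft penalties for donor/acceptor excess.
    d_mw = np.exp(-((mw - 300.0) / 180.0) ** 2)
    d_logp = np.exp(-((logp - 2.5) / 2.5) ** 2)
    d_hbd = 1.0 / (1.0 + max(0, hbd - 5))
    d_hba = 1.0 / (1.0 + max(0, hba - 10))
    qed = float(np.clip((d_mw * d_logp * d_hbd * d_hba) ** 0.5, 0.0, 1.0))
    return PropertyRecord(
        qed=qed, sa=sa, logp=float(logp), mw=float(mw),
        hbd=_clamp_discrete("hbd", hbd), hba=_clamp_discrete("hba", hba),
        ring_count=_clamp_discrete("ring_count", ring_count),
        aromatic_rings=_clamp_discrete("aromatic_rings", aromatic_rings),
    )


def _rdkit_record(mol: Chem.Mol) -> PropertyRecord:
    return PropertyRecord(
        qed=float(QED.qed(mol)),
        sa=float(np.clip(_sascorer().calculateScore(mol), 1.0, 10.0)),
        logp=float(Descriptors.MolLogP(mol)),
        mw=float(Descriptors.MolWt(mol)),
        hbd=_clamp_discrete("hbd", rdMolDescriptors.CalcNumHBD(mol)),
        hba=_clamp_discrete("hba", rdMolDescriptors.CalcNumHBA(mol)),
        ring_count=_clamp_discrete("ring_count", rdMolDescriptors.CalcNumRings(mol)),
        aromatic_rings=_clamp_discrete(
            "aromatic_rings", rdMolDescriptors.CalcNumAromaticRings(mol)),
    )


_BACKENDS = {"rdkit": _rdkit_record, "surrogate": _surrogate_record}


def score_properties(mol, backend: str = "rdkit") -> PropertyRecord:
    """Score a molecule (RDKit mol or SMILES); raises on invalid input."""
    if isinstance(mol, str):
        parsed = Chem.MolFromSmiles(mol)
        if parsed is None:
            raise ValueError(f"invalid molecule: could not parse {mol!r}")
        mol = parsed
    valid, violations = check_validity(mol)
    if not valid:
        raise ValueError(f"invalid molecule: {violations}")
    try:
        fn = _BACKENDS[backend]
    except KeyError:
        raise ValueError(f"unknown property backend {backend!r}") from None
    return fn(mol)


# ---------------------------------------------------------------------------
# Novelty against a training-set fingerprint index
# ---------------------------------------------------------------------------

_fpgen = rdFingerprintGenerator.GetMorganGenerator(radius=FP_RADIUS, fpSize=FP_BITS)


def fingerprint(mol):
    """Morgan fingerprint (radius 2, 2048 bits) of an RDKit mol or SMILES."""
    if isinstance(mol, str):
        mol = Chem.MolFromSmiles(mol)
        if mol is None:
            raise ValueError("could not parse SMILES for fingerprinting")
    return _fpgen.GetFingerprint(mol)


class FingerprintIndex:
    """Training-set fingerprint index for novelty queries."""

    def __init__(self, mols):
        mols = list(mols)
        if not mols:
            raise ValueError("empty training set: cannot build fingerprint index")
        self.smiles = [Chem.MolToSmiles(m) if not isinstance(m, str)
                       else Chem.CanonSmiles(m) for m in mols]
        self.fps = [fingerprint(m) for m in mols]

    def __len__(self) -> int:
        return len(self.fps)

    def max_similarity(self, mol) -> float:
        fp = fingerprint(mol)
        return float(max(DataStructs.BulkTanimotoSimilarity(fp, self.fps)))


def novelty_score(mol, index: FingerprintIndex) -> float:
    """1 − max Tanimoto similarity to the training index; 0 for memorised molecules."""
    return 1.0 - index.max_similarity(mol)


# ---------------------------------------------------------------------------
# Objective vector
# ---------------------------------------------------------------------------

def objective_vector(rec, novelty: float, extra=None) -> np.ndarray:
    """(QED, −SA, Novelty) in maximization orientation — larger is better in every slot.

    ``rec`` is a :class:`PropertyRecord` or any mapping with ``qed`` and ``sa``.
    ``extra`` optionally appends user-supplied objective values (maximization
    orientation) — the open slot for property-specific constraints; the package
    ships no built-in content for it.
    """
    if isinstance(rec, PropertyRecord):
        qed, sa = rec.qed, rec.sa
    else:
        qed, sa = rec["qed"], rec["sa"]
    base = [qed, -sa, novelty]
    if extra is not None:
        base.extend(float(v) for v in extra)
    return np.array(base, dtype=float)
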