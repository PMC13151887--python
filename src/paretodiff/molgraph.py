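"""Molecular graph data model, valence rules, file I/O and scaffold utilities.

Molecules live in two representations here: RDKit ``Mol`` objects for anything
chemical (parsing, sanitisation, scaffolds) and :class:`MoleculeGraph` — the
(X, A, E) tuple the diffusion model operates on — holding Cartesian coordinates,
atom types over the six-element alphabet {C, N, O, F, S, Cl}, an n×n×8 edge
feature tensor and an n×n matrix of predicted bond probabilities.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np
from rdkit import Chem, RDLogger
from rdkit.Chem import BRICS
from rdkit.Chem.Scaffolds import MurckoScaffold

RDLogger.DisableLog("rdApp.*")

logger = logging.getLogger(__name__)

#: Atom alphabet of the generator.
ATOM_TYPES = ("C", "N", "O", "F", "S", "Cl")

#: Edge feature channels: bond-type one-hot (single/double/triple/aromatic),
#: interatomic distance (Å), mean bond-angle cosine, conjugation flag, ring flag.
N_EDGE_CHANNELS = 8

_BOND_ORDER_CHANNEL = {
    Chem.BondType.SINGLE: 0,
    Chem.BondType.DOUBLE: 1,
    Chem.BondType.TRIPLE: 2,
    Chem.BondType.AROMATIC: 3,
}
_BOND_ORDER_VALUE = {0: 1.0, 1: 2.0, 2: 3.0, 3: 1.5}


@dataclass(frozen=True)
class ValenceTable:
    """Maximum heavy-atom valences and the bond distance threshold τ_bond.

    Defaults: C→4, N→3, O→2, F→1, Cl→1 and S→2 (hypervalent sulfur can be
    allowed by passing ``max_valence={"S": 6, ...}``). τ_bond = 1.8 Å is the
    distance below which an atom pair is treated as bonded by the
    bond-consistency loss.
    """

    max_valence: dict = field(
        default_factory=lambda: {"C": 4, "N": 3, "O": 2, "F": 1, "S": 2, "Cl": 1}
    )
    bond_threshold: float = 1.8

    def __post_init__(self):
        if self.bond_threshold <= 0:
            raise ValueError("bond_threshold must be positive")


DEFAULT_VALENCE_TABLE = ValenceTable()


def max_valence(atom_type: str, table: ValenceTable = DEFAULT_VALENCE_TABLE) -> int:
    """Maximum valence for an element symbol, e.g. 4 for carbon, 3 for nitrogen."""
    try:
        return table.max_valence[atom_type]
    except KeyError:
        raise ValueError(
            f"unknown element {atom_type!r}; expected one of {sorted(table.max_valence)}"
        ) from None


@dataclass
class MoleculeGraph:
    """The diffusion state (X, A, E): coordinates, atom types, edge features.

    ``edge_features`` channels 0–3 are the bond-type one-hot, channel 4 the
    pairwise Euclidean distance in Å (filled for *all* pairs, bonded or not,
    because the bond-consistency loss needs d_ij everywhere), channel 5 the mean
    bond-angle cosine over adjacent bond pairs, channels 6/7 conjugation and
    ring-membership flags. ``bond_probs`` is the model's b̂_ij output.
    """

    coords: np.ndarray
    atom_types: list
    edge_features: np.ndarray
    bond_probs: np.ndarray

    @property
    def n(self) -> int:
        return len(self.atom_types)

    def validate(self) -> None:
        """Raise if structural invariants are violated."""
        n = self.n
        if self.coords.shape != (n, 3):
            raise ValueError(f"coords shape {self.coords.shape} != ({n}, 3)")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coords contain non-finite values")
        E = self.edge_features
        if E.shape != (n, n, N_EDGE_CHANNELS):
            raise ValueError(f"edge_features shape {E.shape} != ({n},{n},{N_EDGE_CHANNELS})")
        for ch in (0, 1, 2, 3, 6, 7):
            if not np.allclose(E[:, :, ch], E[:, :, ch].T):
                raise ValueError(f"edge channel {ch} not symmetric")
        if not np.allclose(E[np.arange(n), np.arange(n), :], 0.0):
            raise ValueError("edge feature diagonal not zero")
        B = self.bond_probs
        if B.shape != (n, n) or not np.allclose(B, B.T) or not np.allclose(np.diag(B), 0):
            raise ValueError("bond_probs must be symmetric n×n with zero diagonal")
        if B.min() < 0 or B.max() > 1:
            raise ValueError("bond_probs outside [0, 1]")

    @classmethod
    def from_rdkit(cls, mol: Chem.Mol, center: bool = True) -> "MoleculeGraph":
        """Build a graph from an RDKit mol with a 3D conformer.

        Coordinates are re-centered at the zero center of mass so that the
        translation-invariance assumptions of the denoiser hold on ingestion.
        """
        coords = _conformer_coords(mol)
        if center:
            coords = coords - coords.mean(axis=0, keepdims=True)
        atom_types = [a.GetSymbol() for a in mol.GetAtoms()]
        E = build_edge_features(mol, coords=coords)
        n = len(atom_types)
        probs = np.zeros((n, n))
        for b in mol.GetBonds():
            i, j = b.GetBeginAtomIdx(), b.GetEndAtomIdx()
            probs[i, j] = probs[j, i] = 1.0
        return cls(coords=coords, atom_types=atom_types, edge_features=E, bond_probs=probs)

    def heavy_bond_order_sums(self) -> np.ndarray:
        """Per-atom total bond order from the one-hot channels (aromatic = 1.5)."""
        order = np.zeros((self.n, self.n))
        for ch, val in _BOND_ORDER_VALUE.items():
            order += self.edge_features[:, :, ch] * val
        return order.sum(axis=1)


def _conformer_coords(mol: Chem.Mol) -> np.ndarray:
    if mol.GetNumConformers() == 0:
        raise ValueError("molecule has no conformer (3D coordinates required)")
    conf = mol.GetConformer()
    coords = np.array(
        [[conf.GetAtomPosition(i).x, conf.GetAtomPosition(i).y, conf.GetAtomPosition(i).z]
         for i in range(mol.GetNumAtoms())]
    )
    if not np.all(np.isfinite(coords)):
        bad = int(np.where(~np.isfinite(coords).all(axis=1))[0][0])
        raise ValueError(f"missing/non-finite coordinates for atom {bad}")
    return coords


def build_edge_features(mol: Chem.Mol, coords: np.ndarray | None = None) -> np.ndarray:
    """n×n×8 edge feature tensor for an RDKit mol with coordinates.

    Non-bonded pairs keep an all-zero bond-type one-hot and zero flags but the
    distance channel is still populated with the Euclidean distance — the
    bond-consistency loss needs d_ij for every pair. The bond-angle cosine of a
    bond (i, j) is the mean cosine over all angles the bond forms with other
    bonds incident at i or at j (0 when there are none); this makes channel 5
    symmetric and well-defined for atoms with more than two neighbours.
    """
    if coords is None:
        coords = _conformer_coords(mol)
    n = mol.GetNumAtoms()
    if coords.shape != (n, 3):
        raise ValueError(f"coords shape {coords.shape} incompatible with {n} atoms")
    E = np.zeros((n, n, N_EDGE_CHANNELS))
    diff = coords[:, None, :] - coords[None, :, :]
    dist = np.linalg.norm(diff, axis=-1)
    E[:, :, 4] = dist
    np.fill_diagonal(E[:, :, 4], 0.0)

    ring_info = mol.GetRingInfo()
    for b in mol.GetBonds():
        i, j = b.GetBeginAtomIdx(), b.GetEndAtomIdx()
        ch = _BOND_ORDER_CHANNEL.get(b.GetBondType())
        if ch is None:  # exotic bond order: fall back to single
            ch = 0
        E[i, j, ch] = E[j, i, ch] = 1.0
        E[i, j, 6] = E[j, i, 6] = float(b.GetIsConjugated())
        E[i, j, 7] = E[j, i, 7] = float(ring_info.NumBondRings(b.GetIdx()) > 0)
        E[i, j, 5] = E[j, i, 5] = _mean_angle_cosine(mol, coords, i, j)
    return E


def _mean_angle_cosine(mol: Chem.Mol, coords: np.ndarray, i: int, j: int) -> float:
    """Mean cosine of the angles bond (i,j) forms with adjacent bonds."""
    cosines = []
    for a, b in ((i, j), (j, i)):
        va = coords[b] - coords[a]
        na = np.linalg.norm(va)
        for nb in mol.GetAtomWithIdx(a).GetNeighbors():
            k = nb.GetIdx()
            if k == b:
                continue
            vb = coords[k] - coords[a]
            denom = na * np.linalg.norm(vb)
            if denom > 0:
                cosines.append(float(np.dot(va, vb) / denom))
    return float(np.mean(cosines)) if cosines else 0.0


class ValidityResult(NamedTuple):
    valid: bool
    violations: list


def check_validity(
    mol, table: ValenceTable = DEFAULT_VALENCE_TABLE
) -> ValidityResult:
    """Validity under the heavy-atom valence rule plus RDKit sanitisation.

    Accepts a SMILES string, an RDKit mol or a :class:`MoleculeGraph`. An atom
    is in violation when its total heavy-atom bond order (aromatic counted as
    1.5, rounded down per atom) exceeds the table's maximum valence. Invalid
    input never raises: it yields ``valid=False`` with named reasons.
    """
    violations: list = []
    if isinstance(mol, str):
        parsed = Chem.MolFromSmiles(mol)
        if parsed is None:
            return ValidityResult(False, [f"unparseable: {mol!r}"])
        mol = parsed
    if isinstance(mol, MoleculeGraph):
        sums = mol.heavy_bond_order_sums()
        symbols = mol.atom_types
    else:
        try:
            Chem.SanitizeMol(mol)
        except Exception as exc:  # pragma: no cover - rdkit error text varies
            return ValidityResult(False, [f"sanitization failed: {exc}"])
        n = mol.GetNumAtoms()
        sums = np.zeros(n)
        for b in mol.GetBonds():
            v = b.GetBondTypeAsDouble()
            sums[b.GetBeginAtomIdx()] += v
            sums[b.GetEndAtomIdx()] += v
        symbols = [a.GetSymbol() for a in mol.GetAtoms()]
    for idx, (sym, total) in enumerate(zip(symbols, sums)):
        if sym not in table.max_valence:
            violations.append(f"atom {idx}: unknown element {sym}")
            continue
        # aromatic bonds contribute 1.5; round the per-atom sum down so a
        # benzene carbon (2 aromatic + 1 single = 4.0 -> fine) and a pyridine
        # nitrogen (2 aromatic = 3.0) pass.
        vmax = table.max_valence[sym]
        if np.floor(total + 1e-9) > vmax:
            shown = int(total) if float(total).is_integer() else round(float(total), 2)
            violations.append(f"valence {sym} {shown}>{vmax} (atom {idx})")
    return ValidityResult(len(violations) == 0, violations)


# ---------------------------------------------------------------------------
# File I/O: SMILES line files, SDF V2000, XYZ
# ---------------------------------------------------------------------------

class ReadResult(NamedTuple):
    mols: list
    skipped: int


def read_smiles(path) -> ReadResult:
    """Read a SMILES-lines file (optional tab-separated name), canonicalising.

    Malformed records are skipped with a logged count rather than raising.
    """
    mols, skipped = [], 0
    with open(path, "r", encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            smi = line.split("\t")[0].split()[0]
            m = Chem.MolFromSmiles(smi)
            if m is None:
                skipped += 1
                continue
            mols.append(m)
    if skipped:
        logger.warning("read_smiles(%s): skipped %d malformed records", path, skipped)
    return ReadResult(mols, skipped)


def write_smiles(mols: Sequence, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for m in mols:
            fh.write(Chem.MolToSmiles(m) + "\n")


def read_sdf(path) -> ReadResult:
    supplier = Chem.SDMolSupplier(str(path), removeHs=True)
    mols = [m for m in supplier if m is not None]
    for m in mols:  # stereo assignment is out of scope; keep round-trips stable
        Chem.RemoveStereochemistry(m)
    skipped = len(supplier) - len(mols)
    if skipped:
        logger.warning("read_sdf(%s): skipped %d malformed records", path, skipped)
    return ReadResult(mols, skipped)


def write_sdf(mols: Sequence, path) -> None:
    writer = Chem.SDWriter(str(path))
    try:
        for m in mols:
            writer.write(m)
    finally:
        writer.close()


def read_xyz(path) -> ReadResult:
    """Read (possibly concatenated) XYZ blocks into (symbols, coords) tuples."""
    records, skipped = [], 0
    with open(path, "r", encoding="utf-8") as fh:
        lines = [ln.rstrip("\n") for ln in fh]
    i = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        try:
            n = int(lines[i].strip())
            body = lines[i + 2 : i + 2 + n]
            symbols, coords = [], []
            for ln in body:
                parts = ln.split()
                symbols.append(parts[0])
                coords.append([float(x) for x in parts[1:4]])
            if len(symbols) != n:
                raise ValueError("truncated XYZ block")
            records.append((symbols, np.array(coords)))
            i += 2 + n
        except (ValueError, IndexError):
            skipped += 1
            i += 1
    if skipped:
        logger.warning("read_xyz(%s): skipped %d malformed blocks", path, skipped)
    return ReadResult(records, skipped)


def write_xyz(records: Sequence, path) -> None:
    """Write (symbols, coords) tuples or conformer-bearing RDKit mols as XYZ."""
    with open(path, "w", encoding="utf-8") as fh:
        for rec in records:
            if isinstance(rec, Chem.Mol):
                symbols = [a.GetSymbol() for a in rec.GetAtoms()]
                coords = _conformer_coords(rec)
            else:
                symbols, coords = rec
            fh.write(f"{len(symbols)}\n\n")
            for s, (x, y, z) in zip(symbols, coords):
                fh.write(f"{s} {x:.6f} {y:.6f} {z:.6f}\n")


_READERS = {"smiles": read_smiles, "sdf": read_sdf, "xyz": read_xyz}
_WRITERS = {"smiles": write_smiles, "sdf": write_sdf, "xyz": write_xyz}


def read_molecules(path, fmt: str) -> ReadResult:
    try:
        return _READERS[fmt](path)
    except KeyError:
        raise ValueError(f"unknown format {fmt!r}; expected one of {sorted(_READERS)}") from None


def write_molecules(mols, path, fmt: str) -> None:
    try:
        _WRITERS[fmt](mols, path)
    except KeyError:
        raise ValueError(f"unknown format {fmt!r}; expected one of {sorted(_WRITERS)}") from None


# ---------------------------------------------------------------------------
# Scaffolds and fragments
# ---------------------------------------------------------------------------

def scaffold_and_fragments(mols: Sequence) -> tuple:
    """Bemis–Murcko scaffold multiset and BRICS fragment set for a molecule list.

    Acyclic molecules yield an empty scaffold token '' (counted separately by
    callers interested in ring-bearing scaffolds only). Fragmentation uses
    BRICS bond rules; fragments are canonical SMILES with dummy attachment
    points.
    """
    scaffolds: Counter = Counter()
    fragments: set = set()
    for m in mols:
        core = MurckoScaffold.GetScaffoldForMol(m)
        scaffolds[Chem.MolToSmiles(core) if core.GetNumAtoms() else ""] += 1
        fragments.update(BRICS.BRICSDecompose(m))
    return scaffolds, fragments
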