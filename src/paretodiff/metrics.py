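"""Evaluation metrics for generated molecule sets.

Distribution-learning metrics follow the MOSES conventions: validity is the
parseable/valence-sane fraction, uniqueness the distinct canonical fraction
among valid molecules, and (batch) novelty the fraction of unique valid
molecules absent from the training set — note this exact set-membership
novelty is deliberately distinct from the continuous per-molecule novelty
objective in :mod:`paretodiff.objectives`. Similarity metrics (SNN, IntDiv)
and an FCD-style Fréchet distance over pluggable descriptor vectors cover
sample quality; multi-objective metrics (Pareto efficiency, all-criteria rate,
desirability, hypervolume) cover frontier quality.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import scipy.linalg
from rdkit import Chem, DataStructs
from scipy import stats

from . import morl
from .molgraph import check_validity
from .objectives import fingerprint

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class CriteriaThresholds:
    """Minimum per-molecule thresholds: QED ≥ 0.70, SA ≤ 3.5, Novelty ≥ 0.90."""

    qed_min: float = 0.70
    sa_max: float = 3.5
    novelty_min: float = 0.90


def _canonical_or_none(smi: str):
    m = Chem.MolFromSmiles(smi)
    if m is None:
        return None
    if not check_validity(m).valid:
        return None
    return Chem.MolToSmiles(m)


def distribution_metrics(generated, training) -> tuple:
    """(validity, uniqueness, novelty) of generated SMILES vs a training set."""
    generated = list(generated)
    if not generated:
        raise ValueError("empty generated list")
    canon = [_canonical_or_none(s) for s in generated]
    valid = [c for c in canon if c is not None]
    validity = len(valid) / len(generated)
    if not valid:
        return validity, 0.0, 0.0
    unique = set(valid)
    uniqueness = len(unique) / len(valid)
    train_set = {Chem.CanonSmiles(s) for s in training if Chem.MolFromSmiles(s)}
    novel = [s for s in unique if s not in train_set]
    novelty = len(novel) / len(unique)
    return validity, uniqueness, novelty


def similarity_metrics(generated, reference) -> tuple:
    """(IntDiv, SNN) from Morgan fingerprints.

    IntDiv = 1 − mean pairwise Tanimoto within the generated set (0 with a
    warning for singletons); SNN = mean over generated of the maximum Tanimoto
    to the reference set.
    """
    gen_fps = [fingerprint(m) for m in generated]
    ref_fps = [fingerprint(m) for m in reference]
    if len(gen_fps) < 2:
        logger.warning("IntDiv undefined for a singleton set; reporting 0")
        int_div = 0.0
    else:
        sims = [DataStructs.TanimotoSimilarity(a, b)
                for a, b in itertools.combinations(gen_fps, 2)]
        int_div = 1.0 - float(np.mean(sims))
    snn = float(np.mean([max(DataStructs.BulkTanimotoSimilarity(fp, ref_fps))
                         for fp in gen_fps]))
    return int_div, snn


def frechet_distance(desc_a: np.ndarray, desc_b: np.ndarray) -> float:
    """Fréchet distance between Gaussian fits of two descriptor sets.

    ‖μ_a − μ_b‖² + Tr(Σ_a + Σ_b − 2(Σ_a Σ_b)^{1/2}). Generic over descriptors
    ("FCD-style"): the ChemNet embedding the FCD proper uses is an external
    trained network and out of scope here.
    """
    a = np.asarray(desc_a, dtype=float)
    b = np.asarray(desc_b, dtype=float)
    if a.ndim != 2 or b.ndim != 2 or a.shape[1] != b.shape[1]:
        raise ValueError("descriptor sets must be 2-D with matching dimension")
    if a.shape[0] < 2 or b.shape[0] < 2:
        raise ValueError("need at least 2 vectors per set")
    mu_a, mu_b = a.mean(axis=0), b.mean(axis=0)
    cov_a = np.cov(a, rowvar=False)
    cov_b = np.cov(b, rowvar=False)
    cov_a = np.atleast_2d(cov_a)
    cov_b = np.atleast_2d(cov_b)
    sqrt_prod = scipy.linalg.sqrtm(cov_a @ cov_b)
    if np.iscomplexobj(sqrt_prod):
        sqrt_prod = sqrt_prod.real
    d2 = float(np.sum((mu_a - mu_b) ** 2)
               + np.trace(cov_a + cov_b - 2.0 * sqrt_prod))
    return max(d2, 0.0)


def pareto_efficiency(objectives) -> float:
    """Percent of points on the rank-1 Pareto front (maximization orientation)."""
    objectives = np.asarray(objectives, dtype=float)
    if objectives.size == 0:
        raise ValueError("empty objective list")
    mask = morl.pareto_front_mask(objectives)
    return 100.0 * mask.sum() / objectives.shape[0]


def criteria_met(records, th: CriteriaThresholds = CriteriaThresholds()) -> float:
    """Percent of (qed, sa, novelty) records meeting all thresholds (inclusive)."""
    arr = np.asarray(records, dtype=float)
    if arr.size == 0:
        return 0.0
    ok = ((arr[:, 0] >= th.qed_min) & (arr[:, 1] <= th.sa_max)
          & (arr[:, 2] >= th.novelty_min))
    return 100.0 * ok.mean()


def desirability(values) -> float:
    """Geometric mean of objective values normalized to [0, 1].

    Zero whenever any component is zero — poor performance in a single
    objective collapses the score, by design.
    """
    v = np.asarray(values, dtype=float)
    if np.any((v < 0) | (v > 1)):
        raise ValueError("desirability components must lie in [0, 1]")
    if np.any(v == 0):
        return 0.0
    return float(np.exp(np.mean(np.log(v))))


#: Reporting bounds used to map raw (QED, SA, Novelty) onto [0, 1] for
#: desirability: QED and novelty are native [0, 1]; SA maps from [1, 10],
#: inverted so that easier synthesis scores higher.
def normalize_objectives(qed: float, sa: float, novelty: float) -> np.ndarray:
    sa_norm = (10.0 - np.clip(sa, 1.0, 10.0)) / 9.0
    return np.array([np.clip(qed, 0, 1), sa_norm, np.clip(novelty, 0, 1)])


# ---------------------------------------------------------------------------
# Hypervolume
# ---------------------------------------------------------------------------

def _hv2d(points: np.ndarray, ref: np.ndarray) -> float:
    pts = points - ref
    keep = morl.pareto_front_mask(pts)
    pts = pts[keep]
    order = np.argsort(-pts[:, 0], kind="stable")
    pts = pts[order]
    hv, prev_y = 0.0, 0.0
    # sweep in decreasing x; on a front, y increases as x decreases
    for x, y in pts:
        hv += x * max(y - prev_y, 0.0)
        prev_y = max(prev_y, y)
    return hv


def hypervolume(front, ref=(0.0, 0.0, 0.0), rng: np.random.Generator | None = None,
                mc_samples: int = 1_000_000) -> float:
    """Lebesgue measure of the union of boxes [ref, point].

    Exact for ≤ 3 objectives (sweep over z-slices reduces 3-D to 2-D);
    Monte-Carlo above 3 (estimate within ~1% at the default sample count).
    Dominated points contribute nothing. Raises when a point falls below the
    reference in any coordinate.
    """
    pts = np.asarray(front, dtype=float)
    ref = np.asarray(ref, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != ref.shape[0]:
        raise ValueError("front and reference dimensions disagree")
    if np.any(pts < ref - 1e-12):
        raise ValueError("every point must weakly dominate the reference point")
    m = pts.shape[1]
    if m == 1:
        return float((pts[:, 0] - ref[0]).max())
    if m == 2:
        return _hv2d(pts, ref)
    if m == 3:
        # sweep over z-slabs: within (z_{j-1}, z_j] the dominated area in the
        # xy-plane is that of the points reaching at least z_j
        shifted = pts - ref
        hv, z_prev = 0.0, 0.0
        for z in np.unique(shifted[:, 2]):
            if z <= z_prev:
                continue
            active = shifted[shifted[:, 2] >= z - 1e-15][:, :2]
            if active.size:
                hv += _hv2d(active, np.zeros(2)) * (z - z_prev)
            z_prev = z
        return hv
    rng = rng or np.random.default_rng(0)
    upper = pts.max(axis=0)
    vol_box = np.prod(upper - ref)
    if vol_box == 0:
        return 0.0
    samples = rng.uniform(ref, upper, size=(mc_samples, m))
    hit = np.zeros(mc_samples, dtype=bool)
    for p in pts:
        hit |= (samples <= p).all(axis=1)
    return float(vol_box * hit.mean())


def distribution_match(sample_a, sample_b, properties=("qed", "sa", "logp", "mw")) -> dict:
    """Two-sample KS per property plus the Pearson correlation matrix of sample_a.

    ``sample_a``/``sample_b`` are mappings property → 1-D array (or DataFrames).
    Constant columns yield an undefined (NaN) correlation, reported as missing.
    """
    ks = {}
    for p in properties:
        a, b = np.asarray(sample_a[p], dtype=float), np.asarray(sample_b[p], dtype=float)
        if a.size < 2 or b.size < 2:
            raise ValueError(f"need >= 2 observations per property ({p})")
        stat, pval = stats.ks_2samp(a, b)
        ks[p] = {"statistic": float(stat), "pvalue": float(pval)}
    mat = np.column_stack([np.asarray(sample_a[p], dtype=float) for p in properties])
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(mat, rowvar=False)
    return {"ks": ks, "correlation": corr, "properties": list(properties)}


def relative_change(baseline: float, new: float, direction: str = "higher-better",
                    mode: str = "relative") -> float:
    """Percent improvement / absolute delta / fold change between two scores.

    relative: 100·(new − baseline)/baseline, sign flipped for lower-better so
    an improvement is always positive; absolute: new − baseline; fold:
    new/baseline.
    """
    if direction not in ("higher-better", "lower-better"):
        raise ValueError("direction must be 'higher-better' or 'lower-better'")
    if mode == "absolute":
        return new - baseline
    if baseline == 0:
        raise ValueError(f"zero baseline invalid in {mode!r} mode")
    if mode == "fold":
        return new / baseline
    if mode == "relative":
        change = 100.0 * (new - baseline) / baseline
        return -change if direction == "lower-better" else change
    raise ValueError(f"unknown mode {mode!r}")
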