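"""Score molecular properties and build the (QED, −SA, Novelty) objective.

QED is drug-likeness in [0,1] (higher better), SA synthetic accessibility in
[1,10] (lower better, so it enters negated), and novelty is 1 minus the
maximum Tanimoto fingerprint similarity to the training set.
"""

from rdkit import Chem

from paretodiff.fixtures import gen_toy_molecules
from paretodiff.objectives import (FingerprintIndex, novelty_score,
                                   objective_vector, score_properties)

train = gen_toy_molecules(20, seed=7, with_coords=False)
index = FingerprintIndex(train)

probe = Chem.MolFromSmiles("Cc1ccccc1O")  # a cresol not in the corpus
rec = score_properties(probe, backend="rdkit")
print(f"QED={rec.qed:.3f} SA={rec.sa:.2f} logP={rec.logp:.2f} MW={rec.mw:.1f} "
      f"rings={rec.ring_count} HBD={rec.hbd}")

nov = novelty_score(probe, index)
print(f"novelty vs 20-molecule corpus: {nov:.3f} "
      "(1 = fingerprint-disjoint from the corpus, 0 = memorised)")
print("objective vector (maximization orientation):",
      objective_vector(rec, nov).round(3))

member = train[0]
print("novelty of a training member:", novelty_score(member, index))
# A training molecule evaluated against its own index is never novel (0.0).
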