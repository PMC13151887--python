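"""Build a small molecule corpus, inspect graph features, check validity.

Generates deterministic fixture molecules with 3D coordinates, converts one to
the (coordinates, atom types, edge features) graph the diffusion model sees,
and runs the valence-rule validity check and scaffold extraction.
"""

import numpy as np
from rdkit import Chem

from paretodiff.fixtures import gen_toy_molecules
from paretodiff.molgraph import (MoleculeGraph, check_validity, max_valence,
                                 scaffold_and_fragments)

corpus = gen_toy_molecules(10, seed=42)
print("corpus:", [Chem.MolToSmiles(m) for m in corpus[:5]], "...")

graph = MoleculeGraph.from_rdkit(corpus[0])
print(f"first molecule: {graph.n} heavy atoms, centered coords "
      f"(|mean| = {np.abs(graph.coords.mean(axis=0)).max():.2e} Å)")
bonded = graph.edge_features[:, :, :4].sum(axis=-1) > 0
print(f"bonded pairs: {int(bonded.sum() / 2)}; "
      f"mean bond length {graph.edge_features[:, :, 4][bonded].mean():.3f} Å")

print("max valence C/N/O:", [max_valence(s) for s in "CNO"])
valid, violations = check_validity(corpus[0])
print("validity of first molecule:", valid, violations)
bad = check_validity("C1CC")  # unclosed ring literal
print("malformed SMILES ->", bad.valid, bad.violations)

scaffolds, fragments = scaffold_and_fragments(corpus)
ringy = {k: v for k, v in scaffolds.items() if k}
print(f"{len(ringy)} distinct ring scaffolds, {scaffolds.get('', 0)} acyclic, "
      f"{len(fragments)} fragments")
# Scaffolds count Bemis–Murcko ring systems; the empty token counts
# ring-free molecules, which have no scaffold by definition.
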