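"""Generate the four RMSD-gated augmentations of one molecule.

Each augmented variant (atom dropping, random-walk subgraph, functional-group
transform, BRICS fragment removal) is re-embedded in 3D and accepted only if
its MCS-mapped, rigid-body-aligned RMSD to the original stays below 3.0 A —
large enough to vary the structure, small enough to keep the semantics.
"""

from moltext import build_augmentation_set, generate_conformer, parse_smiles
from moltext.molgraph import to_smiles

aspirin = generate_conformer(parse_smiles("CC(=O)Oc1ccccc1C(=O)O"), seed=7)
aset = build_augmentation_set(aspirin, seed=3)

print(f"original: {to_smiles(aspirin)} ({aspirin.atom_count} atoms)")
for kind, res in aset.members.items():
    print(f"  {kind:22s} -> {to_smiles(res.graph):35s} "
          f"RMSD {res.dissimilarity:.2f} A  accepted={res.accepted}")
print("RMSD < 3.0 means the variant stays semantically close to the original.")
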