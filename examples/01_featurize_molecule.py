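"""Parse a molecule, embed it in 3D and inspect its structural attention bias.

The bias matrix is what the molecule encoder adds to every attention layer's
pre-softmax logits: entry (i, j) combines the path-averaged bond features,
the bond-count shortest-path distance and a radial-kernel MLP of the 3D
interatomic distance between atoms i and j.
"""

import numpy as np

from moltext import (
    EncoderConfig,
    EncodingParams,
    ModelWeights,
    combined_bias,
    encode_molecule,
    generate_conformer,
    parse_smiles,
)

aspirin = generate_conformer(parse_smiles("CC(=O)Oc1ccccc1C(=O)O"), seed=7)
print(f"aspirin: {aspirin.atom_count} heavy atoms, {len(aspirin.bonds)} bonds")

params = EncodingParams.random(seed=1)
bias = combined_bias(aspirin, params, mode="3D")
print(f"bias matrix shape {bias.values.shape}, "
      f"symmetric: {np.allclose(bias.values, bias.values.T)}")
print(f"bias range [{bias.values.min():.3f}, {bias.values.max():.3f}] "
      "(entries weight atom pairs in attention)")

weights = ModelWeights.init(EncoderConfig(), seed=0)
z = encode_molecule(aspirin, weights, mode="3D")
print(f"joint-space embedding: {z.vector.shape[0]} dims, "
      f"norm {np.linalg.norm(z.vector):.3f}")
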