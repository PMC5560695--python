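"""Encode one Calpha trace into structural letters.

Builds an ideal alpha-helix, computes the four-Calpha fragment
descriptors and decodes them with the bundled 27-letter alphabet.
"""

import numpy as np

from saconf import FixtureSpec, build_backbone, compute_descriptors, default_model
from saconf.structural_alphabet import viterbi_encode

coords = build_backbone(FixtureSpec(length=20, segments=[((1, 20), "helix")]))[0]
model = default_model()
desc = compute_descriptors(coords)
letters = viterbi_encode(desc, model)

print(f"chain length p = {len(coords)} residues -> {len(letters)} letters (p - 3)")
print("first descriptor (d1, d2, d3, d4 in Angstrom):",
      np.round(desc[0], 3))
print("structural-letter string:", letters)
print("secondary-structure categories:",
      {l: model.ss_category(l) for l in set(letters)})
# An ideal helix has identical local geometry at every fragment, so one
# helix-category letter repeats along the whole chain.
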