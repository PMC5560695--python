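"""Mining a multi-model NMR-style entry.

Writes a synthetic 10-model NMR-style file, parses it, splits the
models into individual single-model conformations and prints the set
description — the phase-1 view used to assemble a clean ensemble.
"""

import tempfile
from pathlib import Path

from saconf import FixtureSpec, describe_set, parse_structure, split_models, write_ensemble

tmp = Path(tempfile.mkdtemp())
spec = FixtureSpec(n_conformers=10, length=25, seed=3, as_nmr_models=True,
                   segments=[((1, 25), "helix")],
                   flexible_windows=[((8, 14), 0.8)])
truth = write_ensemble(spec, tmp / "in")

parent = parse_structure(tmp / "in" / f"{truth['ids'][0]}.pdb")
print(f"parent entry {parent.id}: method={parent.method.value}, "
      f"{parent.n_models} models")

models = split_models(parent, tmp / "models")
print(f"split into {len(models)} single-model records with artificial IDs:",
      [m.id for m in models])
print((tmp / "models" / "manifest.tsv").read_text().splitlines()[0])

print(describe_set(models).to_string(index=False))
# Each NMR model becomes one conformation in the ensemble; the manifest
# records which artificial ID came from which MODEL block.
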