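"""Variability analysis of a synthetic conformational ensemble.

Generates 20 conformers of a 60-residue chain with a planted 8-residue
flexible window (sigma = 1.0 A) and two point mutations, then computes
per-position neq_AA / neq_SL and detects the variable region.
"""

import tempfile
from pathlib import Path

from saconf import FixtureSpec, default_model, trivial_msa, write_ensemble
from saconf.alignment import project_msla
from saconf.pipeline import encode_chains
from saconf.structure_io import parse_structure
from saconf.variability import (RegionCriteria, detect_regions,
                                mutated_columns, profile_set)

tmp = Path(tempfile.mkdtemp())
spec = FixtureSpec(
    n_conformers=20, length=60, seed=7,
    segments=[((1, 18), "helix"), ((19, 34), "loop"),
              ((35, 50), "strand"), ((51, 60), "helix")],
    flexible_windows=[((25, 32), 1.0)],
    mutations=[(3, 10, "W"), (7, 50, "H")])
truth = write_ensemble(spec, tmp)

model = default_model()
chains = [parse_structure(tmp / f"{sid}.pdb").chains[0] for sid in truth["ids"]]
msa = trivial_msa(chains)                      # conformers share one sequence length
msla = project_msla(msa, encode_chains(chains, model))
profiles, summary = profile_set(msa, msla, model)
regions = detect_regions(profiles, RegionCriteria(l=4, t_var=1.5, t_high=4.0))

print(f"{summary['n_positions']} positions, "
      f"{summary['n_conserved_sl']} structurally conserved "
      f"({summary['pct_conserved_sl']:.1f}% of defined)")
print(f"mean neq_SL = {summary['mean_neq_sl']:.2f} +/- {summary['sd_neq_sl']:.2f}, "
      f"max = {summary['max_neq_sl']:.2f}")
print("variable regions:",
      [f"{r.start}-{r.end} ({r.trigger}, mean {r.mean_neq_sl:.2f})" for r in regions])
print("columns with sequence variability (neq_AA > 1):",
      sorted(mutated_columns(profiles)))
print("planted window:", truth["flexible_windows"][0][0],
      " planted mutations:", [m[1] for m in truth["mutations"]])
# The detected region should bracket the planted window (fragments
# overlapping the window spread the signal ~2 columns each side), and
# the mutated columns are exactly the planted ones.
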