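# Methods

## The variability model

`saconf` treats a set of conformations of one target as a sample from
the target's accessible conformational space and asks, position by
position, how many effectively distinct states that sample shows. Two
descriptions are scored on the same alignment grid: the amino-acid
sequence (mutations, modified or unresolved residues) and the local
backbone conformation discretized by a structural alphabet. The score
is the exponent of the Shannon entropy of the column's symbol
frequencies,

    neq(i) = exp(−Σ_j f_j(i) ln f_j(i)),

read as the *effective number of symbols* at position i: 1 for a
strictly conserved column, the alphabet size (20 amino acids, 27
structural letters) for a uniform column. Unlike a raw symbol count,
neq weights each symbol by its frequency, so a column with one dominant
conformation and one rare outlier scores just above 1 rather than 2 —
which is what makes it usable on unbalanced ensembles where a few
structures oversample one state.

Assumptions worth keeping in mind: chains are treated as exchangeable
observations (no phylogenetic or experimental-redundancy weighting),
and the structural alphabet summarizes only four-Cα local geometry —
rigid-body motions of whole domains that preserve local conformation
are invisible by design.

## Structural alphabet

Each fragment (i, i+1, i+2, i+3) is described by d1 = |Cα(i)−Cα(i+2)|,
d2 = |Cα(i)−Cα(i+3)|, d3 = |Cα(i+1)−Cα(i+3)| and d4, the signed
projection of Cα(i+3) onto the unit normal of the first three Cα. The
first three are rigid-motion invariant distances; d4 carries chirality
(its sign flips under reflection), which separates right-handed helical
geometry from its mirror image. The alphabet is a hidden Markov model
with one 4-D Gaussian emission per letter; the transition matrix
captures the sequential grammar of backbone geometry (helix letters
follow helix letters etc.).

Decoding is Viterbi in log domain, ties broken toward the lower state
index for determinism. Fragments containing an absent Cα, spanning a
numbering discontinuity, or geometrically degenerate (first three Cα
collinear, triangle area < 1e-6 Å²) are missing; they split the chain
into runs decoded independently from the initial distribution, since no
geometric information crosses a gap. A chain of p residues yields p−3
letters, letter j assigned to residue j+2; residues 1, 2 and p carry
none.

Published parameter values for a 27-letter alphabet of this kind are
not redistributable here, so the package ships its own: a 27-state
model trained (Baum–Welch via hmmlearn, k-means initialization, seed
2024, full covariances, 1e-4 Å² diagonal floor) on a version-pinned
corpus of 260 synthetic chains of idealized helix/strand/loop geometry
under graded coordinate noise (σ = 0.05–0.8 Å; a small jitter is always
present because exactly repeated descriptors collapse emission
covariances). After training, states are relabelled so that the letters
conventionally tied to secondary structure hold: the states that decode
ideal helix and strand geometry — completed by descriptor-space
proximity ranking to exactly 4 helix and 5 strand states — receive
{a, A, V, W} and {L, M, N, T, X}; the remaining 18 letters are loop.
Users can train and load alternative models (JSON, with provenance);
for user-trained models the secondary-structure map is assigned by
distance thresholds to ideal geometry (helix < 1.0 Å, strand < 1.5 Å,
the strand reference being the min over its two pleat phases) rather
than by forced counts.

The bundled model is an operational alphabet: it discretizes the
synthetic geometry space finely and assigns canonical categories
correctly on ideal geometry, but its letters are not interchangeable
with any published alphabet's letters on real protein data.

## Alignment and projection

The amino-acid MSA defines the column coordinate system. It can be
computed by mafft (or ClustalW/T-Coffee where installed) or supplied
precomputed; every ingested row is validated against the ATOM-derived
chain sequence, because a silently inconsistent alignment corrupts
every downstream column. The MSLA is a pure per-row projection —
substituting each residue's letter, keeping gaps — so row order and
column indices are identical by construction. The missing symbol '?'
is kept distinct from the gap '-': a gap means the residue is absent
from the chain, '?' means the residue exists but carries no structural
letter. Column indexing is 1-based in every user-facing table.

## Column statistics and classification

Frequencies are computed over observed symbols only; gaps and missing
cells enter neither numerator nor denominator (absence of data, not a
21st symbol). A chain counts as missing at a column when its amino-acid
cell is a gap or its structural cell is '?'; when at least half the
chains are missing (threshold 0.5, configurable) both neq values are
undefined and the column is excluded from summaries. Classification
thresholds: |neq − 1| ≤ 1e-12 conserved (floating-point guard),
< 1.5 weak, ≥ 1.5 variable, ≥ 3 highly, ≥ 5 strongly variable; the
boundary 1.5 counts as variable. The secondary-structure status of a
column is the common category of its observed letters, or CHANGE when
categories mix — letter changes within one category (e.g. two helix
letters) are backbone deformations without secondary-structure change.
Summary standard deviations use the population denominator n: they are
descriptive statistics over all columns, not estimates from a sample.
'X' (unknown residue) is counted as its own symbol.

## Region detection

RegionCriteria(l, t_var, t_high, max_gap): a column is variable when
neq_SL ≥ t_var and a spike when ≥ t_high (both inclusive). Maximal
variable runs are merged across interruptions of at most max_gap
defined sub-threshold columns — undefined columns never bridge — and a
merged cluster is retained when it contains a run of ≥ l successive
variable columns or a spike. Defaults l = 4, t_var = 1.5, t_high = 4,
max_gap = 1; t_high genuinely varies with the ensemble's overall
variability, so named presets (uPA, P53, P53-NMR, PR1) expose the
combinations used in published analyses of those targets, and the CLI
accepts explicit values. The detector is verified against an
independent exhaustive interval scanner.

## Synthetic ensembles

The generator builds Cα-only PDB files from canonical geometry: helix
rise 1.5 Å / twist 100° / radius 2.3 Å; strand Cα spacing 3.8 Å with
alternating ±0.5 Å pleat; loops as curved arcs (radius 5 Å, 1.2 Å
out-of-plane drift per residue) chosen to sit away from both helix and
strand descriptors. Segments are joined by rigid alignment of tangents
so the virtual bond length stays 3.8 Å across junctions. Ground truth
(flexible windows with per-atom Gaussian noise, point mutations,
missing ranges, NMR-style multi-model packaging, HETATM groups,
numbering offsets) is planted deterministically under one seed and
recorded in a truth file.

What these fixtures do not emulate: real side chains and full-backbone
atoms, correlated (hinge- or domain-like) motions, crystal-contact
artifacts, sequence families with indel structure beyond planted
deletions, and experimental noise models. Passing the planted-recovery
tests therefore demonstrates that the machinery detects localized
backbone variability of the planted magnitude (σ = 1.0 Å over 8
residues among 20 conformers), not that the bundled alphabet reproduces
published per-protein statistics — reproducing those requires the
curated PDB chain sets and manually corrected alignments of the
original studies, which are deliberately out of scope here.

## Numerical and design choices

- Chain breaks: fragments are masked across author-numbering
  discontinuities and Cα–Cα steps > 7.6 Å (twice the virtual bond).
  The distance guard is deliberately loose: strained-but-bonded
  geometry is signal, only unmodelled stretches must be cut.
- altLoc: the first-listed alternate location is kept.
- Sequences are ATOM-derived (SEQRES ignored): the analysis concerns
  residues that have coordinates.
- UniProt numbering comes from DBREF records only; no remote lookup.
- Artificial IDs for split NMR models: base-36 counter over 4
  characters, collision-checked against the input ID list.
- Viterbi vs posterior decoding: Viterbi, because a single consistent
  path is what the letter string represents; posterior marginals could
  produce transition-inconsistent letter pairs.
- EM determinism: a fixed seed makes training bit-reproducible;
  identical seeds yield byte-identical model JSON.
- Figures carry JSON sidecars with the exact plotted values; the PyMOL
  script is deterministic text using only portable commands (color,
  show, select-by-resi).
- Problem sizes in the test suite (20-conformer ensembles, 60-residue
  chains, 3-state training instances) are chosen as the smallest sizes
  at which each property is meaningfully exercised.

## Known limitations

- The bundled alphabet is trained on synthetic geometry; for analyses
  whose letters must match a published alphabet, load that model's
  parameters explicitly.
- neq correlates only loosely with rmsf/B-factor style measures; it
  quantifies discrete local-state multiplicity, not displacement
  amplitude.
- No weighting for redundant chains (e.g. 30 copies of one crystal
  form legitimately dominate the frequencies); curate the input set in
  phase 1 if that is not wanted.
- mmCIF input, remote fetching and biological-assembly expansion are
  not supported.
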