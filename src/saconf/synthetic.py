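"""Synthetic conformational ensembles with known ground truth.

Generates PDB-format multiple-target-conformation (MTC) ensembles built
from idealized secondary-structure geometry: canonical alpha-helices
(1.5 A rise, 100 deg twist, 2.3 A radius), near-extended beta-strands
(3.8 A Calpha spacing with an alternating pleat) and smooth loop arcs.
Controlled perturbations — per-atom Gaussian coordinate noise inside
"flexible windows", point mutations, missing-residue ranges, multi-model
NMR-style files and HETATM groups — are planted at known locations and
recorded in a machine-readable truth file, so every downstream stage
(parsing, encoding, alignment, variability detection) can be tested
against ground truth without any external structure files.

Only Calpha atoms are written; that is the information the structural
alphabet consumes.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"

AA1_TO_3 = {
    "A": "ALA", "C": "CYS", "D": "ASP", "E": "GLU", "F": "PHE",
    "G": "GLY", "H": "HIS", "I": "ILE", "K": "LYS", "L": "LEU",
    "M": "MET", "N": "ASN", "P": "PRO", "Q": "GLN", "R": "ARG",
    "S": "SER", "T": "THR", "V": "VAL", "W": "TRP", "Y": "TYR",
    "X": "UNK",
}

# canonical alpha-helix parameters
HELIX_RISE = 1.5      # A per residue along the axis
HELIX_TWIST = 100.0   # degrees per residue
HELIX_RADIUS = 2.3    # A

STRAND_SPACING = 3.8  # A between consecutive Calpha
STRAND_PLEAT = 0.5    # A alternating out-of-axis displacement


@dataclass
class FixtureSpec:
    """Declarative description of a synthetic ensemble.

    Ranges are 1-based inclusive over the chain (before numbering_offset).
    ``segments`` partitions [1, length] into helix/strand/loop stretches;
    unlisted residues default to loop.
    """

    n_conformers: int = 1
    length: int = 50
    segments: list[tuple[tuple[int, int], str]] = field(default_factory=list)
    flexible_windows: list[tuple[tuple[int, int], float]] = field(default_factory=list)
    mutations: list[tuple[int, int, str]] = field(default_factory=list)  # (conformer, pos, AA)
    missing: list[tuple[int, tuple[int, int]]] = field(default_factory=list)  # (conformer, range)
    numbering_offset: int = 0
    seed: int = 0
    het_groups: list[str] = field(default_factory=list)
    as_nmr_models: bool = False
    mirror: bool = False
    chain_id: str = "A"

    def validate(self) -> None:
        covered = np.zeros(self.length + 1, dtype=int)
        for (a, b), geom in self.segments:
            if not (1 <= a <= b <= self.length):
                raise ValueError(f"segment range ({a}, {b}) outside [1, {self.length}]")
            if geom not in ("helix", "strand", "loop"):
                raise ValueError(f"unknown geometry {geom!r}")
            covered[a:b + 1] += 1
        if (covered > 1).any():
            raise ValueError("overlapping contradictory segments")
        for (a, b), sigma in self.flexible_windows:
            if not (1 <= a <= b <= self.length):
                raise ValueError(f"flexible window ({a}, {b}) outside [1, {self.length}]")
            if sigma < 0:
                raise ValueError("noise sigma must be >= 0")
        for conf, pos, aa in self.mutations:
            if not (1 <= pos <= self.length):
                raise ValueError(f"mutation position {pos} outside chain")
            if not (0 <= conf < self.n_conformers):
                raise ValueError(f"mutation conformer {conf} out of range")
        for conf, (a, b) in self.missing:
            if not (1 <= a <= b <= self.length):
                raise ValueError(f"missing range ({a}, {b}) outside chain")


def _helix_points(n: int, phase: int = 0) -> np.ndarray:
    i = np.arange(phase, phase + n, dtype=float)
    t = np.deg2rad(HELIX_TWIST) * i
    return np.column_stack([
        HELIX_RADIUS * np.cos(t),
        HELIX_RADIUS * np.sin(t),
        HELIX_RISE * i,
    ])


def _strand_points(n: int, phase: int = 0) -> np.ndarray:
    i = np.arange(phase, phase + n, dtype=float)
    dy = 2.0 * STRAND_PLEAT  # consecutive pleat change
    dx = math.sqrt(STRAND_SPACING ** 2 - dy ** 2)
    y = STRAND_PLEAT * np.where((np.arange(phase, phase + n) % 2) == 0, 1.0, -1.0)
    return np.column_stack([dx * i, y, np.zeros(n)])


def _loop_points(n: int, phase: int = 0) -> np.ndarray:
    # curved arc with out-of-plane drift, Calpha spacing kept at 3.8 A;
    # curvature strong enough to stay away from both helix and
    # near-extended strand descriptors
    radius = 5.0
    drift = 1.2
    chord = math.sqrt(STRAND_SPACING ** 2 - drift ** 2)
    dtheta = 2.0 * math.asin(chord / (2.0 * radius))
    i = np.arange(phase, phase + n, dtype=float)
    theta = dtheta * i
    return np.column_stack([
        radius * np.sin(theta),
        radius * (1.0 - np.cos(theta)),
        drift * i,
    ])


_GEOMETRY = {"helix": _helix_points, "strand": _strand_points, "loop": _loop_points}


def _align_segment(points: np.ndarray, anchor: np.ndarray, direction: np.ndarray) -> np.ndarray:
    """Rotate/translate a canonical segment so it continues an existing chain.

    The segment's initial tangent is rotated onto ``direction`` and its
    first point placed at ``anchor`` + spacing * direction, keeping the
    junction Calpha-Calpha distance at the canonical spacing.
    """
    tangent = points[1] - points[0] if len(points) > 1 else np.array([1.0, 0.0, 0.0])
    tangent = tangent / np.linalg.norm(tangent)
    direction = direction / np.linalg.norm(direction)
    v = np.cross(tangent, direction)
    c = float(np.dot(tangent, direction))
    if np.linalg.norm(v) < 1e-12:
        rot = np.eye(3) if c > 0 else -np.eye(3)
    else:
        vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
        rot = np.eye(3) + vx + vx @ vx * (1.0 / (1.0 + c))
    moved = (points - points[0]) @ rot.T
    start = anchor + STRAND_SPACING * direction
    return moved + start


def resolved_segments(spec: FixtureSpec) -> list[tuple[tuple[int, int], str]]:
    """Fill uncovered residue ranges with loop geometry, in chain order."""
    marks = ["loop"] * (spec.length + 1)
    for (a, b), geom in spec.segments:
        for k in range(a, b + 1):
            marks[k] = geom
    out: list[tuple[tuple[int, int], str]] = []
    start = 1
    for k in range(2, spec.length + 1):
        if marks[k] != marks[start]:
            out.append(((start, k - 1), marks[start]))
            start = k
    out.append(((start, spec.length), marks[start]))
    return out


def build_backbone(spec: FixtureSpec) -> np.ndarray:
    """Return the ensemble's Calpha coordinates, shape (n_conformers, length, 3).

    The unperturbed template is shared by all conformers; seeded Gaussian
    noise is then added independently per conformer inside each flexible
    window.
    """
    spec.validate()
    segs = resolved_segments(spec)
    coords = np.empty((spec.length, 3))
    pos = 0
    anchor = None
    direction = None
    for (a, b), geom in segs:
        n = b - a + 1
        pts = _GEOMETRY[geom](n)
        if anchor is None:
            placed = pts
        else:
            placed = _align_segment(pts, anchor, direction)
        coords[pos:pos + n] = placed
        pos += n
        anchor = placed[-1]
        if len(placed) > 1:
            direction = placed[-1] - placed[-2]
        elif direction is None:
            direction = np.array([1.0, 0.0, 0.0])
    if spec.mirror:
        coords = coords.copy()
        coords[:, 2] *= -1.0
    rng = np.random.default_rng(spec.seed)
    ensemble = np.repeat(coords[None, :, :], spec.n_conformers, axis=0)
    for conf in range(spec.n_conformers):
        for (a, b), sigma in spec.flexible_windows:
            if sigma > 0:
                ensemble[conf, a - 1:b, :] += rng.normal(0.0, sigma, size=(b - a + 1, 3))
    return ensemble


def base_sequence(spec: FixtureSpec) -> str:
    """Deterministic amino-acid sequence shared by all conformers (pre-mutation)."""
    rng = np.random.default_rng(spec.seed + 1)
    return "".join(AA_ALPHABET[k] for k in rng.integers(0, 20, size=spec.length))


def conformer_sequence(spec: FixtureSpec, conformer: int) -> str:
    seq = list(base_sequence(spec))
    for conf, pos, aa in spec.mutations:
        if conf == conformer:
            seq[pos - 1] = aa
    return "".join(seq)


def _missing_set(spec: FixtureSpec, conformer: int) -> set[int]:
    out: set[int] = set()
    for conf, (a, b) in spec.missing:
        if conf == conformer:
            out.update(range(a, b + 1))
    return out


def _atom_line(serial: int, resname: str, chain: str, resnum: int,
               xyz: Sequence[float], record: str = "ATOM", name: str = "CA",
               element: str = "C") -> str:
    return (
        f"{record:<6s}{serial:>5d} {name:^4s}{'':1s}{resname:>3s} {chain:1s}"
        f"{resnum:>4d}{'':1s}   {xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}"
        f"{1.00:6.2f}{0.00:6.2f}          {element:>2s}"
    )


def _conformer_lines(spec: FixtureSpec, conformer: int, coords: np.ndarray,
                     serial_start: int = 1) -> list[str]:
    seq = conformer_sequence(spec, conformer)
    missing = _missing_set(spec, conformer)
    lines = []
    serial = serial_start
    for k in range(spec.length):
        if (k + 1) in missing:
            continue
        resnum = k + 1 + spec.numbering_offset
        resname = AA1_TO_3.get(seq[k], "UNK")
        lines.append(_atom_line(serial, resname, spec.chain_id, resnum, coords[k]))
        serial += 1
    lines.append(f"TER   {serial:>5d}      {AA1_TO_3.get(seq[-1], 'UNK'):>3s} "
                 f"{spec.chain_id:1s}{spec.length + spec.numbering_offset:>4d}")
    serial += 1
    for h, het in enumerate(spec.het_groups):
        ref = coords[min(5 + 3 * h, spec.length - 1)] + np.array([6.0, 0.0, 0.0])
        lines.append(_atom_line(serial, het, spec.chain_id,
                                900 + h, ref, record="HETATM", name="C1"))
        serial += 1
    # a water, always: parsers must exclude it from HETATM group names
    lines.append(_atom_line(serial, "HOH", spec.chain_id, 990,
                            coords[0] + np.array([8.0, 8.0, 0.0]),
                            record="HETATM", name="O", element="O"))
    return lines


def _structure_id(index: int) -> str:
    """Synthetic 4-character structure IDs: S000, S001, ..."""
    return f"S{index:03d}"


def write_ensemble(spec: FixtureSpec, out_dir: str | Path) -> dict:
    """Write the ensemble as PDB files plus an ID list and a truth file.

    Returns the truth dictionary (also written to ``truth.json``): planted
    flexible windows, mutations, missing ranges, the base sequence and the
    per-file IDs. With ``as_nmr_models`` a single multi-model NMR-style
    file is written; otherwise one single-model X-ray-style file per
    conformer.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    coords = build_backbone(spec)
    ids: list[str] = []
    if spec.as_nmr_models:
        sid = _structure_id(0)
        lines = [f"HEADER    SYNTHETIC ENSEMBLE                      {sid}",
                 "EXPDTA    SOLUTION NMR"]
        for conf in range(spec.n_conformers):
            lines.append(f"MODEL     {conf + 1:>4d}")
            lines.extend(_conformer_lines(spec, conf, coords[conf]))
            lines.append("ENDMDL")
        lines.append("END")
        (out_dir / f"{sid}.pdb").write_text("\n".join(lines) + "\n")
        ids.append(sid)
    else:
        for conf in range(spec.n_conformers):
            sid = _structure_id(conf)
            lines = [f"HEADER    SYNTHETIC ENSEMBLE                      {sid}",
                     "EXPDTA    X-RAY DIFFRACTION",
                     "REMARK   2 RESOLUTION.    1.80 ANGSTROMS."]
            lines.extend(_conformer_lines(spec, conf, coords[conf]))
            lines.append("END")
            (out_dir / f"{sid}.pdb").write_text("\n".join(lines) + "\n")
            ids.append(sid)
    (out_dir / "ids.txt").write_text("\n".join(ids) + "\n")
    truth = {
        "n_conformers": spec.n_conformers,
        "length": spec.length,
        "numbering_offset": spec.numbering_offset,
        "base_sequence": base_sequence(spec),
        "segments": [[list(r), g] for r, g in resolved_segments(spec)],
        "flexible_windows": [[list(r), s] for r, s in spec.flexible_windows],
        "mutations": [list(m) for m in spec.mutations],
        "missing": [[c, list(r)] for c, r in spec.missing],
        "as_nmr_models": spec.as_nmr_models,
        "ids": ids,
        "seed": spec.seed,
    }
    (out_dir / "truth.json").write_text(json.dumps(truth, indent=1))
    return truth


def training_corpus(seed: int = 2024, n_chains: int = 260) -> list[np.ndarray]:
    """Corpus of idealized/perturbed Calpha chains for alphabet training.

    A mixture of pure and noisy helices, strands, loop arcs and composite
    chains, covering the descriptor space broadly enough to fit a
    many-state alphabet. Composition and seed are version-pinned: the
    bundled default model is trained on exactly this corpus.
    """
    rng = np.random.default_rng(seed)
    chains: list[np.ndarray] = []
    kinds = ["helix", "strand", "loop", "mixed"]
    for k in range(n_chains):
        kind = kinds[k % len(kinds)]
        n = int(rng.integers(20, 46))
        if kind == "mixed":
            cut1, cut2 = sorted(rng.integers(6, n - 6, size=2))
            cut2 = max(cut2, cut1 + 4)
            geoms = rng.permutation(["helix", "strand", "loop"])
            spec = FixtureSpec(
                n_conformers=1, length=n, seed=int(rng.integers(0, 2**31 - 1)),
                segments=[((1, int(cut1)), str(geoms[0])),
                          ((int(cut1) + 1, int(cut2)), str(geoms[1])),
                          ((int(cut2) + 1, n), str(geoms[2]))])
        else:
            spec = FixtureSpec(n_conformers=1, length=n,
                               seed=int(rng.integers(0, 2**31 - 1)),
                               segments=[((1, n), kind)])
        coords = build_backbone(spec)[0]
        # always some jitter: exactly repeated descriptors collapse
        # emission covariances during alphabet training
        sigma = float(rng.choice([0.05, 0.1, 0.25, 0.45, 0.8]))
        coords = coords + rng.normal(0.0, sigma, size=coords.shape)
        chains.append(coords)
    return chains
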