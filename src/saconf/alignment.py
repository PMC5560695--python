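"""Amino-acid MSA handling and projection to a structural-letter alignment.

The multiple sequence alignment (MSA) of the C extracted chain
sequences defines the shared column coordinate system. Replacing each
aligned residue by the structural letter of its four-Calpha fragment
(assigned to residue i+2) yields the multiple structural-letter
alignment (MSLA) on exactly the same grid — the device that lets local
3D conformation be compared column-by-column without any 3D
superposition.

Gaps ('-') mark absent residues; the distinct missing symbol ('?')
marks residues present in the sequence but carrying no structural
letter (the two chain termini on each side, and residues inside windows
with absent coordinates), so variability statistics can exclude both.
"""

from __future__ import annotations

import logging
import shutil
import subprocess
import tempfile
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from Bio import AlignIO, SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .structure_io import ChainRecord
from .structural_alphabet import MISSING

GAP = "-"

logger = logging.getLogger(__name__)


class AlignmentInconsistencyError(ValueError):
    """An MSA row's ungapped sequence does not match the extracted chain."""


class AlignerUnavailableError(RuntimeError):
    """Requested external alignment program is not on PATH."""


@dataclass
class MSA:
    """Row-aligned amino-acid strings sharing one column coordinate system."""

    ids: list[str]
    rows: list[str]
    chains: list[ChainRecord]
    # per row: column index (0-based) -> residue index in the chain, or -1 at gaps
    column_map: np.ndarray

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    @property
    def n_cols(self) -> int:
        return len(self.rows[0]) if self.rows else 0


@dataclass
class MSLA:
    """Structural-letter strings on the MSA's grid (same rows/columns)."""

    ids: list[str]
    rows: list[str]

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    @property
    def n_cols(self) -> int:
        return len(self.rows[0]) if self.rows else 0


def extract_sequences(chains: list[ChainRecord]) -> list[SeqRecord]:
    """FASTA records of the chains' ATOM-derived sequences.

    Duplicate ids are disambiguated with a numeric suffix and logged.
    """
    if len(chains) < 2:
        raise ValueError("need at least two chains for an alignment")
    seen: dict[str, int] = {}
    records = []
    for ch in chains:
        base = ch.name or f"chain_{ch.chain_id}"
        if base in seen:
            seen[base] += 1
            name = f"{base}_{seen[base]}"
            logger.warning("duplicate sequence id %s renamed to %s", base, name)
            ch.name = name
        else:
            seen[base] = 0
            name = base
        records.append(SeqRecord(Seq(ch.sequence), id=name, description=""))
    return records


def write_fasta(records: list[SeqRecord], path: str | Path) -> None:
    SeqIO.write(records, str(path), "fasta")


def _read_alignment(path: Path):
    for fmt in ("fasta", "clustal"):
        try:
            aln = AlignIO.read(str(path), fmt)
            if len(aln) >= 2:
                return aln
        except ValueError:
            continue
    raise ValueError(f"could not parse {path} as aligned FASTA or Clustal")


def _run_aligner(engine: str, records: list[SeqRecord]) -> Path:
    exe = {"mafft": "mafft", "clustalw": "clustalw2", "tcoffee": "t_coffee"}[engine]
    found = shutil.which(exe) or (shutil.which("clustalw") if engine == "clustalw" else None)
    if not found:
        raise AlignerUnavailableError(
            f"{engine} executable not found on PATH; align the sequences "
            "yourself and pass the file via precomputed mode")
    tmp = Path(tempfile.mkdtemp(prefix="saconf_aln_"))
    infile = tmp / "sequences.fasta"
    write_fasta(records, infile)
    outfile = tmp / "alignment.fasta"
    if engine == "mafft":
        with open(outfile, "w") as out:
            proc = subprocess.run([found, "--auto", "--quiet", str(infile)],
                                  stdout=out, stderr=subprocess.PIPE, text=True)
    elif engine == "clustalw":
        proc = subprocess.run([found, f"-INFILE={infile}", "-OUTPUT=FASTA",
                               f"-OUTFILE={outfile}"],
                              capture_output=True, text=True)
    else:
        proc = subprocess.run([found, str(infile), "-output", "fasta_aln",
                               "-outfile", str(outfile)],
                              capture_output=True, text=True)
    logger.info("aligner command: %s", " ".join(proc.args) if isinstance(proc.args, list) else proc.args)
    if proc.returncode != 0:
        raise RuntimeError(f"{engine} failed: {proc.stderr[-2000:]}")
    return outfile


def load_or_compute_msa(chains: list[ChainRecord], engine: str = "mafft",
                        msa_path: str | Path | None = None) -> MSA:
    """Obtain the MSA: run an external aligner or ingest a precomputed one.

    Engines: ``mafft``, ``clustalw``, ``tcoffee`` (external executables),
    or ``precomputed`` with ``msa_path`` pointing at an aligned-FASTA or
    Clustal file whose ids match the chain names. Every row is validated
    against its extracted sequence: a mismatch raises
    :class:`AlignmentInconsistencyError` naming the row (misaligned or
    stale alignments are the classic failure mode here).
    """
    if (engine == "precomputed") != (msa_path is not None):
        raise ValueError("msa_path must be given exactly when engine='precomputed'")
    records = extract_sequences(chains)
    if engine == "precomputed":
        aln = _read_alignment(Path(msa_path))
    else:
        aln = _read_alignment(_run_aligner(engine, records))
    by_id = {r.id: str(r.seq).upper() for r in aln}
    if len(by_id) != len(aln):
        raise AlignmentInconsistencyError("alignment contains duplicate row ids")
    rows, ids, ordered_chains = [], [], []
    for rec, ch in zip(records, chains):
        if rec.id not in by_id:
            raise AlignmentInconsistencyError(f"alignment lacks a row for {rec.id}")
        row = by_id[rec.id]
        if row.replace(GAP, "") != ch.sequence.upper():
            raise AlignmentInconsistencyError(
                f"row {rec.id}: ungapped alignment sequence does not match "
                "the sequence extracted from the structure")
        ids.append(rec.id)
        rows.append(row)
        ordered_chains.append(ch)
    P = len(rows[0])
    if any(len(r) != P for r in rows):
        raise AlignmentInconsistencyError("alignment rows have unequal lengths")
    column_map = np.full((len(rows), P), -1, dtype=int)
    for r, row in enumerate(rows):
        j = 0
        for c, cell in enumerate(row):
            if cell != GAP:
                column_map[r, c] = j
                j += 1
    return MSA(ids=ids, rows=rows, chains=ordered_chains, column_map=column_map)


def trivial_msa(chains: list[ChainRecord]) -> MSA:
    """Gapless MSA for chains of identical length (e.g. an ensemble of
    conformers of one sequence). Fails if lengths differ."""
    records = extract_sequences(chains)
    lengths = {len(ch.sequence) for ch in chains}
    if len(lengths) != 1:
        raise ValueError("trivial alignment requires equal-length chains")
    P = lengths.pop()
    column_map = np.tile(np.arange(P), (len(chains), 1))
    return MSA(ids=[r.id for r in records],
               rows=[ch.sequence.upper() for ch in chains],
               chains=list(chains), column_map=column_map)


def letters_per_residue(chain_length: int, letters: str) -> str:
    """Pad a (p-3)-letter encoding onto the chain's p residues.

    Letter j (fragment j, j+1, j+2, j+3) is assigned to residue j+2, so
    residues 1, 2 and p carry the missing symbol.
    """
    if len(letters) != chain_length - 3:
        raise ValueError(f"encoding length {len(letters)} inconsistent with "
                         f"chain length {chain_length} (expected p-3)")
    return MISSING * 2 + letters + MISSING


def project_msla(msa: MSA, encodings: dict[str, str]) -> MSLA:
    """Project per-chain structural-letter strings onto the MSA grid.

    ``encodings`` maps row id -> the chain's (p-3)-letter string. Gap
    cells stay gaps; residues without a letter (termini, missing-
    coordinate windows) carry the missing symbol.
    """
    rows = []
    for r, (rid, row) in enumerate(zip(msa.ids, msa.rows)):
        if rid not in encodings:
            raise ValueError(f"no encoding supplied for MSA row {rid}")
        padded = letters_per_residue(msa.chains[r].length, encodings[rid])
        cells = []
        for c, cell in enumerate(row):
            if cell == GAP:
                cells.append(GAP)
            else:
                cells.append(padded[msa.column_map[r, c]])
        rows.append("".join(cells))
    return MSLA(ids=list(msa.ids), rows=rows)


def correspondence_table(msa: MSA):
    """Per-column mapping: MSA position (1-based) -> author residue
    numbers in each chain, plus UniProt numbers where known."""
    import pandas as pd

    data: dict[str, list] = {"msa_position": list(range(1, msa.n_cols + 1))}
    for r, (rid, ch) in enumerate(zip(msa.ids, msa.chains)):
        numbers = ch.author_numbers()
        col = []
        for c in range(msa.n_cols):
            j = msa.column_map[r, c]
            col.append(numbers[j] if j >= 0 else "")
        data[rid] = col
        if ch.uniprot_id is not None and ch.uniprot_offset is not None:
            ucol = []
            for c in range(msa.n_cols):
                j = msa.column_map[r, c]
                if j >= 0:
                    num, _ = ch.residues[j][0]
                    ucol.append(str(num + ch.uniprot_offset))
                else:
                    ucol.append("")
            data[f"{rid}_uniprot({ch.uniprot_id})"] = ucol
    return pd.DataFrame(data)


def write_msla(msla: MSLA, path: str | Path) -> None:
    """Write the MSLA as aligned-FASTA-style text (letters are case-
    sensitive; '?' marks positions without structural information)."""
    with open(path, "w") as fh:
        for rid, row in zip(msla.ids, msla.rows):
            fh.write(f">{rid}\n{row}\n")
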