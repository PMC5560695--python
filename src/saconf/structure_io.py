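"""Parsing and description of PDB-format structure files.

One parsed file yields a :class:`StructureRecord` holding the file-level
metadata the mining phase reports (experimental method, resolution,
model count, HETATM group names with water excluded) and one
:class:`ChainRecord` per protein chain with the ATOM-derived sequence,
author residue numbering (with insertion codes) and the Calpha trace.

Multi-model NMR entries are split into individual single-model PDB
files, each given a distinct artificial 4-character ID recorded in a
manifest, so every conformation enters the pipeline as one chain.
"""

from __future__ import annotations

import string
import warnings
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path

import numpy as np
import pandas as pd
from Bio.PDB import PDBParser
from Bio.PDB.PDBExceptions import PDBConstructionWarning
from Bio.SeqUtils import seq1

WATER_NAMES = {"HOH", "WAT", "DOD", "H2O"}


class Method(str, Enum):
    XRAY = "XRAY"
    NMR = "NMR"
    MODEL = "MODEL"
    UNKNOWN = "UNKNOWN"


class EmptyStructureError(ValueError):
    """File contains no ATOM records."""


@dataclass
class ChainRecord:
    """One protein chain: sequence, author numbering and Calpha trace."""

    chain_id: str
    residues: list[tuple[tuple[int, str], str]]   # ((resseq, icode), one-letter AA)
    ca_coords: np.ndarray                          # (p, 3), NaN rows where Calpha absent
    uniprot_id: str | None = None
    uniprot_offset: int | None = None              # author number + offset = UniProt number
    name: str = ""

    @property
    def length(self) -> int:
        return len(self.residues)

    @property
    def sequence(self) -> str:
        return "".join(aa for _, aa in self.residues)

    def author_numbers(self) -> list[str]:
        """Author residue numbers as strings, insertion codes appended."""
        return [f"{num}{icode.strip()}" for (num, icode), _ in self.residues]


@dataclass
class StructureRecord:
    """Parsed metadata and chains of one structure file."""

    id: str
    method: Method
    resolution: float | None
    n_models: int
    chains: list[ChainRecord]
    het_names: set[str]
    source_path: Path
    model_number: int | None = None   # set on records produced by split_models

    def chain(self, chain_id: str) -> ChainRecord:
        for ch in self.chains:
            if ch.chain_id == chain_id:
                return ch
        raise KeyError(f"no chain {chain_id!r} in {self.id}")


def _infer_method(header: dict) -> Method:
    text = (header.get("structure_method") or "").lower()
    if "x-ray" in text or "xray" in text or "diffraction" in text:
        return Method.XRAY
    if "nmr" in text:
        return Method.NMR
    if "model" in text or "theoretical" in text:
        return Method.MODEL
    return Method.UNKNOWN


def _parse_dbref(path: Path) -> dict[str, tuple[str, int]]:
    """chain id -> (UniProt accession, author->UniProt numbering offset)."""
    out: dict[str, tuple[str, int]] = {}
    with open(path) as fh:
        for line in fh:
            if line.startswith("DBREF") and len(line) >= 42:
                db = line[26:32].strip()
                if db not in ("UNP", "UNIPROT"):
                    continue
                chain = line[12].strip()
                try:
                    seq_begin = int(line[14:18])
                    db_begin = int(line[55:60])
                except ValueError:
                    continue
                out[chain] = (line[33:41].strip(), db_begin - seq_begin)
    return out


def _first_altloc_ca(residue):
    """The first-listed alternate location of the Calpha atom, or None."""
    if "CA" not in residue:
        return None
    atom = residue["CA"]
    if atom.is_disordered():
        atom = next(iter(atom.child_dict.values()))
    return atom


def parse_structure(path: str | Path, structure_id: str | None = None) -> StructureRecord:
    """Parse one PDB-format file into a StructureRecord.

    The sequence is ATOM-derived (authoritative over SEQRES); residues
    lacking a Calpha are kept in the sequence with their coordinate
    marked absent. Non-standard residue names fall back to 'X'. Water is
    excluded from the HETATM group names.
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"structure file not found: {path}")
    sid = structure_id or path.stem[:4].upper()
    parser = PDBParser(QUIET=True)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", PDBConstructionWarning)
        structure = parser.get_structure(sid, str(path))
    models = list(structure)
    if not models or not any(len(ch) for m in models for ch in m):
        raise EmptyStructureError(f"no ATOM records in {path}")
    header = structure.header or {}
    dbref = _parse_dbref(path)
    first = models[0]
    chains: list[ChainRecord] = []
    het_names: set[str] = set()
    for bio_chain in first:
        residues = []
        coords = []
        for res in bio_chain:
            hetfield, resseq, icode = res.id
            if hetfield != " ":
                name = res.get_resname().strip()
                if hetfield.startswith("H_") and name not in WATER_NAMES:
                    het_names.add(name)
                continue
            aa = seq1(res.get_resname(), undef_code="X")
            if not aa or aa == " ":
                aa = "X"
            residues.append(((resseq, icode), aa.upper()))
            atom = _first_altloc_ca(res)
            coords.append(atom.coord.astype(float) if atom is not None
                          else np.full(3, np.nan))
        if residues:
            uni = dbref.get(bio_chain.id)
            chains.append(ChainRecord(
                chain_id=bio_chain.id,
                residues=residues,
                ca_coords=np.array(coords),
                uniprot_id=uni[0] if uni else None,
                uniprot_offset=uni[1] if uni else None,
                name=f"{sid}_{bio_chain.id}",
            ))
    # waters/het in later models do not add new group names in practice,
    # but scan them anyway so het_names is model-order invariant
    for m in models[1:]:
        for bio_chain in m:
            for res in bio_chain:
                hetfield = res.id[0]
                name = res.get_resname().strip()
                if hetfield.startswith("H_") and name not in WATER_NAMES:
                    het_names.add(name)
    if not chains:
        raise EmptyStructureError(f"no protein ATOM records in {path}")
    resolution = header.get("resolution")
    return StructureRecord(
        id=sid,
        method=_infer_method(header),
        resolution=float(resolution) if resolution is not None else None,
        n_models=len(models),
        chains=chains,
        het_names=het_names,
        source_path=path,
    )


_BASE36 = string.digits + string.ascii_uppercase


def _artificial_id(counter: int) -> str:
    out = ""
    n = counter
    for _ in range(4):
        out = _BASE36[n % 36] + out
        n //= 36
    return out


def artificial_ids(n: int, reserved: set[str]) -> list[str]:
    """n distinct 4-character base-36 IDs avoiding the reserved set."""
    out: list[str] = []
    counter = 0
    while len(out) < n:
        cand = _artificial_id(counter)
        counter += 1
        if cand not in reserved:
            out.append(cand)
            reserved.add(cand)
    return out


def split_models(record: StructureRecord, out_dir: str | Path,
                 reserved_ids: set[str] | None = None) -> list[StructureRecord]:
    """Split a multi-model entry into single-model PDB files.

    Each MODEL block's ATOM/HETATM/TER lines are copied verbatim into
    its own file (so the concatenation of the outputs' coordinate
    records equals the parent's), under a distinct artificial ID listed
    in ``manifest.tsv``. Single-model records are returned unchanged and
    nothing is written.
    """
    if record.n_models == 1:
        return [record]
    out_dir = Path(out_dir)
    try:
        out_dir.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise IOError(f"cannot create output directory {out_dir}: {exc}") from exc
    lines = Path(record.source_path).read_text().splitlines()
    blocks: list[list[str]] = []
    current: list[str] | None = None
    for line in lines:
        tag = line[:6].strip()
        if tag == "MODEL":
            current = []
        elif tag == "ENDMDL":
            if current is not None:
                blocks.append(current)
            current = None
        elif current is not None and tag in ("ATOM", "HETATM", "TER", "ANISOU"):
            current.append(line)
    reserved = reserved_ids if reserved_ids is not None else set()
    reserved.add(record.id)
    ids = artificial_ids(len(blocks), reserved)
    out_records = []
    manifest_rows = []
    for model_no, (block, aid) in enumerate(zip(blocks, ids), start=1):
        out_path = out_dir / f"{aid}.pdb"
        header = [f"HEADER    SPLIT MODEL {model_no} OF {record.id:<24s}{aid}",
                  "EXPDTA    SOLUTION NMR"]
        out_path.write_text("\n".join(header + block + ["END"]) + "\n")
        rec = parse_structure(out_path, structure_id=aid)
        rec.method = record.method
        rec.resolution = record.resolution
        rec.model_number = model_no
        out_records.append(rec)
        manifest_rows.append((record.id, model_no, aid, str(out_path)))
    manifest = out_dir / "manifest.tsv"
    with open(manifest, "a") as fh:
        if manifest.stat().st_size == 0:
            fh.write("parent_id\tmodel\tartificial_id\tpath\n")
        for row in manifest_rows:
            fh.write("\t".join(str(x) for x in row) + "\n")
    return out_records


def describe_set(records: list[StructureRecord]) -> pd.DataFrame:
    """Tabular description of a structure set, one row per record."""
    if not records:
        raise ValueError("need at least one structure record")
    rows = []
    for rec in records:
        rows.append({
            "id": rec.id,
            "method": rec.method.value,
            "resolution": rec.resolution if rec.resolution is not None else "",
            "n_models": rec.n_models,
            "n_chains": len(rec.chains),
            "oligomeric_state": "monomer" if len(rec.chains) == 1 else "oligomer",
            "chain_ids": ",".join(ch.chain_id for ch in rec.chains),
            "chain_lengths": ",".join(str(ch.length) for ch in rec.chains),
            "uniprot_ids": ",".join(ch.uniprot_id or "" for ch in rec.chains),
            "het_names": ",".join(sorted(rec.het_names)),
        })
    return pd.DataFrame(rows)


def read_id_list(path: str | Path) -> list[tuple[str, str | None]]:
    """Read the input ID list: one 4-character ID per line, with an
    optional ``_<chain>`` suffix restricting the record to one chain."""
    out = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        if "_" in line:
            sid, chain = line.split("_", 1)
        else:
            sid, chain = line, None
        if len(sid) != 4:
            raise ValueError(f"structure ID must have 4 characters: {line!r}")
        out.append((sid.upper(), chain))
    return out
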