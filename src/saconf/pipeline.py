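"""End-to-end orchestration of the five-step analysis.

Step 1 parses and describes the structure files (splitting multi-model
NMR entries); step 2 extracts sequences and obtains the MSA; step 3
encodes every chain into structural letters and projects the MSLA;
step 4 computes per-column neq profiles and detects variable regions;
step 5 renders the maps, the neq graphic and the molecular-viewer
script. All outputs land in one directory with the standard file names
(AA_alignment.pdf, SL_alignment.pdf, Neq_graph.pdf, script_pymol.pml,
plus TSV/JSON tables) and a run log recording versions, seed and
timings.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from . import alignment, reporting, structural_alphabet, structure_io, variability
from .structural_alphabet import AlphabetModel, compute_descriptors
from .structure_io import ChainRecord, StructureRecord
from .variability import PRESETS, RegionCriteria

logger = logging.getLogger(__name__)

#: Calpha-Calpha distance above which two residues consecutive in the
#: file cannot be chain-bonded (a break; no fragment spans it). Twice
#: the canonical virtual-bond length: distorted-but-bonded geometry
#: must stay encodable — conformational strain is the signal, not an
#: artifact — while residues flanking an unmodelled stretch are cut.
MAX_CA_CA = 7.6


class StageError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class RunConfig:
    """Parameters of one pipeline run."""

    id_list_path: str | Path
    structure_dir: str | Path
    output_dir: str | Path
    msa_engine: str = "mafft"            # mafft | clustalw | tcoffee | precomputed
    msa_path: str | Path | None = None
    model_path: str | Path | None = None  # default: bundled alphabet
    missing_threshold: float = 0.5
    criteria: RegionCriteria | str = field(default_factory=RegionCriteria)
    reference: str | None = None          # row id for step 5; default first MSA row
    seed: int = 0

    def resolved_criteria(self) -> RegionCriteria:
        crit = PRESETS[self.criteria] if isinstance(self.criteria, str) else self.criteria
        crit.validate()
        return crit

    def validate(self) -> None:
        if not Path(self.id_list_path).exists():
            raise FileNotFoundError(self.id_list_path)
        if not Path(self.structure_dir).is_dir():
            raise NotADirectoryError(self.structure_dir)
        if self.msa_path is not None and not Path(self.msa_path).exists():
            raise FileNotFoundError(self.msa_path)
        if not (0 < self.missing_threshold <= 1):
            raise ValueError("missing_threshold must be in (0, 1]")
        self.resolved_criteria()


def _load_model(config: RunConfig) -> AlphabetModel:
    if config.model_path is not None:
        return AlphabetModel.load(config.model_path)
    return structural_alphabet.default_model()


def collect_chains(config: RunConfig) -> tuple[list[StructureRecord], list[ChainRecord]]:
    """Step 1: parse all listed structures, split NMR models, select chains."""
    entries = structure_io.read_id_list(config.id_list_path)
    sdir = Path(config.structure_dir)
    out_dir = Path(config.output_dir)
    records: list[StructureRecord] = []
    chains: list[ChainRecord] = []
    reserved = {sid for sid, _ in entries}
    for sid, chain_sel in entries:
        matches = [p for ext in ("pdb", "ent", "PDB")
                   for p in sdir.glob(f"*.{ext}") if p.stem.upper() == sid]
        if not matches:
            raise StageError("describe", f"no structure file for ID {sid} in {sdir}")
        rec = structure_io.parse_structure(matches[0], structure_id=sid)
        if rec.n_models > 1:
            split = structure_io.split_models(rec, out_dir / "models",
                                              reserved_ids=reserved)
            records.append(rec)
            use = split
        else:
            records.append(rec)
            use = [rec]
        for r in use:
            if chain_sel is not None:
                chains.append(r.chain(chain_sel))
            else:
                chains.extend(r.chains)
    return records, chains


def chain_descriptors(chain: ChainRecord) -> np.ndarray:
    """Fragment descriptors of one chain, with chain breaks masked.

    A fragment is discarded (missing) when residues inside its window
    are not consecutive in author numbering, or when a Calpha-Calpha
    step exceeds the bonded maximum — residues flanking an unmodelled
    stretch carry no geometric information across it.
    """
    desc = compute_descriptors(chain.ca_coords)
    nums = np.array([num for (num, _), _ in chain.residues])
    icodes = [icode for (_, icode), _ in chain.residues]
    step_break = np.zeros(len(nums) - 1, dtype=bool)
    for k in range(len(nums) - 1):
        dn = nums[k + 1] - nums[k]
        contiguous = dn == 1 or (dn == 0 and icodes[k + 1] != icodes[k])
        if not contiguous:
            step_break[k] = True
    with np.errstate(invalid="ignore"):
        dist = np.linalg.norm(np.diff(chain.ca_coords, axis=0), axis=1)
    step_break |= dist > MAX_CA_CA
    for k in range(len(desc)):
        if step_break[k:k + 3].any():
            desc[k] = np.nan
    return desc


def encode_chains(chains: list[ChainRecord], model: AlphabetModel) -> dict[str, str]:
    """Step 3 (per chain): structural-letter string for every chain, by name."""
    out = {}
    for ch in chains:
        out[ch.name] = structural_alphabet.viterbi_encode(chain_descriptors(ch), model)
    return out


@dataclass
class PipelineResult:
    records: list[StructureRecord]
    chains: list[ChainRecord]
    msa: alignment.MSA
    msla: alignment.MSLA
    profiles: list[variability.ColumnProfile]
    summary: dict
    regions: list[variability.VariableRegion]
    output_dir: Path


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Execute steps 1-5 and write the full output bundle."""
    t0 = time.time()
    config.validate()
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    timings = {}

    def mark(stage):
        timings[stage] = round(time.time() - t0, 3)

    # step 1 — mining/description
    try:
        records, chains = collect_chains(config)
        structure_io.describe_set(records).to_csv(
            out_dir / "description.tsv", sep="\t", index=False)
    except StageError:
        raise
    except Exception as exc:
        raise StageError("describe", str(exc)) from exc
    mark("describe")

    # step 2 — sequences and MSA
    try:
        seq_records = alignment.extract_sequences(chains)
        alignment.write_fasta(seq_records, out_dir / "sequences.fasta")
        msa = alignment.load_or_compute_msa(chains, engine=config.msa_engine,
                                            msa_path=config.msa_path)
        with open(out_dir / "alignment.fasta", "w") as fh:
            for rid, row in zip(msa.ids, msa.rows):
                fh.write(f">{rid}\n{row}\n")
        corr = alignment.correspondence_table(msa)
        corr.to_csv(out_dir / "correspondence.tsv", sep="\t", index=False)
    except StageError:
        raise
    except Exception as exc:
        raise StageError("align", str(exc)) from exc
    mark("align")

    # step 3 — structural-letter encoding and MSLA
    try:
        model = _load_model(config)
        encodings = encode_chains(chains, model)
        msla = alignment.project_msla(msa, encodings)
        alignment.write_msla(msla, out_dir / "msla.fasta")
    except Exception as exc:
        raise StageError("encode", str(exc)) from exc
    mark("encode")

    # step 4 — variability profiles and regions
    try:
        profiles, summary = variability.profile_set(
            msa, msla, model, threshold_missing=config.missing_threshold)
        regions = variability.detect_regions(profiles, config.resolved_criteria())
        variability.profiles_table(profiles).to_csv(
            out_dir / "profiles.tsv", sep="\t", index=False)
        variability.regions_table(regions).to_csv(
            out_dir / "regions.tsv", sep="\t", index=False)
        (out_dir / "summary.json").write_text(json.dumps(summary, indent=1))
    except Exception as exc:
        raise StageError("variability", str(exc)) from exc
    mark("variability")

    # step 5 — figures and viewer script
    try:
        scheme = reporting.ColorScheme.default(model)
        reporting.render_maps(msa, msla, scheme, profiles, out_dir)
        reporting.render_neq_graph(profiles, regions, out_dir / "Neq_graph.pdf")
        ref_id = config.reference or msa.ids[0]
        ref_idx = msa.ids.index(ref_id)
        ref_chain = msa.chains[ref_idx]
        corr = alignment.correspondence_table(msa)
        col_to_res = {int(c): str(r) for c, r in
                      zip(corr["msa_position"], corr[ref_id]) if str(r)}
        muts = variability.mutated_columns(profiles)
        ref_record = next((rec for rec in records
                           if any(ch is ref_chain for ch in rec.chains)), None)
        het = ref_record.het_names if ref_record is not None else set()
        script = reporting.pymol_script(profiles, ref_chain, col_to_res, muts,
                                        het_names=het, scheme=scheme)
        (out_dir / "script_pymol.pml").write_text(script)
    except Exception as exc:
        raise StageError("report", str(exc)) from exc
    mark("report")

    log = {
        "saconf_version": __version__,
        "seed": config.seed,
        "n_structures": len(records),
        "n_chains": len(chains),
        "msa_engine": config.msa_engine,
        "criteria": vars(config.resolved_criteria()),
        "missing_threshold": config.missing_threshold,
        "timings_s": timings,
    }
    (out_dir / "run_log.json").write_text(json.dumps(log, indent=1))
    return PipelineResult(records=records, chains=chains, msa=msa, msla=msla,
                          profiles=profiles, summary=summary, regions=regions,
                          output_dir=out_dir)
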