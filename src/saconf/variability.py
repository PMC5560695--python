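"""Per-position sequence and structural variability of an aligned ensemble.

The variability index is the exponent of the Shannon entropy of the
symbol frequencies observed at an alignment column:

    neq(i) = exp( - sum_j freq_j(i) * ln freq_j(i) )

interpreted as the effective number of distinct symbols at position i.
Computed over amino acids it is neq_AA (1..20); over structural letters
it is neq_SL (1..27). neq = 1 marks a strictly conserved position;
1 < neq < 1.5 a weakly variable one; neq >= 1.5 variable, with >= 3
highly and >= 5 strongly variable. Columns where at least half the
chains lack data are left undefined.

Structurally variable *regions* are maximal stretches of columns whose
neq_SL stays above a threshold for a minimum run length, or single
columns spiking above a higher threshold; short sub-threshold
interruptions may be bridged.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .alignment import GAP, MSA, MSLA
from .structural_alphabet import MISSING, AlphabetModel

CONSERVED = "CONSERVED"
WEAK = "WEAK"
VARIABLE = "VARIABLE"
HIGH = "HIGH"
STRONG = "STRONG"
UNDEFINED = "UNDEFINED"
CHANGE = "CHANGE"

#: floating-point guard: neq within this of 1 counts as strictly conserved
CONSERVED_TOL = 1e-12


def neq(freqs) -> float:
    """Exponent of the Shannon entropy of a frequency vector.

    Natural logarithm; 0*ln(0) = 0. Frequencies must be non-negative
    and sum to 1 (tolerance 1e-9). Bounds: 1 <= neq <= support size,
    with equality at the uniform distribution.
    """
    f = np.asarray(freqs, dtype=float)
    if (f < 0).any():
        raise ValueError("frequencies must be non-negative")
    total = f.sum()
    if abs(total - 1.0) > 1e-9:
        raise ValueError(f"frequencies must sum to 1, got {total!r}")
    nz = f[f > 0]
    return float(np.exp(-(nz * np.log(nz)).sum()))


def _frequencies(symbols: list[str]) -> dict[str, float]:
    counts: dict[str, int] = {}
    for s in symbols:
        counts[s] = counts.get(s, 0) + 1
    n = len(symbols)
    return {s: c / n for s, c in counts.items()}


def classify(value: float | None) -> str:
    """Most specific variability class for a neq value."""
    if value is None:
        return UNDEFINED
    if abs(value - 1.0) <= CONSERVED_TOL:
        return CONSERVED
    if value < 1.5:
        return WEAK
    if value < 3.0:
        return VARIABLE
    if value < 5.0:
        return HIGH
    return STRONG


@dataclass
class ColumnProfile:
    """Variability summary of one alignment column (1-based index)."""

    column: int
    aa_freqs: dict[str, float]
    sl_freqs: dict[str, float]
    neq_aa: float | None
    neq_sl: float | None
    missing_frac: float
    aa_class: str
    sl_class: str
    ss_status: str


def column_profile(msa_col: list[str], msla_col: list[str],
                   model: AlphabetModel, column: int = 1,
                   threshold_missing: float = 0.5) -> ColumnProfile:
    """Profile one column of the paired MSA/MSLA.

    A chain counts as missing at this column when its amino-acid cell is
    a gap or its structural-letter cell carries the missing symbol (no
    structural information). When the missing fraction reaches
    ``threshold_missing`` both neq values are left undefined.
    Frequencies are computed over the observed symbols only — gaps and
    missing cells enter neither numerator nor denominator.
    """
    if len(msa_col) != len(msla_col):
        raise ValueError("MSA and MSLA columns differ in length")
    C = len(msa_col)
    missing = sum(1 for a, s in zip(msa_col, msla_col)
                  if a == GAP or s in (GAP, MISSING))
    missing_frac = missing / C
    aa_obs = [a for a in msa_col if a != GAP]
    sl_obs = [s for s in msla_col if s not in (GAP, MISSING)]
    if missing_frac >= threshold_missing:
        return ColumnProfile(column, {}, {}, None, None, missing_frac,
                             UNDEFINED, UNDEFINED, UNDEFINED)
    aa_freqs = _frequencies(aa_obs)
    sl_freqs = _frequencies(sl_obs)
    neq_aa = neq(list(aa_freqs.values())) if aa_freqs else None
    neq_sl = neq(list(sl_freqs.values())) if sl_freqs else None
    categories = {model.ss_category(s) for s in sl_freqs}
    if not categories:
        ss_status = UNDEFINED
    elif len(categories) == 1:
        ss_status = categories.pop()
    else:
        ss_status = CHANGE
    return ColumnProfile(column, aa_freqs, sl_freqs, neq_aa, neq_sl,
                         missing_frac, classify(neq_aa), classify(neq_sl),
                         ss_status)


@dataclass
class RegionCriteria:
    """Thresholds defining a structurally variable region.

    ``l``: minimum number of successive variable columns for a run
    trigger; ``t_var``: neq_SL at or above which a column is variable
    (1.5 by default, the class boundary); ``t_high``: neq_SL at or
    above which a single column alone seeds a region; ``max_gap``:
    longest sub-threshold interruption bridged when merging runs.
    """

    l: int = 4
    t_var: float = 1.5
    t_high: float = 4.0
    max_gap: int = 1

    def validate(self) -> None:
        if self.l < 1:
            raise ValueError("l must be >= 1")
        if not (self.t_high >= self.t_var > 1.0):
            raise ValueError("need t_high >= t_var > 1")
        if self.max_gap < 0:
            raise ValueError("max_gap must be >= 0")


#: per-dataset presets used in published analyses of this kind
PRESETS = {
    "uPA": RegionCriteria(l=4, t_var=1.5, t_high=4.0, max_gap=1),
    "P53": RegionCriteria(l=5, t_var=1.5, t_high=3.0, max_gap=1),
    "P53-NMR": RegionCriteria(l=7, t_var=1.5, t_high=5.0, max_gap=1),
    "PR1": RegionCriteria(l=4, t_var=1.5, t_high=4.0, max_gap=1),
}

RUN = "RUN"
SPIKE = "SPIKE"
BOTH = "BOTH"


@dataclass
class VariableRegion:
    """Maximal 1-based column interval satisfying the region criteria."""

    start: int
    end: int
    trigger: str
    mean_neq_sl: float

    @property
    def columns(self) -> range:
        return range(self.start, self.end + 1)


def detect_regions(profiles: list[ColumnProfile],
                   criteria: RegionCriteria) -> list[VariableRegion]:
    """Detect structurally variable regions along the profile series.

    A column is *variable* when its neq_SL is defined and >= t_var, and
    a *spike* when >= t_high. Maximal variable runs are merged across
    interruptions of at most ``max_gap`` defined sub-threshold columns
    (undefined columns never bridge). A merged cluster is kept when it
    contains a run of at least ``l`` successive variable columns (RUN),
    a spike column (SPIKE), or both (BOTH); its span runs from its first
    to its last variable column.
    """
    criteria.validate()
    values = [p.neq_sl for p in profiles]
    columns = [p.column for p in profiles]
    n = len(profiles)
    variable = [v is not None and v >= criteria.t_var for v in values]
    spike = [v is not None and v >= criteria.t_high for v in values]
    defined = [v is not None for v in values]

    # maximal runs of variable columns (by series index)
    runs: list[tuple[int, int]] = []
    i = 0
    while i < n:
        if variable[i]:
            j = i
            while j + 1 < n and variable[j + 1]:
                j += 1
            runs.append((i, j))
            i = j + 1
        else:
            i += 1
    # merge runs across short, fully defined, sub-threshold interruptions
    clusters: list[list[tuple[int, int]]] = []
    for run in runs:
        if clusters:
            prev_end = clusters[-1][-1][1]
            gap = range(prev_end + 1, run[0])
            if (len(gap) <= criteria.max_gap
                    and all(defined[g] for g in gap)):
                clusters[-1].append(run)
                continue
        clusters.append([run])
    regions = []
    for cluster in clusters:
        has_run = any(e - s + 1 >= criteria.l for s, e in cluster)
        has_spike = any(spike[k] for s, e in cluster for k in range(s, e + 1))
        if not (has_run or has_spike):
            continue
        start_i = cluster[0][0]
        end_i = cluster[-1][1]
        span_vals = [values[k] for k in range(start_i, end_i + 1)
                     if values[k] is not None]
        trigger = BOTH if (has_run and has_spike) else (RUN if has_run else SPIKE)
        regions.append(VariableRegion(start=columns[start_i], end=columns[end_i],
                                      trigger=trigger,
                                      mean_neq_sl=float(np.mean(span_vals))))
    return regions


def profile_set(msa: MSA, msla: MSLA, model: AlphabetModel,
                threshold_missing: float = 0.5) -> tuple[list[ColumnProfile], dict]:
    """Profile every column and summarize the set.

    The summary reports, separately for sequence and structure, the
    mean +/- sd (population denominator) and maximum of the defined neq
    values, and the count and percentage of strictly conserved columns
    among the defined ones.
    """
    if msa.n_rows != msla.n_rows or msa.n_cols != msla.n_cols:
        raise ValueError("MSA and MSLA are not congruent")
    profiles = []
    for c in range(msa.n_cols):
        msa_col = [row[c] for row in msa.rows]
        msla_col = [row[c] for row in msla.rows]
        profiles.append(column_profile(msa_col, msla_col, model,
                                       column=c + 1,
                                       threshold_missing=threshold_missing))
    summary = {"n_positions": len(profiles)}
    for tag, attr in (("aa", "neq_aa"), ("sl", "neq_sl")):
        vals = np.array([getattr(p, attr) for p in profiles
                         if getattr(p, attr) is not None])
        n_def = len(vals)
        conserved = int((np.abs(vals - 1.0) <= CONSERVED_TOL).sum()) if n_def else 0
        summary[f"n_defined_{tag}"] = n_def
        summary[f"mean_neq_{tag}"] = float(vals.mean()) if n_def else None
        summary[f"sd_neq_{tag}"] = float(vals.std()) if n_def else None
        summary[f"max_neq_{tag}"] = float(vals.max()) if n_def else None
        summary[f"n_conserved_{tag}"] = conserved
        summary[f"pct_conserved_{tag}"] = (100.0 * conserved / n_def) if n_def else None
    return profiles, summary


def profiles_table(profiles: list[ColumnProfile]) -> pd.DataFrame:
    rows = []
    for p in profiles:
        rows.append({
            "column": p.column,
            "neq_aa": p.neq_aa if p.neq_aa is not None else "",
            "neq_sl": p.neq_sl if p.neq_sl is not None else "",
            "aa_class": p.aa_class,
            "sl_class": p.sl_class,
            "ss_status": p.ss_status,
            "missing_frac": p.missing_frac,
        })
    return pd.DataFrame(rows)


def regions_table(regions: list[VariableRegion]) -> pd.DataFrame:
    return pd.DataFrame([{
        "region": f"R{i + 1}",
        "start": r.start,
        "end": r.end,
        "trigger": r.trigger,
        "mean_neq_sl": r.mean_neq_sl,
    } for i, r in enumerate(regions)],
        columns=["region", "start", "end", "trigger", "mean_neq_sl"])


def mutated_columns(profiles: list[ColumnProfile]) -> set[int]:
    """Columns with any amino-acid variability (neq_AA > 1)."""
    return {p.column for p in profiles
            if p.neq_aa is not None and p.neq_aa > 1.0 + CONSERVED_TOL}
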