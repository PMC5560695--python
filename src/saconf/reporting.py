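"""Graphical and molecular-viewer outputs.

Three renderings close the analysis: color-grid maps of the MSA and
MSLA (AA_alignment.pdf / SL_alignment.pdf), the paired neq_AA / neq_SL
bar graphic with secondary-structure coloring and region rectangles
(Neq_graph.pdf), and a PyMOL script (script_pymol.pml) that colors a
reference 3D structure by the structural variability class of each
position, shows mutated positions as sticks and renders ligand HETATM
groups distinctly.

Every figure is accompanied by a JSON sidecar carrying the exact values
plotted, so rendering is testable; the viewer script is deterministic
plain text.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np

from .alignment import MSA, MSLA
from .structural_alphabet import HELIX, LOOP, MISSING, STRAND, AlphabetModel
from .structure_io import ChainRecord
from .variability import (CHANGE, CONSERVED, UNDEFINED, WEAK,
                          ColumnProfile, VariableRegion)

AA_ORDER = "ACDEFGHIKLMNPQRSTVWY"

SS_COLORS = {HELIX: "#d62728", STRAND: "#2ca02c", LOOP: "#7f7f7f",
             CHANGE: "#9467bd", UNDEFINED: "#dddddd"}

#: variability classes on the 3D structure, legend vocabulary:
#: conserved magenta, weakly variable cyan, variable without a
#: secondary-structure change navy, variable with a change dark blue
VARIABILITY_COLORS = {
    "conserved": "#ff00ff",
    "weak": "#00ffff",
    "variable_no_ss_change": "#1f3d99",
    "variable_ss_change": "#00008b",
    "undefined": "#c8c8c8",
}


def _helix_shades(n):
    return [plt.cm.Reds(0.45 + 0.5 * k / max(n - 1, 1)) for k in range(n)]


def _strand_shades(n):
    return [plt.cm.Greens(0.45 + 0.5 * k / max(n - 1, 1)) for k in range(n)]


def _loop_shades(n):
    return [plt.cm.viridis(0.05 + 0.9 * k / max(n - 1, 1)) for k in range(n)]


@dataclass
class ColorScheme:
    """Palettes for the alignment maps and variability classes."""

    aa_palette: dict[str, str] = field(default_factory=dict)
    sl_palette: dict[str, str] = field(default_factory=dict)
    variability_palette: dict[str, str] = field(
        default_factory=lambda: dict(VARIABILITY_COLORS))

    @classmethod
    def default(cls, model: AlphabetModel) -> "ColorScheme":
        aa = {a: matplotlib.colors.to_hex(plt.cm.tab20(i / 20))
              for i, a in enumerate(AA_ORDER)}
        aa["X"] = "#000000"
        helix = [l for l in model.labels if model.ss_category(l) == HELIX]
        strand = [l for l in model.labels if model.ss_category(l) == STRAND]
        loop = [l for l in model.labels if model.ss_category(l) == LOOP]
        sl = {}
        for letters, shades in ((helix, _helix_shades(len(helix))),
                                (strand, _strand_shades(len(strand))),
                                (loop, _loop_shades(len(loop)))):
            for letter, color in zip(letters, shades):
                sl[letter] = matplotlib.colors.to_hex(color)
        return cls(aa_palette=aa, sl_palette=sl)

    def to_json(self) -> str:
        return json.dumps({"aa_palette": self.aa_palette,
                           "sl_palette": self.sl_palette,
                           "variability_palette": self.variability_palette},
                          indent=1, sort_keys=True)


def variability_class(profile: ColumnProfile) -> str:
    """Map a column profile onto the four 3D-coloring classes."""
    if profile.sl_class == UNDEFINED:
        return "undefined"
    if profile.sl_class == CONSERVED:
        return "conserved"
    if profile.sl_class == WEAK:
        return "weak"
    if profile.ss_status == CHANGE:
        return "variable_ss_change"
    return "variable_no_ss_change"


def _grid_figure(rows: list[str], ids: list[str], palette: dict[str, str],
                 classes: list[str], class_palette: dict[str, str],
                 title: str, out: Path) -> None:
    n_rows, n_cols = len(rows), len(rows[0])
    rgb = np.ones((n_rows + 1, n_cols, 3))
    for r, row in enumerate(rows):
        for c, cell in enumerate(row):
            if cell in palette:
                rgb[r, c] = matplotlib.colors.to_rgb(palette[cell])
            elif cell == MISSING:
                rgb[r, c] = (0.85, 0.85, 0.85)
    for c, cls in enumerate(classes):
        rgb[n_rows, c] = matplotlib.colors.to_rgb(class_palette[cls])
    fig, ax = plt.subplots(figsize=(max(4, n_cols / 12), max(2, (n_rows + 1) / 10)))
    ax.imshow(rgb, aspect="auto", interpolation="nearest")
    ax.set_title(title)
    ax.set_xlabel("alignment position")
    ax.set_ylabel("chain")
    ax.set_yticks([])
    fig.savefig(out, bbox_inches="tight")
    plt.close(fig)


def _aa_strip_class(p: ColumnProfile) -> str:
    if p.aa_class == UNDEFINED:
        return "undefined"
    if p.aa_class == CONSERVED:
        return "conserved"
    if p.aa_class == WEAK:
        return "weak"
    return "variable_no_ss_change"


def render_maps(msa: MSA, msla: MSLA, scheme: ColorScheme,
                profiles: list[ColumnProfile], out_prefix: str | Path) -> tuple[Path, Path]:
    """Render AA_alignment.pdf and SL_alignment.pdf with class strips.

    Each map is a rows-by-columns color grid (chains by alignment
    positions) with a one-row strip beneath showing the per-column
    variability class. A JSON sidecar records the symbols and classes.
    """
    if msa.n_rows == 0 or msa.n_cols == 0:
        raise ValueError("cannot render an empty alignment")
    out_prefix = Path(out_prefix)
    out_prefix.mkdir(parents=True, exist_ok=True)
    aa_classes = [_aa_strip_class(p) for p in profiles]
    sl_classes = [variability_class(p) for p in profiles]
    aa_pdf = out_prefix / "AA_alignment.pdf"
    sl_pdf = out_prefix / "SL_alignment.pdf"
    _grid_figure(msa.rows, msa.ids, scheme.aa_palette, aa_classes,
                 scheme.variability_palette, "Amino-acid alignment (MSA)", aa_pdf)
    _grid_figure(msla.rows, msla.ids, scheme.sl_palette, sl_classes,
                 scheme.variability_palette, "Structural-letter alignment (MSLA)", sl_pdf)
    sidecar = {
        "ids": msa.ids,
        "msa_rows": msa.rows,
        "msla_rows": msla.rows,
        "aa_class_strip": aa_classes,
        "sl_class_strip": sl_classes,
        "aa_palette": scheme.aa_palette,
        "sl_palette": scheme.sl_palette,
    }
    (out_prefix / "alignment_maps.json").write_text(
        json.dumps(sidecar, indent=1, sort_keys=True))
    return aa_pdf, sl_pdf


def render_neq_graph(profiles: list[ColumnProfile],
                     regions: list[VariableRegion], out: str | Path) -> Path:
    """Render Neq_graph.pdf: neq_SL bars above, neq_AA bars below.

    neq_SL bars are colored by secondary-structure status (helix red,
    strand green, loop gray, change purple); detected regions appear as
    rectangles. The sidecar holds the exact bar heights and colors.
    """
    if not profiles:
        raise ValueError("need at least one column profile")
    out = Path(out)
    cols = [p.column for p in profiles]
    neq_sl = [p.neq_sl if p.neq_sl is not None else 0.0 for p in profiles]
    neq_aa = [p.neq_aa if p.neq_aa is not None else 0.0 for p in profiles]
    ss_colors = [SS_COLORS[p.ss_status] for p in profiles]
    fig, (ax_sl, ax_aa) = plt.subplots(
        2, 1, sharex=True, figsize=(max(6, len(cols) / 15), 5))
    ax_sl.bar(cols, neq_sl, color=ss_colors, width=1.0)
    ax_sl.set_ylabel("neq_SL")
    for reg in regions:
        ax_sl.axvspan(reg.start - 0.5, reg.end + 0.5, color="#1f77b4", alpha=0.18)
    ax_aa.bar(cols, neq_aa, color="#444444", width=1.0)
    ax_aa.invert_yaxis()
    ax_aa.set_ylabel("neq_AA")
    ax_aa.set_xlabel("alignment position")
    fig.savefig(out, bbox_inches="tight")
    plt.close(fig)
    sidecar = {
        "columns": cols,
        "neq_sl": [p.neq_sl for p in profiles],
        "neq_aa": [p.neq_aa for p in profiles],
        "ss_status": [p.ss_status for p in profiles],
        "bar_colors_sl": ss_colors,
        "regions": [{"start": r.start, "end": r.end, "trigger": r.trigger}
                    for r in regions],
    }
    out.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))
    return out


def pymol_script(profiles: list[ColumnProfile], reference: ChainRecord,
                 column_to_residue: dict[int, str],
                 mutated_columns: set[int],
                 het_names: set[str] | None = None,
                 scheme: ColorScheme | None = None) -> str:
    """PyMOL commands coloring the reference chain by variability class.

    ``column_to_residue`` maps 1-based alignment columns to the
    reference chain's author residue numbers (from the correspondence
    table); columns absent from the reference are skipped. Mutated
    positions are shown as sticks; ligand HETATM groups are shown as
    sticks in a distinct color. Output is deterministic plain text.
    """
    palette = (scheme.variability_palette if scheme is not None
               else dict(VARIABILITY_COLORS))
    lines = [
        "# structural-variability coloring of the reference chain",
        f"# reference: {reference.name or reference.chain_id}",
        "hide everything",
        "show cartoon",
        "color grey80",
    ]
    for name, hexcolor in sorted(palette.items()):
        rgb = matplotlib.colors.to_rgb(hexcolor)
        lines.append(f"set_color saconf_{name}, [{rgb[0]:.4f}, {rgb[1]:.4f}, {rgb[2]:.4f}]")
    chain_sel = f"chain {reference.chain_id}"
    skipped = []
    for p in profiles:
        resi = column_to_residue.get(p.column)
        if not resi:
            skipped.append(p.column)
            continue
        cls = variability_class(p)
        lines.append(f"color saconf_{cls}, {chain_sel} and resi {resi}")
        if p.column in mutated_columns:
            lines.append(f"show sticks, {chain_sel} and resi {resi}")
    for het in sorted(het_names or ()):
        lines.append(f"show sticks, resn {het}")
        lines.append(f"color yellow, resn {het}")
    if skipped:
        lines.append(f"# columns absent from the reference chain: "
                     f"{','.join(str(c) for c in skipped)}")
    return "\n".join(lines) + "\n"
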