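"""Color-coded sequence maps of modification frequencies.

Each row is one sample/timepoint, each column one canonical residue; the cell
color interpolates linearly in RGB from cyan (0% modified) to magenta (100%).
Isoform-absent positions (spliced-out inserts) render as true gaps and
no-coverage positions as grey, so "not observed" is never confused with
"observed unmodified" (0%, cyan).

The per-cell color table (CSV) is the deterministic, testable contract; the
SVG is a cosmetic rendering of the same table.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .ptm import ModFrequencyMap

RGB = tuple[int, int, int]

CYAN: RGB = (0, 255, 255)
MAGENTA: RGB = (255, 0, 255)
NO_COVERAGE_GREY = "#d9d9d9"


@dataclass
class SequenceMapSpec:
    """Layout and color conventions for a sequence map."""

    canonical_sequence: str
    row_order: Optional[Sequence[str]] = None
    color_zero: RGB = CYAN
    color_one: RGB = MAGENTA
    cell_size: int = 10
    wrap: int = 60  # residues per visual line block in the SVG


def interpolate_color(f: float, c0: RGB = CYAN, c1: RGB = MAGENTA) -> str:
    """Linear RGB interpolation, channel = round-half-up(c0 + f*(c1-c0)).

    f=0 gives exactly the cyan anchor, f=1 exactly magenta; the parameter is
    monotone in f on every channel.
    """
    if not 0.0 <= f <= 1.0:
        raise ValueError(f"frequency {f} outside [0, 1]")
    channels = (int(a + f * (b - a) + 0.5) for a, b in zip(c0, c1))
    return "#%02x%02x%02x" % tuple(channels)


def color_table(
    maps: dict[str, ModFrequencyMap], spec: SequenceMapSpec
) -> pd.DataFrame:
    """Deterministic per-cell table: (row, position, residue, frequency, color,
    status). status is covered / no_coverage / absent; only covered cells get a
    frequency and an interpolated color."""
    mod_types = {m.mod_type for m in maps.values()}
    if len(mod_types) > 1:
        raise ValueError(
            f"maps mix modification types {sorted(mod_types)}; render each type "
            "as its own panel"
        )
    rows = list(spec.row_order) if spec.row_order is not None else sorted(maps)
    unknown = [r for r in rows if r not in maps]
    if unknown:
        raise KeyError(f"row_order names absent from maps: {unknown}")
    records = []
    seq = spec.canonical_sequence
    for row in rows:
        fmap = maps[row]
        freq = fmap.frequency
        for pos in range(1, fmap.length + 1):
            if not fmap.mappable[pos - 1]:
                status, color, f = "absent", "", np.nan
            elif not fmap.covered[pos - 1]:
                status, color, f = "no_coverage", NO_COVERAGE_GREY, np.nan
            else:
                f = float(freq[pos - 1])
                status = "covered"
                color = interpolate_color(f, spec.color_zero, spec.color_one)
            records.append(
                {
                    "row": row,
                    "canonical_position": pos,
                    "residue_letter": seq[pos - 1] if pos <= len(seq) else "",
                    "frequency": f,
                    "color": color,
                    "status": status,
                }
            )
    return pd.DataFrame(records)


def _svg_escape(text: str) -> str:
    return text.replace("&", "&amp;").replace("<", "&lt;").replace(">", "&gt;")


def render(
    maps: dict[str, ModFrequencyMap],
    spec: SequenceMapSpec,
    svg_path=None,
    table_path=None,
    footer: str = "",
) -> tuple[str, pd.DataFrame]:
    """Render maps as an SVG sequence map plus the per-cell color table.

    Returns (svg_text, table). Absent positions are left blank (gap);
    no-coverage positions are grey. The SVG wraps the sequence into blocks of
    ``spec.wrap`` residues, one lane of rows per block.
    """
    table = color_table(maps, spec)
    rows = list(dict.fromkeys(table["row"]))
    length = int(table["canonical_position"].max())
    cs = spec.cell_size
    wrap = spec.wrap
    n_blocks = (length + wrap - 1) // wrap
    label_w = 14 * max((len(r) for r in rows), default=1)
    lane_h = (len(rows) + 2) * cs  # rows + residue ruler + spacing
    width = label_w + wrap * cs + 10
    height = n_blocks * lane_h + cs

    parts = [
        f'<svg xmlns="http://www.w3.org/2000/svg" width="{width}" '
        f'height="{height}" font-family="monospace" font-size="{cs - 2}">'
    ]
    by_cell = {
        (r.row, r.canonical_position): r for r in table.itertuples(index=False)
    }
    for block in range(n_blocks):
        y0 = block * lane_h + cs
        start = block * wrap + 1
        end = min(start + wrap - 1, length)
        parts.append(
            f'<text x="{label_w}" y="{y0 - 2}" text-anchor="end" '
            f'fill="#555">{start}-{end}</text>'
        )
        for ri, row in enumerate(rows):
            y = y0 + ri * cs
            parts.append(
                f'<text x="{label_w - 4}" y="{y + cs - 2}" '
                f'text-anchor="end">{_svg_escape(row)}</text>'
            )
            for pos in range(start, end + 1):
                cell = by_cell[(row, pos)]
                if cell.status == "absent":
                    continue  # true gap
                x = label_w + (pos - start) * cs
                parts.append(
                    f'<rect x="{x}" y="{y}" width="{cs}" height="{cs}" '
                    f'fill="{cell.color}" stroke="#ffffff" stroke-width="0.5"/>'
                )
    if footer:
        parts.append(f"<!-- {_svg_escape(footer)} -->")
    parts.append("</svg>")
    svg_text = "\n".join(parts) + "\n"

    if svg_path is not None:
        with open(svg_path, "w") as fh:
            fh.write(svg_text)
    if table_path is not None:
        with open(table_path, "w") as fh:
            if footer:
                fh.write(f"# {footer}\n")
            table.to_csv(fh, index=False)
    return svg_text, table
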