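"""Convergent (lineage-specific) substitution scan over a protein MSA.

A column is called when a foreground clade shares one residue that differs
from a residue conserved across the background taxa — the signature of a
substitution fixed independently in the foreground lineage(s) while the rest
of the phylogeny retains the ancestral state.

Column calls require, in order:
  (a) a strict-majority background consensus present in at least
      ``bg_conservation_min`` of the considered background taxa (ties mean
      no consensus and reject the column);
  (b) unanimity of the foreground residue (or a strict foreground majority
      when ``fg_unanimity`` is off);
  (c) foreground residue != background consensus;
  (d) gap handling: with ``allow_gaps`` gapped taxa are excluded from the
      fractions (a partition side left empty by gaps rejects the column);
      without it any gap rejects the column.

Columns are reported in original 1-based alignment coordinates, gaps
included in the numbering.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import pandas as pd

from .io import Msa

__all__ = ["ConvergentSite", "scan_columns", "column_report"]

GAP = "-"


@dataclass(frozen=True)
class ConvergentSite:
    column: int  # 1-based alignment column
    background_residue: str
    foreground_residue: str
    background_conservation: float  # fraction of considered background taxa


def _consensus(residues: list[str]) -> tuple[str, float] | None:
    """Strict-majority residue and its fraction; None on tie or empty input."""
    if not residues:
        return None
    counts = Counter(residues)
    ranked = counts.most_common()
    if len(ranked) > 1 and ranked[0][1] == ranked[1][1]:
        return None
    res, n = ranked[0]
    return res, n / len(residues)


def scan_columns(
    msa: Msa,
    bg_conservation_min: float = 1.0,
    fg_unanimity: bool = True,
    allow_gaps: bool = False,
) -> list[ConvergentSite]:
    """Scan every alignment column for foreground-specific substitutions."""
    if not msa.foreground or not msa.background:
        raise ValueError("both foreground and background taxa are required")
    if not 0 < bg_conservation_min <= 1:
        raise ValueError("bg_conservation_min must be in (0, 1]")
    fg = sorted(msa.foreground)
    bg = sorted(msa.background)
    sites: list[ConvergentSite] = []
    for col in range(1, msa.length + 1):
        residues = msa.column(col)
        fg_res = [residues[t] for t in fg]
        bg_res = [residues[t] for t in bg]
        if GAP in fg_res or GAP in bg_res:
            if not allow_gaps:
                continue
            fg_res = [r for r in fg_res if r != GAP]
            bg_res = [r for r in bg_res if r != GAP]
            if not fg_res or not bg_res:
                continue
        bg_cons = _consensus(bg_res)
        if bg_cons is None:
            continue
        bg_residue, bg_fraction = bg_cons
        if bg_fraction < bg_conservation_min:
            continue
        if fg_unanimity:
            if len(set(fg_res)) != 1:
                continue
            fg_residue = fg_res[0]
        else:
            fg_cons = _consensus(fg_res)
            if fg_cons is None:
                continue
            fg_residue = fg_cons[0]
        if fg_residue == bg_residue:
            continue
        sites.append(ConvergentSite(col, bg_residue, fg_residue, bg_fraction))
    return sites


def column_report(sites: list[ConvergentSite], msa: Msa) -> pd.DataFrame:
    """One row per called site with per-taxon residues; TSV round-trippable."""
    taxa = sorted(msa.foreground) + sorted(msa.background) + sorted(
        set(msa.sequences) - msa.foreground - msa.background
    )
    rows = []
    for s in sites:
        if not 1 <= s.column <= msa.length:
            raise ValueError(f"site column {s.column} outside alignment")
        residues = msa.column(s.column)
        row = {
            "column": s.column,
            "background_residue": s.background_residue,
            "foreground_residue": s.foreground_residue,
            "background_conservation": s.background_conservation,
        }
        row.update({t: residues[t] for t in taxa})
        rows.append(row)
    cols = [
        "column",
        "background_residue",
        "foreground_residue",
        "background_conservation",
    ] + taxa
    return pd.DataFrame(rows, columns=cols)
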