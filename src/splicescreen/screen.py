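"""Single-cell junction screening: junction references, read matching, and
cell-type specificity calls.

Reads are assigned to junction references by exact substring matching in
either orientation, requiring a minimum overhang on both sides of the
junction midpoint — the same junction-spanning evidence an aligner-based
screen establishes, made exact because the synthetic reads are error-free.
The specificity rule is zero-tolerance: a single junction-spanning read from
a glia, immune or endothelial cell vetoes the junction.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from Bio.Seq import Seq

from .simulate import CELL_TYPES, NEOPLASTIC_TYPES, NON_MALIGNANT_TYPES


@dataclass(frozen=True)
class JunctionReference:
    """Spliced sequence window around one junction (up to 300 nt per side)."""

    junction_id: str
    sequence: str
    midpoint: int


@dataclass
class CellJunctionMatrix:
    counts: pd.DataFrame  # cells x junctions, junction-spanning read counts
    cell_types: pd.Series  # barcode -> cell type

    def __post_init__(self):
        missing = set(self.counts.index) - set(self.cell_types.index)
        if missing:
            raise ValueError(f"barcodes without a cell type: {sorted(missing)[:3]}...")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("negative counts")


def _best_hit(
    seq: str, references: Sequence[JunctionReference], min_overhang: int
) -> Optional[str]:
    """Best junction for one read: largest two-sided overhang, ties by id."""
    best: Optional[tuple[int, str]] = None
    for orient in (seq, str(Seq(seq).reverse_complement())):
        L = len(orient)
        for ref in references:
            start = ref.sequence.find(orient)
            while start != -1:
                left = ref.midpoint - start
                right = start + L - ref.midpoint
                over = min(left, right)
                if over >= min_overhang:
                    cand = (over, ref.junction_id)
                    if best is None or over > best[0] or (over == best[0] and cand[1] < best[1]):
                        best = cand
                start = ref.sequence.find(orient, start + 1)
    return None if best is None else best[1]


def match_reads(
    reads: Iterable[tuple[str, str]],
    references: Sequence[JunctionReference],
    cell_types: pd.Series,
    min_overhang: int = 10,
) -> CellJunctionMatrix:
    """Count junction-spanning reads per cell.

    ``reads`` yields (read_name, sequence) with the cell barcode before the
    first ``|`` of the name. A read counts for at most one junction.
    """
    refs = sorted(references, key=lambda r: r.junction_id)
    jids = [r.junction_id for r in refs]
    counts = pd.DataFrame(0, index=cell_types.index, columns=jids, dtype=int)
    for name, seq in reads:
        if len(seq) < 2 * min_overhang:
            continue
        barcode = name.split("|", 1)[0]
        if barcode not in counts.index:
            continue
        hit = _best_hit(seq, refs, min_overhang)
        if hit is not None:
            counts.loc[barcode, hit] += 1
    return CellJunctionMatrix(counts=counts, cell_types=cell_types)


def cell_type_frequencies(matrix: CellJunctionMatrix) -> pd.DataFrame:
    """Fraction of cells of each type with >= 1 junction-spanning read.

    Long format: junction_id, cell_type, n_cells, n_expressing, fraction.
    Cell types with zero cells get a missing fraction.
    """
    if matrix.counts.shape[1] == 0:
        return pd.DataFrame(
            columns=["junction_id", "cell_type", "n_cells", "n_expressing", "fraction"]
        )
    rows = []
    for ct in CELL_TYPES:
        barcodes = matrix.cell_types.index[matrix.cell_types == ct]
        n_cells = len(barcodes)
        expressed = (matrix.counts.loc[barcodes] > 0).sum(axis=0) if n_cells else None
        for jid in matrix.counts.columns:
            n_expr = int(expressed[jid]) if n_cells else 0
            rows.append(
                {
                    "junction_id": jid,
                    "cell_type": ct,
                    "n_cells": n_cells,
                    "n_expressing": n_expr,
                    "fraction": n_expr / n_cells if n_cells else np.nan,
                }
            )
    return pd.DataFrame(rows)


def _freq_lookup(frequencies: pd.DataFrame, junction_id: str) -> pd.DataFrame:
    sub = frequencies[frequencies["junction_id"] == junction_id]
    if sub.empty:
        raise KeyError(f"no frequency rows for {junction_id}")
    return sub.set_index("cell_type")


def neoplastic_specific(
    junction_id: str, frequencies: pd.DataFrame, min_neoplastic_cells: int = 1
) -> bool:
    """True iff enough neoplastic cells express the junction and not a single
    glia, immune or endothelial cell does."""
    sub = _freq_lookup(frequencies, junction_id)
    n_neo = int(sub.loc[list(NEOPLASTIC_TYPES), "n_expressing"].sum())
    n_other = int(sub.loc[list(NON_MALIGNANT_TYPES), "n_expressing"].sum())
    return n_neo >= min_neoplastic_cells and n_other == 0


def stem_enrichment(junction_id: str, frequencies: pd.DataFrame) -> float:
    """Ratio of stem-like to differentiated expression fractions.

    Returns inf when only stem cells express the junction and NaN when
    neither compartment does (undefined).
    """
    sub = _freq_lookup(frequencies, junction_id)
    stem = float(sub.loc["neoplastic-stem", "fraction"])
    diff = float(sub.loc["neoplastic-differentiated", "fraction"])
    if np.isnan(stem) or np.isnan(diff):
        return np.nan
    if diff == 0:
        return np.inf if stem > 0 else np.nan
    return stem / diff
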