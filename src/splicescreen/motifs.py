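"""RNA-binding-protein motif scanning over differentially spliced regions.

Motifs are position weight matrices scored as log-odds in bits against a
background base composition. Scanning runs over spliced transcript (sense)
sequence, optionally with intron flanks, since binding sites are reported in
coding, untranslated and intronic regions alike. The default acceptance
threshold is 80% of a motif's maximal achievable score.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3, "U": 3}


@dataclass(frozen=True)
class MotifModel:
    motif_id: str
    rbp_name: str
    pwm: np.ndarray  # (length, 4) column-stochastic per position
    background: np.ndarray = None  # (4,)
    score_threshold: Optional[float] = None  # bits; None -> 80% of max

    def __post_init__(self):
        if self.background is None:
            object.__setattr__(self, "background", np.full(4, 0.25))
        pwm = np.asarray(self.pwm, dtype=float)
        if pwm.ndim != 2 or pwm.shape[1] != 4:
            raise ValueError("pwm must be (length, 4)")
        if not np.allclose(pwm.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("each PWM position must sum to 1")
        if not np.isclose(self.background.sum(), 1.0, atol=1e-9):
            raise ValueError("background must sum to 1")

    def __len__(self) -> int:
        return self.pwm.shape[0]

    @property
    def log_odds(self) -> np.ndarray:
        return np.log2(self.pwm / self.background[None, :])

    @property
    def max_score(self) -> float:
        return float(self.log_odds.max(axis=1).sum())

    @property
    def effective_threshold(self) -> float:
        if self.score_threshold is not None:
            return self.score_threshold
        return 0.8 * self.max_score

    @property
    def consensus(self) -> str:
        return "".join("ACGT"[i] for i in self.pwm.argmax(axis=1))


def scan_pwm(sequence: str, motif: MotifModel) -> list[tuple[int, float]]:
    """Log-odds scan of the sense strand; hits where score >= threshold.

    Ambiguous bases contribute 0 bits (scored as background).
    """
    m = len(motif)
    if len(sequence) < m:
        raise ValueError("sequence shorter than motif")
    lut = np.vstack([motif.log_odds.T, np.zeros((1, m))])  # row 4 = ambiguous
    idx = np.array([_BASE_INDEX.get(b, 4) for b in sequence.upper()])
    n_off = len(sequence) - m + 1
    scores = np.zeros(n_off)
    for i in range(m):
        scores += lut[idx[i : i + n_off], i]
    thr = motif.effective_threshold
    return [(int(o), float(s)) for o, s in enumerate(scores) if s >= thr]


def read_pwms(path: str | Path) -> list[MotifModel]:
    """Load motifs from JASPAR-like tabular text.

    Format per motif: a ``>motif_id rbp_name`` header followed by four rows
    ``A/C/G/T(or U)`` of counts or probabilities; counts are converted with a
    0.25 pseudocount.
    """
    motifs = []
    header: Optional[tuple[str, str]] = None
    rows: dict[str, list[float]] = {}

    def _flush():
        if header is None:
            return
        missing = {b for b in "ACGT" if b not in rows}
        if missing:
            raise ValueError(f"motif {header[0]}: missing base rows {sorted(missing)}")
        mat = np.array([rows[b] for b in "ACGT"]).T  # (length, 4)
        if not np.allclose(mat.sum(axis=1), 1.0, atol=1e-6):
            mat = mat + 0.25  # counts: pseudocount then normalize
        mat = mat / mat.sum(axis=1, keepdims=True)
        motifs.append(MotifModel(header[0], header[1], mat))

    for raw in Path(path).read_text().splitlines():
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if line.startswith(">"):
            _flush()
            parts = line[1:].split()
            header = (parts[0], parts[1] if len(parts) > 1 else parts[0])
            rows = {}
        else:
            parts = line.replace("[", " ").replace("]", " ").split()
            base = parts[0].upper().replace("U", "T")
            rows[base] = [float(x) for x in parts[1:]]
    _flush()
    return motifs


def bundled_motifs() -> list[MotifModel]:
    """The small toy motif set shipped with the package."""
    return read_pwms(Path(__file__).parent / "data" / "toy_motifs.txt")


def summarize_hits(hits: pd.DataFrame) -> tuple[pd.Series, pd.DataFrame]:
    """Region distribution and per-motif frequency ranking.

    ``hits`` needs columns motif_id, gene_id, region_class. The region
    distribution sums to 1 over the observed classes; motifs are ranked by
    number of distinct genes hit, ties by total hits then motif_id.
    """
    if hits.empty:
        return pd.Series(dtype=float), pd.DataFrame(
            columns=["motif_id", "n_genes", "n_hits"]
        )
    region = hits["region_class"].value_counts(normalize=True).sort_index()
    per_motif = (
        hits.groupby("motif_id")
        .agg(n_genes=("gene_id", "nunique"), n_hits=("gene_id", "size"))
        .reset_index()
        .sort_values(
            by=["n_genes", "n_hits", "motif_id"], ascending=[False, False, True]
        )
        .reset_index(drop=True)
    )
    return region, per_motif


def exon_motif_enrichment(
    exon: tuple[int, int],
    gene: tuple[int, int],
    hit_positions: Sequence[int],
) -> Optional[float]:
    """Hit density (per kb) inside an exon relative to the whole gene.

    Positions are genomic hit starts. Returns None when the gene has no hits
    (enrichment undefined).
    """
    es, ee = exon
    gs, ge = gene
    if not (gs <= es < ee <= ge):
        raise ValueError("exon must lie within the gene")
    pos = np.asarray(list(hit_positions))
    n_gene = int(((pos >= gs) & (pos < ge)).sum())
    if n_gene == 0:
        return None
    n_exon = int(((pos >= es) & (pos < ee)).sum())
    exon_density = n_exon / ((ee - es) / 1000.0)
    gene_density = n_gene / ((ge - gs) / 1000.0)
    return exon_density / gene_density
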