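"""Junction-spanning nucleotide windows, three-frame neopeptides, and
peptide-database confirmation with decoy-estimated FDR.

Windows are symmetric in spliced (mRNA) coordinates — ``flank`` bases on each
side of the junction in coding orientation — so every derived peptide crosses
the splice. The mass-spectrometry search the confirmation step stands in for
is reduced to exact peptide matching against a plain peptide list, keeping
the decision rule: hits are accepted only while the decoy-estimated false
discovery rate stays at or below 0.05.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from Bio.Seq import Seq

from .coords import IncompatibleJunction, Junction, TranscriptModel


@dataclass(frozen=True)
class JunctionWindow:
    junction_id: str
    flank: int
    sequence: str  # spliced, coding orientation
    actual_left: int
    actual_right: int

    def __post_init__(self):
        if len(self.sequence) != self.actual_left + self.actual_right:
            raise ValueError("window length inconsistent with flank bookkeeping")
        if max(self.actual_left, self.actual_right) > self.flank:
            raise ValueError("flank overrun")

    @property
    def midpoint(self) -> int:
        """The junction sits between positions midpoint-1 and midpoint."""
        return self.actual_left


@dataclass(frozen=True)
class NeopeptideSet:
    junction_id: str
    peptides: tuple[tuple[int, str, bool], ...]  # (frame, peptide, spans_junction)


@dataclass(frozen=True)
class ConfirmationResult:
    junction_id: str
    peptide: str
    matched: bool
    decoy_hit: bool
    passes_fdr: bool


def junction_window(
    genome: dict[str, str],
    transcript: TranscriptModel,
    junction: Junction,
    flank: int = 24,
) -> JunctionWindow | IncompatibleJunction:
    """Spliced window of up to ``flank`` bases either side of a junction.

    Works for junctions absent from the transcript (e.g. exon skipping): the
    window is the transcript prefix ending at the donor joined to the suffix
    starting at the acceptor, so intervening exons are excised. Truncation at
    transcript ends is recorded in ``actual_left``/``actual_right``.
    """
    if flank < 1:
        raise ValueError("flank must be >= 1")
    if transcript.contig != junction.contig or transcript.strand != junction.strand:
        return IncompatibleJunction(junction.key, transcript.transcript_id, "contig/strand mismatch")
    t_don = transcript.genomic_to_transcript(junction.donor_last_base)
    t_acc = transcript.genomic_to_transcript(junction.acceptor_first_base)
    if t_don is None or t_acc is None:
        return IncompatibleJunction(junction.key, transcript.transcript_id, "not exonic")
    if t_acc <= t_don:
        return IncompatibleJunction(
            junction.key, transcript.transcript_id, "acceptor not downstream of donor"
        )
    seq = transcript.spliced_sequence(genome)
    left = seq[max(0, t_don + 1 - flank) : t_don + 1]
    right = seq[t_acc : t_acc + flank]
    return JunctionWindow(
        junction_id=junction.key,
        flank=flank,
        sequence=left + right,
        actual_left=len(left),
        actual_right=len(right),
    )


def derive_neopeptides(window: JunctionWindow) -> NeopeptideSet:
    """Translate a window in all three frames and keep junction-spanning
    fragments.

    Each frame is split at stop codons; a fragment is retained only when its
    codon range straddles the junction midpoint (nt_start < midpoint <
    nt_end), so every emitted peptide is junction-spanning and stop-free.
    """
    if len(window.sequence) < 6:
        raise ValueError("window too short to translate")
    mid = window.midpoint
    peptides: list[tuple[int, str, bool]] = []
    for frame in range(3):
        n_codons = (len(window.sequence) - frame) // 3
        if n_codons == 0:
            continue
        aa = str(Seq(window.sequence[frame : frame + 3 * n_codons]).translate())
        start = 0
        for i, ch in enumerate(aa + "*"):
            if ch != "*":
                continue
            if i > start:
                nt_s = frame + 3 * start
                nt_e = frame + 3 * i
                if nt_s < mid < nt_e:
                    peptides.append((frame, aa[start:i], True))
            start = i + 1
    return NeopeptideSet(junction_id=window.junction_id, peptides=tuple(peptides))


# ---------------------------------------------------------------------------
# Peptide-database confirmation


def make_decoy(peptide: str, rng: np.random.Generator) -> str:
    """Reversed-sequence decoy; palindromes fall back to a seeded shuffle."""
    decoy = peptide[::-1]
    if decoy != peptide:
        return decoy
    chars = list(peptide)
    for _ in range(20):
        rng.shuffle(chars)
        if "".join(chars) != peptide:
            return "".join(chars)
    return decoy  # fully degenerate peptide (single repeated residue)


def confirm_peptides(
    neopeptides: Iterable[tuple[str, str]],
    peptide_db: Sequence[str],
    fdr_threshold: float = 0.05,
    seed: int = 0,
) -> list[ConfirmationResult]:
    """Match junction peptides against a peptide database with decoy FDR.

    ``neopeptides`` yields (junction_id, peptide) pairs. A query matches when
    it occurs verbatim (equality or substring) in any database entry. The FDR
    of the accepted set is estimated as decoy hits over target hits; matches
    pass only while that estimate stays at or below ``fdr_threshold``.
    """
    if not peptide_db:
        raise ValueError("peptide database is empty")
    rng = np.random.default_rng(seed)
    queries = list(neopeptides)
    haystack = "\n".join(peptide_db)
    results = []
    n_target = 0
    n_decoy = 0
    for junction_id, pep in queries:
        matched = pep in haystack
        decoy_hit = make_decoy(pep, rng) in haystack
        n_target += matched
        n_decoy += decoy_hit
        results.append((junction_id, pep, matched, decoy_hit))
    fdr = n_decoy / n_target if n_target else 1.0
    passes = fdr <= fdr_threshold
    return [
        ConfirmationResult(j, p, m, d, passes_fdr=bool(m and passes))
        for j, p, m, d in results
    ]


def per_case_confirmation(
    counts: pd.DataFrame,
    tumor_samples: Sequence[str],
    confirmed_junctions: Sequence[str],
) -> tuple[float, float, pd.DataFrame]:
    """Per-case summary of confirmed neojunctions.

    A case expresses a confirmed neojunction when it has at least one
    supporting read for it. Returns (fraction of cases with >= 1 confirmed
    neojunction, mean confirmed per case, per-case table).
    """
    confirmed = [j for j in confirmed_junctions if j in counts.index]
    per_case = pd.DataFrame(
        {
            "sample_id": list(tumor_samples),
            "n_confirmed": [
                int((counts.loc[confirmed, s] > 0).sum()) if confirmed else 0
                for s in tumor_samples
            ],
        }
    )
    if per_case.empty:
        raise ValueError("no tumor samples")
    frac = float((per_case["n_confirmed"] > 0).mean())
    mean_n = float(per_case["n_confirmed"].mean())
    return frac, mean_n, per_case
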