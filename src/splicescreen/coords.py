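"""Transcript coordinate arithmetic and junction-to-protein projection.

All genomic intervals are 0-based half-open. GFF3 input (1-based inclusive)
is converted at parse time in :mod:`splicescreen.io`. Transcript offsets count
spliced bases 5'->3' in transcript orientation, so offset 0 is the first
transcribed base regardless of strand.

A splice junction is stored as ``(contig, left, right, strand)`` with
``left < right`` on the contig: ``left`` is the exclusive end of the upstream
(genomically-left) exon and ``right`` the start of the downstream exon. In
transcript orientation the donor-side last exonic base is ``left - 1`` on the
plus strand and ``right`` on the minus strand.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import NamedTuple, Optional, Sequence

import pandas as pd
from Bio.Seq import Seq

SURFACE_DOMAIN_LABELS = ("extracellular", "transmembrane", "cytoplasmic")

_JUNCTION_RE = re.compile(r"^(?P<contig>[^:]+):(?P<left>\d+)-(?P<right>\d+):(?P<strand>[+-])$")


class Junction(NamedTuple):
    contig: str
    left: int
    right: int
    strand: str

    @property
    def key(self) -> str:
        return f"{self.contig}:{self.left}-{self.right}:{self.strand}"

    @property
    def donor_last_base(self) -> int:
        """Genomic position of the last exonic base 5' of the junction."""
        return self.left - 1 if self.strand == "+" else self.right

    @property
    def acceptor_first_base(self) -> int:
        """Genomic position of the first exonic base 3' of the junction."""
        return self.right if self.strand == "+" else self.left - 1


def parse_junction(key: str) -> Junction:
    m = _JUNCTION_RE.match(key)
    if m is None:
        raise ValueError(f"malformed junction key: {key!r}")
    left, right = int(m["left"]), int(m["right"])
    if not left < right:
        raise ValueError(f"junction must satisfy left < right: {key!r}")
    return Junction(m["contig"], left, right, m["strand"])


@dataclass(frozen=True)
class TranscriptModel:
    """An annotated transcript: ordered exons and (optionally) a CDS.

    ``exons`` and ``cds`` are genomic intervals sorted by start coordinate
    regardless of strand; strand only governs the direction of the spliced
    walk. The CDS length must be a multiple of 3 when present.
    """

    transcript_id: str
    gene_id: str
    contig: str
    strand: str
    exons: tuple[tuple[int, int], ...]
    cds: tuple[tuple[int, int], ...] = ()
    protein_id: Optional[str] = None

    def __post_init__(self):
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r}")
        for name, ivs in (("exons", self.exons), ("cds", self.cds)):
            prev_end = -1
            for s, e in ivs:
                if not (0 <= s < e):
                    raise ValueError(f"{name} interval [{s},{e}) is invalid")
                if s < prev_end:
                    raise ValueError(f"{name} intervals overlap or are unsorted")
                prev_end = e
        if self.cds and self.cds_length % 3 != 0:
            raise ValueError(
                f"{self.transcript_id}: CDS length {self.cds_length} not divisible by 3"
            )

    # -- basic geometry -------------------------------------------------
    @property
    def spliced_length(self) -> int:
        return sum(e - s for s, e in self.exons)

    @property
    def cds_length(self) -> int:
        return sum(e - s for s, e in self.cds)

    @property
    def span(self) -> tuple[int, int]:
        return self.exons[0][0], self.exons[-1][1]

    def exons_in_transcript_order(self) -> list[tuple[int, int]]:
        return list(self.exons) if self.strand == "+" else list(reversed(self.exons))

    # -- coordinate maps ------------------------------------------------
    def genomic_to_transcript(self, pos: int) -> Optional[int]:
        """Spliced offset of a genomic position, or None if not exonic."""
        acc = 0
        for s, e in self.exons_in_transcript_order():
            if s <= pos < e:
                return acc + (pos - s if self.strand == "+" else e - 1 - pos)
            acc += e - s
        return None

    def transcript_to_genomic(self, offset: int) -> int:
        if offset < 0:
            raise IndexError(offset)
        acc = 0
        for s, e in self.exons_in_transcript_order():
            if offset < acc + (e - s):
                k = offset - acc
                return s + k if self.strand == "+" else e - 1 - k
            acc += e - s
        raise IndexError(f"offset {offset} beyond spliced length {self.spliced_length}")

    # -- sequences ------------------------------------------------------
    def spliced_sequence(self, genome: dict[str, str]) -> str:
        chrom = genome[self.contig]
        seq = "".join(chrom[s:e] for s, e in self.exons)
        return seq if self.strand == "+" else str(Seq(seq).reverse_complement())

    @property
    def cds_start_offset(self) -> Optional[int]:
        """Transcript offset of the first coding base (None when noncoding)."""
        if not self.cds:
            return None
        first = self.cds[0][0] if self.strand == "+" else self.cds[-1][1] - 1
        off = self.genomic_to_transcript(first)
        if off is None:
            raise ValueError(f"{self.transcript_id}: CDS start not exonic")
        return off

    def cds_sequence(self, genome: dict[str, str]) -> str:
        if not self.cds:
            return ""
        start = self.cds_start_offset
        return self.spliced_sequence(genome)[start : start + self.cds_length]

    def protein_sequence(self, genome: dict[str, str]) -> str:
        cds = self.cds_sequence(genome)
        if not cds:
            return ""
        return str(Seq(cds).translate()).rstrip("*")


@dataclass(frozen=True)
class ProteinLocus:
    """A junction projected into protein (or UTR) space on one transcript."""

    junction_id: str
    transcript_id: str
    domain_label: Optional[str]  # extracellular|transmembrane|cytoplasmic|UTR5|UTR3|noncoding|None
    cds_offset: Optional[int] = None
    aa_position: Optional[int] = None
    frame: Optional[int] = None
    is_surface_protein: bool = False


@dataclass(frozen=True)
class IncompatibleJunction:
    junction_id: str
    transcript_id: str
    reason: str


def compatible_transcripts(
    junction: Junction, transcripts: Sequence[TranscriptModel]
) -> list[TranscriptModel]:
    """Transcripts on which both flanking bases of the junction are exonic."""
    out = []
    for t in transcripts:
        if t.contig != junction.contig or t.strand != junction.strand:
            continue
        if (
            t.genomic_to_transcript(junction.donor_last_base) is not None
            and t.genomic_to_transcript(junction.acceptor_first_base) is not None
        ):
            out.append(t)
    return out


def domain_label_for_residue(domains: pd.DataFrame, protein_id: str, aa: int) -> Optional[str]:
    """Look up the topological-domain label containing residue ``aa`` (1-based)."""
    rows = domains[domains["protein_id"] == protein_id]
    hit = rows[(rows["aa_start"] <= aa) & (aa <= rows["aa_end"])]
    if hit.empty:
        return None
    return str(hit.iloc[0]["domain_label"])


def junction_protein_locus(
    junction: Junction,
    transcript: TranscriptModel,
    domains: Optional[pd.DataFrame] = None,
) -> ProteinLocus | IncompatibleJunction:
    """Locate a junction's acceptor-side residue on a transcript.

    The residue reported is the one whose codon contains the first coding base
    on the acceptor (3') side of the junction — the position from which the
    junction alters the protein sequence. Junctions landing upstream of the
    CDS map to UTR5, downstream to UTR3, and CDS-less transcripts to
    noncoding; none of those carry an amino-acid position.
    """
    if transcript.contig != junction.contig or transcript.strand != junction.strand:
        return IncompatibleJunction(junction.key, transcript.transcript_id, "contig/strand mismatch")
    t_don = transcript.genomic_to_transcript(junction.donor_last_base)
    t_acc = transcript.genomic_to_transcript(junction.acceptor_first_base)
    if t_don is None or t_acc is None:
        return IncompatibleJunction(junction.key, transcript.transcript_id, "not exonic")
    if not transcript.cds:
        return ProteinLocus(junction.key, transcript.transcript_id, "noncoding")
    cds_start = transcript.cds_start_offset
    cds_end = cds_start + transcript.cds_length
    if t_acc < cds_start:
        return ProteinLocus(junction.key, transcript.transcript_id, "UTR5")
    if t_acc >= cds_end:
        return ProteinLocus(junction.key, transcript.transcript_id, "UTR3")
    cds_offset = t_acc - cds_start
    aa = cds_offset // 3 + 1
    frame = cds_offset % 3
    label = None
    surface = False
    if domains is not None and transcript.protein_id is not None:
        label = domain_label_for_residue(domains, transcript.protein_id, aa)
        surface = label is not None
    return ProteinLocus(
        junction.key,
        transcript.transcript_id,
        label,
        cds_offset=cds_offset,
        aa_position=aa,
        frame=frame,
        is_surface_protein=surface,
    )


# ---------------------------------------------------------------------------
# Region classification


def representative_transcript(transcripts: Sequence[TranscriptModel]) -> TranscriptModel:
    """Longest-CDS transcript (ties broken by id) — the isoform used for
    region and domain book-keeping when a gene has several."""
    return max(transcripts, key=lambda t: (t.cds_length, t.spliced_length, t.transcript_id))


def classify_base(t: TranscriptModel, pos: int) -> str:
    s, e = t.span
    if not (s <= pos < e):
        return "intergenic"
    for cs, ce in t.cds:
        if cs <= pos < ce:
            return "CDS"
    off = t.genomic_to_transcript(pos)
    if off is None:
        return "intron"
    if not t.cds:
        # noncoding exonic sequence is untranslated; binned with UTR3
        return "UTR3"
    cds_start = t.cds_start_offset
    if off < cds_start:
        return "UTR5"
    return "UTR3"


def classify_region(
    transcripts: Sequence[TranscriptModel], contig: str, start: int, end: int
) -> tuple[list[str], str]:
    """Per-base region classes of a genomic interval plus the majority class.

    Uses the longest-CDS transcript among those of the overlapping gene; bases
    outside every transcript are intergenic.
    """
    if end <= start:
        raise ValueError("empty interval")
    overlapping = [
        t for t in transcripts if t.contig == contig and t.span[0] < end and t.span[1] > start
    ]
    if not overlapping:
        return ["intergenic"] * (end - start), "intergenic"
    rep = representative_transcript(overlapping)
    labels = [classify_base(rep, p) for p in range(start, end)]
    counts: dict[str, int] = {}
    for lab in labels:
        counts[lab] = counts.get(lab, 0) + 1
    majority = max(counts, key=lambda k: (counts[k], k))
    return labels, majority
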