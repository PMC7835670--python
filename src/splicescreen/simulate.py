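"""Synthetic genomes, splicing cohorts, single-cell reads and peptide
databases with planted ground truth.

The generator emulates the study conditions every downstream stage is tested
against: a tumor/normal bulk cohort of junction-count tables with
group-structured PSI, a single-cell read set with cell-type labels, a
cell-surface protein domain annotation, patient HLA serotypes, and a peptide
database seeded with a known subset of true junction peptides.

Each gene carries exactly one alternative-splicing event — a cassette exon
(default), an alternative 3' acceptor, or an alternative 5' donor. The
canonical junction is annotated; the alternative junction is left out of the
annotation so it is discovered de novo downstream. Planted events control
tumor specificity (zero alternative-junction reads in every normal sample),
the protein-domain label of the junction's acceptor-side residue, neoplastic
cell-type restriction, stem-cell bias, and peptide-database membership.

Per-sample PSI heterogeneity follows a Dirichlet centred on the group truth
with a configurable concentration; LSV depth is Poisson. Everything is fully
deterministic under the configuration seed: independent named streams are
derived from it for the reference, bulk counts, single-cell reads, peptide
noise and HLA tables, so each generator is reproducible in isolation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from Bio.Seq import Seq

from .coords import Junction, TranscriptModel, junction_protein_locus
from .peptides import JunctionWindow, derive_neopeptides, junction_window

CELL_TYPES = (
    "neoplastic-stem",
    "neoplastic-differentiated",
    "glia",
    "immune",
    "endothelial",
)
NEOPLASTIC_TYPES = CELL_TYPES[:2]
NON_MALIGNANT_TYPES = CELL_TYPES[2:]

DOMAIN_LABELS = ("extracellular", "transmembrane", "cytoplasmic", "UTR", "noncoding")

_BASES = np.array(list("ACGT"))
_STOPS = ("TAA", "TAG", "TGA")
_NONSTOP_CODONS = tuple(
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in _STOPS
)

_HLA_POOL = (
    "HLA-A*01:01",
    "HLA-A*02:01",
    "HLA-B*07:02",
    "HLA-B*08:01",
    "HLA-C*07:01",
    "HLA-C*07:02",
)

# amino-acid frequencies of naturally occurring proteins (UniProt averages)
AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
AA_FREQ = np.array(
    [8.3, 1.4, 5.5, 6.7, 3.9, 7.1, 2.3, 6.0, 5.8, 9.7, 2.4, 4.1, 4.7, 3.9, 5.5, 6.6, 5.4, 6.9, 1.1, 2.9]
)
AA_FREQ = AA_FREQ / AA_FREQ.sum()

_STREAMS = {"reference": 0, "counts": 1, "sc": 2, "peptides": 3, "hla": 4}


@dataclass
class PlantedEvent:
    """Ground truth planted into one gene's alternative junction."""

    junction_id: str = ""  # resolved by the generator
    tumor_only: bool = False
    domain_label: str = "extracellular"
    neoplastic_only: bool = False
    in_peptide_db: bool = False
    stem_bias: float = 1.0  # stem:differentiated expression-rate ratio
    event_kind: str = "skip"  # skip | alt3 | alt5
    tumor_alt_psi: Optional[float] = None
    normal_alt_psi: Optional[float] = None
    recurrent_alt_psi: Optional[float] = None  # overrides tumor PSI in recurrent samples

    def __post_init__(self):
        if self.domain_label not in DOMAIN_LABELS:
            raise ValueError(f"bad domain label {self.domain_label!r}")
        if self.event_kind not in ("skip", "alt3", "alt5"):
            raise ValueError(f"bad event kind {self.event_kind!r}")


@dataclass
class SimulationConfig:
    seed: int = 0
    n_genes: int = 30
    n_tumor_samples: int = 10
    n_normal_samples: int = 10
    mean_lsv_coverage: float = 100.0
    psi_truth: dict = field(default_factory=dict)  # group -> junction_id -> PSI
    psi_concentration: float = 50.0
    n_cells_per_type: dict = field(default_factory=lambda: {t: 60 for t in CELL_TYPES})
    read_length: int = 60
    planted_events: list = field(default_factory=list)
    surface_fraction: float = 0.4  # unplanted genes given a generic surface topology
    sc_expression_rate: float = 0.3

    def validate(self) -> None:
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")
        if self.psi_concentration <= 0:
            raise ValueError("psi_concentration must be positive")
        if self.read_length < 20:
            raise ValueError("read_length must allow a junction overhang on each side")
        if len(self.planted_events) > self.n_genes:
            raise ValueError("more planted events than genes")
        for group, table in self.psi_truth.items():
            for j, v in table.items():
                if not 0 <= v <= 1:
                    raise ValueError(f"psi_truth[{group}][{j}] outside [0,1]")


def _rng(config: SimulationConfig, stream: str) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(config.seed, spawn_key=(_STREAMS[stream],))
    )


@dataclass
class LsvTruth:
    lsv_id: str
    gene_id: str
    junction_ids: tuple[str, str]  # (canonical, alternative)
    psi: dict  # group -> (psi_canonical, psi_alt)


@dataclass
class ReferenceBundle:
    """Everything generate_reference knows about the toy study system."""

    genome: dict[str, str]
    transcripts: list[TranscriptModel]
    domains: pd.DataFrame  # protein_id, domain_label, aa_start, aa_end (1-based incl.)
    junctions: pd.DataFrame  # junction_id, contig, left, right, strand, gene_id, ...
    lsv_truth: list[LsvTruth]
    truth: pd.DataFrame  # resolved planted-event table
    psi_truth: dict  # group -> junction_id -> PSI

    def transcript_for_gene(self, gene_id: str) -> TranscriptModel:
        for t in self.transcripts:
            if t.gene_id == gene_id:
                return t
        raise KeyError(gene_id)

    def alt_junctions(self) -> pd.DataFrame:
        return self.junctions[self.junctions["role"] == "alt"]


def _rand_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(_BASES, size=n))


def _coding_sequence(rng: np.random.Generator, cds_len: int) -> str:
    assert cds_len % 3 == 0 and cds_len >= 9
    n = cds_len // 3
    body = rng.choice(np.array(_NONSTOP_CODONS), size=n - 2)
    return "ATG" + "".join(body) + str(rng.choice(np.array(_STOPS)))


def _flip(iv: tuple[int, int], L: int) -> tuple[int, int]:
    return (L - iv[1], L - iv[0])


@dataclass
class _GeneBuild:
    transcript: TranscriptModel
    contig_seq: str
    canonical: Junction
    alternative: Junction
    protein: str
    domain_rows: list
    psi: dict
    truth_row: Optional[dict]


def _layout_exons(
    rng: np.random.Generator, exon_lens: Sequence[int], pad: int = 50
) -> tuple[list[tuple[int, int]], int, list[str]]:
    """Place exons with random introns; returns intervals, contig length and
    the per-piece sequence skeleton (exon placeholders as None markers)."""
    intervals = []
    pos = pad
    intron_lens = rng.integers(80, 201, size=len(exon_lens) - 1)
    for i, ln in enumerate(exon_lens):
        intervals.append((pos, pos + ln))
        pos += ln
        if i < len(exon_lens) - 1:
            pos += int(intron_lens[i])
    return intervals, pos + pad, [(_rand_seq(rng, int(l))) for l in intron_lens]


def _build_gene(
    rng: np.random.Generator, idx: int, ev: Optional[PlantedEvent], cfg: SimulationConfig
) -> _GeneBuild:
    contig = f"chr{idx + 1}"
    strand = "+" if idx % 2 == 0 else "-"
    gene_id = f"GENE{idx:03d}"
    transcript_id = f"{gene_id}.t1"

    kind = "coding"
    if ev is not None:
        if ev.domain_label == "UTR":
            kind = "utr3"
        elif ev.domain_label == "noncoding":
            kind = "noncoding"
    if ev is not None:
        event_kind = ev.event_kind
    else:
        event_kind = str(rng.choice(["skip", "alt3", "alt5"], p=[0.7, 0.15, 0.15]))
    if kind != "coding":
        event_kind = "skip"  # UTR/noncoding plants use the cassette layout

    # ---- mRNA and exon lengths in sense (plus-strand) construction space
    if kind == "coding":
        utr5_len, utr3_len = 42, 90
        c0, c5 = 60, 90
        mids = [int(x) for x in rng.integers(54, 120, size=4)]
        cds_len = c0 + sum(mids) + c5
        c5 += (-cds_len) % 3
        cds_len = c0 + sum(mids) + c5
        cds_seq = _coding_sequence(rng, cds_len)
        mrna = _rand_seq(rng, utr5_len) + cds_seq + _rand_seq(rng, utr3_len)
        exon_lens = [utr5_len + c0, *mids, c5 + utr3_len]
        cassette = 2  # transcript-order exon index of the cassette exon
        cds_mrna_span = (utr5_len, utr5_len + cds_len)
    elif kind == "utr3":
        utr5_len, utr3_len = 42, 270
        cds_len = 3 * int(rng.integers(60, 100))
        cds_seq = _coding_sequence(rng, cds_len)
        mrna = _rand_seq(rng, utr5_len) + cds_seq + _rand_seq(rng, utr3_len)
        head = utr5_len + cds_len + 30
        exon_lens = [head, 80, 80, 80]
        cassette = 2
        cds_mrna_span = (utr5_len, utr5_len + cds_len)
    else:  # noncoding
        mrna = _rand_seq(rng, 480)
        exon_lens = [120, 120, 120, 120]
        cassette = 2
        cds_mrna_span = None
    assert sum(exon_lens) == len(mrna)

    exon_ivs, contig_len, introns = _layout_exons(rng, exon_lens)
    # assemble sense contig
    pieces = [_rand_seq(rng, exon_ivs[0][0])]
    off = 0
    for i, (s, e) in enumerate(exon_ivs):
        pieces.append(mrna[off : off + (e - s)])
        off += e - s
        if i < len(exon_ivs) - 1:
            pieces.append(introns[i])
    pieces.append(_rand_seq(rng, contig_len - exon_ivs[-1][1]))
    sense_seq = "".join(pieces)
    assert len(sense_seq) == contig_len

    # CDS genomic intervals in sense space
    cds_ivs: list[tuple[int, int]] = []
    if cds_mrna_span is not None:
        cs, ce = cds_mrna_span
        off = 0
        for s, e in exon_ivs:
            lo, hi = max(cs, off), min(ce, off + (e - s))
            if lo < hi:
                cds_ivs.append((s + (lo - off), s + (hi - off)))
            off += e - s

    # junctions in sense space: anchor exon is cassette-1
    k = cassette
    d1 = exon_ivs[k - 1][1]
    if event_kind == "skip":
        canonical = (d1, exon_ivs[k][0])
        alternative = (d1, exon_ivs[k + 1][0])
    elif event_kind == "alt3":
        canonical = (d1, exon_ivs[k][0])
        alternative = (d1, exon_ivs[k][0] + 9)
    else:  # alt5
        canonical = (d1, exon_ivs[k][0])
        alternative = (d1 - 9, exon_ivs[k][0])

    # ---- strand placement
    if strand == "+":
        contig_seq = sense_seq
        g_exons = exon_ivs
        g_cds = cds_ivs
        jx = [(canonical), (alternative)]
    else:
        contig_seq = str(Seq(sense_seq).reverse_complement())
        g_exons = sorted(_flip(iv, contig_len) for iv in exon_ivs)
        g_cds = sorted(_flip(iv, contig_len) for iv in cds_ivs)
        jx = [
            (contig_len - canonical[1], contig_len - canonical[0]),
            (contig_len - alternative[1], contig_len - alternative[0]),
        ]
    canonical_j = Junction(contig, jx[0][0], jx[0][1], strand)
    alt_j = Junction(contig, jx[1][0], jx[1][1], strand)

    transcript = TranscriptModel(
        transcript_id=transcript_id,
        gene_id=gene_id,
        contig=contig,
        strand=strand,
        exons=tuple(g_exons),
        cds=tuple(g_cds),
        protein_id=f"{gene_id}.p1" if g_cds else None,
    )
    genome = {contig: contig_seq}
    protein = transcript.protein_sequence(genome)

    # ---- surface-domain partition
    domain_rows: list = []
    surface = False
    if kind == "coding":
        if ev is not None and ev.domain_label in ("extracellular", "transmembrane", "cytoplasmic"):
            surface = True
        elif ev is None and (idx % int(max(1, round(1 / max(cfg.surface_fraction, 1e-9)))) == 0):
            surface = True
    if surface:
        L = len(protein)
        locus = junction_protein_locus(alt_j, transcript, None)
        aa = locus.aa_position if getattr(locus, "aa_position", None) else L // 2
        target = ev.domain_label if ev is not None else "extracellular"
        if target == "extracellular":
            b1 = min(max(aa + 5, 2), L - 2)
            b2 = min(b1 + 20, L - 1)
        elif target == "transmembrane":
            b1 = max(aa - 4, 1)
            b2 = min(aa + 4, L - 1)
        else:  # cytoplasmic: residue must fall after the TM segment
            b2 = max(aa - 1, 2)
            b1 = max(b2 - 20, 1)
        segs = [("extracellular", 1, b1), ("transmembrane", b1 + 1, b2), ("cytoplasmic", b2 + 1, L)]
        for label, s, e in segs:
            if s <= e:
                domain_rows.append(
                    {
                        "protein_id": transcript.protein_id,
                        "domain_label": label,
                        "aa_start": s,
                        "aa_end": e,
                    }
                )

    # ---- PSI truth for the event
    if ev is not None and ev.tumor_only:
        tumor_alt = ev.tumor_alt_psi if ev.tumor_alt_psi is not None else float(rng.uniform(0.3, 0.6))
        normal_alt = ev.normal_alt_psi if ev.normal_alt_psi is not None else 0.0
    else:
        base = float(rng.uniform(0.15, 0.5))
        shift = float(rng.choice([0.0, 0.2], p=[0.6, 0.4]) * rng.choice([-1.0, 1.0]))
        tumor_alt = float(np.clip(base + shift, 0.05, 0.9))
        normal_alt = base
        if ev is not None:
            if ev.tumor_alt_psi is not None:
                tumor_alt = ev.tumor_alt_psi
            if ev.normal_alt_psi is not None:
                normal_alt = ev.normal_alt_psi
    psi = {
        "tumor": (1.0 - tumor_alt, tumor_alt),
        "normal": (1.0 - normal_alt, normal_alt),
    }
    if ev is not None and ev.recurrent_alt_psi is not None:
        psi["recurrent"] = (1.0 - ev.recurrent_alt_psi, ev.recurrent_alt_psi)

    truth_row = None
    if ev is not None:
        truth_row = {
            "junction_id": alt_j.key,
            "gene_id": gene_id,
            "tumor_only": ev.tumor_only,
            "domain_label": ev.domain_label,
            "neoplastic_only": ev.neoplastic_only,
            "in_peptide_db": ev.in_peptide_db,
            "stem_bias": ev.stem_bias,
            "event_kind": event_kind,
            "tumor_alt_psi": tumor_alt,
            "normal_alt_psi": normal_alt,
            "recurrent_alt_psi": ev.recurrent_alt_psi,
        }
    return _GeneBuild(transcript, contig_seq, canonical_j, alt_j, protein, domain_rows, psi, truth_row)


def generate_reference(config: SimulationConfig) -> ReferenceBundle:
    """Build the toy genome, annotation, surface domains and planted truth."""
    config.validate()
    rng = _rng(config, "reference")
    genome: dict[str, str] = {}
    transcripts: list[TranscriptModel] = []
    domain_rows: list = []
    junction_rows: list = []
    lsv_truth: list[LsvTruth] = []
    truth_rows: list = []
    psi_truth: dict = {"tumor": {}, "normal": {}}

    for idx in range(config.n_genes):
        ev = config.planted_events[idx] if idx < len(config.planted_events) else None
        gb = _build_gene(rng, idx, ev, config)
        genome[gb.transcript.contig] = gb.contig_seq
        transcripts.append(gb.transcript)
        domain_rows.extend(gb.domain_rows)
        lsv_id = f"{gb.transcript.gene_id}:lsv"
        for role, jx in (("canonical", gb.canonical), ("alt", gb.alternative)):
            junction_rows.append(
                {
                    "junction_id": jx.key,
                    "contig": jx.contig,
                    "left": jx.left,
                    "right": jx.right,
                    "strand": jx.strand,
                    "gene_id": gb.transcript.gene_id,
                    "transcript_id": gb.transcript.transcript_id,
                    "lsv_id": lsv_id,
                    "role": role,
                }
            )
        lsv_truth.append(
            LsvTruth(lsv_id, gb.transcript.gene_id, (gb.canonical.key, gb.alternative.key), gb.psi)
        )
        for group in ("tumor", "normal"):
            psi_truth[group][gb.canonical.key] = gb.psi[group][0]
            psi_truth[group][gb.alternative.key] = gb.psi[group][1]
        if gb.truth_row is not None:
            truth_rows.append(gb.truth_row)

    # user-provided truth overrides, keyed by junction id
    for group, table in config.psi_truth.items():
        for jid, v in table.items():
            psi_truth.setdefault(group, {})[jid] = v
    for lt in lsv_truth:
        for group in ("tumor", "normal"):
            c, a = lt.junction_ids
            lt.psi[group] = (psi_truth[group][c], psi_truth[group][a])
            if abs(sum(lt.psi[group]) - 1.0) > 1e-9:
                raise ValueError(f"psi truth for {lt.lsv_id}/{group} does not sum to 1")

    domains = pd.DataFrame(
        domain_rows, columns=["protein_id", "domain_label", "aa_start", "aa_end"]
    )
    junctions = pd.DataFrame(junction_rows)
    truth = pd.DataFrame(
        truth_rows,
        columns=[
            "junction_id",
            "gene_id",
            "tumor_only",
            "domain_label",
            "neoplastic_only",
            "in_peptide_db",
            "stem_bias",
            "event_kind",
            "tumor_alt_psi",
            "normal_alt_psi",
            "recurrent_alt_psi",
        ],
    )
    return ReferenceBundle(genome, transcripts, domains, junctions, lsv_truth, truth, psi_truth)


# ---------------------------------------------------------------------------
# Bulk junction counts


def sample_table(config: SimulationConfig) -> pd.DataFrame:
    """Sample sheet: tumor samples alternate primary/recurrent subgroups."""
    rows = []
    for i in range(config.n_tumor_samples):
        rows.append(
            {
                "sample_id": f"T{i + 1:02d}",
                "group": "tumor",
                "subgroup": "primary" if i % 2 == 0 else "recurrent",
            }
        )
    for i in range(config.n_normal_samples):
        rows.append({"sample_id": f"N{i + 1:02d}", "group": "normal", "subgroup": "na"})
    return pd.DataFrame(rows)


def simulate_junction_counts(
    config: SimulationConfig, bundle: ReferenceBundle
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Sample a junction-count table (junction x sample).

    Per sample and LSV: PSI ~ Dirichlet(concentration * group truth) with
    exact zeros preserved for zero-truth junctions, depth ~ Poisson(mean
    coverage), counts ~ Multinomial(depth, PSI). Tumor-only plants therefore
    have exactly zero alternative-junction reads in every normal sample.
    """
    config.validate()
    if config.psi_concentration <= 0:
        raise ValueError("psi_concentration must be positive")
    rng = _rng(config, "counts")
    samples = sample_table(config)
    jids = list(bundle.junctions["junction_id"])
    counts = pd.DataFrame(
        0, index=pd.Index(jids, name="junction_id"), columns=list(samples["sample_id"])
    )
    for lt in bundle.lsv_truth:
        for _, srow in samples.iterrows():
            key = srow["group"]
            if key == "tumor" and srow["subgroup"] == "recurrent" and "recurrent" in lt.psi:
                key = "recurrent"
            truth = np.asarray(lt.psi[key], dtype=float)
            psi = np.zeros_like(truth)
            pos = truth > 0
            if pos.sum() == 1:
                psi[pos] = 1.0
            else:
                psi[pos] = rng.dirichlet(config.psi_concentration * truth[pos])
            depth = rng.poisson(config.mean_lsv_coverage)
            if depth > 0:
                c = rng.multinomial(depth, psi)
            else:
                c = np.zeros(len(psi), dtype=int)
            for jid, n in zip(lt.junction_ids, c):
                counts.loc[jid, srow["sample_id"]] = int(n)
    return counts, samples


# ---------------------------------------------------------------------------
# Single-cell reads


def cell_table(config: SimulationConfig) -> pd.DataFrame:
    rows = []
    i = 0
    for ct in CELL_TYPES:
        for _ in range(int(config.n_cells_per_type.get(ct, 0))):
            rows.append({"barcode": f"BC{i:05d}", "cell_type": ct})
            i += 1
    return pd.DataFrame(rows)


def simulate_sc_reads(
    config: SimulationConfig, bundle: ReferenceBundle
) -> tuple[list[tuple[str, str]], pd.DataFrame]:
    """Emit (read_name, sequence) pairs plus the cell annotation table.

    Reads are exact substrings of spliced isoform sequences. Alternative
    junctions emit junction-spanning reads only from permitted cell types
    (all five, or the two neoplastic types for neoplastic-only plants), with
    a stem:differentiated rate ratio given by the planted stem bias. Every
    cell additionally emits a couple of background reads drawn from random
    annotated transcripts.
    """
    config.validate()
    if config.read_length < 2 * 10:
        raise ValueError("read_length must cover a 10 nt overhang on each side")
    rng = _rng(config, "sc")
    cells = cell_table(config)
    truth = bundle.truth.set_index("junction_id") if not bundle.truth.empty else None
    reads: list[tuple[str, str]] = []
    serial = 0

    alt = bundle.alt_junctions()
    windows: dict[str, JunctionWindow] = {}
    for _, row in alt.iterrows():
        t = bundle.transcript_for_gene(row["gene_id"])
        jx = Junction(row["contig"], int(row["left"]), int(row["right"]), row["strand"])
        w = junction_window(bundle.genome, t, jx, flank=config.read_length)
        if isinstance(w, JunctionWindow):
            windows[row["junction_id"]] = w

    base = config.sc_expression_rate
    for _, crow in cells.iterrows():
        bc, ctype = crow["barcode"], crow["cell_type"]
        for jid, w in windows.items():
            permitted = CELL_TYPES
            bias = 1.0
            if truth is not None and jid in truth.index:
                trow = truth.loc[jid]
                if bool(trow["neoplastic_only"]):
                    permitted = NEOPLASTIC_TYPES
                bias = float(trow["stem_bias"])
            if ctype not in permitted:
                continue
            rate = base * bias if ctype == "neoplastic-stem" else base
            if rng.random() >= min(rate, 0.95):
                continue
            n_reads = 1 + rng.poisson(0.7)
            mid = w.midpoint
            L = config.read_length
            lo = max(0, mid + 10 - L)
            hi = min(len(w.sequence) - L, mid - 10)
            if hi < lo:
                continue
            for _ in range(n_reads):
                start = int(rng.integers(lo, hi + 1))
                reads.append((f"{bc}|r{serial}", w.sequence[start : start + L]))
                serial += 1
        # background reads from random annotated transcripts
        for _ in range(2):
            t = bundle.transcripts[int(rng.integers(len(bundle.transcripts)))]
            seq = t.spliced_sequence(bundle.genome)
            if len(seq) <= config.read_length:
                continue
            start = int(rng.integers(0, len(seq) - config.read_length))
            reads.append((f"{bc}|r{serial}", seq[start : start + config.read_length]))
            serial += 1
    return reads, cells


# ---------------------------------------------------------------------------
# Peptide database and HLA tables


def planted_junction_peptides(config: SimulationConfig, bundle: ReferenceBundle) -> dict[str, list[str]]:
    """Three-frame junction-spanning peptides for every alternative junction."""
    out: dict[str, list[str]] = {}
    for _, row in bundle.alt_junctions().iterrows():
        t = bundle.transcript_for_gene(row["gene_id"])
        jx = Junction(row["contig"], int(row["left"]), int(row["right"]), row["strand"])
        w = junction_window(bundle.genome, t, jx, flank=24)
        if isinstance(w, JunctionWindow):
            out[row["junction_id"]] = [p for _, p, _ in derive_neopeptides(w).peptides]
    return out


def simulate_peptide_db(
    config: SimulationConfig,
    true_peptides: Sequence[str],
    exclude: Sequence[str] = (),
    n_noise: int = 200,
) -> list[str]:
    """A peptide list containing the given true junction peptides plus
    seeded noise. No noise peptide contains any peptide from ``exclude``
    (typically all candidate junction peptides), so confirmation hits can
    only come from the planted truth."""
    if not true_peptides:
        raise ValueError("true_peptides must be non-empty")
    rng = _rng(config, "peptides")
    forbidden = sorted(set(exclude) | set(true_peptides))
    noise: list[str] = []
    aa = np.array(list(AA_ALPHABET))
    while len(noise) < n_noise:
        ln = int(rng.integers(8, 16))
        pep = "".join(rng.choice(aa, size=ln, p=AA_FREQ))
        if any(f in pep for f in forbidden):
            continue
        noise.append(pep)
    return sorted(set(true_peptides)) + noise


def simulate_hla(config: SimulationConfig) -> pd.DataFrame:
    """Patient HLA class-I serotypes (long format: one row per allele)."""
    rng = _rng(config, "hla")
    rows = []
    for i in range(config.n_tumor_samples):
        n = int(rng.integers(4, 7))
        alleles = rng.choice(np.array(_HLA_POOL), size=n, replace=False)
        for a in sorted(alleles):
            rows.append({"patient_id": f"T{i + 1:02d}", "allele": str(a)})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# The standard study cohort


def standard_cohort(seed: int = 0, n_genes: int = 30) -> SimulationConfig:
    """The default synthetic study: a 10+10 tumor/normal cohort with eight
    planted events covering the full nomination cascade and its ablations.

    Plants (in gene order): two full-cascade CAR candidates (tumor-only,
    extracellular, neoplastic-only, in the peptide DB; the first with a 2x
    stem bias), a transmembrane and a cytoplasmic variant, a non-neoplastic-
    specific extracellular event, a 3'UTR event, an extracellular event
    absent from the peptide DB, and a noncoding-gene event.
    """
    events = [
        PlantedEvent(tumor_only=True, domain_label="extracellular", neoplastic_only=True,
                     in_peptide_db=True, stem_bias=2.0),
        PlantedEvent(tumor_only=True, domain_label="extracellular", neoplastic_only=True,
                     in_peptide_db=True),
        PlantedEvent(tumor_only=True, domain_label="transmembrane", neoplastic_only=True,
                     in_peptide_db=True),
        PlantedEvent(tumor_only=True, domain_label="cytoplasmic", neoplastic_only=True),
        PlantedEvent(tumor_only=True, domain_label="extracellular", neoplastic_only=False,
                     in_peptide_db=True),
        PlantedEvent(tumor_only=True, domain_label="UTR", neoplastic_only=True),
        PlantedEvent(tumor_only=True, domain_label="extracellular", neoplastic_only=True,
                     in_peptide_db=False),
        PlantedEvent(tumor_only=True, domain_label="noncoding", neoplastic_only=True),
        # two recurrent-enriched background events (detectable in the
        # primary-vs-recurrent contrast; not tumor-specific)
        PlantedEvent(domain_label="cytoplasmic", tumor_alt_psi=0.2,
                     normal_alt_psi=0.2, recurrent_alt_psi=0.7),
        PlantedEvent(domain_label="cytoplasmic", tumor_alt_psi=0.15,
                     normal_alt_psi=0.15, recurrent_alt_psi=0.75),
    ]
    return SimulationConfig(seed=seed, n_genes=n_genes, planted_events=events)
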