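"""End-to-end orchestration: simulate -> quantify -> call -> map -> derive ->
screen -> filter -> scan, under a single config.

The nomination cascade applies filters in order: tumor-specific ->
surface/extracellular -> neoplastic-specific -> (optionally) peptide-confirmed
and strong-binder. Each stage writes its artifact table under the working
directory and logs a record count; stages can be toggled, in which case later
stages read the earlier artifacts from disk. Two orthogonal sample contrasts
are carried: tumor vs normal (the specificity filter) and primary vs
recurrent (differential-splicing and neoantigen summaries).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from . import io as sio
from .coords import (
    Junction,
    TranscriptModel,
    classify_region,
    compatible_transcripts,
    junction_protein_locus,
    parse_junction,
    representative_transcript,
)
from .mhc import PositionWeightPredictor, candidates_to_frame, enumerate_candidates, filter_strong_binders
from .motifs import bundled_motifs, read_pwms, scan_pwm, summarize_hits
from .peptides import (
    JunctionWindow,
    confirm_peptides,
    derive_neopeptides,
    junction_window,
    per_case_confirmation,
)
from .psi import (
    DEFAULT_THRESHOLDS,
    LocalSpliceVariation,
    QuantifiabilityThresholds,
    build_lsvs,
    call_tumor_specific,
    delta_psi,
    estimate_psi,
    group_psi,
)
from .screen import (
    CellJunctionMatrix,
    JunctionReference,
    cell_type_frequencies,
    match_reads,
    neoplastic_specific,
    stem_enrichment,
)
from .simulate import (
    ReferenceBundle,
    SimulationConfig,
    generate_reference,
    planted_junction_peptides,
    simulate_hla,
    simulate_junction_counts,
    simulate_peptide_db,
    simulate_sc_reads,
    standard_cohort,
)

log = logging.getLogger("splicescreen")

ALL_STAGES = (
    "simulate",
    "quantify",
    "dpsi",
    "tumor_specific",
    "map_domains",
    "peptides",
    "confirm",
    "sc_screen",
    "neoantigens",
    "motifs",
    "report",
)

EVENT_TYPES = (
    "exon skipping",
    "alternative 5'",
    "alternative 3'",
    "intron retention",
    "other",
)


@dataclass
class PipelineConfig:
    workdir: Path = Path("splicescreen_run")
    seed: int = 0
    n_genes: int = 30
    thresholds: QuantifiabilityThresholds = field(default_factory=QuantifiabilityThresholds)
    psi_floor: float = 0.1
    dpsi_threshold: float = 0.1
    confidence: float = 0.95
    fdr_threshold: float = 0.05
    percent_rank_threshold: float = 0.5
    min_overhang: int = 10
    min_neoplastic_cells: int = 1
    background_size: int = 2000
    peptide_flank: int = 24
    neoantigen_flank: int = 25
    reference_flank: int = 300
    intron_flank: int = 250
    require_confirmed: bool = True
    require_strong_binder: bool = False
    motif_file: Optional[Path] = None
    stages: tuple = ALL_STAGES
    simulation: Optional[SimulationConfig] = None

    def __post_init__(self):
        self.workdir = Path(self.workdir)
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")
        for name, lo, hi in (
            ("psi_floor", 0, 1),
            ("dpsi_threshold", 0, 1),
            ("confidence", 0, 1),
            ("fdr_threshold", 0, 1),
        ):
            v = getattr(self, name)
            if not lo <= v <= hi:
                raise ValueError(f"{name}={v} outside [{lo},{hi}]")

    def sim_config(self) -> SimulationConfig:
        return self.simulation or standard_cohort(seed=self.seed, n_genes=self.n_genes)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        if "thresholds" in data:
            data["thresholds"] = QuantifiabilityThresholds(**data["thresholds"])
        if "stages" in data:
            data["stages"] = tuple(data["stages"])
        known = {f.name for f in fields(cls)}
        bad = set(data) - known
        if bad:
            raise ValueError(f"unknown config keys: {sorted(bad)}")
        return cls(**data)


class PipelineContext:
    """Artifacts of a run; loads from the working directory when a stage that
    would have produced them in memory was toggled off."""

    def __init__(self, cfg: PipelineConfig):
        self.cfg = cfg
        self.dir = Path(cfg.workdir)
        self._cache: dict = {}

    def path(self, name: str) -> Path:
        return self.dir / name

    def _load(self, key, loader):
        if key not in self._cache:
            self._cache[key] = loader()
        return self._cache[key]

    def set(self, key, value):
        self._cache[key] = value
        return value

    # --- inputs
    @property
    def genome(self):
        return self._load("genome", lambda: sio.read_fasta(self.path("genome.fa")))

    @property
    def transcripts(self) -> list[TranscriptModel]:
        return self._load(
            "transcripts", lambda: sio.transcripts_from_gff3(self.path("annotation.gff3"))
        )

    @property
    def domains(self) -> pd.DataFrame:
        return self._load("domains", lambda: sio.read_table(self.path("domains.tsv")))

    @property
    def counts(self) -> pd.DataFrame:
        return self._load("counts", lambda: sio.read_counts(self.path("junction_counts.tsv")))

    @property
    def samples(self) -> pd.DataFrame:
        return self._load("samples", lambda: sio.read_table(self.path("samples.tsv")))

    @property
    def truth(self) -> pd.DataFrame:
        return self._load("truth", lambda: sio.read_table(self.path("truth.tsv")))

    @property
    def cells(self) -> pd.DataFrame:
        return self._load("cells", lambda: sio.read_table(self.path("cells.tsv")))

    @property
    def reads(self):
        return self._load("reads", lambda: sio.read_fastq(self.path("sc_reads.fastq")))

    @property
    def peptide_db(self):
        return self._load("peptide_db", lambda: sio.read_peptide_db(self.path("peptide_db.txt")))

    @property
    def serotypes(self):
        return self._load("serotypes", lambda: sio.read_serotypes(self.path("hla.tsv")))

    # --- derived tables with disk fallback
    def table(self, key: str, filename: str) -> Optional[pd.DataFrame]:
        if key in self._cache:
            return self._cache[key]
        p = self.path(filename)
        if p.exists():
            return self.set(key, sio.read_table(p))
        return None

    def sample_ids(self, group: str, subgroup: Optional[str] = None) -> list[str]:
        s = self.samples
        m = s["group"] == group
        if subgroup is not None:
            m &= s["subgroup"] == subgroup
        return list(s.loc[m, "sample_id"])


# ---------------------------------------------------------------------------
# Stage implementations


def stage_simulate(ctx: PipelineContext) -> None:
    cfg = ctx.cfg
    sim = cfg.sim_config()
    bundle = generate_reference(sim)
    counts, samples = simulate_junction_counts(sim, bundle)
    reads, cells = simulate_sc_reads(sim, bundle)
    hla = simulate_hla(sim)
    peptides_by_junction = planted_junction_peptides(sim, bundle)
    planted_in_db = (
        set(bundle.truth.loc[bundle.truth["in_peptide_db"], "junction_id"])
        if not bundle.truth.empty
        else set()
    )
    true_peps = sorted(
        {p for j in planted_in_db for p in peptides_by_junction.get(j, [])}
    )
    all_peps = sorted({p for ps in peptides_by_junction.values() for p in ps})
    db = simulate_peptide_db(sim, true_peps or ["SYNTHETICFILLER"], exclude=all_peps)

    ctx.dir.mkdir(parents=True, exist_ok=True)
    sio.write_fasta(bundle.genome, ctx.path("genome.fa"))
    sio.write_gff3(bundle.transcripts, ctx.path("annotation.gff3"))
    sio.write_table(bundle.domains, ctx.path("domains.tsv"))
    sio.write_counts(counts, ctx.path("junction_counts.tsv"))
    sio.write_table(samples, ctx.path("samples.tsv"))
    sio.write_table(bundle.truth, ctx.path("truth.tsv"))
    sio.write_fastq(reads, ctx.path("sc_reads.fastq"))
    sio.write_table(cells, ctx.path("cells.tsv"))
    sio.write_table(hla, ctx.path("hla.tsv"))
    sio.write_peptide_db(db, ctx.path("peptide_db.txt"))

    ctx.set("bundle", bundle)
    ctx.set("genome", bundle.genome)
    ctx.set("transcripts", bundle.transcripts)
    ctx.set("domains", bundle.domains)
    ctx.set("counts", counts)
    ctx.set("samples", samples)
    ctx.set("truth", bundle.truth)
    ctx.set("reads", reads)
    ctx.set("cells", cells)
    ctx.set("peptide_db", db)
    ctx.set("serotypes", sio.read_serotypes(ctx.path("hla.tsv")))
    log.info("stage=simulate genes=%d junctions=%d reads=%d", sim.n_genes, len(counts), len(reads))


def _posteriors(ctx: PipelineContext):
    """LSVs plus per-sample and per-group posteriors (cached, cheap)."""
    if "posteriors" in ctx._cache:
        return ctx._cache["posteriors"]
    thr = ctx.cfg.thresholds
    lsvs = build_lsvs(ctx.counts, ctx.transcripts, thr)
    per_sample: dict[str, dict[str, object]] = {}
    for lsv in lsvs:
        per_sample[lsv.lsv_id] = {
            s: estimate_psi(lsv, ctx.counts.loc[list(lsv.junction_ids), s], thr, scope=s)
            for s in ctx.counts.columns
        }
    groups: dict[str, dict[str, object]] = {}
    for gname, sel in (
        ("tumor", ctx.sample_ids("tumor")),
        ("normal", ctx.sample_ids("normal")),
        ("primary", ctx.sample_ids("tumor", "primary")),
        ("recurrent", ctx.sample_ids("tumor", "recurrent")),
    ):
        if not sel:
            continue
        groups[gname] = {
            lsv.lsv_id: group_psi([per_sample[lsv.lsv_id][s] for s in sel], thr, scope=gname)
            for lsv in lsvs
        }
    return ctx.set("posteriors", (lsvs, per_sample, groups))


def stage_quantify(ctx: PipelineContext) -> None:
    lsvs, per_sample, groups = _posteriors(ctx)
    rows = []
    for lsv in lsvs:
        for gname in ("tumor", "normal"):
            post = groups[gname][lsv.lsv_id]
            for j, jid in enumerate(post.junction_ids):
                rows.append(
                    {
                        "lsv_id": lsv.lsv_id,
                        "gene_id": lsv.gene_id,
                        "junction_id": jid,
                        "group": gname,
                        "e_psi": post.e_psi[j],
                        "ci_low": post.ci95[j, 0],
                        "ci_high": post.ci95[j, 1],
                        "quantifiable": post.quantifiable,
                    }
                )
    df = pd.DataFrame(rows)
    sio.write_table(df, ctx.path("psi.tsv"))
    ctx.set("psi_table", df)
    log.info("stage=quantify lsvs=%d rows=%d", len(lsvs), len(df))


def stage_dpsi(ctx: PipelineContext) -> None:
    cfg = ctx.cfg
    lsvs, per_sample, groups = _posteriors(ctx)
    rows = []
    for contrast, a, b in (
        ("tumor_vs_normal", "tumor", "normal"),
        ("primary_vs_recurrent", "primary", "recurrent"),
    ):
        if a not in groups or b not in groups:
            continue
        for lsv in lsvs:
            ga, gb = groups[a][lsv.lsv_id], groups[b][lsv.lsv_id]
            if not (ga.quantifiable and gb.quantifiable):
                continue
            for res in delta_psi(ga, gb, cfg.dpsi_threshold, cfg.confidence):
                rows.append(
                    {
                        "contrast": contrast,
                        "lsv_id": res.lsv_id,
                        "gene_id": lsv.gene_id,
                        "junction_id": res.junction_id,
                        "e_dpsi": res.e_dpsi,
                        "p_change": res.p_change,
                        "significant": res.significant,
                    }
                )
    df = pd.DataFrame(
        rows,
        columns=["contrast", "lsv_id", "gene_id", "junction_id", "e_dpsi", "p_change", "significant"],
    )
    sio.write_table(df, ctx.path("dpsi.tsv"))
    ctx.set("dpsi_table", df)
    log.info("stage=dpsi rows=%d significant=%d", len(df), int(df["significant"].sum()) if len(df) else 0)


def stage_tumor_specific(ctx: PipelineContext) -> None:
    cfg = ctx.cfg
    lsvs, per_sample, groups = _posteriors(ctx)
    normal_ids = ctx.sample_ids("normal")
    tumor_ids = ctx.sample_ids("tumor")
    rows = []
    for lsv in lsvs:
        tumor_post = groups["tumor"][lsv.lsv_id]
        for jid in lsv.junction_ids:
            call = call_tumor_specific(
                jid,
                ctx.counts.loc[jid, normal_ids],
                tumor_post,
                psi_floor=cfg.psi_floor,
                confidence=cfg.confidence,
                normal_sample_ids=normal_ids,
            )
            pop = float((ctx.counts.loc[jid, tumor_ids] > 0).mean())
            rows.append(
                {
                    "lsv_id": lsv.lsv_id,
                    "gene_id": lsv.gene_id,
                    "junction_id": jid,
                    "normal_total_reads": call.normal_total_reads,
                    "tumor_p_psi_gt_threshold": call.tumor_p_psi_gt_threshold,
                    "group_e_psi": call.group_e_psi,
                    "population_frequency": pop,
                    "passes": call.passes,
                }
            )
    df = pd.DataFrame(rows).drop_duplicates(subset="junction_id")
    sio.write_table(df, ctx.path("neojunctions.tsv"))
    ctx.set("neojunction_table", df)
    log.info("stage=tumor_specific junctions=%d passing=%d", len(df), int(df["passes"].sum()))


def _passing_junctions(ctx: PipelineContext) -> list[str]:
    df = ctx.table("neojunction_table", "neojunctions.tsv")
    if df is None:
        raise RuntimeError("tumor-specific calls unavailable; run the tumor_specific stage first")
    return list(df.loc[df["passes"], "junction_id"])


def stage_map_domains(ctx: PipelineContext) -> None:
    rows = []
    for jid in _passing_junctions(ctx):
        jx = parse_junction(jid)
        for t in compatible_transcripts(jx, ctx.transcripts):
            locus = junction_protein_locus(jx, t, ctx.domains)
            if not hasattr(locus, "domain_label"):
                continue
            rows.append(
                {
                    "junction_id": jid,
                    "transcript_id": t.transcript_id,
                    "gene_id": t.gene_id,
                    "domain_label": locus.domain_label,
                    "aa_position": locus.aa_position,
                    "frame": locus.frame,
                    "is_surface_protein": locus.is_surface_protein,
                }
            )
    df = pd.DataFrame(
        rows,
        columns=[
            "junction_id",
            "transcript_id",
            "gene_id",
            "domain_label",
            "aa_position",
            "frame",
            "is_surface_protein",
        ],
    )
    sio.write_table(df, ctx.path("protein_loci.tsv"))
    ctx.set("locus_table", df)
    n_extr = int((df["domain_label"] == "extracellular").sum()) if len(df) else 0
    log.info("stage=map_domains loci=%d extracellular=%d", len(df), n_extr)


def _window_for(ctx: PipelineContext, jid: str, flank: int) -> Optional[JunctionWindow]:
    jx = parse_junction(jid)
    for t in compatible_transcripts(jx, ctx.transcripts):
        w = junction_window(ctx.genome, t, jx, flank)
        if isinstance(w, JunctionWindow):
            return w
    return None


def stage_peptides(ctx: PipelineContext) -> None:
    cfg = ctx.cfg
    rows = []
    windows = {}
    for jid in _passing_junctions(ctx):
        w = _window_for(ctx, jid, cfg.peptide_flank)
        if w is None:
            continue
        windows[jid] = w
        for frame, pep, spans in derive_neopeptides(w).peptides:
            rows.append(
                {
                    "junction_id": jid,
                    "frame": frame,
                    "peptide": pep,
                    "window": w.sequence,
                    "actual_left": w.actual_left,
                    "actual_right": w.actual_right,
                }
            )
    df = pd.DataFrame(
        rows, columns=["junction_id", "frame", "peptide", "window", "actual_left", "actual_right"]
    )
    sio.write_table(df, ctx.path("neopeptides.tsv"))
    with open(ctx.path("neopeptides.fa"), "w") as fh:
        for _, r in df.iterrows():
            fh.write(f">{r['junction_id']}|frame{r['frame']}\n{r['peptide']}\n")
    ctx.set("peptide_table", df)
    ctx.set("windows", windows)
    log.info("stage=peptides junctions=%d peptides=%d", len(windows), len(df))


def stage_confirm(ctx: PipelineContext) -> None:
    cfg = ctx.cfg
    peps = ctx.table("peptide_table", "neopeptides.tsv")
    if peps is None:
        raise RuntimeError("neopeptides unavailable; run the peptides stage first")
    queries = list(peps[["junction_id", "peptide"]].itertuples(index=False, name=None))
    results = confirm_peptides(queries, ctx.peptide_db, cfg.fdr_threshold, seed=ctx.cfg.seed)
    df = pd.DataFrame(
        [
            {
                "junction_id": r.junction_id,
                "peptide": r.peptide,
                "matched": r.matched,
                "decoy_hit": r.decoy_hit,
                "passes_fdr": r.passes_fdr,
            }
            for r in results
        ],
        columns=["junction_id", "peptide", "matched", "decoy_hit", "passes_fdr"],
    )
    sio.write_table(df, ctx.path("confirmations.tsv"))
    ctx.set("confirmation_table", df)
    confirmed = sorted(set(df.loc[df["passes_fdr"], "junction_id"]))
    frac, mean_n, per_case = per_case_confirmation(ctx.counts, ctx.sample_ids("tumor"), confirmed)
    summary = per_case.copy()
    sio.write_table(summary, ctx.path("case_confirmation.tsv"))
    ctx.set("case_confirmation", (frac, mean_n, per_case))
    log.info(
        "stage=confirm peptides=%d confirmed_junctions=%d case_fraction=%.2f mean_per_case=%.2f",
        len(df), len(confirmed), frac, mean_n,
    )


def stage_sc_screen(ctx: PipelineContext) -> None:
    cfg = ctx.cfg
    refs = []
    for jid in _passing_junctions(ctx):
        w = _window_for(ctx, jid, cfg.reference_flank)
        if w is not None:
            refs.append(JunctionReference(jid, w.sequence, w.midpoint))
    cells = ctx.cells.set_index("barcode")["cell_type"]
    matrix = match_reads(ctx.reads, refs, cells, cfg.min_overhang)
    freqs = cell_type_frequencies(matrix)
    spec_rows = []
    for ref in refs:
        spec_rows.append(
            {
                "junction_id": ref.junction_id,
                "neoplastic_specific": neoplastic_specific(
                    ref.junction_id, freqs, cfg.min_neoplastic_cells
                ),
                "stem_enrichment": stem_enrichment(ref.junction_id, freqs),
            }
        )
    spec = pd.DataFrame(
        spec_rows, columns=["junction_id", "neoplastic_specific", "stem_enrichment"]
    )
    sio.write_cell_matrix(matrix, ctx.path("cell_junction_matrix"))
    sio.write_table(freqs, ctx.path("sc_frequencies.tsv"))
    sio.write_table(spec, ctx.path("sc_specificity.tsv"))
    ctx.set("sc_matrix", matrix)
    ctx.set("sc_frequencies", freqs)
    ctx.set("sc_specificity", spec)
    log.info(
        "stage=sc_screen references=%d matched_reads=%d specific=%d",
        len(refs), int(matrix.counts.to_numpy().sum()), int(spec["neoplastic_specific"].sum()) if len(spec) else 0,
    )


def stage_neoantigens(ctx: PipelineContext) -> None:
    cfg = ctx.cfg
    candidates = []
    presence: dict[str, list[str]] = {}
    tumor_ids = ctx.sample_ids("tumor")
    for jid in _passing_junctions(ctx):
        w = _window_for(ctx, jid, cfg.neoantigen_flank)
        if w is None:
            continue
        for pep in enumerate_candidates(w):
            candidates.append((jid, pep))
        carriers = [s for s in tumor_ids if ctx.counts.loc[jid, s] > 0]
        presence[jid] = carriers
    predictor = PositionWeightPredictor(seed=cfg.seed)
    records = filter_strong_binders(
        candidates,
        ctx.serotypes,
        predictor,
        threshold=cfg.percent_rank_threshold,
        background_size=cfg.background_size,
        seed=cfg.seed,
        patients=presence,
    )
    df = candidates_to_frame(records)
    sio.write_table(df, ctx.path("neoantigens.tsv"))
    ctx.set("neoantigen_table", df)

    # counts of distinct (peptide, allele) neoantigens by presence group
    primary = set(ctx.sample_ids("tumor", "primary"))
    recurrent = set(ctx.sample_ids("tumor", "recurrent"))
    rows = []
    for jid, sub in df.groupby("junction_id"):
        carriers = set(presence.get(jid, []))
        if carriers & primary and carriers & recurrent:
            grp = "shared"
        elif carriers & primary:
            grp = "primary"
        elif carriers & recurrent:
            grp = "recurrent"
        else:
            grp = "none"
        rows.append(
            {
                "junction_id": jid,
                "presence_group": grp,
                "n_neoantigens": int(len(sub[["peptide", "allele"]].drop_duplicates())),
            }
        )
    by_group = pd.DataFrame(rows, columns=["junction_id", "presence_group", "n_neoantigens"])
    sio.write_table(by_group, ctx.path("neoantigen_group_counts.tsv"))
    ctx.set("neoantigen_groups", by_group)
    log.info("stage=neoantigens candidates=%d strong_binders=%d", len(candidates), len(df))


def stage_motifs(ctx: PipelineContext) -> None:
    cfg = ctx.cfg
    dpsi = ctx.table("dpsi_table", "dpsi.tsv")
    if dpsi is None:
        raise RuntimeError("differential-splicing table unavailable; run the dpsi stage first")
    sig_genes = sorted(set(dpsi.loc[dpsi["significant"], "gene_id"].dropna()))
    motifs = read_pwms(cfg.motif_file) if cfg.motif_file else bundled_motifs()
    by_gene = {}
    for t in ctx.transcripts:
        by_gene.setdefault(t.gene_id, []).append(t)
    hit_rows = []
    for gid in sig_genes:
        if gid not in by_gene:
            continue
        rep = representative_transcript(by_gene[gid])
        # scanning universe: spliced transcript plus intron flanks
        segments = [("spliced", rep.spliced_sequence(ctx.genome), None)]
        exons_t = rep.exons_in_transcript_order()
        chrom = ctx.genome[rep.contig]
        for i in range(len(rep.exons) - 1):
            s, e = rep.exons[i][1], rep.exons[i + 1][0]
            lo, hi = s, min(s + cfg.intron_flank, e)
            seg = chrom[lo:hi]
            segments.append((f"intron{i}", seg, (lo, hi)))
        for m in motifs:
            for segname, seq, giv in segments:
                if len(seq) < len(m):
                    continue
                for off, score in scan_pwm(seq, m):
                    if giv is not None:
                        start, end = giv[0] + off, giv[0] + off + len(m)
                        region = "intron"
                    else:
                        g1 = rep.transcript_to_genomic(off)
                        g2 = rep.transcript_to_genomic(off + len(m) - 1)
                        start, end = min(g1, g2), max(g1, g2) + 1
                        _, region = classify_region(by_gene[gid], rep.contig, g1, g1 + 1)
                    hit_rows.append(
                        {
                            "motif_id": m.motif_id,
                            "rbp_name": m.rbp_name,
                            "gene_id": gid,
                            "contig": rep.contig,
                            "start": min(start, end),
                            "end": max(start, end),
                            "strand": rep.strand,
                            "score": score,
                            "region_class": region,
                        }
                    )
    hits = pd.DataFrame(
        hit_rows,
        columns=[
            "motif_id", "rbp_name", "gene_id", "contig", "start", "end", "strand", "score", "region_class",
        ],
    )
    sio.write_table(hits, ctx.path("motif_hits.tsv"))
    if len(hits):
        sio.write_hits_bed(hits, ctx.path("motif_hits.bed"))
    region, ranking = summarize_hits(hits)
    sio.write_table(region.rename("fraction").reset_index(), ctx.path("motif_region_distribution.tsv"))
    sio.write_table(ranking, ctx.path("motif_ranking.tsv"))
    ctx.set("motif_hits", hits)
    ctx.set("motif_summary", (region, ranking))
    log.info("stage=motifs genes=%d hits=%d", len(sig_genes), len(hits))


# ---------------------------------------------------------------------------
# Event classification and the target report


def classify_lsv(
    lsv: LocalSpliceVariation,
    transcripts: Sequence[TranscriptModel],
    ir_junctions: frozenset = frozenset(),
) -> str:
    """Classify an LSV's alternative-splicing type from splice-graph geometry."""
    if any(j in ir_junctions for j in lsv.junction_ids):
        return "intron retention"
    js = [parse_junction(j) for j in lsv.junction_ids]
    exons = sorted(
        {
            iv
            for t in transcripts
            if t.contig == lsv.contig and t.strand == lsv.strand
            for iv in t.exons
        }
    )
    shared_left = len({j.left for j in js}) == 1
    shared_right = len({j.right for j in js}) == 1
    if shared_left == shared_right:
        return "other"
    varying = sorted(j.right for j in js) if shared_left else sorted(j.left for j in js)
    skipped = False
    for v1, v2 in zip(varying, varying[1:]):
        if shared_left:
            lo, hi = v1, v2
        else:
            lo, hi = v1, v2
        if any(lo <= s and e <= hi for s, e in exons):
            skipped = True
    if skipped:
        return "exon skipping"
    if shared_left:  # acceptor coordinate varies genomically
        return "alternative 3'" if lsv.strand == "+" else "alternative 5'"
    return "alternative 5'" if lsv.strand == "+" else "alternative 3'"


def event_type_proportions(
    lsvs: Sequence[LocalSpliceVariation],
    transcripts: Sequence[TranscriptModel],
    ir_junctions: frozenset = frozenset(),
) -> pd.Series:
    """Distribution of AS event types over a set of LSVs (sums to 1)."""
    if not lsvs:
        raise ValueError("no events")
    kinds = [classify_lsv(l, transcripts, ir_junctions) for l in lsvs]
    counts = pd.Series(kinds).value_counts()
    out = pd.Series(0.0, index=list(EVENT_TYPES))
    for k, v in counts.items():
        out[k] = v / len(kinds)
    return out


def stage_report(ctx: PipelineContext) -> pd.DataFrame:
    cfg = ctx.cfg
    neo = ctx.table("neojunction_table", "neojunctions.tsv")
    if neo is None:
        raise RuntimeError("tumor-specific calls unavailable; run the tumor_specific stage first")
    report = neo[
        ["junction_id", "gene_id", "lsv_id", "passes", "group_e_psi", "population_frequency"]
    ].rename(columns={"passes": "tumor_specific"})

    loci = ctx.table("locus_table", "protein_loci.tsv")
    if loci is not None:
        surf = loci.groupby("junction_id").agg(
            surface_protein=("is_surface_protein", "any"),
            extracellular=("domain_label", lambda s: bool((s == "extracellular").any())),
        )
        report = report.merge(surf, on="junction_id", how="left")
        for c in ("surface_protein", "extracellular"):
            report[c] = report[c].eq(True)

    spec = ctx.table("sc_specificity", "sc_specificity.tsv")
    if spec is not None:
        report = report.merge(
            spec[["junction_id", "neoplastic_specific", "stem_enrichment"]],
            on="junction_id",
            how="left",
        )
        report["neoplastic_specific"] = report["neoplastic_specific"].eq(True)

    conf = ctx.table("confirmation_table", "confirmations.tsv")
    if conf is not None:
        confirmed = conf.groupby("junction_id")["passes_fdr"].any().rename("peptide_confirmed")
        report = report.merge(confirmed, on="junction_id", how="left")
        report["peptide_confirmed"] = report["peptide_confirmed"].eq(True)

    ntab = ctx.table("neoantigen_table", "neoantigens.tsv")
    if ntab is not None:
        nb = (
            ntab[ntab["strong_binder"]]
            .groupby("junction_id")
            .apply(lambda s: len(s[["peptide", "allele"]].drop_duplicates()), include_groups=False)
            .rename("strong_binder_count")
        )
        report = report.merge(nb, on="junction_id", how="left")
        report["strong_binder_count"] = report["strong_binder_count"].fillna(0).astype(int)

    nominated = report["tumor_specific"].copy()
    for col in ("surface_protein", "extracellular"):
        if col in report:
            nominated &= report[col]
    if "neoplastic_specific" in report:
        nominated &= report["neoplastic_specific"]
    if cfg.require_confirmed and "peptide_confirmed" in report:
        nominated &= report["peptide_confirmed"]
    if cfg.require_strong_binder and "strong_binder_count" in report:
        nominated &= report["strong_binder_count"] > 0
    report["car_nominated"] = nominated

    # hard joint invariant: no nomination with normal-sample evidence
    bad = report[report["car_nominated"]].merge(
        neo[["junction_id", "normal_total_reads"]], on="junction_id"
    )
    if (bad["normal_total_reads"] > 0).any():
        raise AssertionError("nominated junction with normal-sample reads")

    lsvs, _, _ = _posteriors(ctx)
    props_all = event_type_proportions(lsvs, ctx.transcripts)
    passing_lsvs = [
        l for l in lsvs if any(j in set(_passing_junctions(ctx)) for j in l.junction_ids)
    ]
    props = pd.DataFrame({"all_events": props_all})
    if passing_lsvs:
        props["tumor_specific_events"] = event_type_proportions(passing_lsvs, ctx.transcripts)
    sio.write_table(props.reset_index(names="event_type"), ctx.path("event_type_proportions.tsv"))

    sio.write_table(report, ctx.path("target_report.tsv"))
    ctx.set("target_report", report)
    log.info(
        "stage=report junctions=%d tumor_specific=%d nominated=%d",
        len(report), int(report["tumor_specific"].sum()), int(report["car_nominated"].sum()),
    )
    return report


_STAGE_FUNCS = {
    "simulate": stage_simulate,
    "quantify": stage_quantify,
    "dpsi": stage_dpsi,
    "tumor_specific": stage_tumor_specific,
    "map_domains": stage_map_domains,
    "peptides": stage_peptides,
    "confirm": stage_confirm,
    "sc_screen": stage_sc_screen,
    "neoantigens": stage_neoantigens,
    "motifs": stage_motifs,
    "report": stage_report,
}


def run_pipeline(cfg: PipelineConfig) -> tuple[pd.DataFrame, PipelineContext]:
    """Run the enabled stages in order; returns the target report and the
    run context. A stage failure aborts with the failing stage named;
    artifacts written by earlier stages are preserved."""
    ctx = PipelineContext(cfg)
    ctx.dir.mkdir(parents=True, exist_ok=True)
    report = pd.DataFrame()
    for name in ALL_STAGES:
        if name not in cfg.stages:
            continue
        try:
            out = _STAGE_FUNCS[name](ctx)
        except Exception as exc:
            raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
        if name == "report":
            report = out
    return report, ctx
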