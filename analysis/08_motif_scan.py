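#!/usr/bin/env python
"""Scan differentially spliced genes for RNA-binding-protein motifs.

Takes the genes with significant differential splicing, scans their spliced
transcripts plus 250 nt intron flanks with the bundled PWM set (log-odds,
threshold 80% of each motif's maximum), classifies hits by gene region,
and ranks motifs by the number of genes they hit. Also computes the
cassette-exon vs gene-wide hit-density enrichment for the top motif.

Reads results/cohort/; writes motif_hits.tsv/.bed, motif_ranking.tsv and
motif_region_distribution.tsv there.
"""

from pathlib import Path

from splicescreen import io as sio
from splicescreen.motifs import bundled_motifs, exon_motif_enrichment, scan_pwm
from splicescreen.pipeline import PipelineConfig, run_pipeline

WORKDIR = Path(__file__).resolve().parent.parent / "results" / "cohort"


def main() -> None:
    cfg = PipelineConfig(workdir=WORKDIR, seed=1, stages=("motifs",))
    _, ctx = run_pipeline(cfg)
    hits = sio.read_table(ctx.path("motif_hits.tsv"))
    region = sio.read_table(ctx.path("motif_region_distribution.tsv"))
    ranking = sio.read_table(ctx.path("motif_ranking.tsv"))
    print(f"{len(hits)} motif hits in {hits.gene_id.nunique() if len(hits) else 0} "
          f"differentially spliced genes")
    if len(region):
        print("region distribution:")
        for _, row in region.iterrows():
            print(f"  {row.iloc[0]}: {row.fraction:.2f}")
    if len(ranking):
        print("top motifs by genes hit:")
        for _, row in ranking.head(3).iterrows():
            print(f"  {row.motif_id}: {row.n_genes} genes, {row.n_hits} hits")
        # cassette-exon enrichment for the top-ranked motif on one gene
        top = ranking.iloc[0].motif_id
        sub = hits[hits.motif_id == top]
        if len(sub):
            gid = sub.gene_id.iloc[0]
            t = next(t for t in ctx.transcripts if t.gene_id == gid)
            exon = t.exons[2] if len(t.exons) > 2 else t.exons[0]
            val = exon_motif_enrichment(exon, t.span, list(sub[sub.gene_id == gid].start))
            print(f"cassette-exon enrichment of {top} in {gid}: {val}")


if __name__ == "__main__":
    main()
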