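#!/usr/bin/env python
"""Generate the synthetic study cohort.

Builds a 30-gene toy genome with one alternative-splicing event per gene, a
10 tumor + 10 normal bulk junction-count cohort (tumor samples split
primary/recurrent), 300 barcoded single-cell reads' worth of five cell
types, patient HLA serotypes, and a peptide database seeded with the
junction peptides of the planted events. Eight events are planted to cover
the full CAR-nomination cascade and each of its ablations.

Writes everything under results/cohort/ (FASTA, GFF3, TSV, FASTQ).
"""

from pathlib import Path

from splicescreen.pipeline import PipelineConfig, run_pipeline

WORKDIR = Path(__file__).resolve().parent.parent / "results" / "cohort"
SEED = 1


def main() -> None:
    cfg = PipelineConfig(workdir=WORKDIR, seed=SEED, stages=("simulate",))
    _, ctx = run_pipeline(cfg)
    truth = ctx.truth
    print(f"cohort written to {WORKDIR}")
    print(f"  genes: {len(ctx.transcripts)}, junctions: {len(ctx.counts)}")
    print(f"  samples: {len(ctx.samples)} ({(ctx.samples.group == 'tumor').sum()} tumor)")
    print(f"  single-cell reads: {len(ctx.reads)}, cells: {len(ctx.cells)}")
    print(f"  planted events: {len(truth)} "
          f"({int(truth.tumor_only.sum())} tumor-only, "
          f"{int(truth.neoplastic_only.sum())} neoplastic-only, "
          f"{int(truth.in_peptide_db.sum())} in the peptide DB)")


if __name__ == "__main__":
    main()
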