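#!/usr/bin/env python
"""Project neojunctions onto protein topology.

Maps each tumor-specific junction through its compatible transcripts into
CDS/amino-acid coordinates (the residue whose codon contains the first
coding base on the acceptor side) and looks up the surface-protein domain
containing it. Junctions in extracellular domains are the CAR-target
candidates.

Reads results/cohort/; writes protein_loci.tsv there.
"""

from pathlib import Path

from splicescreen import io as sio
from splicescreen.pipeline import PipelineConfig, run_pipeline

WORKDIR = Path(__file__).resolve().parent.parent / "results" / "cohort"


def main() -> None:
    cfg = PipelineConfig(workdir=WORKDIR, seed=1, stages=("map_domains",))
    _, ctx = run_pipeline(cfg)
    loci = sio.read_table(ctx.path("protein_loci.tsv"))
    surface = loci[loci.is_surface_protein]
    print(f"mapped {loci.junction_id.nunique()} neojunctions "
          f"({surface.junction_id.nunique()} on surface proteins)")
    dist = loci.domain_label.value_counts()
    for label, n in dist.items():
        print(f"  {label}: {n}")
    n_ext = (surface.domain_label == "extracellular").sum()
    if len(surface):
        print(f"extracellular fraction among surface hits: "
              f"{100 * n_ext / len(surface):.1f}%")


if __name__ == "__main__":
    main()
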