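"""Properties of the synthetic-cohort generator: determinism, valid gene
models, planted-truth guarantees, and statistical sanity of sampled counts."""

import numpy as np
import pandas as pd
import pytest
from Bio.Seq import Seq

from splicescreen import io as sio
from splicescreen.coords import parse_junction
from splicescreen.simulate import (
    CELL_TYPES,
    NEOPLASTIC_TYPES,
    PlantedEvent,
    SimulationConfig,
    cell_table,
    generate_reference,
    planted_junction_peptides,
    simulate_junction_counts,
    simulate_peptide_db,
    simulate_sc_reads,
    standard_cohort,
)


def test_reference_is_deterministic(cohort_config, bundle):
    again = generate_reference(cohort_config)
    assert again.genome == bundle.genome
    assert again.transcripts == bundle.transcripts
    pd.testing.assert_frame_equal(again.truth, bundle.truth)
    pd.testing.assert_frame_equal(again.junctions, bundle.junctions)


def test_gene_models_are_valid(bundle):
    """Every CDS is a multiple of 3, starts with ATG, ends with a stop, and
    translates without internal stops."""
    stops = {"TAA", "TAG", "TGA"}
    n_coding = 0
    for t in bundle.transcripts:
        if not t.cds:
            continue
        n_coding += 1
        cds = t.cds_sequence(bundle.genome)
        assert len(cds) % 3 == 0
        assert cds.startswith("ATG")
        assert cds[-3:] in stops
        protein = t.protein_sequence(bundle.genome)
        assert "*" not in protein
        assert len(protein) == len(cds) // 3 - 1
    assert n_coding > 0


def test_minus_strand_exon_order_reverses(bundle):
    minus = [t for t in bundle.transcripts if t.strand == "-"]
    assert minus
    t = minus[0]
    # first transcript base comes from the genomically-last exon
    assert t.genomic_to_transcript(t.exons[-1][1] - 1) == 0
    assert t.genomic_to_transcript(t.exons[0][0]) == t.spliced_length - 1


def test_intervals_within_contig_bounds(bundle):
    for t in bundle.transcripts:
        contig_len = len(bundle.genome[t.contig])
        for s, e in t.exons + t.cds:
            assert 0 <= s < e <= contig_len
    for _, row in bundle.junctions.iterrows():
        assert 0 < row["left"] < row["right"] <= len(bundle.genome[row["contig"]])


def test_psi_truth_sums_to_one_per_lsv(bundle):
    for lt in bundle.lsv_truth:
        for group in ("tumor", "normal"):
            assert sum(lt.psi[group]) == pytest.approx(1.0, abs=1e-9)


def test_planted_junctions_exist_in_annotation(bundle):
    junction_ids = set(bundle.junctions["junction_id"])
    assert set(bundle.truth["junction_id"]) <= junction_ids


def test_truth_table_round_trips(tmp_path, bundle):
    path = tmp_path / "truth.tsv"
    sio.write_table(bundle.truth, path)
    reloaded = sio.read_table(path)
    pd.testing.assert_frame_equal(reloaded, bundle.truth.reset_index(drop=True))


class TestJunctionCounts:
    def test_tumor_only_events_have_zero_normal_reads(self, cohort_config, bundle, cohort):
        counts, samples = cohort
        normal = samples.loc[samples["group"] == "normal", "sample_id"]
        planted = bundle.truth.loc[bundle.truth["tumor_only"], "junction_id"]
        assert counts.loc[planted, normal].to_numpy().sum() == 0

    def test_degenerate_psi_yields_zero_counts(self):
        cfg = SimulationConfig(
            seed=3,
            n_genes=1,
            planted_events=[PlantedEvent(tumor_alt_psi=0.0, normal_alt_psi=0.0)],
        )
        b = generate_reference(cfg)
        counts, _ = simulate_junction_counts(cfg, b)
        alt = b.truth["junction_id"].iloc[0]
        assert (counts.loc[alt] == 0).all()

    def test_pooled_psi_approaches_truth(self):
        """Law of large numbers: pooled empirical PSI at depth 10000 over 50
        samples lands within 0.05 of the planted 0.5."""
        cfg = SimulationConfig(
            seed=11,
            n_genes=1,
            n_tumor_samples=25,
            n_normal_samples=25,
            mean_lsv_coverage=10_000,
            planted_events=[PlantedEvent(tumor_alt_psi=0.5, normal_alt_psi=0.5)],
        )
        b = generate_reference(cfg)
        counts, _ = simulate_junction_counts(cfg, b)
        canonical, alt = b.lsv_truth[0].junction_ids
        pooled = counts.loc[alt].sum() / (counts.loc[alt].sum() + counts.loc[canonical].sum())
        assert pooled == pytest.approx(0.5, abs=0.05)

    def test_rejects_nonpositive_concentration(self, bundle, cohort_config):
        import dataclasses

        cfg = dataclasses.replace(cohort_config)
        cfg.psi_concentration = 0.0
        with pytest.raises(ValueError):
            simulate_junction_counts(cfg, bundle)


@pytest.fixture(scope="module")
def sc(cohort_config, bundle):
    return simulate_sc_reads(cohort_config, bundle)


class TestSingleCellReads:
    def test_reads_are_substrings_of_spliced_isoforms(self, sc, cohort_config, bundle):
        reads, _ = sc
        # admissible sources: annotated transcripts plus alt-junction windows
        from splicescreen.peptides import junction_window
        from splicescreen.coords import Junction

        sources = [t.spliced_sequence(bundle.genome) for t in bundle.transcripts]
        for _, row in bundle.alt_junctions().iterrows():
            t = bundle.transcript_for_gene(row["gene_id"])
            jx = Junction(row["contig"], int(row["left"]), int(row["right"]), row["strand"])
            w = junction_window(bundle.genome, t, jx, flank=cohort_config.read_length)
            sources.append(w.sequence)
        blob = "\n".join(sources)
        for _, seq in reads[:300]:
            assert seq in blob

    def test_neoplastic_only_events_never_in_nonmalignant_cells(self, sc, bundle, cohort_config):
        reads, cells = sc
        ctype = cells.set_index("barcode")["cell_type"]
        restricted = bundle.truth.loc[bundle.truth["neoplastic_only"], "junction_id"]
        from splicescreen.peptides import junction_window
        from splicescreen.coords import Junction

        for jid in restricted:
            row = bundle.junctions.set_index("junction_id").loc[jid]
            t = bundle.transcript_for_gene(row["gene_id"])
            jx = parse_junction(jid)
            w = junction_window(bundle.genome, t, jx, flank=cohort_config.read_length)
            # junction-spanning = crosses the window midpoint by >=10 nt
            core = w.sequence[w.midpoint - 10 : w.midpoint + 10]
            for name, seq in reads:
                if core in seq or str(Seq(core).reverse_complement()) in seq:
                    assert ctype[name.split("|")[0]] in NEOPLASTIC_TYPES

    def test_stem_bias_shows_in_read_emission(self):
        cfg = SimulationConfig(
            seed=5,
            n_genes=1,
            n_cells_per_type={t: 200 for t in CELL_TYPES},
            planted_events=[
                PlantedEvent(tumor_only=True, neoplastic_only=True, stem_bias=2.0)
            ],
        )
        b = generate_reference(cfg)
        reads, cells = simulate_sc_reads(cfg, b)
        ctype = cells.set_index("barcode")["cell_type"]
        jid = b.truth["junction_id"].iloc[0]
        from splicescreen.peptides import junction_window
        from splicescreen.coords import Junction

        row = b.junctions.set_index("junction_id").loc[jid]
        t = b.transcript_for_gene(row["gene_id"])
        w = junction_window(b.genome, t, parse_junction(jid), flank=cfg.read_length)
        core = w.sequence[w.midpoint - 10 : w.midpoint + 10]
        expressing: dict[str, set] = {"neoplastic-stem": set(), "neoplastic-differentiated": set()}
        for name, seq in reads:
            if core in seq:
                bc = name.split("|")[0]
                ct = ctype[bc]
                if ct in expressing:
                    expressing[ct].add(bc)
        ratio = len(expressing["neoplastic-stem"]) / len(expressing["neoplastic-differentiated"])
        assert ratio >= 1.5


class TestPeptideDatabase:
    def test_planted_peptides_present_absent(self, cohort_config, bundle):
        peps = planted_junction_peptides(cohort_config, bundle)
        truth = bundle.truth.set_index("junction_id")
        in_db = [j for j in truth.index if truth.loc[j, "in_peptide_db"]]
        out_db = [j for j in truth.index if not truth.loc[j, "in_peptide_db"]]
        true_peps = sorted({p for j in in_db for p in peps.get(j, [])})
        all_peps = sorted({p for ps in peps.values() for p in ps})
        db = simulate_peptide_db(cohort_config, true_peps, exclude=all_peps)
        blob = "\n".join(db)
        for j in in_db:
            for p in peps.get(j, []):
                assert p in blob
        for j in out_db:
            for p in peps.get(j, []):
                assert p not in blob

    def test_same_seed_identical_lists(self, cohort_config):
        a = simulate_peptide_db(cohort_config, ["MKFLAT"], exclude=["MKFLAT"])
        b = simulate_peptide_db(cohort_config, ["MKFLAT"], exclude=["MKFLAT"])
        assert a == b

    def test_empty_truth_rejected(self, cohort_config):
        with pytest.raises(ValueError):
            simulate_peptide_db(cohort_config, [])


def test_cell_table_covers_all_types(cohort_config):
    cells = cell_table(cohort_config)
    assert set(cells["cell_type"]) == set(CELL_TYPES)
    assert cells["barcode"].is_unique
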