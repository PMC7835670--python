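"""Coordinate projection: transcript offsets, junction-to-protein mapping
against a brute-force translation oracle, and per-base region classes."""

import numpy as np
import pytest

from splicescreen.coords import (
    IncompatibleJunction,
    Junction,
    ProteinLocus,
    TranscriptModel,
    classify_base,
    classify_region,
    compatible_transcripts,
    junction_protein_locus,
    parse_junction,
)

import pandas as pd


def toy_transcript(strand="+"):
    # exons 0-based half-open; CDS starts 6 bases into the first exon
    return TranscriptModel(
        transcript_id="T", gene_id="G", contig="c", strand=strand,
        exons=((10, 40), (100, 160), (200, 245)),
        cds=((16, 40), (100, 160), (200, 215)),
    )


class TestOffsets:
    def test_plus_strand_first_base(self):
        t = toy_transcript("+")
        assert t.genomic_to_transcript(10) == 0
        assert t.transcript_to_genomic(0) == 10

    def test_minus_strand_first_base_is_genomically_last(self):
        t = TranscriptModel(
            transcript_id="T", gene_id="G", contig="c", strand="-",
            exons=((10, 40), (100, 160)),
        )
        assert t.genomic_to_transcript(159) == 0
        assert t.genomic_to_transcript(10) == t.spliced_length - 1
        assert t.transcript_to_genomic(0) == 159

    def test_intronic_position_is_typed_not_exception(self):
        t = toy_transcript("+")
        assert t.genomic_to_transcript(50) is None

    def test_round_trip_identity_both_strands(self, bundle, rng):
        """1000 random exonic positions: genomic -> transcript -> genomic is
        the identity, checked against a brute-force exon walk."""
        total = 0
        for t in bundle.transcripts:
            # brute-force spliced walk in transcript order
            order = t.exons if t.strand == "+" else tuple(reversed(t.exons))
            walk = []
            for s, e in order:
                walk.extend(range(s, e) if t.strand == "+" else range(e - 1, s - 1, -1))
            n = min(90, len(walk))
            for pos in rng.choice(walk, size=n, replace=False):
                off = t.genomic_to_transcript(int(pos))
                assert off == walk.index(int(pos))
                assert t.transcript_to_genomic(off) == int(pos)
                total += 1
        assert total >= 1000


class TestProteinLocus:
    def test_acceptor_side_codon_rule(self):
        """A junction whose acceptor begins codon 11 maps to residue 11 and
        picks up the extracellular label of the domain [5, 50]."""
        # CDS starts at transcript offset 6 (exon0 has a 6 nt 5'UTR region)
        t = TranscriptModel(
            transcript_id="T", gene_id="G", contig="c", strand="+",
            exons=((0, 36), (100, 200)),
            cds=((6, 36), (100, 190)),
            protein_id="P",
        )
        domains = pd.DataFrame(
            [{"protein_id": "P", "domain_label": "extracellular", "aa_start": 5, "aa_end": 50}]
        )
        # exon0 carries 30 coding bases = codons 1..10; acceptor starts codon 11
        locus = junction_protein_locus(Junction("c", 36, 100, "+"), t, domains)
        assert isinstance(locus, ProteinLocus)
        assert locus.aa_position == 11
        assert locus.frame == 0
        assert locus.domain_label == "extracellular"
        assert locus.is_surface_protein

    def test_utr3_junction_has_no_residue(self):
        t = TranscriptModel(
            transcript_id="T", gene_id="G", contig="c", strand="+",
            exons=((0, 30), (100, 130), (200, 260)),
            cds=((0, 30),),
        )
        locus = junction_protein_locus(Junction("c", 130, 200, "+"), t, None)
        assert locus.domain_label == "UTR3"
        assert locus.aa_position is None

    def test_noncoding_transcript(self):
        t = TranscriptModel(
            transcript_id="T", gene_id="G", contig="c", strand="+",
            exons=((0, 30), (100, 130)),
        )
        locus = junction_protein_locus(Junction("c", 30, 100, "+"), t, None)
        assert locus.domain_label == "noncoding"

    def test_incompatible_junction_typed(self):
        t = toy_transcript("+")
        res = junction_protein_locus(Junction("c", 55, 70, "+"), t, None)
        assert isinstance(res, IncompatibleJunction)

    def test_against_full_translation_oracle(self, bundle):
        """Brute-force oracle: translate the full spliced CDS and map the
        acceptor-side base to its residue; labels must agree for every
        alternative junction of the synthetic genes."""
        checked = 0
        for _, row in bundle.junctions.iterrows():
            jx = parse_junction(row["junction_id"])
            for t in compatible_transcripts(jx, bundle.transcripts):
                locus = junction_protein_locus(jx, t, bundle.domains)
                if not isinstance(locus, ProteinLocus) or locus.aa_position is None:
                    continue
                # oracle: base-by-base codon map of the spliced CDS
                cds_start = t.cds_start_offset
                acc = t.genomic_to_transcript(jx.acceptor_first_base)
                residue = (acc - cds_start) // 3 + 1
                assert locus.aa_position == residue
                protein = t.protein_sequence(bundle.genome)
                assert 1 <= residue <= len(protein) + 1
                if locus.is_surface_protein:
                    rows = bundle.domains[bundle.domains["protein_id"] == t.protein_id]
                    labels = [
                        r["domain_label"]
                        for _, r in rows.iterrows()
                        if r["aa_start"] <= residue <= r["aa_end"]
                    ]
                    assert labels == [locus.domain_label]
                checked += 1
        assert checked >= 10

    def test_domain_partition_is_exact(self, bundle):
        """Every residue of every surface protein carries exactly one label."""
        for pid, rows in bundle.domains.groupby("protein_id"):
            t = next(t for t in bundle.transcripts if t.protein_id == pid)
            L = len(t.protein_sequence(bundle.genome))
            cover = np.zeros(L, dtype=int)
            for _, r in rows.iterrows():
                cover[r["aa_start"] - 1 : r["aa_end"]] += 1
            assert (cover == 1).all()

    def test_planted_domain_labels_recovered(self, bundle):
        truth = bundle.truth.set_index("junction_id")
        for jid, row in truth.iterrows():
            if row["domain_label"] not in ("extracellular", "transmembrane", "cytoplasmic"):
                continue
            jx = parse_junction(jid)
            labels = set()
            for t in compatible_transcripts(jx, bundle.transcripts):
                locus = junction_protein_locus(jx, t, bundle.domains)
                if isinstance(locus, ProteinLocus) and locus.domain_label:
                    labels.add(locus.domain_label)
            assert labels == {row["domain_label"]}


class TestClassifyRegion:
    def test_cds_interval(self):
        t = toy_transcript("+")
        labels, majority = classify_region([t], "c", 20, 30)
        assert majority == "CDS"
        assert set(labels) == {"CDS"}

    def test_majority_rule_at_boundary(self):
        t = toy_transcript("+")
        # 60% exonic CDS (34..40), 40% intronic (40..44)
        labels, majority = classify_region([t], "c", 34, 44)
        assert labels.count("CDS") == 6
        assert labels.count("intron") == 4
        assert majority == "CDS"

    def test_intergenic(self):
        t = toy_transcript("+")
        _, majority = classify_region([t], "c", 300, 320)
        assert majority == "intergenic"

    def test_agrees_with_per_base_oracle(self, bundle, rng):
        transcripts = bundle.transcripts
        for _ in range(40):
            t = transcripts[int(rng.integers(len(transcripts)))]
            span = t.span
            start = int(rng.integers(max(0, span[0] - 20), span[1]))
            end = start + int(rng.integers(1, 30))
            labels, majority = classify_region([t], t.contig, start, end)
            oracle = [classify_base(t, p) for p in range(start, end)]
            assert labels == oracle
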