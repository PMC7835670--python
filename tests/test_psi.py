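"""Posterior PSI estimation, group pooling, differential PSI and the
tumor-specific filter, checked against closed forms, scipy Beta quantiles,
quadrature tail masses and Monte-Carlo sampling."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from splicescreen.psi import (
    DEFAULT_THRESHOLDS,
    LocalSpliceVariation,
    QuantifiabilityThresholds,
    build_lsvs,
    call_tumor_specific,
    delta_psi,
    dpsi_distribution,
    estimate_psi,
    group_psi,
    monte_carlo_dpsi,
    p_change_from_masses,
    tail_mass,
)
from splicescreen.simulate import PlantedEvent, SimulationConfig, generate_reference, simulate_junction_counts


def make_lsv(k=2, lsv_id="L1"):
    juncs = tuple(f"chr1:{100 + 10 * i}-{500 + 10 * i}:+" for i in range(k))
    return LocalSpliceVariation(
        lsv_id=lsv_id, gene_id="G", contig="chr1", strand="+", anchor=100,
        kind="source", junction_ids=juncs, denovo=(False,) * k,
    )


class TestEstimatePsi:
    def test_closed_form_posterior_mean(self):
        post = estimate_psi(make_lsv(), [10, 30])
        assert post.e_psi == pytest.approx([10.5 / 41, 30.5 / 41], abs=1e-12)
        assert round(post.e_psi[0], 4) == 0.2561
        assert round(post.e_psi[1], 4) == 0.7439
        assert post.quantifiable

    def test_zero_counts_prior_mean_unquantifiable(self):
        post = estimate_psi(make_lsv(), [0, 0])
        assert post.e_psi == pytest.approx([0.5, 0.5])
        assert not post.quantifiable

    def test_deep_counts_concentrate(self):
        """Beta quantile oracle: (2500, 7500) reads pin PSI near (0.25, 0.75)
        with a credible interval narrower than 0.02."""
        post = estimate_psi(make_lsv(), [2500, 7500])
        assert post.e_psi == pytest.approx([0.25, 0.75], abs=1e-3)
        a, b = 2500.5, 7500.5
        lo, hi = stats.beta.ppf([0.025, 0.975], a, b)
        assert post.ci95[0] == pytest.approx([lo, hi], abs=1e-9)
        assert (post.ci95[:, 1] - post.ci95[:, 0] < 0.02).all()

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            estimate_psi(make_lsv(), [-1, 5])

    def test_normalization_invariants(self):
        post = estimate_psi(make_lsv(k=4), [3, 0, 17, 40])
        assert post.e_psi.sum() == pytest.approx(1.0, abs=1e-9)
        assert post.binned_mass.sum(axis=1) == pytest.approx(np.ones(4), abs=1e-9)
        assert (post.ci95[:, 0] <= post.e_psi).all()
        assert (post.e_psi <= post.ci95[:, 1]).all()

    @given(
        counts=st.lists(st.integers(0, 500), min_size=3, max_size=3),
        extra=st.integers(1, 200),
    )
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_adding_reads_never_decreases_e_psi(self, counts, extra):
        lsv = make_lsv(k=3)
        before = estimate_psi(lsv, counts).e_psi[1]
        boosted = list(counts)
        boosted[1] += extra
        after = estimate_psi(lsv, boosted).e_psi[1]
        assert after >= before - 1e-12


class TestGroupPsi:
    def test_identical_posteriors_idempotent(self):
        post = estimate_psi(make_lsv(), [40, 60])
        grp = group_psi([post] * 5)
        assert grp.e_psi == pytest.approx(post.e_psi, abs=1.5 / DEFAULT_THRESHOLDS.n_bins)
        np.testing.assert_allclose(grp.binned_mass, post.binned_mass, atol=1e-12)
        assert grp.quantifiable

    def test_min_experiments_fraction(self):
        quant = estimate_psi(make_lsv(), [40, 60])
        unquant = estimate_psi(make_lsv(), [1, 2])
        grp = group_psi([quant] * 2 + [unquant] * 8)
        assert not grp.quantifiable  # 0.2 <= 0.5
        grp2 = group_psi([quant] * 6 + [unquant] * 4)
        assert grp2.quantifiable

    def test_bimodal_mixture_mean(self):
        """Two near-point-mass posteriors at PSI 0.2 and 0.8 pool to a group
        expectation within one bin width of 0.5 (direct mixture)."""
        lo = estimate_psi(make_lsv(), [2000, 8000])
        hi = estimate_psi(make_lsv(), [8000, 2000])
        grp = group_psi([lo, hi])
        assert grp.e_psi[0] == pytest.approx(0.5, abs=1.0 / DEFAULT_THRESHOLDS.n_bins)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            group_psi([])


class TestDeltaPsi:
    def test_identical_groups_no_change(self):
        grp = group_psi([estimate_psi(make_lsv(), [30, 70])] * 4)
        res = delta_psi(grp, grp)
        for r in res:
            assert r.e_dpsi == pytest.approx(0.0, abs=1e-12)
            assert not r.significant

    def test_separated_point_masses(self):
        a = group_psi([estimate_psi(make_lsv(), [9000, 1000])] * 3)
        b = group_psi([estimate_psi(make_lsv(), [2000, 8000])] * 3)
        res = delta_psi(a, b)
        assert res[0].e_dpsi == pytest.approx(0.7, abs=1.0 / DEFAULT_THRESHOLDS.n_bins)
        assert res[0].p_change > 0.99
        assert res[0].significant

    def test_mismatched_junctions_rejected(self):
        a = group_psi([estimate_psi(make_lsv(), [30, 70])])
        b = group_psi([estimate_psi(make_lsv(k=3), [30, 60, 10])])
        with pytest.raises(ValueError):
            delta_psi(a, b)

    def test_matches_monte_carlo_oracle(self, rng):
        """Binned convolution vs a 2x10^5-draw Monte-Carlo sampler of the two
        Dirichlet posteriors (the acceptance check runs the full version)."""
        lsv = make_lsv()
        for _ in range(8):
            depth = int(rng.integers(30, 300))
            ca = rng.multinomial(depth, [0.5, 0.5])
            cb = rng.multinomial(depth, rng.dirichlet([2, 2]))
            pa, pb = estimate_psi(lsv, ca), estimate_psi(lsv, cb)
            res = delta_psi(group_psi([pa]), group_psi([pb]))[0]
            mc_e, mc_p = monte_carlo_dpsi(pa.alpha, pb.alpha, 0, n_draws=200_000, rng=rng)
            assert res.e_dpsi == pytest.approx(mc_e, abs=0.02)
            assert res.p_change == pytest.approx(mc_p, abs=0.02)

    def test_dpsi_distribution_normalized(self):
        a = estimate_psi(make_lsv(), [12, 20]).binned_mass[0]
        b = estimate_psi(make_lsv(), [25, 13]).binned_mass[0]
        _, pmf = dpsi_distribution(a, b)
        assert pmf.sum() == pytest.approx(1.0, abs=1e-9)


class TestTumorSpecificFilter:
    def tumor_group(self, counts):
        return group_psi([estimate_psi(make_lsv(), counts)])

    def test_any_normal_read_vetoes(self):
        grp = self.tumor_group([90, 10])
        normal = pd.Series([0, 0, 1], index=["N1", "N2", "N3"])
        call = call_tumor_specific("chr1:100-500:+", normal, grp)
        assert not call.passes
        assert call.normal_total_reads == 1

    def test_strong_tumor_evidence_passes(self):
        """Quadrature oracle: P(PSI > 0.1 | Beta(55.5, 5.5)) ~ 1."""
        grp = self.tumor_group([55, 5])
        normal = pd.Series([0, 0, 0], index=["N1", "N2", "N3"])
        call = call_tumor_specific("chr1:100-500:+", normal, grp)
        oracle = stats.beta.sf(0.1, 55.5, 5.5)
        assert oracle > 0.999
        assert call.tumor_p_psi_gt_threshold == pytest.approx(oracle, abs=0.01)
        assert call.passes

    def test_weak_tumor_evidence_fails(self):
        grp = self.tumor_group([1, 59])
        normal = pd.Series([0, 0, 0], index=["N1", "N2", "N3"])
        call = call_tumor_specific("chr1:100-500:+", normal, grp)
        oracle = stats.beta.sf(0.1, 1.5, 59.5)
        assert oracle < 0.95
        assert call.tumor_p_psi_gt_threshold == pytest.approx(oracle, abs=0.02)
        assert not call.passes

    def test_missing_normal_sample_is_hard_error(self):
        grp = self.tumor_group([55, 5])
        normal = pd.Series([0, 0], index=["N1", "N2"])
        with pytest.raises(KeyError):
            call_tumor_specific(
                "chr1:100-500:+", normal, grp, normal_sample_ids=["N1", "N2", "N3"]
            )

    def test_tail_mass_fractional_bin(self):
        mass = np.full(40, 1 / 40)
        assert tail_mass(mass, 0.1) == pytest.approx(0.9, abs=1e-12)
        assert tail_mass(mass, 0.1125) == pytest.approx(0.8875, abs=1e-12)


class TestBuildLsvs:
    def table(self, keys, reads=20):
        return pd.DataFrame({"S1": [reads] * len(keys)}, index=pd.Index(keys, name="junction_id"))

    def transcripts(self):
        from splicescreen.coords import TranscriptModel

        return [
            TranscriptModel(
                transcript_id="T1", gene_id="G1", contig="chr1", strand="+",
                exons=((50, 100), (200, 260), (400, 470), (600, 660)),
            )
        ]

    def test_shared_donor_groups_into_one_source_lsv(self):
        keys = ["chr1:100-200:+", "chr1:100-400:+", "chr1:100-600:+"]
        lsvs = build_lsvs(self.table(keys), self.transcripts())
        source = [l for l in lsvs if l.kind == "source"]
        assert len(source) == 1
        assert source[0].junction_ids == tuple(keys)

    def test_annotated_zero_read_junction_retained(self):
        df = self.table(["chr1:100-200:+", "chr1:100-400:+"])
        df.loc["chr1:100-200:+"] = 0  # annotated: de novo filter does not apply
        lsvs = build_lsvs(df, self.transcripts())
        assert any("chr1:100-200:+" in l.junction_ids for l in lsvs)

    def test_low_coverage_denovo_junction_dropped(self):
        df = self.table(["chr1:100-200:+", "chr1:100-410:+"])  # second is unannotated
        df.loc["chr1:100-410:+"] = 5  # total == min_denovo_reads -> dropped
        assert build_lsvs(df, self.transcripts()) == []

    def test_singleton_groups_not_emitted(self):
        lsvs = build_lsvs(self.table(["chr1:100-200:+"]), self.transcripts())
        assert lsvs == []

    def test_unknown_contig_is_hard_error(self):
        with pytest.raises(ValueError, match="chrZ"):
            build_lsvs(self.table(["chrZ:100-200:+", "chrZ:100-400:+"]), self.transcripts())


def test_ci_calibration_small():
    """95% credible intervals cover the sample-level true PSI at roughly the
    nominal rate on 200 simulated quantifiable LSVs (the acceptance suite
    runs the full 1000-LSV version)."""
    rng = np.random.default_rng(99)
    lsv = make_lsv()
    covered = 0
    n = 200
    for _ in range(n):
        truth = rng.uniform(0.05, 0.95)
        psi_s = rng.dirichlet(50 * np.array([truth, 1 - truth]))
        counts = rng.multinomial(rng.poisson(100), psi_s)
        post = estimate_psi(lsv, counts)
        lo, hi = post.ci95[0]
        covered += lo <= psi_s[0] <= hi
    assert 0.88 <= covered / n <= 0.99


def test_recovery_on_planted_cohort_small():
    """Planted tumor-specific junctions are recovered from a small cohort and
    nothing with a normal read is ever called (hard invariant)."""
    events = [
        PlantedEvent(tumor_only=True, tumor_alt_psi=0.4) for _ in range(5)
    ]
    cfg = SimulationConfig(seed=21, n_genes=25, mean_lsv_coverage=60, planted_events=events)
    b = generate_reference(cfg)
    counts, samples = simulate_junction_counts(cfg, b)
    normal_ids = list(samples.loc[samples["group"] == "normal", "sample_id"])
    tumor_ids = list(samples.loc[samples["group"] == "tumor", "sample_id"])
    lsvs = build_lsvs(counts, b.transcripts)
    passing = set()
    for lsv in lsvs:
        posts = [
            estimate_psi(lsv, counts.loc[list(lsv.junction_ids), s], scope=s) for s in tumor_ids
        ]
        grp = group_psi(posts)
        for jid in lsv.junction_ids:
            call = call_tumor_specific(jid, counts.loc[jid, normal_ids], grp)
            if call.passes:
                passing.add(jid)
                assert counts.loc[jid, normal_ids].sum() == 0
    planted = set(b.truth["junction_id"])
    assert len(planted & passing) >= 4  # recall >= 0.8 at this small scale
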