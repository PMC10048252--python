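"""Synthetic-cohort generator: haplotype algebra, cohort structure,
expression states, read sets, qPCR plates and the CHX time course."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from inpp5d_iso import (ChxParams, SimConfig, haplotype_frequencies,
                        load_paper_fixture, simulate_amplicon_reads,
                        simulate_chx_timecourse, simulate_cohort,
                        simulate_expression, simulate_qpcr_plate,
                        StandardCurve)
from inpp5d_iso.cohort_sim import cohort_to_frame


class TestHaplotypeFrequencies:
    def test_perfect_ld_symmetric(self):
        hm = haplotype_frequencies(0.5, 0.5, 1.0)
        assert hm.as_array() == pytest.approx([0.5, 0.0, 0.0, 0.5])

    def test_linkage_equilibrium_factorizes(self):
        hm = haplotype_frequencies(0.498, 0.220, 0.0)
        assert hm.haplotype_freqs[(True, True)] == pytest.approx(0.10956)

    def test_study_maf_and_r2(self):
        hm = haplotype_frequencies(0.498, 0.220, 0.18)
        d_expected = math.sqrt(0.18 * 0.498 * 0.502 * 0.220 * 0.780)
        assert hm.d == pytest.approx(d_expected)
        assert hm.haplotype_freqs[(True, True)] == pytest.approx(0.1975,
                                                                 abs=5e-4)

    def test_infeasible_r2_names_maximum(self):
        with pytest.raises(ValueError, match="maximum achievable r2"):
            haplotype_frequencies(0.05, 0.95, 1.0)

    @given(maf_a=st.floats(0.05, 0.95), maf_b=st.floats(0.05, 0.95),
           r2_frac=st.floats(0.0, 1.0),
           d_sign=st.sampled_from([1, -1]))
    @settings(deadline=None, max_examples=100, derandomize=True)
    def test_round_trip_marginals_and_r2(self, maf_a, maf_b, r2_frac, d_sign):
        """Returned frequencies reproduce the requested marginals and r²."""
        pa, qa, pb, qb = maf_a, 1 - maf_a, maf_b, 1 - maf_b
        d_max = min(pa * qb, qa * pb) if d_sign > 0 else min(pa * pb, qa * qb)
        r2 = r2_frac * d_max ** 2 / (pa * qa * pb * qb)
        hm = haplotype_frequencies(maf_a, maf_b, r2, d_sign=d_sign)
        f = hm.as_array()
        assert f.sum() == pytest.approx(1.0, abs=1e-9)
        assert np.all(f >= 0)
        assert f[0] + f[1] == pytest.approx(maf_a, abs=1e-9)
        assert f[0] + f[2] == pytest.approx(maf_b, abs=1e-9)
        d = f[0] - (f[0] + f[1]) * (f[0] + f[2])
        assert d ** 2 / (pa * qa * pb * qb) == pytest.approx(r2, abs=1e-9)


class TestSimulateCohort:
    def test_exact_ad_split(self, hap_model):
        cohort = simulate_cohort(56, hap_model, ad_fraction=0.5, seed=7)
        assert sum(s.ad_status == "AD" for s in cohort) == 28
        assert sum(s.niari == "high" for s in cohort) == 28
        assert all((s.niari == "high") == (s.ad_status == "AD")
                   for s in cohort)

    def test_determinism(self, hap_model):
        a = cohort_to_frame(simulate_cohort(40, hap_model, seed=11))
        b = cohort_to_frame(simulate_cohort(40, hap_model, seed=11))
        assert a.equals(b)

    def test_degenerate_reporter_maf(self, hap_model):
        cohort = simulate_cohort(30, hap_model, reporter_maf=0.0, seed=3)
        assert all(s.genotype_rs1141328 == "GG" for s in cohort)

    def test_hwe_genotype_frequencies_large_n(self, hap_model):
        """Genotype frequencies in a big cohort match HWE within 3 SE."""
        n = 20_000
        cohort = simulate_cohort(n, hap_model, seed=5)
        for snp, maf in (("rs35349669", 0.498), ("rs10933431", 0.220)):
            hom_minor = sum(not s.is_heterozygous(snp)
                            and s.genotype(snp)[0] ==
                            {"rs35349669": "T", "rs10933431": "G"}[snp]
                            for s in cohort)
            het = sum(s.is_heterozygous(snp) for s in cohort)
            for observed, p in ((hom_minor, maf ** 2),
                                (het, 2 * maf * (1 - maf))):
                se = math.sqrt(n * p * (1 - p))
                assert abs(observed - n * p) < 3 * se


class TestPaperFixture:
    def test_genotype_table_cells(self, fixture_tables):
        gt, _ = fixture_tables
        assert gt.loc["GC", "TC"] == 15
        assert int(gt.to_numpy().sum()) == 61

    def test_cohort_composition(self, fixture_tables):
        _, ct = fixture_tables
        assert len(ct) == 56
        assert (ct.ad_status == "AD").sum() == 28
        hets = ct[ct.genotype_rs1141328 == "GA"]
        assert len(hets) == 26
        counts = hets.groupby(["ad_status", "sex"]).size().to_dict()
        assert counts == {("AD", "M"): 5, ("AD", "F"): 6,
                          ("non-AD", "M"): 8, ("non-AD", "F"): 7}

    def test_bit_identical_across_calls(self, fixture_tables):
        gt, ct = fixture_tables
        gt2, ct2 = load_paper_fixture()
        assert gt.equals(gt2) and ct.equals(ct2)


class TestSimulateExpression:
    def test_null_aei_effect_gives_unit_ratio(self, hap_model):
        cohort = simulate_cohort(60, hap_model, seed=2)
        states = simulate_expression(cohort, SimConfig(aei_effect=1.0), seed=2)
        for s, st_ in zip(cohort, states):
            if s.is_heterozygous("rs1141328"):
                assert st_.allelic_ratio_true == 1.0
            else:
                assert st_.allelic_ratio_true is None

    def test_null_niari_fold_balances_groups(self, hap_model):
        cohort = simulate_cohort(600, hap_model, seed=4)
        cfg = SimConfig(niari_fold_effects={}, microglia_log10_sd=0.0)
        states = simulate_expression(cohort, cfg, seed=4)
        hi = [math.log10(st_.copies["ex10-ex12"]) for s, st_ in
              zip(cohort, states) if s.niari == "high"]
        lo = [math.log10(st_.copies["ex10-ex12"]) for s, st_ in
              zip(cohort, states) if s.niari == "low"]
        assert abs(np.mean(hi) - np.mean(lo)) < 0.05

    def test_default_d47_fraction_near_13_percent(self, hap_model):
        cohort = simulate_cohort(400, hap_model, seed=9)
        states = simulate_expression(cohort, SimConfig(), seed=9)
        assert np.mean([s.d47_fraction for s in states]) == pytest.approx(
            0.13, abs=0.01)

    def test_nonpositive_fold_rejected(self, hap_model):
        cohort = simulate_cohort(5, hap_model, seed=1)
        with pytest.raises(ValueError, match="fold"):
            simulate_expression(
                cohort, SimConfig(niari_fold_effects={"ex2-ex3": 0.0}))


class TestSimulateAmpliconReads:
    def _het_sample(self, hap_model):
        cohort = simulate_cohort(50, hap_model, seed=21)
        states = simulate_expression(cohort, SimConfig(), seed=21)
        by_id = {s.sample_id: s for s in states}
        sample = next(s for s in cohort if s.is_heterozygous("rs1141328"))
        return sample, by_id[sample.sample_id]

    def test_homozygote_yields_single_allele(self, hap_model, kmer_pair):
        cohort = simulate_cohort(50, hap_model, seed=22)
        states = simulate_expression(cohort, SimConfig(), seed=22)
        sample = next(s for s in cohort if s.genotype_rs1141328 == "GG")
        state = next(s for s in states if s.sample_id == sample.sample_id)
        reads = simulate_amplicon_reads(sample, "cDNA", state, kmer_pair,
                                        depth=1000, error_rate=0.0,
                                        barcode="AAAA", seed=1)
        assert len(reads) == 1000
        assert all(kmer_pair.kmer_allele1 in r.sequence for r in reads)

    def test_gdna_heterozygote_unbiased(self, hap_model, kmer_pair):
        sample, state = self._het_sample(hap_model)
        reads = simulate_amplicon_reads(sample, "gDNA", state, kmer_pair,
                                        depth=20_000, error_rate=0.0,
                                        barcode="AAAA", seed=2)
        frac = np.mean([kmer_pair.kmer_allele1 in r.sequence for r in reads])
        assert frac == pytest.approx(0.5, abs=4 * math.sqrt(0.25 / 20_000))

    def test_deterministic_under_seed(self, hap_model, kmer_pair):
        sample, state = self._het_sample(hap_model)
        kw = dict(depth=200, error_rate=0.01, barcode="ACGT", seed=33)
        a = simulate_amplicon_reads(sample, "cDNA", state, kmer_pair, **kw)
        b = simulate_amplicon_reads(sample, "cDNA", state, kmer_pair, **kw)
        assert a == b

    def test_unknown_material_rejected(self, hap_model, kmer_pair):
        sample, state = self._het_sample(hap_model)
        with pytest.raises(ValueError, match="material"):
            simulate_amplicon_reads(sample, "RNA", state, kmer_pair,
                                    depth=10, error_rate=0.0, barcode="A",
                                    seed=0)


class TestSimulateQpcrPlate:
    curve = StandardCurve(slope=-3.3219, intercept=37.0, efficiency=1.0,
                          r_squared=1.0)

    def _states(self, hap_model):
        cohort = simulate_cohort(4, hap_model, seed=6)
        return simulate_expression(cohort, SimConfig(), seed=6)

    def test_noise_free_log_linearity(self, hap_model):
        plate = simulate_qpcr_plate(self._states(hap_model), self.curve,
                                    qpcr_sd=0.0, seed=0)
        std = plate[plate.well_type == "standard"]
        by_level = std.groupby("copies")["cq"].mean().sort_index()
        spacing = -np.diff(by_level.to_numpy())
        assert spacing == pytest.approx([3.3219] * len(spacing), abs=1e-9)

    def test_unit_copies_hit_intercept(self):
        class One:
            sample_id = "x"
            copies = {"a": 1.0}
        plate = simulate_qpcr_plate([One()], self.curve, qpcr_sd=0.0, seed=0,
                                    standard_copies=(10.0, 100.0))
        cq = plate[plate.sample_id == "x"]["cq"]
        assert np.allclose(cq, self.curve.intercept)

    def test_deterministic(self, hap_model):
        states = self._states(hap_model)
        a = simulate_qpcr_plate(states, self.curve, qpcr_sd=0.2, seed=5)
        b = simulate_qpcr_plate(states, self.curve, qpcr_sd=0.2, seed=5)
        assert a.equals(b)


class TestChxTimecourse:
    def test_default_design_shape(self):
        tc = simulate_chx_timecourse(ChxParams(), seed=0)
        assert len(tc) == 4 * 2 * 3
        assert set(tc.treatment) == {"CHX", "vehicle"}

    def test_noise_free_arithmetic(self):
        tc = simulate_chx_timecourse(
            ChxParams(baseline=0.13, increment=0.02, noise_sd=0.0), seed=0)
        at8 = tc[(tc.time_h == 8.0) & (tc.treatment == "CHX")].d47_fraction
        assert np.allclose(at8, 0.29)
        veh = tc[tc.treatment == "vehicle"].d47_fraction
        assert np.allclose(veh, 0.13)

    def test_null_increment_equalizes_arms(self):
        tc = simulate_chx_timecourse(
            ChxParams(increment=0.0, noise_sd=0.0), seed=0)
        assert tc.groupby("treatment")["d47_fraction"].mean().nunique() == 1

    def test_invalid_baseline_rejected(self):
        with pytest.raises(ValueError, match="baseline"):
            simulate_chx_timecourse(ChxParams(baseline=1.5), seed=0)
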