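import math

import numpy as np
import pytest

from mrkit.instruments import (
    HarmonizedDataset,
    InstrumentRecord,
    annotate_confounders,
    apply_proxies,
    f_statistic,
    filter_genome_wide,
    filter_weak,
    harmonize,
    ld_clump,
)
from mrkit.simulate import SyntheticConfig, scenario, simulate_two_sample
from mrkit.summary_io import AnnotationTable, LDTable, ProxyEntry, ProxyTable

from conftest import make_assoc


class TestGenomeWideFilter:
    def test_strict_inequality_at_boundary(self):
        recs = [
            make_assoc(snp="rs1", pval=1e-9),
            make_assoc(snp="rs2", pval=5e-8),
            make_assoc(snp="rs3", pval=1e-7),
        ]
        kept = filter_genome_wide(recs, 5e-8)
        assert [r.snp_id for r in kept] == ["rs1"]

    def test_threshold_one_keeps_all_below_one(self):
        recs = [make_assoc(snp=f"rs{i}", pval=0.1 * i + 0.01) for i in range(5)]
        assert filter_genome_wide(recs, 1.0) == recs

    def test_null_gwas_yields_no_hits(self):
        # 100 null SNPs: expected count 100 * 5e-8, i.e. essentially zero
        d = simulate_two_sample(
            SyntheticConfig(j=100, theta_true=0.0, gamma_mean=0.0, gamma_sd=0.0, seed=3)
        )
        assert filter_genome_wide(d.exposure, 5e-8) == []


class TestLDClump:
    def _pair(self, p_a=1e-10, p_b=1e-9, pos_b=2000):
        a = make_assoc(snp="rsA", pval=p_a, pos=1000)
        b = make_assoc(snp="rsB", pval=p_b, pos=pos_b)
        return [a, b]

    def test_correlated_pair_keeps_more_significant(self):
        recs = self._pair()
        kept = ld_clump(recs, LDTable([("rsA", "rsB", 0.5)]))
        assert [r.snp_id for r in kept] == ["rsA"]

    def test_low_r2_pair_keeps_both(self):
        recs = self._pair()
        kept = ld_clump(recs, LDTable([("rsA", "rsB", 0.005)]))
        assert [r.snp_id for r in kept] == ["rsA", "rsB"]

    def test_outside_window_keeps_both(self):
        recs = self._pair(pos_b=20_000_001)
        kept = ld_clump(recs, LDTable([("rsA", "rsB", 0.5)]))
        assert [r.snp_id for r in kept] == ["rsA", "rsB"]

    def test_missing_position_errors(self):
        recs = [make_assoc(snp="rsA", pos=None)]
        with pytest.raises(ValueError, match="chrom/pos"):
            ld_clump(recs, LDTable())

    def test_every_discard_is_justified(self):
        # Invariant: each dropped SNP has r2 above threshold with some
        # retained index SNP within the window.
        rng = np.random.default_rng(0)
        recs = [
            make_assoc(snp=f"rs{i:02d}", pval=float(rng.uniform(1e-12, 1e-8)),
                       pos=1000 + i * 1000)
            for i in range(20)
        ]
        entries = []
        for i in range(20):
            for j in range(i + 1, 20):
                if rng.random() < 0.3:
                    entries.append((f"rs{i:02d}", f"rs{j:02d}", float(rng.uniform(0, 1))))
        ld = LDTable(entries)
        kept = ld_clump(recs, ld, r2_max=0.01, window_bp=10_000_000)
        kept_ids = {r.snp_id for r in kept}
        for r in recs:
            if r.snp_id not in kept_ids:
                assert any(ld.r2(r.snp_id, k) > 0.01 for k in kept_ids)


class TestProxies:
    def test_missing_snp_replaced_by_good_proxy(self):
        recs = [make_assoc(snp="rs1", beta=0.1)]
        proxies = ProxyTable([ProxyEntry("rs1", "rs9", 0.9, True)])
        out = apply_proxies(recs, {"rs9"}, proxies)
        assert out.records[0].snp_id == "rs9"
        assert out.records[0].beta == 0.1
        assert out.log == [("rs1", "proxied_by:rs9")]

    def test_boundary_r2_dropped(self):
        recs = [make_assoc(snp="rs1")]
        proxies = ProxyTable([ProxyEntry("rs1", "rs9", 0.8, True)])
        out = apply_proxies(recs, {"rs9"}, proxies)
        assert out.records == [] and out.log == [("rs1", "dropped_no_proxy")]

    def test_present_snp_unchanged(self):
        recs = [make_assoc(snp="rs1")]
        out = apply_proxies(recs, {"rs1"}, ProxyTable())
        assert out.records == recs

    def test_opposite_orientation_proxy_flips_beta(self):
        recs = [make_assoc(snp="rs1", beta=0.1, eaf=0.3)]
        proxies = ProxyTable([ProxyEntry("rs1", "rs9", 0.95, False)])
        out = apply_proxies(recs, {"rs9"}, proxies)
        assert out.records[0].beta == -0.1
        assert out.records[0].eaf == pytest.approx(0.7)

    def test_best_proxy_wins_with_rsid_tiebreak(self):
        recs = [make_assoc(snp="rs1")]
        proxies = ProxyTable([
            ProxyEntry("rs1", "rs8", 0.9, True),
            ProxyEntry("rs1", "rs7", 0.9, True),
            ProxyEntry("rs1", "rs6", 0.85, True),
        ])
        out = apply_proxies(recs, {"rs6", "rs7", "rs8"}, proxies)
        assert out.records[0].snp_id == "rs7"


class TestWeakFilter:
    def test_f_arithmetic_and_boundary(self):
        strong = InstrumentRecord("rs1", make_assoc(beta=0.05, se=0.01))
        weak = InstrumentRecord("rs2", make_assoc(beta=0.03, se=0.01))
        assert strong.f_stat == pytest.approx(25.0)
        assert weak.f_stat == pytest.approx(9.0)
        kept = filter_weak([strong, weak], f_min=10)
        assert [r.snp_id for r in kept] == ["rs1"]

    def test_exact_threshold_kept(self):
        rec = InstrumentRecord("rs1", make_assoc(beta=math.sqrt(10) * 0.01, se=0.01))
        assert rec.f_stat == pytest.approx(10.0)
        assert filter_weak([rec], f_min=10) == [rec]


class TestHarmonize:
    def test_swapped_alleles_sign_flip(self):
        exp = [make_assoc(snp="rs1", ea="A", oa="G", beta=0.1, eaf=0.3)]
        out = [make_assoc(snp="rs1", ea="G", oa="A", beta=0.05, eaf=0.7)]
        data = harmonize(exp, out)
        row = data.rows[0]
        assert row.action == "sign_flipped"
        assert row.beta_y == pytest.approx(-0.05)
        assert row.eaf_y == pytest.approx(0.3)

    def test_palindromic_intermediate_frequency_dropped(self):
        exp = [make_assoc(snp="rs1", ea="A", oa="T", eaf=0.499)]
        out = [make_assoc(snp="rs1", ea="A", oa="T", eaf=0.499)]
        data = harmonize(exp, out)
        assert data.rows[0].action == "dropped_palindromic"
        assert data.n_snp == 0

    def test_palindromic_clear_frequency_oriented_by_eaf(self):
        exp = [make_assoc(snp="rs1", ea="A", oa="T", beta=0.1, eaf=0.2)]
        out = [make_assoc(snp="rs1", ea="A", oa="T", beta=0.05, eaf=0.8)]
        data = harmonize(exp, out)
        row = data.rows[0]
        assert row.action == "sign_flipped"
        assert row.beta_y == pytest.approx(-0.05)

    def test_palindromic_missing_eaf_dropped_conservatively(self):
        exp = [make_assoc(snp="rs1", ea="A", oa="T", eaf=None)]
        out = [make_assoc(snp="rs1", ea="A", oa="T", eaf=0.2)]
        assert harmonize(exp, out).rows[0].action == "dropped_palindromic"

    def test_strand_flip_retained(self):
        exp = [make_assoc(snp="rs1", ea="C", oa="T", beta=0.1, eaf=0.3)]
        out = [make_assoc(snp="rs1", ea="G", oa="A", beta=0.05, eaf=0.3)]
        data = harmonize(exp, out)
        row = data.rows[0]
        assert row.action == "strand_flipped"
        assert row.beta_y == pytest.approx(0.05)

    def test_strand_flip_plus_swap(self):
        exp = [make_assoc(snp="rs1", ea="C", oa="T", beta=0.1, eaf=0.3)]
        out = [make_assoc(snp="rs1", ea="A", oa="G", beta=0.05, eaf=0.7)]
        row = harmonize(exp, out).rows[0]
        assert row.action == "strand_flipped_and_sign_flipped"
        assert row.beta_y == pytest.approx(-0.05)

    def test_irreconcilable_alleles_dropped(self):
        exp = [make_assoc(snp="rs1", ea="A", oa="G")]
        out = [make_assoc(snp="rs1", ea="A", oa="C")]
        assert harmonize(exp, out).rows[0].action == "dropped_unresolvable"

    def test_intersection_only(self):
        exp = [make_assoc(snp="rs1"), make_assoc(snp="rs2")]
        out = [make_assoc(snp="rs2")]
        data = harmonize(exp, out)
        assert [r.snp_id for r in data.rows] == ["rs2"]

    def test_involution_on_aligned_data(self):
        # Harmonizing an already-aligned pair is the identity.
        exp = [make_assoc(snp=f"rs{i}", beta=0.1 + 0.01 * i) for i in range(5)]
        out = [make_assoc(snp=f"rs{i}", beta=0.05 - 0.01 * i) for i in range(5)]
        first = harmonize(exp, out)
        assert all(r.action == "unchanged" for r in first.rows)
        again = harmonize(exp, out)
        assert first.to_frame().equals(again.to_frame())

    def test_recovers_truth_under_corruption(self):
        # With planted allele swaps and strand flips, harmonization must
        # restore the true aligned outcome effect for every retained
        # non-palindromic SNP.
        d = simulate_two_sample(scenario("palindrome_mix", seed=11))
        data = harmonize(d.exposure, d.outcome)
        truth = d.truth.set_index("snp")
        checked = 0
        for row in data.rows:
            if truth.loc[row.snp_id, "palindromic"]:
                continue
            assert row.retained
            assert row.beta_y == pytest.approx(
                truth.loc[row.snp_id, "beta_y_hat_aligned"], rel=1e-12
            )
            checked += 1
        assert checked > 0


class TestAnnotateConfounders:
    def test_flagged_and_clean(self):
        ann = AnnotationTable([("rs1", "periodontitis"), ("rs2", "height")])
        report = annotate_confounders(["rs1", "rs2"], ann, ["periodontitis"])
        assert report == {"rs1": ["periodontitis"], "rs2": []}

    def test_no_annotations_all_clean(self):
        report = annotate_confounders(["rs1"], AnnotationTable(), ["smoking"])
        assert report == {"rs1": []}

    def test_empty_confounder_list_all_clean(self):
        ann = AnnotationTable([("rs1", "smoking")])
        assert annotate_confounders(["rs1"], ann, []) == {"rs1": []}
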