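"""Allele alignment rules, palindrome resolution, proxies, and invariants."""

import numpy as np
import pytest

import mrkit
from mrkit.harmonization import (DROPPED, KEPT, PALINDROMIC_ALIGNED, SIGN_FLIPPED,
                                 STRAND_COMPLEMENTED, HarmonizationError, harmonize)

from conftest import random_table


def rec(snp="rs1", ea="A", oa="G", beta=0.1, se=0.01, p=1e-9, eaf=0.3, n=50000):
    return mrkit.GwasRecord(snp, ea, oa, beta, se, p, eaf=eaf, n=n)


def one_pair(exp_rec, out_rec, window=(0.42, 0.58)):
    exp = mrkit.SummaryStatsTable("exp", "continuous", [exp_rec])
    out = mrkit.SummaryStatsTable("out", "binary", [out_rec])
    return harmonize(exp, out, window)


class TestAlignmentRules:
    def test_identical_orientation_unchanged(self):
        ds = one_pair(rec(ea="A", oa="G", beta=0.1), rec(ea="A", oa="G", beta=0.05))
        assert ds.by[0] == 0.05 and ds.bx[0, 0] == 0.1
        assert ds.provenance["rs1"] == (KEPT, "")

    def test_swapped_orientation_negates_outcome(self):
        ds = one_pair(rec(ea="A", oa="G", beta=0.1), rec(ea="G", oa="A", beta=0.05, eaf=0.7))
        assert ds.by[0] == -0.05
        assert ds.eaf_y[0] == pytest.approx(0.3)
        assert ds.provenance["rs1"] == (SIGN_FLIPPED, "")

    def test_complementary_strand_resolved(self):
        # A/G on one strand is T/C on the other: same orientation after complement
        ds = one_pair(rec(ea="A", oa="G", beta=0.1), rec(ea="T", oa="C", beta=0.05))
        assert ds.by[0] == 0.05
        assert ds.provenance["rs1"] == (STRAND_COMPLEMENTED, "")

    def test_complement_plus_swap_negates(self):
        ds = one_pair(rec(ea="A", oa="G", beta=0.1), rec(ea="C", oa="T", beta=0.05))
        assert ds.by[0] == -0.05

    def test_incompatible_alleles_dropped(self):
        exp = mrkit.SummaryStatsTable("exp", "continuous",
                                      [rec(ea="A", oa="G"), rec("rs2", ea="A", oa="G")])
        out = mrkit.SummaryStatsTable("out", "binary",
                                      [rec(ea="A", oa="C", beta=0.05),
                                       rec("rs2", ea="A", oa="G", beta=0.05)])
        ds = harmonize(exp, out)
        assert ds.snp_ids == ["rs2"]
        assert ds.provenance["rs1"] == (DROPPED, "incompatible alleles")

    @pytest.mark.parametrize(
        "eaf_exp,eaf_out,expected_sign",
        [
            # rule-table oracle over all eaf quadrants, window (0.42, 0.58)
            (0.30, 0.30, +1),  # both low: same side, keep
            (0.30, 0.71, -1),  # opposite sides: flip
            (0.70, 0.30, -1),
            (0.70, 0.70, +1),
            (0.10, 0.41, +1),  # just outside the window, same side
        ],
    )
    def test_palindrome_eaf_quadrants(self, eaf_exp, eaf_out, expected_sign):
        ds = one_pair(rec(ea="A", oa="T", eaf=eaf_exp),
                      rec(ea="A", oa="T", beta=0.05, eaf=eaf_out))
        assert ds.by[0] == pytest.approx(expected_sign * 0.05)

    @pytest.mark.parametrize("eaf_out", [0.50, 0.45, 0.57, None])
    def test_ambiguous_palindrome_dropped(self, eaf_out):
        exp = mrkit.SummaryStatsTable(
            "exp", "continuous", [rec(ea="C", oa="G", eaf=0.3), rec("rs2")])
        out = mrkit.SummaryStatsTable(
            "out", "binary", [rec(ea="C", oa="G", beta=0.05, eaf=eaf_out),
                              rec("rs2", beta=0.05)])
        ds = harmonize(exp, out)
        assert "rs1" not in ds.snp_ids
        action, reason = ds.provenance["rs1"]
        assert action == DROPPED and "ambiguous palindrome" in reason

    def test_swapped_palindrome_with_concordant_freq_recovered(self):
        # outcome reports the other allele: swap then frequency check agrees
        ds = one_pair(rec(ea="A", oa="T", eaf=0.3),
                      rec(ea="T", oa="A", beta=-0.05, eaf=0.7))
        assert ds.by[0] == pytest.approx(0.05)

    def test_zero_survivors_fatal_with_reasons(self):
        exp = mrkit.SummaryStatsTable("exp", "continuous", [rec(ea="A", oa="T", eaf=0.5)])
        out = mrkit.SummaryStatsTable("out", "binary", [rec(ea="A", oa="T", eaf=0.5)])
        with pytest.raises(HarmonizationError, match="ambiguous palindrome"):
            harmonize(exp, out)


class TestMultivariableMode:
    def test_missing_exposure_zero_beta_inf_se(self):
        e1 = mrkit.SummaryStatsTable("e1", "continuous", [rec(), rec("rs2")])
        e2 = mrkit.SummaryStatsTable("e2", "continuous", [rec()])
        out = mrkit.SummaryStatsTable("out", "binary",
                                      [rec(beta=0.05), rec("rs2", beta=0.02)])
        ds = harmonize([e1, e2], out, mode="multivariable")
        assert ds.snp_ids == ["rs1", "rs2"]
        j = ds.snp_ids.index("rs2")
        assert ds.bx[j, 1] == 0.0 and np.isinf(ds.sx[j, 1])

    def test_univariable_mode_drops_partial_snps(self):
        e1 = mrkit.SummaryStatsTable("e1", "continuous", [rec(), rec("rs2")])
        e2 = mrkit.SummaryStatsTable("e2", "continuous", [rec()])
        out = mrkit.SummaryStatsTable("out", "binary",
                                      [rec(beta=0.05), rec("rs2", beta=0.02)])
        ds = harmonize([e1, e2], out, mode="univariable")
        assert ds.snp_ids == ["rs1"]


class TestInvariants:
    @pytest.mark.parametrize("seed", range(5))
    def test_idempotence(self, seed):
        """Re-harmonizing an already-harmonized dataset changes nothing and
        tags every SNP kept-as-is."""
        cfg = mrkit.SimConfig(n_snps=60, n_exposures=2, theta=(0.3, 0.0),
                              palindromic_frac=0.3, flip_frac=0.3, seed=seed)
        exps, out, _ = mrkit.simulate_dataset(cfg)
        ds1 = harmonize(exps, out, mode="multivariable")
        exps2, out2 = ds1.to_tables()
        ds2 = harmonize(exps2, out2, mode="multivariable")
        assert ds2.snp_ids == ds1.snp_ids
        np.testing.assert_array_equal(ds2.bx, ds1.bx)
        np.testing.assert_array_equal(ds2.by, ds1.by)
        assert all(ds2.provenance[s][0] == KEPT for s in ds2.snp_ids)

    @pytest.mark.parametrize("seed", range(5))
    def test_orientation_invariance(self, seed):
        """Swapping both alleles and negating beta of arbitrary input records
        leaves the harmonized matrices (and the IVW estimate) unchanged."""
        cfg = mrkit.SimConfig(n_snps=80, n_exposures=1, theta=(0.4,),
                              palindromic_frac=0.25, flip_frac=0.0, seed=100 + seed)
        (exp,), out, _ = mrkit.simulate_dataset(cfg)
        rng = np.random.default_rng(seed)
        flip_out = {r.snp_id for r in out if rng.random() < 0.5}
        flip_exp = {r.snp_id for r in exp if rng.random() < 0.5}
        out2 = mrkit.SummaryStatsTable(
            out.trait_id, out.trait_type,
            [r.flipped() if r.snp_id in flip_out else r for r in out])
        exp2 = mrkit.SummaryStatsTable(
            exp.trait_id, exp.trait_type,
            [r.flipped() if r.snp_id in flip_exp else r for r in exp])

        ds_a = harmonize(exp, out)
        ds_b = harmonize(exp2, out2)
        assert ds_a.snp_ids == ds_b.snp_ids
        est_a = mrkit.ivw_fixed_effects(ds_a.bx[:, 0], ds_a.sx[:, 0], ds_a.by, ds_a.sy)
        est_b = mrkit.ivw_fixed_effects(ds_b.bx[:, 0], ds_b.sx[:, 0], ds_b.by, ds_b.sy)
        assert est_a.beta == pytest.approx(est_b.beta, abs=1e-14)

    def test_conservation_every_snp_accounted(self):
        rng = np.random.default_rng(42)
        exp = random_table(rng, 30, "exp")
        out = random_table(rng, 30, "out")
        ds = harmonize(exp, out)
        common = set(exp.snp_ids) & set(out.snp_ids)
        prov = {s: v for s, v in ds.provenance.items()
                if "absent from" not in v[1]}  # outcome-only SNPs logged separately
        assert set(prov) == common
        kept = {s for s, (a, _) in ds.provenance.items() if a != DROPPED}
        dropped = {s for s, (a, r) in ds.provenance.items() if a == DROPPED}
        assert kept | dropped == common and not kept & dropped
        assert set(ds.snp_ids) == kept
        assert all(r for _, (a, r) in ds.provenance.items() if a == DROPPED)


class TestFindProxies:
    def make_candidates(self, specs):
        return mrkit.SummaryStatsTable(
            "out", "binary",
            [rec(s, beta=0.05, p=p) for s, p in specs])

    def test_high_ld_proxy_found(self):
        ld = mrkit.LdTable()
        ld.set("target", "rs9", 0.9)
        cands = self.make_candidates([("rs9", 1e-9)])
        assert mrkit.find_proxies("target", cands, ld, r2_min=0.8) == "rs9"

    def test_all_below_threshold_none(self):
        ld = mrkit.LdTable()
        ld.set("target", "rs9", 0.79)
        cands = self.make_candidates([("rs9", 1e-9)])
        assert mrkit.find_proxies("target", cands, ld, r2_min=0.8) is None

    def test_tie_broken_by_pvalue_then_name(self):
        ld = mrkit.LdTable()
        ld.set("target", "rsA", 0.85)
        ld.set("target", "rsB", 0.85)
        cands = self.make_candidates([("rsA", 1e-9), ("rsB", 1e-8)])
        assert mrkit.find_proxies("target", cands, ld) == "rsA"
        cands_eq = self.make_candidates([("rsB", 1e-9), ("rsA", 1e-9)])
        assert mrkit.find_proxies("target", cands_eq, ld) == "rsA"

    def test_exhaustive_comparison(self):
        """Result always matches a brute-force scan over candidates."""
        rng = np.random.default_rng(5)
        for _ in range(20):
            ld = mrkit.LdTable()
            specs = []
            for i in range(8):
                r2 = float(rng.choice([0.0, 0.5, 0.85, 0.9, 0.95]))
                ld.set("t", f"rs{i}", r2)
                specs.append((f"rs{i}", float(rng.uniform(1e-10, 1e-6))))
            cands = self.make_candidates(specs)
            got = mrkit.find_proxies("t", cands, ld, 0.8)
            qualifying = [(s, p) for s, p in specs if ld.r2("t", s) >= 0.8]
            if not qualifying:
                assert got is None
            else:
                best = min(qualifying, key=lambda sp: (-ld.r2("t", sp[0]), sp[1], sp[0]))
                assert got == best[0]
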