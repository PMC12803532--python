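"""Allele harmonization rules, Wald/IVW closed forms, cis/trans labelling."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import norm

import cardiotraj as ct
from cardiotraj.errors import EstimationError, UsageError
from cardiotraj.mr import GwasPair, classify_cis_trans, harmonize_variants, ivw, wald_ratio
from cardiotraj.synthetic import GwasSimConfig, generate_gwas_pair


def _gwas_row(vid, ea, oa, beta, se=0.1):
    return {"variant_id": vid, "chrom": "1", "pos_bp": 1000,
            "effect_allele": ea, "other_allele": oa,
            "beta": beta, "se": se, "pval": 0.5, "eaf": 0.3}


class TestHarmonize:
    def test_identical_coding_unchanged(self):
        exp = pd.DataFrame([_gwas_row("rs1", "A", "G", 0.2)])
        out = pd.DataFrame([_gwas_row("rs1", "A", "G", 0.1)])
        pair = harmonize_variants(exp, out)
        assert pair.n_dropped == 0
        assert pair.variants["beta_outcome"].iloc[0] == 0.1

    def test_swapped_alleles_flip_sign(self):
        exp = pd.DataFrame([_gwas_row("rs1", "A", "G", 0.2)])
        out = pd.DataFrame([_gwas_row("rs1", "G", "A", 0.1)])
        pair = harmonize_variants(exp, out)
        assert pair.variants["beta_outcome"].iloc[0] == -0.1

    def test_strand_complement_match(self):
        exp = pd.DataFrame([_gwas_row("rs1", "A", "G", 0.2)])
        out = pd.DataFrame([_gwas_row("rs1", "T", "C", 0.1)])  # complement strand
        pair = harmonize_variants(exp, out)
        assert pair.n_dropped == 0
        assert pair.variants["beta_outcome"].iloc[0] == 0.1

    def test_strand_complement_swapped_flips(self):
        exp = pd.DataFrame([_gwas_row("rs1", "A", "G", 0.2)])
        out = pd.DataFrame([_gwas_row("rs1", "C", "T", 0.1)])
        pair = harmonize_variants(exp, out)
        assert pair.variants["beta_outcome"].iloc[0] == -0.1

    def test_palindromic_dropped(self):
        exp = pd.DataFrame([_gwas_row("rs1", "A", "T", 0.2)])
        out = pd.DataFrame([_gwas_row("rs1", "A", "T", 0.1)])
        pair = harmonize_variants(exp, out)
        assert len(pair.variants) == 0
        assert pair.drop_log == [("rs1", "palindromic")]

    def test_irreconcilable_dropped_not_fatal(self):
        exp = pd.DataFrame([_gwas_row("rs1", "A", "G", 0.2),
                            _gwas_row("rs2", "A", "G", 0.3)])
        out = pd.DataFrame([_gwas_row("rs1", "A", "C", 0.1),
                            _gwas_row("rs2", "A", "G", 0.1)])
        pair = harmonize_variants(exp, out)
        assert len(pair.variants) == 1
        assert ("rs1", "irreconcilable_alleles") in pair.drop_log

    def test_involution_on_generated_pairs(self):
        """Harmonizing an already-harmonized pair is the identity (1000 variants)."""
        cfg = GwasSimConfig(n_variants=1000, flip_fraction=0.4,
                            strand_flip_fraction=0.2, palindromic_fraction=0.1,
                            seed=11)
        exp, out, _ = generate_gwas_pair(cfg)
        pair1 = harmonize_variants(exp, out)
        # rebuild an outcome table in exposure coding from the harmonized pair
        exp_kept = exp[exp["variant_id"].isin(pair1.variants["variant_id"])].reset_index(drop=True)
        out2 = exp_kept.copy()
        out2["beta"] = pair1.variants["beta_outcome"].to_numpy()
        out2["se"] = pair1.variants["se_outcome"].to_numpy()
        pair2 = harmonize_variants(exp_kept, out2)
        assert pair2.n_dropped == 0
        pd.testing.assert_frame_equal(pair1.variants.reset_index(drop=True),
                                      pair2.variants.reset_index(drop=True))


class TestWaldRatio:
    def test_arithmetic(self):
        res = wald_ratio(0.5, 0.05, 0.25, 0.1)
        assert res.estimate == pytest.approx(0.5)
        assert res.method == "wald"

    def test_zero_outcome(self):
        res = wald_ratio(0.5, 0.05, 0.0, 0.1)
        assert res.estimate == 0.0
        assert res.p == pytest.approx(1.0)

    def test_delta_method_closed_form(self):
        b_exp, se_exp, b_out, se_out = -0.4, 0.02, 0.12, 0.03
        res = wald_ratio(b_exp, se_exp, b_out, se_out)
        se = se_out / abs(b_exp)
        assert res.se == pytest.approx(se, rel=1e-12)
        assert res.p == pytest.approx(2 * norm.sf(abs(b_out / b_exp) / se), rel=1e-12)

    def test_zero_exposure_rejected(self):
        with pytest.raises(UsageError):
            wald_ratio(0.0, 0.1, 0.1, 0.1)


def _pair(rows):
    return GwasPair(variants=pd.DataFrame(rows, columns=[
        "variant_id", "beta_exposure", "se_exposure", "beta_outcome", "se_outcome"]))


class TestIvw:
    def test_single_variant_delegates_to_wald(self):
        p = _pair([("rs1", 0.5, 0.05, 0.25, 0.1)])
        res = ivw(p)
        w = wald_ratio(0.5, 0.05, 0.25, 0.1)
        assert (res.estimate, res.se, res.method) == (w.estimate, w.se, "wald")

    def test_identical_variants_shrink_se_by_sqrt_k(self):
        one = _pair([("rs1", 0.5, 0.05, 0.25, 0.1)])
        four = _pair([(f"rs{i}", 0.5, 0.05, 0.25, 0.1) for i in range(4)])
        r1, r4 = ivw(one), ivw(four)
        assert r4.estimate == pytest.approx(r1.estimate, rel=1e-12)
        assert r4.se == pytest.approx(r1.se / 2.0, rel=1e-12)

    def test_three_variant_closed_form(self):
        rows = [("rs1", 0.4, 0.02, 0.12, 0.05),
                ("rs2", -0.3, 0.03, -0.06, 0.04),
                ("rs3", 0.2, 0.05, 0.09, 0.06)]
        ratios = np.array([0.12 / 0.4, -0.06 / -0.3, 0.09 / 0.2])
        w = np.array([(abs(b) / s) ** 2 for _, b, _, _, s in rows])
        expected = float(np.sum(w * ratios) / np.sum(w))
        res = ivw(_pair(rows))
        assert res.estimate == pytest.approx(expected, abs=1e-12)
        assert res.se == pytest.approx(1 / np.sqrt(w.sum()), abs=1e-12)
        q = float(np.sum(w * (ratios - expected) ** 2))
        assert res.q_statistic == pytest.approx(q, abs=1e-12)

    def test_q_zero_iff_equal_ratios(self):
        equal = _pair([("rs1", 0.2, 0.01, 0.1, 0.05),
                       ("rs2", 0.4, 0.01, 0.2, 0.03)])
        assert ivw(equal).q_statistic == pytest.approx(0.0, abs=1e-12)
        unequal = _pair([("rs1", 0.2, 0.01, 0.1, 0.05),
                        ("rs2", 0.4, 0.01, 0.1, 0.03)])
        assert ivw(unequal).q_statistic > 1e-6

    def test_order_and_duplication_invariance(self):
        rows = [("rs1", 0.4, 0.02, 0.12, 0.05), ("rs2", -0.3, 0.03, -0.06, 0.04)]
        r = ivw(_pair(rows))
        r_rev = ivw(_pair(rows[::-1]))
        assert r.estimate == pytest.approx(r_rev.estimate, abs=1e-15)
        doubled = ivw(_pair([(f"{v}a", *rest) for v, *rest in rows]
                            + [(f"{v}b", *rest) for v, *rest in rows]))
        assert doubled.estimate == pytest.approx(r.estimate, abs=1e-15)
        assert doubled.se == pytest.approx(r.se / np.sqrt(2), rel=1e-12)

    def test_empty_pair_rejected(self):
        with pytest.raises(EstimationError):
            ivw(_pair([]))


class TestCisTrans:
    @pytest.mark.parametrize("chrom, pos, expected", [
        ("1", 50_000_000, "cis"),
        ("2", 50_000_000, "trans"),
        ("1", 51_000_000, "cis"),      # exactly at the window, inclusive
        ("1", 51_000_001, "trans"),
    ])
    def test_window_rule(self, chrom, pos, expected):
        assert classify_cis_trans(chrom, pos, "1", 50_000_000) == expected


class TestMrScan:
    def test_recovers_true_effect(self):
        cfg = GwasSimConfig(n_variants=30, true_causal_effect=0.3, seed=21)
        exp, out, truth = generate_gwas_pair(cfg)
        table = ct.mr_scan([{"protein": "PROT1", "gene": "G1", "chrom": "1",
                             "tss": cfg.gene_tss, "exposure": exp}],
                           {"lvef": out})
        row = table.iloc[0]
        assert abs(row["estimate"] - truth) < 2 * row["se"]
        assert row["cis_status"] == "cis"

    def test_all_palindromic_untestable(self):
        cfg = GwasSimConfig(n_variants=10, palindromic_fraction=1.0, seed=22)
        exp, out, _ = generate_gwas_pair(cfg)
        table = ct.mr_scan([{"protein": "P", "exposure": exp}], {"o": out})
        assert table.iloc[0]["method"] == "untestable"
        assert table.iloc[0]["n_variants"] == 0

    def test_null_bonferroni_calibration(self):
        """Family-wise rejections under the null stay at the Bonferroni level."""
        n_scans_with_rejection = 0
        for rep in range(20):
            proteins, outcomes = [], {}
            for j in range(20):
                exp, out, _ = generate_gwas_pair(GwasSimConfig(
                    n_variants=20, true_causal_effect=0.0, seed=1000 + rep * 40 + j))
                proteins.append({"protein": f"P{j}", "exposure": exp})
                outcomes[f"P{j}"] = out
            table = ct.mr_scan([{**p, "exposure": p["exposure"]} for p in proteins],
                               {"lvef": outcomes["P0"]})
            # pair each protein with its own outcome to keep the null exact
            rows = []
            for j, p in enumerate(proteins):
                t = ct.mr_scan([p], {"lvef": outcomes[f"P{j}"]}, alpha_policy="none")
                rows.append(t.iloc[0]["p"])
            pvals = np.asarray(rows)
            if np.any(pvals < 0.05 / len(pvals)):
                n_scans_with_rejection += 1
        assert n_scans_with_rejection <= 1

    def test_direction_consistency_flag(self):
        cfg = GwasSimConfig(n_variants=30, true_causal_effect=0.3, seed=23)
        exp, out, _ = generate_gwas_pair(cfg)
        t = ct.mr_scan([{"protein": "P", "exposure": exp, "trajectory_beta": 0.4}],
                       {"o": out})
        assert t.iloc[0]["direction_consistent"] == 1.0


@settings(max_examples=50, deadline=None, derandomize=True)
@given(st.floats(-2, 2), st.floats(0.01, 1), st.floats(-2, 2), st.floats(0.01, 1))
def test_wald_ratio_properties(b_exp, se_exp, b_out, se_out):
    if abs(b_exp) < 1e-6:
        return
    res = wald_ratio(b_exp, se_exp, b_out, se_out)
    assert res.estimate == pytest.approx(b_out / b_exp, rel=1e-12)
    assert res.se > 0
    assert 0 <= res.p <= 1
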