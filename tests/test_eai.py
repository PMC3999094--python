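"""EAI statistics: folded ratios, per-line detection, cohort tests."""
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import thioscreen as ts
from thioscreen.eai import het_cohort_test, cohort_summary, _ancova_allele_pvalue
from thioscreen.simulate import sample_columns


class TestEaiMax:
    @pytest.mark.parametrize("a,b,expected", [
        (10, 10, 1.0), (40, 10, 4.0), (10, 40, 4.0),
    ])
    def test_worked_examples(self, a, b, expected):
        assert ts.eai_max(a, b) == pytest.approx(expected)

    @given(a=st.floats(0.01, 1e4), b=st.floats(0.01, 1e4))
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_agrees_with_two_case_bruteforce(self, a, b):
        brute = a / b if a / b >= b / a else b / a
        assert ts.eai_max(a, b) == pytest.approx(brute, rel=1e-12)
        # label-swap invariance and the product identity
        assert ts.eai_max(a, b) == pytest.approx(ts.eai_max(b, a), rel=1e-12)
        assert ts.eai_max(a, b) * ts.eai_max(b, a) == pytest.approx(
            ts.eai_max(a, b) ** 2, rel=1e-12
        )

    def test_nonpositive_signal_rejected(self):
        with pytest.raises(ValueError):
            ts.eai_max(0.0, 5.0)


class TestEaiRatio:
    @pytest.mark.parametrize("d,v,expected,detected", [
        (4, 1, 4.0, True), (2, 2, 1.0, False), (2, 1, 2.0, True),
    ])
    def test_threshold_boundary_inclusive(self, d, v, expected, detected):
        ratio, flag = ts.eai_ratio(d, v)
        assert ratio == pytest.approx(expected)
        assert flag is detected

    def test_inputs_below_one_rejected(self):
        with pytest.raises(ValueError):
            ts.eai_ratio(0.5, 1.0)


def _signals_for(rows):
    return pd.DataFrame(rows, columns=["line_id", "snp_id", "condition",
                                       "signal_a", "signal_b", "detect"])


def _geno(snp_rows, samples):
    df = pd.DataFrame(snp_rows).set_index("snp_id")
    for s, calls in samples.items():
        df[s] = calls
    return df


class TestDetectLineEai:
    def test_homozygous_and_intergenic_pairs_skipped(self):
        geno = _geno(
            [{"snp_id": "s1", "gene": "G1", "region": "exon"},
             {"snp_id": "s2", "gene": "G2", "region": "intergenic"}],
            {"L1": ["AA", "AB"], "L2": ["AB", "AB"]},
        )
        rows = []
        for snp in ("s1", "s2"):
            for line in ("L1", "L2"):
                for cond in ("vehicle", "drug"):
                    rows.append([line, snp, cond, 10.0, 10.0, "Present"])
        rec = ts.detect_line_eai(_signals_for(rows), geno)
        # only (L2, s1) is het at a genic SNP
        assert rec[["line_id", "snp_id"]].values.tolist() == [["L2", "s1"]]

    def test_absent_or_unpaired_rows_skipped(self):
        geno = _geno([{"snp_id": "s1", "gene": "G1", "region": "CDS"}],
                     {"L1": ["AB"], "L2": ["AB"]})
        rows = [
            ["L1", "s1", "vehicle", 10.0, 10.0, "Absent"],
            ["L1", "s1", "drug", 40.0, 10.0, "Present"],
            ["L2", "s1", "vehicle", 10.0, 10.0, "Present"],
        ]
        rec = ts.detect_line_eai(_signals_for(rows), geno)
        assert len(rec) == 0

    def test_planted_effects_detected_false_positives_rare(self):
        cfg = ts.SimConfig(seed=17, n_snps=150, n_eai_snps=15,
                           n_clinical_snps=0, eai_effect=4.0, noise_sigma=0.15,
                           dropout_rate=0.0, nocall_rate=0.0)
        g = ts.simulate_genotypes(cfg)
        s = ts.simulate_allele_signals(g, cfg)
        rec = ts.detect_line_eai(s, g)
        truth = ts.truth_set(cfg)
        planted = rec["snp_id"].isin(truth.eai_snp_ids)
        assert rec.loc[planted, "detected"].mean() > 0.95
        assert rec.loc[~planted, "detected"].mean() < 0.05

    def test_unknown_line_raises(self):
        geno = _geno([{"snp_id": "s1", "gene": "G1", "region": "CDS"}],
                     {"L1": ["AB"]})
        rows = [["LX", "s1", "vehicle", 1.0, 1.0, "Present"]]
        with pytest.raises(ValueError, match="absent from genotype"):
            ts.detect_line_eai(_signals_for(rows), geno)


class TestHetCohortTest:
    def test_insufficient_het_lines(self):
        wide = pd.DataFrame({"va": [10, 10], "vb": [10, 10],
                             "da": [40, 40], "db": [10, 10]})
        res = het_cohort_test("s1", wide)
        assert res["responsive"] is False
        assert res["reason"] == "insufficient_het"
        assert np.isnan(res["p_ttest"])

    def test_strong_planted_effect_is_responsive(self):
        rng = np.random.default_rng(8)
        n = 10
        noise = lambda: rng.lognormal(0, 0.1, n)
        wide = pd.DataFrame({
            "va": 100 * noise(), "vb": 100 * noise(),
            "da": 100 * noise(), "db": 400 * noise(),
        })
        res = het_cohort_test("s1", wide)
        assert res["responsive"]
        assert res["p_ttest"] < 0.01
        assert res["max_fold"] >= 2

    def test_fold_rule_variants(self):
        rng = np.random.default_rng(9)
        n = 8
        # strong baseline imbalance in BOTH conditions: drug_abs fold is
        # large, but the drug/vehicle ratio-of-ratios stays near 1
        noise = lambda: rng.lognormal(0, 0.05, n)
        wide = pd.DataFrame({
            "va": 400 * noise(), "vb": 100 * noise(),
            "da": 400 * noise(), "db": 100 * noise(),
        })
        abs_rule = het_cohort_test("s1", wide, fold_rule="drug_abs")
        rel_rule = het_cohort_test("s1", wide, fold_rule="ratio_of_ratios")
        assert abs_rule["max_fold"] >= 2
        assert rel_rule["max_fold"] < 2

    def test_ancova_matches_statsmodels_oracle(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(10)
        n = 12
        allele = np.concatenate([np.zeros(n), np.ones(n)])
        log_veh = rng.normal(5, 1, 2 * n)
        log_drug = 0.5 * allele + 0.8 * log_veh + rng.normal(0, 0.3, 2 * n)
        p_fast = _ancova_allele_pvalue(log_drug, allele, log_veh)
        X = sm.add_constant(np.column_stack([allele, log_veh]))
        p_ref = sm.OLS(log_drug, X).fit().pvalues[1]
        assert p_fast == pytest.approx(p_ref, abs=1e-10)


class TestEaiAnalysisInvariances:
    def test_allele_label_swap_leaves_results_unchanged(
        self, small_cfg, line_genotypes, allele_signals
    ):
        base = ts.EaiAnalysis(allele_signals, line_genotypes).fit()
        swapped_sig = allele_signals.rename(
            columns={"signal_a": "signal_b", "signal_b": "signal_a"}
        )
        swap = {"AA": "BB", "BB": "AA", "AB": "AB", "NoCall": "NoCall"}
        samples = sample_columns(line_genotypes)
        swapped_geno = line_genotypes.copy()
        swapped_geno[samples] = swapped_geno[samples].map(swap.get)
        other = ts.EaiAnalysis(swapped_sig, swapped_geno).fit()
        pd.testing.assert_frame_equal(base.per_line, other.per_line)
        pd.testing.assert_frame_equal(base.cohort, other.cohort)

    def test_condition_scale_invariance(self, line_genotypes, allele_signals):
        base = ts.EaiAnalysis(allele_signals, line_genotypes).fit()
        scaled = allele_signals.copy()
        drug = scaled["condition"] == "drug"
        scaled.loc[drug, ["signal_a", "signal_b"]] *= 37.5
        other = ts.EaiAnalysis(scaled, line_genotypes).fit()
        pd.testing.assert_frame_equal(base.per_line, other.per_line)
        # ANCOVA intercept absorbs the common scale; both arms' p unchanged
        assert np.allclose(base.cohort["p_ttest"].fillna(-1),
                           other.cohort["p_ttest"].fillna(-1), atol=1e-10)
        assert np.allclose(base.cohort["p_ancova"].fillna(-1),
                           other.cohort["p_ancova"].fillna(-1), atol=1e-8)

    def test_truth_recovery_with_planted_effects(self, small_cfg,
                                                 line_genotypes, allele_signals):
        res = ts.EaiAnalysis(allele_signals, line_genotypes).fit()
        truth = ts.truth_set(small_cfg)
        responsive = set(res.responsive["snp_id"])
        assert truth.eai_snp_ids <= responsive
        false = responsive - truth.eai_snp_ids
        assert len(false) <= 0.1 * max(len(responsive), 1)


class TestCohortSummary:
    def test_empty_inputs(self):
        empty_cohort = pd.DataFrame(columns=["snp_id", "responsive"])
        empty_lines = pd.DataFrame(columns=["line_id", "snp_id", "detected"])
        out = cohort_summary(empty_cohort, empty_lines)
        assert out["n_responsive_snps"] == 0
        assert out["n_detected_records"] == 0
        assert out["per_line_detected"] == {}

    def test_per_line_counts_conserved(self, line_genotypes, allele_signals):
        res = ts.EaiAnalysis(allele_signals, line_genotypes).fit()
        out = res.summary_counts()
        assert sum(out["per_line_detected"].values()) == out["n_detected_records"]
        assert out["n_detected_records"] == int(res.per_line["detected"].sum())
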