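"""Fixed-effect and random-effects pooling, ACAT, inflation diagnostics."""

import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import cauchy

from exoburden import (
    acat,
    combine_masks_acat,
    dersimonian_laird,
    genomic_lambda,
    ivw_fixed,
    significance_threshold,
    two_stage_meta,
)


class TestIVWFixed:
    def test_equal_weight_arithmetic(self):
        m = ivw_fixed([1.0, 2.0], [1.0, 1.0])
        assert m.pooled_beta == pytest.approx(1.5)
        assert m.pooled_se == pytest.approx(1 / np.sqrt(2))

    def test_single_study_identity(self):
        m = ivw_fixed([0.7], [0.2])
        assert m.pooled_beta == 0.7 and m.pooled_se == 0.2 and m.het_p == 1.0

    def test_split_study_weight_algebra(self):
        # one study split in two with se * sqrt(2) each pools back identically
        single = ivw_fixed([1.3], [0.4])
        split = ivw_fixed([1.3, 1.3], [0.4 * np.sqrt(2)] * 2)
        assert split.pooled_beta == pytest.approx(single.pooled_beta)
        assert split.pooled_se == pytest.approx(single.pooled_se)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            ivw_fixed([], [])
        with pytest.raises(ValueError):
            ivw_fixed([1.0], [0.0])


class TestDerSimonianLaird:
    def test_homogeneous_inputs_reduce_to_fixed(self):
        m = dersimonian_laird([0.5, 0.5, 0.5], [0.2, 0.2, 0.2])
        f = ivw_fixed([0.5, 0.5, 0.5], [0.2, 0.2, 0.2])
        assert m.tau2 == 0.0
        assert m.pooled_beta == pytest.approx(f.pooled_beta)
        assert m.pooled_se == pytest.approx(f.pooled_se)

    def test_small_q_floors_tau2(self):
        # hand computation: Q = 0.5 < k-1 = 1 so tau2 = 0
        m = dersimonian_laird([1.0, 2.0], [1.0, 1.0])
        assert m.q_stat == pytest.approx(0.5)
        assert m.tau2 == 0.0
        assert m.pooled_beta == pytest.approx(1.5)

    def test_dispersed_inputs_inflate_se(self):
        f = ivw_fixed([0.0, 3.0, -2.0, 4.0], [0.3] * 4)
        m = dersimonian_laird([0.0, 3.0, -2.0, 4.0], [0.3] * 4)
        assert m.tau2 > 0
        assert m.pooled_se > f.pooled_se

    def test_single_input_passthrough(self):
        m = dersimonian_laird([1.1], [0.5])
        assert (m.pooled_beta, m.pooled_se, m.tau2, m.het_p) == (1.1, 0.5, 0.0, 1.0)

    def test_matches_metafor_oracle(self):
        # independent oracle: R metafor rma(method="DL")
        betas = [0.2, 0.9, 1.5, 0.4]
        ses = [0.25, 0.4, 0.3, 0.5]
        script = textwrap.dedent(
            """
            suppressMessages(library(metafor))
            fit <- rma(yi=c(0.2,0.9,1.5,0.4), sei=c(0.25,0.4,0.3,0.5), method="DL")
            cat(fit$beta[1], fit$se, fit$tau2, fit$QE, "\\n")
            """
        )
        out = subprocess.run(
            ["Rscript", "-e", script], capture_output=True, text=True, check=True
        )
        r_beta, r_se, r_tau2, r_q = map(float, out.stdout.split())
        m = dersimonian_laird(betas, ses)
        assert m.pooled_beta == pytest.approx(r_beta, rel=1e-6)
        assert m.pooled_se == pytest.approx(r_se, rel=1e-6)
        assert m.tau2 == pytest.approx(r_tau2, rel=1e-6)
        assert m.q_stat == pytest.approx(r_q, rel=1e-6)


class TestACAT:
    def test_equal_p_fixed_point(self):
        for p in (0.5, 0.01, 0.9):
            assert acat([p, p, p]).combined_p == pytest.approx(p, abs=1e-12)

    def test_two_component_cauchy_oracle(self):
        # independent oracle: standard Cauchy distribution function
        pvals = np.array([0.01, 0.5])
        t = np.mean(np.tan((0.5 - pvals) * np.pi))
        expected = 1 - cauchy.cdf(t)
        assert acat([0.01, 0.5]).combined_p == pytest.approx(expected, abs=1e-6)
        assert acat([0.01, 0.5]).combined_p == pytest.approx(0.0200, abs=5e-4)

    def test_extra_half_component_pulls_toward_half(self):
        base = acat([0.01, 0.02]).combined_p
        diluted = acat([0.01, 0.02, 0.5]).combined_p
        assert base < diluted < 0.5

    def test_tiny_p_stability(self):
        p = acat([1e-30, 0.5]).combined_p
        assert 0 < p < 1e-29

    def test_weight_rescaling_invariance(self):
        a = acat([0.01, 0.3, 0.7], weights=[1, 2, 3]).combined_p
        b = acat([0.01, 0.3, 0.7], weights=[10, 20, 30]).combined_p
        assert a == pytest.approx(b, rel=1e-12)

    @pytest.mark.parametrize("bad", [[0.0, 0.5], [0.5, 1.0], []])
    def test_invalid_pvalues(self, bad):
        with pytest.raises(ValueError):
            acat(bad)

    @given(st.lists(st.floats(1e-12, 1 - 1e-12), min_size=1, max_size=8))
    @settings(max_examples=100, deadline=None)
    def test_output_in_open_interval(self, pvals):
        assert 0 < acat(pvals).combined_p < 1


class TestTwoStage:
    def frame(self, rows):
        return pd.DataFrame(
            rows,
            columns=["unit", "mask", "maf_threshold", "phenotype", "ancestry",
                     "cohort", "beta", "se"],
        )

    def test_single_ancestry_equals_fixed_effect(self):
        rows = [
            ("G1", "M3", 0.001, "A2", "EUR", "c1", 1.0, 0.5),
            ("G1", "M3", 0.001, "A2", "EUR", "c2", 1.4, 0.4),
        ]
        res = two_stage_meta(self.frame(rows)).iloc[0]
        f = ivw_fixed([1.0, 1.4], [0.5, 0.4])
        assert res["beta"] == pytest.approx(f.pooled_beta)
        assert res["se"] == pytest.approx(f.pooled_se)
        assert res["k_ancestries"] == 1

    def test_order_invariance(self):
        rows = [
            ("G1", "M3", 0.001, "A2", "EUR", "c1", 1.0, 0.5),
            ("G1", "M3", 0.001, "A2", "SAS", "c2", 0.4, 0.6),
            ("G1", "M3", 0.001, "A2", "AFR", "c3", 0.9, 0.7),
        ]
        a = two_stage_meta(self.frame(rows))
        b = two_stage_meta(self.frame(rows[::-1]))
        pd.testing.assert_frame_equal(a, b)

    def test_stagewise_equals_manual_composition(self):
        rows = [
            ("G1", "M3", 0.001, "A2", "EUR", "c1", 1.0, 0.5),
            ("G1", "M3", 0.001, "A2", "EUR", "c2", 1.6, 0.4),
            ("G1", "M3", 0.001, "A2", "SAS", "c3", 0.2, 0.6),
        ]
        res = two_stage_meta(self.frame(rows)).iloc[0]
        eur = ivw_fixed([1.0, 1.6], [0.5, 0.4])
        manual = dersimonian_laird(
            [eur.pooled_beta, 0.2], [eur.pooled_se, 0.6]
        )
        assert res["beta"] == pytest.approx(manual.pooled_beta)
        assert res["se"] == pytest.approx(manual.pooled_se)
        assert res["het_p"] == pytest.approx(manual.het_p)

    def test_carrier_counts_summed(self):
        df = self.frame(
            [
                ("G1", "M3", 0.001, "A2", "EUR", "c1", 1.0, 0.5),
                ("G1", "M3", 0.001, "A2", "SAS", "c2", 0.4, 0.6),
            ]
        )
        df["case_counts"] = ["10|1|2", "20|3|0"]
        df["control_counts"] = ["100|5|0", "200|0|0"]
        res = two_stage_meta(df).iloc[0]
        assert res["case_counts"] == "30|4|2"
        assert res["control_counts"] == "300|5|0"


class TestCombineMasks:
    def meta_frame(self, ps):
        return pd.DataFrame(
            {
                "unit": "G1",
                "phenotype": "A2",
                "mask": [f"M{i}" for i in range(len(ps))],
                "p": ps,
            }
        )

    def test_single_mask_identity(self):
        res = combine_masks_acat(self.meta_frame([0.037]))
        assert res["acat_p"].iloc[0] == pytest.approx(0.037, abs=1e-12)

    def test_equal_p_fixed_point(self):
        res = combine_masks_acat(self.meta_frame([1e-5, 1e-5, 1e-5]))
        assert res["acat_p"].iloc[0] == pytest.approx(1e-5, rel=1e-6)


class TestNullFalsePositives:
    def test_no_exome_significant_genes_under_null(self):
        # two-stage pooling of null per-ancestry effects: across seeded
        # replicates of 2,000 genes x 3 ancestries, (almost) no gene may
        # cross the exome-wide threshold 0.05/20,000
        rng = np.random.default_rng(2024)
        threshold = significance_threshold(20_000)
        clean_reps = 0
        for _ in range(20):
            ses = rng.uniform(0.3, 1.5, size=(2000, 3))
            betas = rng.normal(0.0, ses)
            hits = 0
            for g in range(2000):
                if dersimonian_laird(betas[g], ses[g]).pooled_p < threshold:
                    hits += 1
            clean_reps += hits == 0
        assert clean_reps >= 19


class TestLambdaAndThresholds:
    def test_half_p_is_unit_lambda(self):
        assert genomic_lambda([0.5]) == pytest.approx(1.0)

    def test_uniform_null_near_one(self):
        rng = np.random.default_rng(123)
        lam = genomic_lambda(rng.uniform(size=10_000))
        assert 0.95 < lam < 1.05

    def test_halving_p_increases_lambda(self):
        rng = np.random.default_rng(5)
        p = rng.uniform(size=2000)
        assert genomic_lambda(p / 2) > genomic_lambda(p)

    @pytest.mark.parametrize(
        "n, expected", [(20_000, 2.5e-6), (46, 0.05 / 46), (10, 0.005)]
    )
    def test_bonferroni(self, n, expected):
        assert significance_threshold(n) == pytest.approx(expected, rel=1e-12)


class TestQQData:
    def test_sorted_with_expected_quantiles(self):
        from exoburden import qq_data

        meta = pd.DataFrame({"unit": ["a", "b", "c"], "p": [0.5, 0.01, 0.9]})
        out = qq_data(meta)
        assert list(out["unit"]) == ["b", "a", "c"]
        assert out["neg_log10_p"].iloc[0] == pytest.approx(2.0)
        assert (out["expected_neg_log10_p"].diff().dropna() < 0).all()
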