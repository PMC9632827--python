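"""Association layer: PCs, burden tests, single-variant tests, stratification."""

import numpy as np
import pandas as pd
import pytest

from exoburden import (
    CovariateSet,
    burden_test,
    collapse_genes,
    compute_pcs,
    sex_stratified_burden,
    single_variant_test,
)
from exoburden.association import SINGLE_VARIANT_MAC_MIN, SINGLE_VARIANT_MAF_MIN

from conftest import make_genotypes


def pheno_frame(y, age=None, sex=None, cohort="c1", ancestry="EUR"):
    n = len(y)
    y = np.asarray(y, dtype=int)
    return pd.DataFrame(
        {
            "sample": [f"S{i}" for i in range(n)],
            "a2": y,
            "b2": y,
            "c2": y,
            "age": np.full(n, 55.0) if age is None else age,
            "sex": np.zeros(n, dtype=int) if sex is None else sex,
            "ancestry": ancestry,
            "cohort": cohort,
        }
    )


class TestComputePCs:
    def two_pop_genotypes(self, n_per=150, m=80, seed=0):
        rng = np.random.default_rng(seed)
        p1 = rng.uniform(0.1, 0.5, m)
        p2 = np.clip(p1 + rng.choice([-0.25, 0.25], m), 0.05, 0.9)
        dos = np.vstack(
            [rng.binomial(2, p1, (n_per, m)), rng.binomial(2, p2, (n_per, m))]
        ).astype(np.int8)
        return make_genotypes(dos), np.r_[np.zeros(n_per), np.ones(n_per)]

    def test_pc1_separates_subpopulations(self):
        g, pop = self.two_pop_genotypes()
        pcs = compute_pcs(g, "common", k=4)
        # point-biserial correlation of PC1 with population label
        r = np.corrcoef(pcs[:, 0], pop)[0, 1]
        assert abs(r) > 0.9

    def test_orthonormal_scores(self):
        g, _ = self.two_pop_genotypes(seed=1)
        pcs = compute_pcs(g, "common", k=5)
        np.testing.assert_allclose(pcs.T @ pcs, np.eye(5), atol=1e-8)

    def test_reconstruction_error_decreases_in_k(self):
        g, _ = self.two_pop_genotypes(seed=2)
        dos = g.dosage.astype(float)
        z = dos - dos.mean(0)
        errs = []
        for k in (1, 3, 6, 10):
            pcs = compute_pcs(g, "common", k=k)
            proj = pcs @ (pcs.T @ z)
            errs.append(np.linalg.norm(z - proj))
        assert all(b <= a + 1e-9 for a, b in zip(errs, errs[1:]))

    def test_k_beyond_supply_rejected(self):
        g, _ = self.two_pop_genotypes(m=10, seed=3)
        with pytest.raises(ValueError):
            compute_pcs(g, "common", k=11)

    def test_deterministic_sign(self):
        g, _ = self.two_pop_genotypes(seed=4)
        a = compute_pcs(g, "common", k=3)
        b = compute_pcs(g, "common", k=3)
        np.testing.assert_array_equal(a, b)


class TestBurdenTest:
    def scores_for(self, dosage, mask="M3", thr=0.001):
        g = make_genotypes(dosage)
        return collapse_genes(g, {"G": g.keys.tolist()}, mask, thr)

    def test_effect_direction_recovered(self):
        rng = np.random.default_rng(8)
        n = 4000
        carrier = (rng.random(n) < 0.02).astype(np.int8)
        p = np.where(carrier, 0.30, 0.05)
        y = (rng.random(n) < p).astype(int)
        b = self.scores_for(carrier[:, None])
        res = burden_test(
            b, pheno_frame(y), CovariateSet(age=np.full(n, 55.0), sex=np.zeros(n))
        )
        assert len(res) == 1
        r = res[0]
        assert r.beta > 0 and r.p < 1e-4
        assert r.odds_ratio == pytest.approx(np.exp(r.beta))

    def test_all_zero_gene_omitted(self):
        n = 200
        y = np.r_[np.ones(40, int), np.zeros(160, int)]
        b = self.scores_for(np.zeros((n, 1), dtype=np.int8))
        res = burden_test(
            b, pheno_frame(y), CovariateSet(age=np.full(n, 55.0), sex=np.zeros(n))
        )
        assert res == []

    def test_carrier_counts_attached(self):
        n = 100
        dosage = np.zeros((n, 1), dtype=np.int8)
        dosage[:3, 0] = 1
        dosage[3, 0] = 2
        y = np.r_[np.ones(10, int), np.zeros(90, int)]
        b = self.scores_for(dosage)
        res = burden_test(
            b, pheno_frame(y), CovariateSet(age=np.full(n, 55.0), sex=np.zeros(n))
        )[0]
        assert res.case_counts == "6|3|1"
        assert res.control_counts == "90|0|0"

    def test_null_permutation_calibration(self):
        # permuted labels: p-values roughly uniform across many null genes
        rng = np.random.default_rng(9)
        n, n_genes = 800, 60
        dosage = (rng.random((n, n_genes)) < 0.04).astype(np.int8)
        g = make_genotypes(dosage)
        qual = {f"G{j}": [g.keys.iloc[j]] for j in range(n_genes)}
        b = collapse_genes(g, qual, "M3", 0.001)
        y = rng.permutation(np.r_[np.ones(100, int), np.zeros(n - 100, int)])
        res = burden_test(
            b, pheno_frame(y), CovariateSet(age=np.full(n, 55.0), sex=np.zeros(n))
        )
        ps = np.array([r.p for r in res])
        assert 0.2 < ps.mean() < 0.8
        assert (ps < 0.05).mean() < 0.2


class TestSingleVariant:
    def test_frequency_gates(self):
        rng = np.random.default_rng(10)
        n = 5000
        common = rng.binomial(2, 0.05, n)     # passes both gates
        rare = np.zeros(n, dtype=np.int8)     # MAF 5e-4 < 0.1%: excluded
        rare[:5] = 1
        lowmac = np.zeros(n, dtype=np.int8)   # MAC 5 < 6: excluded
        lowmac[:5] = 1
        mid = np.zeros(n, dtype=np.int8)      # MAF 0.0012, MAC 12: passes
        mid[:12] = 1
        dosage = np.column_stack([common, rare, lowmac, mid]).astype(np.int8)
        g = make_genotypes(dosage)
        y = rng.binomial(1, 0.2, n)
        res = single_variant_test(
            g, pheno_frame(y), CovariateSet(age=np.full(n, 55.0), sex=np.zeros(n))
        )
        tested = {r.unit for r in res}
        assert g.keys.iloc[0] in tested and g.keys.iloc[3] in tested
        assert g.keys.iloc[1] not in tested and g.keys.iloc[2] not in tested

    def test_planted_common_effect_recovered(self):
        rng = np.random.default_rng(11)
        n = 6000
        dos = rng.binomial(2, 0.1, n).astype(np.int8)
        from scipy.special import expit

        beta = 0.5
        y = (rng.random(n) < expit(-2.0 + beta * dos)).astype(int)
        g = make_genotypes(dos[:, None])
        res = single_variant_test(
            g, pheno_frame(y), CovariateSet(age=np.full(n, 55.0), sex=np.zeros(n))
        )[0]
        assert res.beta - 1.96 * res.se < beta < res.beta + 1.96 * res.se


class TestSexStratified:
    def make_x_setup(self, seed=12):
        rng = np.random.default_rng(seed)
        n = 3000
        is_male = rng.random(n) < 0.5
        maf = 0.01
        dos = np.where(
            is_male, 2 * rng.binomial(1, maf, n), rng.binomial(2, maf, n)
        ).astype(np.int8)
        g = make_genotypes(dos[:, None], chroms=["X"], is_male=is_male)
        scores = collapse_genes(g, {"GX": g.keys.tolist()}, "M3", 0.001)
        from scipy.special import expit

        y = (rng.random(n) < expit(-2.5 + 1.2 * (dos > 0))).astype(int)
        pheno = pheno_frame(y, sex=is_male.astype(int))
        cov = CovariateSet(age=np.full(n, 55.0), sex=is_male.astype(int))
        return scores, pheno, cov, is_male

    def test_male_carriers_score_two_female_score_one(self):
        scores, pheno, cov, is_male = self.make_x_setup()
        s = scores.scores.iloc[0].to_numpy()
        assert set(np.unique(s[is_male])) <= {0, 2}
        assert 1 in np.unique(s[~is_male])

    def test_strata_partition_pooled_counts(self):
        scores, pheno, cov, is_male = self.make_x_setup()
        male = sex_stratified_burden(scores, pheno, cov, "male")[0]
        female = sex_stratified_burden(scores, pheno, cov, "female")[0]

        def parse(c):
            return np.array([int(x) for x in c.split("|")])

        pooled_cases = parse(male.case_counts) + parse(female.case_counts)
        y = pheno["a2"].to_numpy(bool)
        all_counts = scores.carrier_counts(y).iloc[0]
        np.testing.assert_array_equal(
            pooled_cases,
            all_counts[["case_n0", "case_n1", "case_n2"]].to_numpy(),
        )

    def test_bad_stratum_rejected(self):
        scores, pheno, cov, _ = self.make_x_setup()
        with pytest.raises(ValueError):
            sex_stratified_burden(scores, pheno, cov, "other")
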