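"""Association scan: normality gate, BH step-up (against an independent
implementation), the likelihood-ratio R^2 identity, LD r^2 and scan
calibration/power at small scale."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

from flavorhap.association import (
    bh_adjust,
    ld_r2,
    normalize_phenotype,
    pve,
    rank_inverse_normal,
    scan,
    subpopulation_covariates,
)


class TestNormalizePhenotype:
    def test_normal_sample_left_untransformed(self):
        rng = np.random.default_rng(4)
        values = pd.Series(rng.normal(10, 2, size=100))
        out = normalize_phenotype(values)
        assert not out.was_transformed
        assert out.values.equals(values)

    def test_skewed_sample_transformed_to_normality(self):
        rng = np.random.default_rng(4)
        values = pd.Series(rng.exponential(1.0, size=100))
        out = normalize_phenotype(values)
        assert out.was_transformed
        assert out.shapiro_p < 0.01
        assert stats.shapiro(out.values).pvalue > 0.01

    def test_rank_invariance_under_monotone_transform(self):
        rng = np.random.default_rng(9)
        values = pd.Series(rng.exponential(2.0, size=50))
        a = normalize_phenotype(values)
        b = normalize_phenotype(np.log(values) * 3 + 1)  # same ranks, still non-normal
        if a.was_transformed and b.was_transformed:
            assert np.allclose(a.values, b.values)
        # ranks always preserved
        assert (a.values.rank() == values.rank()).all()

    def test_missing_values_stay_missing(self):
        rng = np.random.default_rng(1)
        values = pd.Series(rng.exponential(1.0, size=60))
        values.iloc[5] = np.nan
        out = normalize_phenotype(values)
        assert np.isnan(out.values.iloc[5])
        assert out.values.notna().sum() == 59

    def test_constant_errors(self):
        with pytest.raises(ValueError, match="constant"):
            normalize_phenotype(pd.Series([1.0] * 20))

    def test_gate_level(self):
        """An actually-normal phenotype is transformed only ~1% of the time."""
        transformed = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            out = normalize_phenotype(pd.Series(rng.normal(size=100)))
            transformed += out.was_transformed
        assert transformed <= 5

    def test_blom_offsets(self):
        out = rank_inverse_normal(np.array([3.0, 1.0, 2.0]))
        expect = stats.norm.ppf((np.array([3, 1, 2]) - 0.375) / 3.25)
        assert np.allclose(out, expect)


class TestBhAdjust:
    def test_hand_computed_step_up_example(self):
        q = bh_adjust(np.array([0.01, 0.02, 0.03, 0.2]))
        assert np.allclose(q, [0.04, 0.04, 0.04, 0.2])

    def test_single_p_is_unchanged(self):
        assert bh_adjust(np.array([0.37]))[0] == pytest.approx(0.37)

    def test_all_equal_stay_equal(self):
        q = bh_adjust(np.full(7, 0.2))
        assert np.allclose(q, 0.2)

    def test_matches_independent_implementation(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(0)
        for _ in range(50):
            p = rng.uniform(1e-12, 1.0, size=int(rng.integers(1, 200)))
            mine = bh_adjust(p)
            theirs = multipletests(p, method="fdr_bh")[1]
            assert np.allclose(mine, theirs, atol=1e-12)

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust(np.array([0.0, 0.5]))
        with pytest.raises(ValueError):
            bh_adjust(np.array([0.5, 1.2]))

    @given(st.integers(0, 10_000))
    def test_permutation_invariance(self, seed):
        rng = np.random.default_rng(seed)
        p = rng.uniform(1e-6, 1.0, size=20)
        perm = rng.permutation(20)
        assert np.allclose(bh_adjust(p)[perm], bh_adjust(p[perm]))


class TestPve:
    def test_identity_with_ols_r2(self):
        """Without covariates the likelihood-ratio R^2 difference equals the
        OLS R^2 of phenotype ~ dosage to 1e-10."""
        rng = np.random.default_rng(42)
        x = rng.integers(0, 3, size=166).astype(float)
        y = 0.5 * x + rng.normal(0, 1.0, size=166)
        got = pve(y, x)
        r = np.corrcoef(x, y)[0, 1]
        assert got == pytest.approx(r * r, abs=1e-10)

    def test_orthogonal_dosage_gives_zero(self):
        x = np.array([0.0, 2.0, 0.0, 2.0] * 10)
        y = np.array([1.0, 1.0, -1.0, -1.0] * 10)  # exactly orthogonal, centered
        assert abs(pve(y, x)) < 1e-8

    def test_affine_invariance(self):
        rng = np.random.default_rng(3)
        x = rng.integers(0, 3, size=80).astype(float)
        y = x + rng.normal(size=80)
        assert pve(3.0 * y - 7.0, x) == pytest.approx(pve(y, x), abs=1e-12)

    def test_covariates_absorb_structure(self):
        rng = np.random.default_rng(8)
        group = np.repeat([0.0, 1.0], 50)
        x = group * 2  # dosage fully confounded with the group
        y = group * 3 + rng.normal(0, 0.5, size=100)
        full = pve(y, x)
        adjusted = pve(y, x, covariates=group.reshape(-1, 1))
        assert adjusted < full * 0.1

    def test_too_few_observations(self):
        with pytest.raises(ValueError):
            pve(np.array([1.0, 2.0]), np.array([0.0, 1.0]))


class TestLdR2:
    def test_identical_vectors(self):
        x = np.array([0.0, 1.0, 2.0, 0.0, 2.0])
        assert ld_r2(x, x) == pytest.approx(1.0)

    def test_orthogonal_dosages(self):
        x = np.array([0.0, 0.0, 2.0, 2.0])
        y = np.array([0.0, 2.0, 0.0, 2.0])
        assert ld_r2(x, y) == pytest.approx(0.0, abs=1e-12)

    def test_complete_ld_frequency_mismatch(self):
        # alt of x always accompanies alt of y, but y is commoner: r^2 < 1
        x = np.array([2.0, 2.0, 0.0, 0.0, 0.0, 0.0])
        y = np.array([2.0, 2.0, 2.0, 2.0, 0.0, 0.0])
        r = np.corrcoef(x, y)[0, 1]
        assert ld_r2(x, y) == pytest.approx(r * r)
        assert ld_r2(x, y) < 1.0

    def test_missing_pairs_and_errors(self):
        x = np.array([0.0, np.nan, 2.0])
        y = np.array([0.0, 1.0, np.nan])
        with pytest.raises(ValueError, match="3"):
            ld_r2(x, y)
        with pytest.raises(ValueError, match="variance"):
            ld_r2(np.array([1.0, 1.0, 1.0]), np.array([0.0, 1.0, 2.0]))


def _dosage_frame(rng, n=166, m=50, maf_low=0.05, maf_high=0.5):
    freqs = rng.uniform(maf_low, maf_high, size=m)
    x = rng.binomial(2, freqs, size=(n, m)).astype(float)
    return pd.DataFrame(x, index=[f"s{i}" for i in range(n)],
                        columns=[f"v{j}" for j in range(m)])


class TestScan:
    def test_monomorphic_and_low_maf_skipped(self):
        rng = np.random.default_rng(0)
        df = _dosage_frame(rng, n=100, m=5)
        df["v0"] = 0.0  # monomorphic
        df["v1"] = [2.0] + [0.0] * 99  # MAF 1% < 2% floor
        y = pd.Series(rng.normal(size=100), index=df.index)
        res = scan(df, y)
        assert "v0" not in set(res["variant_id"])
        assert "v1" not in set(res["variant_id"])
        assert len(res) == 3

    def test_planted_effect_detected(self):
        rng = np.random.default_rng(5)
        df = _dosage_frame(rng, n=166, m=100)
        x = df["v7"].to_numpy()
        beta = np.sqrt(0.15 / 0.85) / x.std()
        y = pd.Series(beta * x + rng.normal(size=166), index=df.index)
        res = scan(df, y).sort_values("p")
        assert res.iloc[0]["variant_id"] == "v7"
        assert res.iloc[0]["tier"] in ("fdr05", "fdr01")
        assert 0.05 < res.iloc[0]["pve"] < 0.30

    def test_null_calibration_small(self):
        """Permuted phenotype: ~5% of variants reach p < 0.05."""
        rates = []
        for seed in range(10):
            rng = np.random.default_rng(seed)
            df = _dosage_frame(rng, n=166, m=200)
            y = pd.Series(rng.normal(size=166), index=df.index)
            res = scan(df, y)
            rates.append((res["p"] < 0.05).mean())
        assert abs(np.mean(rates) - 0.05) < 0.02

    def test_covariates_reduce_confounded_inflation(self):
        """With phenotype structure aligned to subpopulations, adding
        subpopulation covariates moves the null p-value distribution back
        toward uniform (median chi-square toward 0.455)."""
        stat_plain, stat_adj = [], []
        for seed in range(5):
            rng = np.random.default_rng(seed)
            groups = pd.Series(np.repeat(list("ABCD"), 40), index=[f"s{i}" for i in range(160)])
            freqs = {g: rng.uniform(0.1, 0.9, size=80) for g in "ABCD"}
            x = np.vstack([rng.binomial(2, freqs[g], size=(1, 80))[0] for g in groups])
            df = pd.DataFrame(x.astype(float), index=groups.index,
                              columns=[f"v{j}" for j in range(80)])
            y = pd.Series(
                groups.map({"A": 0.0, "B": 1.0, "C": 2.0, "D": 3.0}).to_numpy()
                + rng.normal(0, 1.0, size=160),
                index=groups.index,
            )
            cov = subpopulation_covariates(groups)
            res_plain = scan(df, y)
            res_adj = scan(df, y, covariates=cov)
            to_chi2 = lambda p: stats.chi2.isf(p, df=1)
            stat_plain.append(np.median(to_chi2(res_plain["p"])))
            stat_adj.append(np.median(to_chi2(res_adj["p"])))
        null_median = 0.455
        assert abs(np.median(stat_adj) - null_median) < abs(np.median(stat_plain) - null_median)

    def test_tiers_follow_q_thresholds(self):
        rng = np.random.default_rng(11)
        df = _dosage_frame(rng, n=166, m=60)
        x = df["v3"].to_numpy()
        y = pd.Series(1.0 * x + rng.normal(size=166), index=df.index)
        res = scan(df, y)
        assert ((res["tier"] == "fdr01") == (res["q"] <= 0.01)).all()
        assert ((res["tier"] == "fdr05") == ((res["q"] > 0.01) & (res["q"] <= 0.05))).all()
        assert np.allclose(res["neg_log10_p"], -np.log10(res["p"]))
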