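"""Association-analysis tests: OLS against a normal-equations oracle,
Benjamini-Hochberg against brute-force enumeration, significance maps, and
statistical calibration of the whole testing stack on truth tables."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from neurotraj.association import (
    add_fdr,
    covariate_correlations,
    fdr_adjust,
    ols_covariance,
    significance_map,
)
from neurotraj.synthetic import CohortConfig, generate_cohort


def bh_bruteforce(p):
    """Independent step-up enumeration: q_(i) = min_{j>=i} m p_(j) / j."""
    p = np.asarray(p, float)
    m = p.size
    order = np.argsort(p, kind="stable")
    q = np.empty(m)
    for rank_i in range(m):
        candidates = [m * p[order[j]] / (j + 1) for j in range(rank_i, m)]
        q[order[rank_i]] = min(1.0, min(candidates))
    return q


class TestFdrAdjust:
    def test_worked_example(self):
        q = fdr_adjust([0.001, 0.01, 0.02, 0.5])
        np.testing.assert_allclose(q, [0.004, 0.02, 4 * 0.02 / 3, 0.5],
                                   atol=1e-12)

    def test_single_p_unchanged(self):
        assert fdr_adjust([0.037])[0] == pytest.approx(0.037)

    def test_all_ones_stay_one(self):
        np.testing.assert_allclose(fdr_adjust([1.0, 1.0, 1.0]), 1.0)

    def test_empty_family(self):
        assert fdr_adjust([]).size == 0

    def test_matches_bruteforce_on_random_vectors(self):
        rng = np.random.default_rng(2024)
        for _ in range(200):
            m = rng.integers(1, 40)
            p = rng.random(m) ** rng.uniform(0.5, 3)
            np.testing.assert_allclose(fdr_adjust(p), bh_bruteforce(p),
                                       atol=1e-12)

    @settings(deadline=None, max_examples=100)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=25))
    def test_properties(self, p):
        q = fdr_adjust(p)
        assert np.all(q >= np.asarray(p) - 1e-12)
        assert np.all((q >= 0) & (q <= 1))
        # monotone: ordering by p implies ordering by q
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-12)

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            fdr_adjust([0.5, 1.5])


# printed worked fixture: 6 subjects, hand-checkable design
_SIX = pd.DataFrame({
    "subject_id": list("abcdef"),
    "sex_female": [0, 1, 0, 1, 0, 1],
    "apoe4_count": [0, 0, 1, 1, 2, 2],
    "education_years": [12.0, 16.0, 14.0, 18.0, 12.0, 20.0],
})
_SIX_TAU = np.array([75.0, 74.0, 73.5, 72.0, 71.0, 70.5])
_SIX_XI = np.array([-0.2, 0.1, 0.0, 0.3, -0.1, 0.4])


class TestOlsCovariance:
    def _individual(self):
        return pd.DataFrame({
            "subject_id": _SIX["subject_id"], "region": "region_1",
            "tau": _SIX_TAU, "xi": _SIX_XI,
        })

    def test_matches_normal_equations(self):
        # 12 subjects (the printed 6-subject design twice, relabeled) to
        # satisfy the n >= 10 precondition while keeping the fixture small
        ind = self._individual()
        ind2 = ind.copy()
        ind2["subject_id"] = [s + "2" for s in ind2["subject_id"]]
        cov2 = _SIX.copy()
        cov2["subject_id"] = [s + "2" for s in cov2["subject_id"]]
        individual = pd.concat([ind, ind2], ignore_index=True)
        covariates = pd.concat([_SIX, cov2], ignore_index=True)

        res = ols_covariance(individual, covariates)
        X = np.column_stack([
            np.ones(12),
            np.tile(_SIX["sex_female"], 2),
            np.tile(_SIX["apoe4_count"], 2),
            np.tile(_SIX["education_years"], 2),
        ])
        for parameter, y in (("onset", np.tile(_SIX_TAU, 2)),
                             ("log_pace", np.tile(_SIX_XI, 2))):
            beta = np.linalg.solve(X.T @ X, X.T @ y)
            got = res[res["parameter"] == parameter].set_index("covariate")
            assert got.loc["sex_female", "beta"] == pytest.approx(beta[1], abs=1e-10)
            assert got.loc["apoe4_count", "beta"] == pytest.approx(beta[2], abs=1e-10)
            assert got.loc["education_years", "beta"] == pytest.approx(beta[3], abs=1e-10)

    def test_constant_response_gives_zero_betas(self):
        ind = self._individual()
        ind2 = ind.copy()
        ind2["subject_id"] = [s + "2" for s in ind2["subject_id"]]
        individual = pd.concat([ind, ind2], ignore_index=True)
        individual["tau"] = 74.0
        cov2 = _SIX.copy()
        cov2["subject_id"] = [s + "2" for s in cov2["subject_id"]]
        covariates = pd.concat([_SIX, cov2], ignore_index=True)
        res = ols_covariance(individual, covariates)
        onset = res[res["parameter"] == "onset"]
        assert (onset["beta"] == 0).all()
        assert onset["p"].isna().all()

    def test_constant_covariate_flagged_na(self):
        rng = np.random.default_rng(0)
        n = 30
        cov = pd.DataFrame({
            "subject_id": [f"s{i}" for i in range(n)],
            "sex_female": rng.integers(0, 2, n),
            "apoe4_count": np.zeros(n, dtype=int),   # constant
            "education_years": rng.normal(16, 3, n),
        })
        ind = pd.DataFrame({
            "subject_id": cov["subject_id"], "region": "r",
            "tau": rng.normal(74, 7, n), "xi": rng.normal(0, 0.5, n),
        })
        with pytest.warns(UserWarning, match="constant covariate"):
            res = ols_covariance(ind, cov)
        apoe = res[res["covariate"] == "apoe4_count"]
        assert apoe["beta"].isna().all()
        sex = res[res["covariate"] == "sex_female"]
        assert sex["beta"].notna().all()

    def test_too_few_subjects_rejected(self):
        with pytest.raises(ValueError, match=">= 10"):
            ols_covariance(self._individual(), _SIX)

    def test_percent_pace_is_exp_beta_minus_one(self):
        rng = np.random.default_rng(1)
        n = 50
        cov = pd.DataFrame({
            "subject_id": [f"s{i}" for i in range(n)],
            "sex_female": rng.integers(0, 2, n),
            "apoe4_count": rng.integers(0, 3, n),
            "education_years": rng.normal(16, 3, n),
        })
        ind = pd.DataFrame({
            "subject_id": cov["subject_id"], "region": "r",
            "tau": rng.normal(74, 7, n), "xi": rng.normal(0, 0.5, n),
        })
        res = ols_covariance(ind, cov)
        pace = res[res["parameter"] == "log_pace"]
        np.testing.assert_allclose(pace["percent_pace"],
                                   (np.exp(pace["beta"]) - 1) * 100, atol=1e-12)

    def test_disattenuation_scales_beta_not_t(self):
        rng = np.random.default_rng(2)
        n = 60
        cov = pd.DataFrame({
            "subject_id": [f"s{i}" for i in range(n)],
            "sex_female": rng.integers(0, 2, n),
            "apoe4_count": rng.integers(0, 3, n),
            "education_years": rng.normal(16, 3, n),
        })
        ind = pd.DataFrame({
            "subject_id": cov["subject_id"], "region": "r",
            "tau": rng.normal(74, 7, n), "xi": rng.normal(0, 0.5, n),
            "tau_var": np.full(n, 4.0), "xi_var": np.full(n, 0.05),
        })
        raw = ols_covariance(ind, cov, disattenuate=False)
        corr = ols_covariance(ind, cov, disattenuate=True)
        lam = corr[corr["parameter"] == "onset"]["attenuation_lambda"].iloc[0]
        assert 0 < lam < 1
        np.testing.assert_allclose(
            corr[corr["parameter"] == "onset"]["beta"],
            raw[raw["parameter"] == "onset"]["beta"] / lam, atol=1e-12)
        np.testing.assert_allclose(corr["t"], raw["t"], atol=1e-12)
        np.testing.assert_allclose(corr["p"], raw["p"], atol=1e-12)


class TestSignificanceMap:
    def _table(self, rows):
        return pd.DataFrame(rows)

    def test_sign_convention(self):
        res = self._table([
            {"region": "r1", "parameter": "log_pace", "covariate": "sex_female",
             "beta": 0.2, "q": 0.001},     # faster pace => risk => +3
            {"region": "r2", "parameter": "onset", "covariate": "sex_female",
             "beta": -2.0, "q": 0.01},     # earlier onset => risk => +2
            {"region": "r3", "parameter": "onset", "covariate": "sex_female",
             "beta": +2.0, "q": 0.01},     # later onset => protective => -2
        ])
        out = significance_map(res).set_index("region")
        assert out.loc["r1", "signed_neglog10_q"] == pytest.approx(3.0)
        assert out.loc["r2", "signed_neglog10_q"] == pytest.approx(2.0)
        assert out.loc["r3", "signed_neglog10_q"] == pytest.approx(-2.0)

    def test_q_above_alpha_masked(self):
        res = self._table([
            {"region": "r1", "parameter": "onset", "covariate": "sex_female",
             "beta": -1.0, "q": 0.06},
        ])
        assert significance_map(res).empty

    def test_requires_fdr_first(self):
        res = self._table([{"region": "r", "parameter": "onset",
                            "covariate": "sex_female", "beta": 1.0}])
        with pytest.raises(ValueError, match="add_fdr"):
            significance_map(res)


class TestAddFdr:
    def test_family_per_map_vs_pooled(self):
        rng = np.random.default_rng(5)
        rows = []
        for region in [f"r{i}" for i in range(20)]:
            for parameter in ("onset", "log_pace"):
                rows.append({"region": region, "parameter": parameter,
                             "covariate": "sex_female", "beta": 1.0,
                             "p": rng.random()})
        res = pd.DataFrame(rows)
        per_map = add_fdr(res, family="per-map")
        pooled = add_fdr(res, family="pooled")
        # per-map corrects over 20 tests; pooled over 40
        sub = res["parameter"] == "onset"
        np.testing.assert_allclose(
            per_map.loc[sub, "q"], fdr_adjust(res.loc[sub, "p"]), atol=1e-12)
        np.testing.assert_allclose(
            pooled["q"], fdr_adjust(res["p"]), atol=1e-12)
        with pytest.raises(ValueError, match="family"):
            add_fdr(res, family="bonferroni")


class TestStatisticalCalibration:
    """Type-I error and FDR control of the testing stack on truth tables."""

    def test_null_type_one_error_within_binomial_band(self):
        cfg = CohortConfig(n_subjects=150, n_regions=100, seed=31,
                           covariate_effects={})
        _, cov, truth = generate_cohort(cfg)
        res = ols_covariance(truth.individual, cov)
        for (_, _), grp in res.groupby(["parameter", "covariate"]):
            frac = (grp["p"] < 0.05).mean()
            assert 0.0 <= frac <= 0.12   # 100 tests: loose per-family guard

    def test_fdr_controls_false_discovery_proportion(self):
        # 100 regions, 20 with a real APOE onset shift; FDP averaged over
        # 10 generator seeds stays near the nominal 0.05 level
        fdp = []
        for seed in range(10):
            effects = [{} for _ in range(100)]
            for r in range(20):
                effects[r] = {"apoe4_count": (-1.5, 0.0)}
            cfg = CohortConfig(n_subjects=150, n_regions=100, seed=100 + seed,
                               covariate_effects=effects)
            _, cov, truth = generate_cohort(cfg)
            res = add_fdr(ols_covariance(truth.individual, cov))
            sub = res[(res["parameter"] == "onset")
                      & (res["covariate"] == "apoe4_count")
                      & (res["q"] <= 0.05)]
            if len(sub):
                nonnull = {f"region_{r + 1}" for r in range(20)}
                false = (~sub["region"].isin(nonnull)).sum()
                fdp.append(false / len(sub))
            else:
                fdp.append(0.0)
        assert np.mean(fdp) <= 0.12


class TestCovariateCorrelations:
    def test_independent_covariates_nearly_uncorrelated(self):
        cfg = CohortConfig(n_subjects=2000, n_regions=1, seed=23)
        _, cov, _ = generate_cohort(cfg)
        out = covariate_correlations(cov)
        assert (out["abs_correlation"] <= 0.1).all()

    def test_duplicated_covariate_is_perfectly_correlated(self):
        cov = pd.DataFrame({
            "subject_id": ["a", "b", "c", "d"],
            "sex_female": [0, 1, 0, 1],
            "apoe4_count": [0, 1, 0, 1],   # identical to sex
            "education_years": [12, 16, 14, 18],
        })
        out = covariate_correlations(cov).set_index(
            ["covariate_a", "covariate_b"])
        assert out.loc[("apoe4_count", "sex_female"),
                       "abs_correlation"] == pytest.approx(1.0)

    def test_imposed_correlation_recovered(self, rng):
        n = 3000
        edu = rng.normal(16, 3, n)
        # anti-correlate sex with education through a shared latent
        p = 1 / (1 + np.exp((edu - 16) / 2.0))
        sex = (rng.random(n) < p).astype(int)
        cov = pd.DataFrame({
            "subject_id": [f"s{i}" for i in range(n)],
            "sex_female": sex,
            "apoe4_count": rng.integers(0, 3, n),
            "education_years": edu,
        })
        target = abs(np.corrcoef(sex, edu)[0, 1])
        out = covariate_correlations(cov).set_index(
            ["covariate_a", "covariate_b"])
        got = out.loc[("sex_female", "education_years"), "abs_correlation"]
        assert got == pytest.approx(target, abs=1e-12)
        assert got > 0.2

    def test_zero_variance_covariate_warns_na(self):
        cov = pd.DataFrame({
            "subject_id": ["a", "b", "c"],
            "sex_female": [1, 1, 1],
            "apoe4_count": [0, 1, 2],
            "education_years": [12, 16, 14],
        })
        with pytest.warns(UserWarning, match="zero-variance"):
            out = covariate_correlations(cov)
        assert out["abs_correlation"].isna().sum() == 2
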