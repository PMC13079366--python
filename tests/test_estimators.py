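"""Estimator correctness against closed-form oracles and statsmodels."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

import genlottery as gl
from genlottery.cohort import AnalysisSample
from genlottery.estimators import (
    DegenerateVariationError,
    ModelSpec,
    WeakInstrumentError,
    parental_earnings_quartiles,
)
from genlottery.regress import RankDeficiencyError, cluster_ols, factorize_clusters


def toy_sample(y, s, z=None, fam=None, covs=None, byear=None):
    n = len(y)
    df = pd.DataFrame({
        "id": [f"i{k}" for k in range(n)],
        "family_id": [f"f{g}" for g in (fam if fam is not None else range(n))],
        "family_index": fam if fam is not None else np.arange(n),
        "birth_year": byear if byear is not None else np.full(n, 1970),
        "schooling_years": s,
        "earnings_prime": np.exp(y),
        "log_earnings": y,
    })
    names = []
    if z is not None:
        df["piv_std"] = z
    if covs is not None:
        for k, v in covs.items():
            df[k] = v
            names.append(k)
    return AnalysisSample(label="toy", df=df, covariate_names=names)


class TestClusterOLS:
    def test_matches_statsmodels_cluster(self, rng):
        n = 400
        X = np.column_stack([np.ones(n), rng.normal(size=(n, 2))])
        y = X @ [1.0, 0.5, -0.3] + rng.normal(size=n)
        cl = rng.integers(0, 25, size=n)
        beta, cov, _, _ = cluster_ols(y, X, cl)
        fit = sm.OLS(y, X).fit(cov_type="cluster", cov_kwds={"groups": cl})
        assert np.allclose(beta, fit.params)
        assert np.allclose(np.sqrt(np.diag(cov)), fit.bse, rtol=1e-8)

    def test_singleton_clusters_equal_hc1(self, rng):
        n = 150
        X = np.column_stack([np.ones(n), rng.normal(size=n)])
        y = X @ [0.2, 1.1] + rng.normal(size=n) * (1 + X[:, 1] ** 2)
        _, cov, _, _ = cluster_ols(y, X, np.arange(n))
        fit = sm.OLS(y, X).fit(cov_type="HC1")
        assert np.allclose(np.sqrt(np.diag(cov)), fit.bse, rtol=1e-8)


class TestOLS:
    def test_exact_fit(self):
        s = np.array([10.0, 11, 12, 13, 14, 15])
        res = gl.fit_ols(toy_sample(2 * s, s), ModelSpec())
        assert res.beta == pytest.approx(2.0, abs=1e-10)
        assert res.se < 1e-8

    def test_six_point_normal_equation_oracle(self, rng):
        s = np.array([10.0, 12, 12, 14, 16, 18])
        c = np.array([1.0, 0, 1, 0, 1, 0])
        y = np.array([11.0, 11.8, 12.4, 13.1, 14.9, 15.2])
        X = np.column_stack([np.ones(6), s, c])
        expected = np.linalg.solve(X.T @ X, X.T @ y)[1]
        res = gl.fit_ols(toy_sample(y, s, covs={"c": c}), ModelSpec())
        assert res.beta == pytest.approx(expected, abs=1e-10)

    def test_rank_deficiency_names_columns(self):
        s = np.arange(8.0)
        res = toy_sample(np.ones(8), s, covs={"dup": s.copy()})
        with pytest.raises(RankDeficiencyError, match="dup|schooling"):
            gl.fit_ols(res, ModelSpec())

    def test_confounding_bias_detected(self):
        cfg = gl.preset("individual_confounding", n_families=15000, seed=30,
                        genotyped_family_prob=1.0)
        samples, _ = gl.build_samples(gl.simulate_population(cfg))
        res = gl.fit_ols(samples["full"], ModelSpec())
        assert (res.beta - cfg.beta_true) / res.se > 3


class TestFamilyFE:
    def test_invariant_to_family_level_shifts(self, rng):
        fam = np.repeat(np.arange(30), 2)
        s = rng.integers(10, 18, size=60).astype(float)
        y = 0.1 * s + rng.normal(size=60)
        base = gl.fit_family_fe(toy_sample(y, s, fam=fam), ModelSpec())
        shifted = gl.fit_family_fe(
            toy_sample(y + 5.0 * fam, s, fam=fam), ModelSpec())
        assert shifted.beta == pytest.approx(base.beta, abs=1e-10)

    def test_pair_difference_oracle(self, rng):
        fam = np.repeat(np.arange(40), 2)
        s = rng.integers(9, 19, size=80).astype(float)
        y = 0.08 * s + 0.3 * rng.normal(size=80)
        res = gl.fit_family_fe(toy_sample(y, s, fam=fam), ModelSpec())
        ds = s[::2] - s[1::2]
        dy = y[::2] - y[1::2]
        assert res.beta == pytest.approx(np.sum(ds * dy) / np.sum(ds * ds), abs=1e-10)

    def test_degenerate_variation_error(self):
        fam = np.repeat(np.arange(10), 2)
        s = np.repeat(np.arange(10) + 8.0, 2)  # concordant within family
        with pytest.raises(DegenerateVariationError):
            gl.fit_family_fe(toy_sample(np.ones(20), s, fam=fam), ModelSpec())

    def test_family_constant_covariates_dropped(self, rng):
        fam = np.repeat(np.arange(50), 2)
        s = rng.integers(9, 19, size=100).astype(float)
        y = 0.08 * s + rng.normal(size=100)
        covs = {"const_in_fam": np.repeat(rng.normal(size=50), 2)}
        res = gl.fit_family_fe(toy_sample(y, s, fam=fam, covs=covs), ModelSpec())
        assert res.extras["dropped_covariates"] == ["const_in_fam"]

    def test_recovers_truth_under_dynastic_confounding(self):
        cfg = gl.preset("family_confounding", n_families=20000, seed=31,
                        offspring_dist=(0.0, 1.0, 0.0), twin_prob=0.0)
        samples, _ = gl.build_samples(gl.simulate_population(cfg))
        fe = gl.fit_family_fe(samples["sibling"], ModelSpec())
        ols = gl.fit_ols(samples["full"], ModelSpec())
        assert abs(fe.beta - cfg.beta_true) < 3 * fe.se
        assert (ols.beta - cfg.beta_true) / ols.se > 3


class TestTSLS:
    def test_instrument_equals_exposure_gives_ols(self, rng):
        s = rng.integers(9, 19, size=100).astype(float)
        y = 0.1 * s + rng.normal(size=100)
        z = (s - s.mean()) / s.std()
        iv = gl.fit_tsls(toy_sample(y, s, z=z), ModelSpec(instrument="piv_std"))
        ols = gl.fit_ols(toy_sample(y, s), ModelSpec())
        assert iv.beta == pytest.approx(ols.beta, abs=1e-10)

    def test_wald_ratio_oracle_20_rows(self, rng):
        z = rng.normal(size=20)
        s = 10 + 2 * z + rng.normal(size=20)
        y = 0.1 * s + rng.normal(size=20)
        res = gl.fit_tsls(toy_sample(y, s, z=z), ModelSpec(instrument="piv_std"))
        zc, yc, sc = z - z.mean(), y - y.mean(), s - s.mean()
        assert res.beta == pytest.approx(np.sum(zc * yc) / np.sum(zc * sc), abs=1e-12)

    def test_fwl_equivalence_with_explicit_two_stage(self, rng):
        n = 200
        z = rng.normal(size=n)
        c = rng.normal(size=(n, 2))
        s = 12 + z + c @ [0.5, -0.2] + rng.normal(size=n)
        y = 0.08 * s + c @ [0.3, 0.1] + rng.normal(size=n)
        res = gl.fit_tsls(toy_sample(y, s, z=z, covs={"c1": c[:, 0], "c2": c[:, 1]}),
                          ModelSpec(instrument="piv_std"))
        # explicit 2SLS: first stage with covariates, then second stage
        X1 = np.column_stack([np.ones(n), z, c])
        s_hat = X1 @ np.linalg.lstsq(X1, s, rcond=None)[0]
        X2 = np.column_stack([np.ones(n), s_hat, c])
        beta2 = np.linalg.lstsq(X2, y, rcond=None)[0][1]
        assert res.beta == pytest.approx(beta2, rel=1e-8)

    def test_scale_equivariance_absolute_outcome(self, genotyped):
        spec = ModelSpec(outcome="abs", instrument="piv_std")
        base = gl.fit_tsls(genotyped, spec)
        scaled = genotyped.subset(np.arange(genotyped.n))
        scaled.df["earnings_prime"] *= 3.0
        res = gl.fit_tsls(scaled, spec)
        assert res.beta == pytest.approx(3.0 * base.beta, rel=1e-10)
        assert res.se == pytest.approx(3.0 * base.se, rel=1e-10)

    def test_weak_instrument_error(self, rng):
        s = rng.integers(9, 19, size=50).astype(float)
        z = np.zeros(50)
        with pytest.raises(WeakInstrumentError):
            gl.fit_tsls(toy_sample(rng.normal(size=50), s, z=z),
                        ModelSpec(instrument="piv_std"))

    def test_mr_unbiased_under_individual_confounding(self):
        cfg = gl.preset("individual_confounding", n_families=15000, seed=32,
                        genotyped_family_prob=1.0)
        samples, _ = gl.build_samples(gl.simulate_population(cfg))
        mr = gl.fit_tsls(samples["genotyped"], ModelSpec(instrument="piv_std"))
        assert abs(mr.beta - cfg.beta_true) < 3 * mr.se
        assert mr.F_first_stage > 10


class TestSiblingMR:
    def test_mz_only_raises_weak_instrument(self):
        cfg = gl.SimConfig(n_families=800, twin_prob=1.0, mz_share=1.0,
                           offspring_dist=(0.0, 1.0, 0.0),
                           genotyped_family_prob=1.0, seed=33)
        samples, _ = gl.build_samples(gl.simulate_population(cfg))
        with pytest.raises(WeakInstrumentError):
            gl.fit_sibling_mr(samples["genotyped_sibling"],
                              ModelSpec(instrument="piv_std"))

    def test_pair_differenced_wald_oracle(self, rng):
        fam = np.repeat(np.arange(60), 2)
        z = rng.normal(size=120)
        s = 12 + z + rng.normal(size=120)
        y = 0.1 * s + rng.normal(size=120)
        res = gl.fit_sibling_mr(toy_sample(y, s, z=z, fam=fam),
                                ModelSpec(instrument="piv_std"))
        dz, dy, ds = z[::2] - z[1::2], y[::2] - y[1::2], s[::2] - s[1::2]
        assert res.beta == pytest.approx(np.sum(dz * dy) / np.sum(dz * ds), abs=1e-10)

    def test_recovers_truth_under_family_confounding(self):
        cfg = gl.preset("family_confounding", n_families=20000, seed=34,
                        offspring_dist=(0.0, 1.0, 0.0), twin_prob=0.0,
                        genotyped_family_prob=1.0)
        samples, _ = gl.build_samples(gl.simulate_population(cfg))
        pop_mr = gl.fit_tsls(samples["genotyped"], ModelSpec(instrument="piv_std"))
        sib_mr = gl.fit_sibling_mr(samples["genotyped_sibling"],
                                   ModelSpec(instrument="piv_std"))
        assert (pop_mr.beta - cfg.beta_true) / pop_mr.se > 3
        assert abs(sib_mr.beta - cfg.beta_true) < 3 * sib_mr.se


class TestAndersonRubin:
    def test_p_value_maximized_at_point_estimate(self, genotyped):
        spec = ModelSpec(instrument="piv_std")
        tsls = gl.fit_tsls(genotyped, spec)
        ar = gl.ar_confidence_interval(genotyped, spec)
        p0 = ar.p_value(tsls.beta)
        for shift in (-4, -2, 2, 4):
            assert ar.p_value(tsls.beta + shift * tsls.se) < p0

    def test_strong_instrument_ar_close_to_wald(self):
        cfg = gl.preset("null", n_families=3000, seed=37, pi_first_stage=0.6,
                        genotyped_family_prob=1.0)
        samples, _ = gl.build_samples(gl.simulate_population(cfg))
        sample = samples["genotyped"]
        spec = ModelSpec(instrument="piv_std")
        tsls = gl.fit_tsls(sample, spec)
        assert tsls.F_first_stage > 100
        ar = gl.ar_confidence_interval(sample, spec)
        width = tsls.ci_high - tsls.ci_low
        assert abs(ar.ci_low - tsls.ci_low) < 0.1 * width
        assert abs(ar.ci_high - tsls.ci_high) < 0.1 * width
        assert ar.ci_low < tsls.beta < ar.ci_high


class TestBalance:
    def test_independent_covariate_balanced(self, genotyped):
        frame, joint = gl.balance_test(genotyped, covariates=["sex", "birth_year"])
        assert np.all(np.abs(frame["coef"]) < 0.03)
        assert joint["p"] > 0.001

    def test_dynastic_between_vs_within(self):
        cfg = gl.preset("family_confounding", n_families=8000, seed=35,
                        offspring_dist=(0.0, 1.0, 0.0), genotyped_family_prob=1.0)
        samples, _ = gl.build_samples(gl.simulate_population(cfg))
        between, _ = gl.balance_test(samples["genotyped"])
        pe = between.set_index("covariate").loc["parental_education", "coef"]
        assert pe > 0.05  # genetic transmission + assortment show up between families
        within, _ = gl.balance_test(samples["genotyped_sibling"], within_family=True)
        within = within[~within["skipped"]].set_index("covariate")
        varying = [c for c in ("sex", "birth_order", "mother_age_at_birth")
                   if c in within.index]
        assert np.all(np.abs(within.loc[varying, "coef"]) < 0.03)

    def test_constant_covariate_skipped_with_warning(self, genotyped):
        sub = genotyped.subset(np.arange(genotyped.n))
        sub.df["constant"] = 1.0
        with pytest.warns(UserWarning, match="constant"):
            frame, _ = gl.balance_test(sub, covariates=["constant", "sex"])
        assert frame.set_index("covariate").loc["constant", "skipped"]


class TestStratified:
    def test_quartiles_partition_with_ties_low(self):
        v = np.array([1.0, 2, 2, 2, 3, 4, 5, 6])
        q = parental_earnings_quartiles(v)
        assert set(q) <= {0, 1, 2, 3}
        cuts = np.quantile(v, [0.25, 0.5, 0.75])
        # values exactly at the first cut (2.0) go to the lower stratum
        assert cuts[0] == 2.0
        assert np.all(q[v == 2.0] == 0)

    def test_homogeneous_strata_agree(self, null_samples):
        res = gl.stratified_estimates(null_samples["genotyped"], ModelSpec(),
                                      "sex", estimator=gl.fit_ols)
        (a, b) = (res[0], res[1])
        pooled_se = np.hypot(a.se, b.se)
        assert abs(a.beta - b.beta) < 3 * pooled_se

    def test_planted_sex_gap_recovered(self):
        cfg = gl.preset("null", n_families=12000, seed=36, sex_return_gap=0.03,
                        genotyped_family_prob=1.0)
        samples, _ = gl.build_samples(gl.simulate_population(cfg))
        res = gl.stratified_estimates(samples["genotyped"], ModelSpec(),
                                      "sex", estimator=gl.fit_ols)
        assert res[1].beta > res[0].beta
        assert (res[1].beta - res[0].beta) == pytest.approx(0.03, abs=0.01)

    def test_quartile_strata_partition_sample(self, genotyped):
        res = gl.stratified_estimates(genotyped, ModelSpec(),
                                      "parental_earnings_quartile",
                                      estimator=gl.fit_ols, min_n=10)
        assert sum(r.n for r in res.values()) == genotyped.n
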