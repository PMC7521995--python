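"""Weighted Cox fitting, time-varying and interaction models, likelihood
ratio tests, and concordance — checked against closed forms, brute-force
oracles, and simulation."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import optimize, special, stats

from carrierprs import (AnalysisDataset, FitError, PrsVector, SimulationConfig,
                        assign_percentiles, build_analysis_dataset,
                        calibrate_sampling_weights, categorical_percentile_fit,
                        concordance, fit_prospective_cox, fit_time_varying_prs,
                        fit_weighted_cox, interaction_models,
                        likelihood_ratio_test, simulate_retrospective_cohort,
                        split_episodes)


def _dataset(time, event, z, weights=None, cluster=None, stratum=None,
             entry=None, **extra):
    n = len(time)
    t = pd.DataFrame({
        "carrier_id": [f"c{i}" for i in range(n)],
        "entry_age": entry if entry is not None else 0.0,
        "exit_age": np.asarray(time, float),
        "event": np.asarray(event, int),
        "stratum": stratum if stratum is not None else "all",
        "cluster": cluster if cluster is not None else [f"c{i}" for i in range(n)],
        "sampling_weight": weights if weights is not None else 1.0,
        "z": np.asarray(z, float),
    })
    for k, v in extra.items():
        t[k] = v
    return AnalysisDataset(table=t, outcome="breast", covariates=["z"])


def _brute_force_beta(time, event, z, weights=None):
    """Maximize the (Breslow-weighted) partial likelihood by 1-D search;
    valid for untied event times."""
    w = np.ones(len(time)) if weights is None else np.asarray(weights, float)
    time, event, z = map(np.asarray, (time, event, z))
    assert len(np.unique(time[event == 1])) == event.sum(), "oracle needs no ties"

    def negll(beta):
        ll = 0.0
        for i in np.flatnonzero(event):
            risk = time >= time[i]
            ll += w[i] * (beta * z[i]
                          - np.log(np.sum(w[risk] * np.exp(beta * z[risk]))))
        return -ll

    res = optimize.minimize_scalar(negll, bounds=(-5, 5), method="bounded",
                                   options={"xatol": 1e-10})
    return res.x


class TestWeightedCox:
    def test_three_subject_closed_form(self):
        """Events at t=1 (z=1), t=2 (z=0), censored t=3 (z=1): the score
        equation solves to beta = -(1/2) ln 2."""
        ds = _dataset([1, 2, 3], [1, 1, 0], [1, 0, 1])
        fit = fit_weighted_cox(ds, strata=False, cluster=False)
        assert fit.coefficients["z"] == pytest.approx(-0.5 * np.log(2), abs=1e-6)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_brute_force_on_tiny_data(self, seed):
        """With unit weights, one stratum and no ties the fit agrees with an
        exhaustive partial-likelihood maximization to 1e-6."""
        rng = np.random.default_rng(seed)
        n = 6
        time = rng.permutation(np.arange(1.0, n + 1))
        event = rng.random(n) < 0.7
        event[rng.integers(n)] = True
        z = rng.normal(size=n)
        ds = _dataset(time, event, z)
        fit = fit_weighted_cox(ds, strata=False, cluster=False)
        assert fit.coefficients["z"] == pytest.approx(
            _brute_force_beta(time, event, z), abs=1e-6)

    def test_weighted_fit_matches_weighted_brute_force(self):
        rng = np.random.default_rng(3)
        n = 6
        time = np.arange(1.0, n + 1)
        event = np.array([1, 0, 1, 1, 0, 1])
        z = rng.normal(size=n)
        w = np.array([0.5, 1.0, 2.0, 1.5, 0.8, 1.2])
        ds = _dataset(time, event, z, weights=w)
        fit = fit_weighted_cox(ds, strata=False, cluster=False)
        assert fit.coefficients["z"] == pytest.approx(
            _brute_force_beta(time, event, z, w), abs=1e-5)

    def test_null_covariate_gives_zero_effect(self):
        """A covariate permuted against outcomes estimates beta ~ 0."""
        rng = np.random.default_rng(7)
        n = 2000
        z = rng.standard_normal(n)
        time = rng.exponential(50, n).clip(1, 79.5)
        event = rng.random(n) < 0.5
        ds = _dataset(time, event, rng.permutation(z))
        fit = fit_weighted_cox(ds, strata=False, cluster=False)
        assert abs(fit.coefficients["z"]) < 3 * fit.se["z"]

    def test_no_events_is_error(self):
        ds = _dataset([1, 2], [0, 0], [0.5, -0.5])
        with pytest.raises(FitError):
            fit_weighted_cox(ds)

    def test_collinear_covariates_rejected(self):
        ds = _dataset([1, 2, 3, 4], [1, 0, 1, 0], [1, 2, 3, 4],
                      z2=[2.0, 4.0, 6.0, 8.0])
        ds.covariates = ["z", "z2"]
        with pytest.raises(FitError, match="collinear"):
            fit_weighted_cox(ds, covariates=["z", "z2"], strata=False,
                             cluster=False)

    def test_robust_variance_exceeds_naive_under_clustering(self):
        """Positively correlated outcomes within families inflate the
        cluster-sandwich variance above the naive model-based one."""
        rng = np.random.default_rng(11)
        n_fam = 300
        fam_z = rng.standard_normal(n_fam)
        fam_frail = rng.normal(0, 0.8, n_fam)
        rows_t, rows_e, rows_z, rows_c = [], [], [], []
        for f in range(n_fam):
            for _ in range(3):  # trios share PRS and frailty: strong clustering
                z = fam_z[f]
                lam = 0.02 * np.exp(0.3 * z + fam_frail[f])
                t = rng.exponential(1 / lam)
                c = rng.uniform(10, 60)
                rows_t.append(min(t, c, 79.0))
                rows_e.append(int(t <= min(c, 79.0)))
                rows_z.append(z)
                rows_c.append(f"f{f}")
        ds = _dataset(rows_t, rows_e, rows_z, cluster=rows_c)
        fit = fit_weighted_cox(ds, strata=False, cluster=True, naive=True)
        assert (fit.robust_covariance.loc["z", "z"]
                > fit.naive_covariance.loc["z", "z"])

    def test_sandwich_matches_lifelines_robust_se(self):
        """On tie-free data without delayed entry the in-package cluster
        sandwich reproduces lifelines' robust standard errors."""
        from lifelines import CoxPHFitter

        rng = np.random.default_rng(17)
        n = 400
        df = pd.DataFrame({
            "t": rng.uniform(1.0, 79.0, n),  # tie-free, within the age cap
            "e": (rng.random(n) < 0.6).astype(int),
            "z": rng.normal(size=n), "z2": rng.normal(size=n),
            "fam": [f"f{i // 2}" for i in range(n)],
        })
        ll = CoxPHFitter().fit(df, "t", "e", cluster_col="fam", robust=True)
        ds = _dataset(df["t"], df["e"], df["z"], cluster=df["fam"],
                      z2=df["z2"])
        fit = fit_weighted_cox(ds, covariates=["z", "z2"], strata=False,
                               cluster=True)
        np.testing.assert_allclose(fit.se[["z", "z2"]],
                                   ll.standard_errors_[["z", "z2"]], rtol=1e-4)

    def test_stratified_fit_drops_eventless_strata(self):
        ds = _dataset([1, 2, 3, 4], [1, 1, 0, 0], [0.3, -0.2, 0.1, 0.4],
                      stratum=["a", "a", "b", "b"])
        fit = fit_weighted_cox(ds, cluster=False)
        assert fit.n == 2


class TestProspective:
    def test_zero_entry_reduces_to_retrospective(self, breast_curve):
        """With entry ages all zero the prospective estimator equals the
        unweighted retrospective fit on the same data."""
        cfg = SimulationConfig(n_carriers=2000, beta0=np.log(1.3),
                               incidence=breast_curve,
                               target_affected_fraction=None, seed=21)
        cohort, _ = simulate_retrospective_cohort(cfg)
        cohort = cohort.assign(age_recruit=0.001)
        retro = fit_weighted_cox(build_analysis_dataset(cohort, "breast"))
        prosp = fit_prospective_cox(cohort, "breast")
        assert prosp.coefficients["prs_standardized"] == pytest.approx(
            retro.coefficients["prs_standardized"], abs=1e-8)

    def test_agrees_with_retrospective_without_ascertainment(self, breast_curve):
        """Prospective (left-truncated) and retrospective estimators agree
        within Monte-Carlo error on unascertained data."""
        from carrierprs import simulate_prospective_cohort

        cfg = SimulationConfig(n_carriers=6000, beta0=np.log(1.3),
                               incidence=breast_curve,
                               target_affected_fraction=None, seed=22)
        cohort, _ = simulate_prospective_cohort(cfg)
        prosp = fit_prospective_cox(cohort, "breast")
        retro = fit_weighted_cox(build_analysis_dataset(cohort, "breast"))
        diff = (prosp.coefficients["prs_standardized"]
                - retro.coefficients["prs_standardized"])
        assert abs(diff) < 3 * np.hypot(prosp.se["prs_standardized"],
                                        retro.se["prs_standardized"])


class TestTimeVarying:
    def test_constant_effect_gives_unit_interaction(self, breast_curve):
        cfg = SimulationConfig(n_carriers=2500, beta0=np.log(1.4),
                               incidence=breast_curve, seed=31)
        cohort, _ = simulate_retrospective_cohort(cfg)
        ds = build_analysis_dataset(cohort, "breast")
        fit = fit_time_varying_prs(ds, strata=False)
        lo, hi = fit.confidence_interval("prs_by_age")
        assert lo < 1.0 < hi

    def test_decreasing_effect_recovered(self, breast_curve):
        """Simulated log HR beta(t) = beta0 + beta1 t with beta1 < 0 is
        recovered by the episode-split interaction fit within 3 SEs."""
        beta0, beta1 = 0.9, -0.012
        cfg = SimulationConfig(n_carriers=4000, beta0=beta0, beta1=beta1,
                               incidence=breast_curve, seed=32)
        cohort, _ = simulate_retrospective_cohort(cfg)
        ds = build_analysis_dataset(cohort, "breast")
        fit = fit_time_varying_prs(ds, strata=False)
        assert abs(fit.coefficients["prs_standardized"] - beta0) \
            < 3 * fit.se["prs_standardized"]
        assert abs(fit.coefficients["prs_by_age"] - beta1) < 3 * fit.se["prs_by_age"]
        assert fit.hazard_ratio("prs_by_age") < 1.0

    def test_split_preserves_events_and_exposure(self):
        ds = _dataset([2.0, 3.0, 4.0], [1, 1, 0], [0.1, -0.3, 0.5])
        split = split_episodes(ds, prs_col="z")
        assert split["event"].sum() == 2
        exposure = (split["exit_age"] - split["entry_age"]).groupby(
            split["carrier_id"]).sum().sort_index()
        assert exposure.tolist() == [2.0, 3.0, 4.0]
        # covariate at each episode end equals z * stop age
        np.testing.assert_allclose(split["prs_by_age"],
                                   split["z"] * split["exit_age"])


class TestLikelihoodRatio:
    def test_identical_models_give_zero(self):
        ds = _dataset([1, 2, 3, 4], [1, 1, 0, 1], [0.5, -0.5, 0.2, 0.1])
        fit = fit_weighted_cox(ds, strata=False, cluster=False)
        stat, df, p = likelihood_ratio_test(fit, fit)
        assert stat == 0.0 and df == 0 and p == 1.0

    def test_df_counts_parameters(self):
        rng = np.random.default_rng(5)
        n = 100
        ds = _dataset(rng.exponential(10, n).clip(0.1, 79.9), rng.random(n) < 0.6,
                      rng.normal(size=n), z2=rng.normal(size=n))
        small = fit_weighted_cox(ds, covariates=["z"], strata=False, cluster=False)
        big = fit_weighted_cox(ds, covariates=["z", "z2"], strata=False,
                               cluster=False)
        stat, df, p = likelihood_ratio_test(small, big)
        assert df == 1 and stat >= 0

    def test_non_nested_rejected(self):
        rng = np.random.default_rng(6)
        n = 50
        ds = _dataset(rng.exponential(10, n).clip(0.1, 79.9), rng.random(n) < 0.6,
                      rng.normal(size=n), z2=rng.normal(size=n))
        a = fit_weighted_cox(ds, covariates=["z"], strata=False, cluster=False)
        b = fit_weighted_cox(ds, covariates=["z2"], strata=False, cluster=False)
        with pytest.raises(FitError, match="nested"):
            likelihood_ratio_test(a, b)

    def test_null_distribution_is_chi_square(self):
        """Under H0 (independent extra covariate, unit weights) the LRT
        statistic follows chi-square(1): KS test at the 1% level."""
        rng = np.random.default_rng(8)
        stats_ = []
        n = 60
        for _ in range(400):
            time = rng.exponential(10, n).clip(0.1, 79.9)
            event = rng.random(n) < 0.7
            z = rng.normal(size=n)
            z2 = rng.normal(size=n)
            ds = _dataset(time, event, z, z2=z2)
            small = fit_weighted_cox(ds, covariates=["z"], strata=False,
                                     cluster=False)
            big = fit_weighted_cox(ds, covariates=["z", "z2"], strata=False,
                                   cluster=False)
            stats_.append(likelihood_ratio_test(small, big)[0])
        _, pval = stats.kstest(stats_, stats.chi2(1).cdf)
        assert pval > 0.01


class TestInteractionModels:
    def test_homogeneous_groups_not_flagged(self, ascertained_cohort,
                                            breast_curve):
        cohort, _ = ascertained_cohort
        ds = build_analysis_dataset(cohort, "breast")
        _, wds = calibrate_sampling_weights(ds, breast_curve)
        res = interaction_models(wds, "group_variant_class")
        assert res["lrt"]["p"] > 0.01  # simulated with one common slope
        hrs = res["per_group"]["hr"]
        assert np.all((hrs > 1.05) & (hrs < 1.6))

    def test_two_group_difference_detected(self):
        """Slopes differing by 0.3 in log HR are detected and recovered."""
        rng = np.random.default_rng(9)
        rows = []
        for g, beta in (("I", 0.2), ("II", 0.5)):
            n = 4000
            z = rng.standard_normal(n)
            lam = 0.02 * np.exp(beta * z)
            t = rng.exponential(1 / lam)
            c = rng.uniform(20, 70, n)
            rows.append(pd.DataFrame({
                "time": np.minimum(t, c), "event": (t <= c).astype(int),
                "z": z, "grp": g}))
        df = pd.concat(rows, ignore_index=True)
        ds = _dataset(df["time"], df["event"], df["z"], grp=df["grp"])
        res = interaction_models(ds, "grp", prs_col="z")
        assert res["lrt"]["p"] < 0.01
        assert res["p_difference"] < 0.01
        est = res["per_group"]["coef"]
        assert est["prs_x_I"] == pytest.approx(0.2, abs=0.1)
        assert est["prs_x_II"] == pytest.approx(0.5, abs=0.1)

    def test_single_group_rejected(self):
        ds = _dataset([1, 2, 3], [1, 1, 0], [0.1, 0.2, 0.3], grp="only")
        with pytest.raises(FitError):
            interaction_models(ds, "grp", prs_col="z")


@pytest.fixture(scope="module")
def categorical_fitted(ascertained_cohort, breast_curve):
    cohort, _ = ascertained_cohort
    ds = build_analysis_dataset(cohort, "breast")
    _, wds = calibrate_sampling_weights(ds, breast_curve)
    t = wds.table
    prs = PrsVector(t["carrier_id"].tolist(),
                    t["prs_standardized"].to_numpy(),
                    standardized=t["prs_standardized"].to_numpy())
    scheme, labels = assign_percentiles(
        prs, t.loc[t["event"] == 0, "carrier_id"].tolist())
    return categorical_percentile_fit(wds, labels, scheme), scheme


class TestCategoricalPercentiles:

    def test_bin_hazard_ratios_increase(self, categorical_fitted):
        """Bin-specific HRs relative to the 40-60 reference rise monotonically
        in expectation; require < 1 below and > 1 above the reference."""
        res, scheme = categorical_fitted
        hr = res["fit"].summary()["hr"]
        below = [f"prs_bin_{k}" for k in range(4)]
        above = [f"prs_bin_{k}" for k in range(5, 9)]
        assert (hr[below] < 1).all() and (hr[above] > 1).all()
        assert hr["prs_bin_0"] < hr["prs_bin_3"]
        assert hr["prs_bin_5"] < hr["prs_bin_8"]

    def test_expected_hr_uses_truncated_normal_mean(self, categorical_fitted):
        """The continuous-model prediction for the top bin uses
        E[z | top 5%] = phi(z_0.95)/0.05 ~ 2.063."""
        res, scheme = categorical_fitted
        beta = res["fit_continuous"].coefficients["prs_standardized"]
        top = res["expected_hr_continuous"]["95-100"]
        ez_top = stats.norm.pdf(special.ndtri(0.95)) / 0.05
        ez_ref = 0.0  # symmetric 40-60 bin
        assert top == pytest.approx(np.exp(beta * (ez_top - ez_ref)), rel=1e-10)

    def test_continuous_model_not_rejected_under_continuous_truth(self, categorical_fitted):
        res, _ = categorical_fitted
        assert res["lrt_vs_continuous"]["p"] > 0.01


class TestConcordance:
    def test_perfect_ranking(self):
        ds = _dataset([1, 2, 3, 4], [1, 1, 1, 0], [4, 3, 2, 1.0])
        fit = fit_weighted_cox(ds, strata=False, cluster=False)
        res = concordance(ds, fit=fit, n_bootstrap=10, seed=0)
        assert res.c_statistic == 1.0

    def test_random_score_near_half(self):
        rng = np.random.default_rng(13)
        n = 600
        ds = _dataset(rng.exponential(10, n).clip(0.1, 79.9), rng.random(n) < 0.6,
                      rng.normal(size=n))
        res = concordance(ds, score=rng.normal(size=n), n_bootstrap=30, seed=1)
        assert res.c_statistic == pytest.approx(0.5, abs=0.05)

    def test_matches_exhaustive_pair_count(self):
        """On n=20 the pooled C equals a brute-force enumeration of usable
        pairs exactly."""
        rng = np.random.default_rng(14)
        n = 20
        time = rng.integers(1, 10, n).astype(float)
        event = (rng.random(n) < 0.6).astype(int)
        score = rng.normal(size=n)
        strat = rng.choice(["a", "b"], n)
        ds = _dataset(time, event, score, stratum=strat)
        res = concordance(ds, score=score, n_bootstrap=5, seed=2)
        conc = pairs = 0.0
        for i, j in itertools.permutations(range(n), 2):
            if strat[i] != strat[j] or not event[i]:
                continue
            if time[i] < time[j] or (time[i] == time[j] and not event[j]):
                pairs += 1
                if score[i] > score[j]:
                    conc += 1
                elif score[i] == score[j]:
                    conc += 0.5
        assert res.n_pairs == pairs
        assert res.c_statistic == pytest.approx(conc / pairs, abs=1e-12)

    def test_no_comparable_pairs_is_error(self):
        ds = _dataset([5.0, 5.0], [1, 1], [0.1, 0.2])
        with pytest.raises(FitError, match="pairs"):
            concordance(ds, score=np.array([0.1, 0.2]), n_bootstrap=2, seed=0)

    def test_bootstrap_se_is_seeded(self):
        rng = np.random.default_rng(15)
        n = 100
        ds = _dataset(rng.exponential(10, n).clip(0.1, 79.9), rng.random(n) < 0.6,
                      rng.normal(size=n), cluster=[f"f{i//2}" for i in range(n)])
        fit = fit_weighted_cox(ds, strata=False, cluster=True)
        r1 = concordance(ds, fit=fit, n_bootstrap=40, seed=5)
        r2 = concordance(ds, fit=fit, n_bootstrap=40, seed=5)
        assert r1.bootstrap_se == r2.bootstrap_se > 0
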