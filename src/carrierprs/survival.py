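"""Weighted, stratified Cox models with family-clustered robust variance.

Model fitting is delegated to lifelines' partial-likelihood machinery
(Efron ties); this module owns the analysis contracts: sampling-weighted
retrospective fits, left-truncated prospective fits, the time-varying
PRS-by-age model via episode splitting, interaction/heterogeneity models,
categorical-percentile models, likelihood-ratio tests, and Harrell's
concordance with a cluster bootstrap.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import AnalysisDataset, CohortError, build_analysis_dataset
from .prs import PercentileScheme
from .risk import discretize_standard_normal

logger = logging.getLogger("carrierprs")

_FIT_OPTIONS = {"precision": 1e-09, "max_steps": 200}


class FitError(RuntimeError):
    pass


@dataclass
class CoxFitResult:
    """Log hazard ratios with robust (cluster-sandwich) uncertainty."""

    coefficients: pd.Series
    robust_covariance: pd.DataFrame
    naive_covariance: Optional[pd.DataFrame]
    loglik: float
    loglik_null: Optional[float]
    n: int
    n_events: int
    covariates: list[str]
    extras: dict = field(default_factory=dict)

    @property
    def se(self) -> pd.Series:
        return pd.Series(np.sqrt(np.diag(self.robust_covariance)),
                         index=self.coefficients.index)

    def hazard_ratio(self, term: str) -> float:
        return float(np.exp(self.coefficients[term]))

    def confidence_interval(self, term: str, level: float = 0.95) -> tuple[float, float]:
        zcrit = stats.norm.ppf(0.5 + level / 2)
        b, s = self.coefficients[term], self.se[term]
        return float(np.exp(b - zcrit * s)), float(np.exp(b + zcrit * s))

    def p_value(self, term: str) -> float:
        zstat = self.coefficients[term] / self.se[term]
        return float(2 * stats.norm.sf(abs(zstat)))

    def summary(self) -> pd.DataFrame:
        rows = []
        for term in self.coefficients.index:
            lo, hi = self.confidence_interval(term)
            rows.append({"term": term, "coef": self.coefficients[term],
                         "hr": self.hazard_ratio(term), "ci_low": lo,
                         "ci_high": hi, "se": self.se[term],
                         "p": self.p_value(term)})
        return pd.DataFrame(rows).set_index("term")


@dataclass
class ConcordanceResult:
    c_statistic: float
    bootstrap_se: float
    n_bootstrap: int
    n_pairs: int


def _score_residuals(x: np.ndarray, time: np.ndarray, event: np.ndarray,
                     weights: np.ndarray, entry: np.ndarray,
                     beta: np.ndarray) -> np.ndarray:
    """Weighted Cox score residuals within one stratum (Breslow-style risk
    sets, delayed entry honoured), ``w_i * integral (x_i - xbar(t)) dM_i``."""
    order = np.argsort(time, kind="stable")
    x, time, event, weights, entry = (x[order], time[order], event[order],
                                      weights[order], entry[order])
    n, d = x.shape
    r = np.exp(np.clip(x @ beta, -700, 700))
    wr = weights * r
    # S0/S1 at each subject's time: revcumsum over T minus entries >= t
    s0_T = np.cumsum(wr[::-1])[::-1]
    s1_T = np.cumsum((x * wr[:, None])[::-1], axis=0)[::-1]
    e_order = np.argsort(entry, kind="stable")
    e_sorted = entry[e_order]
    wr_e = np.cumsum(wr[e_order][::-1])[::-1]
    s1_e = np.cumsum((x * wr[:, None])[e_order][::-1], axis=0)[::-1]

    def risk_sums(t):
        """S0, S1 over subjects with entry < t <= T, vectorized over sorted t."""
        iT = np.searchsorted(time, t, side="left")
        s0 = np.where(iT < n, s0_T[np.minimum(iT, n - 1)], 0.0)
        s1 = np.where((iT < n)[:, None], s1_T[np.minimum(iT, n - 1)], 0.0)
        iE = np.searchsorted(e_sorted, t, side="left")
        s0 = s0 - np.where(iE < n, wr_e[np.minimum(iE, n - 1)], 0.0)
        s1 = s1 - np.where((iE < n)[:, None], s1_e[np.minimum(iE, n - 1)], 0.0)
        return s0, s1

    ev_idx = np.flatnonzero(event == 1)
    if len(ev_idx) == 0:
        return np.zeros_like(x)
    t_ev = np.unique(time[ev_idx])
    s0_ev, s1_ev = risk_sums(t_ev)
    xbar_ev = s1_ev / s0_ev[:, None]
    # weighted event mass per distinct event time
    wmass = np.zeros(len(t_ev))
    np.add.at(wmass, np.searchsorted(t_ev, time[ev_idx]), weights[ev_idx])
    a = wmass / s0_ev  # cumulative-hazard increments
    b = xbar_ev * a[:, None]
    A = np.concatenate([[0.0], np.cumsum(a)])
    B = np.vstack([np.zeros(d), np.cumsum(b, axis=0)])
    # window (entry_i, T_i]: event times with entry_i < t_k <= T_i
    hi = np.searchsorted(t_ev, time, side="right")
    lo = np.searchsorted(t_ev, entry, side="right")
    resid = -r[:, None] * (x * (A[hi] - A[lo])[:, None] - (B[hi] - B[lo]))
    pos = np.searchsorted(t_ev, time)
    is_event = event == 1
    resid[is_event] += x[is_event] - xbar_ev[pos[is_event]]
    resid *= weights[:, None]
    out = np.empty_like(resid)
    out[order] = resid
    return out


def cluster_robust_covariance(t: pd.DataFrame, covariates: Sequence[str],
                              beta: np.ndarray, naive_cov: np.ndarray,
                              strata: Optional[str], cluster: str,
                              weights_col: str = "sampling_weight",
                              entry_col: str = "entry_age",
                              duration_col: str = "exit_age",
                              event_col: str = "event") -> np.ndarray:
    """Family-clustered sandwich ``A^-1 (sum_g U_g U_g^T) A^-1`` with
    ``A^-1`` the naive (model-based) covariance and ``U_g`` the cluster-summed
    score residuals."""
    x = t[list(covariates)].to_numpy(float)
    resid = np.empty_like(x)
    groups = t.groupby(strata).indices.values() if strata else [np.arange(len(t))]
    for idx in groups:
        idx = np.asarray(idx)
        resid[idx] = _score_residuals(
            x[idx], t[duration_col].to_numpy(float)[idx],
            t[event_col].to_numpy(int)[idx],
            t[weights_col].to_numpy(float)[idx],
            t[entry_col].to_numpy(float)[idx], beta)
    dfbeta = resid @ naive_cov
    grouped = pd.DataFrame(dfbeta).groupby(t[cluster].to_numpy()).sum().to_numpy()
    return grouped.T @ grouped


def _lifelines_fit(df: pd.DataFrame, covariates: Sequence[str],
                   duration_col: str = "exit_age", event_col: str = "event",
                   entry_col: Optional[str] = None,
                   strata: Optional[str] = None,
                   weights_col: Optional[str] = None,
                   cluster_col: Optional[str] = None,
                   robust: bool = True):
    from lifelines import CoxPHFitter
    from lifelines.exceptions import ConvergenceError

    cols = list(covariates) + [duration_col, event_col]
    for extra in (entry_col, strata, weights_col, cluster_col):
        if extra:
            cols.append(extra)
    x = df[list(dict.fromkeys(cols))].copy()
    mat = x[list(covariates)].to_numpy(float)
    if np.linalg.matrix_rank(mat - mat.mean(axis=0)) < len(covariates):
        raise FitError(f"collinear covariates among {list(covariates)}")
    fitter = CoxPHFitter()
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fitter.fit(x, duration_col=duration_col, event_col=event_col,
                       entry_col=entry_col, strata=strata, weights_col=weights_col,
                       cluster_col=cluster_col, robust=robust,
                       fit_options=dict(_FIT_OPTIONS))
    except ConvergenceError as err:
        raise FitError(f"Cox partial likelihood did not converge: {err}") from err
    return fitter


def fit_weighted_cox(dataset: AnalysisDataset,
                     covariates: Optional[Sequence[str]] = None,
                     strata: bool = True, cluster: bool = True,
                     naive: bool = False, null_loglik: bool = False,
                     ) -> CoxFitResult:
    """Maximize the sampling-weighted stratified partial likelihood.

    Retrospective datasets enter the risk set at age 0 (age is the time
    scale); prospective datasets carry delayed entry at recruitment.  Robust
    covariance is the cluster sandwich over families, which also absorbs the
    extra variability induced by non-unit sampling weights.
    """
    covs = list(covariates) if covariates is not None else list(dataset.covariates)
    t = dataset.table
    if dataset.n_events == 0:
        raise FitError("no events in the analysis dataset")
    strat_col = "stratum" if strata else None
    if strata:
        per = t.groupby("stratum")["event"].sum()
        empty = per[per == 0]
        if len(empty):
            logger.info("dropping %d event-free strata", len(empty))
            t = t[~t["stratum"].isin(empty.index)]
    weights_col = "sampling_weight" if (t["sampling_weight"] != 1.0).any() else None
    entry_col = "entry_age" if (t["entry_age"] > 0).any() else None
    fitter = _lifelines_fit(t, covs, entry_col=entry_col, strata=strat_col,
                            weights_col=weights_col, robust=False)
    naive_cov = fitter.variance_matrix_.loc[covs, covs]
    if cluster:
        robust = cluster_robust_covariance(
            t, covs, fitter.params_.loc[covs].to_numpy(), naive_cov.to_numpy(),
            strata=strat_col, cluster="cluster")
        robust_cov = pd.DataFrame(robust, index=covs, columns=covs)
    else:
        robust_cov = naive_cov
    llnull = _null_loglik(fitter) if null_loglik else None
    return CoxFitResult(coefficients=fitter.params_.copy(),
                        robust_covariance=robust_cov,
                        naive_covariance=naive_cov,
                        loglik=float(fitter.log_likelihood_), loglik_null=llnull,
                        n=len(t), n_events=int(t["event"].sum()), covariates=covs)


def _null_loglik(fitter) -> float:
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = fitter.log_likelihood_ratio_test()
    return float(fitter.log_likelihood_ - res.test_statistic / 2.0)


def fit_prospective_cox(cohort, outcome: str,
                        covariates: Sequence[str] = ("prs_standardized",),
                        **kwargs) -> CoxFitResult:
    """Left-truncated (delayed-entry) unweighted Cox fit on the prospective
    follow-up period; carriers affected before recruitment are excluded."""
    ds = build_analysis_dataset(cohort, outcome, covariates=covariates,
                                prospective=True, **kwargs)
    if ds.n_events == 0:
        raise FitError("no incident events after recruitment")
    return fit_weighted_cox(ds)


# ---------------------------------------------------------------------------
# time-varying PRS


def split_episodes(dataset: AnalysisDataset, prs_col: str = "prs_standardized",
                   ) -> pd.DataFrame:
    """Episode-split rows at distinct event ages (counting-process form).

    Each subject contributes one row per event age inside (entry, exit]; the
    PRS-by-age covariate evaluated at the episode's stop age equals its value
    in the risk set at that age, so the split fit is the exact risk-set
    evaluation of a time-varying ``z * age`` covariate.
    """
    t = dataset.table
    event_ages = np.unique(t.loc[t["event"] == 1, "exit_age"].to_numpy(float))
    entry = t["entry_age"].to_numpy(float)
    exit_ = t["exit_age"].to_numpy(float)
    lo = np.searchsorted(event_ages, entry, side="right")
    hi = np.searchsorted(event_ages, exit_, side="left")  # cuts strictly inside
    counts = hi - lo + 1
    idx = np.repeat(np.arange(len(t)), counts)
    pos = np.concatenate([np.arange(lo[i], lo[i] + counts[i]) for i in range(len(t))])
    stop = np.where(pos < hi[idx], event_ages[np.minimum(pos, len(event_ages) - 1)],
                    exit_[idx])
    is_last = pos == hi[idx]
    start = np.empty_like(stop)
    first = np.concatenate([[True], idx[1:] != idx[:-1]])
    start[first] = entry[idx[first]]
    start[~first] = stop[np.flatnonzero(~first) - 1]
    out = t.iloc[idx].copy().reset_index(drop=True)
    out["entry_age"] = start
    out["exit_age"] = stop
    out["event"] = np.where(is_last, t["event"].to_numpy(int)[idx], 0)
    out["prs_by_age"] = out[prs_col].to_numpy(float) * stop
    return out


def fit_time_varying_prs(dataset: AnalysisDataset,
                         prs_col: str = "prs_standardized",
                         extra_covariates: Sequence[str] = (),
                         strata: bool = True, cluster: bool = True,
                         ) -> CoxFitResult:
    """PRS main effect plus a per-year PRS-by-age interaction.

    The main-effect hazard ratio applies at age zero and decays (for a
    negative interaction) by the interaction hazard ratio per year of age,
    mirroring an age-in-years interaction fitted without centering.
    """
    split = split_episodes(dataset, prs_col=prs_col)
    ds2 = AnalysisDataset(table=split, outcome=dataset.outcome,
                          covariates=[prs_col, "prs_by_age", *extra_covariates],
                          prospective=True)  # entry/stop form
    t = ds2.table
    weights_col = "sampling_weight" if (t["sampling_weight"] != 1.0).any() else None
    strat_col = "stratum" if strata else None
    fitter = _lifelines_fit(t, ds2.covariates, entry_col="entry_age",
                            strata=strat_col, weights_col=weights_col,
                            robust=False)
    covs = ds2.covariates
    naive_cov = fitter.variance_matrix_.loc[covs, covs]
    if cluster:
        # episodes of one carrier share a family id, so the cluster sandwich
        # also absorbs the episode-splitting
        robust = cluster_robust_covariance(
            t, covs, fitter.params_.loc[covs].to_numpy(), naive_cov.to_numpy(),
            strata=strat_col, cluster="cluster")
        robust_cov = pd.DataFrame(robust, index=covs, columns=covs)
    else:
        robust_cov = naive_cov
    return CoxFitResult(coefficients=fitter.params_.copy(),
                        robust_covariance=robust_cov,
                        naive_covariance=naive_cov,
                        loglik=float(fitter.log_likelihood_), loglik_null=None,
                        n=dataset.table.shape[0], n_events=dataset.n_events,
                        covariates=covs)


# ---------------------------------------------------------------------------
# model comparison


def _lrt(ll_nested: float, ll_full: float, df: int) -> tuple[float, int, float]:
    stat = max(0.0, 2.0 * (ll_full - ll_nested))
    if df == 0:
        return stat, 0, 1.0
    return stat, df, float(stats.chi2.sf(stat, df))


def likelihood_ratio_test(nested: CoxFitResult, full: CoxFitResult,
                          df: Optional[int] = None) -> tuple[float, int, float]:
    """2*(l_full - l_nested) against a chi-square on the extra parameters.

    The covariates of ``nested`` must be a subset of ``full``'s unless the
    nesting is a reparametrization, in which case pass ``df`` explicitly.
    With non-unit sampling weights the statistic is computed from the
    weighted log likelihood and the chi-square reference is approximate (a
    caveat is logged).
    """
    if df is None:
        if not set(nested.covariates) <= set(full.covariates):
            raise FitError("models are not nested: "
                           f"{nested.covariates} vs {full.covariates}")
        df = len(full.covariates) - len(nested.covariates)
    logger.debug("LRT on weighted likelihood: chi-square reference approximate")
    return _lrt(nested.loglik, full.loglik, df)


def interaction_models(dataset: AnalysisDataset, group_col: str,
                       prs_col: str = "prs_standardized",
                       extra_covariates: Sequence[str] = (),
                       ) -> dict:
    """Group-specific per-SD hazard ratios plus a heterogeneity LRT.

    Fits a model with one PRS slope per group (and group main effects),
    compares it with the common-slope model by LRT, and returns a Wald p for
    the pairwise slope difference when exactly two groups are present.
    """
    t = dataset.table.copy()
    groups = sorted(t[group_col].dropna().unique())
    if len(groups) < 2:
        raise FitError(f"need at least two groups in {group_col!r}, got {groups}")
    per_events = t.groupby(group_col)["event"].sum()
    if (per_events == 0).any():
        raise FitError(f"groups without events: "
                       f"{per_events[per_events == 0].index.tolist()}")
    slope_cols, main_cols = [], []
    for g in groups:
        ind = (t[group_col] == g).astype(float)
        t[f"prs_x_{g}"] = ind * t[prs_col]
        slope_cols.append(f"prs_x_{g}")
        if g != groups[0]:
            t[f"grp_{g}"] = ind
            main_cols.append(f"grp_{g}")
    ds_full = AnalysisDataset(table=t, outcome=dataset.outcome,
                              covariates=slope_cols + main_cols + list(extra_covariates),
                              prospective=dataset.prospective)
    full = fit_weighted_cox(ds_full)
    ds_common = AnalysisDataset(table=t, outcome=dataset.outcome,
                                covariates=[prs_col] + main_cols + list(extra_covariates),
                                prospective=dataset.prospective)
    common = fit_weighted_cox(ds_common)
    # the common-slope model is nested by reparametrization (equal slopes)
    stat, df, p_lrt = likelihood_ratio_test(common, full, df=len(groups) - 1)
    result = {"groups": groups,
              "per_group": full.summary().loc[slope_cols],
              "fit_full": full, "fit_common": common,
              "lrt": {"statistic": stat, "df": df, "p": p_lrt}}
    if len(groups) == 2:
        a, b = slope_cols
        diff = full.coefficients[a] - full.coefficients[b]
        var = (full.robust_covariance.loc[a, a] + full.robust_covariance.loc[b, b]
               - 2 * full.robust_covariance.loc[a, b])
        zstat = diff / np.sqrt(var)
        result["p_difference"] = float(2 * stats.norm.sf(abs(zstat)))
    return result


def categorical_percentile_fit(dataset: AnalysisDataset, labels: np.ndarray,
                               scheme: PercentileScheme,
                               prs_col: str = "prs_standardized",
                               extra_covariates: Sequence[str] = (),
                               ) -> dict:
    """Per-percentile-bin hazard ratios versus the reference (40-60) bin.

    Also returns the hazard ratios expected at each bin under the continuous
    per-SD fit, ``exp(beta * E[z | bin])`` for a standard-normal score, and
    an LRT asking whether the bin indicators add to the continuous model.
    """
    t = dataset.table.copy()
    if len(labels) != len(t):
        raise FitError("labels length does not match the dataset")
    labels = np.asarray(labels)
    ref = scheme.reference_bin
    if not (t.loc[labels == ref, "event"].sum() > 0):
        raise FitError("reference percentile bin has no events")
    counts = np.bincount(labels, minlength=scheme.n_categories)
    merged = labels.copy()
    for k in np.where(counts == 0)[0]:
        neighbor = k - 1 if k > 0 else k + 1
        logger.warning("empty percentile bin %d collapsed into %d", k, neighbor)
        merged[merged == k] = neighbor
    ind_cols = []
    for k in range(scheme.n_categories):
        if k == ref or (merged == k).sum() == 0:
            continue
        col = f"prs_bin_{k}"
        t[col] = (merged == k).astype(float)
        ind_cols.append(col)
    ds_cat = AnalysisDataset(table=t, outcome=dataset.outcome,
                             covariates=ind_cols + list(extra_covariates),
                             prospective=dataset.prospective)
    cat_fit = fit_weighted_cox(ds_cat)
    ds_cont = AnalysisDataset(table=t, outcome=dataset.outcome,
                              covariates=[prs_col] + list(extra_covariates),
                              prospective=dataset.prospective)
    cont_fit = fit_weighted_cox(ds_cont)
    ds_both = AnalysisDataset(table=t, outcome=dataset.outcome,
                              covariates=[prs_col] + ind_cols + list(extra_covariates),
                              prospective=dataset.prospective)
    both_fit = fit_weighted_cox(ds_both)
    stat, df, p_lrt = likelihood_ratio_test(cont_fit, both_fit)
    mix = discretize_standard_normal(scheme.bin_edges)
    beta = float(cont_fit.coefficients[prs_col])
    expected_hr = np.exp(beta * (mix.z - mix.z[ref]))
    return {"fit": cat_fit, "fit_continuous": cont_fit,
            "expected_hr_continuous": pd.Series(expected_hr, index=scheme.labels()),
            "lrt_vs_continuous": {"statistic": stat, "df": df, "p": p_lrt}}


# ---------------------------------------------------------------------------
# concordance


def _pair_counts(time: np.ndarray, event: np.ndarray, score: np.ndarray,
                 ) -> tuple[float, float]:
    """Concordant (ties count half) and comparable pair counts, by exhaustive
    enumeration over usable pairs (event before a later exit)."""
    conc = 0.0
    npairs = 0.0
    order = np.argsort(time, kind="stable")
    time, event, score = time[order], event[order], score[order]
    n = len(time)
    for i in range(n):
        if not event[i]:
            continue
        later = (time > time[i]) | ((time == time[i]) & (event == 0))
        later[i] = False
        npairs += later.sum()
        conc += (score[i] > score[later]).sum() + 0.5 * (score[i] == score[later]).sum()
    return conc, npairs


def concordance(dataset: AnalysisDataset, fit: Optional[CoxFitResult] = None,
                score: Optional[np.ndarray] = None, n_bootstrap: int = 1000,
                seed: int = 0, stratified: bool = True) -> ConcordanceResult:
    """Harrell's C of the linear predictor, pooled over strata.

    Pairs are formed within strata (an event versus any subject exiting
    later) and pooled by summing concordant and comparable counts; the
    standard error comes from a seeded bootstrap over family clusters.
    """
    t = dataset.table
    if score is None:
        if fit is None:
            raise FitError("provide a fitted model or a score vector")
        score = t[fit.covariates].to_numpy(float) @ fit.coefficients.to_numpy()
    score = np.asarray(score, float)
    strata = t["stratum"].to_numpy() if stratified else np.zeros(len(t))
    time = t["exit_age"].to_numpy(float)
    event = t["event"].to_numpy(int)

    def pooled_c(mask_idx) -> tuple[float, float]:
        conc = npairs = 0.0
        s_, tt, ee, sc = (strata[mask_idx], time[mask_idx], event[mask_idx],
                          score[mask_idx])
        for s in np.unique(s_):
            m = s_ == s
            c, npr = _pair_counts(tt[m], ee[m], sc[m])
            conc += c
            npairs += npr
        return conc, npairs

    all_idx = np.arange(len(t))
    conc, npairs = pooled_c(all_idx)
    if npairs == 0:
        raise FitError("no comparable pairs for concordance")
    cstat = conc / npairs

    clusters = t["cluster"].to_numpy()
    uniq = np.unique(clusters)
    members = {c: np.flatnonzero(clusters == c) for c in uniq}
    rng = np.random.default_rng(seed)
    boots = []
    for _ in range(n_bootstrap):
        chosen = rng.choice(uniq, size=len(uniq), replace=True)
        idx = np.concatenate([members[c] for c in chosen])
        c, npr = pooled_c(idx)
        if npr > 0:
            boots.append(c / npr)
    se = float(np.std(boots, ddof=1)) if len(boots) > 1 else float("nan")
    return ConcordanceResult(c_statistic=float(cstat), bootstrap_se=se,
                             n_bootstrap=len(boots), n_pairs=int(npairs))
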