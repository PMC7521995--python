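"""Config-driven orchestration: retrospective and prospective association
tables and percentile-specific absolute-risk tables, written as tidy CSV
with a seed/config-hash provenance header."""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import cohort as _cohort
from . import risk as _risk
from . import simulate as _simulate
from . import survival as _survival
from .prs import DEFAULT_PERCENTILE_EDGES, DEFAULT_REFERENCE_BIN, PrsVector, assign_percentiles

logger = logging.getLogger("carrierprs")


@dataclass
class RunConfig:
    """What to run and where; loadable from YAML."""

    outdir: str = "out"
    seed: int = 0
    cohort_csv: Optional[str] = None
    incidence_csv: Optional[str] = None
    outcomes: Sequence[str] = ("breast",)
    covariates: Sequence[str] = ("prs_standardized",)
    percentile_edges: Sequence[float] = DEFAULT_PERCENTILE_EDGES
    n_bootstrap: int = 200
    weight_bin_width: float = 5.0
    hr_by_outcome: dict = field(default_factory=dict)  # for risk prediction
    risk_percentiles: Sequence[float] = (5, 10, 25, 50, 75, 90, 95)
    simulate: Optional[dict] = None  # SimulationConfig overrides

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def digest(self) -> str:
        payload = {k: v for k, v in asdict(self).items() if k != "outdir"}
        blob = json.dumps(payload, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


def _write(df: pd.DataFrame, path: Path, config: RunConfig) -> Path:
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(f"# seed={config.seed} config={config.digest()}\n")
        df.to_csv(fh, index=False)
    return path


def _load_inputs(config: RunConfig):
    if config.cohort_csv:
        cohort = _cohort.read_cohort_csv(config.cohort_csv)
        curve = (_risk.IncidenceCurve.from_csv(config.incidence_csv)
                 if config.incidence_csv else None)
        return cohort, curve
    if config.simulate is None:
        raise ValueError("config needs either cohort_csv or a simulate section")
    params = dict(config.simulate)
    target = params.pop("incidence_cumulative_risk", 0.72)
    shape = params.pop("incidence_shape", None) or params.get("outcome", "breast")
    curve = _simulate.make_incidence_fixture(target, shape=shape)
    cfg = _simulate.SimulationConfig(incidence=curve, seed=config.seed, **params)
    cohort, truth = _simulate.simulate_retrospective_cohort(cfg)
    logger.info("simulated cohort: %s", truth)
    return cohort, curve


def run_retrospective(config: RunConfig) -> dict[str, Path]:
    """Per-outcome continuous, FH-adjusted, categorical-percentile and
    age-varying PRS association tables, plus concordance."""
    outdir = Path(config.outdir)
    cohort, curve = _load_inputs(config)
    rows, cat_rows, tv_rows, c_rows = [], [], [], []
    for outcome in config.outcomes:
        ds = _cohort.build_analysis_dataset(cohort, outcome,
                                            covariates=config.covariates)
        if curve is not None:
            _, ds = _cohort.calibrate_sampling_weights(ds, curve)
        for adjusted in (False, True):
            ds_a = _cohort.build_analysis_dataset(
                cohort, outcome, covariates=config.covariates,
                include_family_history=adjusted)
            ds_a.table["sampling_weight"] = ds.table["sampling_weight"].to_numpy()
            fit = _survival.fit_weighted_cox(ds_a)
            summ = fit.summary().loc["prs_standardized"]
            rows.append({"outcome": outcome,
                         "adjustment": "FH adjusted" if adjusted else "No FH adjustment",
                         "n_unaffected": len(ds_a) - fit.n_events,
                         "n_affected": fit.n_events, "hr": summ["hr"],
                         "ci_low": summ["ci_low"], "ci_high": summ["ci_high"],
                         "p": summ["p"]})
        # categorical percentiles, reference thresholds from unaffected carriers
        prs = PrsVector(carrier_ids=ds.table["carrier_id"].tolist(),
                        raw=ds.table["prs_standardized"].to_numpy(),
                        standardized=ds.table["prs_standardized"].to_numpy())
        unaffected = ds.table.loc[ds.table["event"] == 0, "carrier_id"].tolist()
        scheme, labels = assign_percentiles(prs, unaffected,
                                            config.percentile_edges,
                                            DEFAULT_REFERENCE_BIN)
        cat = _survival.categorical_percentile_fit(ds, labels, scheme)
        for term, row in cat["fit"].summary().iterrows():
            cat_rows.append({"outcome": outcome, "term": term, **row.to_dict()})
        tv = _survival.fit_time_varying_prs(ds)
        for term in ("prs_standardized", "prs_by_age"):
            lo, hi = tv.confidence_interval(term)
            tv_rows.append({"outcome": outcome, "term": term,
                            "hr": tv.hazard_ratio(term), "ci_low": lo,
                            "ci_high": hi, "p": tv.p_value(term)})
        fit_cont = _survival.fit_weighted_cox(ds)
        conc = _survival.concordance(ds, fit=fit_cont,
                                     n_bootstrap=config.n_bootstrap,
                                     seed=config.seed)
        c_rows.append({"outcome": outcome, "c_statistic": conc.c_statistic,
                       "bootstrap_se": conc.bootstrap_se,
                       "n_bootstrap": conc.n_bootstrap})
    return {
        "associations": _write(pd.DataFrame(rows), outdir / "retrospective_associations.csv", config),
        "categorical": _write(pd.DataFrame(cat_rows), outdir / "retrospective_percentile_categories.csv", config),
        "age_varying": _write(pd.DataFrame(tv_rows), outdir / "retrospective_age_varying.csv", config),
        "concordance": _write(pd.DataFrame(c_rows), outdir / "retrospective_concordance.csv", config),
    }


def run_prospective(config: RunConfig) -> dict[str, Path]:
    """Incident-event association table on the prospective follow-up period."""
    outdir = Path(config.outdir)
    if config.cohort_csv:
        cohort = _cohort.read_cohort_csv(config.cohort_csv)
    else:
        params = dict(config.simulate or {})
        target = params.pop("incidence_cumulative_risk", 0.72)
        shape = params.pop("incidence_shape", None) or params.get("outcome", "breast")
        curve = _simulate.make_incidence_fixture(target, shape=shape)
        cfg = _simulate.SimulationConfig(incidence=curve, seed=config.seed, **params)
        cohort, _ = _simulate.simulate_prospective_cohort(cfg)
    rows = []
    for outcome in config.outcomes:
        fit = _survival.fit_prospective_cox(cohort, outcome,
                                            covariates=config.covariates)
        summ = fit.summary().loc["prs_standardized"]
        if fit.n_events == 0:
            raise _survival.FitError(f"no incident {outcome} events")
        rows.append({"outcome": outcome, "n_at_risk": fit.n,
                     "incident_cancers": fit.n_events, "hr": summ["hr"],
                     "ci_low": summ["ci_low"], "ci_high": summ["ci_high"],
                     "p": summ["p"]})
    return {"prospective": _write(pd.DataFrame(rows),
                                  outdir / "prospective_associations.csv", config)}


def run_risk_prediction(config: RunConfig,
                        incidence_by_outcome: Optional[dict] = None,
                        ) -> dict[str, Path]:
    """Percentile-specific cumulative and 10-year risks from per-SD HRs and
    average carrier incidence curves."""
    outdir = Path(config.outdir)
    if incidence_by_outcome is None:
        incidence_by_outcome = {}
        sim = dict(config.simulate or {})
        for outcome, spec in (config.hr_by_outcome or {"breast": {"hr": 1.29}}).items():
            target = spec.get("cumulative_risk", sim.get("incidence_cumulative_risk", 0.72))
            shape = "ovarian" if outcome == "ovarian" else "breast"
            incidence_by_outcome[outcome] = _simulate.make_incidence_fixture(
                target, shape=shape)
    risk_rows, ten_rows = [], []
    for outcome, curve in incidence_by_outcome.items():
        spec = (config.hr_by_outcome or {}).get(outcome, {"hr": 1.29})
        loghr = _risk.AgeVaryingLogHR(np.log(spec["hr"]),
                                      np.log(spec.get("hr_per_year", 1.0)))
        surface = _risk.solve_constrained_hazard(curve, loghr)
        avg = surface.mixture_average_risk
        for pct in config.risk_percentiles:
            fcurve = _risk.risk_by_percentile(surface, [pct])[:, 0]
            for i, age in enumerate(surface.ages):
                risk_rows.append({"outcome": outcome, "percentile": pct,
                                  "age": age, "cumulative_risk": fcurve[i],
                                  "mixture_average_risk": avg[i]})
            for age in range(int(surface.ages[0]), int(surface.ages[-1]) - 9, 5):
                ten_rows.append({"outcome": outcome, "percentile": pct, "age": age,
                                 "ten_year_risk": _risk.ten_year_risk(surface, pct, age)})
    return {
        "risks": _write(pd.DataFrame(risk_rows), outdir / "predicted_risks.csv", config),
        "ten_year": _write(pd.DataFrame(ten_rows), outdir / "ten_year_risks.csv", config),
    }
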