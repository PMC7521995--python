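"""Synthetic carrier cohorts, genotypes, and incidence fixtures.

Generates data with the statistical structure the analysis assumes —
standard-normal standardized PRS with first-degree-relative correlation
0.5, proportional-hazards (optionally age-varying) PRS effects on an
age-as-time-scale hazard, competing censoring by risk-reducing surgery and
end of follow-up, ER-status missingness, and clinic-style ascertainment in
which affected carriers are oversampled — so every analysis stage can be
exercised and parameter recovery verified without any data download.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np
import pandas as pd

from .prs import DosageMatrix, WeightTable, PrsValidationError
from .risk import (AgeVaryingLogHR, IncidenceCurve, RiskModelError,
                   equal_probability_mixture, solve_constrained_hazard)

logger = logging.getLogger("carrierprs")


class SimulationError(ValueError):
    pass


@dataclass
class SimulationConfig:
    """Stated world for a synthetic carrier cohort.

    The defaults describe a clinic-ascertained retrospective cohort: 50%
    affected after oversampling, follow-up ending around the sixth decade,
    modest risk-reducing surgery uptake, and a substantial fraction of
    missing tumor ER status.
    """

    n_carriers: int = 10_000
    gene: str = "BRCA1"
    outcome: str = "breast"  # breast | ovarian
    beta0: float = np.log(1.29)
    beta1: float = 0.0  # per-year change in the per-SD log HR
    reference_age: float = 0.0
    incidence: Optional[IncidenceCurve] = None  # population average for carriers
    target_affected_fraction: Optional[float] = 0.5  # None = no ascertainment
    family_size_probs: tuple = (0.7, 0.2, 0.1)  # P(singleton, sib-pair, trio)
    family_prs_correlation: float = 0.5
    surgery_rate: float = 0.008  # mastectomy (breast) / RRSO (ovarian) hazard /yr
    surgery_min_age: float = 25.0
    competing_cancer_rate: float = 0.002  # the other cancer, censoring /yr
    followup_mean: float = 55.0
    followup_sd: float = 12.0
    recruit_mean: float = 42.0
    recruit_sd: float = 10.0
    er_positive_fraction: float = 0.35
    er_missing_fraction: float = 0.30
    birth_year_range: tuple = (1930, 1990)
    n_countries: int = 5
    ashkenazi_fraction: float = 0.05
    age_start: float = 18.0
    round_ages: bool = True  # record ages in whole years, as real cohorts do
    age_end: float = 80.0
    seed: int = 0

    def truth(self) -> dict:
        d = {k: v for k, v in asdict(self).items() if k != "incidence"}
        if self.incidence is not None:
            d["incidence_label"] = self.incidence.label
            d["incidence_cumulative_risk_80"] = self.incidence.cumulative_risk(80.0)
        return d


# ---------------------------------------------------------------------------
# incidence fixtures

_SHAPES = {
    # relative hazard levels on 5-year bins 18-25-30-...-80 (13 bins);
    # breast risk rises steeply through the 30s and 40s then plateaus,
    # ovarian risk starts later and keeps rising
    "breast": np.array([0.10, 0.35, 0.80, 1.00, 1.10, 1.10, 1.05, 1.00,
                        0.95, 0.90, 0.85, 0.80]),
    "ovarian": np.array([0.02, 0.05, 0.15, 0.35, 0.60, 0.85, 1.00, 1.05,
                         1.05, 1.00, 0.95, 0.90]),
    "flat": np.ones(12),
}
_SHAPE_EDGES = np.array([18.0, 25, 30, 35, 40, 45, 50, 55, 60, 65, 70, 75, 80])


def make_incidence_fixture(cumulative_target: float, shape: str = "breast",
                           label: str = "") -> IncidenceCurve:
    """Piecewise-constant incidence whose cumulative risk at 80 equals the
    target (e.g. 0.72 for the average carrier breast-cancer risk)."""
    if not 0 < cumulative_target < 1:
        raise SimulationError(
            f"cumulative target must lie in (0,1), got {cumulative_target}")
    if shape not in _SHAPES:
        raise SimulationError(f"unknown shape {shape!r}; options {sorted(_SHAPES)}")
    rel = _SHAPES[shape]
    widths = np.diff(_SHAPE_EDGES)
    total = -np.log1p(-cumulative_target)
    scale = total / float(rel @ widths)
    return IncidenceCurve(_SHAPE_EDGES[:-1], _SHAPE_EDGES[1:], scale * rel,
                          label=label or f"{shape}:{cumulative_target:g}")


# ---------------------------------------------------------------------------
# genotypes


def simulate_genotypes(weights: WeightTable, n: int, seed: int = 0) -> DosageMatrix:
    """Hardy-Weinberg genotypes at the weight table's allele frequencies."""
    freqs = weights.frequencies
    if np.isnan(freqs).any():
        missing = [v for v, f in zip(weights.variant_ids, freqs) if np.isnan(f)]
        raise PrsValidationError(
            f"weight table lacks allele frequencies for {missing[:10]}")
    rng = np.random.default_rng(seed)
    dosages = rng.binomial(2, freqs, size=(n, len(freqs))).astype(float)
    return DosageMatrix(carrier_ids=[f"S{i:06d}" for i in range(n)],
                        variant_ids=list(weights.variant_ids), dosages=dosages,
                        counted_allele=list(weights.table["effect_allele"]),
                        other_allele=list(weights.table["other_allele"]))


# ---------------------------------------------------------------------------
# cohorts


def _family_prs(rng, n_families: int, sizes: np.ndarray, rho: float) -> np.ndarray:
    """Member scores with pairwise within-family correlation ``rho``:
    z = sqrt(rho)*family + sqrt(1-rho)*individual."""
    fam = np.repeat(rng.standard_normal(n_families), sizes)
    ind = rng.standard_normal(sizes.sum())
    return np.sqrt(rho) * fam + np.sqrt(1 - rho) * ind


def _event_ages(rng, z: np.ndarray, cfg: SimulationConfig,
                deltas: np.ndarray, ages: np.ndarray) -> np.ndarray:
    """Disease ages by inversion of the cumulative hazard
    ``H_z(t) = sum_u delta_u exp(beta(u) z)`` with the person's position
    inside the failure year interpolated (hazard constant within the year).
    Returns inf when no event occurs by the grid end."""
    beta_t = cfg.beta0 + cfg.beta1 * (ages[:-1] - cfg.reference_age)
    loghaz = np.outer(z, beta_t)  # n x T
    np.clip(loghaz, -700, 700, out=loghaz)
    haz = np.exp(loghaz) * deltas  # per-year integrated hazard
    cum = np.cumsum(haz, axis=1)
    e = rng.exponential(size=len(z))
    idx = (cum < e[:, None]).sum(axis=1)  # first year index where cum >= e
    out = np.full(len(z), np.inf)
    hit = idx < len(deltas)
    prev = np.where(idx == 0, 0.0, cum[np.arange(len(z)), np.maximum(idx - 1, 0)])
    frac = np.divide(e - prev, haz[np.arange(len(z)), np.minimum(idx, len(deltas) - 1)],
                     out=np.ones(len(z)), where=hit)
    out[hit] = ages[0] + idx[hit] + np.clip(frac[hit], 0, 1)
    return out


def _simulate_pool(cfg: SimulationConfig, rng, n_pool: int,
                   id_offset: int = 0) -> pd.DataFrame:
    """Unascertained carrier pool with observed event/censoring ages."""
    if cfg.incidence is None:
        raise SimulationError("config.incidence is required")
    if cfg.outcome not in ("breast", "ovarian"):
        raise SimulationError(f"outcome must be breast or ovarian, got {cfg.outcome}")
    mean_size = np.average([1, 2, 3], weights=cfg.family_size_probs)
    n_fam = int(np.ceil(n_pool / mean_size)) + 1
    sizes = rng.choice([1, 2, 3], size=n_fam, p=cfg.family_size_probs)
    n = int(sizes.sum())
    fam_ids = np.repeat(np.arange(n_fam), sizes)
    z = _family_prs(rng, n_fam, sizes, cfg.family_prs_correlation)

    # baseline consistent with the average incidence under the PRS mixture
    loghr = AgeVaryingLogHR(cfg.beta0, cfg.beta1, cfg.reference_age)
    surface = solve_constrained_hazard(cfg.incidence, loghr,
                                       equal_probability_mixture(201),
                                       age_start=cfg.age_start, age_end=cfg.age_end)
    t_disease = _event_ages(rng, z, cfg, surface.baseline_increments, surface.ages)

    t_surgery = cfg.surgery_min_age + rng.exponential(
        1.0 / cfg.surgery_rate, size=n) if cfg.surgery_rate > 0 else np.full(n, np.inf)
    t_other = (cfg.age_start + rng.exponential(1.0 / cfg.competing_cancer_rate, size=n)
               if cfg.competing_cancer_rate > 0 else np.full(n, np.inf))
    t_fu = np.clip(rng.normal(cfg.followup_mean, cfg.followup_sd, size=n),
                   cfg.age_start + 1.0, cfg.age_end)

    t_end = np.minimum.reduce([t_disease, t_surgery, t_other, t_fu])
    disease_first = t_disease <= t_end
    surgery_first = (t_surgery <= t_end) & ~disease_first
    other_first = (t_other <= t_end) & ~disease_first & ~surgery_first

    df = pd.DataFrame({
        "carrier_id": [f"C{id_offset + i:08d}" for i in range(n)],
        "family_id": [f"F{id_offset + int(f):08d}" for f in fam_ids],
        "gene": cfg.gene,
        "birth_year": rng.integers(*cfg.birth_year_range, size=n),
        "country": rng.integers(0, cfg.n_countries, size=n).astype(str),
        "ashkenazi": rng.random(n) < cfg.ashkenazi_fraction,
        "age_recruit": np.clip(rng.normal(cfg.recruit_mean, cfg.recruit_sd, size=n),
                               18.0, 75.0),
        "age_last_followup": t_fu,
        "prs_standardized": z,
        "fh_breast": rng.choice([0, 1, 2], size=n, p=[0.6, 0.3, 0.1]),
        "fh_ovarian": rng.choice([0, 1, 2], size=n, p=[0.8, 0.15, 0.05]),
        "variant_class": rng.choice(["I", "II", "unknown"], size=n,
                                    p=[0.65, 0.25, 0.10]),
        "variant_location_group": rng.choice(["5prime", "central", "3prime"], size=n),
        "pc1": rng.normal(0, 1, n), "pc2": rng.normal(0, 1, n),
        "pc3": rng.normal(0, 1, n), "pc4": rng.normal(0, 1, n),
    })
    disease_age = np.where(disease_first, t_disease, np.nan)
    other_age = np.where(other_first, t_other, np.nan)
    surgery_age = np.where(surgery_first, t_surgery, np.nan)
    if cfg.outcome == "breast":
        df["age_bc"] = disease_age
        df["age_oc"] = other_age
        df["age_mastectomy"] = surgery_age
        df["age_rrso"] = np.nan
    else:
        df["age_oc"] = disease_age
        df["age_bc"] = other_age
        df["age_rrso"] = surgery_age
        df["age_mastectomy"] = np.nan
    # follow-up always extends to the end of observation
    df["age_last_followup"] = np.maximum(t_fu, t_end)

    er = np.full(n, None, dtype=object)
    bc_mask = df["age_bc"].notna().to_numpy()
    u = rng.random(n)
    pos = rng.random(n) < cfg.er_positive_fraction
    er_known = bc_mask & (u >= cfg.er_missing_fraction)
    er[er_known & pos] = "positive"
    er[er_known & ~pos] = "negative"
    df["er_status"] = er
    df["affected"] = disease_first
    if cfg.round_ages:
        # year-recorded ages, producing the heavy ties typical of real cohorts;
        # rounding is monotone so event/censoring order is preserved
        for col in ("age_bc", "age_oc", "age_mastectomy", "age_rrso",
                    "age_last_followup", "age_recruit"):
            df[col] = np.round(df[col].astype(float))
    return df


def _ascertain(df: pd.DataFrame, cfg: SimulationConfig, rng) -> pd.DataFrame:
    """Two-phase sampling of families by proband disease status until the
    proband affected fraction reaches the target."""
    if cfg.target_affected_fraction is None:
        out = df.iloc[:cfg.n_carriers]
        return out.drop(columns=["affected"]).reset_index(drop=True)
    f = cfg.target_affected_fraction
    if not 0 < f < 1:
        raise SimulationError("target affected fraction must be in (0,1)")
    proband = df.groupby("family_id", sort=False).head(1)
    aff_fams = proband.loc[proband["affected"], "family_id"].to_numpy()
    unaff_fams = proband.loc[~proband["affected"], "family_id"].to_numpy()
    mean_size = len(df) / df["family_id"].nunique()
    n_fam_total = int(np.ceil(cfg.n_carriers / mean_size))
    n_aff = int(round(f * n_fam_total))
    n_unaff = n_fam_total - n_aff
    if n_aff > len(aff_fams) or n_unaff > len(unaff_fams):
        raise SimulationError(
            f"cannot reach affected fraction {f}: pool has {len(aff_fams)} affected "
            f"and {len(unaff_fams)} unaffected proband families")
    chosen = np.concatenate([rng.choice(aff_fams, n_aff, replace=False),
                             rng.choice(unaff_fams, n_unaff, replace=False)])
    out = df[df["family_id"].isin(set(chosen))]
    achieved = out["affected"].mean()
    logger.info("ascertained %d carriers, affected fraction %.3f (target %.3f)",
                len(out), achieved, f)
    return out.drop(columns=["affected"]).reset_index(drop=True)


def simulate_retrospective_cohort(cfg: SimulationConfig,
                                  ) -> tuple[pd.DataFrame, dict]:
    """Ascertained retrospective carrier cohort plus the generating truth.

    The unascertained pool is grown in rounds until it contains enough
    affected and unaffected proband families to meet the target affected
    fraction at the requested cohort size.
    """
    rng = np.random.default_rng(cfg.seed)
    if cfg.target_affected_fraction is None:
        pool = _simulate_pool(cfg, rng, cfg.n_carriers)
        cohort = _ascertain(pool, cfg, rng)
        return cohort, _finish_truth(cfg, cohort)
    f = cfg.target_affected_fraction
    if not 0 < f < 1:
        raise SimulationError("target affected fraction must be in (0,1)")
    chunks: list[pd.DataFrame] = []
    offset = 0
    mean_size = np.average([1, 2, 3], weights=cfg.family_size_probs)
    n_fam_total = int(np.ceil(cfg.n_carriers / mean_size))
    need_aff = int(round(f * n_fam_total))
    need_unaff = n_fam_total - need_aff
    for round_ in range(30):
        n_pool = max(cfg.n_carriers, 2 * cfg.n_carriers if round_ else 3 * cfg.n_carriers)
        chunks.append(_simulate_pool(cfg, rng, n_pool, id_offset=offset))
        offset += len(chunks[-1]) + 1
        pool = pd.concat(chunks, ignore_index=True) if len(chunks) > 1 else chunks[0]
        proband = pool.groupby("family_id", sort=False).head(1)
        if (proband["affected"].sum() >= need_aff
                and (~proband["affected"]).sum() >= need_unaff):
            break
    else:
        raise SimulationError(
            f"cannot reach affected fraction {f} after {offset} simulated carriers; "
            "the outcome may be too rare for this target")
    cohort = _ascertain(pool, cfg, rng)
    return cohort, _finish_truth(cfg, cohort)


def _finish_truth(cfg: SimulationConfig, cohort) -> dict:
    truth = cfg.truth()
    if cohort is not None:
        truth["n_generated"] = len(cohort)
        truth["affected_fraction"] = float(
            cohort["age_bc" if cfg.outcome == "breast" else "age_oc"].notna().mean())
    return truth


def simulate_prospective_cohort(cfg: SimulationConfig,
                                ) -> tuple[pd.DataFrame, dict]:
    """Carriers unaffected (and still under observation) at recruitment,
    with follow-up and incident events beyond the recruitment age; no
    outcome-dependent sampling."""
    # inflate the pool so enough carriers survive the at-recruitment exclusion
    cfg_pool = SimulationConfig(**{**asdict_no_curve(cfg), "incidence": cfg.incidence,
                                   "target_affected_fraction": None,
                                   "n_carriers": int(cfg.n_carriers * 2.5)})
    rng = np.random.default_rng(cfg.seed)
    pool = _simulate_pool(cfg_pool, rng, cfg_pool.n_carriers)
    event_col = "age_bc" if cfg.outcome == "breast" else "age_oc"
    censor_cols = [c for c in ("age_oc", "age_mastectomy", "age_rrso", "age_bc")
                   if c != event_col]
    t_end = pool[[event_col, *censor_cols, "age_last_followup"]].min(axis=1)
    ok = t_end > pool["age_recruit"]
    out = pool.loc[ok].drop(columns=["affected"]).head(cfg.n_carriers)
    truth = cfg.truth()
    truth["n_generated"] = len(out)
    truth["n_incident"] = int(out[event_col].notna().sum())
    return out.reset_index(drop=True), truth


def asdict_no_curve(cfg: SimulationConfig) -> dict:
    d = asdict(cfg)
    d.pop("incidence", None)
    return d


def parameter_recovery(outcome: str, hr_true: float, cumulative_risk: float,
                       seed: int, n_carriers: int = 20_000, gene: str = "BRCA1",
                       target_affected_fraction: float = 0.5,
                       **config_overrides) -> dict:
    """Simulate an ascertained carrier cohort under a known per-SD hazard
    ratio, calibrate sampling weights to the generating incidence, fit the
    weighted Cox model, and report the recovered hazard ratio.

    This is the end-to-end recovery harness: the generating baseline hazard
    is itself the constrained solution for the stated average incidence, so
    the cohort's population incidence matches the curve the weights are
    calibrated against.
    """
    from .cohort import build_analysis_dataset, calibrate_sampling_weights
    from .survival import fit_weighted_cox

    shape = "ovarian" if outcome == "ovarian" else "breast"
    curve = make_incidence_fixture(cumulative_risk, shape=shape)
    defaults = dict(surgery_rate=0.012 if outcome == "ovarian" else 0.008)
    defaults.update(config_overrides)
    cfg = SimulationConfig(n_carriers=n_carriers, gene=gene, outcome=outcome,
                           beta0=float(np.log(hr_true)), incidence=curve,
                           target_affected_fraction=target_affected_fraction,
                           seed=int(seed) % (2 ** 31), **defaults)
    cohort, truth = simulate_retrospective_cohort(cfg)
    ds = build_analysis_dataset(cohort, outcome)
    _, weighted = calibrate_sampling_weights(ds, curve)
    fit = fit_weighted_cox(weighted)
    term = "prs_standardized"
    lo, hi = fit.confidence_interval(term)
    return {"hr": fit.hazard_ratio(term), "hr_true": float(hr_true),
            "beta": float(fit.coefficients[term]), "se": float(fit.se[term]),
            "ci_low": lo, "ci_high": hi, "n": len(ds), "n_events": fit.n_events,
            "affected_fraction": truth["affected_fraction"]}
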