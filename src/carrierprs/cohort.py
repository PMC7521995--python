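"""Carrier-cohort analysis datasets and ascertainment sampling weights.

Turns a carrier phenotype table into an outcome-specific survival dataset
(applying the censoring rules for breast, ER-specific breast, and ovarian
outcomes) and calibrates age- and disease-specific sampling weights so the
weighted age-specific incidence in the — clinically ascertained, hence
case-enriched — cohort agrees with external incidence estimates for
carriers.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .risk import IncidenceCurve, RiskModelError

logger = logging.getLogger("carrierprs")

MAX_AGE = 80.0

#: columns understood in a carrier phenotype table; ages in years (fractional
#: allowed), missing values empty/NaN.
COHORT_COLUMNS = [
    "carrier_id", "family_id", "gene", "birth_year", "country", "ashkenazi",
    "age_recruit", "age_last_followup", "age_bc", "er_status", "age_oc",
    "age_mastectomy", "age_rrso", "fh_breast", "fh_ovarian", "variant_class",
    "variant_location_group", "pc1", "pc2", "pc3", "pc4", "prs_standardized",
]

OUTCOMES = ("breast", "er_positive", "er_negative", "ovarian")


class CohortError(ValueError):
    pass


@dataclass
class CarrierRecord:
    """One carrier's phenotype row; see :data:`COHORT_COLUMNS` for semantics."""

    carrier_id: str
    family_id: str
    gene: str
    birth_year: float
    country: str
    ashkenazi: bool
    age_recruit: float
    age_last_followup: float
    age_bc: Optional[float] = None
    er_status: Optional[str] = None  # positive | negative | None (missing)
    age_oc: Optional[float] = None
    age_mastectomy: Optional[float] = None
    age_rrso: Optional[float] = None
    fh_breast: int = 0  # 0, 1, 2 (= two or more affected relatives)
    fh_ovarian: int = 0
    variant_class: str = "unknown"  # I | II | unknown
    variant_location_group: str = "unknown"
    pc1: float = 0.0
    pc2: float = 0.0
    pc3: float = 0.0
    pc4: float = 0.0
    prs_standardized: float = np.nan


def as_cohort_frame(cohort) -> pd.DataFrame:
    """Accept a DataFrame or an iterable of :class:`CarrierRecord`."""
    if isinstance(cohort, pd.DataFrame):
        df = cohort.copy()
    else:
        df = pd.DataFrame([vars(r) for r in cohort])
    missing = [c for c in ("carrier_id", "family_id", "age_last_followup") if c not in df.columns]
    if missing:
        raise CohortError(f"cohort table lacks required columns: {missing}")
    for c in COHORT_COLUMNS:
        if c not in df.columns:
            df[c] = np.nan
    return df


def read_cohort_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path, comment="#",
                     dtype={"carrier_id": str, "family_id": str})
    return as_cohort_frame(df)


@dataclass
class AnalysisDataset:
    """Survival rows ready for (weighted) Cox fitting.

    ``table`` columns: carrier_id, entry_age, exit_age, event, stratum,
    cluster, sampling_weight, plus whatever covariates were requested.
    """

    table: pd.DataFrame
    outcome: str
    covariates: list[str]
    prospective: bool = False

    def __post_init__(self) -> None:
        t = self.table
        if (t["exit_age"] <= t["entry_age"]).any():
            bad = t.loc[t["exit_age"] <= t["entry_age"], "carrier_id"].tolist()
            raise CohortError(f"entry age >= exit age for carriers {bad[:10]}")
        if (t["exit_age"] > MAX_AGE).any():
            raise CohortError("exit ages must be capped at 80")
        if (t["sampling_weight"] <= 0).any():
            raise CohortError("sampling weights must be positive")

    @property
    def n_events(self) -> int:
        return int(self.table["event"].sum())

    def __len__(self) -> int:
        return len(self.table)


_FH_COLUMN = {"breast": "fh_breast", "er_positive": "fh_breast",
              "er_negative": "fh_breast", "ovarian": "fh_ovarian"}


def build_analysis_dataset(cohort, outcome: str,
                           covariates: Sequence[str] = ("prs_standardized",),
                           prospective: bool = False,
                           censor_ovarian_at_bc: bool = True,
                           include_family_history: bool = False,
                           ) -> AnalysisDataset:
    """Apply the outcome's censoring rules and assemble a survival dataset.

    Breast outcomes censor at the first of breast diagnosis, ovarian
    diagnosis, risk-reducing mastectomy, last follow-up, or age 80; the
    ovarian outcome censors at RRSO instead of mastectomy (and, by default,
    also at a breast cancer diagnosis).  ER-specific outcomes treat a
    diagnosis of the opposite receptor status as censoring and exclude
    affected carriers whose ER status is missing.  In prospective mode entry
    is the recruitment age and carriers affected (or fully censored) before
    recruitment are excluded.
    """
    if outcome not in OUTCOMES:
        raise CohortError(f"unknown outcome {outcome!r}; expected one of {OUTCOMES}")
    df = as_cohort_frame(cohort)

    for col in ("age_bc", "age_oc"):
        bad = df[col].notna() & (df[col] > df["age_last_followup"])
        if bad.any():
            raise CohortError(
                f"{col} after last follow-up for carriers "
                f"{df.loc[bad, 'carrier_id'].tolist()[:10]}")

    if outcome in ("er_positive", "er_negative"):
        er = df["er_status"].where(df["er_status"].isin(["positive", "negative"]))
        missing_er = df["age_bc"].notna() & er.isna()
        if missing_er.any():
            logger.info("excluding %d affected carriers with missing ER status",
                        int(missing_er.sum()))
            df = df.loc[~missing_er].copy()
        want = "positive" if outcome == "er_positive" else "negative"
        event_age = df["age_bc"].where(df["er_status"] == want)
        censor_ages = [df["age_bc"].where(df["er_status"] != want),
                       df["age_oc"], df["age_mastectomy"]]
    elif outcome == "breast":
        event_age = df["age_bc"]
        censor_ages = [df["age_oc"], df["age_mastectomy"]]
    else:  # ovarian
        event_age = df["age_oc"]
        censor_ages = [df["age_rrso"]]
        if censor_ovarian_at_bc:
            censor_ages.append(df["age_bc"])

    fu = df["age_last_followup"].clip(upper=MAX_AGE)
    exit_age = pd.concat([event_age, fu] + censor_ages, axis=1).min(axis=1)
    exit_age = exit_age.clip(upper=MAX_AGE)
    # diagnosis takes precedence on ties, matching its leading place in the
    # censoring list
    event = event_age.notna() & (event_age <= exit_age)

    out = pd.DataFrame({
        "carrier_id": df["carrier_id"].astype(str),
        "entry_age": 0.0,
        "exit_age": exit_age.astype(float),
        "event": event.astype(int),
        "stratum": (df["country"].astype(str) + "|" +
                    df["ashkenazi"].fillna(False).astype(bool).astype(str)),
        "cluster": df["family_id"].astype(str),
        "sampling_weight": 1.0,
    })

    covariates = list(covariates)
    if include_family_history:
        fh = pd.to_numeric(df[_FH_COLUMN[outcome]], errors="coerce").fillna(0)
        out["fh_one"] = (fh == 1).astype(float)
        out["fh_two_plus"] = (fh >= 2).astype(float)
        covariates += ["fh_one", "fh_two_plus"]
    for cov in covariates:
        if cov in out.columns:
            continue
        if cov == "birth_cohort":
            out[cov] = (pd.to_numeric(df["birth_year"], errors="coerce") - 1950.0) / 10.0
        elif cov in df.columns:
            out[cov] = pd.to_numeric(df[cov], errors="coerce").to_numpy()
        else:
            raise CohortError(f"unknown covariate {cov!r}")
    out["group_variant_class"] = df["variant_class"].astype(str).to_numpy()
    out["group_location"] = df["variant_location_group"].astype(str).to_numpy()
    out["group_country"] = df["country"].astype(str).to_numpy()

    if prospective:
        entry = pd.to_numeric(df["age_recruit"], errors="coerce")
        if entry.isna().any():
            raise CohortError("prospective mode requires age_recruit for every carrier")
        affected_before = event_age.notna() & (event_age <= entry)
        out["entry_age"] = entry.to_numpy(float)
        keep = (~affected_before & (out["exit_age"] > out["entry_age"])).to_numpy()
        dropped = int((~keep).sum())
        if dropped:
            logger.info("prospective mode: excluding %d carriers affected or "
                        "censored before recruitment", dropped)
        out = out.loc[keep]

    out = out.dropna(subset=covariates)
    return AnalysisDataset(table=out.reset_index(drop=True), outcome=outcome,
                           covariates=covariates, prospective=prospective)


# ---------------------------------------------------------------------------
# sampling-weight calibration


@dataclass(frozen=True)
class SamplingWeightScheme:
    """Per-age-bin affected/unaffected weights calibrating the cohort's
    weighted age-specific incidence to an external curve."""

    bin_edges: np.ndarray  # length B+1
    target_affected_fraction: np.ndarray  # p_j
    observed_affected_fraction: np.ndarray  # q_j
    weight_affected: np.ndarray
    weight_unaffected: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "age_start": self.bin_edges[:-1], "age_end": self.bin_edges[1:],
            "target_affected_fraction": self.target_affected_fraction,
            "observed_affected_fraction": self.observed_affected_fraction,
            "weight_affected": self.weight_affected,
            "weight_unaffected": self.weight_unaffected,
        })


def weight_pair(p: float, q: float) -> tuple[float, float]:
    """Affected/unaffected weights making the weighted affected fraction of a
    bin equal its target: ``w_aff = p/q``, ``w_unaff = (1-p)/(1-q)``."""
    if not (0 < p < 1):
        raise CohortError(f"target affected fraction must be in (0,1), got {p}")
    if not (0 < q < 1):
        raise CohortError(f"observed affected fraction must be in (0,1), got {q}")
    return p / q, (1.0 - p) / (1.0 - q)


def default_age_bins(width: float = 5.0, lo: float = 18.0,
                     hi: float = MAX_AGE) -> np.ndarray:
    edges = np.arange(lo, hi, width)
    return np.append(edges, hi)


def _person_years_in_bins(entry, exit_, weights, edges) -> np.ndarray:
    lo = np.maximum.outer(entry, edges[:-1])
    hi = np.minimum.outer(exit_, edges[1:])
    overlap = np.clip(hi - lo, 0.0, None)
    return weights @ overlap


def _expected_events(entry, exit_, weights, edges, curve: IncidenceCurve) -> np.ndarray:
    """Weighted expected event count per bin under the external incidence,
    integrating the curve over each subject's time at risk within the bin."""
    # refine bins to the curve's breakpoints so the rate is constant per piece
    out = np.zeros(len(edges) - 1)
    for j in range(len(edges) - 1):
        cuts = np.unique(np.concatenate(
            [[edges[j], edges[j + 1]],
             curve.age_start[(curve.age_start > edges[j]) & (curve.age_start < edges[j + 1])]]))
        for a, b in zip(cuts[:-1], cuts[1:]):
            lam = curve.rate_at(a)
            ov = np.clip(np.minimum(exit_, b) - np.maximum(entry, a), 0.0, None)
            out[j] += lam * float(weights @ ov)
    return out


def calibrate_sampling_weights(dataset: AnalysisDataset, external: IncidenceCurve,
                               age_bins: Optional[np.ndarray] = None,
                               max_iter: int = 200, tol: float = 1e-12,
                               ) -> tuple[SamplingWeightScheme, AnalysisDataset]:
    """Calibrate age- and disease-specific sampling weights.

    In each age bin ``j`` the target affected fraction among exits is
    ``p_j = E_j / N_j`` with ``E_j`` the expected events implied by the
    external incidence applied to the cohort's (weighted) person-time, and
    ``q_j = D_j / N_j`` the observed fraction; affected exits in the bin are
    weighted ``p_j/q_j`` and unaffected ``(1-p_j)/(1-q_j)``.  Because the
    weights themselves change the person-time, the scheme is iterated to a
    fixed point; at convergence the weighted age-specific incidence equals
    the external curve bin by bin.
    """
    t = dataset.table
    auto_merge = age_bins is None
    if auto_merge:
        # bins aligned with the external curve's pieces, so the weighted
        # incidence is compared against a constant rate within each bin
        edges = np.unique(np.concatenate([external.age_start, external.age_end]))
        edges = edges[(edges >= 18.0) & (edges <= MAX_AGE)]
    else:
        edges = np.asarray(age_bins, float)
    if not external.covers(edges[0], edges[-1]):
        raise RiskModelError(
            f"external curve does not cover the weight bins [{edges[0]}, {edges[-1]}]")
    entry = t["entry_age"].to_numpy(float)
    exit_ = t["exit_age"].to_numpy(float)
    event = t["event"].to_numpy(int)

    def _tabulate(edges):
        # exit age exactly at a bin's upper edge counts in that bin
        bin_of = np.clip(np.searchsorted(edges, exit_, side="left") - 1,
                         0, len(edges) - 2)
        n_j = np.bincount(bin_of, minlength=len(edges) - 1).astype(float)
        d_j = np.bincount(bin_of, weights=event, minlength=len(edges) - 1).astype(float)
        return bin_of, n_j, d_j

    bin_of, n_j, d_j = _tabulate(edges)
    if auto_merge:
        # coarsen until every bin holds both affected and unaffected exits
        while len(edges) > 2:
            bad = (n_j == 0) | (d_j == 0) | (d_j == n_j)
            if not bad.any():
                break
            j = int(np.flatnonzero(bad)[0])
            edges = np.delete(edges, j + 1 if j == 0 else j)
            bin_of, n_j, d_j = _tabulate(edges)
    occupied = n_j > 0
    if not occupied.any():
        raise CohortError("no exits fall inside the weight bins")
    bad = occupied & ((d_j == 0) | (d_j == n_j))
    if bad.any():
        lo = edges[:-1][bad]
        raise CohortError(
            "age bins starting at "
            f"{lo.tolist()} lack affected or unaffected exits; use coarser bins")

    w_aff = np.ones(len(edges) - 1)
    w_unaff = np.ones(len(edges) - 1)
    q_j = np.divide(d_j, n_j, out=np.zeros_like(d_j), where=occupied)
    p_j = q_j.copy()
    for it in range(max_iter):
        w = np.where(event == 1, w_aff[bin_of], w_unaff[bin_of])
        e_j = _expected_events(entry, exit_, w, edges, external)
        p_new = np.divide(e_j, n_j, out=np.zeros_like(e_j), where=occupied)
        if (p_new[occupied] >= 1).any():
            raise CohortError("external incidence implies every exit affected in "
                              "some bin; incompatible with a sampling-weight model")
        if (p_new[occupied] <= 0).any():
            raise CohortError("external incidence implies zero affected exits in "
                              "an occupied bin")
        w_aff_new = np.where(occupied, np.divide(p_new, q_j, out=np.ones_like(q_j),
                                                 where=occupied), 1.0)
        w_unaff_new = np.where(occupied,
                               np.divide(1 - p_new, 1 - q_j, out=np.ones_like(q_j),
                                         where=occupied), 1.0)
        delta = max(np.abs(w_aff_new - w_aff).max(), np.abs(w_unaff_new - w_unaff).max())
        w_aff, w_unaff, p_j = w_aff_new, w_unaff_new, p_new
        if delta < tol:
            break
    else:
        logger.warning("weight calibration stopped after %d iterations "
                       "(last change %.2e)", max_iter, delta)

    scheme = SamplingWeightScheme(bin_edges=edges, target_affected_fraction=p_j,
                                  observed_affected_fraction=q_j,
                                  weight_affected=w_aff, weight_unaffected=w_unaff)
    new_table = t.copy()
    new_table["sampling_weight"] = np.where(event == 1, w_aff[bin_of], w_unaff[bin_of])
    weighted = AnalysisDataset(table=new_table, outcome=dataset.outcome,
                               covariates=list(dataset.covariates),
                               prospective=dataset.prospective)
    return scheme, weighted


def weighted_incidence(dataset: AnalysisDataset,
                       age_bins: np.ndarray) -> pd.DataFrame:
    """Weighted events / weighted person-years per age bin (diagnostic)."""
    t = dataset.table
    edges = np.asarray(age_bins, float)
    w = t["sampling_weight"].to_numpy(float)
    entry = t["entry_age"].to_numpy(float)
    exit_ = t["exit_age"].to_numpy(float)
    event = t["event"].to_numpy(int)
    py = _person_years_in_bins(entry, exit_, w, edges)
    bin_of = np.clip(np.searchsorted(edges, exit_, side="left") - 1, 0, len(edges) - 2)
    ev = np.bincount(bin_of, weights=w * event, minlength=len(edges) - 1)
    with np.errstate(invalid="ignore", divide="ignore"):
        inc = ev / py
    return pd.DataFrame({"age_start": edges[:-1], "age_end": edges[1:],
                         "weighted_events": ev, "weighted_person_years": py,
                         "weighted_incidence": inc})
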