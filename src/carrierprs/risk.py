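"""Absolute (penetrance) risk prediction by PRS percentile.

Converts a per-SD log hazard ratio (optionally log-linear in age) plus an
external average incidence curve for carriers into percentile-specific
cumulative risks, under the constraint that the mixture-average incidence
over PRS categories reproduces the external curve at every age.  The
constraint accounts for depletion of susceptibles: carriers with high
polygenic load fail early, so the baseline hazard implied by a fixed
average incidence is pulled below the average at later ages.

The solver works on an annual age grid with piecewise-constant hazards.
Each year it solves a one-dimensional equation for the baseline
cumulative-hazard increment so that the mixture-average survival decays
exactly by the external curve's survival factor; cumulative conservation
therefore holds to root-finder precision, and the instantaneous-hazard
identity ``lambda0 = lambdabar * sum(p S) / sum(p S RR)`` holds exactly at
every grid age.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy import optimize, special, stats

logger = logging.getLogger("carrierprs")


class RiskModelError(ValueError):
    pass


@dataclass(frozen=True)
class IncidenceCurve:
    """Piecewise-constant average incidence (events per person-year) by age."""

    age_start: np.ndarray
    age_end: np.ndarray
    incidence: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        s = np.asarray(self.age_start, float)
        e = np.asarray(self.age_end, float)
        lam = np.asarray(self.incidence, float)
        if not (len(s) == len(e) == len(lam)) or len(s) == 0:
            raise RiskModelError("incidence curve fields must be equal-length, nonempty")
        if not ((e > s).all() and (s[1:] == e[:-1]).all()):
            raise RiskModelError("intervals must be contiguous and non-overlapping")
        if not (np.isfinite(lam).all() and (lam >= 0).all()):
            raise RiskModelError("incidences must be finite and nonnegative")
        object.__setattr__(self, "age_start", s)
        object.__setattr__(self, "age_end", e)
        object.__setattr__(self, "incidence", lam)

    def covers(self, lo: float, hi: float) -> bool:
        return self.age_start[0] <= lo and self.age_end[-1] >= hi

    def rate_at(self, age) -> np.ndarray:
        """Incidence applying in the year [age, age+1) (half-open intervals)."""
        age = np.asarray(age, float)
        idx = np.searchsorted(self.age_end, age, side="right")
        if (idx >= len(self.incidence)).any() or (age < self.age_start[0]).any():
            raise RiskModelError("age outside the incidence curve's support")
        return self.incidence[idx]

    def cumulative_hazard(self, age: float) -> float:
        """Integral of the incidence from the curve start to ``age``."""
        widths = np.clip(np.minimum(self.age_end, age) - self.age_start, 0, None)
        return float(np.sum(widths * self.incidence))

    def cumulative_risk(self, age: float) -> float:
        return 1.0 - float(np.exp(-self.cumulative_hazard(age)))

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({"age_start": self.age_start, "age_end": self.age_end,
                             "incidence_per_year": self.incidence})

    @classmethod
    def from_csv(cls, path, label: str = "") -> "IncidenceCurve":
        import pandas as pd

        df = pd.read_csv(path, comment="#")
        return cls(df["age_start"].to_numpy(), df["age_end"].to_numpy(),
                   df["incidence_per_year"].to_numpy(), label=label or str(path))


@dataclass(frozen=True)
class AgeVaryingLogHR:
    """Per-SD log hazard ratio, optionally log-linear in age.

    ``beta(t) = beta0 + beta1 * (t - reference_age)``; with ``beta1 = 0``
    this is the ordinary proportional-hazards effect. ``reference_age=0``
    matches an age-in-years interaction fitted without centering.
    """

    beta0: float
    beta1: float = 0.0
    reference_age: float = 0.0

    def __post_init__(self) -> None:
        if not (np.isfinite(self.beta0) and np.isfinite(self.beta1)):
            raise RiskModelError("log hazard ratios must be finite")

    def at(self, age) -> np.ndarray:
        return self.beta0 + self.beta1 * (np.asarray(age, float) - self.reference_age)


@dataclass(frozen=True)
class PrsMixture:
    """Discrete mixture approximating the standardized PRS distribution."""

    z: np.ndarray
    p: np.ndarray

    def __post_init__(self) -> None:
        z = np.asarray(self.z, float)
        p = np.asarray(self.p, float)
        if z.shape != p.shape or z.ndim != 1 or len(z) == 0:
            raise RiskModelError("mixture z and p must be equal-length vectors")
        if (p <= 0).any() or abs(p.sum() - 1.0) > 1e-8:
            raise RiskModelError("mixture probabilities must be positive and sum to 1")
        if not (np.diff(z) >= 0).all():
            raise RiskModelError("mixture z values must be ordered")
        object.__setattr__(self, "z", z)
        object.__setattr__(self, "p", p)


@dataclass(frozen=True)
class PenetranceSurface:
    """Solved baseline hazard and per-category risk curves on an annual grid.

    ``ages`` has T+1 entries (grid ages); ``survival`` is K x (T+1) with
    ``survival[:, 0] = 1``; ``baseline_increments`` (length T) are the
    baseline cumulative-hazard increments per year; ``baseline_hazard`` is
    the instantaneous baseline rate at each of the first T grid ages.
    """

    ages: np.ndarray
    mixture: PrsMixture
    loghr: AgeVaryingLogHR
    baseline_increments: np.ndarray
    baseline_hazard: np.ndarray
    survival: np.ndarray
    average_incidence: np.ndarray

    @property
    def cumulative_risk(self) -> np.ndarray:
        """K x (T+1) matrix of F_k(t) = 1 - S_k(t)."""
        return 1.0 - self.survival

    @property
    def mixture_average_risk(self) -> np.ndarray:
        return 1.0 - self.mixture.p @ self.survival

    def to_frame(self, percentiles: Sequence[float] = (5, 10, 25, 50, 75, 90, 95)):
        import pandas as pd

        rows = []
        for pct in percentiles:
            fcurve = risk_by_percentile(self, [pct])[:, 0]
            for i, a in enumerate(self.ages):
                rows.append({"age": float(a), "percentile": float(pct),
                             "cumulative_risk": float(fcurve[i])})
        return pd.DataFrame(rows)


def discretize_standard_normal(bin_edges: Sequence[float]) -> PrsMixture:
    """Equal-definition mixture of a standard normal over percentile bins.

    Each category's representative value is the conditional mean
    ``E[z | bin] = (phi(a) - phi(b)) / (Phi(b) - Phi(a))``.
    """
    edges = np.asarray(bin_edges, float)
    if ((edges <= 0) | (edges >= 100)).any() or not (np.diff(edges) > 0).all():
        raise RiskModelError("bin edges must be strictly increasing within (0,100)")
    probs = np.concatenate(([0.0], edges / 100.0, [1.0]))
    a = special.ndtri(probs[:-1])
    b = special.ndtri(probs[1:])
    p = probs[1:] - probs[:-1]
    z = (stats.norm.pdf(a) - stats.norm.pdf(b)) / p
    return PrsMixture(z=z, p=p)


def equal_probability_mixture(n_bins: int = 201) -> PrsMixture:
    """Fine equal-probability discretization used by the solver by default."""
    edges = np.linspace(0, 100, n_bins + 1)[1:-1]
    return discretize_standard_normal(edges)


def solve_constrained_hazard(external: IncidenceCurve, loghr: AgeVaryingLogHR,
                             mixture: Optional[PrsMixture] = None,
                             age_start: Optional[float] = None,
                             age_end: float = 80.0) -> PenetranceSurface:
    """Solve for the baseline hazard whose PRS mixture reproduces ``external``.

    At every grid year the baseline increment ``delta`` solves
    ``sum_k p_k S_k(t) exp(-RR_k(t) delta) = Sbar(t) exp(-lambdabar(t))``,
    so the probability-weighted average survival tracks the external curve's
    survival exactly.  Raises if the external curve exhausts the cohort
    (average cumulative risk reaching 1) before ``age_end``.
    """
    if mixture is None:
        mixture = equal_probability_mixture()
    if age_start is None:
        # start where the curve starts, so the mixture-average cumulative risk
        # reproduces the curve's own cumulative risk
        age_start = float(external.age_start[0])
    if not external.covers(age_start, age_end):
        raise RiskModelError(
            f"incidence curve does not cover [{age_start}, {age_end}]")
    ages = np.arange(age_start, age_end + 1.0)
    T = len(ages) - 1
    p, z = mixture.p, mixture.z
    S = np.empty((len(z), T + 1))
    S[:, 0] = 1.0
    deltas = np.empty(T)
    lam0_inst = np.empty(T)
    lambar = external.rate_at(ages[:-1])
    sbar = 1.0
    for t in range(T):
        rr = np.exp(loghr.at(ages[t]) * z)
        s_now = S[:, t]
        target = sbar * np.exp(-lambar[t])
        if target <= 0:
            raise RiskModelError("external incidence implies certain failure "
                                 f"before age {ages[t + 1]}")
        lam0_inst[t] = lambar[t] * (p @ s_now) / (p @ (s_now * rr))
        if lambar[t] == 0:
            deltas[t] = 0.0
        else:
            def f(d):
                return p @ (s_now * np.exp(-rr * d)) - target

            hi = lambar[t] / rr.min() + 1e-12
            deltas[t] = optimize.brentq(f, 0.0, hi, xtol=1e-15, rtol=1e-15)
        S[:, t + 1] = s_now * np.exp(-rr * deltas[t])
        sbar = target
    return PenetranceSurface(ages=ages, mixture=mixture, loghr=loghr,
                             baseline_increments=deltas, baseline_hazard=lam0_inst,
                             survival=S, average_incidence=lambar)


def risk_by_percentile(surface: PenetranceSurface,
                       percentiles: Sequence[float]) -> np.ndarray:
    """Cumulative risk curves at exact percentile z-values, ``(T+1) x len(pcts)``.

    Evaluated with the solved baseline increments at ``z = Phi^-1(pct/100)``
    rather than at the mixture's representative category means, so headline
    percentiles carry no discretization bias.
    """
    pcts = np.asarray(percentiles, float)
    if ((pcts <= 0) | (pcts >= 100)).any():
        raise RiskModelError("percentiles must lie strictly within (0, 100)")
    z = special.ndtri(pcts / 100.0)
    beta_t = surface.loghr.at(surface.ages[:-1])  # (T,)
    rr = np.exp(np.outer(beta_t, z))  # T x P
    cumhaz = np.concatenate(
        [np.zeros((1, len(z))),
         np.cumsum(surface.baseline_increments[:, None] * rr, axis=0)])
    return 1.0 - np.exp(-cumhaz)


def ten_year_risk(surface: PenetranceSurface, percentile: float,
                  age: float) -> float:
    """P(event in [age, age+10] | event-free at age) at a PRS percentile."""
    ages = surface.ages
    if age < ages[0] or age + 10 > ages[-1]:
        raise RiskModelError(f"[{age}, {age + 10}] not within the solved grid")
    curve = risk_by_percentile(surface, [percentile])[:, 0]
    i = int(np.searchsorted(ages, age))
    j = int(np.searchsorted(ages, age + 10))
    if ages[i] != age or ages[j] != age + 10:
        raise RiskModelError("age and age+10 must be grid ages")
    fa, fb = curve[i], curve[j]
    if fa >= 1.0:
        raise RiskModelError("risk already 1 at the conditioning age")
    return float((fb - fa) / (1.0 - fa))


def subgroup_risks(external_by_group: Mapping[str, IncidenceCurve],
                   loghr: AgeVaryingLogHR,
                   mixture: Optional[PrsMixture] = None,
                   **kwargs) -> dict[str, PenetranceSurface]:
    """Independent constrained solves per subgroup (family history, variant
    location), sharing the per-SD hazard ratio across groups."""
    if not external_by_group:
        raise RiskModelError("no subgroup incidence curves supplied")
    return {g: solve_constrained_hazard(curve, loghr, mixture, **kwargs)
            for g, curve in external_by_group.items()}
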