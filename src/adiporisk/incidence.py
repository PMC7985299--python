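"""Expected cumulative incidence under competing mortality.

Given age-specific event and all-cause mortality rates (per person-year),
the expected cumulative incidence is accumulated over discrete steps with
the piecewise-constant-hazard competing-risk solution

    dCI = S(t) * lambda/(lambda+mu) * (1 - exp(-(lambda+mu) dt)),

where S is the probability of being event-free and alive.  Subgroup curves
are derived from group prevalences and rate ratios (odds ratios used as
rate-ratio estimates, a rare-event approximation): at every step a baseline
scaling is solved so that the prevalence-weighted group increments
reproduce the marginal increment, while mortality is left untouched across
groups.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import brentq

__all__ = [
    "GroupSpec", "IncidenceCurve", "validate_rate_table",
    "expected_cumulative_incidence", "group_specific_incidence",
]


@dataclass(frozen=True)
class GroupSpec:
    """A risk stratum: its population share and its rate ratio."""

    label: str
    prevalence: float
    rate_ratio: float


@dataclass(frozen=True)
class IncidenceCurve:
    """Cumulative incidence CI(t) and event-free-alive probability S(t)."""

    time: np.ndarray       # years from start
    ci: np.ndarray
    surv: np.ndarray

    def at(self, t: float) -> float:
        """CI at time t (grid lookup with interpolation)."""
        return float(np.interp(t, self.time, self.ci))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"t": self.time, "ci": self.ci, "s": self.surv})


def validate_rate_table(rates: pd.DataFrame) -> pd.DataFrame:
    req = {"age", "incidence_rate", "mortality_rate"}
    if not req.issubset(rates.columns):
        raise ValueError(f"rate table needs columns {sorted(req)}")
    df = rates.sort_values("age").reset_index(drop=True)
    if (df[["incidence_rate", "mortality_rate"]].to_numpy() < 0).any():
        raise ValueError("rates must be >= 0")
    ages = df["age"].to_numpy(float)
    if len(ages) > 1 and np.any(np.diff(ages) <= 0):
        raise ValueError("age bands must be strictly increasing")
    return df


def _rates_at(df: pd.DataFrame, age: float) -> tuple[float, float]:
    ages = df["age"].to_numpy(float)
    idx = int(np.searchsorted(ages, age, side="right") - 1)
    if idx < 0 or age >= ages[-1] + 1.0:
        raise ValueError(f"age {age:.1f} outside the rate table")
    return (float(df["incidence_rate"].iloc[idx]),
            float(df["mortality_rate"].iloc[idx]))


def _step_increment(lam: float, mu: float, s: float, dt: float) -> tuple[float, float]:
    """(dCI, survival multiplier) for one piecewise-constant-hazard step."""
    tot = lam + mu
    if tot <= 0:
        return 0.0, 1.0
    shrink = np.exp(-tot * dt)
    return s * (lam / tot) * (1.0 - shrink), shrink


def expected_cumulative_incidence(
    rates: pd.DataFrame,
    start_age: float,
    horizon_years: float,
    step_years: float = 1.0,
) -> IncidenceCurve:
    """Expected cumulative incidence from ``start_age`` over the horizon.

    The age advances along the rate table; each step uses the exact
    constant-hazard competing-risk solution, so halving the step changes
    nothing when rates are constant within bands.
    """
    if step_years <= 0:
        raise ValueError("step_years must be > 0")
    df = validate_rate_table(rates)
    n = int(np.ceil(horizon_years / step_years - 1e-12))
    t_grid = [0.0]
    ci_grid = [0.0]
    s_grid = [1.0]
    ci, s = 0.0, 1.0
    t = 0.0
    for _ in range(n):
        dt = min(step_years, horizon_years - t)
        lam, mu = _rates_at(df, start_age + t)
        dci, shrink = _step_increment(lam, mu, s, dt)
        ci += dci
        s *= shrink
        t += dt
        t_grid.append(t)
        ci_grid.append(ci)
        s_grid.append(s)
    return IncidenceCurve(np.array(t_grid), np.array(ci_grid), np.array(s_grid))


def group_specific_incidence(
    rates: pd.DataFrame,
    groups: list[GroupSpec],
    start_age: float,
    horizon_years: float,
    step_years: float = 1.0,
) -> dict[str, IncidenceCurve]:
    """Per-group incidence curves consistent with the marginal curve.

    At each step a scaling ``c`` of the baseline event hazard is solved so
    that the prevalence-weighted sum of group increments equals the
    marginal increment; group g then advances with hazard
    ``rate_ratio_g * c * lambda(age)`` (mortality unchanged).  The
    prevalence-weighted mean of the group curves therefore reproduces the
    marginal curve by construction.  The marginal curve is returned under
    the key ``"marginal"``.
    """
    if step_years <= 0:
        raise ValueError("step_years must be > 0")
    prev = np.array([g.prevalence for g in groups], dtype=float)
    rr = np.array([g.rate_ratio for g in groups], dtype=float)
    if abs(prev.sum() - 1.0) > 1e-9:
        raise ValueError("group prevalences must sum to 1")
    if np.any(prev <= 0) or np.any(rr <= 0):
        raise ValueError("prevalences and rate ratios must be > 0")
    df = validate_rate_table(rates)

    marginal = expected_cumulative_incidence(df, start_age, horizon_years,
                                             step_years)
    k = len(groups)
    s_g = np.ones(k)
    ci_g = np.zeros(k)
    curves_ci = [np.zeros(k)]
    curves_s = [np.ones(k)]
    for i in range(1, len(marginal.time)):
        t0, t1 = marginal.time[i - 1], marginal.time[i]
        dt = t1 - t0
        lam, mu = _rates_at(df, start_age + t0)
        d_marg = marginal.ci[i] - marginal.ci[i - 1]

        def weighted_inc(c):
            tot = rr * c * lam + mu
            with np.errstate(divide="ignore", invalid="ignore"):
                frac = np.where(tot > 0, rr * c * lam / np.where(tot > 0, tot, 1.0), 0.0)
            return float(np.sum(prev * s_g * frac * (1.0 - np.exp(-tot * dt))))

        if lam <= 0 or d_marg <= 0:
            c = 0.0
        else:
            hi = 1.0
            while weighted_inc(hi) < d_marg and hi < 1e8:
                hi *= 2.0
            c = brentq(lambda x: weighted_inc(x) - d_marg, 0.0, hi,
                       xtol=1e-14, rtol=1e-13)
        tot = rr * c * lam + mu
        frac = np.where(tot > 0, np.divide(rr * c * lam, tot,
                                           out=np.zeros_like(tot),
                                           where=tot > 0), 0.0)
        ci_g = ci_g + s_g * frac * (1.0 - np.exp(-tot * dt))
        s_g = s_g * np.exp(-tot * dt)
        curves_ci.append(ci_g.copy())
        curves_s.append(s_g.copy())

    ci_mat = np.array(curves_ci)
    s_mat = np.array(curves_s)
    out = {g.label: IncidenceCurve(marginal.time, ci_mat[:, j], s_mat[:, j])
           for j, g in enumerate(groups)}
    out["marginal"] = marginal
    return out
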