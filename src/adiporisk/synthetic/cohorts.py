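"""Age-matched nested case-control cohorts with a known conditional estimand.

A full cohort is simulated under a proportional-hazards model with
exponential event times; cases are subjects whose event falls inside the
follow-up window, and each case's controls are drawn from the subjects still
at risk at the case's event time whose baseline age matches within the
matching window (incidence-density sampling).  Under this design the
conditional-logistic odds ratio estimates the hazard-rate ratio, so the
generator's ``log_odds`` are the estimand the downstream fit should recover.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class Covariate:
    """Marginal model for one baseline covariate.

    ``bernoulli``: prevalence in (0, 1).  ``normal``: mean/sd plus an
    optional linear age trend (units of the covariate per year).
    """

    kind: str = "bernoulli"
    prevalence: float = 0.5
    mean: float = 0.0
    sd: float = 1.0
    age_slope: float | None = None


@dataclass(frozen=True)
class AgeDist:
    mean: float = 57.0
    sd: float = 10.0
    low: float = 30.0
    high: float = 88.0


@dataclass(frozen=True)
class CohortSpec:
    """Study-design parameters for the nested case-control generator.

    Defaults mirror a DCIS-after-BCS setting: diagnosis ages centred in the
    late fifties, age matching to within half a year, one or two controls
    per case, a high-prevalence binary marker (COX-2-like) and a continuous
    adipocyte-size covariate that drifts upward with age.
    """

    n_sets: int = 250
    controls_per_set_dist: dict[int, float] = field(
        default_factory=lambda: {1: 0.5, 2: 0.5})
    age_dist: AgeDist = field(default_factory=AgeDist)
    age_match_window_years: float = 0.5
    covariate_model: dict[str, Covariate] | None = None
    log_odds: dict[str, float] = field(
        default_factory=lambda: {"cox2_high": float(np.log(3.70)),
                                 "area_p75_um2": float(np.log(1.17)) / 1000.0})
    age_area_slope: float = 80.0       # µm² area_p75 per year of age
    baseline_rate: float = 0.02        # events per person-year at mean covariates
    followup_years: float = 15.0
    cohort_factor: float = 6.0         # simulated cohort size = factor * n_sets
    seed: int = 0

    def resolved_covariates(self) -> dict[str, Covariate]:
        if self.covariate_model is not None:
            return dict(self.covariate_model)
        return {
            "cox2_high": Covariate("bernoulli", prevalence=0.6),
            "area_p75_um2": Covariate("normal", mean=6400.0, sd=1600.0,
                                      age_slope=self.age_area_slope),
        }

    def validate(self) -> None:
        if self.n_sets < 1:
            raise ValueError("n_sets must be >= 1")
        if self.age_match_window_years < 0:
            raise ValueError("age_match_window_years must be >= 0")
        probs = np.array(list(self.controls_per_set_dist.values()), dtype=float)
        keys = list(self.controls_per_set_dist.keys())
        if not keys or any(k < 1 or k > 4 for k in keys):
            raise ValueError("controls_per_set_dist must be over {1..4}")
        if np.any(probs < 0) or not np.isclose(probs.sum(), 1.0):
            raise ValueError("controls_per_set_dist probabilities must sum to 1")
        for name, cov in self.resolved_covariates().items():
            if cov.kind == "bernoulli" and not (0.0 < cov.prevalence < 1.0):
                raise ValueError(
                    f"covariate {name!r}: prevalence must lie strictly in (0, 1)")
            if cov.kind not in ("bernoulli", "normal"):
                raise ValueError(f"covariate {name!r}: unknown kind {cov.kind!r}")
        unknown = set(self.log_odds) - set(self.resolved_covariates())
        if unknown:
            raise ValueError(f"log_odds refer to unknown covariates: {sorted(unknown)}")


def generate_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Simulate a matched case-control table.

    Returns a DataFrame with one row per subject-in-set: ``set_id``,
    ``patient_id``, ``is_case``, ``age_years`` and one column per covariate.
    Every set has exactly one case; within-set baseline ages differ by at
    most ``age_match_window_years``.  Deterministic per ``spec.seed``.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n = max(int(spec.cohort_factor * spec.n_sets), 400)
    ad = spec.age_dist
    age = np.clip(rng.normal(ad.mean, ad.sd, size=n), ad.low, ad.high)

    covs: dict[str, np.ndarray] = {}
    for name, cov in spec.resolved_covariates().items():
        if cov.kind == "bernoulli":
            covs[name] = (rng.random(n) < cov.prevalence).astype(float)
        else:
            slope = 0.0 if cov.age_slope is None else cov.age_slope
            covs[name] = (cov.mean + slope * (age - ad.mean)
                          + rng.normal(0.0, cov.sd, size=n))

    eta = np.zeros(n)
    for name, beta in spec.log_odds.items():
        eta += beta * covs[name]
    hazard = spec.baseline_rate * np.exp(eta - eta.mean())
    t_event = rng.exponential(1.0 / hazard)

    # half the matching window either side of the case's age keeps the
    # within-set age *spread* within the window
    half_w = spec.age_match_window_years / 2.0
    age_order = np.argsort(age, kind="stable")
    age_sorted = age[age_order]

    ratios = np.array(list(spec.controls_per_set_dist.keys()))
    ratio_p = np.array(list(spec.controls_per_set_dist.values()), dtype=float)

    case_order = np.argsort(t_event, kind="stable")
    rows_pid: list[int] = []
    rows_set: list[int] = []
    rows_case: list[bool] = []
    n_formed = 0
    for i in case_order:
        if n_formed >= spec.n_sets:
            break
        if t_event[i] > spec.followup_years:
            break  # no further events inside follow-up
        m = int(rng.choice(ratios, p=ratio_p))
        lo = np.searchsorted(age_sorted, age[i] - half_w, side="left")
        hi = np.searchsorted(age_sorted, age[i] + half_w, side="right")
        cand = age_order[lo:hi]
        cand = cand[(t_event[cand] > t_event[i]) & (cand != i)]
        if len(cand) < m:
            continue  # not enough age-matched subjects still at risk
        controls = rng.choice(cand, size=m, replace=False)
        rows_pid.append(int(i))
        rows_set.append(n_formed)
        rows_case.append(True)
        for j in controls:
            rows_pid.append(int(j))
            rows_set.append(n_formed)
            rows_case.append(False)
        n_formed += 1
    if n_formed < spec.n_sets:
        raise RuntimeError(
            f"only {n_formed}/{spec.n_sets} matched sets could be formed; "
            "increase cohort_factor, baseline_rate or the age window"
        )

    pid = np.array(rows_pid)
    data = {
        "set_id": np.array(rows_set),
        "patient_id": pid,
        "is_case": np.array(rows_case),
        "age_years": age[pid],
    }
    for name, x in covs.items():
        data[name] = x[pid]
    return pd.DataFrame(data)
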