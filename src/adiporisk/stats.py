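"""Matched case-control statistics.

The central tool is conditional logistic regression: with one case per
matched set, the within-set likelihood

    L(beta) = prod_sets  exp(x_case . beta) / sum_{j in set} exp(x_j . beta)

conditions out every set-level nuisance (here: age at diagnosis, via the
matched design), so the exponentiated coefficients are odds ratios
interpretable as rate ratios under incidence-density sampling.  The
likelihood is maximised by Newton-Raphson with step-halving; standard
errors come from the observed information, 95% CIs are Wald-based and
p-values are likelihood-ratio based.

Also here: pooled quartile coding (the patient-level exposure coding),
menopausal-status proxies from age, the P <= 0.1 multivariable entry rule
with optional interaction terms, and the standard group-comparison and
correlation tests.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "NonIdentifiableError", "ConvergenceError", "FitResult", "TestResult",
    "QuartileCoding", "assign_quartiles", "age_category", "crude_odds_ratio",
    "conditional_logistic_fit", "likelihood_ratio_test",
    "build_multivariable", "MultivariableResult", "group_comparisons",
    "normality_test",
]

_WALD_Z = 1.959964  # two-sided 95%


class NonIdentifiableError(ValueError):
    """A model term has no within-set variation anywhere in the data."""


class ConvergenceError(RuntimeError):
    """Newton iterations did not converge; carries the last iterate."""

    def __init__(self, msg: str, last_beta: np.ndarray):
        super().__init__(msg)
        self.last_beta = last_beta


# ---------------------------------------------------------------------------
# coding helpers


@dataclass(frozen=True)
class QuartileCoding:
    codes: np.ndarray            # 1..4 (0 for missing input values)
    boundaries: np.ndarray       # the 25/50/75 cut points
    q4_indicator: np.ndarray     # 1.0 for q4, 0.0 otherwise (NaN if missing)


def assign_quartiles(values, boundaries=None) -> QuartileCoding:
    """Pooled quartile coding with half-open [low, high) intervals.

    Cut points default to the 25th/50th/75th percentiles of the pooled
    finite values (linear interpolation).  A value equal to a cut point
    falls in the upper quartile, matching half-open interval coding.
    """
    v = np.asarray(values, dtype=float)
    finite = np.isfinite(v)
    if boundaries is None:
        if finite.sum() < 4:
            raise ValueError("need at least 4 finite values for quartiles")
        if np.ptp(v[finite]) == 0:
            raise ValueError("all values identical: quartiles undefined")
        boundaries = np.quantile(v[finite], [0.25, 0.50, 0.75])
    boundaries = np.asarray(boundaries, dtype=float)
    if boundaries.shape != (3,) or np.any(np.diff(boundaries) < 0):
        raise ValueError("boundaries must be 3 non-decreasing cut points")
    codes = np.zeros(v.shape, dtype=int)
    codes[finite] = 1 + np.searchsorted(boundaries, v[finite], side="right")
    q4 = np.where(finite, (codes == 4).astype(float), np.nan)
    return QuartileCoding(codes=codes, boundaries=boundaries, q4_indicator=q4)


_AGE_CATEGORIES = ("premenopausal", "perimenopausal", "postmenopausal")


def age_category(age_years):
    """Menopausal-status proxy: <45 pre, 45-<55 peri, >=55 postmenopausal."""
    a = np.asarray(age_years, dtype=float)
    if np.any(~np.isfinite(a)) or np.any(a <= 0):
        raise ValueError("ages must be positive and finite")
    idx = np.searchsorted([45.0, 55.0], a, side="right")
    if np.ndim(age_years) == 0:
        return _AGE_CATEGORIES[int(idx)]
    return np.array(_AGE_CATEGORIES, dtype=object)[idx]


def crude_odds_ratio(case_exposed: int, case_unexposed: int,
                     control_exposed: int, control_unexposed: int) -> float:
    """Contingency-table OR ignoring the matching.

    This is *not* the matched-set estimate: whenever the matching variable
    relates to exposure, the crude OR and the conditional OR differ.
    """
    if min(case_unexposed, control_exposed) <= 0:
        raise ValueError("crude OR undefined with zero off-diagonal counts")
    return (case_exposed * control_unexposed) / (case_unexposed * control_exposed)


# ---------------------------------------------------------------------------
# conditional logistic regression


@dataclass(frozen=True)
class FitResult:
    """Conditional-likelihood fit: log-ORs, Wald CIs and the log-likelihood."""

    terms: tuple[str, ...]
    beta: np.ndarray
    se: np.ndarray
    loglik: float
    n_sets_used: int
    n_iter: int
    converged: bool
    dropped_terms: tuple[str, ...] = ()
    separation: bool = False
    set_ids: frozenset = field(default_factory=frozenset, repr=False)

    @property
    def or_(self) -> np.ndarray:
        return np.exp(self.beta)

    @property
    def wald_ci_95(self) -> np.ndarray:
        lo = np.exp(self.beta - _WALD_Z * self.se)
        hi = np.exp(self.beta + _WALD_Z * self.se)
        return np.column_stack([lo, hi])

    def summary(self) -> pd.DataFrame:
        ci = self.wald_ci_95 if len(self.terms) else np.empty((0, 2))
        return pd.DataFrame({
            "term": list(self.terms),
            "beta": self.beta, "se": self.se, "or": self.or_,
            "ci_low": ci[:, 0] if len(self.terms) else [],
            "ci_high": ci[:, 1] if len(self.terms) else [],
        })


def _build_design(df: pd.DataFrame, terms: list[str],
                  scales: dict[str, float] | None) -> np.ndarray:
    cols = []
    for t in terms:
        if ":" in t:
            a, b = t.split(":", 1)
            col = df[a].to_numpy(float) * df[b].to_numpy(float)
        else:
            col = df[t].to_numpy(float)
        if scales and t in scales:
            col = col / scales[t]
        cols.append(col)
    if not cols:
        return np.empty((len(df), 0))
    return np.column_stack(cols)


def conditional_logistic_fit(
    records: pd.DataFrame,
    terms: list[str] | tuple[str, ...],
    scales: dict[str, float] | None = None,
    max_iter: int = 50,
    tol: float = 1e-8,
) -> FitResult:
    """Maximise the matched-set conditional likelihood.

    ``records`` needs ``set_id`` and boolean ``is_case`` columns plus the
    covariates named in ``terms`` (``"a:b"`` denotes the product
    interaction).  ``scales`` rescales a term's unit (e.g. ``{"area":
    1000}`` reports the OR per 10³ µm²).  Sets with any missing model
    covariate are dropped whole (set-level complete-case analysis).

    Raises :class:`NonIdentifiableError` for a term with no within-set
    variation anywhere; collinear terms are dropped with a warning.
    Non-convergence raises :class:`ConvergenceError` with the last iterate.
    """
    terms = list(terms)
    df = records.copy()
    needed = {c for t in terms for c in (t.split(":", 1) if ":" in t else [t])}
    missing_cols = needed - set(df.columns)
    if missing_cols:
        raise KeyError(f"missing covariate columns: {sorted(missing_cols)}")

    X_all = _build_design(df, terms, scales)
    ok_row = np.all(np.isfinite(X_all), axis=1) if terms else np.ones(len(df), bool)
    bad_sets = set(df.loc[~ok_row, "set_id"])
    if bad_sets:
        df = df[~df["set_id"].isin(bad_sets)].copy()
        X_all = _build_design(df, terms, scales)

    # order rows by set; validate the 1-case-per-set design
    df = df.reset_index(drop=True)
    order = np.argsort(df["set_id"].to_numpy(), kind="stable")
    set_arr = df["set_id"].to_numpy()[order]
    case_arr = df["is_case"].to_numpy(bool)[order]
    X = X_all[order]
    uniq, starts, counts = np.unique(set_arr, return_index=True, return_counts=True)
    cases_per_set = np.add.reduceat(case_arr.astype(int), starts)
    if np.any(cases_per_set != 1):
        raise ValueError("every matched set must contain exactly one case")
    informative = counts >= 2
    if informative.sum() < 2:
        raise ValueError("need at least 2 informative (case + control) sets")
    keep_rows = np.isin(set_arr, uniq[informative])
    set_arr, case_arr, X = set_arr[keep_rows], case_arr[keep_rows], X[keep_rows]
    uniq, starts = np.unique(set_arr, return_index=True)
    n_sets = len(uniq)
    row_set = np.searchsorted(uniq, set_arr)

    # identifiability: centre within sets, then rank-screen the columns
    kept_idx: list[int] = []
    dropped: list[str] = []
    if terms:
        set_means = np.add.reduceat(X, starts, axis=0) / \
            np.add.reduceat(np.ones(len(X)), starts)[:, None]
        Xc = X - set_means[row_set]
        norms = np.linalg.norm(Xc, axis=0)
        scale0 = max(norms.max(), 1.0)
        # order-preserving rank screen: earlier terms win over later copies
        Q = np.empty((Xc.shape[0], 0))
        for j, t in enumerate(terms):
            if norms[j] < 1e-10 * scale0:
                raise NonIdentifiableError(
                    f"term {t!r} has no within-set variation")
            v = Xc[:, j]
            r = v - Q @ (Q.T @ v)
            if np.linalg.norm(r) > 1e-8 * norms[j]:
                kept_idx.append(j)
                Q = np.column_stack([Q, r / np.linalg.norm(r)])
            else:
                dropped.append(t)
        if dropped:
            warnings.warn(
                f"dropping collinear term(s): {dropped}", stacklevel=2)
    X = X[:, kept_idx]
    kept_terms = tuple(terms[j] for j in kept_idx)
    p = X.shape[1]

    case_rows = np.nonzero(case_arr)[0]

    def _eval(beta, want_derivs=True):
        eta = X @ beta if p else np.zeros(len(X))
        m = np.maximum.reduceat(eta, starts)
        z = np.exp(eta - m[row_set])
        denom = np.add.reduceat(z, starts)
        ll = float(np.sum(eta[case_rows]) - np.sum(m + np.log(denom)))
        if not want_derivs:
            return ll, None, None
        w = z / denom[row_set]
        S = np.add.reduceat(w[:, None] * X, starts, axis=0) if p else \
            np.empty((n_sets, 0))
        g = X[case_rows].sum(axis=0) - S.sum(axis=0)
        info = X.T @ (w[:, None] * X) - S.T @ S
        return ll, g, info

    beta = np.zeros(p)
    ll, g, info = _eval(beta)
    n_iter = 0
    converged = p == 0
    for n_iter in range(1, max_iter + 1):
        if p == 0:
            break
        if np.max(np.abs(g)) < tol:
            converged = True
            break
        try:
            delta = np.linalg.solve(info, g)
        except np.linalg.LinAlgError as exc:  # pragma: no cover - defensive
            raise ConvergenceError(
                f"singular information matrix at iteration {n_iter}", beta
            ) from exc
        step = 1.0
        for _ in range(30):
            ll_new, _, _ = _eval(beta + step * delta, want_derivs=False)
            if ll_new >= ll - 1e-12:
                break
            step /= 2.0
        beta = beta + step * delta
        ll, g, info = _eval(beta)
    else:
        raise ConvergenceError(
            f"no convergence in {max_iter} Newton iterations "
            f"(max |gradient| = {np.max(np.abs(g)):.3g})", beta)

    separation = bool(p and np.max(np.abs(beta)) > 15.0)
    if separation:
        warnings.warn("very large |log-OR|: possible separation", stacklevel=2)
    if p:
        cov = np.linalg.inv(info)
        se = np.sqrt(np.diag(cov))
    else:
        se = np.empty(0)
    return FitResult(
        terms=kept_terms, beta=beta, se=se, loglik=ll,
        n_sets_used=n_sets, n_iter=n_iter, converged=converged,
        dropped_terms=tuple(dropped), separation=separation,
        set_ids=frozenset(uniq.tolist()),
    )


# ---------------------------------------------------------------------------
# inference


@dataclass(frozen=True)
class TestResult:
    statistic: float
    df: int | None
    p_value: float
    extra: dict = field(default_factory=dict)


def likelihood_ratio_test(fit_null: FitResult, fit_full: FitResult) -> TestResult:
    """LR test of nested conditional-logistic fits on identical sets."""
    if fit_null.set_ids != fit_full.set_ids:
        raise ValueError("fits use different matched sets; LR test invalid")
    if not set(fit_null.terms).issubset(fit_full.terms):
        raise ValueError("models are not nested")
    df = len(fit_full.terms) - len(fit_null.terms)
    stat = max(0.0, 2.0 * (fit_full.loglik - fit_null.loglik))
    p = float(sps.chi2.sf(stat, df)) if df > 0 else 1.0
    return TestResult(statistic=stat, df=df, p_value=p)


@dataclass(frozen=True)
class MultivariableResult:
    fit: FitResult | None
    inclusion_log: tuple[dict, ...]


def build_multivariable(
    records: pd.DataFrame,
    candidates: list[str],
    entry_p: float = 0.1,
    interactions: list[tuple[str, str]] | None = None,
    scales: dict[str, float] | None = None,
) -> MultivariableResult:
    """Screen candidates univariately and fit the multivariable model.

    Every candidate with a univariate likelihood-ratio p-value <= ``entry_p``
    enters the joint model.  Optional interaction terms between included
    main effects are LR-tested against the main-effects model and retained
    under the same rule.  All decisions are returned in the inclusion log.
    """
    if not candidates:
        raise ValueError("candidate list is empty")
    log: list[dict] = []
    included: list[str] = []
    for cand in candidates:
        fit_u = conditional_logistic_fit(records, [cand], scales=scales)
        null_u = conditional_logistic_fit(
            records[records["set_id"].isin(fit_u.set_ids)], [])
        p = likelihood_ratio_test(null_u, fit_u).p_value
        take = p <= entry_p
        log.append({"term": cand, "kind": "main", "p_lr": p, "included": take})
        if take:
            included.append(cand)
    if not included:
        warnings.warn("no candidate met the entry threshold: empty model",
                      stacklevel=2)
        return MultivariableResult(fit=None, inclusion_log=tuple(log))
    fit = conditional_logistic_fit(records, included, scales=scales)
    if interactions:
        for a, b in interactions:
            if a not in included or b not in included:
                log.append({"term": f"{a}:{b}", "kind": "interaction",
                            "p_lr": None, "included": False,
                            "note": "main effect(s) not in model"})
                continue
            fit_int = conditional_logistic_fit(
                records, included + [f"{a}:{b}"], scales=scales)
            base = conditional_logistic_fit(
                records[records["set_id"].isin(fit_int.set_ids)],
                included, scales=scales)
            p = likelihood_ratio_test(base, fit_int).p_value
            take = p <= entry_p
            log.append({"term": f"{a}:{b}", "kind": "interaction",
                        "p_lr": p, "included": take})
            if take:
                included = included + [f"{a}:{b}"]
                fit = fit_int
    return MultivariableResult(fit=fit, inclusion_log=tuple(log))


# ---------------------------------------------------------------------------
# group comparisons / correlation


def _check_groups(groups, min_groups=2):
    arrs = [np.asarray(g, dtype=float) for g in groups]
    if len(arrs) < min_groups:
        raise ValueError(f"need at least {min_groups} groups")
    for g in arrs:
        if len(g) < 2:
            raise ValueError("every group needs at least 2 observations")
    return arrs


def group_comparisons(groups, method: str) -> TestResult:
    """Two-sided location tests and Spearman correlation.

    ``groups`` is a sequence of per-group value arrays; for ``spearman`` it
    is the two paired vectors and the result carries rho with a Fisher-z
    95% CI in ``extra``.
    """
    if method == "spearman":
        x, y = _check_groups(groups, min_groups=2)
        if len(x) != len(y):
            raise ValueError("spearman needs paired vectors of equal length")
        rho, p = sps.spearmanr(x, y)
        n = len(x)
        if n > 3 and abs(rho) < 1.0:
            z = np.arctanh(rho)
            hw = _WALD_Z / np.sqrt(n - 3)
            ci = (float(np.tanh(z - hw)), float(np.tanh(z + hw)))
        else:
            ci = (float(rho), float(rho))
        return TestResult(statistic=float(rho), df=None, p_value=float(p),
                          extra={"rho_ci_95": ci, "n": n})
    arrs = _check_groups(groups)
    if method == "mann_whitney":
        if len(arrs) != 2:
            raise ValueError("mann_whitney needs exactly 2 groups")
        stat, p = sps.mannwhitneyu(*arrs, alternative="two-sided")
        return TestResult(float(stat), None, float(p))
    if method == "kruskal_wallis":
        stat, p = sps.kruskal(*arrs)
        return TestResult(float(stat), len(arrs) - 1, float(p))
    if method == "t_test":
        if len(arrs) != 2:
            raise ValueError("t_test needs exactly 2 groups")
        stat, p = sps.ttest_ind(*arrs)
        return TestResult(float(stat), len(arrs[0]) + len(arrs[1]) - 2, float(p))
    if method == "anova":
        stat, p = sps.f_oneway(*arrs)
        return TestResult(float(stat), len(arrs) - 1, float(p))
    raise ValueError(f"unknown method {method!r}")


def normality_test(values) -> TestResult:
    """Shapiro-Wilk departure-from-normality screen."""
    v = np.asarray(values, dtype=float)
    if len(v) < 3:
        raise ValueError("Shapiro-Wilk needs at least 3 observations")
    stat, p = sps.shapiro(v)
    return TestResult(float(stat), None, float(p))
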