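"""Survival stratification by the imaging phenotype.

Median split on EV/CV, Kaplan-Meier product-limit curves, the two-group
log-rank test, a Cox proportional-hazards fit with Efron tie handling
(Newton-Raphson on the partial likelihood, relative log-likelihood
convergence < 1e-9, max 100 iterations), age subgroup analyses, and the
mesenchymal-vs-rest phenotype comparison by pooled-variance t-test.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .ce_association import CE_HIGH, CE_LOW, GroupAssignment
from .errors import ConfigError, DataError, FitError

__all__ = [
    "median_split",
    "KMCurve",
    "km_estimate",
    "LogrankResult",
    "logrank_test",
    "CoxResult",
    "cox_fit",
    "cox_score_test",
    "SurvivalComparison",
    "compare_groups",
    "age_subgroup_analysis",
    "TTestResult",
    "compare_ratio_by_subtype",
]


def median_split(features: pd.DataFrame) -> GroupAssignment:
    """Dichotomize by the median EV/CV ratio.

    Samples strictly above the median are CE-high; samples at or below it
    are CE-low (median ties go to CE-low by documented convention).
    """
    ratios = features["ratio"]
    if len(ratios) < 2:
        raise DataError(f"need at least 2 samples to split, got {len(ratios)}")
    if ratios.nunique() == 1:
        raise DataError("all EV/CV ratios identical: no median split possible")
    med = float(ratios.median())
    groups = pd.Series(
        np.where(ratios > med, CE_HIGH, CE_LOW),
        index=features.index,
        name="group",
    )
    return GroupAssignment(groups=groups, k=0)


@dataclass
class KMCurve:
    """Product-limit estimate over the distinct event times."""

    times: np.ndarray
    n_risk: np.ndarray
    n_event: np.ndarray
    survival: np.ndarray
    n_subjects: int

    @property
    def median_time(self) -> float:
        """Smallest time with S(t) <= 0.5, NaN if never reached."""
        below = self.times[self.survival <= 0.5]
        return float(below[0]) if below.size else float("nan")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time": self.times,
                "n_risk": self.n_risk,
                "n_event": self.n_event,
                "survival": self.survival,
            }
        )


def _check_surv(times, events) -> tuple[np.ndarray, np.ndarray]:
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    if t.shape != e.shape or t.ndim != 1:
        raise DataError("times and events must be 1-d and equal length")
    if t.size == 0:
        raise DataError("need at least one subject")
    if np.any(~np.isfinite(t)) or np.any(t <= 0):
        raise DataError("survival times must be positive and finite")
    if not np.isin(e, [0, 1]).all():
        raise DataError("event flags must be 0 or 1")
    return t, e


def km_estimate(times, events) -> KMCurve:
    """Kaplan-Meier product-limit estimator at the distinct event times."""
    t, e = _check_surv(times, events)
    ev_times = np.unique(t[e == 1])
    n_risk = np.array([(t >= u).sum() for u in ev_times], dtype=int)
    n_event = np.array([((t == u) & (e == 1)).sum() for u in ev_times], dtype=int)
    with np.errstate(invalid="ignore"):
        surv = np.cumprod(1.0 - n_event / n_risk)
    return KMCurve(
        times=ev_times,
        n_risk=n_risk,
        n_event=n_event,
        survival=surv,
        n_subjects=t.size,
    )


@dataclass(frozen=True)
class LogrankResult:
    chi2: float
    p: float

    @property
    def defined(self) -> bool:
        return not math.isnan(self.chi2)


def logrank_test(times_a, events_a, times_b, events_b) -> LogrankResult:
    """Two-group log-rank test: chi2 = (sum O - sum E)^2 / sum V, 1 df.

    With no events anywhere the statistic is undefined and reported as
    missing (NaN), never as zero.
    """
    ta, ea = _check_surv(times_a, events_a)
    tb, eb = _check_surv(times_b, events_b)
    t = np.concatenate([ta, tb])
    e = np.concatenate([ea, eb])
    in_a = np.concatenate([np.ones_like(ta, bool), np.zeros_like(tb, bool)])
    if e.sum() == 0:
        return LogrankResult(float("nan"), float("nan"))
    o_minus_e = 0.0
    var = 0.0
    for u in np.unique(t[e == 1]):
        at_risk = t >= u
        n = at_risk.sum()
        n1 = (at_risk & in_a).sum()
        d = ((t == u) & (e == 1)).sum()
        d1 = ((t == u) & (e == 1) & in_a).sum()
        o_minus_e += d1 - d * n1 / n
        if n > 1:
            var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    if var == 0:
        return LogrankResult(float("nan"), float("nan"))
    chi2 = o_minus_e**2 / var
    return LogrankResult(float(chi2), float(stats.chi2.sf(chi2, df=1)))


# ---------------------------------------------------------------------------
# Cox proportional hazards (Efron ties)


def _efron_quantities(t, e, X, beta):
    """Partial log-likelihood, score vector and information matrix.

    Subjects are pre-sorted by descending time so risk-set sums are prefix
    cumulative sums.
    """
    n, p = X.shape
    eta = X @ beta
    eta = np.clip(eta, -500, 500)
    w = np.exp(eta)
    wx = w[:, None] * X
    wxx = wx[:, :, None] * X[:, None, :]

    c0 = np.cumsum(w)
    c1 = np.cumsum(wx, axis=0)
    c2 = np.cumsum(wxx, axis=0)

    ll = 0.0
    score = np.zeros(p)
    info = np.zeros((p, p))
    i = 0
    while i < n:
        j = i
        while j < n and t[j] == t[i]:
            j += 1
        # block [i, j): all subjects with this time; risk set = [0, j)
        d_idx = np.arange(i, j)[e[i:j] == 1]
        d = d_idx.size
        if d:
            s0r = c0[j - 1]
            s1r = c1[j - 1]
            s2r = c2[j - 1]
            s0d = w[d_idx].sum()
            s1d = wx[d_idx].sum(axis=0)
            s2d = wxx[d_idx].sum(axis=0)
            ll += eta[d_idx].sum()
            score += X[d_idx].sum(axis=0)
            for l in range(d):
                frac = l / d
                phi = s0r - frac * s0d
                psi = s1r - frac * s1d
                chi = s2r - frac * s2d
                ll -= np.log(phi)
                score -= psi / phi
                info += chi / phi - np.outer(psi, psi) / phi**2
        i = j
    return ll, score, info


def _prepare_design(times, events, covariates):
    t, e = _check_surv(times, events)
    X = np.asarray(covariates, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if X.shape[0] != t.size:
        raise DataError("covariate rows must match the number of subjects")
    if not np.isfinite(X).all():
        raise DataError("covariates must be finite")
    const = np.all(X == X[0, :], axis=0)
    if const.any():
        raise ConfigError(
            f"covariate column(s) {np.flatnonzero(const).tolist()} are "
            "constant: no information"
        )
    order = np.argsort(-t, kind="stable")
    return t[order], e[order], X[order]


@dataclass
class CoxResult:
    """Per-covariate hazard ratios from the Efron partial likelihood."""

    names: list[str]
    coef: np.ndarray
    se: np.ndarray
    loglik: float
    n_iter: int
    n: int
    n_events: int
    hr: np.ndarray = field(init=False)
    ci_low: np.ndarray = field(init=False)
    ci_high: np.ndarray = field(init=False)
    p: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        z = self.coef / self.se
        zcrit = stats.norm.ppf(0.975)
        self.hr = np.exp(self.coef)
        self.ci_low = np.exp(self.coef - zcrit * self.se)
        self.ci_high = np.exp(self.coef + zcrit * self.se)
        self.p = 2.0 * stats.norm.sf(np.abs(z))

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "coef": self.coef,
                "hr": self.hr,
                "ci_low": self.ci_low,
                "ci_high": self.ci_high,
                "p": self.p,
            },
            index=pd.Index(self.names, name="covariate"),
        )


def cox_fit(
    times, events, covariates, names: list[str] | None = None,
    tol: float = 1e-9, max_iter: int = 100,
) -> CoxResult:
    """Newton-Raphson maximization of the Efron partial likelihood.

    Convergence when the relative log-likelihood change drops below ``tol``;
    monotone likelihood (perfect separation) and non-convergence raise
    :class:`FitError` with a diagnostic.
    """
    t, e, X = _prepare_design(times, events, covariates)
    n, p = X.shape
    n_events = int(e.sum())
    if n_events < p:
        raise DataError(
            f"{n_events} events cannot support {p} covariate(s)"
        )
    if names is None:
        names = [f"x{i}" for i in range(p)]
    beta = np.zeros(p)
    ll, score, info = _efron_quantities(t, e, X, beta)
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        try:
            step = np.linalg.solve(info, score)
        except np.linalg.LinAlgError:
            raise FitError("singular information matrix in Cox fit")
        # step-halving to guarantee likelihood ascent
        new_ll = -np.inf
        for _ in range(30):
            cand = beta + step
            new_ll, new_score, new_info = _efron_quantities(t, e, X, cand)
            if new_ll >= ll or not np.isfinite(new_ll):
                break
            step = step / 2.0
        if not np.isfinite(new_ll):
            raise FitError("non-finite partial likelihood in Cox fit")
        rel = abs(new_ll - ll) / (abs(ll) + 1.0)
        beta, ll, score, info = cand, new_ll, new_score, new_info
        if np.abs(beta).max() > 50:
            raise FitError(
                "monotone likelihood (perfect separation): coefficient "
                f"diverged to {beta}"
            )
        if rel < tol:
            break
    else:
        raise FitError(f"Cox fit did not converge in {max_iter} iterations")
    try:
        cov = np.linalg.inv(info)
    except np.linalg.LinAlgError:
        raise FitError("singular information matrix at the Cox solution")
    se = np.sqrt(np.diag(cov))
    if np.any(se > 100):
        raise FitError(
            "monotone likelihood (perfect separation): standard error "
            f"diverged ({se})"
        )
    return CoxResult(
        names=list(names), coef=beta, se=se, loglik=float(ll),
        n_iter=n_iter, n=n, n_events=n_events,
    )


def cox_score_test(times, events, covariates) -> tuple[float, float]:
    """Score (Rao) test of beta = 0 for the Cox model.

    With a single binary covariate and no tied event times this equals the
    log-rank chi-square.
    """
    t, e, X = _prepare_design(times, events, covariates)
    _, score, info = _efron_quantities(t, e, X, np.zeros(X.shape[1]))
    chi2 = float(score @ np.linalg.solve(info, score))
    return chi2, float(stats.chi2.sf(chi2, df=X.shape[1]))


# ---------------------------------------------------------------------------
# Cohort-level comparisons


@dataclass
class SurvivalComparison:
    """KM curves per group plus log-rank (and optional Cox) statistics."""

    km_curves: dict[str, KMCurve]
    logrank: LogrankResult
    n_per_group: dict[str, int]
    cox: CoxResult | None = None
    evaluable: bool = True
    note: str = ""


def compare_groups(
    groups: GroupAssignment,
    clinical: pd.DataFrame,
    with_cox: bool = True,
) -> SurvivalComparison:
    """KM + log-rank for CE-high vs CE-low; Cox adjusts the split for age."""
    merged = clinical.join(groups.groups, how="inner")
    sub = {
        name: merged[merged["group"] == name] for name in (CE_HIGH, CE_LOW)
    }
    for name, df in sub.items():
        if df.empty:
            raise DataError(f"group {name} has no samples with clinical data")
    km = {
        name: km_estimate(df["os_time"], df["os_event"])
        for name, df in sub.items()
    }
    lr = logrank_test(
        sub[CE_HIGH]["os_time"], sub[CE_HIGH]["os_event"],
        sub[CE_LOW]["os_time"], sub[CE_LOW]["os_event"],
    )
    cox = None
    if with_cox:
        both = pd.concat([sub[CE_HIGH], sub[CE_LOW]])
        design = np.column_stack(
            [(both["group"] == CE_HIGH).astype(float), both["age"]]
        )
        try:
            cox = cox_fit(
                both["os_time"], both["os_event"], design,
                names=["ce_high", "age"],
            )
        except (FitError, ConfigError, DataError):
            cox = None
    return SurvivalComparison(
        km_curves=km,
        logrank=lr,
        n_per_group={k: len(v) for k, v in sub.items()},
        cox=cox,
    )


def age_subgroup_analysis(
    features: pd.DataFrame,
    clinical: pd.DataFrame,
    cutoff: float = 60.0,
    global_median: bool = False,
) -> dict[str, SurvivalComparison]:
    """Median split + KM + log-rank within age strata (< cutoff, >= cutoff).

    By default the EV/CV median is recomputed within each stratum
    (``global_median=True`` reuses the whole-cohort split instead). An
    empty or unsplittable stratum is reported not-evaluable, not raised.
    """
    shared = features.index.intersection(clinical.index)
    feats = features.loc[shared]
    clin = clinical.loc[shared]
    strata = {
        "younger": clin.index[clin["age"] < cutoff],
        "older": clin.index[clin["age"] >= cutoff],
    }
    full_split = None
    if global_median:
        full_split = median_split(feats)
    out: dict[str, SurvivalComparison] = {}
    for name, ids in strata.items():
        if len(ids) < 4:
            out[name] = SurvivalComparison(
                km_curves={}, logrank=LogrankResult(float("nan"), float("nan")),
                n_per_group={}, evaluable=False,
                note=f"stratum {name} has {len(ids)} samples; not evaluable",
            )
            continue
        try:
            if global_median:
                ga = GroupAssignment(
                    groups=full_split.groups.loc[ids], k=0
                )
            else:
                ga = median_split(feats.loc[ids])
            out[name] = compare_groups(ga, clin.loc[ids], with_cox=False)
        except (DataError, ConfigError) as exc:
            out[name] = SurvivalComparison(
                km_curves={}, logrank=LogrankResult(float("nan"), float("nan")),
                n_per_group={}, evaluable=False, note=str(exc),
            )
    return out


@dataclass(frozen=True)
class TTestResult:
    t: float
    p: float
    mean_a: float
    mean_b: float
    n_a: int
    n_b: int
    infinite_separation: bool = False


def compare_ratio_by_subtype(
    features: pd.DataFrame, clinical: pd.DataFrame,
    subtype: str = "mesenchymal",
) -> TTestResult:
    """Pooled-variance two-sided t-test of EV/CV: one subtype vs the rest.

    Zero pooled variance with unequal means is reported as an
    infinite-separation flag (t undefined) instead of applying an epsilon.
    """
    shared = features.index.intersection(clinical.index)
    ratios = features.loc[shared, "ratio"]
    labels = clinical.loc[shared, "subtype"]
    a = ratios[labels == subtype].to_numpy()
    b = ratios[labels != subtype].to_numpy()
    if a.size < 2 or b.size < 2:
        raise DataError(
            f"need >= 2 samples per pool; got {a.size} {subtype} and "
            f"{b.size} others"
        )
    df = a.size + b.size - 2
    sp2 = ((a.size - 1) * a.var(ddof=1) + (b.size - 1) * b.var(ddof=1)) / df
    if sp2 == 0:
        if a.mean() == b.mean():
            return TTestResult(0.0, 1.0, a.mean(), b.mean(), a.size, b.size)
        return TTestResult(
            float("nan"), float("nan"), a.mean(), b.mean(), a.size, b.size,
            infinite_separation=True,
        )
    tstat = (a.mean() - b.mean()) / math.sqrt(sp2 * (1 / a.size + 1 / b.size))
    return TTestResult(
        float(tstat), float(2.0 * stats.t.sf(abs(tstat), df)),
        float(a.mean()), float(b.mean()), a.size, b.size,
    )
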