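"""Kaplan-Meier estimation, log-rank comparison and outcome-restricted logistic models.

Survival stratification of score-defined groups follows the standard
right-censored toolkit: the product-limit estimator (fit through lifelines)
with Greenwood variance and complementary-log-log confidence intervals, the
two-group log-rank test built from the per-event-time hypergeometric tables,
and a multivariate logistic regression on the outcome-restricted subset
(patients who died of disease or survived at least ``min_followup`` years),
fit by maximum likelihood (IRLS) through statsmodels with Wald p-values.

Conventions: subjects censored exactly at an event time remain in the risk
set at that time; log-rank ties use the multiple-event hypergeometric
variance correction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from lifelines import KaplanMeierFitter
from scipy import stats

from .io import ClinicalTable

__all__ = [
    "KMCurve",
    "SurvivalEstimate",
    "LogrankResult",
    "LogisticFit",
    "km_estimate",
    "survival_at",
    "logrank_test",
    "restrict_outcome_subset",
    "multivariate_logistic",
]


@dataclass(frozen=True)
class KMCurve:
    """Product-limit estimate tabulated at the distinct event times.

    ``survival[i]`` is S(t) just after ``event_times[i]``; ``greenwood_var``
    is the accumulated Greenwood variance of S at that point (NaN once the
    estimate reaches 0, where the variance formula degenerates).
    """

    event_times: np.ndarray
    at_risk: np.ndarray
    events: np.ndarray
    survival: np.ndarray
    greenwood_var: np.ndarray
    max_followup: float
    n_subjects: int

    def __post_init__(self) -> None:
        if np.any(np.diff(self.survival) > 1e-12):
            raise ValueError("survival estimate must be non-increasing")


@dataclass(frozen=True)
class SurvivalEstimate:
    estimate: float
    ci_lower: float
    ci_upper: float
    conf: float
    extrapolated: bool


@dataclass(frozen=True)
class LogrankResult:
    chi2: float
    df: int
    p: float
    group_levels: tuple[str, str]
    observed: tuple[float, float]
    expected: tuple[float, float]


@dataclass(frozen=True)
class LogisticFit:
    """Per-covariate coefficients, odds ratios and Wald p-values (+ intercept)."""

    table: pd.DataFrame  # index: term; columns: coef, odds_ratio, p
    n_used: int
    n_excluded: int
    converged: bool
    separation: bool

    def odds_ratio(self, term: str) -> float:
        return float(self.table.loc[term, "odds_ratio"])

    def p_value(self, term: str) -> float:
        return float(self.table.loc[term, "p"])


def _check_times_events(times, events) -> tuple[np.ndarray, np.ndarray]:
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if times.shape != events.shape or times.ndim != 1 or times.size < 1:
        raise ValueError("times and events must be equal-length nonempty vectors")
    if not np.all(np.isfinite(times)) or (times < 0).any():
        raise ValueError("times must be finite and >= 0")
    if not np.isin(events, (0, 1)).all():
        raise ValueError("events must be 0/1")
    return times, events


def km_estimate(times, events) -> KMCurve:
    """Kaplan-Meier product-limit estimator with Greenwood variance."""
    times, events = _check_times_events(times, events)
    kmf = KaplanMeierFitter()
    kmf.fit(times, event_observed=events)
    table = kmf.event_table
    ev = table[table["observed"] > 0]
    event_times = ev.index.to_numpy(dtype=float)
    at_risk = ev["at_risk"].to_numpy(dtype=int)
    d = ev["observed"].to_numpy(dtype=int)
    surv = kmf.survival_function_["KM_estimate"].reindex(event_times).to_numpy(dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = d / (at_risk * (at_risk - d)).astype(float)
        greenwood = surv**2 * np.cumsum(terms)
    greenwood[surv == 0] = np.nan
    return KMCurve(
        event_times=event_times,
        at_risk=at_risk,
        events=d,
        survival=surv,
        greenwood_var=greenwood,
        max_followup=float(times.max()),
        n_subjects=int(times.size),
    )


def survival_at(curve: KMCurve, t: float, conf: float = 0.95) -> SurvivalEstimate:
    """Evaluate S(t) with a complementary-log-log Greenwood confidence interval.

    The log-log transform keeps the interval inside [0, 1] and matches the
    asymmetric intervals conventionally reported for small risk sets.  A
    query beyond the last follow-up time returns the last value flagged as
    extrapolated.
    """
    if t < 0:
        raise ValueError("t must be >= 0")
    extrapolated = t > curve.max_followup
    idx = int(np.searchsorted(curve.event_times, t, side="right")) - 1
    if idx < 0:
        return SurvivalEstimate(1.0, 1.0, 1.0, conf, extrapolated)
    s = float(curve.survival[idx])
    var = float(curve.greenwood_var[idx])
    if s <= 0.0:
        return SurvivalEstimate(0.0, 0.0, 0.0, conf, extrapolated)
    if s >= 1.0 or not np.isfinite(var) or var == 0.0:
        return SurvivalEstimate(s, s, s, conf, extrapolated)
    z = stats.norm.ppf(0.5 + conf / 2)
    se_cll = np.sqrt(var) / (s * abs(np.log(s)))
    lower = float(np.clip(s ** np.exp(z * se_cll), 0.0, 1.0))
    upper = float(np.clip(s ** np.exp(-z * se_cll), 0.0, 1.0))
    return SurvivalEstimate(s, lower, upper, conf, extrapolated)


def logrank_test(times, events, groups) -> LogrankResult:
    """Two-group log-rank test from the per-event-time hypergeometric tables.

    At each distinct event time the observed events in group 1 are compared
    with their conditional (hypergeometric) expectation given the risk sets;
    the squared standardized sum is chi-square with 1 df.
    """
    times, events = _check_times_events(times, events)
    groups = np.asarray(groups)
    levels = np.unique(groups)
    if len(levels) != 2:
        raise ValueError(f"need exactly 2 group levels, got {list(levels)}")
    if events.sum() == 0:
        raise ValueError("no events observed; log-rank test undefined")

    order = np.argsort(times, kind="stable")
    t, e, in1 = times[order], events[order], (groups[order] == levels[0])
    n = t.size
    n1 = int(in1.sum())
    uniq_t, first_idx = np.unique(t, return_index=True)
    # events per distinct time, overall and in group 1
    seg = np.append(first_idx, n)
    cum_e = np.concatenate(([0], np.cumsum(e)))
    cum_e1 = np.concatenate(([0], np.cumsum(e & in1)))
    cum_g1 = np.concatenate(([0], np.cumsum(in1)))
    d = cum_e[seg[1:]] - cum_e[seg[:-1]]
    d1 = cum_e1[seg[1:]] - cum_e1[seg[:-1]]
    n_at = n - first_idx
    n1_at = n1 - cum_g1[first_idx]

    mask = d > 0
    d, d1, n_at, n1_at = d[mask], d1[mask], n_at[mask], n1_at[mask]
    frac1 = n1_at / n_at
    e1 = d * frac1
    with np.errstate(divide="ignore", invalid="ignore"):
        v = d * frac1 * (1 - frac1) * (n_at - d) / (n_at - 1)
    v[n_at <= 1] = 0.0
    o1, exp1, var = float(d1.sum()), float(e1.sum()), float(v.sum())
    total = float(d.sum())
    chi2 = 0.0 if var == 0 else (o1 - exp1) ** 2 / var
    p = float(stats.chi2.sf(chi2, df=1)) if var > 0 else 1.0
    return LogrankResult(
        chi2=float(chi2),
        df=1,
        p=p,
        group_levels=(str(levels[0]), str(levels[1])),
        observed=(o1, total - o1),
        expected=(exp1, total - exp1),
    )


def restrict_outcome_subset(
    clinical: ClinicalTable, min_followup: float = 3.0
) -> tuple[np.ndarray, list[str]]:
    """Binary-outcome subset: deaths, plus survivors followed >= ``min_followup`` years.

    Censored subjects with shorter follow-up carry no usable outcome and are
    dropped.  Returns (outcome vector: 1 = died, 0 = long-term survivor,
    kept sample ids).
    """
    df = clinical.data
    died = df["os_event"] == 1
    long_survivor = (df["os_event"] == 0) & (df["os_time"] >= min_followup)
    kept = df[died | long_survivor]
    if kept.empty:
        raise ValueError("outcome restriction leaves no samples")
    outcome = (kept["os_event"] == 1).to_numpy(dtype=int)
    return outcome, list(kept["sample_id"])


_SEPARATION_COEF_BOUND = 15.0  # on standardized covariates


def multivariate_logistic(outcome, covariates: pd.DataFrame) -> LogisticFit:
    """Maximum-likelihood logistic regression with Wald inference.

    Rows with missing covariate values are excluded (counted in
    ``n_excluded``).  Fitting runs through statsmodels' IRLS/Newton solver
    (tolerance 1e-8, at most 100 iterations).  Quasi-complete separation is
    flagged — any standardized coefficient beyond 15 in magnitude, or solver
    failure — and returned as ``converged=False`` rather than raised: the
    coefficient estimates are then unreliable.
    """
    outcome = np.asarray(outcome, dtype=float)
    if covariates.shape[1] < 1:
        raise ValueError("need at least one covariate")
    if len(outcome) != len(covariates):
        raise ValueError("outcome and covariates lengths differ")
    x = covariates.astype(float)
    complete = ~x.isna().any(axis=1).to_numpy()
    n_excluded = int((~complete).sum())
    x, y = x.loc[complete], outcome[complete]
    if len(np.unique(y)) < 2:
        raise ValueError("outcome has a single class; logistic model undefined")
    stds = x.to_numpy().std(axis=0)
    constant = [c for c, s in zip(x.columns, stds) if s == 0]
    if constant:
        raise ValueError(f"constant covariates: {constant}")

    design = sm.add_constant(x, has_constant="add")
    converged, separation = True, False
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            fit = sm.Logit(y, design).fit(disp=0, maxiter=100, tol=1e-8)
            converged = bool(fit.mle_retvals.get("converged", True))
            params, pvalues = fit.params, fit.pvalues
        except Exception:
            # Newton can fail outright under perfect separation; the IRLS GLM
            # path returns the diverging estimate instead, which the
            # standardized-coefficient check below flags.
            glm = sm.GLM(y, design, family=sm.families.Binomial())
            fit = glm.fit(maxiter=100, tol=1e-8)
            converged = False
            params, pvalues = fit.params, fit.pvalues

    std_coefs = params.drop("const").to_numpy() * stds
    if np.any(np.abs(std_coefs) > _SEPARATION_COEF_BOUND) or not np.all(
        np.isfinite(params.to_numpy())
    ):
        separation = True
        converged = False

    table = pd.DataFrame(
        {
            "coef": params,
            "odds_ratio": np.exp(params),
            "p": pvalues,
        }
    )
    return LogisticFit(
        table=table,
        n_used=int(len(y)),
        n_excluded=n_excluded,
        converged=converged,
        separation=separation,
    )
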