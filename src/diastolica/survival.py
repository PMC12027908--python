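"""Survival-analysis workflow: descriptives, Kaplan-Meier, Cox, BIC stepwise.

The statistical chain mirrors common clinical-cohort practice: Shapiro-Wilk
normality routing of continuous variables to t-test / Mann-Whitney summaries,
Fisher's exact test for categorical variables, Kaplan-Meier curves for
median-dichotomized predictors, Cox proportional-hazards regression (Efron tie
handling, via lifelines), forward stepwise selection by the Bayesian
information criterion with the number of *events* as the BIC sample size,
percentile bootstrap confidence intervals over patient resamples, and
Harrell's concordance index.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import (
    BootstrapError,
    ConcordanceError,
    ConvergenceError,
    DegeneracyError,
    DegenerateSplitError,
    ParameterError,
)

__all__ = [
    "KMCurve",
    "CoxFit",
    "SelectedModel",
    "median_dichotomize",
    "kaplan_meier",
    "fit_cox",
    "cox_partial_loglik",
    "bootstrap_ci",
    "stepwise_bic",
    "harrell_c",
    "compare_descriptives",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class KMCurve:
    """Product-limit survival estimate evaluated at the event times."""

    event_times: np.ndarray            # years, distinct times with >= 1 event
    survival_probabilities: np.ndarray  # S(t) just after each event time
    at_risk: np.ndarray                # risk-set size just before each event time

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time": self.event_times,
                "survival": self.survival_probabilities,
                "at_risk": self.at_risk,
            }
        )


@dataclass(frozen=True)
class CoxFit:
    """A fitted proportional-hazards model."""

    names: tuple[str, ...]
    coefficients: np.ndarray
    hazard_ratios: np.ndarray
    ci_lower: np.ndarray          # on the HR scale
    ci_upper: np.ndarray
    p_values: np.ndarray          # Wald
    log_partial_likelihood: float
    n_events: int
    ci_method: str = "wald"       # "wald" | "bootstrap"

    def linear_predictor(self, X: pd.DataFrame) -> np.ndarray:
        return X[list(self.names)].to_numpy(dtype=float) @ self.coefficients

    def summary_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "coef": self.coefficients,
                "HR": self.hazard_ratios,
                "ci_lower": self.ci_lower,
                "ci_upper": self.ci_upper,
                "p": self.p_values,
            },
            index=list(self.names),
        )


@dataclass(frozen=True)
class SelectedModel:
    """Result of forward stepwise selection by BIC."""

    selected: tuple[str, ...]
    bic_trajectory: tuple[float, ...]  # BIC of the null model then each accepted step
    final_fit: CoxFit | None
    c_statistic: float | None


def median_dichotomize(values: Sequence[float] | np.ndarray) -> tuple[float, np.ndarray]:
    """Split at the sample median; indicator is 1 strictly above the cut-off."""
    x = np.asarray(values, dtype=float)
    x = x[np.isfinite(x)]
    if len(x) < 2:
        raise ParameterError("need at least 2 finite values")
    if np.all(x == x[0]):
        raise DegenerateSplitError("all values identical: no median split exists")
    cutoff = float(np.median(x))
    indicator = (np.asarray(values, dtype=float) > cutoff).astype(int)
    return cutoff, indicator


def kaplan_meier(times: np.ndarray, events: np.ndarray) -> KMCurve:
    """Kaplan-Meier product-limit estimator (via lifelines)."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if len(times) != len(events):
        raise ParameterError("times and events must have equal length")
    if np.any(times <= 0):
        raise ParameterError("times must be positive")

    from lifelines import KaplanMeierFitter

    kmf = KaplanMeierFitter()
    kmf.fit(times, events)
    table = kmf.event_table
    has_event = table["observed"] > 0
    event_times = table.index.to_numpy(dtype=float)[has_event]
    at_risk = table["at_risk"].to_numpy(dtype=float)[has_event]
    surv = kmf.survival_function_at_times(event_times).to_numpy(dtype=float)
    return KMCurve(event_times=event_times, survival_probabilities=surv, at_risk=at_risk)


def cox_partial_loglik(
    lp: np.ndarray, times: np.ndarray, events: np.ndarray
) -> float:
    """Efron partial log-likelihood for a fixed linear predictor.

    Used for the null model in stepwise selection (``lp = 0``) and as an
    internal consistency check against the fitted likelihood.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    lp = np.broadcast_to(np.asarray(lp, dtype=float), times.shape)
    theta = np.exp(lp)
    ll = 0.0
    for t in np.unique(times[events == 1]):
        dead = (times == t) & (events == 1)
        at_risk = times >= t
        d = int(dead.sum())
        risk_sum = float(theta[at_risk].sum())
        dead_sum = float(theta[dead].sum())
        ll += float(lp[dead].sum())
        for l in range(d):
            ll -= np.log(risk_sum - (l / d) * dead_sum)
    return float(ll)


def fit_cox(
    X: pd.DataFrame,
    times: np.ndarray,
    events: np.ndarray,
    tie_method: str = "efron",
    bootstrap_B: int | None = None,
    bootstrap_seed: int | None = None,
) -> CoxFit:
    """Maximize the Cox partial likelihood (Efron ties) over ``X``.

    Wald p-values always; confidence intervals are Wald by default, or
    percentile-bootstrap over patient resamples when ``bootstrap_B`` is given.
    """
    if tie_method != "efron":
        raise ParameterError(f"only Efron tie handling is supported, got {tie_method!r}")
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    n_events = int(events.sum())
    if n_events < 1:
        raise DegeneracyError("no events: Cox model is unidentifiable")
    if X.shape[1] >= len(X):
        raise DegeneracyError("more covariates than subjects")
    constant = [c for c in X.columns if np.ptp(X[c].to_numpy(dtype=float)) == 0]
    if constant:
        raise DegeneracyError(f"constant covariate(s): {constant}")

    from lifelines import CoxPHFitter
    from lifelines.exceptions import ConvergenceError as _LLConvergenceError

    df = X.copy()
    df["__time__"] = times
    df["__event__"] = events
    cph = CoxPHFitter()
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph.fit(df, duration_col="__time__", event_col="__event__")
    except _LLConvergenceError as exc:
        raise ConvergenceError(
            f"partial-likelihood maximization did not converge "
            f"(possible monotone likelihood / perfect separation): {exc}"
        ) from exc

    names = tuple(X.columns)
    coef = cph.params_.reindex(list(names)).to_numpy(dtype=float)
    summary = cph.summary
    p = summary["p"].reindex(list(names)).to_numpy(dtype=float)
    with np.errstate(over="ignore"):
        lo = np.exp(summary["coef lower 95%"].reindex(list(names)).to_numpy(dtype=float))
        hi = np.exp(summary["coef upper 95%"].reindex(list(names)).to_numpy(dtype=float))
    fit = CoxFit(
        names=names,
        coefficients=coef,
        hazard_ratios=np.exp(coef),
        ci_lower=lo,
        ci_upper=hi,
        p_values=p,
        log_partial_likelihood=float(cph.log_likelihood_),
        n_events=n_events,
        ci_method="wald",
    )
    if bootstrap_B:
        fit = _attach_bootstrap_cis(fit, X, times, events, bootstrap_B, bootstrap_seed)
    return fit


def _attach_bootstrap_cis(
    fit: CoxFit,
    X: pd.DataFrame,
    times: np.ndarray,
    events: np.ndarray,
    B: int,
    seed: int | None,
) -> CoxFit:
    data = X.copy()
    data["__time__"] = times
    data["__event__"] = events
    names = list(fit.names)

    def statistic(resample: pd.DataFrame) -> np.ndarray:
        refit = fit_cox(
            resample[names],
            resample["__time__"].to_numpy(),
            resample["__event__"].to_numpy(),
        )
        return refit.coefficients

    lo, hi = bootstrap_ci(statistic, data, B=B, seed=seed)
    return CoxFit(
        names=fit.names,
        coefficients=fit.coefficients,
        hazard_ratios=fit.hazard_ratios,
        ci_lower=np.exp(np.atleast_1d(lo)),
        ci_upper=np.exp(np.atleast_1d(hi)),
        p_values=fit.p_values,
        log_partial_likelihood=fit.log_partial_likelihood,
        n_events=fit.n_events,
        ci_method="bootstrap",
    )


def bootstrap_ci(
    statistic: Callable[[pd.DataFrame], float | np.ndarray],
    data: pd.DataFrame,
    B: int = 1000,
    level: float = 0.95,
    seed: int | None = None,
) -> tuple[np.ndarray | float, np.ndarray | float]:
    """Percentile bootstrap interval over patient (row) resamples.

    Rows are resampled jointly with replacement, so covariates, follow-up and
    event status stay paired.  Raises :class:`BootstrapError` when the
    statistic fails on more than 10% of resamples.
    """
    if B < 2:
        raise ParameterError("B must be at least 2")
    if not 0 < level < 1:
        raise ParameterError("level must be in (0, 1)")
    rng = np.random.default_rng(seed)
    n = len(data)
    values = []
    failures = 0
    for _ in range(B):
        idx = rng.integers(0, n, size=n)
        try:
            values.append(np.atleast_1d(np.asarray(statistic(data.iloc[idx]), dtype=float)))
        except Exception:
            failures += 1
    if failures > 0.1 * B:
        raise BootstrapError(f"statistic failed on {failures}/{B} resamples")
    stacked = np.vstack(values)
    alpha = (1.0 - level) / 2.0
    lo = np.percentile(stacked, 100 * alpha, axis=0)
    hi = np.percentile(stacked, 100 * (1 - alpha), axis=0)
    if stacked.shape[1] == 1:
        return float(lo[0]), float(hi[0])
    return lo, hi


def stepwise_bic(
    candidates: pd.DataFrame,
    times: np.ndarray,
    events: np.ndarray,
) -> SelectedModel:
    """Forward stepwise Cox selection by BIC.

    ``BIC = -2 log PL + k ln(d)`` with ``d`` the number of events.  Starting
    from the empty model, the candidate lowering BIC the most is added at each
    step (ties broken by input column order); selection stops when no addition
    lowers BIC.  Candidates whose fit fails are skipped with a warning.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    n_events = int(events.sum())
    if candidates.shape[1] < 1:
        raise ParameterError("need at least one candidate covariate")
    if n_events < 1:
        raise DegeneracyError("no events: selection is impossible")
    log_d = np.log(n_events)

    null_ll = cox_partial_loglik(np.zeros(len(times)), times, events)
    current_bic = -2.0 * null_ll
    trajectory = [current_bic]
    selected: list[str] = []
    remaining = list(candidates.columns)
    best_fit: CoxFit | None = None

    while remaining:
        step_best: tuple[float, str, CoxFit] | None = None
        for name in remaining:
            cols = selected + [name]
            try:
                fit = fit_cox(candidates[cols], times, events)
            except (DegeneracyError, ConvergenceError) as exc:
                logger.warning("stepwise: skipping candidate %r (%s)", name, exc)
                continue
            bic = float(-2.0 * fit.log_partial_likelihood + len(cols) * log_d)
            if step_best is None or bic < step_best[0]:  # strict: first best wins ties
                step_best = (bic, name, fit)
        if step_best is None or step_best[0] >= current_bic:
            break
        current_bic, chosen, best_fit = step_best
        trajectory.append(current_bic)
        selected.append(chosen)
        remaining.remove(chosen)

    c_stat = None
    if best_fit is not None:
        lp = best_fit.linear_predictor(candidates)
        c_stat = harrell_c(lp, times, events)
    return SelectedModel(
        selected=tuple(selected),
        bic_trajectory=tuple(trajectory),
        final_fit=best_fit,
        c_statistic=c_stat,
    )


def harrell_c(risks: np.ndarray, times: np.ndarray, events: np.ndarray) -> float:
    """Harrell's concordance index for right-censored data.

    A pair is usable when the subject with the strictly shorter time had the
    event; it scores 1 if that subject also has the higher risk, 0.5 on tied
    risks, 0 otherwise.
    """
    risks = np.asarray(risks, dtype=float)
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if not (len(risks) == len(times) == len(events)):
        raise ParameterError("risks, times and events must have equal length")

    # usable[i, j]: subject i died strictly before subject j's time
    usable = (times[:, None] < times[None, :]) & (events[:, None] == 1)
    n_usable = int(usable.sum())
    if n_usable == 0:
        raise ConcordanceError("no usable pairs: concordance undefined")
    concordant = usable & (risks[:, None] > risks[None, :])
    tied = usable & (risks[:, None] == risks[None, :])
    return float((concordant.sum() + 0.5 * tied.sum()) / n_usable)


def _is_binary(x: np.ndarray) -> bool:
    vals = np.unique(x[np.isfinite(x)])
    return len(vals) <= 2 and np.all(np.isin(vals, (0.0, 1.0)))


def compare_descriptives(
    df: pd.DataFrame,
    group: np.ndarray,
    variables: Sequence[str] | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Group comparison table with Shapiro-Wilk routing.

    Continuous variables: Shapiro-Wilk in each group at ``alpha``; if both
    groups look normal the summary is mean +/- SD and the test an unpaired
    Student t-test, otherwise median (IQR) and a two-sided Mann-Whitney U
    test.  Binary variables: counts (%) and Fisher's exact two-sided test.
    Variables with fewer than 3 observations in a group are skipped with a
    warning.
    """
    group = np.asarray(group, dtype=bool)
    if variables is None:
        variables = [c for c in df.columns if c not in ("patient_id",)]
    rows = []
    for name in variables:
        x = df[name].to_numpy(dtype=float)
        g0, g1 = x[~group], x[group]
        if len(g0) < 3 or len(g1) < 3:
            warnings.warn(f"skipping {name!r}: a group has fewer than 3 observations")
            continue
        if _is_binary(x):
            a, b = int(g0.sum()), int(len(g0) - g0.sum())
            c, d = int(g1.sum()), int(len(g1) - g1.sum())
            _, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
            rows.append(
                {
                    "variable": name,
                    "type": "categorical",
                    "group0": f"{a} ({100 * a / len(g0):.0f}%)",
                    "group1": f"{c} ({100 * c / len(g1):.0f}%)",
                    "test": "fisher",
                    "p": float(p),
                }
            )
            continue
        normal = all(
            stats.shapiro(g).pvalue > alpha if len(np.unique(g)) > 1 else False
            for g in (g0, g1)
        )
        if normal:
            _, p = stats.ttest_ind(g0, g1, equal_var=True)
            summ0 = f"{g0.mean():.2f} ± {g0.std(ddof=1):.2f}"
            summ1 = f"{g1.mean():.2f} ± {g1.std(ddof=1):.2f}"
            test = "t-test"
        else:
            _, p = stats.mannwhitneyu(g0, g1, alternative="two-sided")
            q0 = np.percentile(g0, [25, 50, 75])
            q1 = np.percentile(g1, [25, 50, 75])
            summ0 = f"{q0[1]:.2f} ({q0[0]:.2f}–{q0[2]:.2f})"
            summ1 = f"{q1[1]:.2f} ({q1[0]:.2f}–{q1[2]:.2f})"
            test = "mann-whitney"
        rows.append(
            {
                "variable": name,
                "type": "continuous",
                "group0": summ0,
                "group1": summ1,
                "test": test,
                "p": float(p),
            }
        )
    return pd.DataFrame(rows)
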