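"""Kaplan-Meier estimation, log-rank tests and proportional-hazards models.

Times are in months throughout.  The product-limit curve and the log-rank
statistic are delegated to lifelines; the Cox model maximizes the partial
likelihood with Breslow tie handling by Newton iterations (Efron handling
is available via lifelines).  A median that the curve never crosses is
reported with an explicit "not reached" flag, never as infinity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from scipy import stats

from .io import DataFormatError, SampleAnnotations, STAGES


@dataclass
class SurvivalCurve:
    """Product-limit estimate over the distinct event times."""

    times: np.ndarray  # distinct event times, ascending
    survival: np.ndarray  # S(t) at each event time
    at_risk: np.ndarray  # numbers at risk just before each event time
    n: int
    median: float | None  # None iff not reached
    median_reached: bool

    def __post_init__(self) -> None:
        if np.any(np.diff(self.survival) > 1e-12):
            raise DataFormatError("survival curve must be non-increasing")

    def survival_at(self, t: float) -> float:
        """S(t) (right-continuous step function, S(0) = 1)."""
        idx = np.searchsorted(self.times, t, side="right")
        return 1.0 if idx == 0 else float(self.survival[idx - 1])


@dataclass
class LogRankResult:
    statistic: float
    df: int
    p_value: float


@dataclass
class CoxResult:
    """Per-covariate partial-likelihood estimates with Wald inference."""

    table: pd.DataFrame  # coef, hr, se, ci_low, ci_high, p
    converged: bool
    ties: str
    n: int
    n_events: int
    warnings_: list[str] = field(default_factory=list)


def _check_surv(times, events) -> tuple[np.ndarray, np.ndarray]:
    t = np.asarray(times, dtype=float)
    e = np.asarray(events)
    if t.size == 0:
        raise DataFormatError("empty survival input")
    if (t < 0).any():
        raise DataFormatError("times must be non-negative")
    if not np.isin(e, [0, 1]).all():
        raise DataFormatError("events must be 0/1")
    return t, e.astype(int)


def km_estimate(times: Sequence[float], events: Sequence[int]) -> SurvivalCurve:
    """Kaplan-Meier product-limit estimator.

    The median is the smallest event time with S(t) <= 0.5; if the curve
    never drops that far the median is flagged "not reached".
    """
    t, e = _check_surv(times, events)
    kmf = KaplanMeierFitter()
    kmf.fit(t, e)
    table = kmf.event_table
    event_rows = table[table["observed"] > 0]
    grid = event_rows.index.to_numpy(dtype=float)
    surv = kmf.survival_function_at_times(grid).to_numpy(dtype=float)
    at_risk = event_rows["at_risk"].to_numpy(dtype=int)
    med = kmf.median_survival_time_
    reached = np.isfinite(med)
    return SurvivalCurve(
        times=grid,
        survival=surv,
        at_risk=at_risk,
        n=len(t),
        median=float(med) if reached else None,
        median_reached=bool(reached),
    )


def logrank_test(
    groups: Mapping[str, tuple[Sequence[float], Sequence[int]]]
) -> LogRankResult:
    """Multi-group log-rank test (observed-minus-expected, hypergeometric
    variance), chi-square with (groups - 1) degrees of freedom."""
    if len(groups) < 2:
        raise DataFormatError("need >= 2 groups")
    all_t, all_e, all_g = [], [], []
    for name, (times, events) in groups.items():
        t, e = _check_surv(times, events)
        all_t.append(t)
        all_e.append(e)
        all_g.append(np.repeat(name, len(t)))
    t = np.concatenate(all_t)
    e = np.concatenate(all_e)
    g = np.concatenate(all_g)
    if e.sum() == 0:
        raise DataFormatError("no events in any group")
    res = multivariate_logrank_test(t, g, e)
    return LogRankResult(float(res.test_statistic), len(groups) - 1, float(res.p_value))


def _breslow_newton(
    t: np.ndarray, e: np.ndarray, x: np.ndarray, tol: float, max_iter: int
):
    """Newton-Raphson on the Breslow partial log-likelihood.

    Returns (beta, covariance, converged, messages).
    """
    n, p = x.shape
    order = np.argsort(t, kind="stable")
    t, e, x = t[order], e[order], x[order]
    event_times = np.unique(t[e == 1])
    beta = np.zeros(p)
    converged = False
    messages: list[str] = []
    info = np.eye(p)
    for _ in range(max_iter):
        eta = x @ beta
        eta -= eta.max()  # guard overflow; cancels in all ratios
        w = np.exp(eta)
        grad = np.zeros(p)
        info = np.zeros((p, p))
        for et in event_times:
            risk = t >= et
            dead = (t == et) & (e == 1)
            d = int(dead.sum())
            wr = w[risk]
            xr = x[risk]
            s0 = wr.sum()
            s1 = wr @ xr
            mu = s1 / s0
            grad += x[dead].sum(axis=0) - d * mu
            s2 = xr.T @ (xr * wr[:, None])
            info += d * (s2 / s0 - np.outer(mu, mu))
        try:
            step = np.linalg.solve(info, grad)
        except np.linalg.LinAlgError:
            messages.append("singular information matrix")
            break
        beta = beta + step
        if np.abs(step).max() < tol:
            converged = True
            break
    if np.abs(beta).max() > 15:
        messages.append("possible separation: estimate diverging")
        converged = False
    try:
        cov = np.linalg.inv(info)
    except np.linalg.LinAlgError:
        cov = np.full((p, p), np.nan)
        messages.append("information matrix not invertible")
    return beta, cov, converged, messages


def cox_fit(
    times: Sequence[float],
    events: Sequence[int],
    covariates: pd.DataFrame,
    ties: str = "breslow",
    tol: float = 1e-8,
    max_iter: int = 50,
) -> CoxResult:
    """Cox proportional-hazards fit.

    Breslow tie handling is computed here by Newton iterations on the
    partial likelihood (observed-information Wald CIs); ``ties="efron"``
    delegates to lifelines.  Non-convergence and suspected separation are
    flagged, never silently reported as converged.
    """
    t, e = _check_surv(times, events)
    if covariates.shape[1] < 1:
        raise DataFormatError("need >= 1 covariate")
    if e.sum() == 0:
        raise DataFormatError("no events")
    x = covariates.to_numpy(dtype=float)
    if len(x) != len(t):
        raise DataFormatError("covariates and times differ in length")
    const = x.std(axis=0) == 0
    if const.any():
        bad = covariates.columns[int(np.argmax(const))]
        raise DataFormatError(f"covariate {bad!r} is constant")
    if ties == "breslow":
        beta, cov, converged, messages = _breslow_newton(t, e, x, tol, max_iter)
        se = np.sqrt(np.diag(cov))
    elif ties == "efron":
        df = covariates.copy()
        df["_time"] = t
        df["_event"] = e
        cph = CoxPHFitter()
        cph.fit(df, duration_col="_time", event_col="_event")
        beta = cph.params_.to_numpy()
        se = cph.standard_errors_.to_numpy()
        converged, messages = True, []
    else:
        raise DataFormatError(f"unknown tie handling {ties!r}")
    z = stats.norm.ppf(0.975)
    table = pd.DataFrame(
        {
            "coef": beta,
            "hr": np.exp(beta),
            "se": se,
            "ci_low": np.exp(beta - z * se),
            "ci_high": np.exp(beta + z * se),
            "p": 2 * stats.norm.sf(np.abs(beta) / se),
        },
        index=list(covariates.columns),
    )
    for m in messages:
        warnings.warn(m)
    return CoxResult(table, converged, ties, len(t), int(e.sum()), messages)


def _stage_dummies(stage: pd.Series) -> pd.DataFrame:
    """Dummy-code stage against the IA reference (unknown rows dropped upstream)."""
    levels = [s for s in STAGES if s not in ("IA", "unknown")]
    cols = {f"stage_{lv}": (stage == lv).astype(float) for lv in levels}
    df = pd.DataFrame(cols, index=stage.index)
    return df.loc[:, df.std(axis=0) > 0]


def stratified_report(
    groups: pd.Series,
    annotations: SampleAnnotations,
    strata: str = "stage",
    endpoint: str = "dfs",
    min_stratum_size: int = 5,
    ties: str = "breslow",
) -> dict:
    """Per-stratum KM + log-rank for a grouping, plus stage-adjusted Cox.

    ``groups`` maps sample -> group label (signature class or quartile).
    Strata smaller than ``min_stratum_size`` are reported as
    "insufficient n".  The pooled Cox uses the grouping dummy-coded against
    its first (sorted) level, adjusted for stage against IA; samples with
    unknown stage are excluded from the adjusted model only.
    """
    times, events = annotations.survival(endpoint)
    shared = [s for s in groups.index if s in times.index]
    groups = groups.loc[shared]
    times, events = times.loc[shared], events.loc[shared]

    def km_by_group(idx) -> dict:
        out = {}
        for name in sorted(groups.loc[idx].unique()):
            members = groups.loc[idx][groups.loc[idx] == name].index
            out[str(name)] = km_estimate(times.loc[members], events.loc[members])
        return out

    def logrank_by_group(idx):
        data = {
            str(name): (
                times.loc[groups.loc[idx][groups.loc[idx] == name].index],
                events.loc[groups.loc[idx][groups.loc[idx] == name].index],
            )
            for name in sorted(groups.loc[idx].unique())
        }
        data = {k: v for k, v in data.items() if len(v[0]) > 0}
        if len(data) < 2:
            return None
        try:
            return logrank_test(data)
        except DataFormatError:
            return None

    report: dict = {
        "endpoint": endpoint,
        "pooled": {"km": km_by_group(groups.index), "logrank": logrank_by_group(groups.index)},
        "strata": {},
    }

    strata_values = annotations.df.loc[shared, strata]
    for value in sorted(strata_values.unique()):
        idx = strata_values.index[strata_values == value]
        if len(idx) < min_stratum_size:
            report["strata"][str(value)] = {"n": len(idx), "note": "insufficient n"}
            continue
        entry: dict = {"n": len(idx), "km": km_by_group(idx), "logrank": logrank_by_group(idx)}
        report["strata"][str(value)] = entry
    if not any("km" in v for v in report["strata"].values()):
        raise DataFormatError("no stratum meets the minimum size")

    # pooled stage-adjusted Cox with the grouping as exposure
    levels = sorted(groups.unique())
    exposure = pd.DataFrame(
        {f"group_{lv}": (groups == lv).astype(float) for lv in levels[1:]},
        index=groups.index,
    )
    if strata == "stage":
        known = annotations.df.loc[shared, "stage"] != "unknown"
        idx = groups.index[known]
        covs = pd.concat(
            [exposure.loc[idx], _stage_dummies(annotations.df.loc[idx, "stage"])],
            axis=1,
        )
    else:
        idx = groups.index
        covs = exposure
    covs = covs.loc[:, covs.std(axis=0) > 0]
    try:
        report["cox_adjusted"] = cox_fit(
            times.loc[idx], events.loc[idx], covs, ties=ties
        )
    except DataFormatError as exc:
        report["cox_adjusted"] = None
        warnings.warn(f"adjusted Cox model skipped: {exc}")
    return report
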