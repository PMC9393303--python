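"""Survival statistics: Kaplan-Meier curves, the two-group log-rank test,
and univariate Cox proportional-hazards regression.

Model fitting is delegated to lifelines (Kaplan-Meier product-limit
estimate, log-rank chi-square with hypergeometric variance, Cox partial
likelihood with the Efron tie correction by default). The Greenwood
variance is computed from the Kaplan-Meier event table, and the Cox score
test at beta = 0 — which coincides with the log-rank statistic for a binary
tie-free covariate — is implemented directly since fitters do not expose
it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError
from lifelines.statistics import logrank_test as _ll_logrank
from scipy import stats

from .io import SurvivalTable


@dataclass
class KMCurve:
    """Product-limit survival estimate over the distinct event times."""

    times: np.ndarray          # distinct event times (events only)
    at_risk: np.ndarray
    events: np.ndarray
    survival: np.ndarray       # S(t) just after each event time
    variance: np.ndarray       # Greenwood variance of S(t)

    def survival_at(self, t: float) -> float:
        """Step-function evaluation of S(t)."""
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


@dataclass
class CoxResult:
    beta: float
    se: float
    hazard_ratio: float
    ci_low: float
    ci_high: float
    pval: float
    n: int
    n_events: int
    ties: str


def _extract(records, event=None):
    if isinstance(records, SurvivalTable):
        return records.time, records.event
    return np.asarray(records, dtype=float), np.asarray(event, dtype=int)


def kaplan_meier(records: SurvivalTable | np.ndarray, event=None) -> KMCurve:
    """Kaplan-Meier estimate S(t) = prod_{t_i <= t} (1 - d_i / n_i).

    Accepts a :class:`SurvivalTable` or (time, event) arrays. If every
    subject is censored the curve is constant at 1 (with a warning).
    """
    time, ev = _extract(records, event)
    if time.size == 0:
        raise ValueError("need at least one record")
    kmf = KaplanMeierFitter()
    kmf.fit(time, ev)
    table = kmf.event_table
    with_events = table[table["observed"] > 0]
    if with_events.empty:
        import warnings

        warnings.warn("all subjects censored: survival curve is constant at 1")
        empty = np.array([])
        return KMCurve(times=empty, at_risk=empty, events=empty,
                       survival=empty, variance=empty)
    times = with_events.index.to_numpy(dtype=float)
    d = with_events["observed"].to_numpy(dtype=float)
    n = with_events["at_risk"].to_numpy(dtype=float)
    surv = np.cumprod(1.0 - d / n)
    # Greenwood: var S(t) = S(t)^2 * sum_{t_i<=t} d_i / (n_i (n_i - d_i))
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(n > d, d / (n * (n - d)), np.inf)
    var = surv ** 2 * np.cumsum(terms)
    var = np.where(np.isfinite(var), var, 0.0)  # S=0 at the last event
    return KMCurve(times=times, at_risk=n, events=d, survival=surv, variance=var)


def logrank_test(time, event, groups) -> tuple[float, float]:
    """Two-group log-rank test; chi-square (O - E)^2 / V with hypergeometric
    variance summed over distinct event times, p from chi2(1)."""
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    groups = np.asarray(groups)
    labels = pd.unique(groups)
    if len(labels) != 2:
        raise ValueError(f"log-rank test needs exactly 2 strata, got {len(labels)}")
    mask = groups == labels[0]
    if mask.sum() == 0 or (~mask).sum() == 0:
        raise ValueError("a stratum has no subjects")
    if event.sum() == 0:
        raise ValueError("no events in either stratum")
    res = _ll_logrank(time[mask], time[~mask], event[mask], event[~mask])
    return float(res.test_statistic), float(res.p_value)


def logrank_test_table(records: SurvivalTable, strata: pd.Series) -> tuple[float, float]:
    strata = pd.Series(strata).reindex(records.sample_ids)
    if strata.isna().any():
        raise ValueError("every sample needs a stratum label")
    return logrank_test(records.time, records.event, strata.to_numpy())


def cox_univariate(records: SurvivalTable | np.ndarray, covariate=None,
                   event=None, ties: str = "efron",
                   max_iter: int = 50) -> CoxResult:
    """Univariate Cox proportional-hazards fit (Newton-Raphson on the
    partial likelihood; Efron tie handling by default, Breslow by flag).
    Reports the Wald confidence interval exp(beta +/- 1.96 SE)."""
    if isinstance(records, SurvivalTable):
        time, ev = records.time, records.event
        x = records.covariate(covariate) if isinstance(covariate, str) \
            else np.asarray(covariate, dtype=float)
    else:
        time = np.asarray(records, dtype=float)
        x = np.asarray(covariate, dtype=float)
        ev = np.asarray(event, dtype=int)
    if ties not in ("efron", "breslow"):
        raise ValueError("ties must be 'efron' or 'breslow'")
    if np.all(x == x[0]):
        raise ValueError("covariate is constant")
    if ev.sum() < 10:
        raise ValueError(f"need >=10 events, got {int(ev.sum())}")

    df = pd.DataFrame({"time": time, "event": ev, "x": x})
    fitter = CoxPHFitter()
    try:
        fitter.fit(df, duration_col="time", event_col="event",
                   fit_options={"step_size": 0.95, "max_steps": max_iter})
    except ConvergenceError as exc:
        raise RuntimeError(f"Cox fit did not converge in {max_iter} iterations: {exc}") from exc
    beta = float(fitter.params_["x"])
    se = float(fitter.standard_errors_["x"])
    ci_low, ci_high = np.exp(beta - 1.959963984540054 * se), np.exp(beta + 1.959963984540054 * se)
    return CoxResult(beta=beta, se=se, hazard_ratio=float(np.exp(beta)),
                     ci_low=float(ci_low), ci_high=float(ci_high),
                     pval=float(fitter.summary.loc["x", "p"]),
                     n=len(df), n_events=int(ev.sum()), ties=ties)


def cox_score_test(time, event, x) -> tuple[float, float]:
    """Cox partial-likelihood score test at beta = 0: chi2 = U^2 / I with

        U = sum_events (x_i - mean_{R_i} x)
        I = sum_events var_{R_i} x

    over risk sets R_i. For a binary covariate without tied event times this
    equals the log-rank chi-square.
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    x = np.asarray(x, dtype=float)
    order = np.argsort(-time, kind="stable")  # decreasing time: risk sets grow
    t_s, e_s, x_s = time[order], event[order], x[order]
    # Tied times share a risk set: use the cumulative sums at the end of
    # each tied block.
    n_total = len(t_s)
    block_end = np.empty(n_total, dtype=int)
    j = 0
    while j < n_total:
        k = j
        while k + 1 < n_total and t_s[k + 1] == t_s[j]:
            k += 1
        block_end[j:k + 1] = k
        j = k + 1
    csum = np.cumsum(x_s)[block_end]
    csum2 = np.cumsum(x_s ** 2)[block_end]
    n_at_risk = (block_end + 1).astype(float)
    mean_r = csum / n_at_risk
    var_r = csum2 / n_at_risk - mean_r ** 2
    ev_mask = e_s == 1
    u = float(np.sum(x_s[ev_mask] - mean_r[ev_mask]))
    info = float(np.sum(var_r[ev_mask]))
    if info <= 0:
        raise ValueError("zero information: covariate constant within risk sets")
    chi2 = u * u / info
    return chi2, float(stats.chi2.sf(chi2, df=1))
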