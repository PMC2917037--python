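"""Survival comparison across genomic subtypes and covariate strata.

Thin, validated wrappers over lifelines: Kaplan-Meier product-limit curves,
the k-group log-rank test, and Cox proportional-hazards regression with
Efron tie handling. Endpoints are overall survival (OS) and distant
metastasis-free survival (DMFS), in years.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError
from lifelines.statistics import multivariate_logrank_test


class SurvivalError(ValueError):
    pass


def _validate(times, events) -> tuple[np.ndarray, np.ndarray]:
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if len(times) == 0:
        raise SurvivalError("no samples")
    if len(times) != len(events):
        raise SurvivalError("time/event length mismatch")
    if np.any(times <= 0):
        raise SurvivalError("nonpositive survival time")
    if not np.isin(events, [0, 1]).all():
        raise SurvivalError("event flags must be 0/1")
    return times, events


@dataclass
class KMEstimate:
    """Product-limit estimate: step function S(t) plus censor marks."""

    times: np.ndarray  # step locations (event times), ascending
    survival: np.ndarray  # S(t) just after each step
    censor_times: np.ndarray

    def at(self, t: float) -> float:
        """S(t); 1 before the first event."""
        ix = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if ix < 0 else float(self.survival[ix])


def kaplan_meier(times, events) -> KMEstimate:
    """Kaplan-Meier estimator; S(0) = 1, steps only at event times."""
    times, events = _validate(times, events)
    kmf = KaplanMeierFitter()
    kmf.fit(times, events)
    sf = kmf.survival_function_["KM_estimate"]
    event_times = np.sort(np.unique(times[events == 1]))
    surv = np.array([float(sf.loc[t]) for t in event_times])
    return KMEstimate(event_times, surv, np.sort(times[events == 0]))


def logrank_test(times, events, groups) -> tuple[float, int, float]:
    """k-group log-rank test; returns (chi-square, df = k - 1, p)."""
    times, events = _validate(times, events)
    groups = np.asarray(groups)
    labels = np.unique(groups)
    if len(labels) < 2:
        raise SurvivalError("log-rank needs >= 2 groups")
    res = multivariate_logrank_test(times, groups, events)
    return float(res.test_statistic), len(labels) - 1, float(res.p_value)


def cox_ph(
    data: pd.DataFrame,
    duration_col: str,
    event_col: str,
    covariates: list[str],
    ties: str = "efron",
    max_iter: int = 50,
) -> pd.DataFrame:
    """Cox proportional-hazards fit; per-covariate HR, 95% Wald CI, and p.

    Raises on no events, on covariates constant across samples, on fewer
    events than covariates, and on non-convergence.
    """
    times, events = _validate(data[duration_col], data[event_col])
    if events.sum() == 0:
        raise SurvivalError("no events observed")
    if events.sum() < len(covariates):
        raise SurvivalError(
            f"{int(events.sum())} events but {len(covariates)} covariates"
        )
    sub = data[[duration_col, event_col] + covariates].copy()
    for c in covariates:
        col = sub[c].astype(float)
        if col.nunique() < 2:
            raise SurvivalError(f"covariate {c!r} is constant across samples")
        sub[c] = col
    cph = CoxPHFitter()
    try:
        cph.fit(
            sub,
            duration_col=duration_col,
            event_col=event_col,
            fit_options={"max_steps": max_iter},
        )
    except ConvergenceError as err:
        raise SurvivalError(f"Cox fit did not converge: {err}") from err
    summ = cph.summary
    out = pd.DataFrame(
        {
            "hr": np.exp(summ["coef"]),
            "ci_lower": np.exp(summ["coef lower 95%"]),
            "ci_upper": np.exp(summ["coef upper 95%"]),
            "p": summ["p"],
        }
    )
    out.index.name = "covariate"
    return out


def km_by_group(data: pd.DataFrame, duration_col: str, event_col: str, group_col: str):
    """Kaplan-Meier estimates per group, as a dict label -> KMEstimate."""
    out = {}
    for label, sub in data.groupby(group_col):
        out[str(label)] = kaplan_meier(sub[duration_col], sub[event_col])
    return out
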