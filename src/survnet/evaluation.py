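"""Censored-data metrics and analysis procedures.

Harrell's concordance index, median-score dichotomization into high/low
risk groups, the Kaplan-Meier product-limit estimator with Greenwood bands,
the two-group log-rank test, and the input-dropout robustness experiment on
a frozen model.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Union

import numpy as np
import pandas as pd
from scipy import stats as sps

from .data_model import EncodedCohort


class UndefinedMetricError(ValueError):
    """The requested metric is undefined on this input (e.g. no events)."""


def concordance_index(risk: np.ndarray, t: np.ndarray, s: np.ndarray) -> float:
    """Harrell's C over event-anchored comparable pairs.

    A pair (i, j) is comparable when subject i died (``s_i = 1``) strictly
    before j's observed time (``t_i < t_j``).  Credit 1 when
    ``risk_i > risk_j``, 0.5 on risk ties, 0 otherwise.  Pairs with tied
    times are incomparable.  0.5 is chance level, 1 perfect.
    """
    risk = np.asarray(risk, dtype=float)
    t = np.asarray(t, dtype=float)
    s = np.asarray(s, dtype=float)
    if not (risk.shape == t.shape == s.shape):
        raise ValueError("risk, t, s must share shape")
    numer = 0.0
    denom = 0
    for i in np.flatnonzero(s == 1):
        later = t > t[i]
        denom += int(later.sum())
        numer += (risk[i] > risk[later]).sum() + 0.5 * (risk[i] == risk[later]).sum()
    if denom == 0:
        raise UndefinedMetricError("no comparable pairs")
    return float(numer / denom)


@dataclass
class RiskGroups:
    """Median-threshold dichotomization: high where the score strictly
    exceeds the threshold, low otherwise (ties fall low)."""

    threshold: float
    high: np.ndarray  # boolean per patient

    @property
    def labels(self) -> np.ndarray:
        return np.where(self.high, "high", "low")


def dichotomize(
    risk: np.ndarray, reference: Optional[np.ndarray] = None
) -> RiskGroups:
    """Split patients at the median of ``reference`` (default: the scores
    themselves, i.e. the test-set median)."""
    risk = np.asarray(risk, dtype=float)
    if risk.size == 0:
        raise ValueError("empty risk vector")
    ref = risk if reference is None else np.asarray(reference, dtype=float)
    if ref.size == 0:
        raise ValueError("empty reference vector")
    threshold = float(np.median(ref))
    return RiskGroups(threshold=threshold, high=risk > threshold)


@dataclass
class SurvivalCurve:
    """Kaplan-Meier step function with per-event-time counts.

    ``survival[k]`` is the product-limit estimate just after
    ``event_times[k]``; the curve starts at 1 at time 0.  The optional 95%
    band uses the Greenwood variance on the log(-log) scale.
    """

    event_times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    deaths: np.ndarray
    ci_lower: Optional[np.ndarray] = None
    ci_upper: Optional[np.ndarray] = None

    def evaluate(self, times: np.ndarray) -> np.ndarray:
        """Step-function value at arbitrary times."""
        times = np.atleast_1d(np.asarray(times, dtype=float))
        idx = np.searchsorted(self.event_times, times, side="right") - 1
        out = np.ones_like(times, dtype=float)
        has = idx >= 0
        out[has] = self.survival[idx[has]]
        return out


def kaplan_meier(t: np.ndarray, s: np.ndarray, confidence: float = 0.95) -> SurvivalCurve:
    """Product-limit estimator under right censoring.

    Censored times tied with an event time count as at risk at that time
    (events happen first).  The confidence band uses Greenwood's variance
    mapped through log(-log S), undefined where S is 0 or 1.
    """
    t = np.asarray(t, dtype=float)
    s = np.asarray(s, dtype=float)
    if t.size == 0:
        raise ValueError("empty sample")
    if np.any(t <= 0):
        raise ValueError("times must be positive")
    event_times = np.unique(t[s == 1])
    if event_times.size == 0:
        return SurvivalCurve(
            event_times=np.empty(0),
            survival=np.empty(0),
            at_risk=np.empty(0, dtype=int),
            deaths=np.empty(0, dtype=int),
        )
    at_risk = np.array([(t >= tau).sum() for tau in event_times])
    deaths = np.array([((t == tau) & (s == 1)).sum() for tau in event_times])
    frac = 1.0 - deaths / at_risk
    survival = np.cumprod(frac)

    # Greenwood on the log(-log) scale
    z = sps.norm.ppf(0.5 + confidence / 2.0)
    gw = np.cumsum(deaths / (at_risk * (at_risk - deaths)
                             + np.finfo(float).tiny))
    with np.errstate(divide="ignore", invalid="ignore"):
        log_s = np.log(survival)
        se = np.sqrt(gw) / np.abs(log_s)
        lower = survival ** np.exp(z * se)
        upper = survival ** np.exp(-z * se)
    bad = (survival <= 0) | (survival >= 1)
    lower[bad] = np.nan
    upper[bad] = np.nan
    return SurvivalCurve(
        event_times=event_times,
        survival=survival,
        at_risk=at_risk,
        deaths=deaths,
        ci_lower=lower,
        ci_upper=upper,
    )


def logrank_test(
    groups: Union[RiskGroups, np.ndarray], t: np.ndarray, s: np.ndarray
) -> tuple[float, float]:
    """Two-group log-rank test: (chi-square statistic, p-value on 1 df).

    Observed-minus-expected events per event time under the shared-hazard
    null, hypergeometric variance.
    """
    if isinstance(groups, RiskGroups):
        in_a = np.asarray(groups.high, dtype=bool)
    else:
        arr = np.asarray(groups)
        if arr.dtype == bool:
            in_a = arr
        else:
            labels = np.unique(arr)
            if labels.size != 2:
                raise ValueError("need exactly two groups")
            in_a = arr == labels[0]
    t = np.asarray(t, dtype=float)
    s = np.asarray(s, dtype=float)
    if in_a.all() or (~in_a).all():
        raise ValueError("both groups must be nonempty")
    if s.sum() == 0:
        raise UndefinedMetricError("no events")

    observed = 0.0
    expected = 0.0
    variance = 0.0
    for tau in np.unique(t[s == 1]):
        at_risk = t >= tau
        n_j = at_risk.sum()
        n_a = (at_risk & in_a).sum()
        if n_j == 0:
            continue
        dying = (t == tau) & (s == 1)
        d_j = dying.sum()
        d_a = (dying & in_a).sum()
        observed += d_a
        expected += d_j * n_a / n_j
        if n_j > 1:
            variance += (
                d_j * (n_a / n_j) * (1 - n_a / n_j) * (n_j - d_j) / (n_j - 1)
            )
    if variance == 0:
        return 0.0, 1.0
    statistic = (observed - expected) ** 2 / variance
    p_value = float(sps.chi2.sf(statistic, df=1))
    return float(statistic), p_value


def robustness_experiment(
    model,
    test_cohort: EncodedCohort,
    dp_grid,
    repeats: int = 100,
    seed: int = 0,
) -> pd.DataFrame:
    """Score a frozen model on the test set under random input dropout.

    For each drop probability ``dp`` and repeat, every covariate entry is
    independently turned missing (value and indicator zeroed) with
    probability ``dp``; the inference-mode concordance is recorded.
    Returns a long-format table with columns ``dp``, ``run``, ``cindex``.
    ``dp = 0`` reproduces the clean concordance exactly on every repeat.
    """
    dp_grid = list(dp_grid)
    if any(dp < 0 or dp >= 1 for dp in dp_grid):
        raise ValueError("drop probabilities must be in [0, 1)")
    if repeats < 1:
        raise ValueError("repeats must be >= 1")
    rng = np.random.default_rng(seed)
    rows = []
    for dp in dp_grid:
        for run in range(repeats):
            if dp == 0:
                X = test_cohort.X
            else:
                keep = rng.uniform(size=test_cohort.X.shape) >= dp
                X = test_cohort.X * keep
            risk = model.predict_risk(X)
            c = concordance_index(risk, test_cohort.t, test_cohort.s)
            rows.append({"dp": dp, "run": run, "cindex": c})
    return pd.DataFrame(rows, columns=["dp", "run", "cindex"])
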