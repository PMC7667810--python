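"""Model-agnostic predictive evaluation for right-censored data.

Implements Harrell's concordance index, the inverse-probability-of-
censoring-weighted (IPCW) Brier score with its reverse Kaplan-Meier
censoring estimate, prediction-error curves and their time average (the
Integrated Brier Score), and decile-based calibration against Kaplan-
Meier observed survival.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter

from .discretize import SurvivalDataset

__all__ = [
    "CensoringEstimate",
    "EvaluationReport",
    "concordance_index",
    "reverse_km",
    "brier_ipcw",
    "prediction_error_curve",
    "integrated_brier",
    "calibration_table",
]


@dataclass
class CensoringEstimate:
    """Step-function estimate of P(uncensored beyond t), from the
    Kaplan-Meier estimator with the roles of event and censoring swapped.

    ``times``/``values`` give the right-continuous step function; the
    left limit C(t-) is the value just before t (1 before the first drop).
    ``median_followup`` is the first time with C(t) <= 0.5 (a standard
    summary of follow-up duration), or NaN if never reached.
    """

    times: np.ndarray
    values: np.ndarray
    median_followup: float

    def evaluate(self, t):
        t = np.asarray(t, dtype=float)
        idx = np.searchsorted(self.times, t, side="right") - 1
        out = np.where(idx >= 0, self.values[np.maximum(idx, 0)], 1.0)
        return float(out) if t.ndim == 0 else out

    def evaluate_left(self, t):
        """Left limit C(t-); C(0-) = 1."""
        t = np.asarray(t, dtype=float)
        idx = np.searchsorted(self.times, t, side="left") - 1
        out = np.where(idx >= 0, self.values[np.maximum(idx, 0)], 1.0)
        return float(out) if t.ndim == 0 else out


def reverse_km(data: SurvivalDataset) -> CensoringEstimate:
    """Reverse Kaplan-Meier: product-limit estimate of the censoring
    distribution (event indicator flipped)."""
    if data.n < 1:
        raise ValueError("empty dataset")
    kmf = KaplanMeierFitter()
    kmf.fit(data.time, event_observed=1 - data.event)
    sf = kmf.survival_function_
    times = sf.index.to_numpy(dtype=float)
    values = sf.iloc[:, 0].to_numpy(dtype=float)
    below = values <= 0.5
    median = float(times[below][0]) if below.any() else float("nan")
    return CensoringEstimate(times=times, values=values, median_followup=median)


def concordance_index(risk_scores, data: SurvivalDataset) -> float:
    """Harrell's C: among comparable pairs (t_i < t_j with d_i = 1), the
    fraction where the earlier failure carries the higher risk score;
    score ties count 0.5, time-tied pairs are not comparable.

    Defined only for models with a scalar risk ordering (e.g. the Cox
    prognostic index); discrete-hazard networks have no unique ordering.
    """
    scores = np.asarray(risk_scores, dtype=float)
    t, d = data.time, data.event
    if scores.shape[0] != data.n:
        raise ValueError("one risk score per subject required")
    concordant = 0.0
    comparable = 0
    event_idx = np.flatnonzero(d == 1)
    for i in event_idx:
        later = t > t[i]
        m = int(later.sum())
        if m == 0:
            continue
        comparable += m
        s_i, s_j = scores[i], scores[later]
        concordant += float((s_i > s_j).sum()) + 0.5 * float((s_i == s_j).sum())
    if comparable == 0:
        raise ValueError("no comparable pairs; C-index undefined")
    return concordant / comparable


def brier_ipcw(
    surv_prob_at_t0,
    data: SurvivalDataset,
    t0: float,
    censoring: CensoringEstimate | None = None,
) -> float:
    """IPCW-weighted Brier score at horizon ``t0``.

    Each subject with an observed status at t0 (event by t0, or still
    under observation past t0) contributes its squared error
    ``(1{t_i > t0} - S_hat(t0|x_i))^2`` weighted by the inverse censoring
    probability: C(t_i-) for early events and C(t0) for survivors.
    Subjects censored before t0 contribute 0; the denominator is all n.
    """
    s_hat = np.asarray(surv_prob_at_t0, dtype=float)
    if s_hat.shape[0] != data.n:
        raise ValueError("one predicted survival probability per subject required")
    if np.any(s_hat < 0) or np.any(s_hat > 1):
        raise ValueError("survival predictions must lie in [0, 1]")
    if t0 <= 0:
        raise ValueError("t0 must be positive")
    if censoring is None:
        censoring = reverse_km(data)
    t, d = data.time, data.event
    event_by_t0 = (t <= t0) & (d == 1)
    after_t0 = t > t0
    total = 0.0
    c_t0 = censoring.evaluate(t0)
    if after_t0.any():
        if c_t0 <= 0:
            raise ValueError(f"censoring estimate is 0 at t0={t0}; weights undefined")
        total += float(((1.0 - s_hat[after_t0]) ** 2).sum()) / c_t0
    if event_by_t0.any():
        c_left = censoring.evaluate_left(t[event_by_t0])
        if np.any(c_left <= 0):
            bad = data.ids[event_by_t0][np.asarray(c_left) <= 0]
            raise ValueError(
                f"censoring estimate is 0 just before the event time of subject(s) {bad[:5]}"
            )
        total += float(((0.0 - s_hat[event_by_t0]) ** 2 / c_left).sum())
    return total / data.n


def prediction_error_curve(
    surv_matrix,
    data: SurvivalDataset,
    times,
    censoring: CensoringEstimate | None = None,
) -> dict[float, float]:
    """IPCW Brier score at each requested time; ``surv_matrix`` has one
    column of predictions per time."""
    surv_matrix = np.asarray(surv_matrix, dtype=float)
    times = np.asarray(times, dtype=float)
    if surv_matrix.ndim != 2 or surv_matrix.shape != (data.n, times.shape[0]):
        raise ValueError("surv_matrix must be (n_subjects, n_times)")
    if censoring is None:
        censoring = reverse_km(data)
    return {
        float(t): brier_ipcw(surv_matrix[:, j], data, float(t), censoring)
        for j, t in enumerate(times)
    }


def integrated_brier(
    curve: dict[float, float],
    t_hor: float | None = None,
    method: str = "trapezoid",
) -> float:
    """Time-averaged prediction error up to the horizon.

    ``trapezoid`` (default) integrates the piecewise-linear curve anchored
    at Err(0) = 0 and divides by the horizon; ``mean`` averages the curve
    values directly.
    """
    if not curve:
        raise ValueError("empty prediction-error curve")
    times = np.array(sorted(curve))
    vals = np.array([curve[t] for t in times])
    if t_hor is None:
        t_hor = float(times[-1])
    keep = times <= t_hor
    times, vals = times[keep], vals[keep]
    if times.size == 0:
        raise ValueError("no curve points at or below the horizon")
    if method == "trapezoid":
        tt = np.concatenate([[0.0], times]) if times[0] > 0 else times
        vv = np.concatenate([[0.0], vals]) if times[0] > 0 else vals
        return float(np.trapezoid(vv, tt) / t_hor)
    if method == "mean":
        return float(vals.mean())
    raise ValueError("method must be 'trapezoid' or 'mean'")


def _km_at(kmf: KaplanMeierFitter, t: float) -> tuple[float, float, float]:
    est = float(kmf.survival_function_at_times(t).iloc[0])
    ci = kmf.confidence_interval_survival_function_
    idx = np.searchsorted(ci.index.to_numpy(dtype=float), t, side="right") - 1
    if idx < 0:
        return est, 1.0, 1.0
    lo, hi = ci.iloc[idx, 0], ci.iloc[idx, 1]
    return est, float(lo), float(hi)


def calibration_table(
    surv_prob_at_t,
    data: SurvivalDataset,
    t: float,
    n_groups: int = 10,
) -> pd.DataFrame:
    """Decile calibration at time ``t``: subjects are split into
    ``n_groups`` equal-sized groups by predicted survival probability
    (stable ties, sizes within +/-1); each group reports the mean
    prediction against the Kaplan-Meier observed survival with its 95%
    confidence interval (Greenwood variance on the log(-log) scale).
    """
    pred = np.asarray(surv_prob_at_t, dtype=float)
    if pred.shape[0] != data.n:
        raise ValueError("one prediction per subject required")
    if data.n < n_groups:
        raise ValueError(f"need at least {n_groups} subjects for {n_groups} groups")
    if np.all(pred == pred[0]):
        warnings.warn(
            "all predictions identical; calibration collapses to a single group",
            stacklevel=2,
        )
        groups = [np.arange(data.n)]
    else:
        order = np.argsort(pred, kind="stable")
        groups = np.array_split(order, n_groups)
    rows = []
    for g, idx in enumerate(groups, start=1):
        kmf = KaplanMeierFitter()
        kmf.fit(data.time[idx], event_observed=data.event[idx])
        obs, lo, hi = _km_at(kmf, t)
        rows.append(
            {
                "group": g,
                "n": len(idx),
                "mean_predicted": float(pred[idx].mean()),
                "km_observed": obs,
                "ci_lower": lo,
                "ci_upper": hi,
            }
        )
    return pd.DataFrame(rows)


@dataclass
class EvaluationReport:
    """Test-set performance of one model: discrimination (C-index, when a
    scalar risk ordering exists), per-time Brier errors and their IBS."""

    model: str
    ibs: float
    brier_by_time: dict[float, float]
    t_hor: float
    n_test: int
    c_index: float | None = None

    def to_dict(self) -> dict:
        return {
            "model": self.model,
            "ibs": self.ibs,
            "c_index": self.c_index,
            "t_hor": self.t_hor,
            "n_test": self.n_test,
            "brier_by_time": {str(k): v for k, v in self.brier_by_time.items()},
        }

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"model": self.model, "metric": "brier", "time": t, "value": v}
            for t, v in sorted(self.brier_by_time.items())
        ]
        rows.append({"model": self.model, "metric": "ibs", "time": self.t_hor, "value": self.ibs})
        if self.c_index is not None:
            rows.append({"model": self.model, "metric": "c_index", "time": None, "value": self.c_index})
        return pd.DataFrame(rows)
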