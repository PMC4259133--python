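"""Prediction-quality measures for censored survival data.

Brier score / integrated Brier score with inverse-probability-of-censoring
weights (Graf), Harrell-type concordance index, and the recovery-rate
bookkeeping statistic used in the simulation study.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from lifelines import KaplanMeierFitter

from .cox import BreslowBaseline, SurvivalDataset

__all__ = [
    "PredictedSurvival",
    "km_censoring",
    "brier_score",
    "ibs",
    "concordance_index",
    "recovery_rate",
    "predict_survival",
]


@dataclass
class StepSurvival:
    """Right-continuous nonincreasing step function with value 1 at t = 0."""

    times: np.ndarray   # ascending jump times
    values: np.ndarray  # function value at/after each jump time

    def at(self, t):
        idx = np.searchsorted(self.times, np.asarray(t, dtype=float), side="right")
        vals = np.concatenate([[1.0], self.values])
        out = vals[idx]
        return out if out.ndim else float(out)

    def at_minus(self, t):
        """Left limit: value just before t."""
        idx = np.searchsorted(self.times, np.asarray(t, dtype=float), side="left")
        vals = np.concatenate([[1.0], self.values])
        out = vals[idx]
        return out if out.ndim else float(out)


@dataclass
class PredictedSurvival:
    """Per-subject predicted survival curves S(t | x_i) as step functions."""

    times: np.ndarray    # shared jump times (training event times), ascending
    curves: np.ndarray   # (n_subjects, len(times)); row i is S(times | x_i)

    def at(self, t) -> np.ndarray:
        """S(t | x_i) for every subject; S = 1 before the first jump."""
        idx = int(np.searchsorted(self.times, float(t), side="right"))
        if idx == 0:
            return np.ones(self.curves.shape[0])
        return self.curves[:, idx - 1]


def predict_survival(baseline: BreslowBaseline, X, beta) -> PredictedSurvival:
    """Survival curves S(t|x) = exp(-H0(t) e^{x beta}) from a Breslow baseline."""
    eta = np.asarray(X, dtype=float) @ np.asarray(beta, dtype=float).ravel()
    return PredictedSurvival(times=baseline.event_times,
                             curves=baseline.survival(baseline.event_times, eta))


def km_censoring(data: SurvivalDataset) -> StepSurvival:
    """Kaplan-Meier estimate G(t) of the censoring survival function.

    Censorings are treated as events and events as censorings; used as the
    inverse-probability weight in the Brier score.
    """
    kmf = KaplanMeierFitter()
    kmf.fit(data.time, event_observed=1 - data.event)
    sf = kmf.survival_function_
    times = sf.index.to_numpy(dtype=float)
    values = sf.iloc[:, 0].to_numpy(dtype=float)
    keep = times > 0
    return StepSurvival(times=times[keep], values=values[keep])


def brier_score(data: SurvivalDataset, pred: PredictedSurvival, t: float,
                cens: StepSurvival | None = None,
                return_excluded: bool = False):
    """IPC-weighted Brier score at horizon t (Graf estimator).

    BS(t) averages, over subjects with positive censoring weight,
    S(t|x)^2 / G(t_i-) for subjects with an observed event by t, and
    (1 - S(t|x))^2 / G(t) for subjects still at risk past t; subjects
    censored before t contribute nothing.  Weights with G = 0 are excluded
    (count available via ``return_excluded``).
    """
    if t <= 0:
        raise ValueError("the Brier horizon t must be positive")
    G = cens if cens is not None else km_censoring(data)
    S_t = pred.at(t)
    event_by_t = (data.time <= t) & (data.event == 1)
    at_risk = data.time > t

    g_event = np.asarray(G.at_minus(data.time))
    g_t = float(G.at(t))
    terms = np.zeros(data.n)
    include = np.ones(data.n, dtype=bool)

    m = event_by_t
    ok = g_event > 0
    terms[m & ok] = S_t[m & ok] ** 2 / g_event[m & ok]
    include[m & ~ok] = False

    if g_t > 0:
        terms[at_risk] = (1.0 - S_t[at_risk]) ** 2 / g_t
    else:
        include[at_risk] = False

    n_excluded = int((~include).sum())
    if n_excluded:
        warnings.warn(f"{n_excluded} subjects excluded from BS({t}): zero "
                      "censoring weight")
    n_inc = int(include.sum())
    bs = float(terms[include].sum() / n_inc) if n_inc else float("nan")
    return (bs, n_excluded) if return_excluded else bs


def ibs(data: SurvivalDataset, pred: PredictedSurvival) -> float:
    """Integrated Brier score over (0, max t_i], normalized by max t_i.

    BS(t) is a right-continuous step function whose jumps occur only at
    observed times and at the prediction curves' jump times, so the
    integral is an exact weighted sum over that grid.
    """
    tau = float(data.time.max())
    cens = km_censoring(data)
    grid = np.unique(np.concatenate([
        [0.0], data.time[data.time < tau], pred.times[pred.times < tau],
        cens.times[cens.times < tau], [tau]]))
    grid = grid[(grid >= 0) & (grid <= tau)]
    widths = np.diff(grid)
    total = 0.0
    for left, w in zip(grid[:-1], widths):
        if left == 0.0:
            # on (0, first jump): nobody has failed, S(0|x) = 1, G = 1
            bs = float(np.mean((1.0 - pred.at(0.0)) ** 2))
        else:
            # BS is constant on [left, next); evaluate at the left edge
            bs = brier_score(data, pred, left, cens=cens)
        total += bs * w
    return total / tau


def concordance_index(data: SurvivalDataset, risk_scores) -> float:
    """Concordance index of a risk score (higher score = shorter survival).

    A pair (i, j) is comparable when t_i < t_j and subject i had an event;
    it counts as concordant when risk_i > risk_j, half when tied.  Perfect
    risk ordering gives 1; random scores give 0.5 in expectation.
    """
    f = np.asarray(risk_scores, dtype=float).ravel()
    if f.shape[0] != data.n:
        raise ValueError("one risk score per subject required")
    t, d = data.time, data.event
    comp = (t[:, None] < t[None, :]) & (d[:, None] == 1)
    n_comp = int(comp.sum())
    if n_comp == 0:
        raise ValueError("no comparable pairs: concordance index undefined")
    conc = (f[:, None] > f[None, :]) & comp
    ties = (f[:, None] == f[None, :]) & comp
    return float((conc.sum() + 0.5 * ties.sum()) / n_comp)


def recovery_rate(relevant_counts, total_counts) -> float:
    """Ratio of mean #selected true-signal variables to mean #selected overall.

    Both inputs are per-replicate counts; the means are taken before the
    ratio.  Undefined (raises) when nothing is ever selected.
    """
    rel = np.asarray(relevant_counts, dtype=float)
    tot = np.asarray(total_counts, dtype=float)
    if rel.shape != tot.shape or rel.ndim != 1 or rel.size == 0:
        raise ValueError("need matching nonempty 1-d count vectors")
    if np.any(rel > tot):
        raise ValueError("relevant counts cannot exceed total counts")
    mean_tot = tot.mean()
    if mean_tot == 0:
        raise ValueError("no variables selected in any replicate: "
                         "recovery rate undefined")
    return float(rel.mean() / mean_tot)
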