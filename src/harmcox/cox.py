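"""Cox proportional-hazards core: partial likelihood, its derivatives in
linear-predictor space, the working least-squares linearization, and the
Breslow baseline hazard.

The partial log-likelihood for right-censored data (t_i, delta_i, x_i) is

    l(beta) = sum_{i: delta_i = 1} [ eta_i - log sum_{j in R_i} exp(eta_j) ],

with eta = X beta and risk set R_i = {j : t_j >= t_i}.  Tied event times are
handled with the Breslow convention (plain sums over the shared risk set).

For penalized fitting with p >> n the likelihood is replaced by a working
least-squares problem: with mu = -dl/deta and A = -d2l/deta deta^T, the
second-order expansion of -l around eta0 is minimized at
z = eta0 + A^- (dl/deta), and with C^T C = A the quadratic
(1/2)||C z - C X beta||^2 reproduces that expansion up to a constant.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "SurvivalDataset",
    "QuadraticApprox",
    "partial_loglik",
    "eta_gradient_hessian",
    "quadratic_approx",
    "breslow_baseline",
    "BreslowBaseline",
]


@dataclass
class SurvivalDataset:
    """Right-censored survival data: covariates, observed times, event flags.

    Attributes
    ----------
    X : (n, p) ndarray
        Covariate matrix.
    time : (n,) ndarray
        Observed times, strictly positive (event or censoring time).
    event : (n,) ndarray of {0, 1}
        1 = event observed, 0 = right-censored.
    feature_names : list of str
        Column labels; generated as x1..xp when absent.
    """

    X: np.ndarray
    time: np.ndarray
    event: np.ndarray
    feature_names: list = field(default=None)

    def __post_init__(self):
        self.X = np.atleast_2d(np.asarray(self.X, dtype=float))
        self.time = np.asarray(self.time, dtype=float).ravel()
        self.event = np.asarray(self.event).ravel().astype(int)
        n = self.time.shape[0]
        if self.X.shape[0] != n or self.event.shape[0] != n:
            raise ValueError("X, time and event must have matching first dimension")
        if n < 2:
            raise ValueError("need at least two subjects")
        if np.any(~np.isfinite(self.X)) or np.any(~np.isfinite(self.time)):
            raise ValueError("missing or non-finite values are not allowed")
        if np.any(self.time <= 0):
            raise ValueError("all observed times must be strictly positive")
        if not np.all(np.isin(self.event, (0, 1))):
            raise ValueError("event indicators must be 0 or 1")
        if self.event.sum() == 0:
            raise ValueError("at least one event is required")
        if self.feature_names is None:
            self.feature_names = [f"x{j + 1}" for j in range(self.X.shape[1])]

    @property
    def n(self) -> int:
        return self.time.shape[0]

    @property
    def p(self) -> int:
        return self.X.shape[1]

    def subset(self, idx) -> "SurvivalDataset":
        idx = np.asarray(idx)
        return SurvivalDataset(self.X[idx], self.time[idx], self.event[idx],
                               list(self.feature_names))

    # -- delimited text I/O: columns `time,status,<feature names>` ----------

    @classmethod
    def from_table(cls, path_or_buf, sep=",") -> "SurvivalDataset":
        df = pd.read_csv(path_or_buf, sep=sep)
        for col in ("time", "status"):
            if col not in df.columns:
                raise ValueError(f"input table must contain a '{col}' column")
        feats = [c for c in df.columns if c not in ("time", "status")]
        return cls(df[feats].to_numpy(float), df["time"].to_numpy(float),
                   df["status"].to_numpy(), feats)

    def to_table(self, path_or_buf=None, sep=","):
        df = pd.DataFrame(self.X, columns=self.feature_names)
        df.insert(0, "status", self.event)
        df.insert(0, "time", self.time)
        if path_or_buf is None:
            buf = io.StringIO()
            df.to_csv(buf, sep=sep, index=False)
            return buf.getvalue()
        df.to_csv(path_or_buf, sep=sep, index=False)


def _risk_order(data: SurvivalDataset):
    """Sort by ascending time, events before censorings at ties."""
    return np.lexsort((1 - data.event, data.time))


def _log_risk_sums(time_sorted, eta_sorted):
    """log sum_{j: t_j >= t_i} exp(eta_j) for each sorted position i."""
    rev = np.logaddexp.accumulate(eta_sorted[::-1])[::-1]
    # risk set of subject i starts at the first index sharing its time
    start = np.searchsorted(time_sorted, time_sorted, side="left")
    return rev[start], start


def partial_loglik(data: SurvivalDataset, beta) -> float:
    """Cox partial log-likelihood l(beta), Breslow ties, log-sum-exp guarded."""
    beta = np.asarray(beta, dtype=float).ravel()
    if beta.shape[0] != data.p:
        raise ValueError("beta length must equal the number of covariates")
    return partial_loglik_eta(data, data.X @ beta)


def partial_loglik_eta(data: SurvivalDataset, eta) -> float:
    """Partial log-likelihood as a function of the linear predictor eta."""
    eta = np.asarray(eta, dtype=float).ravel()
    order = _risk_order(data)
    ts, es, hs = data.time[order], data.event[order], eta[order]
    log_s, _ = _log_risk_sums(ts, hs)
    d = es == 1
    return float(np.sum(hs[d] - log_s[d]))


def eta_gradient_hessian(data: SurvivalDataset, beta):
    """First and second derivatives of -l with respect to eta.

    Returns
    -------
    mu : (n,) ndarray
        mu = -dl/deta.
    A : (n, n) ndarray
        A = -d2l/deta deta^T; symmetric PSD with zero row sums (the partial
        likelihood is invariant to adding a constant to eta).
    """
    beta = np.asarray(beta, dtype=float).ravel()
    eta = data.X @ beta
    n = data.n
    order = _risk_order(data)
    ts, es, hs = data.time[order], data.event[order], eta[order]

    log_s, start = _log_risk_sums(ts, hs)
    d_idx = np.flatnonzero(es == 1)
    # W[d, q] = exp(eta_q) / S_d  for q in the risk set of event d, else 0
    W = np.exp(hs[None, :] - log_s[d_idx, None])
    cols = np.arange(n)[None, :]
    W[cols < start[d_idx][:, None]] = 0.0

    w_sum = W.sum(axis=0)
    mu_sorted = -es + w_sum
    A_sorted = np.diag(w_sum) - W.T @ W

    mu = np.empty(n)
    mu[order] = mu_sorted
    A = np.empty((n, n))
    A[np.ix_(order, order)] = A_sorted
    return mu, A


@dataclass
class QuadraticApprox:
    """Working least-squares form of the Cox likelihood at an expansion point.

    (1/2)||y_hat - x_hat beta||^2 equals the second-order expansion of
    -l(beta) around ``beta0`` up to an additive constant.
    """

    x_hat: np.ndarray      # (n, p) = C X
    y_hat: np.ndarray      # (n,)   = C z
    eta: np.ndarray        # linear predictor at the expansion point
    beta0: np.ndarray      # expansion point
    jitter: float = 0.0    # ridge added to A before the Choleski factor


def quadratic_approx(data: SurvivalDataset, beta) -> QuadraticApprox:
    """Linearize the Cox likelihood at ``beta`` into (x_hat, y_hat).

    z = eta + A^- (dl/deta) is the working response in eta-space (A^- a
    pseudo-inverse: A annihilates constants, so it is rank deficient by
    construction); C is the Choleski factor of A + eps*I with
    eps = 1e-8 tr(A)/n, giving C^T C ~= A.
    """
    beta = np.asarray(beta, dtype=float).ravel()
    mu, A = eta_gradient_hessian(data, beta)
    eta = data.X @ beta
    n = data.n

    A = 0.5 * (A + A.T)
    eps = 1e-8 * np.trace(A) / n
    if eps <= 0:
        eps = 1e-12
    A_pinv = np.linalg.pinv(A, hermitian=True)
    z = eta - A_pinv @ mu            # mu = -dl/deta, so this steps uphill in l
    try:
        L = np.linalg.cholesky(A + eps * np.eye(n))
    except np.linalg.LinAlgError:
        eps *= 1e4
        warnings.warn("Hessian numerically singular; ridge jitter increased")
        L = np.linalg.cholesky(A + eps * np.eye(n))
    C = L.T                          # C^T C = A + eps I
    return QuadraticApprox(x_hat=C @ data.X, y_hat=C @ z, eta=eta,
                           beta0=beta, jitter=eps)


@dataclass
class BreslowBaseline:
    """Breslow cumulative baseline hazard: a nondecreasing step function.

    ``H0(t)`` jumps by (number of events at t) / (sum of exp(eta) over the
    risk set) at each distinct event time; with beta = 0 this is the
    Nelson-Aalen estimator.
    """

    event_times: np.ndarray   # distinct event times, ascending
    cum_hazard: np.ndarray    # H0 at those times

    def cumulative_hazard(self, times):
        times = np.asarray(times, dtype=float)
        idx = np.searchsorted(self.event_times, times, side="right")
        H = np.concatenate([[0.0], self.cum_hazard])
        out = H[idx]
        return out if out.ndim else float(out)

    def survival(self, times, eta):
        """S(t | x) = exp(-H0(t) exp(eta)) for each subject; shape (n, len(times))."""
        H = np.atleast_1d(self.cumulative_hazard(times))
        eta = np.atleast_1d(np.asarray(eta, dtype=float))
        return np.exp(-np.outer(np.exp(eta), H))


def breslow_baseline(data: SurvivalDataset, beta) -> BreslowBaseline:
    """Estimate the cumulative baseline hazard given fitted coefficients."""
    beta = np.asarray(beta, dtype=float).ravel()
    eta = data.X @ beta
    order = _risk_order(data)
    ts, es, hs = data.time[order], data.event[order], eta[order]
    log_s, start = _log_risk_sums(ts, hs)

    d = es == 1
    ev_times = ts[d]
    contrib = np.exp(-log_s[d])      # 1 / sum_{j in R_i} exp(eta_j), per event
    uniq, inv_idx = np.unique(ev_times, return_inverse=True)
    jumps = np.bincount(inv_idx, weights=contrib)
    return BreslowBaseline(event_times=uniq, cum_hazard=np.cumsum(jumps))
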