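"""Generalized path seeking (GPS) for the harmonic-regularized Cox model.

Instead of solving a penalized optimization for each value of a tuning
multiplier, the solver walks a path directly in coefficient space.  At path
position v the working least-squares gradient g_j = (1/n) sum_i
(y_hat_i - x_hat_i beta) x_hat_ij is divided by the penalty slope
p_j = P'(|beta_j|), and the single coordinate with the largest |g_j / p_j|
is nudged by a small increment delta_v in the direction of that ratio's
sign — coordinates whose sign opposes their ratio are corrected first.
Regularization strength is the path position itself: early points are
heavily shrunk and sparse, the terminus approaches the unpenalized fit.

Because the Cox loss is not quadratic, an outer loop re-linearizes the
partial likelihood (``quadratic_approx``) at the current coefficients and
resumes the walk, until the terminal coefficients stabilize.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .cox import QuadraticApprox, SurvivalDataset, quadratic_approx
from .penalty import penalty_derivative

__all__ = ["PathConfig", "CoefficientPath", "compute_tau", "gps_inner_path", "fit"]

ETA_DIVERGENCE_BOUND = 30.0


@dataclass(frozen=True)
class PathConfig:
    """Knobs of the path-seeking solver.

    delta_v : coordinate step size on standardized covariates.
    tau_tol : the inner loop stops once max_j |tau_j| falls below this
        (the practical reading of "until tau_j = 0").
    max_inner_steps : cap on steps per inner walk.
    max_outer_iters : cap on re-linearizations.
    outer_tol : relative change in terminal beta declaring outer convergence.
    relinearize_every : optional earlier cap per inner walk, forcing more
        frequent re-linearization than full inner convergence.
    """

    delta_v: float = 0.01
    tau_tol: float = 1e-4
    max_inner_steps: int = 20000
    max_outer_iters: int = 20
    outer_tol: float = 1e-4
    relinearize_every: int | None = None

    def __post_init__(self):
        if self.delta_v <= 0 or self.tau_tol <= 0 or self.outer_tol <= 0:
            raise ValueError("delta_v, tau_tol and outer_tol must be positive")
        if self.max_inner_steps < 1 or self.max_outer_iters < 1:
            raise ValueError("iteration caps must be at least 1")


@dataclass
class CoefficientPath:
    """A recorded GPS path: single-coordinate moves from a start vector.

    Point k (k = 0..n_points-1) is ``beta_start`` plus the first k moves;
    consecutive points differ in exactly one coordinate by at most delta_v
    in absolute value (less when a move is clamped at a sign change).
    """

    beta_start: np.ndarray
    move_index: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))
    move_delta: np.ndarray = field(default_factory=lambda: np.empty(0))
    v: np.ndarray = field(default_factory=lambda: np.zeros(1))   # len n_points
    nnz: np.ndarray = None                                       # len n_points
    tau_max: np.ndarray = None    # max_j |tau_j| at each point: the effective
                                  # penalty strength, decreasing along the path
    converged: bool = True
    selected_index: int | None = None
    scale: np.ndarray = None    # covariate scales if fit on standardized data
    center: np.ndarray = None

    def __post_init__(self):
        if self.nnz is None:
            self.nnz = np.array([int(np.count_nonzero(self.beta_start))])
        if self.tau_max is None:
            self.tau_max = np.full(self.n_points, np.nan)

    @property
    def n_points(self) -> int:
        return len(self.move_index) + 1

    def beta_at(self, k: int, original_scale: bool = False) -> np.ndarray:
        """Coefficient vector at path point k (supports negative indexing)."""
        k = range(self.n_points)[k]
        beta = self.beta_start.copy()
        np.add.at(beta, self.move_index[:k], self.move_delta[:k])
        if original_scale and self.scale is not None:
            beta = beta / self.scale
        return beta

    @property
    def beta_final(self) -> np.ndarray:
        return self.beta_at(self.n_points - 1)

    def active_set(self, k: int) -> np.ndarray:
        return np.flatnonzero(self.beta_at(k))

    def extend(self, other: "CoefficientPath") -> None:
        """Append another path that starts where this one ends (in place)."""
        if not np.allclose(other.beta_start, self.beta_final):
            raise ValueError("paths are not contiguous")
        self.move_index = np.concatenate([self.move_index, other.move_index])
        self.move_delta = np.concatenate([self.move_delta, other.move_delta])
        self.v = np.concatenate([self.v, self.v[-1] + other.v[1:]])
        self.nnz = np.concatenate([self.nnz, other.nnz[1:]])
        # at the junction the re-linearized tau supersedes the stale one
        self.tau_max = np.concatenate([self.tau_max[:-1], other.tau_max])
        self.converged = other.converged

    def to_table(self, path_or_buf=None, every: int = 1):
        """Sparse text export: one row per point, `index:value` pairs."""
        import io

        rows = []
        for k in range(0, self.n_points, every):
            beta = self.beta_at(k, original_scale=self.scale is not None)
            nz = np.flatnonzero(beta)
            enc = ";".join(f"{j}:{beta[j]:.6g}" for j in nz)
            rows.append(f"{self.v[k]:.6g}\t{len(nz)}\t{enc}")
        text = "v\tnnz\tcoefficients\n" + "\n".join(rows) + "\n"
        if path_or_buf is None:
            return text
        with open(path_or_buf, "w") as fh:
            fh.write(text)


def compute_tau(approx: QuadraticApprox, beta, a: float) -> np.ndarray:
    """Gradient-to-penalty-slope ratios tau_j = g_j / p_j at ``beta``."""
    beta = np.asarray(beta, dtype=float).ravel()
    n = approx.x_hat.shape[0]
    resid = approx.y_hat - approx.x_hat @ beta
    g = approx.x_hat.T @ resid / n
    p = penalty_derivative(np.abs(beta), a)
    return g / p


def gps_inner_path(approx: QuadraticApprox, beta0, a: float,
                   config: PathConfig) -> CoefficientPath:
    """Walk the GPS path on one working least-squares problem.

    Each step: compute tau; let S = {j : tau_j * beta_j < 0}; pick
    j* = argmax |tau_j| over S if S is nonempty, else over all j (lowest
    index on ties); move beta_{j*} by delta_v * sign(tau_{j*}), clamping at
    zero if the move would flip its sign.  Stops when max|tau| <= tau_tol
    (converged) or at the step cap (warning flag set).
    """
    beta = np.asarray(beta0, dtype=float).ravel().copy()
    n, p = approx.x_hat.shape
    cap = config.max_inner_steps
    if config.relinearize_every is not None:
        cap = min(cap, config.relinearize_every)

    # maintain the residual and recompute g = x_hat^T r / n each step: O(n p)
    # per step beats an O(p^2 n) Gram precompute for the short walks between
    # re-linearizations
    resid = approx.y_hat - approx.x_hat @ beta
    col_ms = np.einsum("ij,ij->j", approx.x_hat, approx.x_hat) / n
    pder = penalty_derivative(np.abs(beta), a)

    move_index, move_delta, v_list, nnz_list, tau_list = [], [], [0.0], [], []
    nnz = int(np.count_nonzero(beta))
    nnz_list.append(nnz)
    converged = False

    for _ in range(cap + 1):
        g = approx.x_hat.T @ resid / n
        tau = g / pder
        abs_tau = np.abs(tau)
        tau_list.append(float(abs_tau.max(initial=0.0)))
        if tau_list[-1] <= config.tau_tol:
            converged = True
            break
        if len(move_index) == cap:
            break
        # only meaningfully nonzero ratios count as sign-opposed (a zeroed
        # working gradient can leave a +-1e-16 tau on a finished coordinate)
        opposed = np.flatnonzero((tau * beta < 0) & (abs_tau > config.tau_tol))
        if opposed.size:
            j = opposed[np.argmax(abs_tau[opposed])]
        else:
            j = int(np.argmax(abs_tau))
        # cap the move at the coordinate minimizer of the working loss so the
        # walk can settle instead of oscillating +-delta_v around it
        limit = abs(g[j]) / col_ms[j] if col_ms[j] > 0 else config.delta_v
        if min(config.delta_v, limit) < 1e-12:
            converged = True     # numerically stationary along every coordinate
            break
        step = min(config.delta_v, limit) * np.sign(tau[j])
        old = beta[j]
        new = old + step
        if old != 0.0 and np.sign(new) == -np.sign(old):
            new = 0.0                       # clamp: never cross zero in one move
            step = -old
        beta[j] = new
        if old == 0.0 and new != 0.0:
            nnz += 1
        elif old != 0.0 and new == 0.0:
            nnz -= 1
        resid -= step * approx.x_hat[:, j]
        pder[j] = penalty_derivative(abs(new), a)
        move_index.append(j)
        move_delta.append(step)
        v_list.append(v_list[-1] + abs(step))
        nnz_list.append(nnz)

    return CoefficientPath(
        beta_start=np.asarray(beta0, dtype=float).ravel().copy(),
        move_index=np.asarray(move_index, dtype=int),
        move_delta=np.asarray(move_delta, dtype=float),
        v=np.asarray(v_list), nnz=np.asarray(nnz_list, dtype=int),
        tau_max=np.asarray(tau_list), converged=converged)


def fit(data: SurvivalDataset, a: float,
        config: PathConfig | None = None) -> CoefficientPath:
    """Fit the harmonic-regularized Cox path on a dataset.

    Covariates are centered and scaled to unit variance internally (a shared
    step delta_v presumes comparable scales); ``beta_at(k,
    original_scale=True)`` maps any path point back.  Alternates
    linearization of the partial likelihood with inner GPS walks until the
    terminal coefficients change by less than ``outer_tol`` (relative) or
    the caps are hit.  All intermediate points are retained so that model
    selection can pick any position on the path.
    """
    if config is None:
        config = PathConfig()
    center = data.X.mean(axis=0)
    scale = data.X.std(axis=0)
    scale[scale == 0] = 1.0
    std = SurvivalDataset((data.X - center) / scale, data.time, data.event,
                          list(data.feature_names))

    beta = np.zeros(data.p)
    full = None
    steps_left = config.max_inner_steps
    for _ in range(config.max_outer_iters):
        eta = std.X @ beta
        if np.max(np.abs(eta)) > ETA_DIVERGENCE_BOUND:
            warnings.warn("linear predictor diverged; stopping path early")
            full.converged = False
            break
        approx = quadratic_approx(std, beta)
        inner_cfg = config if steps_left == config.max_inner_steps else \
            PathConfig(config.delta_v, config.tau_tol, max(steps_left, 1),
                       config.max_outer_iters, config.outer_tol,
                       config.relinearize_every)
        inner = gps_inner_path(approx, beta, a, inner_cfg)
        if full is None:
            full = inner
        else:
            full.extend(inner)
        steps_left -= len(inner.move_index)
        beta_new = inner.beta_final
        denom = max(1.0, float(np.linalg.norm(beta)))
        delta = float(np.linalg.norm(beta_new - beta)) / denom
        beta = beta_new
        if delta < config.outer_tol or steps_left <= 0:
            break

    full.scale = scale
    full.center = center
    return full
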