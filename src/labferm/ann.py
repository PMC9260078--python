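"""Neural-network track: one hidden layer, five classical trainers.

The network family is fixed by the study design: three inputs (time h,
WF %, SF %), one hidden layer of at most 10 neurons with a sigmoid transfer
bounded in (-1, 1), one linear output — ``y = A f(B x + bi) + bii``.
Training minimizes mean squared error in the network's working (scaled)
space over all weights and biases, with one of

* ``levenberg_marquardt`` — damped Gauss-Newton on the residual vector,
* ``quasi_newton_bfgs`` — BFGS inverse-Hessian updates with a Wolfe search,
* ``scaled_conjugate_gradient`` — Moller's SCG, no line search,
* ``cg_fletcher`` — Fletcher-Reeves conjugate gradient with restarts,
* ``cg_polak_ribiere`` — Polak-Ribiere (plus-variant) conjugate gradient,
* ``quasi_newton_dfp`` — Davidon-Fletcher-Powell updates (the alternative
  reading of a "Fletcher-Powell" trainer; ``cg_fletcher`` is the default
  mapping for that name).

All randomness (initial weights, the train/test split offset) is drawn from
explicit integer seeds, so identical data + config + seed reproduce the
trained model bit for bit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import line_search

from .dataio import ViabilityDataset
from .models import ANNModel, ScalingSpec, _activation, _activation_deriv

__all__ = [
    "FitMetrics",
    "TrainingConfig",
    "TrainingHistory",
    "evaluate",
    "forward",
    "model_comparison",
    "network_jacobian",
    "split_systematic",
    "train",
]

METHODS = (
    "levenberg_marquardt",
    "quasi_newton_bfgs",
    "scaled_conjugate_gradient",
    "cg_fletcher",
    "cg_polak_ribiere",
    "quasi_newton_dfp",
)


@dataclass(frozen=True)
class TrainingConfig:
    """Trainer settings; defaults follow the study's stated budget.

    ``neurons`` is capped at 10 and the hidden-layer count is fixed at one.
    ``lm_lambda0`` and the two factors control Levenberg-Marquardt damping:
    lambda is multiplied by ``lm_increase`` on a rejected step and divided
    by ``lm_decrease`` on an accepted one.
    """

    method: str = "levenberg_marquardt"
    neurons: int = 8
    max_epochs: int = 1000
    grad_tol: float = 1e-7
    cost_goal: float = 0.0
    lm_lambda0: float = 1e-3
    lm_increase: float = 10.0
    lm_decrease: float = 10.0
    train_fraction: float = 0.75
    seed: int = 0
    activation: str = "tanh"
    scaling_mode: str = "inputs_and_output_scaled"

    def __post_init__(self):
        if self.method not in METHODS:
            raise ValueError(f"unknown method {self.method!r}; expected one of {METHODS}")
        if not 1 <= self.neurons <= 10:
            raise ValueError("neurons must be between 1 and 10")
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError("train_fraction must be in (0, 1)")
        if self.grad_tol <= 0 or self.max_epochs < 1:
            raise ValueError("positive grad_tol and max_epochs required")


@dataclass
class TrainingHistory:
    """Accepted-cost trajectory of one training run."""

    method: str
    costs: list[float]
    converged: bool
    message: str

    @property
    def epochs(self) -> int:
        return len(self.costs) - 1


@dataclass(frozen=True)
class FitMetrics:
    """Performance summary: MSE, correlation R, and regression p-value."""

    mse: float
    r_value: float
    p_value: float


# ---------------------------------------------------------------------------
# parameter flattening and derivatives

def _pack(A, B, bi, bii) -> np.ndarray:
    return np.concatenate([A, B.ravel(), bi, [bii]])


def _unpack(theta: np.ndarray, n: int):
    A = theta[:n]
    B = theta[n : n + 3 * n].reshape(n, 3)
    bi = theta[4 * n : 5 * n]
    bii = theta[5 * n]
    return A, B, bi, bii


def _core_output(theta, n, X, activation):
    A, B, bi, bii = _unpack(theta, n)
    f = _activation(X @ B.T + bi, activation)
    return f @ A + bii, f, A


def network_jacobian(model: ANNModel, inputs: np.ndarray) -> np.ndarray:
    """Analytic derivatives of the core output w.r.t. every weight and bias.

    ``inputs`` is an (N, 3) batch already in the network's scaled input
    space; the result is (N, P) with the flattened parameter ordering
    ``[A (n), B row-major (n x 3), bi (n), bii]``.  Row-wise:
    dy/dA_k = f(z_k), dy/dB_kj = A_k f'(z_k) x_j, dy/dbi_k = A_k f'(z_k),
    dy/dbii = 1, with f' expressed through f (for the printed transfer
    f' = (f^2 - 1)/2; for tanh f' = 1 - f^2).
    """
    X = np.atleast_2d(np.asarray(inputs, dtype=float))
    theta = _pack(model.A, model.B, model.bi, model.bii)
    return _jacobian(theta, model.n_hidden, X, model.activation)


def _jacobian(theta, n, X, activation):
    A, B, bi, _ = _unpack(theta, n)
    f = _activation(X @ B.T + bi, activation)          # (N, n)
    fprime = _activation_deriv(f, activation)          # (N, n)
    g = A * fprime                                     # (N, n)
    N = X.shape[0]
    J = np.empty((N, 5 * n + 1))
    J[:, :n] = f
    J[:, n : 4 * n] = (g[:, :, None] * X[:, None, :]).reshape(N, 3 * n)
    J[:, 4 * n : 5 * n] = g
    J[:, 5 * n] = 1.0
    return J


def forward(model: ANNModel, x) -> np.ndarray:
    """Closed-form network evaluation on raw (time, WF, SF) inputs."""
    return model.predict(x)


# ---------------------------------------------------------------------------
# data splitting

def split_systematic(
    ds: ViabilityDataset, train_fraction: float = 0.75, seed: int = 0
) -> tuple[ViabilityDataset, ViabilityDataset]:
    """Systematic stratified train/test split along the response.

    Rows are sorted ascending by viability; with the default 75 % training
    fraction every 4th sorted row, starting at a seed-drawn offset in
    {0, 1, 2, 3}, forms the test set, so test values interleave the training
    range 1-in-4 and only four distinct splits exist.  Both sets are
    returned in sorted order.
    """
    if not 0.0 < train_fraction < 1.0:
        raise ValueError("train_fraction must be in (0, 1)")
    period = int(round(1.0 / (1.0 - train_fraction)))
    n = len(ds)
    if n < period:
        raise ValueError(f"need at least {period} rows, got {n}")
    order = ds.df["viability_log10cfu_ml"].to_numpy().argsort(kind="stable")
    offset = int(np.random.default_rng(seed).integers(period))
    test_pos = np.arange(offset, n, period)
    mask = np.zeros(n, dtype=bool)
    mask[test_pos] = True
    sorted_df = ds.df.iloc[order].reset_index(drop=True)
    return (
        ViabilityDataset(sorted_df[~mask]),
        ViabilityDataset(sorted_df[mask]),
    )


# ---------------------------------------------------------------------------
# trainers

def _data_scaling(ds: ViabilityDataset, mode: str) -> ScalingSpec:
    """Min-max scaling fitted on the training data, per the chosen mode."""
    if mode == "raw":
        return ScalingSpec(mode="raw")
    pts, y = ds.points, ds.viability
    lo, hi = pts.min(axis=0), pts.max(axis=0)
    span = hi - lo
    hi = np.where(span > 0, hi, lo + 1.0)  # guard constant columns
    if mode == "inputs_scaled":
        return ScalingSpec(mode=mode, in_lo=tuple(lo), in_hi=tuple(hi))
    out_lo, out_hi = float(y.min()), float(y.max())
    if out_hi <= out_lo:
        out_hi = out_lo + 1.0
    return ScalingSpec(
        mode="inputs_and_output_scaled",
        in_lo=tuple(lo), in_hi=tuple(hi), out_lo=out_lo, out_hi=out_hi,
    )


def _check_finite(cost: float, method: str) -> None:
    if not np.isfinite(cost):
        raise RuntimeError(f"{method}: cost became non-finite during training")


def _train_lm(theta, n, X, t, cfg, activation):
    """Damped Gauss-Newton: accepted steps never increase the cost."""
    N = len(t)
    lam = cfg.lm_lambda0
    r = _core_output(theta, n, X, activation)[0] - t
    cost = float(r @ r) / N
    costs = [cost]
    converged, msg = False, "max epochs reached"
    for _ in range(cfg.max_epochs):
        J = _jacobian(theta, n, X, activation)
        grad = 2.0 * (J.T @ r) / N
        if np.max(np.abs(grad)) < cfg.grad_tol:
            converged, msg = True, "gradient tolerance reached"
            break
        JtJ = J.T @ J
        accepted = False
        for _ in range(30):  # inner damping adjustments
            try:
                delta = np.linalg.solve(JtJ + lam * np.eye(JtJ.shape[0]), -J.T @ r)
            except np.linalg.LinAlgError:
                lam *= cfg.lm_increase
                continue
            trial = theta + delta
            r_trial = _core_output(trial, n, X, activation)[0] - t
            cost_trial = float(r_trial @ r_trial) / N
            _check_finite(cost_trial, "levenberg_marquardt")
            if cost_trial < cost:
                theta, r, cost = trial, r_trial, cost_trial
                lam = max(lam / cfg.lm_decrease, 1e-15)
                accepted = True
                break
            lam *= cfg.lm_increase
        if not accepted:
            converged, msg = True, "no descent step found (local minimum)"
            break
        costs.append(cost)
        if cost <= cfg.cost_goal:
            converged, msg = True, "cost goal reached"
            break
    return theta, costs, converged, msg


def _wolfe_step(cost_fn, grad_fn, theta, d, g, cost):
    """Strong-Wolfe line search with a backtracking fallback."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        alpha = line_search(cost_fn, grad_fn, theta, d, gfk=g, old_fval=cost)[0]
    if alpha is not None and alpha > 0:
        return alpha
    # backtracking Armijo fallback
    alpha, slope = 1.0, float(g @ d)
    for _ in range(40):
        if cost_fn(theta + alpha * d) <= cost + 1e-4 * alpha * slope:
            return alpha
        alpha *= 0.5
    return None


def _train_first_order(theta, n, X, t, cfg, activation):
    """Shared loop for BFGS, DFP and the two conjugate-gradient variants."""
    N = len(t)

    def cost_fn(th):
        r = _core_output(th, n, X, activation)[0] - t
        return float(r @ r) / N

    def grad_fn(th):
        r = _core_output(th, n, X, activation)[0] - t
        return 2.0 * (_jacobian(th, n, X, activation).T @ r) / N

    P = theta.size
    quasi_newton = cfg.method in ("quasi_newton_bfgs", "quasi_newton_dfp")
    H = np.eye(P)
    cost, g = cost_fn(theta), grad_fn(theta)
    costs = [cost]
    d = -g
    converged, msg = False, "max epochs reached"
    best = (cost, theta.copy())
    for k in range(cfg.max_epochs):
        if np.max(np.abs(g)) < cfg.grad_tol:
            converged, msg = True, "gradient tolerance reached"
            break
        if quasi_newton:
            d = -H @ g
        elif k % P == 0 and k > 0:
            d = -g  # periodic CG restart
        if g @ d >= 0:  # not a descent direction: restart steepest
            d = -g
            if quasi_newton:
                H = np.eye(P)
        alpha = _wolfe_step(cost_fn, grad_fn, theta, d, g, cost)
        if alpha is None:
            converged, msg = True, "line search failed (no descent)"
            break
        theta_new = theta + alpha * d
        g_new = grad_fn(theta_new)
        cost_new = cost_fn(theta_new)
        _check_finite(cost_new, cfg.method)
        s, yk = theta_new - theta, g_new - g
        if quasi_newton:
            sy = float(s @ yk)
            if sy > 1e-12:
                if cfg.method == "quasi_newton_bfgs":
                    rho = 1.0 / sy
                    V = np.eye(P) - rho * np.outer(s, yk)
                    H = V @ H @ V.T + rho * np.outer(s, s)
                else:  # DFP
                    Hy = H @ yk
                    H = H + np.outer(s, s) / sy - np.outer(Hy, Hy) / float(yk @ Hy)
        else:
            gg_prev = float(g @ g)
            if cfg.method == "cg_fletcher":
                beta = float(g_new @ g_new) / gg_prev
            else:  # Polak-Ribiere plus
                beta = max(0.0, float(g_new @ (g_new - g)) / gg_prev)
            d = -g_new + beta * d
        theta, g, cost = theta_new, g_new, cost_new
        costs.append(cost)
        if cost < best[0]:
            best = (cost, theta.copy())
        if cost <= cfg.cost_goal:
            converged, msg = True, "cost goal reached"
            break
    if best[0] < cost:
        theta = best[1]
    return theta, costs, converged, msg


def _train_scg(theta, n, X, t, cfg, activation):
    """Moller's scaled conjugate gradient (trust-region scaling, no search)."""
    N = len(t)

    def cost_fn(th):
        r = _core_output(th, n, X, activation)[0] - t
        return float(r @ r) / N

    def grad_fn(th):
        r = _core_output(th, n, X, activation)[0] - t
        return 2.0 * (_jacobian(th, n, X, activation).T @ r) / N

    sigma0, lam, lam_bar = 1e-4, 1e-6, 0.0
    cost = cost_fn(theta)
    g = grad_fn(theta)
    r_dir = -g
    d = r_dir.copy()
    success = True
    costs = [cost]
    converged, msg = False, "max epochs reached"
    P = theta.size
    delta = 0.0
    for k in range(cfg.max_epochs):
        if np.max(np.abs(g)) < cfg.grad_tol:
            converged, msg = True, "gradient tolerance reached"
            break
        d_norm2 = float(d @ d)
        if d_norm2 == 0:
            converged, msg = True, "zero search direction"
            break
        if success:
            sigma = sigma0 / np.sqrt(d_norm2)
            s_vec = (grad_fn(theta + sigma * d) - g) / sigma
            delta = float(d @ s_vec)
        delta_k = delta + (lam - lam_bar) * d_norm2
        if delta_k <= 0:  # make the Hessian model positive definite
            lam_bar = 2.0 * (lam - delta_k / d_norm2)
            delta_k = -delta + lam * d_norm2
            lam = lam_bar
        mu = float(d @ r_dir)
        alpha = mu / delta_k
        theta_new = theta + alpha * d
        cost_new = cost_fn(theta_new)
        _check_finite(cost_new, "scaled_conjugate_gradient")
        comparison = 2.0 * delta_k * (cost - cost_new) / mu**2
        if comparison >= 0:  # successful step
            theta, cost = theta_new, cost_new
            g_new = grad_fn(theta)
            r_new = -g_new
            lam_bar, success = 0.0, True
            if (k + 1) % P == 0:
                d = r_new
            else:
                beta = (float(r_new @ r_new) - float(r_new @ r_dir)) / mu
                d = r_new + beta * d
            g, r_dir = g_new, r_new
            if comparison >= 0.75:
                lam = max(lam / 4.0, 1e-15)
            costs.append(cost)
            if cost <= cfg.cost_goal:
                converged, msg = True, "cost goal reached"
                break
        else:
            lam_bar, success = lam, False
        if comparison < 0.25:
            lam = lam + delta_k * (1.0 - comparison) / d_norm2
        if lam > 1e12:
            converged, msg = True, "trust region collapsed"
            break
    return theta, costs, converged, msg


def train(
    ds_train: ViabilityDataset, config: TrainingConfig
) -> tuple[ANNModel, TrainingHistory]:
    """Fit a one-hidden-layer network to a training set.

    Inputs and targets are min-max scaled per ``config.scaling_mode`` using
    the training data's ranges; the cost is the mean squared error in that
    working space.  Initial weights are uniform(-0.5, 0.5) from the seed.
    Returns the best-cost iterate and the accepted-cost history; if the
    epoch budget runs out first the history's ``converged`` flag is False.
    """
    if len(ds_train) < 2:
        raise ValueError("training set too small")
    scaling = _data_scaling(ds_train, config.scaling_mode)
    X = scaling.scale_inputs(ds_train.points)
    t = scaling.scale_output(ds_train.viability)
    n = config.neurons
    rng = np.random.default_rng(config.seed)
    theta0 = rng.uniform(-0.5, 0.5, size=5 * n + 1)

    if config.method == "levenberg_marquardt":
        theta, costs, converged, msg = _train_lm(
            theta0, n, X, t, config, config.activation)
    elif config.method == "scaled_conjugate_gradient":
        theta, costs, converged, msg = _train_scg(
            theta0, n, X, t, config, config.activation)
    else:
        theta, costs, converged, msg = _train_first_order(
            theta0, n, X, t, config, config.activation)

    A, B, bi, bii = _unpack(theta, n)
    model = ANNModel(
        A=A, B=B, bi=bi, bii=bii, scaling=scaling,
        activation=config.activation,
        notes=f"trained with {config.method}, seed {config.seed}",
    )
    return model, TrainingHistory(config.method, [float(c) for c in costs],
                                  converged, msg)


# ---------------------------------------------------------------------------
# evaluation

def evaluate(model: ANNModel, ds: ViabilityDataset) -> FitMetrics:
    """Table-style performance of a model on a dataset.

    MSE and Pearson R of predictions vs observations (raw response scale),
    plus the p-value of the observed-on-predicted simple regression F-test.
    With fewer than 3 rows the p-value (and R) are undefined and reported
    as NaN.
    """
    pred = model.predict(ds.points)
    obs = ds.viability
    mse = float(np.mean((pred - obs) ** 2))
    if len(obs) < 3:
        return FitMetrics(mse=mse, r_value=np.nan, p_value=np.nan)
    if np.ptp(pred) == 0 or np.ptp(obs) == 0:
        return FitMetrics(mse=mse, r_value=np.nan, p_value=np.nan)
    res = stats.linregress(pred, obs)
    return FitMetrics(mse=mse, r_value=float(res.rvalue), p_value=float(res.pvalue))


def model_comparison(candidates: Sequence[tuple[str, FitMetrics]]) -> pd.DataFrame:
    """Rank candidate models: ascending MSE, ties broken by R descending."""
    if not candidates:
        raise ValueError("at least one candidate required")
    df = pd.DataFrame(
        [(label, m.mse, m.r_value, m.p_value) for label, m in candidates],
        columns=["model", "mse", "r_value", "p_value"],
    )
    df = df.sort_values(
        ["mse", "r_value"], ascending=[True, False], kind="stable"
    ).reset_index(drop=True)
    return df
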