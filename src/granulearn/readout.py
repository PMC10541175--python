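"""Purkinje-cell readouts: least squares, ridge, nonnegative, online.

A readout neuron predicts f_hat(x) = w . h(x) (+ b for the nonnegative
variant) from expansion-layer activity. Performance is the fraction of
sign errors for categorical tasks, or the relative mean squared error
E[(f - f_hat)^2] / E[f^2] for continuous tasks, averaged over target
dimensions when there are several.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.linalg
from scipy.optimize import minimize

__all__ = [
    "ReadoutModel",
    "fit_least_squares",
    "fit_ridge",
    "fit_nonnegative",
    "fit_online_cf",
    "silent_fraction",
    "evaluate",
]


@dataclass
class ReadoutModel:
    """Fitted readout weights (M x Q) with optional bias and metadata."""

    w: np.ndarray
    bias: np.ndarray | None = None
    method: str = "lstsq"
    params: dict = field(default_factory=dict)

    def predict(self, H: np.ndarray) -> np.ndarray:
        """Predictions H^T w (+ bias) for activity H (M x P); returns P x Q."""
        out = np.asarray(H).T @ self.w
        if self.bias is not None:
            out = out + self.bias
        return out


def _as_2d_targets(Y: np.ndarray) -> np.ndarray:
    Y = np.asarray(Y, dtype=float)
    return Y[:, None] if Y.ndim == 1 else Y


def fit_least_squares(H: np.ndarray, Y: np.ndarray) -> ReadoutModel:
    """Minimum-norm least-squares readout.

    For M > P the P x P Gram system is solved (w = H G^+ Y with
    G = H^T H), which yields the same minimum-norm solution as the
    pseudo-inverse of H^T at a fraction of the cost.
    """
    H = np.asarray(H)
    Y = _as_2d_targets(Y)
    M, P = H.shape
    if Y.shape[0] != P:
        raise ValueError("activity and targets disagree on pattern count")
    if M > P:
        G = (H.T @ H).astype(np.float64)
        alpha, *_ = scipy.linalg.lstsq(G, Y, lapack_driver="gelsd")
        w = (H @ alpha).astype(np.float64)
    else:
        w, *_ = scipy.linalg.lstsq(H.T.astype(np.float64), Y, lapack_driver="gelsd")
    return ReadoutModel(w=w, method="lstsq")


def fit_ridge(H: np.ndarray, Y: np.ndarray, alpha_ridge: float) -> ReadoutModel:
    """Ridge readout minimizing sum_mu ||Y_mu - w.h_mu||^2 + M alpha ||w||^2.

    Note the regularizer scales with the layer size M, so alpha_ridge is
    comparable across expansion widths. alpha_ridge = 0 recovers least
    squares.
    """
    if alpha_ridge < 0:
        raise ValueError("alpha_ridge must be nonnegative")
    if alpha_ridge == 0:
        model = fit_least_squares(H, Y)
        model.method = "ridge"
        model.params = {"alpha_ridge": 0.0}
        return model
    H = np.asarray(H, dtype=np.float64)
    Y = _as_2d_targets(Y)
    M, P = H.shape
    lam = M * alpha_ridge
    if M > P:
        # dual form: w = H (H^T H + lam I)^{-1} Y
        G = H.T @ H
        w = H @ scipy.linalg.solve(G + lam * np.eye(P), Y, assume_a="pos")
    else:
        w = scipy.linalg.solve(H @ H.T + lam * np.eye(M), H @ Y, assume_a="pos")
    return ReadoutModel(w=w, method="ridge", params={"alpha_ridge": alpha_ridge})


def _nonneg_newton(H: np.ndarray, y: np.ndarray, lam: float,
                   max_iter: int = 200, tol: float = 1e-10):
    """Semismooth Newton solver for ridge-regularized nonnegative LS.

    At the optimum of min_{w>=0,b} 0.5||H^T w + b - y||^2
    + 0.5 lam ||w||^2 the KKT conditions give the rectified dual form
    w = (H alpha)_+ with alpha = -(residual)/lam and sum(alpha) = 0
    (free bias), reducing the M-dimensional program to a piecewise
    linear system in P+1 unknowns. The ridge term regularizes the
    Newton matrix, so convergence is fast and robust. Returns None on
    failure (caller falls back to a projected quasi-Newton solve).
    """
    M, P = H.shape
    alpha = np.zeros(P)
    b = float(np.mean(y))
    scale = max(float(np.max(np.abs(y))), 1e-30)

    def system(alpha, b):
        w = np.maximum(H @ alpha, 0.0)
        F = np.concatenate([H.T @ w + b - y + lam * alpha, [alpha.sum() * scale]])
        return w, F

    w, F = system(alpha, b)
    for _ in range(max_iter):
        res_norm = float(np.max(np.abs(F)))
        if res_norm <= tol * scale:
            return np.maximum(H @ alpha, 0.0), b
        active = (H @ alpha) > 0
        J = np.empty((P + 1, P + 1))
        Hs = H[active]
        J[:P, :P] = Hs.T @ Hs + lam * np.eye(P)
        J[:P, P] = 1.0
        J[P, :P] = scale
        J[P, P] = 0.0
        try:
            delta = scipy.linalg.solve(J, -F)
        except scipy.linalg.LinAlgError:
            return None
        step = 1.0
        for _ in range(50):
            a_new = alpha + step * delta[:P]
            b_new = b + step * delta[P]
            w_new, F_new = system(a_new, b_new)
            if np.max(np.abs(F_new)) < res_norm:
                alpha, b, F = a_new, b_new, F_new
                break
            step *= 0.5
        else:
            return None
    return None


def fit_nonnegative(
    H: np.ndarray,
    y: np.ndarray,
    l2: float = 1e-2,
    tol: float = 1e-12,
    max_iter: int = 20_000,
) -> ReadoutModel:
    """Nonnegative least squares with a free bias.

    Solves min_{w >= 0, b} 0.5 ||H^T w + b - y||^2
    + 0.5 lam ||w||^2 with lam = l2 * mean(H^2). The default l2 = 1e-2
    corresponds to requiring robustness of the readout against ~10%
    relative activity noise; without it the wide-layer optimum is a
    degenerate face of interpolating solutions that exploit
    arbitrarily ill-conditioned directions of the empirical kernel,
    and the returned point (hence the silent-synapse fraction) would
    be an artifact of solver internals. The program is solved by a
    semismooth Newton method on the P-dimensional dual KKT system
    (exact active sets: silent weights are exactly zero), falling back
    to projected L-BFGS-B if the Newton iteration fails. Targets must
    be nonnegative (map categories to {0, 1}; take |f| for signed
    continuous targets).
    """
    H = np.asarray(H, dtype=np.float64)
    y = np.asarray(y, dtype=float).ravel()
    M, P = H.shape
    if y.shape[0] != P:
        raise ValueError("activity and targets disagree on pattern count")
    if np.any(y < 0):
        raise ValueError("nonnegative readout requires nonnegative targets")

    lam = l2 * max(float(np.mean(H * H)), 1e-30)

    if lam > 0:
        sol = _nonneg_newton(H, y, lam)
        if sol is not None:
            w, b = sol
            return ReadoutModel(w=w[:, None], bias=np.array([b]),
                                method="nonneg", params={"l2": l2})

    def objective(z):
        w, b = z[:M], z[M]
        r = H.T @ w + b - y
        obj = 0.5 * float(r @ r) + 0.5 * lam * float(w @ w)
        grad = np.empty(M + 1)
        grad[:M] = H @ r + lam * w
        grad[M] = r.sum()
        return obj, grad

    z0 = np.zeros(M + 1)
    bounds = [(0.0, None)] * M + [(None, None)]
    res = minimize(objective, z0, jac=True, method="L-BFGS-B", bounds=bounds,
                   options={"maxiter": max_iter, "ftol": tol, "gtol": 1e-12,
                            "maxfun": 10 * max_iter})
    pg = np.asarray(res.jac, dtype=float).copy()
    at_bound = res.x[:M] <= 1e-14
    pg[:M][at_bound] = np.minimum(pg[:M][at_bound], 0.0)
    grad_norm = float(np.max(np.abs(pg)))
    if not res.success and grad_norm > 1e-6 * max(1.0, float(np.max(np.abs(y)))):
        raise RuntimeError(f"nonnegative readout failed to converge: {res.message}")
    w = np.maximum(res.x[:M], 0.0)
    return ReadoutModel(w=w[:, None], bias=np.array([res.x[M]]),
                        method="nonneg", params={"l2": l2})


def silent_fraction(w: np.ndarray, tol: float | None = None) -> float:
    """Fraction of readout weights that are silent (<= tol).

    Default tolerance is 1e-6 times the largest absolute weight.
    """
    w = np.asarray(w).ravel()
    if tol is None:
        tol = 1e-6 * float(np.max(np.abs(w))) if w.size else 0.0
    return float(np.mean(w <= tol))


def fit_online_cf(
    H: np.ndarray,
    y: np.ndarray,
    eta: float,
    n_epochs: int,
    seed=None,
    divergence_factor: float = 10.0,
) -> ReadoutModel:
    """Online climbing-fiber (LMS/delta) rule.

    Each epoch presents the P training patterns in a fresh random order;
    for each pattern the weights are updated by Delta w = eta c h(x)
    with climbing-fiber error c = f(x) - w . h(x). Weights start at
    zero. Training aborts with a diagnostic if the epoch-mean squared
    error grows by ``divergence_factor`` over a 10-epoch window.
    """
    if eta <= 0:
        raise ValueError("learning rate eta must be positive")
    H = np.asarray(H, dtype=np.float64)
    y = np.asarray(y, dtype=float).ravel()
    M, P = H.shape
    rng = np.random.default_rng(seed)
    w = np.zeros(M)
    window: list[float] = []
    for epoch in range(n_epochs):
        order = rng.permutation(P)
        sq = 0.0
        with np.errstate(over="ignore", invalid="ignore"):
            for mu in order:
                h = H[:, mu]
                c = y[mu] - w @ h
                w += (eta * c) * h
                sq += c * c
        mse = sq / P
        if not np.isfinite(mse):
            raise RuntimeError(f"online rule diverged (non-finite error) at epoch {epoch}")
        window.append(mse)
        if len(window) > 10:
            window.pop(0)
            if window[0] > 0 and mse > divergence_factor * window[0] and mse > 1e-12:
                raise RuntimeError(
                    f"online rule diverging at epoch {epoch}: "
                    f"mse {window[0]:.3g} -> {mse:.3g}"
                )
    return ReadoutModel(w=w[:, None], method="online",
                        params={"eta": eta, "n_epochs": n_epochs, "seed": seed})


def evaluate(
    model: ReadoutModel,
    H_test: np.ndarray,
    Y_test: np.ndarray,
    task_kind: str,
) -> float:
    """Test error of a fitted readout.

    Continuous targets: relative mean squared error
    E[(f - f_hat)^2] / E[f^2] per target dimension, averaged across
    dimensions. Categorical: fraction of sign errors, with sign(0)
    counted as +1.
    """
    Y = _as_2d_targets(Y_test)
    preds = model.predict(H_test)
    if preds.shape != Y.shape:
        raise ValueError("prediction and target shapes disagree")
    if task_kind == "categorical":
        decisions = np.where(preds >= 0, 1.0, -1.0)
        return float(np.mean(decisions != Y))
    if task_kind == "continuous":
        denom = np.mean(Y**2, axis=0)
        if np.any(denom == 0):
            raise ValueError("zero target power: relative error undefined")
        rel = np.mean((Y - preds) ** 2, axis=0) / denom
        return float(np.mean(rel))
    raise ValueError(f"unknown task kind {task_kind!r}")
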