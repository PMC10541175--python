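"""Kernel-spectral theory of expansion-layer generalization.

In the infinite-width limit, an expansion layer with Gaussian effective
weights and threshold-power nonlinearity phi(u) = max(u, 0)^p induces a
dot-product kernel on the sphere of task variables,

    K(rho) = E[(u - theta)_+^p (v - theta)_+^p],

with (u, v) standard bivariate normal of correlation rho = x . x'. Under
the uniform input measure its eigenfunctions are the spherical
harmonics; the Funk–Hecke theorem reduces each degree-k eigenvalue to a
1-D weighted integral of K against the degree-k ultraspherical
(Gegenbauer) polynomial. Decomposing a target function in the same
basis yields an analytic prediction of the generalization error of
kernel (ridge) regression with P training samples, via the standard
self-consistent spectral theory: with kappa solving

    kappa = ridge + kappa * sum_a lambda_a / (P lambda_a + kappa),

the normalized error is
    [sum_a cbar2_a kappa^2 / (P lambda_a + kappa)^2]
      / [(1 - gamma_v) sum_a cbar2_a],
    gamma_v = sum_a P lambda_a^2 / (P lambda_a + kappa)^2,

where sums run over modes (degeneracy-weighted degrees). All spectra use
the convention of harmonics orthonormal under the uniform probability
measure on the sphere.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import integrate, optimize, special
from scipy.stats import norm

__all__ = [
    "KernelModel",
    "KernelSpectrum",
    "TargetSpectrum",
    "GeneralizationPrediction",
    "analytic_kernel",
    "empirical_kernel",
    "kernel_eigenvalues",
    "gp_target_spectrum",
    "project_target_power",
    "predict_generalization_error",
    "degeneracy",
    "gegenbauer_normalized",
]


# ---------------------------------------------------------------------------
# Kernel of the infinite-width expansion layer
# ---------------------------------------------------------------------------


def _truncated_power_moment(mu, s, p: int):
    """E[(mu + s Z)_+^p] for Z ~ N(0,1), vectorized over mu and s >= 0.

    Uses the recursion I_p = mu I_{p-1} + (p-1) s^2 I_{p-2} with
    I_0 = Phi(mu/s), I_1 = mu Phi(mu/s) + s phi(mu/s); for s = 0 the
    moment degenerates to (mu)_+^p.
    """
    mu = np.asarray(mu, dtype=float)
    s = np.asarray(s, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(s > 0, mu / np.where(s > 0, s, 1.0), np.where(mu > 0, np.inf, -np.inf))
    I_prev = norm.cdf(z)          # I_0
    if p == 0:
        return I_prev
    I = mu * I_prev + s * norm.pdf(z)  # I_1
    for q in range(2, p + 1):
        I, I_prev = mu * I + (q - 1) * s**2 * I_prev, I
    return I


def _gl_panels(a: float, b: float, n_panels: int, n_nodes: int):
    """Composite Gauss-Legendre nodes and weights on [a, b]."""
    x, w = np.polynomial.legendre.leggauss(n_nodes)
    edges = np.linspace(a, b, n_panels + 1)
    half = np.diff(edges) / 2.0
    mid = (edges[:-1] + edges[1:]) / 2.0
    nodes = (mid[:, None] + half[:, None] * x[None, :]).ravel()
    weights = (half[:, None] * w[None, :]).ravel()
    return nodes, weights


def analytic_kernel(rho, theta: float, power: int = 1, normalize: bool = False):
    """Infinite-width kernel K(rho) = E[(u-theta)_+^p (v-theta)_+^p].

    (u, v) are standard bivariate normal with correlation rho. Evaluated
    by conditioning on u — the conditional moment E[(v-theta)_+^p | u]
    has a closed form via the Gaussian truncated-power recursion — and
    composite Gauss-Legendre quadrature over u on [theta, theta+13]
    (the integrand carries a standard normal density, so the truncated
    tail is below 1e-30); the integrand is smooth on that interval, so
    the panels resolve it to ~1e-12. rho = 1 is fully closed-form. With
    ``normalize=True`` returns K(rho)/K(1) so that identical inputs
    have overlap 1.
    """
    if power < 1:
        raise ValueError("power must be >= 1")
    rho_arr = np.atleast_1d(np.asarray(rho, dtype=float))
    if np.any(np.abs(rho_arr) > 1.0 + 1e-12):
        raise ValueError("rho must lie in [-1, 1]")
    rho_arr = np.clip(rho_arr, -1.0, 1.0)
    K1 = float(_truncated_power_moment(-theta, np.asarray(1.0), 2 * power))
    u, wu = _gl_panels(theta, theta + 13.0, 16, 60)
    base = norm.pdf(u) * (u - theta) ** power * wu          # (n_u,)
    s = np.sqrt(np.maximum(0.0, 1.0 - rho_arr**2))[:, None]
    cond = _truncated_power_moment(rho_arr[:, None] * u[None, :] - theta, s, power)
    out = cond @ base
    out[rho_arr == 1.0] = K1
    if normalize:
        out = out / K1
    return out if np.ndim(rho) else float(out[0])


def empirical_kernel(H_a: np.ndarray, H_b: np.ndarray) -> np.ndarray:
    """Finite-width kernel (1/M) H_a^T H_b between two activity batches."""
    H_a, H_b = np.atleast_2d(H_a), np.atleast_2d(H_b)
    if H_a.shape[0] != H_b.shape[0]:
        raise ValueError("activity batches disagree on layer size M")
    return (H_a.T @ H_b) / H_a.shape[0]


@dataclass
class KernelModel:
    """Dot-product kernel of a thresholded infinite-width expansion.

    ``theta`` is the activation threshold; the implied coding level is
    f = P(Z > theta) for standard normal preactivations.
    """

    theta: float
    power: int = 1
    normalization: str = "raw"   # or "unit-diagonal"

    @classmethod
    def from_coding_level(cls, f: float, power: int = 1, normalization: str = "raw"):
        if not 0.0 < f < 1.0:
            raise ValueError("coding level must lie in (0, 1)")
        return cls(theta=float(norm.ppf(1.0 - f)), power=power,
                   normalization=normalization)

    @property
    def f(self) -> float:
        return float(norm.sf(self.theta))

    def __call__(self, rho):
        return analytic_kernel(rho, self.theta, self.power,
                               normalize=self.normalization == "unit-diagonal")

    @property
    def diagonal(self) -> float:
        """K(1), the kernel value at identical inputs."""
        return float(_truncated_power_moment(-self.theta, 1.0, 2 * self.power))


# ---------------------------------------------------------------------------
# Funk–Hecke eigendecomposition on the sphere
# ---------------------------------------------------------------------------


def degeneracy(D: int, k) -> np.ndarray:
    """Number N(D, k) of independent degree-k spherical harmonics in R^D."""
    if D < 2:
        raise ValueError("sphere dimension parameter D must be >= 2")
    k_arr = np.atleast_1d(np.asarray(k, dtype=int))
    out = np.empty(k_arr.shape, dtype=float)
    for i, kk in enumerate(k_arr):
        if kk == 0:
            out[i] = 1.0
        elif D == 2:
            out[i] = 2.0
        else:
            out[i] = (2 * kk + D - 2) / (D - 2) * special.comb(kk + D - 3, kk)
    return out if np.ndim(k) else float(out[0])


def gegenbauer_normalized(k: int, D: int, t: np.ndarray) -> np.ndarray:
    """Degree-k ultraspherical polynomial with P_{k,D}(1) = 1.

    Legendre for D = 3, Chebyshev (cos k arccos t) for D = 2, and the
    Gegenbauer polynomial with parameter (D-2)/2 otherwise.
    """
    t = np.asarray(t, dtype=float)
    if D == 2:
        return np.cos(k * np.arccos(np.clip(t, -1.0, 1.0)))
    if D == 3:
        return special.eval_legendre(k, t)
    alpha = (D - 2) / 2.0
    return special.eval_gegenbauer(k, alpha, t) / special.eval_gegenbauer(k, alpha, 1.0)


def _funk_hecke(kernel_fn, D: int, k_max: int,
                n_start: int = 256, n_max: int = 8192, rtol: float = 1e-10) -> np.ndarray:
    """Per-degree eigenvalues of a dot-product kernel on the sphere.

    lambda_k = int K(t) P_{k,D}(t) w(t) dt / int w(t) dt with weight
    w(t) = (1 - t^2)^{(D-3)/2}. Gauss–Legendre nodes with the weight
    folded into the integrand (Chebyshev–Gauss for D = 2, where the
    weight is singular at the endpoints); node count is doubled until
    the spectrum is stable.
    """
    prev = None
    n = n_start
    while True:
        if D == 2:
            i = np.arange(1, n + 1)
            t = np.cos((2 * i - 1) * np.pi / (2 * n))
            kv = np.asarray(kernel_fn(t))
            lam = np.array([np.mean(kv * gegenbauer_normalized(k, D, t))
                            for k in range(k_max + 1)])
        else:
            t, wq = np.polynomial.legendre.leggauss(n)
            wgt = wq * (1.0 - t * t) ** ((D - 3) / 2.0)
            norm_const = wgt.sum()
            kv = np.asarray(kernel_fn(t))
            lam = np.array([np.sum(kv * gegenbauer_normalized(k, D, t) * wgt)
                            for k in range(k_max + 1)]) / norm_const
        if prev is not None:
            scale = max(np.max(np.abs(lam)), 1e-300)
            if np.max(np.abs(lam - prev)) < rtol * scale:
                return lam
        if n >= n_max:
            if prev is None:
                return lam
            raise RuntimeError(
                "Funk-Hecke quadrature did not converge under node doubling"
            )
        prev = lam
        n *= 2


@dataclass
class KernelSpectrum:
    """Per-degree kernel eigenvalues with their degeneracies."""

    D: int
    lambdas: np.ndarray
    degeneracies: np.ndarray

    def __post_init__(self):
        self.lambdas = np.asarray(self.lambdas, dtype=float)
        self.degeneracies = np.asarray(self.degeneracies, dtype=float)
        if np.any(self.lambdas < -1e-10 * max(self.trace, 1e-300)):
            raise ValueError("kernel spectrum has a substantially negative eigenvalue")
        self.lambdas = np.maximum(self.lambdas, 0.0)

    @property
    def k_max(self) -> int:
        return len(self.lambdas) - 1

    @property
    def trace(self) -> float:
        """sum_k N(D,k) lambda_k; equals K(1) for an adequate k_max."""
        return float(np.sum(np.abs(self.lambdas) * self.degeneracies))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "degree": np.arange(self.k_max + 1),
            "eigenvalue": self.lambdas,
            "degeneracy": self.degeneracies,
        })


@dataclass
class TargetSpectrum:
    """Per-degree expected target power (per mode) on the sphere."""

    D: int
    mode_power: np.ndarray       # cbar^2_k, expected power per mode
    degeneracies: np.ndarray

    def __post_init__(self):
        self.mode_power = np.maximum(np.asarray(self.mode_power, dtype=float), 0.0)
        self.degeneracies = np.asarray(self.degeneracies, dtype=float)

    @property
    def k_max(self) -> int:
        return len(self.mode_power) - 1

    @property
    def degree_power(self) -> np.ndarray:
        """Total power per degree, N(D,k) cbar^2_k."""
        return self.mode_power * self.degeneracies

    @property
    def total_power(self) -> float:
        return float(np.sum(self.degree_power))

    def normalized(self) -> "TargetSpectrum":
        return TargetSpectrum(self.D, self.mode_power / self.total_power,
                              self.degeneracies)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "degree": np.arange(self.k_max + 1),
            "mode_power": self.mode_power,
            "degeneracy": self.degeneracies,
            "degree_power": self.degree_power,
        })


def default_k_max(D: int) -> int:
    """Truncation degree capturing >= 99% of the kernel trace for the
    default settings (60 for D = 3, 25 for D = 6, interpolated elsewhere)."""
    if D <= 3:
        return 60
    if D <= 6:
        return 40 if D < 6 else 25
    return 20


def kernel_eigenvalues(kernel: KernelModel, D: int, k_max: int | None = None) -> KernelSpectrum:
    """Funk–Hecke spectrum of the infinite-width expansion kernel."""
    if D < 2:
        raise ValueError("D must be >= 2")
    k_max = default_k_max(D) if k_max is None else k_max
    if k_max < 0:
        raise ValueError("k_max must be >= 0")
    fn = lambda t: analytic_kernel(t, kernel.theta, kernel.power,
                                   normalize=kernel.normalization == "unit-diagonal")
    lam = _funk_hecke(fn, D, k_max)
    return KernelSpectrum(D=D, lambdas=lam,
                          degeneracies=degeneracy(D, np.arange(k_max + 1)))


def gp_target_spectrum(gamma: float, D: int, k_max: int | None = None) -> TargetSpectrum:
    """Expected per-mode power of a Gaussian-process target on the sphere.

    On the unit sphere ||x - x'||^2 = 2 - 2 x.x', so the squared
    exponential covariance is the dot-product kernel
    C(t) = exp(-(1 - t)/gamma^2); the expected squared coefficient of a
    GP draw on each harmonic equals the covariance eigenvalue, obtained
    by the same Funk–Hecke quadrature.
    """
    if gamma <= 0:
        raise ValueError("gamma must be positive")
    if D < 2:
        raise ValueError("D must be >= 2")
    k_max = default_k_max(D) if k_max is None else k_max
    fn = lambda t: np.exp(-(1.0 - np.asarray(t)) / gamma**2)
    lam = _funk_hecke(fn, D, k_max)
    return TargetSpectrum(D=D, mode_power=np.maximum(lam, 0.0),
                          degeneracies=degeneracy(D, np.arange(k_max + 1)))


def project_target_power(
    inputs: np.ndarray, targets: np.ndarray, D: int, k_max: int
) -> TargetSpectrum:
    """Empirical per-degree power of a target sampled on the sphere.

    Uses the addition theorem: the total degree-k power is
    N(D,k) E[f(x) f(x') P_{k,D}(x . x')] over independent input pairs,
    estimated from all off-diagonal sample pairs.
    """
    X = np.atleast_2d(np.asarray(inputs, dtype=float))
    y = np.asarray(targets, dtype=float).ravel()
    P = X.shape[0]
    if X.shape[1] != D:
        raise ValueError("inputs dimension disagrees with D")
    if y.shape[0] != P:
        raise ValueError("inputs and targets disagree on sample count")
    G = np.clip(X @ X.T, -1.0, 1.0)
    outer = np.outer(y, y)
    off = ~np.eye(P, dtype=bool)
    n_pairs = P * (P - 1)
    degs = degeneracy(D, np.arange(k_max + 1))
    degree_power = np.empty(k_max + 1)
    for k in range(k_max + 1):
        Pk = gegenbauer_normalized(k, D, G)
        degree_power[k] = degs[k] * float(np.sum(outer[off] * Pk[off])) / n_pairs
    return TargetSpectrum(D=D, mode_power=np.maximum(degree_power, 0.0) / degs,
                          degeneracies=degs)


# ---------------------------------------------------------------------------
# Generalization-error prediction
# ---------------------------------------------------------------------------


@dataclass
class GeneralizationPrediction:
    """Predicted normalized generalization error of kernel regression.

    ``kappa`` is the self-consistent scale, ``variance_factor`` the
    over-fitting amplification 1/(1 - gamma_v); the error constants of
    the per-mode form Error = C1 sum_a (c_a / (C2 + lambda_a))^2 are
    C2 = kappa / P and C1 = C2^2 * variance_factor.
    """

    P: int
    kappa: float
    variance_factor: float
    error: float
    degree_error_shares: np.ndarray
    ridge: float

    @property
    def C2(self) -> float:
        return self.kappa / self.P if self.P > 0 else math.inf

    @property
    def C1(self) -> float:
        return self.C2**2 * self.variance_factor

    def summary(self) -> dict:
        return {"P": self.P, "kappa": self.kappa,
                "variance_factor": self.variance_factor, "error": self.error,
                "C1": self.C1, "C2": self.C2, "ridge": self.ridge}


def predict_generalization_error(
    spectrum: KernelSpectrum,
    target: TargetSpectrum,
    P: int,
    ridge: float = 0.0,
) -> GeneralizationPrediction:
    """Predict the relative mean-squared generalization error.

    ``spectrum`` and ``target`` must share (D, k_max). ``ridge`` is the
    explicit regularization of kernel ridge regression; for ridgeless
    (interpolating) regression a jitter of 1e-9 K(1) stabilizes the
    root finding and changes the prediction negligibly.
    """
    if spectrum.D != target.D or spectrum.k_max != target.k_max:
        raise ValueError("kernel and target spectra must share (D, k_max)")
    if P < 0:
        raise ValueError("P must be nonnegative")
    lam = spectrum.lambdas
    Nk = spectrum.degeneracies
    c2 = target.mode_power
    trace = spectrum.trace
    ridge_eff = ridge if ridge > 0 else 1e-9 * trace

    def gap(kappa):
        return kappa - ridge_eff - kappa * np.sum(Nk * lam / (P * lam + kappa))

    hi = ridge_eff + trace + 1e-300
    lo = min(1e-14 * hi, ridge_eff)
    while gap(hi) < 0:
        hi *= 2.0
    kappa = float(optimize.brentq(gap, lo, hi, xtol=1e-300, rtol=1e-14))
    denom = P * lam + kappa
    gamma_v = float(np.sum(Nk * P * lam**2 / denom**2))
    if gamma_v >= 1.0:
        raise FloatingPointError(
            f"mode-variance sum gamma_v = {gamma_v:.6f} >= 1: prediction diverges"
        )
    total = float(np.sum(Nk * c2))
    if total <= 0:
        raise ValueError("target spectrum has zero total power")
    shares = Nk * c2 * kappa**2 / denom**2
    error = float(np.sum(shares)) / ((1.0 - gamma_v) * total)
    return GeneralizationPrediction(
        P=P, kappa=kappa, variance_factor=1.0 / (1.0 - gamma_v),
        error=error, degree_error_shares=shares / max(np.sum(shares), 1e-300),
        ridge=ridge_eff,
    )
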