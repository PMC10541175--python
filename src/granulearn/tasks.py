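"""Synthetic learning tasks for cerebellar expansion-layer models.

Every task used in this package is generated internally; there is no
external data. Four families are provided:

* random categorization — random input patterns with binary labels, the
  classic Marr–Albus benchmark; generalization is probed with noisy
  copies of the training patterns,
* Gaussian-process regression — smooth targets on the unit sphere whose
  spatial length scale controls how quickly the output varies,
* two-joint arm forward model — predict the Cartesian hand displacement
  of a planar arm after a fixed horizon from its sensorimotor state,
* VOR adaptation — piecewise-linear Purkinje-cell tuning targets with
  exponentially tuned mossy-fiber input channels.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "TaskDataset",
    "ArmParameters",
    "ArmState",
    "VorTaskSpec",
    "sample_random_categorization",
    "sample_gp_task",
    "simulate_arm",
    "sample_arm_task",
    "sample_vor_task",
    "vor_target_grid",
    "default_mossy_parameters",
    "sample_sphere",
]

TASK_KINDS = ("categorical", "continuous")
INPUT_MODES = ("task_subspace", "direct_input_layer")


@dataclass
class TaskDataset:
    """Train/test inputs and targets plus generator metadata.

    ``train_inputs`` is P x D (task variables, or input-layer activities
    when ``input_mode == "direct_input_layer"``); targets are P x Q with
    Q = 1 except for the arm task (Q = 2, one per Cartesian coordinate).
    """

    train_inputs: np.ndarray
    train_targets: np.ndarray
    test_inputs: np.ndarray
    test_targets: np.ndarray
    task_kind: str
    input_mode: str = "task_subspace"
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in ("train_inputs", "train_targets", "test_inputs", "test_targets"):
            arr = np.atleast_2d(np.asarray(getattr(self, name), dtype=float))
            setattr(self, name, arr)
        if self.task_kind not in TASK_KINDS:
            raise ValueError(f"task_kind must be one of {TASK_KINDS}")
        if self.input_mode not in INPUT_MODES:
            raise ValueError(f"input_mode must be one of {INPUT_MODES}")
        if self.train_inputs.shape[0] != self.train_targets.shape[0]:
            raise ValueError("train inputs/targets pattern counts differ")
        if self.test_inputs.shape[0] != self.test_targets.shape[0]:
            raise ValueError("test inputs/targets pattern counts differ")
        if self.train_inputs.shape[1] != self.test_inputs.shape[1]:
            raise ValueError("train/test input dimensions differ")
        if self.train_targets.shape[1] != self.test_targets.shape[1]:
            raise ValueError("train/test target dimensions differ")
        if self.task_kind == "categorical":
            vals = np.unique(np.concatenate([self.train_targets.ravel(), self.test_targets.ravel()]))
            if not np.all(np.isin(vals, (-1.0, 1.0))):
                raise ValueError("categorical targets must take values in {-1, +1}")

    @property
    def n_train(self) -> int:
        return self.train_inputs.shape[0]

    @property
    def n_test(self) -> int:
        return self.test_inputs.shape[0]

    @property
    def input_dim(self) -> int:
        return self.train_inputs.shape[1]

    @property
    def n_targets(self) -> int:
        return self.train_targets.shape[1]

    # -- serialization: one CSV table per array, one JSON block of metadata --

    _TABLES = ("train_inputs", "train_targets", "test_inputs", "test_targets")

    def save(self, path: str | Path) -> Path:
        """Write the dataset to ``path`` (a directory) as CSV + JSON."""
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        for name in self._TABLES:
            pd.DataFrame(getattr(self, name)).to_csv(
                path / f"{name}.csv", index=False, float_format="%.17g"
            )
        meta = {
            "task_kind": self.task_kind,
            "input_mode": self.input_mode,
            "metadata": _jsonable(self.metadata),
        }
        (path / "metadata.json").write_text(json.dumps(meta, indent=1))
        return path

    @classmethod
    def load(cls, path: str | Path) -> "TaskDataset":
        path = Path(path)
        meta = json.loads((path / "metadata.json").read_text())
        arrays = {
            name: pd.read_csv(path / f"{name}.csv",
                              float_precision="round_trip").to_numpy(dtype=float)
            for name in cls._TABLES
        }
        return cls(
            task_kind=meta["task_kind"],
            input_mode=meta["input_mode"],
            metadata=meta["metadata"],
            **arrays,
        )


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.generic):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if obj is None or isinstance(obj, (bool, int, float, str)):
        return obj
    return repr(obj)


def sample_sphere(n: int, D: int, rng: np.random.Generator) -> np.ndarray:
    """Draw ``n`` points uniformly on the unit sphere in ``D`` dimensions.

    Gaussian vectors are normalized; the (measure-zero) zero vector is
    resampled.
    """
    x = rng.standard_normal((n, D))
    norms = np.linalg.norm(x, axis=1)
    while np.any(norms == 0.0):
        bad = norms == 0.0
        x[bad] = rng.standard_normal((int(bad.sum()), D))
        norms = np.linalg.norm(x, axis=1)
    return x / norms[:, None]


def sample_random_categorization(
    P: int, D: int, epsilon: float, seed=None
) -> TaskDataset:
    """Random binary categorization with noisy test copies.

    Training inputs have i.i.d. normal(0, 1/D) entries and labels +/-1
    with equal probability. Each training pattern x is paired with one
    test pattern sqrt(1 - eps^2) x + eps eta, eta ~ normal(0, I/D),
    carrying the same label, so the train/test correlation is
    sqrt(1 - eps^2) on average.
    """
    if P < 1 or D < 1:
        raise ValueError("P and D must be >= 1")
    if not 0.0 <= epsilon <= 1.0:
        raise ValueError(f"epsilon must lie in [0, 1], got {epsilon}")
    rng = np.random.default_rng(seed)
    scale = 1.0 / math.sqrt(D)
    x = rng.standard_normal((P, D)) * scale
    y = (rng.integers(0, 2, size=P) * 2 - 1).astype(float)
    eta = rng.standard_normal((P, D)) * scale
    x_test = math.sqrt(1.0 - epsilon**2) * x + epsilon * eta
    return TaskDataset(
        train_inputs=x,
        train_targets=y[:, None],
        test_inputs=x_test,
        test_targets=y[:, None],
        task_kind="categorical",
        metadata={"family": "random_categorization", "P": P, "D": D,
                  "epsilon": epsilon, "seed": seed},
    )


def _gp_covariance(X: np.ndarray, gamma: float) -> np.ndarray:
    sq = np.sum(X**2, axis=1)
    d2 = sq[:, None] + sq[None, :] - 2.0 * X @ X.T
    np.maximum(d2, 0.0, out=d2)
    return np.exp(-d2 / (2.0 * gamma**2))


def _jittered_cholesky(C: np.ndarray, jitter0: float = 1e-10, n_escalations: int = 3):
    jitter = jitter0
    for _ in range(n_escalations + 1):
        try:
            return np.linalg.cholesky(C + jitter * np.eye(C.shape[0]))
        except np.linalg.LinAlgError:
            jitter *= 10.0
    raise np.linalg.LinAlgError(
        f"GP covariance Cholesky failed up to jitter {jitter / 10.0:g}"
    )


def sample_gp_task(
    P_train: int, P_test: int, D: int, gamma: float, seed=None
) -> TaskDataset:
    """Gaussian-process target on the unit sphere.

    Inputs are uniform on the sphere; targets are a single joint draw
    from GP(0, C) over the union of train and test points, with squared
    exponential covariance C(x, x') = exp(-||x - x'||^2 / (2 gamma^2)).
    """
    if gamma <= 0:
        raise ValueError("gamma must be positive")
    rng = np.random.default_rng(seed)
    X = sample_sphere(P_train + P_test, D, rng)
    L = _jittered_cholesky(_gp_covariance(X, gamma))
    f = L @ rng.standard_normal(P_train + P_test)
    return TaskDataset(
        train_inputs=X[:P_train],
        train_targets=f[:P_train, None],
        test_inputs=X[P_train:],
        test_targets=f[P_train:, None],
        task_kind="continuous",
        metadata={"family": "gp", "P": P_train, "P_test": P_test, "D": D,
                  "gamma": gamma, "seed": seed},
    )


# ---------------------------------------------------------------------------
# Two-joint planar arm
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ArmParameters:
    """Physical parameters of the planar two-joint arm (SI units)."""

    m1: float = 3.0       # upper segment mass, kg
    m2: float = 2.5       # lower segment mass, kg
    l1: float = 0.3       # upper segment length, m
    l2: float = 0.35      # lower segment length, m
    lbar2: float = 0.21   # lower segment center of mass, m
    I1: float = 0.1       # upper moment of inertia, kg m^2
    I2: float = 0.12      # lower moment of inertia, kg m^2
    D1: float = 0.05      # upper joint friction, kg m^2 / s
    D2: float = 0.01      # lower joint friction, kg m^2 / s
    delta: float = 0.2    # prediction horizon, s

    def __post_init__(self):
        for name in ("m1", "m2", "l1", "l2", "lbar2", "I1", "I2", "delta"):
            if getattr(self, name) <= 0:
                raise ValueError(f"arm parameter {name} must be strictly positive")
        for name in ("D1", "D2"):
            if getattr(self, name) < 0:
                raise ValueError(f"friction {name} must be nonnegative")


@dataclass
class ArmState:
    """Joint angles (rad), angular velocities (rad/s) and torques (N m)."""

    theta1: float
    theta2: float
    dtheta1: float = 0.0
    dtheta2: float = 0.0
    u1: float = 0.0
    u2: float = 0.0

    def __post_init__(self):
        vals = [self.theta1, self.theta2, self.dtheta1, self.dtheta2, self.u1, self.u2]
        if not np.all(np.isfinite(vals)):
            raise ValueError("arm state must be finite")


def _inertia(theta2: float, p: ArmParameters) -> np.ndarray:
    # Symmetric inertia matrix; the coupling term uses the lower-arm center
    # of mass so that kinetic energy is conserved in the frictionless,
    # unforced case.
    a = p.m2 * p.l1 * p.lbar2 * math.cos(theta2)
    return np.array(
        [[p.I1 + p.I2 + p.m2 * p.l1**2 + 2.0 * a, p.I2 + a],
         [p.I2 + a, p.I2]]
    )


def _arm_derivatives(y: np.ndarray, u: np.ndarray, p: ArmParameters) -> np.ndarray:
    th2 = y[1]
    dth = y[2:4]
    a = p.m2 * p.l1 * p.lbar2 * math.sin(th2)
    C = np.array([[-2.0 * a * dth[1] + p.D1, -a * dth[1]],
                  [a * dth[0], p.D2]])
    M = _inertia(th2, p)
    ddth = np.linalg.solve(M, u - C @ dth)
    return np.concatenate([dth, ddth])


def _hand_position(theta1: float, theta2: float, p: ArmParameters) -> np.ndarray:
    return np.array(
        [p.l1 * math.cos(theta1) + p.l2 * math.cos(theta1 + theta2),
         p.l1 * math.sin(theta1) + p.l2 * math.sin(theta1 + theta2)]
    )


def kinetic_energy(state_vec: np.ndarray, params: ArmParameters) -> float:
    """Kinetic energy 0.5 dtheta^T M(theta) dtheta for a (4,) state vector."""
    dth = state_vec[2:4]
    return 0.5 * float(dth @ _inertia(state_vec[1], params) @ dth)


def integrate_arm(
    state: ArmState,
    params: ArmParameters | None = None,
    delta: float | None = None,
    dt: float = 1e-3,
) -> np.ndarray:
    """Integrate the arm dynamics and return the final (theta1, theta2,
    dtheta1, dtheta2) state vector.

    Fixed-step classical Runge–Kutta (RK4); torques are held constant
    over the horizon.
    """
    params = params or ArmParameters()
    delta = params.delta if delta is None else delta
    if delta <= 0 or dt <= 0:
        raise ValueError("delta and dt must be positive")
    y = np.array([state.theta1, state.theta2, state.dtheta1, state.dtheta2])
    u = np.array([state.u1, state.u2])
    n_steps = max(1, int(round(delta / dt)))
    h = delta / n_steps
    for _ in range(n_steps):
        k1 = _arm_derivatives(y, u, params)
        k2 = _arm_derivatives(y + 0.5 * h * k1, u, params)
        k3 = _arm_derivatives(y + 0.5 * h * k2, u, params)
        k4 = _arm_derivatives(y + h * k3, u, params)
        y = y + (h / 6.0) * (k1 + 2.0 * k2 + 2.0 * k3 + k4)
    return y


def simulate_arm(
    state: ArmState,
    params: ArmParameters | None = None,
    delta: float | None = None,
    dt: float = 1e-3,
) -> np.ndarray:
    """Cartesian hand displacement (2-vector, meters) after time ``delta``."""
    params = params or ArmParameters()
    y = integrate_arm(state, params, delta, dt)
    start = _hand_position(state.theta1, state.theta2, params)
    end = _hand_position(y[0], y[1], params)
    return end - start


def sample_arm_task(
    P: int,
    P_test: int | None = None,
    sigma_theta: float = 0.1,
    sigma_dtheta: float = 0.1,
    sigma_u: float = 1.0,
    params: ArmParameters | None = None,
    seed=None,
) -> TaskDataset:
    """Forward-model task: predict hand displacement from the arm state.

    Inputs are 6-D Gaussian draws scaled by (sigma_theta, sigma_theta,
    sigma_dtheta, sigma_dtheta, sigma_u, sigma_u), normalized to unit
    norm. Angles get a pi/4 offset when building the initial condition;
    torques are held constant over the horizon. Targets are the two
    Cartesian components of the hand displacement; test patterns are
    fresh draws from the same distribution.
    """
    if min(sigma_theta, sigma_dtheta, sigma_u) <= 0:
        raise ValueError("scales must be positive")
    params = params or ArmParameters()
    P_test = P if P_test is None else P_test
    rng = np.random.default_rng(seed)
    scales = np.array([sigma_theta, sigma_theta, sigma_dtheta, sigma_dtheta,
                       sigma_u, sigma_u])

    def draw(n: int):
        x = rng.standard_normal((n, 6)) * scales
        norms = np.linalg.norm(x, axis=1)
        while np.any(norms == 0.0):
            bad = norms == 0.0
            x[bad] = rng.standard_normal((int(bad.sum()), 6)) * scales
            norms = np.linalg.norm(x, axis=1)
        x /= norms[:, None]
        targets = np.empty((n, 2))
        for i in range(n):
            state = ArmState(
                theta1=math.pi / 4 + x[i, 0], theta2=math.pi / 4 + x[i, 1],
                dtheta1=x[i, 2], dtheta2=x[i, 3], u1=x[i, 4], u2=x[i, 5],
            )
            targets[i] = simulate_arm(state, params)
        return x, targets

    x_tr, y_tr = draw(P)
    x_te, y_te = draw(P_test)
    return TaskDataset(
        train_inputs=x_tr, train_targets=y_tr,
        test_inputs=x_te, test_targets=y_te,
        task_kind="continuous",
        metadata={"family": "arm", "P": P, "P_test": P_test,
                  "sigma_theta": sigma_theta, "sigma_dtheta": sigma_dtheta,
                  "sigma_u": sigma_u, "delta": params.delta, "seed": seed},
    )


# ---------------------------------------------------------------------------
# Vestibulo-ocular reflex (VOR)
# ---------------------------------------------------------------------------


def default_mossy_parameters() -> list[tuple[float, int, float]]:
    """The 24 mossy-fiber tuning parameter combinations (gain, preferred
    direction, baseline): gains on 6 equally spaced points in [0.1, 1],
    direction in {-1, +1}, baseline in {0, 1}."""
    gains = np.linspace(0.1, 1.0, 6)
    return [(float(g), r, float(b)) for g in gains for r in (-1, 1) for b in (0.0, 1.0)]


@dataclass
class VorTaskSpec:
    """Piecewise-linear Purkinje tuning target and mossy-fiber battery."""

    m1: float
    m2: float
    b: float = 0.1
    c: float = -0.2
    mossy_params: list = field(default_factory=default_mossy_parameters)

    def __post_init__(self):
        if not -1.0 <= self.c <= 1.0:
            raise ValueError("breakpoint c must lie inside [-1, 1]")
        for g, r, bj in self.mossy_params:
            if r not in (-1, 1):
                raise ValueError("mossy-fiber direction r must be -1 or +1")

    def target(self, v: np.ndarray) -> np.ndarray:
        """Purkinje-cell firing-rate target at head velocity ``v``."""
        v = np.asarray(v, dtype=float)
        return np.where(v < self.c,
                        self.m1 * (v - self.c) + self.b,
                        self.m2 * (v - self.c) + self.b)

    def mossy_activity(self, v: np.ndarray) -> np.ndarray:
        """Input-layer activities n_j(v) = g_j exp(v r_j) + b_j, shape (len(v), 24)."""
        v = np.asarray(v, dtype=float)[:, None]
        g = np.array([p[0] for p in self.mossy_params])
        r = np.array([p[1] for p in self.mossy_params], dtype=float)
        b = np.array([p[2] for p in self.mossy_params])
        return g * np.exp(v * r) + b


def vor_target_grid(b: float = 0.1, c: float = -0.2) -> list[VorTaskSpec]:
    """The 25-target battery: all slope pairs on a 5-point grid over [-2, 2]."""
    slopes = np.linspace(-2.0, 2.0, 5)
    return [VorTaskSpec(m1=float(m1), m2=float(m2), b=b, c=c)
            for m1 in slopes for m2 in slopes]


def sample_vor_task(
    spec: VorTaskSpec, n_points: int = 100, P_train: int = 30, seed=None
) -> TaskDataset:
    """Sample a VOR adaptation dataset for one target function.

    Head velocities are uniform on [-1, 1]; inputs are the 24 mossy-fiber
    activities (direct input-layer mode, bypassing the task-subspace
    embedding); a random subset of ``P_train`` points is used for
    training and the remainder for testing.
    """
    if n_points < P_train:
        raise ValueError("n_points must be >= P_train")
    rng = np.random.default_rng(seed)
    v = rng.uniform(-1.0, 1.0, size=n_points)
    n = spec.mossy_activity(v)
    f = spec.target(v)
    perm = rng.permutation(n_points)
    tr, te = perm[:P_train], perm[P_train:]
    return TaskDataset(
        train_inputs=n[tr], train_targets=f[tr, None],
        test_inputs=n[te], test_targets=f[te, None],
        task_kind="continuous",
        input_mode="direct_input_layer",
        metadata={"family": "vor", "m1": spec.m1, "m2": spec.m2, "b": spec.b,
                  "c": spec.c, "n_points": n_points, "P": P_train,
                  "head_velocity_train": v[tr].tolist(),
                  "head_velocity_test": v[te].tolist(), "seed": seed},
    )
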