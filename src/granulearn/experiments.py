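"""Config-driven experiments: coding-level sweeps, architecture sweeps,
theory-vs-simulation comparisons.

Each experiment is described by an :class:`ExperimentConfig` (task,
network, sweep, replication and readout blocks). Named presets cover
the standard simulation settings of the model (random categorization,
Gaussian-process regression at several length scales, sparse and
clustered connectivity, in-degree and expansion-ratio sweeps, the arm
forward model, the mushroom-body categorization and VOR adaptation
tasks). Every result row carries the config hash and per-row seeds so
it can be reproduced independently.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import network as net
from . import readout as ro
from . import tasks
from . import theory

__all__ = [
    "DEFAULT_F_GRID",
    "DEFAULT_GAMMA_GRID",
    "ExperimentConfig",
    "SweepResult",
    "OptimalCodingLevel",
    "get_preset",
    "list_presets",
    "run_coding_level_sweep",
    "run_architecture_sweep",
    "run_theory_comparison",
    "find_optimal_coding_level",
    "input_layer_baseline",
    "make_fixtures",
]

# denser near zero, where categorization optima live
DEFAULT_F_GRID = (0.005, 0.01, 0.02, 0.03, 0.05, 0.075, 0.1,
                  0.15, 0.2, 0.25, 0.3, 0.35, 0.4, 0.5)
DEFAULT_GAMMA_GRID = (0.25, 0.5, 1.0, 2.0)


@dataclass
class ExperimentConfig:
    """Description of one experiment.

    ``task``: family and parameters; ``network``: architecture;
    ``sweep``: what is varied; ``replication``: number of seeds and the
    base seed; ``readout``: fitting method.
    """

    task: dict
    network: dict
    sweep: dict
    replication: dict = field(default_factory=lambda: {"n_seeds": 10, "base_seed": 0})
    readout: dict = field(default_factory=lambda: {"method": "lstsq"})
    name: str = "custom"

    def scaled(self, scale: float) -> "ExperimentConfig":
        """Divide the layer size M (or S) and the seed count by ``scale``
        for quick runs; scale = 1 reproduces the preset as printed."""
        if scale <= 0:
            raise ValueError("scale must be positive")
        cfg = ExperimentConfig(**json.loads(json.dumps(asdict(self))))
        for key in ("M",):
            if key in cfg.network and cfg.network[key]:
                cfg.network[key] = max(64, int(round(cfg.network[key] / scale)))
        if "S" in cfg.sweep:
            cfg.sweep["S"] = max(64, int(round(cfg.sweep["S"] / scale)))
        cfg.replication["n_seeds"] = max(1, int(round(cfg.replication["n_seeds"] / scale)))
        return cfg

    def hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=float)
        return hashlib.md5(payload.encode()).hexdigest()[:12]


@dataclass
class SweepResult:
    """Aggregated sweep rows plus per-replicate raw rows and provenance."""

    table: pd.DataFrame
    raw: pd.DataFrame
    config: ExperimentConfig
    provenance: dict

    def save(self, outdir: str | Path) -> Path:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.table.to_csv(outdir / "sweep.csv", index=False, float_format="%.10g")
        self.raw.to_csv(outdir / "raw.csv", index=False, float_format="%.10g")
        summary = {"provenance": self.provenance, "config": asdict(self.config)}
        if "f" in self.table.columns:
            opt = find_optimal_coding_level(self)
            summary["optimum"] = asdict(opt)
        (outdir / "summary.json").write_text(json.dumps(summary, indent=1, default=float))
        return outdir


@dataclass
class OptimalCodingLevel:
    """Estimated error-minimizing coding level on the sweep grid."""

    f_star: float
    resolution: float
    boundary: bool = False
    flat: bool = False
    interval: tuple | None = None


def _seed_for(base_seed: int, *keys: int) -> np.random.SeedSequence:
    """Counter-based per-row seed derivation; rows are independently
    reproducible from (base_seed, keys)."""
    return np.random.SeedSequence(entropy=int(base_seed), spawn_key=tuple(int(k) for k in keys))


# ---------------------------------------------------------------------------
# task / network construction from config blocks
# ---------------------------------------------------------------------------


def _make_task(task_cfg: dict, seed) -> tuple:
    """Returns (X_train, Y_train, X_test, Y_test, task_kind, direct_input)."""
    family = task_cfg["family"]
    if family == "random_categorization":
        ds = tasks.sample_random_categorization(
            task_cfg["P"], task_cfg["D"], task_cfg.get("epsilon", 0.1), seed=seed)
    elif family == "gp":
        ds = tasks.sample_gp_task(
            task_cfg["P"], task_cfg.get("P_test", 500), task_cfg["D"],
            task_cfg["gamma"], seed=seed)
    elif family == "arm":
        ds = tasks.sample_arm_task(
            task_cfg["P"], task_cfg.get("P_test", task_cfg["P"]), seed=seed)
    elif family == "vor":
        return _make_vor_battery(
            task_cfg.get("n_points", 100), task_cfg.get("P", 30), seed)
    else:
        raise ValueError(f"unknown task family {family!r}")
    return (ds.train_inputs, ds.train_targets, ds.test_inputs, ds.test_targets,
            ds.task_kind, ds.input_mode == "direct_input_layer")


def _make_vor_battery(n_points: int, P_train: int, seed):
    """All 25 piecewise-linear VOR targets on a shared head-velocity
    sample; errors downstream are averaged across targets."""
    rng = np.random.default_rng(seed)
    v = rng.uniform(-1.0, 1.0, size=n_points)
    spec0 = tasks.VorTaskSpec(m1=0.0, m2=0.0)
    X = spec0.mossy_activity(v)
    Y = np.column_stack([s.target(v) for s in tasks.vor_target_grid()])
    perm = rng.permutation(n_points)
    tr, te = perm[:P_train], perm[P_train:]
    return X[tr], Y[tr], X[te], Y[te], "continuous", True


def _build_net(net_cfg: dict, input_dim: int, direct_input: bool, seed) -> net.ExpansionNetwork:
    return net.build_network(
        M=net_cfg["M"],
        D=input_dim,
        N=net_cfg.get("N"),
        K=net_cfg.get("K"),
        weight_kind=net_cfg.get("weight_kind", "dense_gaussian"),
        embedding_kind=net_cfg.get("embedding_kind", "distributed_orthonormal"),
        global_inhibition=net_cfg.get("global_inhibition", False),
        power=net_cfg.get("power", 1),
        direct_input=direct_input,
        seed=seed,
    )


def _fit(H_tr, Y_tr, readout_cfg: dict) -> ro.ReadoutModel:
    method = readout_cfg.get("method", "lstsq")
    if method == "lstsq":
        return ro.fit_least_squares(H_tr, Y_tr)
    if method == "ridge":
        return ro.fit_ridge(H_tr, Y_tr, readout_cfg.get("alpha_ridge", 0.0))
    raise ValueError(f"unsupported sweep readout method {method!r}")


def _activity_pair(pre_tr, pre_te, f, power, use_wta, calib_seed):
    """Train/test activity at coding level ``f`` from shared preactivations."""
    if use_wta:
        act_tr = net.winner_take_all(pre_tr, f)
        act_te = net.winner_take_all(pre_te, f)
        if power != 1:
            act_tr.H **= power
            act_te.H **= power
        return act_tr, act_te, None
    pool = pre_tr.ravel()
    if pool.size > 2_000_000:
        rng = np.random.default_rng(calib_seed)
        pool = pool[rng.integers(0, pool.size, size=2_000_000)]
    theta = float(np.quantile(pool, 1.0 - f))
    act_tr = net._activity_from_preactivations(pre_tr, theta, power)
    act_te = net._activity_from_preactivations(pre_te, theta, power)
    return act_tr, act_te, theta


def _aggregate(raw: pd.DataFrame, by: str) -> pd.DataFrame:
    grp = raw.groupby(by)["error"]
    table = grp.agg(mean_error="mean", sd="std", n_seeds="count").reset_index()
    table["sem"] = (table.pop("sd") / np.sqrt(table["n_seeds"])).fillna(0.0)
    table["measured_f"] = raw.groupby(by)["measured_f"].mean().values
    return table.sort_values(by).reset_index(drop=True)


# ---------------------------------------------------------------------------
# sweeps
# ---------------------------------------------------------------------------


def run_coding_level_sweep(config: ExperimentConfig, progress: bool = False) -> SweepResult:
    """Error versus coding level, averaged over task/network seeds.

    For each replicate a fresh task and network are drawn; the coding
    level is swept by moving the shared threshold (or the winner-take-all
    fraction for clustered representations) on the same preactivations.
    Stage failures are logged per (f, seed) and skipped; more than 50%
    failures aborts the sweep.
    """
    f_grid = config.sweep.get("f_grid", DEFAULT_F_GRID)
    n_seeds = config.replication["n_seeds"]
    base_seed = config.replication["base_seed"]
    use_wta = (config.network.get("embedding_kind") == "clustered_blocks"
               or config.network.get("winner_take_all", False))
    power = config.network.get("power", 1)
    rows, failures = [], []
    for rep in range(n_seeds):
        ss = _seed_for(base_seed, 0, rep)
        task_seed, net_seed, calib_seed = ss.spawn(3)
        X_tr, Y_tr, X_te, Y_te, task_kind, direct = _make_task(config.task, task_seed)
        network = _build_net(config.network, X_tr.shape[1], direct, net_seed)
        pre_tr = network.preactivations(X_tr, dtype=np.float32)
        pre_te = network.preactivations(X_te, dtype=np.float32)
        for f in f_grid:
            try:
                act_tr, act_te, _ = _activity_pair(
                    pre_tr, pre_te, f, power, use_wta, calib_seed)
                model = _fit(act_tr.H, Y_tr, config.readout)
                err = ro.evaluate(model, act_te.H, Y_te, task_kind)
                rows.append({"f": f, "rep": rep, "error": err,
                             "measured_f": act_tr.measured_f})
            except (ValueError, np.linalg.LinAlgError, RuntimeError) as exc:
                failures.append({"f": f, "rep": rep, "error_msg": str(exc)})
        if progress:
            print(f"[sweep {config.name}] replicate {rep + 1}/{n_seeds}")
    total = n_seeds * len(f_grid)
    if len(failures) > 0.5 * total:
        raise RuntimeError(f"more than half of sweep runs failed ({len(failures)}/{total})")
    raw = pd.DataFrame(rows)
    return SweepResult(
        table=_aggregate(raw, "f"), raw=raw, config=config,
        provenance={"config_hash": config.hash(), "base_seed": base_seed,
                    "n_seeds": n_seeds, "failures": failures},
    )


def find_optimal_coding_level(result: SweepResult) -> OptimalCodingLevel:
    """Argmin of the mean error curve, with flat/boundary diagnostics.

    Ties break toward smaller f; the grid spacing around the optimum is
    reported as the resolution. A curve whose total variation is below
    the pooled standard error is reported as a flat interval instead of
    a point.
    """
    table = result.table if isinstance(result, SweepResult) else result
    if len(table) < 3:
        raise ValueError("need at least 3 grid points to locate an optimum")
    fs = table["f"].to_numpy()
    errs = table["mean_error"].to_numpy()
    sems = table["sem"].to_numpy()
    pooled_sem = float(np.sqrt(np.mean(sems**2)))
    spread = float(errs.max() - errs.min())
    idx = int(np.argmin(errs))  # argmin returns the first (smallest-f) minimum
    resolution = float(np.diff(fs).max())
    if spread < pooled_sem:
        return OptimalCodingLevel(
            f_star=float(fs[idx]), resolution=resolution, flat=True,
            interval=(float(fs[0]), float(fs[-1])))
    boundary = idx in (0, len(fs) - 1)
    return OptimalCodingLevel(f_star=float(fs[idx]), resolution=resolution,
                              boundary=boundary)


def run_architecture_sweep(config: ExperimentConfig, progress: bool = False) -> SweepResult:
    """Error versus in-degree K (at fixed synapse count S = M K) or
    versus expansion ratio M/N, at a fixed coding level."""
    sweep = config.sweep
    kind = sweep["kind"]
    f = sweep.get("f", 0.3)
    n_seeds = config.replication["n_seeds"]
    base_seed = config.replication["base_seed"]
    power = config.network.get("power", 1)
    if kind == "in_degree":
        values = sweep["K_grid"]
        S = sweep["S"]
        col = "K"
    elif kind == "expansion_ratio":
        values = sweep["ratio_grid"]
        col = "M_over_N"
    else:
        raise ValueError(f"unknown architecture sweep kind {kind!r}")
    rows, failures = [], []
    for vi, value in enumerate(values):
        net_cfg = dict(config.network)
        if kind == "in_degree":
            net_cfg["K"] = int(value)
            net_cfg["M"] = max(1, S // int(value))
        else:
            net_cfg["M"] = int(round(value * config.network["N"]))
        for rep in range(n_seeds):
            ss = _seed_for(base_seed, 1, vi, rep)
            task_seed, net_seed, calib_seed = ss.spawn(3)
            try:
                X_tr, Y_tr, X_te, Y_te, task_kind, direct = _make_task(config.task, task_seed)
                network = _build_net(net_cfg, X_tr.shape[1], direct, net_seed)
                pre_tr = network.preactivations(X_tr, dtype=np.float32)
                pre_te = network.preactivations(X_te, dtype=np.float32)
                act_tr, act_te, _ = _activity_pair(pre_tr, pre_te, f, power, False, calib_seed)
                model = _fit(act_tr.H, Y_tr, config.readout)
                err = ro.evaluate(model, act_te.H, Y_te, task_kind)
                rows.append({col: value, "rep": rep, "error": err,
                             "measured_f": act_tr.measured_f,
                             "M": net_cfg["M"]})
            except (ValueError, np.linalg.LinAlgError, RuntimeError) as exc:
                failures.append({col: value, "rep": rep, "error_msg": str(exc)})
        if progress:
            print(f"[arch {config.name}] {col}={value} done")
    total = len(values) * n_seeds
    if len(failures) > 0.5 * total:
        raise RuntimeError(f"more than half of sweep runs failed ({len(failures)}/{total})")
    raw = pd.DataFrame(rows)
    table = _aggregate(raw, col)
    table["M"] = raw.groupby(col)["M"].first().values
    return SweepResult(
        table=table, raw=raw, config=config,
        provenance={"config_hash": config.hash(), "base_seed": base_seed,
                    "n_seeds": n_seeds, "failures": failures},
    )


def run_theory_comparison(config: ExperimentConfig, progress: bool = False) -> pd.DataFrame:
    """Pair analytic generalization-error predictions with matched
    finite-width simulations for Gaussian-process targets.

    Returns rows (gamma, f, P, sim_error, sim_sem, predicted_error,
    n_seeds). Predictions are deterministic; simulations average
    ridgeless least-squares readouts of dense Gaussian networks over
    seeds, reusing one input draw and network per seed across the P
    grid.
    """
    sweep = config.sweep
    gammas = sweep.get("gammas", (1.0,))
    fs = sweep.get("fs", (0.3,))
    P_grid = sorted(sweep.get("P_grid", (10, 30, 100)))
    P_test = sweep.get("P_test", 400)
    D = config.task["D"]
    M = config.network["M"]
    k_max = sweep.get("k_max", theory.default_k_max(D))
    n_seeds = config.replication["n_seeds"]
    base_seed = config.replication["base_seed"]
    P_max = max(P_grid)

    predictions = {}
    for f in fs:
        spec = theory.kernel_eigenvalues(theory.KernelModel.from_coding_level(f), D, k_max)
        for gamma in gammas:
            tspec = theory.gp_target_spectrum(gamma, D, k_max)
            for P in P_grid:
                predictions[(gamma, f, P)] = theory.predict_generalization_error(
                    spec, tspec, P).error

    rows = []
    for gi, gamma in enumerate(gammas):
        for rep in range(n_seeds):
            ss = _seed_for(base_seed, 2, gi, rep)
            task_seed, net_seed = ss.spawn(2)
            ds = tasks.sample_gp_task(P_max, P_test, D, gamma, seed=task_seed)
            X = np.vstack([ds.train_inputs, ds.test_inputs])
            y = np.vstack([ds.train_targets, ds.test_targets]).ravel()
            J = np.random.default_rng(net_seed).standard_normal((M, D)).astype(np.float32)
            pre = J @ X.T.astype(np.float32)
            for f in fs:
                theta = float(theory.KernelModel.from_coding_level(f).theta)
                H = np.maximum(pre - theta, 0.0)
                for P in P_grid:
                    model = ro.fit_least_squares(H[:, :P], y[:P])
                    err = ro.evaluate(model, H[:, P_max:], y[P_max:, None], "continuous")
                    rows.append({"gamma": gamma, "f": f, "P": P, "rep": rep, "error": err})
            if progress:
                print(f"[theory {config.name}] gamma={gamma} rep {rep + 1}/{n_seeds}")
    raw = pd.DataFrame(rows)
    grp = raw.groupby(["gamma", "f", "P"])["error"]
    out = grp.agg(sim_error="mean", sd="std", n_seeds="count").reset_index()
    out["sim_sem"] = (out.pop("sd") / np.sqrt(out["n_seeds"])).fillna(0.0)
    out["predicted_error"] = [predictions[(g, f, P)]
                              for g, f, P in zip(out["gamma"], out["f"], out["P"])]
    return out


def input_layer_baseline(dataset: tasks.TaskDataset) -> float:
    """Error of a least-squares readout fitted directly on the input
    layer (the performance floor the expansion layer must beat)."""
    if dataset.task_kind != "continuous":
        raise ValueError("input-layer baseline is defined for continuous tasks")
    model = ro.fit_least_squares(dataset.train_inputs.T, dataset.train_targets)
    return ro.evaluate(model, dataset.test_inputs.T, dataset.test_targets,
                       dataset.task_kind)


# ---------------------------------------------------------------------------
# presets (standard simulation settings)
# ---------------------------------------------------------------------------


def _presets() -> dict:
    reps = lambda n: {"n_seeds": n, "base_seed": 0}
    return {
        # random categorization, dense Gaussian effective weights
        "categorization": ExperimentConfig(
            name="categorization",
            task={"family": "random_categorization", "P": 1000, "D": 50, "epsilon": 0.1},
            network={"M": 10_000},
            sweep={"kind": "coding_level", "f_grid": list(DEFAULT_F_GRID)},
            replication=reps(20)),
        # Gaussian-process targets, one preset per length scale
        "gp": ExperimentConfig(
            name="gp",
            task={"family": "gp", "P": 30, "P_test": 500, "D": 3, "gamma": 1.0},
            network={"M": 200_000},
            sweep={"kind": "coding_level", "f_grid": list(DEFAULT_F_GRID)},
            replication=reps(200)),
        "gp-sparse": ExperimentConfig(
            name="gp-sparse",
            task={"family": "gp", "P": 30, "P_test": 500, "D": 3, "gamma": 1.0},
            network={"M": 200_000, "N": 7000, "K": 4,
                     "weight_kind": "sparse_homogeneous", "global_inhibition": True},
            sweep={"kind": "coding_level", "f_grid": list(DEFAULT_F_GRID)},
            replication=reps(200)),
        "gp-clustered": ExperimentConfig(
            name="gp-clustered",
            task={"family": "gp", "P": 30, "P_test": 500, "D": 3, "gamma": 1.0},
            network={"M": 200_000, "N": 999, "K": 4,
                     "weight_kind": "sparse_homogeneous",
                     "embedding_kind": "clustered_blocks",
                     "global_inhibition": False},
            sweep={"kind": "coding_level", "f_grid": list(DEFAULT_F_GRID)},
            replication=reps(100)),
        "in-degree": ExperimentConfig(
            name="in-degree",
            task={"family": "gp", "P": 200, "P_test": 500, "D": 3, "gamma": 1.0},
            network={"M": 0, "N": 100, "weight_kind": "sparse_homogeneous",
                     "global_inhibition": True},
            sweep={"kind": "in_degree", "S": 10_000, "f": 0.3,
                   "K_grid": [1, 2, 4, 8, 16, 32, 64, 100]},
            replication=reps(20)),
        "expansion-ratio": ExperimentConfig(
            name="expansion-ratio",
            task={"family": "gp", "P": 200, "P_test": 500, "D": 3, "gamma": 1.0},
            network={"N": 700, "K": 4, "weight_kind": "sparse_homogeneous",
                     "global_inhibition": True},
            sweep={"kind": "expansion_ratio", "f": 0.3,
                   "ratio_grid": [1, 2, 5, 10, 20, 30]},
            replication=reps(20)),
        "theory-gp": ExperimentConfig(
            name="theory-gp",
            task={"family": "gp", "D": 3},
            network={"M": 200_000},
            sweep={"kind": "theory", "gammas": [0.5, 1.0, 2.0], "fs": [0.1, 0.3],
                   "P_grid": [10, 30, 100], "P_test": 300},
            replication=reps(50)),
        "arm": ExperimentConfig(
            name="arm",
            task={"family": "arm", "P": 100, "P_test": 500},
            network={"M": 20_000},
            sweep={"kind": "coding_level", "f_grid": list(DEFAULT_F_GRID)},
            replication=reps(20)),
        "mushroom-body": ExperimentConfig(
            name="mushroom-body",
            task={"family": "random_categorization", "P": 100, "D": 50, "epsilon": 0.1},
            network={"M": 10_000, "N": 50, "K": 7,
                     "weight_kind": "sparse_homogeneous", "global_inhibition": True},
            sweep={"kind": "coding_level", "f_grid": list(DEFAULT_F_GRID)},
            replication=reps(20)),
        "vor": ExperimentConfig(
            name="vor",
            task={"family": "vor", "P": 30, "n_points": 100},
            network={"M": 20_000},
            sweep={"kind": "coding_level", "f_grid": list(DEFAULT_F_GRID)},
            replication=reps(20)),
    }


def list_presets() -> list[str]:
    return sorted(_presets())


def get_preset(name: str, *, gamma: float | None = None,
               base_seed: int | None = None, n_seeds: int | None = None,
               scale: float = 1.0) -> ExperimentConfig:
    """Fetch a named preset, optionally overriding the GP length scale,
    seeding, or applying a speed scale factor."""
    presets = _presets()
    if name not in presets:
        raise KeyError(f"unknown preset {name!r}; available: {sorted(presets)}")
    cfg = presets[name]
    if gamma is not None:
        if cfg.task.get("family") != "gp":
            raise ValueError("gamma override only applies to GP presets")
        cfg.task["gamma"] = gamma
    if base_seed is not None:
        cfg.replication["base_seed"] = int(base_seed)
    if n_seeds is not None:
        cfg.replication["n_seeds"] = int(n_seeds)
    if scale != 1.0:
        cfg = cfg.scaled(scale)
    return cfg


def make_fixtures(seed: int = 0) -> dict:
    """Small deterministic bundle of datasets and networks for tests.

    Covers every task family and network kind at toy sizes (M = 200,
    N = 24, D = 3, P = 20); bit-stable across calls with the same seed.
    """
    ss = np.random.SeedSequence(seed)
    seeds = ss.spawn(8)
    datasets = {
        "categorization": tasks.sample_random_categorization(20, 3, 0.1, seed=seeds[0]),
        "gp": tasks.sample_gp_task(20, 20, 3, 1.0, seed=seeds[1]),
        "arm": tasks.sample_arm_task(10, 10, seed=seeds[2]),
        "vor": tasks.sample_vor_task(tasks.VorTaskSpec(m1=1.0, m2=-1.0),
                                     n_points=40, P_train=20, seed=seeds[3]),
    }
    networks = {
        "dense": net.build_network(200, 3, seed=seeds[4]),
        "sparse": net.build_network(200, 3, N=24, K=4,
                                    weight_kind="sparse_homogeneous",
                                    global_inhibition=True, seed=seeds[5]),
        "sparse_truncnorm": net.build_network(200, 3, N=24, K=4,
                                              weight_kind="sparse_truncnorm",
                                              global_inhibition=True, seed=seeds[6]),
        "clustered": net.build_network(200, 3, N=24, K=4,
                                       weight_kind="sparse_homogeneous",
                                       embedding_kind="clustered_blocks",
                                       seed=seeds[7]),
    }
    return {"datasets": datasets, "networks": networks, "seed": seed}
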