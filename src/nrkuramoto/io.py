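"""Configuration files, trajectory persistence and run manifests.

Configs are TOML or JSON with two tables, ``model`` and ``sim``, plus an
``experiment`` selector.  Trajectories are written as a CSV of
``(t, R, R2)``, an ``.npz`` archive for any stored frames, and a JSON
sidecar holding parameters, configuration, seed and a format version.
Adjacency matrices travel as whitespace-delimited edge lists with 1-based
node ids.
"""

from __future__ import annotations

import hashlib
import json
import tomllib
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigError
from .integrate import SimConfig, Trajectory, simulate
from .model import ModelParams
from .sampling import sample_initial_condition

__all__ = [
    "FORMAT_VERSION",
    "read_edge_list",
    "write_edge_list",
    "parse_omega",
    "load_run_config",
    "write_trajectory",
    "read_trajectory",
    "run_from_config",
]

FORMAT_VERSION = 1


def read_edge_list(path) -> np.ndarray:
    """Adjacency matrix from an undirected, 1-based edge list."""
    edges = []
    n_max = 0
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        a, b = (int(tok) for tok in line.split()[:2])
        if a < 1 or b < 1 or a == b:
            raise ConfigError(f"invalid edge '{line}': ids are 1-based and distinct")
        edges.append((a - 1, b - 1))
        n_max = max(n_max, a, b)
    adj = np.zeros((n_max, n_max))
    for a, b in edges:
        adj[a, b] = adj[b, a] = 1.0
    return adj


def write_edge_list(adj: np.ndarray, path) -> None:
    """Write the upper triangle of a 0/1 adjacency matrix as 1-based edges."""
    lines = []
    n = adj.shape[0]
    for i in range(n):
        for j in range(i + 1, n):
            if adj[i, j]:
                lines.append(f"{i + 1} {j + 1}")
    Path(path).write_text("\n".join(lines) + "\n")


def parse_omega(value, N: int, rng: np.random.Generator | None = None):
    """Natural-frequency spec: scalar, explicit list, or ``"normal(mean,std)"``."""
    if isinstance(value, str):
        v = value.strip()
        if v.startswith("normal(") and v.endswith(")"):
            try:
                mean_s, std_s = v[len("normal(") : -1].split(",")
                mean, std = float(mean_s), float(std_s)
            except ValueError as exc:
                raise ConfigError(f"cannot parse omega spec '{value}'") from exc
            if rng is None:
                rng = np.random.default_rng()
            return rng.normal(mean, std, size=N)
        raise ConfigError(f"unknown omega spec '{value}'")
    if isinstance(value, (list, tuple)):
        arr = np.asarray(value, dtype=float)
        if arr.shape != (N,):
            raise ConfigError("explicit omega list must have length N")
        return arr
    return float(value)


_MODEL_KEYS = {
    "N",
    "eps1",
    "eps2",
    "beta1",
    "beta2",
    "sigma",
    "omega",
    "gamma0",
    "alpha",
    "variant",
    "adjacency_file",
}
_SIM_KEYS = {
    "dt",
    "n_steps",
    "transient_fraction",
    "record_stride",
    "seed",
    "store_couplings",
    "store_theta_frames",
    "store_phases",
}


def load_run_config(path) -> dict:
    """Parse and validate a TOML/JSON run configuration.

    Returns ``{"params": ModelParams, "sim": SimConfig, "experiment": str,
    "output_dir": Path, "raw": dict}``.
    """
    path = Path(path)
    raw_text = path.read_text()
    if path.suffix == ".json":
        raw = json.loads(raw_text)
    else:
        raw = tomllib.loads(raw_text)
    model = dict(raw.get("model", {}))
    sim = dict(raw.get("sim", {}))
    for key in model:
        if key not in _MODEL_KEYS:
            raise ConfigError(f"unknown key model.{key}")
    for key in sim:
        if key not in _SIM_KEYS:
            raise ConfigError(f"unknown key sim.{key}")
    if "N" not in model:
        raise ConfigError("model.N is required")
    n = int(model.pop("N"))
    adjacency = None
    adj_file = model.pop("adjacency_file", None)
    if adj_file is not None:
        adjacency = read_edge_list(path.parent / adj_file)
    seed = sim.get("seed")
    omega = parse_omega(
        model.pop("omega", 0.0),
        n,
        rng=np.random.default_rng(seed) if seed is not None else None,
    )
    try:
        params = ModelParams(N=n, omega=omega, adjacency=adjacency, **model)
        sim_cfg = SimConfig(**sim)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"invalid configuration: {exc}") from exc
    return {
        "params": params,
        "sim": sim_cfg,
        "experiment": raw.get("experiment", "simulate"),
        "output_dir": Path(raw.get("output_dir", ".")),
        "raw": raw,
    }


def _params_meta(params: ModelParams) -> dict:
    d = asdict(params)
    d["omega"] = np.asarray(params.omega_vector).tolist()
    d["adjacency"] = (
        None if params.adjacency is None else np.asarray(params.adjacency).tolist()
    )
    return d


def write_trajectory(traj: Trajectory, basepath) -> None:
    """Persist a trajectory as ``<base>.csv``, ``<base>.npz``, ``<base>.json``."""
    base = Path(basepath)
    pd.DataFrame({"t": traj.times, "R": traj.R, "R2": traj.R2}).to_csv(
        base.with_suffix(".csv"), index=False
    )
    arrays = {"psi2": traj.psi2}
    if traj.theta_frames is not None:
        arrays["theta_frames"] = traj.theta_frames
    if traj.k_frames is not None:
        arrays["k_frames"] = traj.k_frames
    if traj.theta_full is not None:
        arrays["theta_full"] = traj.theta_full
    if traj.final_state is not None:
        arrays["final_theta"] = traj.final_state.theta
        arrays["final_k"] = traj.final_state.k
    np.savez_compressed(base.with_suffix(".npz"), **arrays)
    meta = {
        "format_version": FORMAT_VERSION,
        "seed": traj.seed,
        "frame_stride": traj.frame_stride,
        "params": None if traj.params is None else _params_meta(traj.params),
        "config": None if traj.config is None else asdict(traj.config),
    }
    base.with_suffix(".json").write_text(json.dumps(meta, indent=2, sort_keys=True))


def read_trajectory(basepath) -> Trajectory:
    """Load a trajectory written by :func:`write_trajectory`."""
    base = Path(basepath)
    try:
        meta = json.loads(base.with_suffix(".json").read_text())
    except (OSError, json.JSONDecodeError) as exc:
        raise ConfigError(f"cannot read trajectory metadata at {base}: {exc}") from exc
    if meta.get("format_version") != FORMAT_VERSION:
        raise ConfigError(
            f"trajectory archive version {meta.get('format_version')} "
            f"does not match expected {FORMAT_VERSION}"
        )
    table = pd.read_csv(base.with_suffix(".csv"))
    with np.load(base.with_suffix(".npz")) as npz:
        arrays = {k: npz[k] for k in npz.files}
    params = None
    if meta["params"] is not None:
        pm = dict(meta["params"])
        pm["omega"] = np.asarray(pm["omega"])
        pm["adjacency"] = (
            None if pm["adjacency"] is None else np.asarray(pm["adjacency"])
        )
        params = ModelParams(**pm)
    config = SimConfig(**meta["config"]) if meta["config"] is not None else None
    from .model import SystemState

    final = None
    if "final_theta" in arrays:
        final = SystemState(
            theta=arrays["final_theta"],
            k=arrays["final_k"],
            t=float(table["t"].iloc[-1]),
        )
    return Trajectory(
        times=table["t"].to_numpy(),
        R=table["R"].to_numpy(),
        R2=table["R2"].to_numpy(),
        psi2=arrays["psi2"],
        frame_stride=int(meta["frame_stride"]),
        theta_frames=arrays.get("theta_frames"),
        k_frames=arrays.get("k_frames"),
        theta_full=arrays.get("theta_full"),
        seed=meta["seed"],
        params=params,
        config=config,
        final_state=final,
    )


def run_from_config(path, output_dir=None) -> dict:
    """Execute the experiment named in a config file; write artifacts.

    Currently the ``simulate`` experiment is wired here (sweeps have their
    own entry points in :mod:`nrkuramoto.experiments` and the CLI).  Writes
    the trajectory triple plus a ``manifest.json`` binding the outputs to
    the config hash and seed; reruns with identical config and seed produce
    byte-identical summaries.
    """
    cfg = load_run_config(path)
    out = Path(output_dir) if output_dir is not None else cfg["output_dir"]
    out.mkdir(parents=True, exist_ok=True)
    params, sim = cfg["params"], cfg["sim"]
    ic = sample_initial_condition(
        params.N, seed=np.random.SeedSequence(sim.seed if sim.seed is not None else 0)
    )
    traj = simulate(params, sim, ic.as_state())
    write_trajectory(traj, out / "trajectory")
    mr, mr2 = traj.mean_order_parameters()
    from .observables import classify_state

    summary = {
        "mean_R": mr,
        "mean_R2": mr2,
        "classification": classify_state(mr, mr2),
        "n_steps": sim.n_steps,
        "seed": sim.seed,
    }
    (out / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
    config_hash = hashlib.sha256(
        json.dumps(cfg["raw"], sort_keys=True).encode()
    ).hexdigest()
    manifest = {
        "config_hash": config_hash,
        "seed": sim.seed,
        "format_version": FORMAT_VERSION,
        "artifacts": ["trajectory.csv", "trajectory.npz", "trajectory.json", "summary.json"],
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return summary
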