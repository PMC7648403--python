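"""Configuration files, plain-text rasters, tables, and run manifests.

All interchange formats are plain text: YAML configs (strictly validated —
unknown keys are rejected so a typo in a rate name cannot pass silently),
whitespace-delimited rasters with a one-line ``nx ny dx`` header, and
comma-delimited tables with a header row.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

from .fvm import SolverConfig
from .grid import Grid
from .kernel import ReleaseSpec
from .params import AnnulusData, ParameterSet, SpraySchedule, validate_parameters

__all__ = [
    "RunConfig",
    "RunManifest",
    "load_config",
    "save_config",
    "packaged_config",
    "read_raster",
    "write_raster",
    "read_annuli",
    "write_annuli",
]

_PARAM_KEYS = {"D", "gamma", "mu1_base", "mu1_insecticide", "mu2", "r", "e", "k"}
_GRID_KEYS = {"nx", "ny", "dx", "origin"}
_SCHEDULE_KEYS = {"period", "rate", "window", "start_time"}
_RUN_KEYS = {"dt", "t_end", "nonlinear_tol", "max_inner_iters", "snapshot_times"}
_RELEASE_KEYS = {"M0", "t"}
_ANNULI_KEYS = {"edges", "counts", "weights"}
_SCENARIO_KEYS = {
    "block_size",
    "street_width",
    "n_blocks_x",
    "n_blocks_y",
    "big_blocks",
    "house_factor",
    "spray_dilation_cells",
}
_TOP_KEYS = {
    "parameters",
    "grid",
    "schedule",
    "run",
    "release",
    "annuli",
    "scenario",
    "alpha",
}


def _as_float(value: Any, context: str) -> float:
    """Floats, ints, or fractional strings like '1/48'."""
    if isinstance(value, bool):
        raise ValueError(f"{context}: expected a number, got a boolean")
    if isinstance(value, (int, float)):
        return float(value)
    if isinstance(value, str) and "/" in value:
        num, _, den = value.partition("/")
        return float(num) / float(den)
    if isinstance(value, str):
        return float(value)
    raise ValueError(f"{context}: expected a number, got {type(value).__name__}")


def _check_keys(section: Mapping[str, Any], allowed: set[str], name: str) -> None:
    if not isinstance(section, Mapping):
        raise ValueError(f"config section {name!r} must be a mapping")
    unknown = set(section) - allowed
    if unknown:
        raise ValueError(
            f"unknown key(s) {sorted(unknown)} in config section {name!r}; "
            f"allowed: {sorted(allowed)}"
        )


@dataclass
class RunConfig:
    """Validated contents of a run configuration file."""

    parameters: ParameterSet | None = None
    grid: Grid | None = None
    schedule: SpraySchedule | None = None
    solver: SolverConfig | None = None
    release: ReleaseSpec | None = None
    annuli: AnnulusData | None = None
    scenario: dict[str, Any] | None = None
    alpha: float | None = None
    raw: dict[str, Any] = field(default_factory=dict)


def load_config(path: str | Path) -> RunConfig:
    """Parse and validate a YAML run configuration (strict keys)."""
    path = Path(path)
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, Mapping):
        raise ValueError(f"{path}: config root must be a mapping")
    _check_keys(data, _TOP_KEYS, "<root>")
    cfg = RunConfig(raw=dict(data))

    if "parameters" in data:
        sec = data["parameters"]
        _check_keys(sec, _PARAM_KEYS, "parameters")
        missing = {"D", "gamma", "mu1_base", "mu2", "r", "e", "k"} - set(sec)
        if missing:
            raise ValueError(f"parameters section missing required key(s) {sorted(missing)}")
        kwargs = {k: _as_float(v, f"parameters.{k}") for k, v in sec.items()}
        cfg.parameters = validate_parameters(ParameterSet(**kwargs))

    if "grid" in data:
        sec = data["grid"]
        _check_keys(sec, _GRID_KEYS, "grid")
        origin = tuple(float(v) for v in sec.get("origin", (0.0, 0.0)))
        cfg.grid = Grid(
            nx=int(sec["nx"]),
            ny=int(sec["ny"]),
            dx=_as_float(sec["dx"], "grid.dx"),
            origin=origin,
        )

    if "schedule" in data:
        sec = data["schedule"]
        _check_keys(sec, _SCHEDULE_KEYS, "schedule")
        cfg.schedule = SpraySchedule(
            period=_as_float(sec["period"], "schedule.period"),
            rate=_as_float(sec["rate"], "schedule.rate"),
            window=_as_float(sec.get("window", "0.5/24"), "schedule.window"),
            start_time=_as_float(sec.get("start_time", 0.0), "schedule.start_time"),
        )

    if "run" in data:
        sec = data["run"]
        _check_keys(sec, _RUN_KEYS, "run")
        cfg.solver = SolverConfig(
            dt=_as_float(sec.get("dt", "1/48"), "run.dt"),
            t_end=_as_float(sec["t_end"], "run.t_end"),
            nonlinear_tol=_as_float(sec.get("nonlinear_tol", 1e-10), "run.nonlinear_tol"),
            max_inner_iters=int(sec.get("max_inner_iters", 50)),
            snapshot_times=tuple(
                _as_float(v, "run.snapshot_times") for v in sec.get("snapshot_times", ())
            ),
        )

    if "release" in data:
        sec = data["release"]
        _check_keys(sec, _RELEASE_KEYS, "release")
        cfg.release = ReleaseSpec(
            M0=_as_float(sec["M0"], "release.M0"), t=_as_float(sec["t"], "release.t")
        )

    if "annuli" in data:
        sec = data["annuli"]
        _check_keys(sec, _ANNULI_KEYS, "annuli")
        cfg.annuli = AnnulusData(
            edges=[_as_float(v, "annuli.edges") for v in sec["edges"]],
            counts=sec.get("counts"),
            weights=sec.get("weights"),
        )

    if "scenario" in data:
        sec = data["scenario"]
        _check_keys(sec, _SCENARIO_KEYS, "scenario")
        cfg.scenario = dict(sec)

    if "alpha" in data:
        cfg.alpha = _as_float(data["alpha"], "alpha")

    return cfg


def save_config(cfg: RunConfig, path: str | Path) -> None:
    """Write a RunConfig back to YAML (round-trips through load_config)."""
    data: dict[str, Any] = {}
    if cfg.parameters is not None:
        p = cfg.parameters
        data["parameters"] = {
            "D": p.D,
            "gamma": p.gamma,
            "mu1_base": p.mu1_base,
            "mu1_insecticide": p.mu1_insecticide,
            "mu2": p.mu2,
            "r": p.r,
            "e": p.e,
            "k": p.k,
        }
    if cfg.grid is not None:
        g = cfg.grid
        data["grid"] = {"nx": g.nx, "ny": g.ny, "dx": g.dx, "origin": list(g.origin)}
    if cfg.schedule is not None:
        s = cfg.schedule
        data["schedule"] = {
            "period": s.period,
            "rate": s.rate,
            "window": s.window,
            "start_time": s.start_time,
        }
    if cfg.solver is not None:
        r = cfg.solver
        data["run"] = {
            "dt": r.dt,
            "t_end": r.t_end,
            "nonlinear_tol": r.nonlinear_tol,
            "max_inner_iters": r.max_inner_iters,
            "snapshot_times": list(r.snapshot_times),
        }
    if cfg.release is not None:
        data["release"] = {"M0": cfg.release.M0, "t": cfg.release.t}
    if cfg.annuli is not None:
        a = cfg.annuli
        data["annuli"] = {
            "edges": list(a.edges),
            "counts": list(a.counts),
            "weights": list(a.weights),
        }
    if cfg.scenario is not None:
        data["scenario"] = cfg.scenario
    if cfg.alpha is not None:
        data["alpha"] = cfg.alpha
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=False)


def packaged_config(name: str = "table5.cfg") -> Path:
    """Path of a configuration file bundled with the package."""
    from importlib.resources import files

    return Path(str(files("aedesdyn").joinpath("data", name)))


# ---------------------------------------------------------------------------
# Rasters
# ---------------------------------------------------------------------------

def write_raster(path: str | Path, grid: Grid, array: np.ndarray, fmt: str = "%.10g") -> None:
    """Plain-text raster: header 'nx ny dx', then one line per grid row.

    The first data line is row j = 0 (southmost); values run west to east.
    Boolean masks are written as 0/1.
    """
    array = np.asarray(array)
    if array.shape != grid.shape:
        raise ValueError(f"array shape {array.shape} != grid shape {grid.shape}")
    if array.dtype == bool:
        array = array.astype(int)
        fmt = "%d"
    with open(path, "w") as fh:
        fh.write(f"{grid.nx} {grid.ny} {grid.dx:.10g}\n")
        np.savetxt(fh, array, fmt=fmt)


def read_raster(path: str | Path, dtype=float) -> tuple[Grid, np.ndarray]:
    with open(path) as fh:
        header = fh.readline().split()
        if len(header) != 3:
            raise ValueError(f"{path}: expected header 'nx ny dx'")
        nx, ny, dx = int(header[0]), int(header[1]), float(header[2])
        array = np.loadtxt(fh, dtype=dtype)
    array = np.atleast_2d(array)
    if array.shape != (ny, nx):
        raise ValueError(f"{path}: data shape {array.shape} != header ({ny}, {nx})")
    return Grid(nx=nx, ny=ny, dx=dx), array


# ---------------------------------------------------------------------------
# Annulus tables
# ---------------------------------------------------------------------------

def write_annuli(path: str | Path, annuli: AnnulusData) -> None:
    """Comma-delimited ring table: r_inner_m, r_outer_m, count, weight."""
    df = pd.DataFrame(
        {
            "r_inner_m": annuli.inner,
            "r_outer_m": annuli.outer,
            "count": list(annuli.counts),
            "weight": list(annuli.weights),
        }
    )
    df.to_csv(path, index=False)


def read_annuli(path: str | Path) -> AnnulusData:
    df = pd.read_csv(path)
    required = {"r_inner_m", "r_outer_m", "count", "weight"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: expected columns {sorted(required)}")
    inner = df["r_inner_m"].to_numpy(dtype=float)
    outer = df["r_outer_m"].to_numpy(dtype=float)
    if not np.allclose(inner[1:], outer[:-1]):
        raise ValueError(f"{path}: rings must be contiguous (r_inner[i+1] == r_outer[i])")
    edges = np.concatenate([inner[:1], outer])
    return AnnulusData(edges=edges, counts=df["count"].tolist(), weights=df["weight"].tolist())


# ---------------------------------------------------------------------------
# Run manifest
# ---------------------------------------------------------------------------

@dataclass
class RunManifest:
    """Reproducibility record emitted once per CLI run."""

    command: str
    config_snapshot: dict[str, Any]
    seed: int | None
    outputs: list[str]
    wall_time_s: float
    version: str = ""

    def write(self, path: str | Path) -> None:
        if not self.version:
            from . import __version__

            self.version = __version__
        payload = {
            "command": self.command,
            "version": self.version,
            "seed": self.seed,
            "wall_time_s": round(self.wall_time_s, 3),
            "outputs": self.outputs,
            "config": self.config_snapshot,
            "written_at_unix": int(time.time()),
        }
        with open(path, "w") as fh:
            yaml.safe_dump(payload, fh, sort_keys=False)
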