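"""Configuration parsing and trajectory/result serialization.

Run configurations are flat key-value documents (YAML, of which JSON is a
subset): a capacity ``K``, one block per clone with the five rates, an
optional downstream block, an initial state (explicit counts or the string
``"equilibrium"``), a time span, an output grid and an event list.
Trajectories are tidy CSV (time, clone, compartment, value) written at
full float precision so round trips are lossless.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .events import ConfigError, Event, events_from_dicts
from .model import StateVector, Trajectory
from .params import RATE_NAMES, CloneParams, DownstreamParams, SystemParams

__all__ = [
    "RunConfig",
    "load_config",
    "save_config",
    "parse_system",
    "write_trajectory",
    "read_trajectory",
]


def parse_system(doc: dict) -> SystemParams:
    """Build SystemParams from a config mapping, validating every key."""
    if "K" not in doc:
        raise ConfigError("missing required key 'K' (niche capacity)")
    try:
        K = float(doc["K"])
    except (TypeError, ValueError):
        raise ConfigError(f"'K' must be a number, got {doc['K']!r}") from None
    raw_clones = doc.get("clones")
    if not raw_clones:
        raise ConfigError("missing or empty 'clones' list")
    clones = []
    for i, block in enumerate(raw_clones):
        if not isinstance(block, dict):
            raise ConfigError(f"clone {i} must be a mapping of rates")
        unknown = set(block) - set(RATE_NAMES) - {"label"}
        if unknown:
            raise ConfigError(f"clone {i} has unknown key(s) {sorted(unknown)}")
        missing = set(RATE_NAMES) - set(block)
        if missing:
            raise ConfigError(f"clone {i} is missing rate(s) {sorted(missing)}")
        try:
            clones.append(CloneParams(
                **{name: float(block[name]) for name in RATE_NAMES},
                label=block.get("label"),
            ))
        except ValueError as err:
            raise ConfigError(f"clone {i}: {err}") from None
    downstream = None
    if doc.get("downstream") is not None:
        block = doc["downstream"]
        unknown = set(block) - {"amplification", "clearance"}
        if unknown:
            raise ConfigError(f"downstream block has unknown key(s) {sorted(unknown)}")
        try:
            downstream = DownstreamParams(
                amplification=float(block.get("amplification", 1.0)),
                clearance=float(block.get("clearance", 1.0)),
            )
        except ValueError as err:
            raise ConfigError(f"downstream: {err}") from None
    try:
        return SystemParams(K=K, clones=tuple(clones), downstream=downstream)
    except ValueError as err:
        raise ConfigError(str(err)) from None


def _system_to_dict(params: SystemParams) -> dict:
    doc: dict = {"K": params.K, "clones": [c.as_dict() for c in params.clones]}
    if params.downstream is not None:
        doc["downstream"] = {
            "amplification": params.downstream.amplification,
            "clearance": params.downstream.clearance,
        }
    return doc


@dataclass
class RunConfig:
    """Validated simulation run: system, initial state, span, grid, events."""

    params: SystemParams
    init: StateVector | str
    t_span: tuple[float, float]
    grid: np.ndarray
    events: list[Event] = field(default_factory=list)
    rtol: float = 1e-9
    atol: float = 1e-12
    method: str = "Radau"
    seed: int = 0

    def resolve_init(self) -> StateVector:
        if isinstance(self.init, StateVector):
            return self.init
        from .equilibrium import equilibrium_state

        return equilibrium_state(self.params)

    def to_dict(self) -> dict:
        doc = _system_to_dict(self.params)
        if isinstance(self.init, str):
            doc["init"] = self.init
        else:
            init: dict = {"N": self.init.N.tolist(), "A": self.init.A.tolist(),
                          "I": self.init.I.tolist()}
            if self.init.D is not None:
                init["D"] = self.init.D.tolist()
            doc["init"] = init
        doc["t_span"] = [self.t_span[0], self.t_span[1]]
        doc["grid"] = self.grid.tolist()
        if self.events:
            doc["events"] = [e.to_dict() for e in self.events]
        doc.update(rtol=self.rtol, atol=self.atol, method=self.method, seed=self.seed)
        return doc


_RUN_KEYS = {"K", "clones", "downstream", "init", "t_span", "grid", "events",
             "rtol", "atol", "method", "seed"}


def _config_from_dict(doc: dict) -> RunConfig:
    unknown = set(doc) - _RUN_KEYS
    if unknown:
        raise ConfigError(f"unknown config key(s): {sorted(unknown)}")
    params = parse_system(doc)
    init_doc = doc.get("init", "equilibrium")
    if isinstance(init_doc, str):
        if init_doc != "equilibrium":
            raise ConfigError(f"init must be 'equilibrium' or an explicit state, got {init_doc!r}")
        init: StateVector | str = "equilibrium"
    else:
        unknown = set(init_doc) - {"N", "A", "I", "D"}
        if unknown:
            raise ConfigError(f"init block has unknown key(s) {sorted(unknown)}")
        missing = {"N", "A", "I"} - set(init_doc)
        if missing:
            raise ConfigError(f"init block is missing component(s) {sorted(missing)}")
        init = StateVector(N=init_doc["N"], A=init_doc["A"], I=init_doc["I"],
                           D=init_doc.get("D"))
    if "t_span" not in doc:
        raise ConfigError("missing required key 't_span'")
    t_span = doc["t_span"]
    if not (isinstance(t_span, (list, tuple)) and len(t_span) == 2):
        raise ConfigError("'t_span' must be a [t0, t1] pair")
    t0, t1 = float(t_span[0]), float(t_span[1])
    grid_doc = doc.get("grid", {"n": 501})
    if isinstance(grid_doc, dict):
        unknown = set(grid_doc) - {"n"}
        if unknown:
            raise ConfigError(f"grid block has unknown key(s) {sorted(unknown)}")
        grid = np.linspace(t0, t1, int(grid_doc.get("n", 501)))
    else:
        grid = np.asarray(grid_doc, dtype=float)
    events = events_from_dicts(doc.get("events", []) or [])
    rtol = float(doc.get("rtol", 1e-9))
    atol = float(doc.get("atol", 1e-12))
    if rtol <= 0 or atol <= 0:
        raise ConfigError("solver tolerances 'rtol' and 'atol' must be positive")
    return RunConfig(
        params=params, init=init, t_span=(t0, t1), grid=grid, events=events,
        rtol=rtol, atol=atol, method=str(doc.get("method", "Radau")),
        seed=int(doc.get("seed", 0)),
    )


def load_config(path) -> RunConfig:
    """Load and validate a run configuration from a YAML/JSON file."""
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict):
        raise ConfigError(f"config file {path} does not contain a mapping")
    return _config_from_dict(doc)


def save_config(config: RunConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=False)


def write_trajectory(traj: Trajectory, path) -> None:
    """Tidy CSV: time, clone, compartment, value. Floats are written with
    Python repr precision, so reading back is lossless."""
    traj.to_frame().to_csv(path, index=False, float_format="%.17g")


def read_trajectory(path) -> Trajectory:
    df = pd.read_csv(path, float_precision="round_trip")
    required = {"time", "clone", "compartment", "value"}
    missing = required - set(df.columns)
    if missing:
        raise ConfigError(f"trajectory file is missing column(s) {sorted(missing)}")
    if len(df) == 0:
        return Trajectory(times=np.empty(0), N=np.empty((0, 0)), A=np.empty((0, 0)),
                          I=np.empty((0, 0)), flux=np.empty((0, 0)), clone_labels=[])
    times = np.array(sorted(df["time"].unique()))
    labels = list(pd.unique(df["clone"]))
    comps = {}
    for comp in ("N", "A", "I", "flux", "D"):
        sub = df[df["compartment"] == comp]
        if len(sub) == 0:
            continue
        wide = sub.pivot(index="time", columns="clone", values="value")
        comps[comp] = wide.loc[times, labels].to_numpy()
    return Trajectory(
        times=times, N=comps["N"], A=comps["A"], I=comps["I"], flux=comps["flux"],
        D=comps.get("D"), clone_labels=labels,
    )
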