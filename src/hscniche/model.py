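"""Deterministic ODE core: state container, right-hand side, integrator.

For each clone j sharing a niche with E = K - sum_k N_k empty spaces:

    dN_j/dt = b_j I_j E - u_j N_j
    dA_j/dt = u_j N_j - (r_j + d_Aj) A_j
    dI_j/dt = 2 r_j A_j - b_j I_j E - d_Ij I_j

Niche-bound cells (N) are quiescent; detachment activates them (A); a
division consumes one active cell and yields two inactive daughters (I),
which must reattach to remain stem cells or are otherwise lost to
differentiation. The only sinks are the differentiation terms d_A A and
d_I I; the only source is the factor-2 division term. An optional lumped
progenitor pool integrates the amplified differentiation flux:

    dD_j/dt = amp (d_Aj A_j + d_Ij I_j) - clear D_j
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .events import Event, apply_event, sorted_schedule, ConfigError
from .params import SystemParams

__all__ = [
    "StateVector",
    "Trajectory",
    "IntegrationError",
    "rhs",
    "progenitor_flux",
    "simulate",
    "simulate_to_steady_state",
]

_NEG_TOL = 1e-8


class IntegrationError(RuntimeError):
    """Raised when the ODE solver fails; carries the time of failure."""

    def __init__(self, message: str, t_fail: float):
        super().__init__(f"{message} (t = {t_fail:g})")
        self.t_fail = t_fail


@dataclass
class StateVector:
    """Per-clone cell counts: niche-bound ``N``, active ``A``, inactive
    ``I`` and, optionally, downstream progenitors ``D``. All in cells."""

    N: np.ndarray
    A: np.ndarray
    I: np.ndarray
    D: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.N = np.atleast_1d(np.asarray(self.N, dtype=float)).copy()
        self.A = np.atleast_1d(np.asarray(self.A, dtype=float)).copy()
        self.I = np.atleast_1d(np.asarray(self.I, dtype=float)).copy()
        if self.D is not None:
            self.D = np.atleast_1d(np.asarray(self.D, dtype=float)).copy()
        m = len(self.N)
        for name in ("A", "I", "D"):
            arr = getattr(self, name)
            if arr is not None and len(arr) != m:
                raise ValueError(f"state component {name} has length {len(arr)}, expected {m}")

    @property
    def n_clones(self) -> int:
        return len(self.N)

    def validate(self, params: SystemParams) -> None:
        if self.n_clones != params.n_clones:
            raise ValueError(
                f"state has {self.n_clones} clone(s), params have {params.n_clones}"
            )
        if params.has_downstream and self.D is None:
            raise ValueError("params include a downstream pool but the state has no D")
        for name in ("N", "A", "I", "D"):
            arr = getattr(self, name)
            if arr is not None and np.any(arr < -_NEG_TOL):
                raise ValueError(f"negative cell count in state component {name}")
        if self.N.sum() > params.K * (1 + 1e-9) + _NEG_TOL:
            raise ValueError(
                f"niche over-filled: sum(N) = {self.N.sum():g} exceeds capacity K = {params.K:g}"
            )

    def copy(self) -> "StateVector":
        return StateVector(self.N, self.A, self.I, None if self.D is None else self.D)

    def total_stem(self) -> np.ndarray:
        """Per-clone total stem-cell count N + A + I."""
        return self.N + self.A + self.I

    def to_array(self) -> np.ndarray:
        parts = [self.N, self.A, self.I]
        if self.D is not None:
            parts.append(self.D)
        return np.concatenate(parts)

    @classmethod
    def from_array(cls, y: np.ndarray, n_clones: int, downstream: bool) -> "StateVector":
        m = n_clones
        D = y[3 * m : 4 * m] if downstream else None
        return cls(N=y[:m], A=y[m : 2 * m], I=y[2 * m : 3 * m], D=D)

    @classmethod
    def zeros(cls, n_clones: int, downstream: bool = False) -> "StateVector":
        z = np.zeros(n_clones)
        return cls(N=z, A=z.copy(), I=z.copy(), D=z.copy() if downstream else None)


def _unpack_params(params: SystemParams):
    b = np.array([c.b for c in params.clones])
    u = np.array([c.u for c in params.clones])
    r = np.array([c.r for c in params.clones])
    d_A = np.array([c.d_A for c in params.clones])
    d_I = np.array([c.d_I for c in params.clones])
    return b, u, r, d_A, d_I


def _rhs_flat(t: float, y: np.ndarray, params: SystemParams, rates) -> np.ndarray:
    b, u, r, d_A, d_I = rates
    m = params.n_clones
    N, A, I = y[:m], y[m : 2 * m], y[2 * m : 3 * m]
    E = params.K - N.sum()
    attach = b * I * E
    dN = attach - u * N
    dA = u * N - (r + d_A) * A
    dI = 2.0 * r * A - attach - d_I * I
    if params.has_downstream:
        D = y[3 * m : 4 * m]
        ds = params.downstream
        dD = ds.amplification * (d_A * A + d_I * I) - ds.clearance * D
        return np.concatenate([dN, dA, dI, dD])
    return np.concatenate([dN, dA, dI])


def rhs(state: StateVector, params: SystemParams, t: float = 0.0) -> StateVector:
    """Exact time-derivative of the state under the niche model."""
    state.validate(params)
    y = _rhs_flat(t, state.to_array(), params, _unpack_params(params))
    return StateVector.from_array(y, params.n_clones, params.has_downstream)


def progenitor_flux(state: StateVector, params: SystemParams) -> np.ndarray:
    """Per-clone progenitor production d_A*A + d_I*I, cells/day.

    This flux (rather than the optional downstream pool) is the quantity the
    headline analyses use: mature cell production scales with it.
    """
    state.validate(params)
    _, _, _, d_A, d_I = _unpack_params(params)
    return d_A * state.A + d_I * state.I


@dataclass
class Trajectory:
    """Time grid plus full state and per-clone progenitor flux.

    Arrays ``N``, ``A``, ``I``, ``flux`` (and optionally ``D``) have shape
    (n_times, n_clones).
    """

    times: np.ndarray
    N: np.ndarray
    A: np.ndarray
    I: np.ndarray
    flux: np.ndarray
    D: np.ndarray | None = None
    clone_labels: list[str] = field(default_factory=list)

    @property
    def n_clones(self) -> int:
        return self.N.shape[1]

    def state_at(self, index: int) -> StateVector:
        return StateVector(
            N=self.N[index],
            A=self.A[index],
            I=self.I[index],
            D=None if self.D is None else self.D[index],
        )

    def final_state(self) -> StateVector:
        return self.state_at(-1)

    def unbound(self) -> np.ndarray:
        """Per-clone free (active + inactive) cells, shape (n_times, n_clones)."""
        return self.A + self.I

    def niche_fraction(self) -> np.ndarray:
        """Per-clone share of occupied niches; NaN where the niche is empty."""
        total = self.N.sum(axis=1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(total > 0, self.N / total, np.nan)

    def to_frame(self) -> pd.DataFrame:
        """Tidy long-format table: time, clone, compartment, value."""
        labels = self.clone_labels or [f"clone{j}" for j in range(self.n_clones)]
        blocks = []
        comps = {"N": self.N, "A": self.A, "I": self.I, "flux": self.flux}
        if self.D is not None:
            comps["D"] = self.D
        if self.n_clones == 0 or len(self.times) == 0:
            return pd.DataFrame(columns=["time", "clone", "compartment", "value"])
        for comp, arr in comps.items():
            for j, lab in enumerate(labels):
                blocks.append(
                    pd.DataFrame(
                        {
                            "time": self.times,
                            "clone": lab,
                            "compartment": comp,
                            "value": arr[:, j],
                        }
                    )
                )
        return pd.concat(blocks, ignore_index=True)


def _segment_boundaries(events: Sequence[Event], t0: float, t1: float):
    """Group events by time; reject events outside [t0, t1]."""
    for e in events:
        if e.time < t0 - 1e-12 or e.time > t1 + 1e-12:
            raise ConfigError(f"event at t = {e.time:g} lies outside t_span [{t0:g}, {t1:g}]")
    grouped: dict[float, list[Event]] = {}
    for e in sorted_schedule(events):
        grouped.setdefault(e.time, []).append(e)
    return grouped


def simulate(
    params: SystemParams,
    init: StateVector,
    t_span: tuple[float, float],
    events: Sequence[Event] = (),
    output_grid: np.ndarray | None = None,
    rtol: float = 1e-9,
    atol: float = 1e-12,
    method: str = "Radau",
) -> Trajectory:
    """Integrate the niche model over ``t_span``, restarting at every event.

    The output grid is decoupled from the internal (adaptive, stiff-capable)
    steps. A grid point that coincides with an event time reports the
    post-event state.
    """
    t0, t1 = float(t_span[0]), float(t_span[1])
    if not t1 > t0:
        raise ValueError("t_span must satisfy t1 > t0")
    init.validate(params)
    if output_grid is None:
        output_grid = np.linspace(t0, t1, 501)
    grid = np.asarray(output_grid, dtype=float)
    if grid.ndim != 1 or len(grid) == 0 or np.any(np.diff(grid) <= 0):
        raise ValueError("output_grid must be a strictly increasing 1-D array")
    if grid[0] < t0 - 1e-12 or grid[-1] > t1 + 1e-12:
        raise ValueError("output_grid must lie within t_span")

    grouped = _segment_boundaries(events, t0, t1)
    cur_params = params
    state = init.copy()
    # events scheduled exactly at t0 fire before integration starts
    if t0 in grouped:
        for e in grouped.pop(t0):
            cur_params, state = apply_event(e, cur_params, state)
    eps = 1e-9 * max(1.0, abs(t1))
    terminal_events = [e for t in grouped if abs(t - t1) <= eps for e in grouped[t]]
    boundaries = sorted(t for t in grouped if t0 + eps < t < t1 - eps)
    seg_edges = [t0] + boundaries + [t1]

    times_out: list[float] = []
    rows: list[np.ndarray] = []
    flux_rows: list[np.ndarray] = []

    def record(t: float, y: np.ndarray, p: SystemParams) -> None:
        sv = StateVector.from_array(y, p.n_clones, p.has_downstream)
        times_out.append(t)
        rows.append(np.asarray(y, dtype=float).copy())
        _, _, _, d_A, d_I = _unpack_params(p)
        flux_rows.append(d_A * sv.A + d_I * sv.I)

    y = state.to_array()
    for k in range(len(seg_edges) - 1):
        s, e = seg_edges[k], seg_edges[k + 1]
        # record grid points at the segment start (post-event state)
        for t in grid[np.abs(grid - s) <= eps]:
            record(t, y, cur_params)
        inner = grid[(grid > s + eps) & (grid < e - eps)]
        t_eval = np.append(inner, e)
        rates = _unpack_params(cur_params)
        sol = solve_ivp(
            _rhs_flat,
            (s, e),
            y,
            method=method,
            t_eval=t_eval,
            rtol=rtol,
            atol=atol,
            args=(cur_params, rates),
        )
        if not sol.success:
            raise IntegrationError(f"ODE solver failed: {sol.message}", sol.t[-1] if len(sol.t) else s)
        for t, col in zip(sol.t[:-1], np.asarray(sol.y)[:, :-1].T):
            record(t, col, cur_params)
        y = np.asarray(sol.y)[:, -1]
        if k < len(seg_edges) - 2:
            for ev in grouped[e]:
                sv = StateVector.from_array(y, cur_params.n_clones, cur_params.has_downstream)
                cur_params, sv = apply_event(ev, cur_params, sv)
                y = sv.to_array()
    # events scheduled exactly at t1 fire before the final state is reported
    for ev in terminal_events:
        sv = StateVector.from_array(y, cur_params.n_clones, cur_params.has_downstream)
        cur_params, sv = apply_event(ev, cur_params, sv)
        y = sv.to_array()
    for t in grid[np.abs(grid - t1) <= eps]:
        record(t, y, cur_params)

    arr = np.vstack(rows)
    m = cur_params.n_clones
    traj = Trajectory(
        times=np.asarray(times_out),
        N=arr[:, :m],
        A=arr[:, m : 2 * m],
        I=arr[:, 2 * m : 3 * m],
        flux=np.vstack(flux_rows),
        D=arr[:, 3 * m : 4 * m] if cur_params.has_downstream else None,
        clone_labels=params.clone_labels(),
    )
    return traj


def simulate_to_steady_state(
    params: SystemParams,
    init: StateVector,
    rtol: float = 1e-10,
    atol: float = 1e-12,
    ss_tol: float = 1e-10,
    max_chunks: int = 80,
    chunk: float | None = None,
    method: str = "Radau",
) -> StateVector:
    """Integrate in growing chunks until the state stops changing.

    Convergence is declared when the relative change of every component over
    a whole chunk falls below ``ss_tol``. The chunk length defaults to a
    multiple of the slowest kinetic timescale in the parameter set.
    """
    init.validate(params)
    if chunk is None:
        scales = []
        for c in params.clones:
            for v in (c.u, c.d_I, c.r - c.d_A, c.b):
                if v > 0:
                    scales.append(v)
        slowest = min(scales) if scales else 1.0
        chunk = min(50.0 / slowest, 1e5)
    y = init.to_array()
    t = 0.0
    scale = max(1.0, params.K)
    for _ in range(max_chunks):
        rates = _unpack_params(params)
        sol = solve_ivp(
            _rhs_flat,
            (t, t + chunk),
            y,
            method=method,
            rtol=rtol,
            atol=atol,
            args=(params, rates),
        )
        if not sol.success:
            raise IntegrationError(f"ODE solver failed: {sol.message}", sol.t[-1])
        y_new = sol.y[:, -1]
        delta = np.max(np.abs(y_new - y) / (np.abs(y_new) + 1e-12 * scale))
        t += chunk
        y = y_new
        if delta < ss_tol:
            break
        chunk = min(chunk * 1.5, 1e6)
    return StateVector.from_array(y, params.n_clones, params.has_downstream)
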