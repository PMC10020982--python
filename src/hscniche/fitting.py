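"""Parameter estimation by simulated annealing.

The cost is the sum of squared residuals between an observed table
(time, clone, compartment, count) and the matching model outputs.
Proposals are independent multiplicative log-normal steps, which keep every
rate positive with no upper bound; acceptance follows the Metropolis rule
under a geometric cooling schedule T_k = T0 * alpha^k.

Raw rates are not uniquely identifiable from bulk count time series —
different rate combinations can produce near-identical trajectories — so
recovery is reported on identifiable derived quantities (fitness F, vacant
niches E*, the inactive/active ratio, the progenitor flux) rather than on
the raw parameter vector. Pairwise-equality constraints between parameters
can be imposed to reduce the searched dimension.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .equilibrium import empty_niche_equilibrium, fitness, monoclonal_equilibrium
from .model import StateVector, simulate
from .params import RATE_NAMES, SystemParams

__all__ = [
    "FitProblem",
    "FitResult",
    "get_param",
    "set_param",
    "ssr_cost",
    "simulated_annealing",
]

_OBSERVABLES = ("N", "A", "I", "D", "flux")


def get_param(params: SystemParams, path: str) -> float:
    """Read a parameter by path: ``"K"`` or ``"clone<j>.<rate>"``."""
    if path == "K":
        return params.K
    try:
        clone_part, rate = path.split(".")
        j = int(clone_part.removeprefix("clone"))
        if rate not in RATE_NAMES:
            raise ValueError
        return getattr(params.clones[j], rate)
    except (ValueError, IndexError):
        raise ValueError(f"unknown parameter path {path!r}") from None


def set_param(params: SystemParams, path: str, value: float) -> SystemParams:
    """Return a copy of ``params`` with the path set to ``value``."""
    if path == "K":
        return dataclasses.replace(params, K=value)
    clone_part, rate = path.split(".")
    j = int(clone_part.removeprefix("clone"))
    return params.replace_clone(j, params.clones[j].with_(**{rate: value}))


@dataclass
class FitProblem:
    """An estimation problem: observations, a parameter template, and the
    set of free parameters.

    ``initial_state`` may be an explicit :class:`StateVector`, the string
    ``"equilibrium"`` (homeostasis of the candidate parameters), or a
    callable mapping candidate parameters to a start state — e.g. a
    depleted equilibrium for recovery experiments, so the start state is
    consistent with each candidate.
    ``equal_pairs`` ties the second path of each pair to the first; tied
    parameters move together throughout the search.
    """

    observed: pd.DataFrame
    params: SystemParams
    free: tuple[str, ...]
    equal_pairs: tuple[tuple[str, str], ...] = ()
    initial_state: StateVector | str | Callable[[SystemParams], StateVector] = "equilibrium"
    t0: float = 0.0
    rtol: float = 1e-6
    atol: float = 1e-9
    method: str = "LSODA"

    def __post_init__(self) -> None:
        required = {"time", "clone", "compartment", "count"}
        missing = required - set(self.observed.columns)
        if missing:
            raise ValueError(f"observed table is missing column(s) {sorted(missing)}")
        labels = set(self.params.clone_labels())
        bad_clones = set(self.observed["clone"]) - labels
        if bad_clones:
            raise ValueError(f"observed clone(s) {sorted(bad_clones)} not in model ({sorted(labels)})")
        bad_comps = set(self.observed["compartment"]) - set(_OBSERVABLES)
        if bad_comps:
            raise ValueError(f"observed compartment(s) {sorted(bad_comps)} are not model observables")
        for path in self.free:
            get_param(self.params, path)
        for a, b in self.equal_pairs:
            get_param(self.params, a)
            get_param(self.params, b)

    def build_params(self, values: Sequence[float]) -> SystemParams:
        """Parameters with the free vector applied and equality ties enforced."""
        if len(values) != len(self.free):
            raise ValueError(f"expected {len(self.free)} free values, got {len(values)}")
        p = self.params
        for path, v in zip(self.free, values):
            p = set_param(p, path, float(v))
        for a, b in self.equal_pairs:
            p = set_param(p, b, get_param(p, a))
        return p

    def start_values(self) -> np.ndarray:
        return np.array([get_param(self.params, path) for path in self.free])

    def _resolve_init(self, params: SystemParams) -> StateVector:
        if isinstance(self.initial_state, StateVector):
            return self.initial_state
        if callable(self.initial_state):
            return self.initial_state(params)
        if self.initial_state == "equilibrium":
            from .equilibrium import equilibrium_state

            return equilibrium_state(params)
        raise ValueError(f"unknown initial_state spec {self.initial_state!r}")


def ssr_cost(values: Sequence[float], problem: FitProblem) -> float:
    """Sum of squared residuals at the given free-parameter values.

    Returns +inf when the candidate cannot be simulated (invalid rates, no
    equilibrium, integrator failure), so such proposals are rejected.
    """
    try:
        params = problem.build_params(values)
        init = problem._resolve_init(params)
        obs_times = np.sort(problem.observed["time"].unique())
        t0 = min(problem.t0, obs_times[0])
        grid = np.union1d(obs_times, [t0])
        traj = simulate(params, init, (t0, obs_times[-1]), output_grid=grid,
                        rtol=problem.rtol, atol=problem.atol, method=problem.method)
    except Exception:
        return np.inf
    labels = params.clone_labels()
    comps = {"N": traj.N, "A": traj.A, "I": traj.I, "flux": traj.flux}
    if traj.D is not None:
        comps["D"] = traj.D
    time_index = {t: i for i, t in enumerate(traj.times)}
    ssr = 0.0
    for row in problem.observed.itertuples(index=False):
        i = time_index[row.time]
        j = labels.index(row.clone)
        predicted = comps[row.compartment][i, j]
        ssr += (row.count - predicted) ** 2
    return float(ssr)


@dataclass
class FitResult:
    """Best point found by annealing plus identifiable summaries.

    ``summaries`` holds, per clone, the derived quantities on which
    recovery should be judged: fitness F, vacant niches E*, the
    inactive/active ratio (r - d_A)/d_I and (single-clone systems) flux*.
    """

    best_params: SystemParams
    best_values: dict[str, float]
    best_cost: float
    cost_trace: np.ndarray
    acceptance_rate: float
    seed: int
    summaries: dict[str, dict[str, float]]


def _summaries(params: SystemParams) -> dict[str, dict[str, float]]:
    out: dict[str, dict[str, float]] = {}
    for label, clone in zip(params.clone_labels(), params.clones):
        entry = {"fitness": fitness(clone)}
        if clone.persistent and clone.b > 0:
            entry["E_star"] = empty_niche_equilibrium(clone)
            entry["inactive_active_ratio"] = (clone.r - clone.d_A) / clone.d_I if clone.d_I > 0 else np.inf
        out[label] = entry
    if params.n_clones == 1:
        eq = monoclonal_equilibrium(params, check_stability=False)
        if eq.exists:
            out[params.clone_labels()[0]]["flux_star"] = eq.flux_star
    return out


def simulated_annealing(
    problem: FitProblem,
    x0: Sequence[float] | None = None,
    seed: int = 0,
    max_iter: int = 20_000,
    T0: float | None = None,
    alpha: float = 0.999,
    sigma: float = 0.05,
    adapt: bool = True,
    target_acceptance: float = 0.3,
    restart_interval: int = 1000,
) -> FitResult:
    """Metropolis annealing with geometric cooling and log-normal proposals.

    ``T0`` defaults to the cost at the start point, so the initial
    acceptance is permissive regardless of data scale. With ``adapt`` the
    proposal width is nudged every 200 iterations toward the target
    acceptance rate. Every ``restart_interval`` iterations the walker is
    returned to the best-ever point if it has drifted substantially uphill
    (elitist restart), which guards against freezing in a poor basin; set
    ``restart_interval=0`` to disable. Reproducible under a fixed seed;
    the best-ever point is returned (not the final one).
    """
    if max_iter < 1:
        raise ValueError("max_iter must be at least 1")
    rng = np.random.default_rng(seed)
    x = np.array(problem.start_values() if x0 is None else x0, dtype=float)
    if np.any(x <= 0):
        raise ValueError("initial free parameters must be positive for log-scale proposals")
    cost = ssr_cost(x, problem)
    if not np.isfinite(cost) and T0 is None:
        raise ValueError("cost at the start point is not finite; supply T0 explicitly")
    T = float(cost) if T0 is None else float(T0)
    if T <= 0:
        T = 1e-300  # pure downhill search
    best_x, best_cost = x.copy(), cost
    trace = np.empty(max_iter)
    accepted = 0
    window_accepted = 0
    cur_sigma = sigma
    for k in range(max_iter):
        proposal = x * np.exp(cur_sigma * rng.standard_normal(len(x)))
        new_cost = ssr_cost(proposal, problem)
        delta = new_cost - cost
        if delta <= 0 or (np.isfinite(new_cost) and rng.random() < np.exp(-delta / max(T, 1e-300))):
            x, cost = proposal, new_cost
            accepted += 1
            window_accepted += 1
            if cost < best_cost:
                best_x, best_cost = x.copy(), cost
        trace[k] = cost
        T *= alpha
        if adapt and (k + 1) % 200 == 0:
            rate = window_accepted / 200
            cur_sigma = float(np.clip(cur_sigma * np.exp(0.5 * (rate - target_acceptance)), 3e-3, 1.0))
            window_accepted = 0
        if restart_interval and (k + 1) % restart_interval == 0:
            if cost > 1.5 * best_cost + 1e-12:
                x, cost = best_x.copy(), best_cost
    best_params = problem.build_params(best_x)
    return FitResult(
        best_params=best_params,
        best_values=dict(zip(problem.free, best_x)),
        best_cost=float(best_cost),
        cost_trace=trace,
        acceptance_rate=accepted / max_iter,
        seed=seed,
        summaries=_summaries(best_params),
    )
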