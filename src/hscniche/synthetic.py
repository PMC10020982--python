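"""Synthetic observation generator.

Emulates the structure of the murine experiments the model is built
around — decline of stem cells without a niche, recovery after partial
depletion, and clonal competition time courses — as (optionally noisy)
samples of the model's own trajectories. Every dataset carries its ground
truth, so parameter-recovery studies can score estimates against the
generating parameters.

Noise is multiplicative log-normal (cell counts are positive); ``sigma`` is
the standard deviation of the log-ratio between noisy and noiseless counts.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .competition import competition_initial_state
from .equilibrium import equilibrium_state
from .model import StateVector, Trajectory, simulate
from .params import CloneParams, SystemParams

__all__ = [
    "SyntheticDesign",
    "SyntheticDataset",
    "generate",
    "sample_clone_params",
    "sample_neutral_variant",
]

EXPERIMENTS = ("recovery_after_depletion", "no_niche_decline", "competition_timecourse")


@dataclass(frozen=True)
class SyntheticDesign:
    """Specification of a synthetic experiment.

    ``kill_fraction`` applies to recovery experiments (default 50%
    depletion, emulating acute blood loss); ``init_unbound`` gives the
    starting (A, I) pools per clone for niche-free decline;
    ``fractions`` are the initial niche shares for competition runs.
    """

    params: SystemParams
    experiment: str
    times: tuple[float, ...]
    sigma: float = 0.0
    replicates: int = 1
    seed: int = 0
    kill_fraction: float = 0.5
    init_unbound: tuple[float, float] = (10.0, 10.0)
    fractions: tuple[float, ...] = (0.9, 0.1)
    compartments: tuple[str, ...] = ("N", "A", "I")

    def __post_init__(self) -> None:
        if self.experiment not in EXPERIMENTS:
            raise ValueError(f"unknown experiment {self.experiment!r}; expected one of {EXPERIMENTS}")
        times = tuple(float(t) for t in self.times)
        if len(times) < 2 or np.any(np.diff(times) <= 0):
            raise ValueError("times must be strictly increasing with at least two points")
        object.__setattr__(self, "times", times)
        if self.sigma < 0:
            raise ValueError("sigma must be non-negative")
        if self.replicates < 1:
            raise ValueError("replicates must be at least 1")
        if not (0.0 <= self.kill_fraction < 1.0):
            raise ValueError("kill_fraction must lie in [0, 1)")


@dataclass
class SyntheticDataset:
    """Observed table plus the ground truth that generated it."""

    observed: pd.DataFrame
    truth_params: SystemParams
    truth_trajectory: Trajectory
    design: SyntheticDesign


def _initial_state(design: SyntheticDesign) -> tuple[SystemParams, StateVector]:
    params = design.params
    if design.experiment == "recovery_after_depletion":
        init = equilibrium_state(params)
        factor = 1.0 - design.kill_fraction
        init = StateVector(
            N=init.N * factor, A=init.A * factor, I=init.I * factor,
            D=None if init.D is None else init.D * factor,
        )
        return params, init
    if design.experiment == "no_niche_decline":
        params = dataclasses.replace(params, K=0.0)
        m = params.n_clones
        A0, I0 = design.init_unbound
        return params, StateVector(
            N=np.zeros(m), A=np.full(m, A0), I=np.full(m, I0),
            D=np.zeros(m) if params.has_downstream else None,
        )
    # competition_timecourse
    if params.n_clones < 2:
        raise ValueError("competition_timecourse requires at least two clones")
    return params, competition_initial_state(params, design.fractions)


def generate(design: SyntheticDesign) -> SyntheticDataset:
    """Simulate the designed experiment and sample it at the given times.

    Deterministic under a fixed seed; the noiseless trajectory is returned
    unchanged alongside the noisy table.
    """
    params, init = _initial_state(design)
    times = np.asarray(design.times)
    traj = simulate(params, init, (times[0], times[-1]), output_grid=times)
    labels = params.clone_labels()
    comps = {"N": traj.N, "A": traj.A, "I": traj.I, "flux": traj.flux}
    if traj.D is not None:
        comps["D"] = traj.D
    rng = np.random.default_rng(design.seed)
    rows = []
    for rep in range(design.replicates):
        for comp in design.compartments:
            if comp not in comps:
                raise ValueError(f"compartment {comp!r} not available in this experiment")
            values = comps[comp]
            for j, lab in enumerate(labels):
                noiseless = values[:, j]
                if design.sigma > 0:
                    noisy = noiseless * np.exp(design.sigma * rng.standard_normal(len(times)))
                else:
                    noisy = noiseless
                rows.append(pd.DataFrame({
                    "time": times, "clone": lab, "compartment": comp,
                    "count": noisy, "replicate": rep,
                }))
    observed = pd.concat(rows, ignore_index=True)
    return SyntheticDataset(
        observed=observed, truth_params=params, truth_trajectory=traj, design=design
    )


def sample_clone_params(
    rng: np.random.Generator,
    K: float = 100.0,
    vacancy_fraction_range: tuple[float, float] = (0.01, 0.6),
    label: str | None = None,
) -> CloneParams:
    """Draw a random persistent clone whose monoclonal equilibrium exists.

    Rates are drawn log-uniformly on physiologically spread ranges
    (detachment 0.03-1/day, active-cell kinetics 0.1-1/day with a division
    surplus of 20%-500% over differentiation, inactive differentiation
    0.1-3/day); the attachment rate is then set so the homeostatic vacancy
    E* is a uniform draw of the given fraction of K, which guarantees
    r > d_A and E* < K by construction.
    """
    u = 10.0 ** rng.uniform(-1.5, 0.0)
    d_A = 10.0 ** rng.uniform(-1.0, 0.0)
    r = d_A * (1.0 + 10.0 ** rng.uniform(-0.7, 0.7))
    d_I = 10.0 ** rng.uniform(-1.0, 0.5)
    E_star = K * rng.uniform(*vacancy_fraction_range)
    b = d_I * (r + d_A) / (E_star * (r - d_A))
    return CloneParams(b=b, u=u, r=r, d_A=d_A, d_I=d_I, label=label)


def sample_neutral_variant(
    clone: CloneParams, rng: np.random.Generator, label: str | None = None
) -> CloneParams:
    """A clone with identical fitness but different raw rates: b and d_I
    co-scaled by a common factor and u rescaled independently — both
    changes leave F = (b/d_I)(r-d_A)/(r+d_A) untouched."""
    scale = 10.0 ** rng.uniform(-0.5, 0.5)
    u_scale = 10.0 ** rng.uniform(-0.5, 0.5)
    return clone.with_(b=clone.b * scale, d_I=clone.d_I * scale, u=clone.u * u_scale, label=label)
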