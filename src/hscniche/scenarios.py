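"""Intervention scenarios: parameter shifts, mobilization, transplantation.

The engine composes timed events (parameter scaling, cell addition,
fractional kill) on top of the ODE core:

* **Preconditioning** — an instantaneous fractional kill of all host
  compartments at protocol start (the dose-response shape is not modelled;
  the surviving fraction is the control variable).
* **Transplantation** — donor cells enter the inactive unbound pool (only
  inactive cells can attach, so grafted cells must home through it), as a
  single dose or split into several doses on subsequent days.
* **Mobilization** — a temporary multiplication of the detachment rate u of
  all niche-resident clones while the agent is available; agents are not
  clone-selective.

Endpoints are donor niche chimerism (N_donor / sum N) and the cancer-stem-
cell burden (total CSC stem cells and their niche fraction).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .equilibrium import equilibrium_state
from .events import Event, sorted_schedule
from .model import StateVector, Trajectory, simulate
from .params import CloneParams, SystemParams

__all__ = [
    "MobilizationPulse",
    "ProtocolResult",
    "MobilizationComparison",
    "run_schedule",
    "transplant_protocol",
    "mobilization_hsct",
]

DEFAULT_ENDPOINT = 365.0


@dataclass(frozen=True)
class MobilizationPulse:
    """Temporary scaling of the detachment rate u.

    ``clones=None`` applies the pulse to every clone present when it starts
    (mobilizing agents are not clone-selective).
    """

    start: float
    duration: float
    u_multiplier: float
    clones: tuple[int, ...] | None = None

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError("mobilization duration must be positive")
        if self.u_multiplier < 0:
            raise ValueError("u_multiplier must be non-negative")

    def events(self) -> list[Event]:
        targets = self.clones if self.clones is not None else (None,)
        evs = []
        for c in targets:
            evs.append(Event(time=self.start, kind="scale_param", clone=c,
                             target="u", magnitude=self.u_multiplier))
            if self.u_multiplier > 0:
                evs.append(Event(time=self.start + self.duration, kind="scale_param",
                                 clone=c, target="u", magnitude=1.0 / self.u_multiplier))
        return evs


@dataclass
class ProtocolResult:
    """Endpoint summary of an intervention protocol."""

    endpoint_time: float
    donor_chimerism: float | None
    csc_burden_cells: float
    csc_burden_fraction: float
    trajectory: Trajectory


def run_schedule(
    params: SystemParams,
    init: StateVector,
    events: Sequence[Event],
    t_span: tuple[float, float],
    output_grid: np.ndarray | None = None,
    **solver_kwargs,
) -> Trajectory:
    """Integrate with a (sorted) event schedule; thin wrapper over
    :func:`hscniche.model.simulate`."""
    return simulate(params, init, t_span, events=sorted_schedule(events),
                    output_grid=output_grid, **solver_kwargs)


def _endpoint_summary(
    traj: Trajectory, host_indices: Sequence[int], donor_index: int | None
) -> tuple[float | None, float, float]:
    final = traj.final_state()
    N_tot = final.N.sum()
    chimerism = None
    if donor_index is not None:
        chimerism = float(final.N[donor_index] / N_tot) if N_tot > 0 else float("nan")
    burden_cells = float(final.total_stem()[list(host_indices)].sum())
    burden_frac = float(final.N[list(host_indices)].sum() / N_tot) if N_tot > 0 else float("nan")
    return chimerism, burden_cells, burden_frac


def transplant_protocol(
    host: SystemParams,
    donor: CloneParams,
    total_dose: float,
    n_doses: int = 1,
    dose_interval: float = 1.0,
    preconditioning_fraction: float = 0.0,
    mobilization: MobilizationPulse | None = None,
    host_init: StateVector | None = None,
    first_dose_time: float = 0.0,
    endpoint: float = DEFAULT_ENDPOINT,
    output_grid: np.ndarray | None = None,
    **solver_kwargs,
) -> ProtocolResult:
    """Simulate an HSCT protocol and report donor niche chimerism.

    The host starts at its homeostatic equilibrium (or ``host_init``);
    preconditioning kills a fraction of every host compartment at t = 0;
    the graft is split into ``n_doses`` equal portions ``dose_interval``
    days apart, each added to the donor's inactive pool.
    """
    if n_doses < 1:
        raise ValueError("n_doses must be at least 1")
    if n_doses > 1 and dose_interval <= 0:
        raise ValueError("dose_interval must be positive when n_doses > 1")
    if not (0.0 <= preconditioning_fraction <= 1.0):
        raise ValueError("preconditioning_fraction must lie in [0, 1]")
    if host_init is None:
        host_init = equilibrium_state(host)
    n_host = host.n_clones
    donor_index = n_host
    import dataclasses

    donor = dataclasses.replace(donor, label=donor.label or "donor")
    params = host.with_clone(donor)
    zeros = np.zeros(1)
    init = StateVector(
        N=np.concatenate([host_init.N, zeros]),
        A=np.concatenate([host_init.A, zeros]),
        I=np.concatenate([host_init.I, zeros]),
        D=None if host_init.D is None else np.concatenate([host_init.D, zeros]),
    )
    events: list[Event] = []
    if preconditioning_fraction > 0:
        for j in range(n_host):
            events.append(Event(time=0.0, kind="kill_fraction", clone=j,
                                target="all", magnitude=preconditioning_fraction))
    if mobilization is not None:
        events.extend(mobilization.events())
    per_dose = total_dose / n_doses
    for k in range(n_doses):
        events.append(Event(time=first_dose_time + k * dose_interval,
                            kind="add_cells", clone=donor_index,
                            target="I", magnitude=per_dose))
    traj = run_schedule(params, init, events, (0.0, endpoint),
                        output_grid=output_grid, **solver_kwargs)
    chimerism, burden_cells, burden_frac = _endpoint_summary(
        traj, range(n_host), donor_index
    )
    return ProtocolResult(
        endpoint_time=endpoint,
        donor_chimerism=chimerism,
        csc_burden_cells=burden_cells,
        csc_burden_fraction=burden_frac,
        trajectory=traj,
    )


@dataclass
class MobilizationComparison:
    """Paired protocols with and without a mobilization pulse before HSCT."""

    with_mobilization: ProtocolResult
    without_mobilization: ProtocolResult

    @property
    def relative_csc_reduction(self) -> float:
        """(burden_without - burden_with) / burden_without at the endpoint."""
        without = self.without_mobilization.csc_burden_cells
        if without == 0.0:
            return 0.0
        return (without - self.with_mobilization.csc_burden_cells) / without


def mobilization_hsct(
    host: SystemParams,
    donor: CloneParams,
    mobilization_days: float,
    u_multiplier: float,
    transplant_dose: float,
    n_doses: int = 1,
    dose_interval: float = 1.0,
    endpoint: float = DEFAULT_ENDPOINT,
    **solver_kwargs,
) -> MobilizationComparison:
    """Mobilizing agents followed by HSCT, compared against HSCT alone.

    The host niche is populated by its resident (e.g. CSC) clone at
    monoclonal equilibrium. In the mobilized arm, u of all resident clones
    is multiplied by ``u_multiplier`` from day 0 for ``mobilization_days``;
    the transplant is given at the end of the pulse in both arms so only
    the pulse differs. ``transplant_dose = 0`` isolates the effect of the
    mobilizing agent itself.
    """
    if mobilization_days <= 0:
        raise ValueError("mobilization_days must be positive")
    pulse = MobilizationPulse(
        start=0.0, duration=mobilization_days, u_multiplier=u_multiplier,
        clones=tuple(range(host.n_clones)),
    )
    common = dict(
        host=host, donor=donor, total_dose=transplant_dose, n_doses=n_doses,
        dose_interval=dose_interval, first_dose_time=mobilization_days,
        endpoint=endpoint, **solver_kwargs,
    )
    with_mob = transplant_protocol(mobilization=pulse, **common)
    without_mob = transplant_protocol(mobilization=None, **common)
    return MobilizationComparison(with_mobilization=with_mob, without_mobilization=without_mob)
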