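"""Multi-clone competition for a shared niche.

Outcome prediction follows the fitness ordering: the clone with the highest
F = (b/d_I)(r - d_A)/(r + d_A) excludes the others; ties (within a relative
tolerance) correspond to neutral competition, where niche composition is
preserved. The winner's long-run vacant-niche count is 1/F — the clone that
leaves the fewest empty niches in monoclonal equilibrium wins, the analogue
of the resource-competition R* rule.

Niche-level and progenitor-level clonal abundance can diverge: a clone's
progenitor output share scales with u_j N_j, so a fast-detaching clone is
over-represented downstream relative to its niche share. This is why blood
or bulk-marrow measurements of clonal burden (e.g. MRD) need not reflect
the stem-cell compartment.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .equilibrium import empty_niche_equilibrium, fitness
from .model import StateVector, Trajectory, simulate
from .params import CloneParams, SystemParams

__all__ = [
    "CompetitionOutcome",
    "predict_outcome",
    "competition_initial_state",
    "simulate_competition",
    "abundance_metrics",
]


@dataclass(frozen=True)
class CompetitionOutcome:
    """Predicted (and, after simulation, measured) outcome of a contest.

    ``predicted_winner`` is a clone index, ``"neutral"`` (top fitness values
    equal within tolerance), or ``"extinction"`` (no persistent clone).
    ``exclusion_times`` maps losing clone indices to the first time their
    niche fraction falls below the threshold, or None if not reached.
    """

    predicted_winner: int | str
    fitness_values: tuple[float, ...]
    final_E: float | None = None
    exclusion_times: dict[int, float | None] | None = None


def predict_outcome(clones: Sequence[CloneParams], tolerance: float = 1e-9) -> CompetitionOutcome:
    """Predict the contest outcome from the fitness ordering alone."""
    if len(clones) < 2:
        raise ValueError("a contest needs at least two clones")
    F = tuple(fitness(c) for c in clones)
    Fmax = max(F)
    if Fmax == 0.0:
        return CompetitionOutcome(predicted_winner="extinction", fitness_values=F, final_E=None)
    top = [j for j, f in enumerate(F) if abs(f - Fmax) <= tolerance * Fmax]
    if len(top) > 1:
        return CompetitionOutcome(predicted_winner="neutral", fitness_values=F, final_E=1.0 / Fmax)
    return CompetitionOutcome(predicted_winner=top[0], fitness_values=F, final_E=1.0 / Fmax)


def competition_initial_state(
    params: SystemParams,
    fractions: Sequence[float],
    reference: int = 0,
) -> StateVector:
    """Niche filled to the reference clone's monoclonal N*, split by the
    given fractions; unbound pools start at their per-clone conditional
    equilibria (A_j = u_j N_j/(r_j+d_Aj), I_j = A_j (r_j-d_Aj)/d_Ij).

    For neutral clones this lies exactly on the equilibrium manifold, so
    niche composition starts — and stays — at the given fractions.
    """
    fractions = np.asarray(fractions, dtype=float)
    if len(fractions) != params.n_clones:
        raise ValueError("one niche fraction per clone is required")
    if np.any(fractions < 0) or fractions.sum() > 1 + 1e-12:
        raise ValueError("fractions must be non-negative and sum to at most 1")
    ref = params.clones[reference]
    E_ref = empty_niche_equilibrium(ref)
    if E_ref >= params.K:
        raise ValueError("reference clone cannot sustain a positive equilibrium in this niche")
    N_total = params.K - E_ref
    N = fractions * N_total
    A = np.empty_like(N)
    I = np.empty_like(N)
    for j, c in enumerate(params.clones):
        A[j] = c.u * N[j] / (c.r + c.d_A) if (c.r + c.d_A) > 0 else 0.0
        I[j] = A[j] * (c.r - c.d_A) / c.d_I if c.d_I > 0 else 0.0
    D = None
    if params.has_downstream:
        ds = params.downstream
        flux = np.array([c.d_A for c in params.clones]) * A + np.array(
            [c.d_I for c in params.clones]
        ) * I
        D = ds.amplification * flux / ds.clearance
    return StateVector(N=N, A=A, I=I, D=D)


def simulate_competition(
    params: SystemParams,
    initial_niche_fractions: Sequence[float],
    t_span: tuple[float, float],
    output_grid: np.ndarray | None = None,
    exclusion_threshold: float = 0.01,
    reference: int = 0,
    tolerance: float = 1e-9,
    **solver_kwargs,
) -> tuple[Trajectory, CompetitionOutcome]:
    """Run a contest from the shared-niche quasi-equilibrium and measure
    exclusion times (first crossing below ``exclusion_threshold`` niche
    fraction) for every clone other than the predicted winner."""
    init = competition_initial_state(params, initial_niche_fractions, reference=reference)
    traj = simulate(params, init, t_span, output_grid=output_grid, **solver_kwargs)
    pred = predict_outcome(params.clones, tolerance=tolerance)
    frac = traj.niche_fraction()
    exclusion: dict[int, float | None] = {}
    losers = (
        range(params.n_clones)
        if pred.predicted_winner == "extinction"
        else [j for j in range(params.n_clones) if j != pred.predicted_winner]
    )
    if pred.predicted_winner != "neutral":
        for j in losers:
            below = np.where(frac[:, j] < exclusion_threshold)[0]
            exclusion[j] = float(traj.times[below[0]]) if len(below) else None
    outcome = CompetitionOutcome(
        predicted_winner=pred.predicted_winner,
        fitness_values=pred.fitness_values,
        final_E=pred.final_E,
        exclusion_times=exclusion or None,
    )
    return traj, outcome


def abundance_metrics(traj: Trajectory, clone: int) -> tuple[np.ndarray, np.ndarray]:
    """Time series of (niche_fraction, progenitor_output_fraction) for one
    clone: N_j / sum N and flux_j / sum flux. NaN where the denominator
    vanishes."""
    if traj.n_clones < 1 or not (0 <= clone < traj.n_clones):
        raise ValueError(f"clone index {clone} out of range for trajectory")
    N_tot = traj.N.sum(axis=1)
    flux_tot = traj.flux.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        niche = np.where(N_tot > 0, traj.N[:, clone] / N_tot, np.nan)
        output = np.where(flux_tot > 0, traj.flux[:, clone] / flux_tot, np.nan)
    return niche, output
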