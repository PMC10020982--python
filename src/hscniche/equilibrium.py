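"""Closed-form homeostatic equilibria, clonal fitness, and comparative statics.

For a single persistent clone (r > d_A) the positive equilibrium satisfies

    E* = d_I (r + d_A) / (b (r - d_A))        vacant niche spaces
    N* = K - E*                               niche-bound (quiescent) cells
    A* = u N* / (r + d_A)                     active cells
    I* = A* (r - d_A) / d_I                   inactive cells
    flux* = d_A A* + d_I I* = r A*            progenitor production

The clonal fitness

    F = (b / d_I) (r - d_A) / (r + d_A) = 1 / E*

orders competition outcomes: in a shared niche the clone with the highest F
excludes the others, and its monoclonal vacant-niche count is the smallest.
F is independent of the detachment rate u and of the capacity K.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np

from .model import StateVector, _rhs_flat, _unpack_params
from .params import CloneParams, SystemParams

__all__ = [
    "EquilibriumResult",
    "NoPositiveEquilibrium",
    "fitness",
    "empty_niche_equilibrium",
    "monoclonal_equilibrium",
    "equilibrium_state",
    "jacobian",
    "comparative_statics",
    "comparative_statics_table",
    "TABLE_PARAMETERS",
    "TABLE_QUANTITIES",
]

TABLE_PARAMETERS = ("K", "u", "r", "d_A", "d_I", "b")
TABLE_QUANTITIES = ("N_star", "I_star", "A_star", "flux_star")


class NoPositiveEquilibrium(ValueError):
    """The clone has no positive homeostatic equilibrium (r <= d_A)."""


@dataclass(frozen=True)
class EquilibriumResult:
    """Homeostatic equilibrium of a single clone in a niche of capacity K.

    ``exists`` is False when the clone cannot sustain a positive
    equilibrium (non-persistent, or E* >= K). ``degenerate`` flags the
    frozen-niche family at u = 0 (any N with A = I = 0 is stationary).
    """

    N_star: float
    A_star: float
    I_star: float
    E_star: float
    flux_star: float
    exists: bool
    stable: bool
    degenerate: str | None = None


def fitness(clone: CloneParams) -> float:
    """Clonal fitness F = (b/d_I)(r - d_A)/(r + d_A); 0 for non-persistent clones.

    Strictly increasing in b and r, strictly decreasing in d_I and d_A,
    independent of u. Defining F = 0 when r <= d_A keeps fitness orderings
    total.
    """
    if clone.r + clone.d_A == 0.0:
        raise ValueError("fitness undefined: r + d_A = 0")
    if not clone.persistent:
        return 0.0
    if clone.d_I == 0.0:
        return np.inf
    return (clone.b / clone.d_I) * (clone.r - clone.d_A) / (clone.r + clone.d_A)


def empty_niche_equilibrium(clone: CloneParams) -> float:
    """Vacant niche spaces at monoclonal homeostasis, E* = 1/F.

    Independent of the detachment rate u and of the capacity K.
    """
    if not clone.persistent:
        raise NoPositiveEquilibrium(
            "no positive equilibrium: division rate r must exceed d_A"
        )
    if clone.b == 0.0:
        raise NoPositiveEquilibrium("no positive equilibrium: attachment rate b is zero")
    return clone.d_I * (clone.r + clone.d_A) / (clone.b * (clone.r - clone.d_A))


def monoclonal_equilibrium(params: SystemParams, check_stability: bool = True) -> EquilibriumResult:
    """Closed-form homeostatic equilibrium for a single-clone system."""
    if params.n_clones != 1:
        raise ValueError("monoclonal_equilibrium requires exactly one clone")
    clone = params.clones[0]
    if not clone.persistent or clone.b == 0.0:
        return EquilibriumResult(
            N_star=0.0, A_star=0.0, I_star=0.0, E_star=np.inf, flux_star=0.0,
            exists=False, stable=False,
            degenerate="non-persistent" if not clone.persistent else "no-attachment",
        )
    E_star = empty_niche_equilibrium(clone)
    if E_star >= params.K:
        return EquilibriumResult(
            N_star=0.0, A_star=0.0, I_star=0.0, E_star=E_star, flux_star=0.0,
            exists=False, stable=False, degenerate=None,
        )
    N_star = params.K - E_star
    if clone.u == 0.0:
        # frozen niche: any occupancy with empty unbound pools is stationary
        return EquilibriumResult(
            N_star=float("nan"), A_star=0.0, I_star=0.0, E_star=E_star,
            flux_star=0.0, exists=False, stable=False, degenerate="frozen-niche",
        )
    A_star = clone.u * N_star / (clone.r + clone.d_A)
    I_star = A_star * (clone.r - clone.d_A) / clone.d_I
    flux_star = clone.r * A_star
    stable = False
    if check_stability:
        state = StateVector(N=[N_star], A=[A_star], I=[I_star])
        eigs = np.linalg.eigvals(jacobian(params, state))
        stable = bool(np.all(eigs.real < 1e-8))
    return EquilibriumResult(
        N_star=N_star, A_star=A_star, I_star=I_star, E_star=E_star,
        flux_star=flux_star, exists=True, stable=stable,
    )


def equilibrium_state(params: SystemParams) -> StateVector:
    """Monoclonal equilibrium as a StateVector (downstream pool, if present,
    at its own steady state amp*flux/clear). Raises if no positive equilibrium."""
    eq = monoclonal_equilibrium(params, check_stability=False)
    if not eq.exists:
        raise NoPositiveEquilibrium(
            f"system has no positive monoclonal equilibrium ({eq.degenerate or 'E* >= K'})"
        )
    D = None
    if params.has_downstream:
        ds = params.downstream
        D = [ds.amplification * eq.flux_star / ds.clearance]
    return StateVector(N=[eq.N_star], A=[eq.A_star], I=[eq.I_star], D=D)


def jacobian(params: SystemParams, state: StateVector, h_rel: float = 1e-7) -> np.ndarray:
    """Numerical Jacobian of the model right-hand side at ``state``
    (central differences)."""
    y0 = state.to_array()
    n = len(y0)
    rates = _unpack_params(params)
    J = np.empty((n, n))
    for i in range(n):
        h = h_rel * max(abs(y0[i]), 1.0)
        yp, ym = y0.copy(), y0.copy()
        yp[i] += h
        ym[i] -= h
        J[:, i] = (_rhs_flat(0.0, yp, params, rates) - _rhs_flat(0.0, ym, params, rates)) / (2 * h)
    return J


def _perturb(params: SystemParams, name: str, rel_step: float) -> SystemParams:
    import dataclasses

    if name == "K":
        return dataclasses.replace(params, K=params.K * (1 + rel_step))
    clone = params.clones[0]
    value = getattr(clone, name)
    return params.replace_clone(0, clone.with_(**{name: value * (1 + rel_step)}))


def comparative_statics(
    params: SystemParams,
    parameter_name: str,
    rel_step: float = 0.01,
    deadband: float = 1e-9,
) -> tuple[str, str, str, str]:
    """Signs of the response of (N*, I*, A*, flux*) to a relative increase
    of one parameter, each in {"+", "-", "0"}.

    Computed by re-evaluating the closed-form equilibrium at the perturbed
    parameter; relative changes below ``deadband`` are reported as "0".
    """
    if parameter_name not in TABLE_PARAMETERS:
        raise ValueError(f"unknown parameter {parameter_name!r}; expected one of {TABLE_PARAMETERS}")
    base = monoclonal_equilibrium(params, check_stability=False)
    pert = monoclonal_equilibrium(_perturb(params, parameter_name, rel_step), check_stability=False)
    if not (base.exists and pert.exists):
        raise NoPositiveEquilibrium(
            f"equilibrium does not exist at the baseline or after perturbing {parameter_name}"
        )
    signs = []
    for q in TABLE_QUANTITIES:
        v0, v1 = getattr(base, q), getattr(pert, q)
        rel = (v1 - v0) / max(abs(v0), 1e-300)
        signs.append("0" if abs(rel) < deadband else ("+" if rel > 0 else "-"))
    return tuple(signs)


def comparative_statics_table(params: SystemParams, rel_step: float = 0.01) -> dict[str, tuple]:
    """Full sign matrix: parameter -> signs for (N*, I*, A*, flux*)."""
    return {name: comparative_statics(params, name, rel_step) for name in TABLE_PARAMETERS}
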