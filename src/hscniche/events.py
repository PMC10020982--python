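"""Timed interventions applied to a running simulation.

An :class:`Event` changes either the parameters (``scale_param``,
``set_param``) or the state (``add_cells``, ``kill_fraction``) at a fixed
time. The integrator restarts at every event time, so discontinuities are
handled exactly.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import TYPE_CHECKING, Iterable, Sequence

import numpy as np

from .params import RATE_NAMES, CloneParams, SystemParams

if TYPE_CHECKING:
    from .model import StateVector

EVENT_KINDS = ("scale_param", "set_param", "add_cells", "kill_fraction")
COMPARTMENTS = ("N", "A", "I", "D")


class ConfigError(ValueError):
    """Invalid configuration (unknown key, bad value, unknown target)."""


@dataclass(frozen=True)
class Event:
    """A timed intervention.

    Parameters
    ----------
    time : float
        Day at which the event fires.
    kind : str
        One of ``scale_param``, ``set_param``, ``add_cells``,
        ``kill_fraction``.
    clone : int or None
        Index of the clone affected; ``None`` applies the event to every
        clone (for ``K`` the clone index is ignored).
    target : str
        Parameter name (``b``, ``u``, ``r``, ``d_A``, ``d_I``, ``K``) for
        parameter events; compartment (``N``, ``A``, ``I``, ``D`` or
        ``all``) for cell events. ``add_cells`` defaults to the inactive
        pool ``I`` — grafted cells must home before they can attach.
    magnitude : float
        Scale factor, new value, cell count, or kill fraction in [0, 1].
    """

    time: float
    kind: str
    magnitude: float
    clone: int | None = None
    target: str | None = None

    def __post_init__(self) -> None:
        if self.kind not in EVENT_KINDS:
            raise ConfigError(f"unknown event kind {self.kind!r}; expected one of {EVENT_KINDS}")
        if self.kind in ("scale_param", "set_param"):
            if self.target not in RATE_NAMES + ("K",):
                raise ConfigError(
                    f"event target {self.target!r} is not a parameter "
                    f"(expected one of {RATE_NAMES + ('K',)})"
                )
            if self.kind == "set_param" and self.magnitude < 0:
                raise ConfigError("set_param magnitude must be non-negative")
            if self.kind == "scale_param" and self.magnitude < 0:
                raise ConfigError("scale_param magnitude must be non-negative")
        elif self.kind == "add_cells":
            if self.magnitude < 0:
                raise ConfigError("add_cells magnitude must be non-negative")
            if self.target is not None and self.target not in COMPARTMENTS:
                raise ConfigError(f"add_cells target {self.target!r} is not a compartment")
        elif self.kind == "kill_fraction":
            if not (0.0 <= self.magnitude <= 1.0):
                raise ConfigError("kill_fraction magnitude must lie in [0, 1]")
            if self.target is not None and self.target not in COMPARTMENTS + ("all",):
                raise ConfigError(f"kill_fraction target {self.target!r} is not a compartment")

    def to_dict(self) -> dict:
        d = {"time": self.time, "kind": self.kind, "magnitude": self.magnitude}
        if self.clone is not None:
            d["clone"] = self.clone
        if self.target is not None:
            d["target"] = self.target
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "Event":
        unknown = set(d) - {"time", "kind", "magnitude", "clone", "target"}
        if unknown:
            raise ConfigError(f"unknown event key(s): {sorted(unknown)}")
        for key in ("time", "kind", "magnitude"):
            if key not in d:
                raise ConfigError(f"event is missing required key {key!r}")
        return cls(
            time=float(d["time"]),
            kind=str(d["kind"]),
            magnitude=float(d["magnitude"]),
            clone=None if d.get("clone") is None else int(d["clone"]),
            target=d.get("target"),
        )


def _clone_indices(event: Event, params: SystemParams) -> list[int]:
    if event.clone is None:
        return list(range(params.n_clones))
    if not (0 <= event.clone < params.n_clones):
        raise ConfigError(
            f"event references clone {event.clone} but the system has "
            f"{params.n_clones} clone(s)"
        )
    return [event.clone]


def apply_event(
    event: Event, params: SystemParams, state: "StateVector"
) -> tuple[SystemParams, "StateVector"]:
    """Apply one event, returning the (possibly new) params and state."""
    state = state.copy()
    if event.kind in ("scale_param", "set_param"):
        if event.target == "K":
            new_K = event.magnitude if event.kind == "set_param" else params.K * event.magnitude
            import dataclasses

            params = dataclasses.replace(params, K=new_K)
        else:
            for j in _clone_indices(event, params):
                clone = params.clones[j]
                old = getattr(clone, event.target)
                new = event.magnitude if event.kind == "set_param" else old * event.magnitude
                params = params.replace_clone(j, clone.with_(**{event.target: new}))
    elif event.kind == "add_cells":
        target = event.target or "I"
        for j in _clone_indices(event, params):
            arr = getattr(state, target)
            if arr is None:
                raise ConfigError("add_cells targets D but the system has no downstream pool")
            arr[j] += event.magnitude
    elif event.kind == "kill_fraction":
        target = event.target or "all"
        names = COMPARTMENTS if target == "all" else (target,)
        survive = 1.0 - event.magnitude
        for j in _clone_indices(event, params):
            for name in names:
                arr = getattr(state, name)
                if arr is None:
                    if target == "all":
                        continue
                    raise ConfigError("kill_fraction targets D but the system has no downstream pool")
                arr[j] *= survive
    return params, state


def sorted_schedule(events: Iterable[Event]) -> list[Event]:
    return sorted(events, key=lambda e: e.time)


def events_from_dicts(items: Sequence[dict]) -> list[Event]:
    return [Event.from_dict(d) for d in items]
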