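"""When and where on the tree the fitness landscape changes.

Three timing regimes are supported:

stochastic
    changes arrive as a Poisson process with rate ``lam`` per unit branch
    length, drawn inside the event loop as an extra exponential clock
    competing with the substitutions;
periodic
    changes occur at fixed global times ``interval, 2*interval, ...``
    measured as distance from the root, on every lineage crossing that
    depth; the replacement landscape is either ``shared`` by all lineages
    alive at a tick or drawn independently per lineage;
explicit
    changes occur at user-given branch coordinates (child-node name, offset
    from the parent end), optionally with user-given replacement vectors.

Branch coordinates are half-open: ``0 <= offset < branch_length``, so an
event landing on a node belongs to the branches below it.  Events falling
within ``SNAP_EPS`` of a node are snapped to the node to keep floating-point
round-off from scheduling a change an instant before a split instead of on
the daughter branches.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence, Union

import numpy as np

from .landscape_core import FitnessVector
from .landscape_generation import LandscapeRule, derive_new_landscape
from .phylogeny import Tree

__all__ = [
    "StochasticRegime",
    "PeriodicRegime",
    "ExplicitRegime",
    "ScheduledEvent",
    "ChangeRecord",
    "ChangeSchedule",
    "build_change_schedule",
    "resolve_sharing",
]

#: Events within this distance of a node are snapped onto the node.
SNAP_EPS = 1e-9


@dataclass(frozen=True)
class StochasticRegime:
    """Poisson landscape changes at ``rate`` per unit branch length.

    When ``scale_with_q`` is set and the rate matrix is left raw, the rate is
    multiplied by the landscape's expected substitution rate so that changes
    keep pace with the (unnormalized) molecular clock.
    """

    rate: float
    scale_with_q: bool = False

    def __post_init__(self):
        if self.rate < 0:
            raise ValueError(f"stochastic change rate must be >= 0, got {self.rate}")


@dataclass(frozen=True)
class PeriodicRegime:
    """Deterministic changes every ``interval`` units of global time."""

    interval: float
    sharing: str = "independent"

    def __post_init__(self):
        if self.interval <= 0:
            raise ValueError(f"periodic interval must be > 0, got {self.interval}")
        if self.sharing not in ("independent", "shared"):
            raise ValueError(f"sharing must be 'independent' or 'shared', got {self.sharing!r}")


@dataclass(frozen=True)
class ScheduledEvent:
    """A deterministic change at branch coordinate (branch, offset)."""

    branch: str
    offset: float
    new_fitness: Optional[FitnessVector] = None
    tick_index: Optional[int] = None  # set for periodic events


@dataclass(frozen=True)
class ExplicitRegime:
    """User-supplied change times, optionally with replacement vectors."""

    events: tuple[ScheduledEvent, ...]

    def __init__(self, events: Sequence[ScheduledEvent]):
        object.__setattr__(self, "events", tuple(events))


@dataclass(frozen=True)
class NoChangeRegime:
    """The landscape never changes."""


Regime = Union[StochasticRegime, PeriodicRegime, ExplicitRegime, NoChangeRegime]


@dataclass(frozen=True)
class ChangeRecord:
    """One realized landscape change, as written to the change log."""

    landscape_id: int
    branch: str
    global_time: float
    offset: float
    fitness_after: FitnessVector


@dataclass
class ChangeSchedule:
    """Regime plus the precomputed deterministic event list (time-sorted)."""

    regime: Regime
    events: list[ScheduledEvent] = field(default_factory=list)
    _by_branch: dict = field(default_factory=dict, repr=False)

    def events_for_branch(self, branch: str) -> list[ScheduledEvent]:
        return self._by_branch.get(branch, [])


def _periodic_events(tree: Tree, regime: PeriodicRegime) -> list[ScheduledEvent]:
    events = []
    for node in tree.bfs():
        if node.parent is None:
            continue
        t_parent = tree.global_time[node.parent.name]
        length = node.branch_length
        if length <= 0:
            continue
        k = max(1, int(np.floor(t_parent / regime.interval - SNAP_EPS)))
        while True:
            g = k * regime.interval
            if g >= t_parent + length - SNAP_EPS:
                break  # at or beyond the child node: belongs to daughters
            if g >= t_parent - SNAP_EPS:
                offset = max(0.0, g - t_parent)
                if abs(g - t_parent) <= SNAP_EPS:
                    offset = 0.0
                events.append(ScheduledEvent(node.name, offset, tick_index=k))
            k += 1
    return events


def _validate_explicit(tree: Tree, regime: ExplicitRegime) -> list[ScheduledEvent]:
    events = []
    for ev in regime.events:
        if ev.branch not in tree.node_index:
            raise ValueError(f"explicit change references unknown branch {ev.branch!r}")
        node = tree.node_index[ev.branch]
        if node.parent is None:
            raise ValueError(
                f"explicit change placed on the root {ev.branch!r}; the root has no branch "
                "and the initial landscape governs from time 0"
            )
        length = node.branch_length
        offset = ev.offset
        if abs(offset) <= SNAP_EPS:
            offset = 0.0
        if abs(offset - length) <= SNAP_EPS and node.children:
            # snap to the child node: the change belongs to the daughter branches
            for child in node.children:
                events.append(ScheduledEvent(child.name, 0.0, ev.new_fitness, ev.tick_index))
            continue
        if not (0 <= offset < length) and not (node.is_leaf and abs(offset - length) <= SNAP_EPS):
            raise ValueError(
                f"explicit change at offset {ev.offset} lies outside branch {ev.branch!r} "
                f"of length {length}"
            )
        offset = min(offset, length)
        events.append(ScheduledEvent(ev.branch, offset, ev.new_fitness, ev.tick_index))
    return events


def build_change_schedule(tree: Tree, regime: Regime) -> ChangeSchedule:
    """Precompute the deterministic change events for ``regime`` on ``tree``.

    Periodic regimes yield one event per (tick, branch-spanning-that-depth)
    pair; explicit regimes are validated and snapped; stochastic and
    no-change regimes have no precomputed events (stochastic changes are
    drawn in the event loop).
    """
    if isinstance(regime, PeriodicRegime):
        events = _periodic_events(tree, regime)
    elif isinstance(regime, ExplicitRegime):
        events = _validate_explicit(tree, regime)
    elif isinstance(regime, (StochasticRegime, NoChangeRegime)):
        events = []
    else:
        raise TypeError(f"unknown regime {regime!r}")
    key = lambda ev: tree.global_time[tree.node_index[ev.branch].parent.name] + ev.offset
    events.sort(key=key)
    schedule = ChangeSchedule(regime, events)
    for ev in events:
        schedule._by_branch.setdefault(ev.branch, []).append(ev)
    for evs in schedule._by_branch.values():
        evs.sort(key=lambda ev: ev.offset)
    return schedule


def resolve_sharing(
    regime: PeriodicRegime,
    lineages: Sequence[str],
    epoch_vector: FitnessVector,
    previous_by_lineage: dict[str, FitnessVector],
    rule: LandscapeRule,
    rng: np.random.Generator,
    change_index: int = 0,
) -> dict[str, FitnessVector]:
    """Assign the replacement landscape(s) for one periodic tick.

    In ``shared`` mode a single vector is derived once from the common epoch
    landscape and handed to every lineage alive at the tick; in
    ``independent`` mode each lineage gets a fresh derivation from its own
    previous landscape.
    """
    if regime.sharing == "shared":
        vec = derive_new_landscape(rule, epoch_vector, None, change_index, rng)
        return {br: vec for br in lineages}
    return {
        br: derive_new_landscape(rule, previous_by_lineage[br], None, change_index, rng)
        for br in lineages
    }
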