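"""The Gillespie event loop over the phylogeny.

Evolution proceeds forward in time along every branch, visiting nodes in
breadth-first order so each branch starts from its parent's end state.  On a
branch the total exit rate is the sum over positions of the current allele's
rate of leaving (``-q_ii``), plus the stochastic landscape-change rate when
that regime is active.  Waiting times are exponential in the total rate; a
waiting time that overshoots the next deterministic landscape change or the
branch end is discarded in favour of that deterministic event (the
exponential's memorylessness makes the redraw statistically neutral).  When
a substitution fires, the position is chosen proportionally to its exit
rate and the new allele proportionally to ``q_ij``.  Every landscape change
instates a new fitness vector and triggers recomputation of ``Q`` and
``pi`` before simulation resumes; the recomputation is lazy, so runs whose
statistic does not consult ``Q`` (for example change counting on an empty
sequence) skip the linear algebra without changing any sampled law.

Random draws follow a fixed order — waiting time, event type, position, new
allele — so a seed reproduces bit-identically everywhere.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .landscape_core import (
    Alphabet,
    FitnessVector,
    MutationMatrix,
    RateMatrix,
    StationaryDistribution,
    build_rate_system,
    expected_substitution_rate,
    build_raw_rate_matrix,
    stationary_distribution,
)
from .landscape_generation import LandscapeRule, derive_new_landscape, sample_fitness_vector
from .phylogeny import Tree, TreeNode
from .scheduling import (
    ChangeRecord,
    ChangeSchedule,
    ExplicitRegime,
    NoChangeRegime,
    PeriodicRegime,
    Regime,
    ScheduledEvent,
    StochasticRegime,
    build_change_schedule,
)

__all__ = [
    "InstanceSettings",
    "SequenceState",
    "Event",
    "SimulationResult",
    "LandscapeContext",
    "sample_root_sequence",
    "draw_next_event",
    "simulate_branch",
    "run_simulation",
]


@dataclass(frozen=True)
class InstanceSettings:
    """Everything one landscape instance needs to run on a tree."""

    alphabet: Alphabet
    length: int
    rule: LandscapeRule
    regime: Regime
    mutation: Optional[MutationMatrix] = None
    scaling_mode: str = "normalized"
    root_sequence: Optional[str] = None
    record_changes: bool = True
    record_events: bool = False

    def __post_init__(self):
        if self.length < 0:
            raise ValueError("sequence length must be >= 0")
        if self.rule.change_rule in ("increase_current", "decrease_current") and self.length != 1:
            raise ValueError(
                f"{self.rule.change_rule} adjusts the fitness of 'the current allele' and is "
                f"only defined for a landscape governing exactly one position (got length "
                f"{self.length})"
            )
        if self.rule.change_rule in ("increase_current", "decrease_current") and (
            isinstance(self.regime, PeriodicRegime) and self.regime.sharing == "shared"
        ):
            raise ValueError(
                "shared periodic changes are incompatible with increase/decrease rules: "
                "parallel lineages carry different current alleles"
            )
        if self.rule.change_rule == "explicit" and not isinstance(self.regime, ExplicitRegime):
            raise ValueError(
                "explicit replacement vectors require explicitly specified change times"
            )
        if self.rule.change_rule == "resample" and self.rule.init_source.kind in ("file", "flat"):
            raise ValueError(
                "resample redraws from the initial distribution; it needs a gamma or "
                "lognormal initial landscape, not a fixed vector"
            )
        if isinstance(self.regime, (PeriodicRegime, StochasticRegime)) and self.rule.change_rule == "none":
            raise ValueError(
                f"the timing regime schedules changes but change_rule is 'none'; pick a rule"
            )

    @property
    def mutation_matrix(self) -> MutationMatrix:
        return self.mutation if self.mutation is not None else MutationMatrix.uniform(self.alphabet)


class LandscapeContext:
    """A landscape instance's current fitness vector with lazy ``Q`` and ``pi``."""

    __slots__ = ("fitness", "mutation", "scaling_mode", "landscape_id", "_Q", "_pi")

    def __init__(self, fitness: FitnessVector, mutation: MutationMatrix, scaling_mode: str, landscape_id: int = 0):
        self.fitness = fitness
        self.mutation = mutation
        self.scaling_mode = scaling_mode
        self.landscape_id = landscape_id
        self._Q: Optional[RateMatrix] = None
        self._pi: Optional[StationaryDistribution] = None

    def _build(self) -> None:
        self._Q, self._pi = build_rate_system(self.fitness, self.mutation, self.scaling_mode)

    @property
    def Q(self) -> RateMatrix:
        if self._Q is None:
            self._build()
        return self._Q

    @property
    def pi(self) -> StationaryDistribution:
        if self._pi is None:
            self._build()
        return self._pi

    def changed_to(self, fitness: FitnessVector, landscape_id: int) -> "LandscapeContext":
        return LandscapeContext(fitness, self.mutation, self.scaling_mode, landscape_id)


@dataclass
class SequenceState:
    """Alleles (as indices) at each position governed by one landscape."""

    alleles: np.ndarray
    landscape_id: int = 0

    def copy(self) -> "SequenceState":
        return SequenceState(self.alleles.copy(), self.landscape_id)


@dataclass(frozen=True)
class Event:
    """One realized event on a branch (time relative to the branch start)."""

    kind: str  # "substitution" | "landscape_change" | "deterministic_change"
    time: float
    position: Optional[int] = None
    from_allele: Optional[int] = None
    to_allele: Optional[int] = None
    landscape_id: Optional[int] = None

    def __post_init__(self):
        if self.kind == "substitution" and self.from_allele == self.to_allele:
            raise ValueError("substitution must change the allele")


@dataclass
class SimulationResult:
    """Sequences at every node plus the ordered landscape-change log.

    ``n_changes`` counts every realized landscape change even when the
    per-event log was not recorded.
    """

    node_sequences: dict[str, str]
    change_log: list[ChangeRecord]
    n_changes: int = 0
    seed: Optional[int] = None
    alphabet: Optional[Alphabet] = None


def sample_root_sequence(
    pi: StationaryDistribution,
    length: int,
    rng: np.random.Generator,
    user_sequence: Optional[str] = None,
) -> SequenceState:
    """Root state: i.i.d. draws from ``pi``, or the user's sequence verbatim.

    A user-supplied root is validated against the alphabet and length only;
    how plausible it is under ``pi`` is the user's own affair.
    """
    alphabet = pi.alphabet
    if user_sequence is not None:
        if len(user_sequence) != length:
            raise ValueError(
                f"root sequence has length {len(user_sequence)}, expected {length}"
            )
        return SequenceState(alphabet.encode(user_sequence))
    if length == 0:
        return SequenceState(np.empty(0, dtype=np.intp))
    cum = np.cumsum(pi.probs)
    draws = rng.random(length)
    return SequenceState(np.searchsorted(cum, draws).astype(np.intp))


def draw_next_event(
    state: SequenceState,
    Q: RateMatrix,
    lam: float,
    time_to_next_deterministic: float,
    time_to_branch_end: float,
    rng: np.random.Generator,
) -> Optional[Event]:
    """One step of the Gillespie race on a branch.

    Returns the next event, a ``deterministic_change`` if the exponential
    waiting time overshoots the scheduled change, or ``None`` when the
    branch elapses first.  Times are relative to "now".
    """
    if time_to_branch_end < 0 or time_to_next_deterministic < 0:
        raise ValueError("remaining times must be nonnegative")
    exit_rates = Q.exit_rates
    per_pos = exit_rates[state.alleles]
    total_sub = float(per_pos.sum())
    R = total_sub + lam
    horizon = min(time_to_next_deterministic, time_to_branch_end)
    wait = rng.exponential(1.0 / R) if R > 0 else np.inf
    if wait >= horizon:
        if time_to_next_deterministic <= time_to_branch_end:
            return Event("deterministic_change", time_to_next_deterministic)
        return None
    if lam > 0 and rng.random() * R >= total_sub:
        return Event("landscape_change", wait)
    # substitution: position proportional to exit rate, allele proportional to q_ij
    if state.alleles.size == 1:
        pos = 0
    else:
        cum = np.cumsum(per_pos)
        pos = int(np.searchsorted(cum, rng.random() * cum[-1]))
        pos = min(pos, state.alleles.size - 1)
    a = int(state.alleles[pos])
    row = Q.rates[a].copy()
    row[a] = 0.0
    cum = np.cumsum(row)
    b = int(np.searchsorted(cum, rng.random() * cum[-1]))
    b = min(b, Q.alphabet.size - 1)
    return Event("substitution", wait, position=pos, from_allele=a, to_allele=b)


class SharedChain:
    """The single landscape chain used by shared periodic ticks.

    Tick ``k``'s vector is derived from tick ``k-1``'s (the common epoch
    landscape), once, regardless of how many lineages cross the tick; all of
    them receive the identical vector.
    """

    def __init__(self, initial: FitnessVector, rule: LandscapeRule, rng: np.random.Generator):
        self._chain: list[FitnessVector] = [initial]
        self._rule = rule
        self._rng = rng

    def vector_at(self, tick: int) -> FitnessVector:
        while len(self._chain) <= tick:
            k = len(self._chain)
            self._chain.append(
                derive_new_landscape(self._rule, self._chain[-1], None, k - 1, self._rng)
            )
        return self._chain[tick]


def _effective_lambda(regime: Regime, ctx: LandscapeContext, scaling_mode: str) -> float:
    if not isinstance(regime, StochasticRegime):
        return 0.0
    lam = regime.rate
    if regime.scale_with_q and scaling_mode == "raw":
        raw = build_raw_rate_matrix(ctx.fitness, ctx.mutation)
        pi = stationary_distribution(ctx.fitness, ctx.mutation, raw)
        lam *= expected_substitution_rate(raw, pi)
    return lam


def simulate_branch(
    state: SequenceState,
    ctx: LandscapeContext,
    branch_length: float,
    settings: InstanceSettings,
    rng: np.random.Generator,
    det_events: Sequence[ScheduledEvent] = (),
    shared_chain: Optional[SharedChain] = None,
    branch_name: str = "",
    t_parent: float = 0.0,
    change_log: Optional[list] = None,
    change_counter: Optional[list] = None,
    events_out: Optional[list] = None,
) -> tuple[SequenceState, LandscapeContext]:
    """Evolve ``state`` along one branch, returning the end state and context.

    ``det_events`` are the deterministic changes scheduled on this branch
    (offsets from the branch start, sorted).  ``change_counter`` is a 1-item
    list holding the running landscape-change count, shared across branches
    so landscape ids and explicit-vector indices are global to the run.
    """
    state = state.copy()
    counter = change_counter if change_counter is not None else [0]
    det = list(det_events)
    det_idx = 0
    t = 0.0
    lam = _effective_lambda(settings.regime, ctx, settings.scaling_mode)

    def apply_change(offset: float, scheduled: Optional[ScheduledEvent]) -> None:
        nonlocal ctx
        idx = counter[0]
        if scheduled is not None and scheduled.new_fitness is not None:
            new_vec = scheduled.new_fitness
        elif (
            shared_chain is not None
            and scheduled is not None
            and scheduled.tick_index is not None
        ):
            new_vec = shared_chain.vector_at(scheduled.tick_index)
        else:
            allele = int(state.alleles[0]) if state.alleles.size == 1 else None
            new_vec = derive_new_landscape(settings.rule, ctx.fitness, allele, idx, rng)
        counter[0] = idx + 1
        ctx = ctx.changed_to(new_vec, idx + 1)
        state.landscape_id = ctx.landscape_id
        if change_log is not None:
            change_log.append(
                ChangeRecord(ctx.landscape_id, branch_name, t_parent + offset, offset, new_vec)
            )

    # events snapped onto the parent node apply before anything happens here
    while det_idx < len(det) and det[det_idx].offset <= 0.0:
        apply_change(0.0, det[det_idx])
        det_idx += 1

    exit_rates = ctx.Q.exit_rates if (state.alleles.size and branch_length > 0) else None
    while True:
        next_det = det[det_idx].offset if det_idx < len(det) else np.inf
        total_sub = float(exit_rates[state.alleles].sum()) if exit_rates is not None else 0.0
        R = total_sub + lam
        wait = rng.exponential(1.0 / R) if R > 0 else np.inf
        horizon = min(next_det, branch_length)
        if t + wait >= horizon:
            if next_det <= branch_length:
                t = next_det
                apply_change(t, det[det_idx])
                det_idx += 1
                exit_rates = ctx.Q.exit_rates if state.alleles.size else None
                lam = _effective_lambda(settings.regime, ctx, settings.scaling_mode)
                continue
            break
        t += wait
        if lam > 0 and rng.random() * R >= total_sub:
            apply_change(t, None)
            exit_rates = ctx.Q.exit_rates if state.alleles.size else None
            lam = _effective_lambda(settings.regime, ctx, settings.scaling_mode)
            if events_out is not None:
                events_out.append(Event("landscape_change", t, landscape_id=ctx.landscape_id))
            continue
        # substitution
        per_pos = exit_rates[state.alleles]
        if state.alleles.size == 1:
            pos = 0
        else:
            cum = np.cumsum(per_pos)
            pos = min(int(np.searchsorted(cum, rng.random() * cum[-1])), state.alleles.size - 1)
        a = int(state.alleles[pos])
        row = ctx.Q.rates[a].copy()
        row[a] = 0.0
        cum = np.cumsum(row)
        b = min(int(np.searchsorted(cum, rng.random() * cum[-1])), len(row) - 1)
        state.alleles[pos] = b
        if events_out is not None:
            events_out.append(Event("substitution", t, position=pos, from_allele=a, to_allele=b))
    return state, ctx


def run_simulation(
    tree: Tree,
    settings: InstanceSettings,
    rng: np.random.Generator,
    seed: Optional[int] = None,
) -> SimulationResult:
    """Simulate one landscape instance over the whole tree.

    The initial landscape is instantiated (sampled or fixed), the root
    sequence drawn from its stationary distribution unless supplied, and
    every branch is then simulated in breadth-first order so parents finish
    before their children.  Returns the sequence at every node and the
    time-ordered change log.
    """
    alphabet = settings.alphabet
    F0 = sample_fitness_vector(settings.rule, alphabet, rng)
    ctx0 = LandscapeContext(F0, settings.mutation_matrix, settings.scaling_mode)
    root_state = sample_root_sequence(ctx0.pi, settings.length, rng, settings.root_sequence)
    schedule = build_change_schedule(tree, settings.regime)

    shared_chain = None
    if isinstance(settings.regime, PeriodicRegime) and settings.regime.sharing == "shared":
        shared_chain = SharedChain(F0, settings.rule, rng)

    change_log: list[ChangeRecord] = [] if settings.record_changes else None
    counter = [0]
    node_sequences: dict[str, str] = {}
    states: dict[str, tuple[SequenceState, LandscapeContext]] = {
        tree.root.name: (root_state, ctx0)
    }
    node_sequences[tree.root.name] = alphabet.decode(root_state.alleles)
    for node in tree.bfs():
        parent_state, parent_ctx = states[node.name]
        for child in node.children:
            end_state, end_ctx = simulate_branch(
                parent_state,
                parent_ctx,
                child.branch_length,
                settings,
                rng,
                det_events=schedule.events_for_branch(child.name),
                shared_chain=shared_chain,
                branch_name=child.name,
                t_parent=tree.global_time[node.name],
                change_log=change_log,
                change_counter=counter,
            )
            states[child.name] = (end_state, end_ctx)
            node_sequences[child.name] = alphabet.decode(end_state.alleles)
        del states[node.name]
    log = change_log if change_log is not None else []
    log.sort(key=lambda rec: (rec.global_time, rec.branch))
    return SimulationResult(node_sequences, log, n_changes=counter[0], seed=seed, alphabet=alphabet)
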