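"""Discrete-event engine: scheduling, predicates, the state transition.

One transition processes every event due at the current tick and advances
model time by exactly one.  Events are owner-bound, guarded by predicate
trees over local factor concentrations, and carry an integer priority
(lower executes earlier among interdependent events).  Events whose
footprints (owner plus touched coordinates) are disjoint commute and run in
queue order; interdependent events run afterwards in priority order with a
PRNG tie-break, so conflicts (e.g. two movers claiming one coordinate)
resolve deterministically for a fixed seed.

Mechanism implementations live in :mod:`organoidsim.mechanisms`; they
register handlers in the dispatch tables below.
"""

from __future__ import annotations

import heapq
import json
import logging
from dataclasses import dataclass, field as dc_field
from typing import Callable

import numpy as np

from .space import Coord, Lattice, SpatialMark, neighborhood
from .signals import FactorField

logger = logging.getLogger("organoidsim")

# Default execution priorities per mechanism family: destructive events
# resolve before constructive ones so a dying cell never divides or moves
# in the same transition.
PRIORITY_DEATH = 0
PRIORITY_DIVISION = 1
PRIORITY_DIFFERENTIATION = 2
PRIORITY_LOCOMOTION = 3
PRIORITY_GROWTH = 4
PRIORITY_SECRETION = 5

DEFAULT_PRIORITIES = {
    "apoptose": PRIORITY_DEATH,
    "necrose": PRIORITY_DEATH,
    "divide_symmetric": PRIORITY_DIVISION,
    "divide_asymmetric": PRIORITY_DIVISION,
    "_divide_complete": PRIORITY_DIVISION,
    "differentiate": PRIORITY_DIFFERENTIATION,
    "move": PRIORITY_LOCOMOTION,
    "grow_axon": PRIORITY_GROWTH,
    "form_terminal": PRIORITY_GROWTH,
    "form_spine": PRIORITY_GROWTH,
    "form_synapse": PRIORITY_GROWTH,
    "sprout_neurites": PRIORITY_GROWTH,
    "transduce": PRIORITY_SECRETION,
    "secrete_factor": PRIORITY_SECRETION,
}

#: mechanism name -> handler(state, event, pathway) -> (outcome, details)
MECHANISM_HANDLERS: dict[str, Callable] = {}
#: mechanism name -> footprint(state, event) -> set[Coord]
MECHANISM_FOOTPRINTS: dict[str, Callable] = {}

#: Outcomes recorded when log_level == "summary" (the default): every
#: state-changing execution plus hard skips; routine retries and secretions
#: are elided to keep logs compact.
NOTABLE_OUTCOMES = frozenset(
    {
        "divided",
        "differentiated",
        "apoptosed",
        "necrosed",
        "moved",
        "sprouted",
        "terminal-formed",
        "spine-formed",
        "synapse-formed",
        "activated",
        "placed",
    }
)


class ConfigurationError(ValueError):
    """Raised for invalid configurations or guard references."""


# ---------------------------------------------------------------------------
# Predicates
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Condition:
    """Leaf condition: compare a factor concentration against thresholds.

    ``radius`` 0 reads the cell's own coordinate; radius r > 0 takes the max
    over the Chebyshev-r neighborhood (presence within reach).  Comparisons
    are inclusive: a concentration exactly at the threshold satisfies both
    ``ge`` and ``le``.
    """

    factor: str
    op: str  # "ge" | "le" | "between"
    threshold: float
    threshold_hi: float | None = None
    radius: int = 0

    def __post_init__(self):
        if self.op not in ("ge", "le", "between"):
            raise ConfigurationError(f"unknown comparison op {self.op!r}")
        if self.op == "between" and self.threshold_hi is None:
            raise ConfigurationError("'between' condition needs threshold_hi")


@dataclass(frozen=True)
class PredicateTree:
    """AND/OR tree over leaf conditions; an empty tree is vacuously true."""

    kind: str = "and"  # "and" | "or" | "leaf"
    children: tuple["PredicateTree", ...] = ()
    leaf: Condition | None = None

    def __post_init__(self):
        if self.kind not in ("and", "or", "leaf"):
            raise ConfigurationError(f"unknown predicate node kind {self.kind!r}")
        if self.kind == "leaf" and self.leaf is None:
            raise ConfigurationError("leaf predicate node needs a condition")

    def factors(self) -> set[str]:
        if self.kind == "leaf":
            return {self.leaf.factor}
        out: set[str] = set()
        for ch in self.children:
            out |= ch.factors()
        return out


_warned_empty_fields: set[tuple[str, str]] = set()


def evaluate_predicate(tree: PredicateTree | None, state: "ModelState",
                       at: Coord) -> bool:
    """Pure evaluation of a predicate tree at a coordinate."""
    if tree is None:
        return True
    if tree.kind == "leaf":
        cond = tree.leaf
        field = state.fields.get(cond.factor)
        if field is None:
            raise ConfigurationError(
                f"guard references undeclared factor {cond.factor!r}"
            )
        if field._lo is None:
            key = (cond.factor, "empty")
            if key not in _warned_empty_fields:
                _warned_empty_fields.add(key)
                logger.warning(
                    "guard references factor %r whose field is empty", cond.factor
                )
        if cond.radius > 0:
            value = field.max_in_ball(at, cond.radius)
        else:
            value = field.concentration_at(at)
        if cond.op == "ge":
            return value >= cond.threshold
        if cond.op == "le":
            return value <= cond.threshold
        return cond.threshold <= value <= cond.threshold_hi
    if tree.kind == "and":
        return all(evaluate_predicate(ch, state, at) for ch in tree.children)
    return any(evaluate_predicate(ch, state, at) for ch in tree.children)


# ---------------------------------------------------------------------------
# Events and model state
# ---------------------------------------------------------------------------


@dataclass
class Event:
    """Owner-bound, prioritized, guarded unit of work."""

    owner_id: int
    pathway_id: str
    due_tick: int
    priority: int
    mechanism: str
    guard: PredicateTree | None = None
    params: dict = dc_field(default_factory=dict)
    at: Coord | None = None  # coordinate override (e.g. axon terminals)
    internal: bool = False  # engine-internal; immune to pause/deactivation
    seq: int = -1  # insertion index, set by schedule()


class ModelState:
    """Full simulation state at a tick: lattice, objects, fields, queue."""

    def __init__(self, lattice: Lattice, rng: np.random.Generator, biology,
                 model_config=None):
        self.tick = 0
        self.lattice = lattice
        self.rng = rng
        self.biology = biology  # BiologicalConfig (pathways, cell types)
        self.model_config = model_config
        self.objects: dict[int, object] = {}  # id -> Cell | SpatialMark
        self.fields: dict[str, FactorField] = {}
        self.queue: list[tuple[int, int, int, Event]] = []
        self.paused_owners: set[int] = set()
        self.frozen: dict[int, list[Event]] = {}
        self.connection_log: list = []  # ConnectionRecord
        self.out_history: dict[int, list[int]] = {}
        self.records: list[str] = []  # serialized event-log lines
        self.log_level = "summary"  # "none" | "summary" | "full"
        self.census: dict[str, int] = {}  # live count per cell type
        self.census_history: list[tuple[int, dict[str, int]]] = []
        self.birth_count = 0
        self.death_count = 0
        self._next_id = 0
        self._next_seq = 0

    # -- identifiers -----------------------------------------------------

    def new_id(self) -> int:
        self._next_id += 1
        return self._next_id

    def _seq(self) -> int:
        self._next_seq += 1
        return self._next_seq

    # -- object helpers --------------------------------------------------

    def alive(self, owner_id: int) -> bool:
        obj = self.objects.get(owner_id)
        if obj is None:
            return False
        status = getattr(obj, "status", "active")
        return status != "removed"

    def log(self, event: Event, outcome: str, details: dict | None = None):
        if self.log_level == "none":
            return
        if self.log_level == "summary" and outcome not in NOTABLE_OUTCOMES:
            return
        owner = self.objects.get(event.owner_id)
        coord = event.at
        if coord is None and owner is not None:
            coord = getattr(owner, "position", None) or getattr(
                owner, "coordinate", None
            )
        rec = {
            "tick": self.tick,
            "owner_id": event.owner_id,
            "owner_type": getattr(owner, "type", None)
            or type(owner).__name__ if owner is not None else None,
            "pathway": event.pathway_id,
            "outcome": outcome,
            "coordinate": list(coord) if coord is not None else None,
            "details": details or {},
        }
        self.records.append(json.dumps(rec, separators=(",", ":")))


# ---------------------------------------------------------------------------
# Scheduling
# ---------------------------------------------------------------------------


def schedule(state: ModelState, event: Event) -> None:
    """Insert an event into the queue, ordered by (due, priority, insertion)."""
    if event.due_tick < state.tick:
        raise ValueError(
            f"event due at tick {event.due_tick} scheduled at tick {state.tick}"
        )
    if not state.alive(event.owner_id):
        raise ConfigurationError(
            f"cannot schedule event for unknown/removed owner {event.owner_id}"
        )
    event.seq = state._seq()
    heapq.heappush(state.queue, (event.due_tick, event.priority, event.seq, event))


def schedule_pathway(state: ModelState, owner_id: int, pathway_id: str,
                     due_tick: int, at: Coord | None = None,
                     params: dict | None = None) -> None:
    """Schedule the next occurrence of a configured signaling pathway."""
    pw = state.biology.pathways[pathway_id]
    ev = Event(
        owner_id=owner_id,
        pathway_id=pathway_id,
        due_tick=due_tick,
        priority=pw.priority,
        mechanism=pw.mechanism,
        guard=pw.guard,
        params=params if params is not None else pw.params,
        at=at,
    )
    schedule(state, ev)


# ---------------------------------------------------------------------------
# Pathway interruption semantics
# ---------------------------------------------------------------------------


def interrupt_pathways(state: ModelState, owner_id: int, mode: str) -> None:
    """Pause, disrupt, or terminate all of an owner's pending events.

    pause:     queued events are retained but frozen until release.
    disrupt:   queued events are removed; the caller resets the pathway set.
    terminate: queued events are removed permanently (owner is being
               removed; nothing can be scheduled for it again).
    """
    if mode == "pause":
        state.paused_owners.add(owner_id)
        return
    if mode not in ("disrupt", "terminate"):
        raise ValueError(f"unknown interrupt mode {mode!r}")
    state.queue = [
        entry
        for entry in state.queue
        if entry[3].owner_id != owner_id or entry[3].internal
    ]
    heapq.heapify(state.queue)
    state.frozen.pop(owner_id, None)
    state.paused_owners.discard(owner_id)


def release_pathways(state: ModelState, owner_id: int) -> None:
    """End a pause: frozen events re-enter the queue in their frozen order."""
    state.paused_owners.discard(owner_id)
    for ev in state.frozen.pop(owner_id, []):
        ev.due_tick = max(ev.due_tick, state.tick)
        event = ev
        event.seq = state._seq()
        heapq.heappush(state.queue, (event.due_tick, event.priority,
                                     event.seq, event))


# ---------------------------------------------------------------------------
# The state transition
# ---------------------------------------------------------------------------


def _footprint(state: ModelState, ev: Event) -> frozenset[Coord]:
    fn = MECHANISM_FOOTPRINTS.get(ev.mechanism)
    if fn is not None:
        return fn(state, ev)
    owner = state.objects.get(ev.owner_id)
    coord = ev.at or getattr(owner, "position", None) or getattr(
        owner, "coordinate", None
    )
    return frozenset({coord}) if coord is not None else frozenset()


def _gate_passes(state: ModelState, pathway, at: Coord) -> bool:
    gate = pathway.gate
    if gate is None:
        return True
    p = gate if isinstance(gate, (int, float)) else gate(state, at)
    if p >= 1.0:
        return True
    if p <= 0.0:
        return False
    return float(state.rng.random()) < p


def step(state: ModelState) -> None:
    """Process every event due at the current tick; advance time by one.

    Independent events execute first in queue order; interdependent events
    (overlapping footprints or shared owner) follow in priority order with a
    PRNG tie-break drawn in canonical (owner, pathway, insertion) order.
    After event processing every factor field spreads and degrades once, and
    spatial marks emit their factors.
    """
    now = state.tick
    due: list[Event] = []
    while state.queue and state.queue[0][0] <= now:
        entry = heapq.heappop(state.queue)
        if entry[0] < now:  # pragma: no cover - guarded by schedule()
            raise RuntimeError("event queue contains a past-due event")
        due.append(entry[3])

    if due:
        owner_counts: dict[int, int] = {}
        coord_counts: dict[Coord, int] = {}
        feet = []
        for ev in due:
            fp = _footprint(state, ev)
            feet.append(fp)
            owner_counts[ev.owner_id] = owner_counts.get(ev.owner_id, 0) + 1
            for c in fp:
                coord_counts[c] = coord_counts.get(c, 0) + 1
        independent, dependent = [], []
        for ev, fp in zip(due, feet):
            if owner_counts[ev.owner_id] == 1 and all(
                coord_counts[c] == 1 for c in fp
            ):
                independent.append(ev)
            else:
                dependent.append(ev)
        # canonical draw order guarantees replay determinism; one key per
        # owner, so a single owner's equal-priority events keep their
        # insertion order while cross-owner conflicts break randomly
        dependent.sort(key=lambda e: (e.owner_id, e.pathway_id, e.seq))
        tiebreak: dict[int, float] = {}
        for e in dependent:
            if e.owner_id not in tiebreak:
                tiebreak[e.owner_id] = float(state.rng.random())
        dependent.sort(
            key=lambda e: (e.priority, tiebreak[e.owner_id], e.seq))
        for ev in independent + dependent:
            _execute(state, ev)

    # field phase: marks emit, then every active field spreads and decays
    cadence = getattr(state.model_config, "diffusion_every", 1) or 1
    for obj in state.objects.values():
        if isinstance(obj, SpatialMark):
            for fname in obj.emitted_factors:
                state.fields[fname].secrete(obj.coordinate)
    if now % cadence == 0:
        for field in state.fields.values():
            field.diffuse_step()
            field.degrade_step()

    state.tick = now + 1
    state.census_history.append((state.tick, dict(state.census)))


def _execute(state: ModelState, ev: Event) -> None:
    owner = state.objects.get(ev.owner_id)
    if owner is None or not state.alive(ev.owner_id):
        state.log(ev, "owner-removed")
        return
    if ev.owner_id in state.paused_owners and not ev.internal:
        state.frozen.setdefault(ev.owner_id, []).append(ev)
        return
    pw = state.biology.pathways.get(ev.pathway_id)
    if pw is None:
        raise ConfigurationError(f"event references unknown pathway {ev.pathway_id!r}")
    active = getattr(owner, "active_pathways", None)
    if active is not None and not ev.internal and ev.pathway_id not in active:
        state.log(ev, "pathway-inactive")
        return
    at = ev.at
    if at is None:
        at = getattr(owner, "position", None) or getattr(owner, "coordinate", None)
    outcome, details = "executed", {}
    if ev.guard is not None and not evaluate_predicate(ev.guard, state, at):
        outcome = "guard-failed"
    elif not _gate_passes(state, pw, at):
        outcome = "gate-closed"
    else:
        handler = MECHANISM_HANDLERS.get(ev.mechanism)
        if handler is None:
            raise ConfigurationError(f"unknown mechanism {ev.mechanism!r}")
        outcome, details = handler(state, ev, pw)
    state.log(ev, outcome, details)
    # cyclic pathways reschedule themselves unless consumed or dropped
    if ev.internal or pw.one_shot and outcome not in ("guard-failed", "gate-closed"):
        return
    if outcome == "guard-failed" and pw.on_guard_fail == "drop":
        return
    if outcome in ("consumed", "terminal-formed"):
        return
    if state.alive(ev.owner_id):
        active = getattr(state.objects[ev.owner_id], "active_pathways", None)
        if active is None or ev.pathway_id in active:
            schedule_pathway(
                state, ev.owner_id, ev.pathway_id, state.tick + pw.period,
                at=ev.at, params=ev.params,
            )


def run(state: ModelState, ticks: int) -> ModelState:
    """Advance the model by ``ticks`` transitions."""
    for _ in range(ticks):
        step(state)
    return state
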