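"""Built-in mechanism set: the only behaviors attachable to cells.

A configuration never adds code; it parametrizes the mechanisms here into
signaling pathways (division, differentiation, death, locomotion, secretion,
transduction, axon growth and the synaptogenesis handshake).  Each handler
receives the model state, the triggering event and its pathway, mutates the
state, and returns an ``(outcome, details)`` pair for the event log.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass, field as dc_field

from .space import (
    Coord,
    Lattice,
    chebyshev_distance,
    neighborhood,
    vacant_neighbors,
)
from .signals import GradientRule, pick_gradient_coordinate
from .events import (
    ConfigurationError,
    Event,
    MECHANISM_FOOTPRINTS,
    MECHANISM_HANDLERS,
    ModelState,
    PRIORITY_DIVISION,
    interrupt_pathways,
    release_pathways,
    schedule,
    schedule_pathway,
)

# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CellType:
    """Declared cell type: factor interfaces, pathway set, potency rank.

    ``potency`` orders the lineage: asymmetric division and differentiation
    may only produce types of strictly lower potency.
    """

    name: str
    potency: int
    receives: tuple[str, ...] = ()
    emits: tuple[str, ...] = ()
    pathways: tuple[str, ...] = ()
    initial_pathways: tuple[str, ...] = ()


@dataclass(frozen=True)
class SignalingPathway:
    """A parametrized mechanism: the unit of configurable cell behavior.

    Pathways fire cyclically with the given period; the guard is evaluated
    at fire time and on failure the pathway retries next period (or drops).
    ``gate`` is a constant probability or a callable ``(state, at) -> p``.
    """

    id: str
    mechanism: str
    period: int = 1
    priority: int = 5
    guard: object = None
    gate: object = None
    on_guard_fail: str = "retry"  # or "drop"
    one_shot: bool = False
    params: dict = dc_field(default_factory=dict)

    def __post_init__(self):
        if self.period < 1:
            raise ConfigurationError(f"pathway {self.id}: period must be >= 1")
        if self.on_guard_fail not in ("retry", "drop"):
            raise ConfigurationError(
                f"pathway {self.id}: unknown guard-failure policy"
            )
        if isinstance(self.gate, (int, float)) and not 0.0 <= self.gate <= 1.0:
            raise ConfigurationError(
                f"pathway {self.id}: gate probability outside [0,1]"
            )


@dataclass
class Neurite:
    """An axon or dendrite: a Chebyshev-1 chain anchored at the soma."""

    owner_id: int
    kind: str  # "axon" | "dendrite"
    path: list[Coord]
    cone: str = "growing-forward"
    # growing-forward | reversing | terminal-pending | terminal-formed
    terminals: list[Coord] = dc_field(default_factory=list)

    @property
    def length(self) -> int:
        return len(self.path) - 1

    @property
    def tip(self) -> Coord:
        return self.path[-1]


@dataclass
class Cell:
    """A cell body occupying one lattice coordinate."""

    id: int
    type: str
    position: Coord
    born_tick: int = 0
    status: str = "active"
    # active | paused(dividing) | paused(differentiating) | removed
    removed_tick: int | None = None
    axon: Neurite | None = None
    dendrite: Neurite | None = None
    spine_formed: bool = False
    active_pathways: set[str] = dc_field(default_factory=set)


@dataclass(frozen=True)
class ConnectionRecord:
    """A formed synapse, with its repetition class.

    The class is judged against the presynaptic cell's ordered history:
    same partner as the immediately previous connection -> sequentially
    repeated; same partner seen earlier -> non-sequentially repeated;
    otherwise single.
    """

    pre_id: int
    post_id: int
    formed_tick: int
    category: str  # single | sequentially-repeated | non-sequentially-repeated
    pre_type: str = ""
    post_type: str = ""


# ---------------------------------------------------------------------------
# Census bookkeeping (used by analysis conservation checks)
# ---------------------------------------------------------------------------


def _census_add(state: ModelState, type_name: str, n: int = 1) -> None:
    state.census[type_name] = state.census.get(type_name, 0) + n


def register_birth(state: ModelState, cell: Cell) -> None:
    state.objects[cell.id] = cell
    state.lattice.place(cell.id, cell.position)
    _census_add(state, cell.type, 1)
    state.birth_count += 1


def launch_initial_pathways(state: ModelState, cell: Cell, due: int) -> None:
    """(Re)start a cell's initial pathway set.

    Each pathway's first firing happens one full period after launch (so a
    freshly divided cell completes a cell cycle before dividing again);
    period-1 pathways fire immediately at the launch tick.
    """
    ct = state.biology.cell_types[cell.type]
    cell.active_pathways = set(ct.initial_pathways)
    for pid in ct.initial_pathways:
        pw = state.biology.pathways[pid]
        schedule_pathway(state, cell.id, pid, due + pw.period - 1)


# ---------------------------------------------------------------------------
# A* locomotion on the lattice
# ---------------------------------------------------------------------------


def a_star(lattice: Lattice, start: Coord, goal: Coord,
           ignore_occupancy: bool = False) -> list[Coord] | None:
    """Shortest vacant-coordinate route under the Chebyshev metric.

    Unit steps cost 1 regardless of direction (diagonal moves included), so
    the Chebyshev distance is an admissible, consistent heuristic.  Returns
    the coordinate sequence from start to goal, or None when unreachable.
    Ties break lexicographically for replay determinism.
    """
    if start == goal:
        return [start]
    frontier: list[tuple[int, int, Coord]] = [(chebyshev_distance(start, goal), 0,
                                               start)]
    came: dict[Coord, Coord] = {}
    gscore: dict[Coord, int] = {start: 0}
    while frontier:
        _, g, cur = heapq.heappop(frontier)
        if cur == goal:
            path = [cur]
            while cur in came:
                cur = came[cur]
                path.append(cur)
            path.reverse()
            return path
        if g > gscore.get(cur, g):
            continue
        for nxt in neighborhood(cur, 1, lattice):
            if nxt != goal and not ignore_occupancy and not lattice.is_vacant(nxt):
                continue
            ng = g + 1
            if ng < gscore.get(nxt, 1 << 30):
                gscore[nxt] = ng
                came[nxt] = cur
                heapq.heappush(
                    frontier, (ng + chebyshev_distance(nxt, goal), ng, nxt)
                )
    return None


# ---------------------------------------------------------------------------
# Handlers
# ---------------------------------------------------------------------------


def _cell(state: ModelState, ev: Event) -> Cell:
    return state.objects[ev.owner_id]


def handle_secrete(state, ev, pw):
    factor = ev.params.get("factor") or pw.params["factor"]
    at = ev.at or _cell(state, ev).position
    state.fields[factor].secrete(at, ev.params.get("power"))
    return "secreted", {}


def handle_transduce(state, ev, pw):
    """Switch pathways on/off for the owner once the guard has passed."""
    cell = _cell(state, ev)
    activated = []
    for pid in ev.params.get("activate", ()):
        if pid not in cell.active_pathways:
            cell.active_pathways.add(pid)
            schedule_pathway(state, cell.id, pid, state.tick + 1)
            activated.append(pid)
    for pid in ev.params.get("deactivate", ()):
        cell.active_pathways.discard(pid)
    if ev.params.get("deactivate_self"):
        cell.active_pathways.discard(ev.pathway_id)
    if not activated and not ev.params.get("deactivate"):
        return "executed", {}
    return "activated", {"on": activated, "off": list(ev.params.get("deactivate", ()))}


def handle_move(state, ev, pw):
    """One unit step of locomotion, chemotactic or A*-routed."""
    cell = _cell(state, ev)
    target = ev.params.get("target")
    if target is not None:
        target = tuple(target)
        if cell.position == target:
            return "arrived", {}
        path = a_star(state.lattice, cell.position, target)
        if path is None or len(path) < 2:
            return "blocked", {}
        nxt = path[1]
        if not state.lattice.is_vacant(nxt):
            return "blocked", {}
    else:
        rule = GradientRule(
            factor=ev.params["factor"],
            direction=ev.params.get("direction", "gradient"),
            min_concentration=ev.params.get("min_concentration", 0.0),
        )
        nxt = pick_gradient_coordinate(state, cell.position, rule)
        if nxt is None:
            return "no-step", {}
    state.lattice.vacate(cell.id, cell.position)
    state.lattice.place(cell.id, nxt)
    prev, cell.position = cell.position, nxt
    return "moved", {"from": list(prev)}


def handle_divide(state, ev, pw):
    """Begin mitosis: pause other pathways, schedule completion.

    Division is deferred (retried next cycle) when the cell is fully
    enclosed, so an enclosed stem cell keeps its other pathways running.
    """
    cell = _cell(state, ev)
    mode = "asymmetric" if ev.mechanism == "divide_asymmetric" else "symmetric"
    daughter_type = cell.type if mode == "symmetric" else ev.params["daughter"]
    parent_ct = state.biology.cell_types[cell.type]
    daughter_ct = state.biology.cell_types[daughter_type]
    if mode == "asymmetric" and daughter_ct.potency >= parent_ct.potency:
        raise ConfigurationError(
            f"asymmetric division {cell.type} -> {daughter_type} does not "
            "reduce potency"
        )
    if not vacant_neighbors(cell.position, state.lattice):
        return "deferred", {}
    cell.status = "paused(dividing)"
    interrupt_pathways(state, cell.id, "pause")
    done = Event(
        owner_id=cell.id,
        pathway_id=ev.pathway_id,
        due_tick=state.tick + int(ev.params.get("duration", 1)),
        priority=PRIORITY_DIVISION,
        mechanism="_divide_complete",
        params={"daughter_type": daughter_type},
        internal=True,
    )
    schedule(state, done)
    return "division-started", {"mode": mode}


def handle_divide_complete(state, ev, pw):
    cell = _cell(state, ev)
    spots = vacant_neighbors(cell.position, state.lattice)
    if not spots:
        # the placement found at trigger time was taken meanwhile: cancel
        # this attempt (rather than staying paused forever) and let the
        # cyclic division pathway retry from a live cell
        cell.status = "active"
        interrupt_pathways(state, cell.id, "disrupt")
        release_pathways(state, cell.id)
        launch_initial_pathways(state, cell, state.tick + 1)
        return "division-cancelled", {}
    spot = spots[int(state.rng.integers(len(spots)))]
    daughter = Cell(
        id=state.new_id(),
        type=ev.params["daughter_type"],
        position=spot,
        born_tick=state.tick,
    )
    register_birth(state, daughter)
    # both daughters relaunch the initial pathways of their types
    cell.status = "active"
    interrupt_pathways(state, cell.id, "disrupt")
    release_pathways(state, cell.id)
    launch_initial_pathways(state, cell, state.tick + 1)
    launch_initial_pathways(state, daughter, state.tick + 1)
    return "divided", {"daughter": daughter.id, "daughter_type": daughter.type,
                       "at": list(spot)}


def handle_differentiate(state, ev, pw):
    """Swap the cell's type once an eligible lineage target exists.

    Each target may carry a concentration interval on a factor; among the
    currently satisfied targets one is drawn with the configured weights
    (uniform over the overlap of intersecting intervals when unweighted).
    """
    cell = _cell(state, ev)
    eligible = []
    for tgt in ev.params["targets"]:
        factor = tgt.get("factor")
        if factor is not None:
            v = state.fields[factor].concentration_at(cell.position)
            lo = tgt.get("lo", 0.0)
            hi = tgt.get("hi")
            if v < lo or (hi is not None and v > hi):
                continue
        eligible.append(tgt)
    if not eligible:
        return "no-eligible-target", {}
    weights = [float(t.get("weight", 1.0)) for t in eligible]
    total = sum(weights)
    r = float(state.rng.random()) * total
    acc = 0.0
    chosen = eligible[-1]
    for tgt, w in zip(eligible, weights):
        acc += w
        if r < acc:
            chosen = tgt
            break
    new_type = chosen["type"]
    if (cell.type, new_type) not in state.biology.lineage_edges:
        raise ConfigurationError(
            f"differentiation {cell.type} -> {new_type} not in lineage"
        )
    old = cell.type
    interrupt_pathways(state, cell.id, "disrupt")
    _census_add(state, old, -1)
    cell.type = new_type
    _census_add(state, new_type, 1)
    cell.status = "active"
    launch_initial_pathways(state, cell, state.tick + 1)
    return "differentiated", {"from": old, "to": new_type}


def handle_kill(state, ev, pw):
    """Apoptosis or necrosis: irreversible removal of the cell.

    Apoptosis leaves the intercellular environment untouched; necrosis
    deposits the configured factor payload at the death coordinate.
    """
    cell = _cell(state, ev)
    if cell.status == "removed":
        return "already-removed", {}
    mode = "necrosed" if ev.mechanism == "necrose" else "apoptosed"
    if ev.mechanism == "necrose":
        for factor, amount in ev.params.get("payload", {}).items():
            state.fields[factor].secrete(cell.position, float(amount))
    interrupt_pathways(state, cell.id, "terminate")
    state.lattice.vacate(cell.id, cell.position)
    cell.status = "removed"
    cell.removed_tick = state.tick
    _census_add(state, cell.type, -1)
    state.death_count += 1
    return mode, {}


def handle_sprout(state, ev, pw):
    """Form the axon and/or dendritic tree and start their pathways."""
    cell = _cell(state, ev)
    details = {}
    if ev.params.get("axon", False) and cell.axon is None:
        cell.axon = Neurite(owner_id=cell.id, kind="axon", path=[cell.position])
        state.lattice.add_passthrough(cell.id, cell.position)
        details["axon"] = True
    if ev.params.get("dendrite", False) and cell.dendrite is None:
        cell.dendrite = Neurite(owner_id=cell.id, kind="dendrite",
                                path=[cell.position])
        details["dendrite"] = True
    for pid in ev.params.get("activate", ()):
        if pid not in cell.active_pathways:
            cell.active_pathways.add(pid)
            schedule_pathway(state, cell.id, pid, state.tick + 1)
    for pid in ev.params.get("deactivate", ()):
        cell.active_pathways.discard(pid)
    cell.active_pathways.discard(ev.pathway_id)
    return "sprouted", details


def handle_grow_axon(state, ev, pw):
    """One step of the growth-cone automaton.

    Forward search: no guidance signal in reach -> not growing; guidance
    present and the connection signal in reach -> arrest growth and form a
    terminal; otherwise extend the path one coordinate up the guidance
    gradient.  After a synapse the cone travels against the gradient until
    the guidance signal fades, then resumes the forward search.  Axons are
    sizeless: growth cones traverse coordinates occupied by cell bodies.
    """
    cell = _cell(state, ev)
    axon = cell.axon
    if axon is None:
        return "no-axon", {}
    if axon.cone in ("terminal-pending", "terminal-formed"):
        return "awaiting-synapse", {}
    p = ev.params
    agf = state.fields[p["agf"]]
    sense = int(p.get("sense_radius", 1))
    tip = axon.tip
    agf_level = agf.max_in_ball(tip, sense)
    agf_present = agf_level >= p["agf_threshold"]
    if axon.cone == "reversing":
        # hysteresis: stop retreating while still inside the presence
        # region, so the forward search immediately finds signal again
        release = p.get("agf_release", 2.0 * p["agf_threshold"])
        if agf_level < release:
            axon.cone = "growing-forward"
            return "search-resumed", {}
        rule = GradientRule(factor=p["agf"], direction="anti-gradient")
        nxt = pick_gradient_coordinate(
            state, tip, rule, ignore_occupancy=True,
            exclude=(axon.path[-2],) if len(axon.path) > 1 else (),
        )
        if nxt is None:
            return "no-candidate", {}
        axon.path.append(nxt)
        state.lattice.add_passthrough(cell.id, nxt)
        return "reversed", {}
    # growing-forward
    if not agf_present:
        return "no-signal", {}
    acf = state.fields[p["acf"]]
    if acf.max_in_ball(tip, sense) >= p["acf_threshold"]:
        axon.cone = "terminal-pending"
        done = Event(
            owner_id=cell.id, pathway_id=ev.pathway_id,
            due_tick=state.tick + 1, priority=pw.priority,
            mechanism="form_terminal", params=p, internal=True, at=tip,
        )
        schedule(state, done)
        return "growth-arrested", {}
    rule = GradientRule(factor=p["agf"], direction="gradient",
                        min_concentration=p.get("agf_floor", 0.0))
    nxt = pick_gradient_coordinate(
        state, tip, rule, ignore_occupancy=True,
        exclude=(axon.path[-2],) if len(axon.path) > 1 else (),
    )
    if nxt is None:
        return "no-candidate", {}
    axon.path.append(nxt)
    state.lattice.add_passthrough(cell.id, nxt)
    return "extended", {}


def handle_form_terminal(state, ev, pw):
    """Create an axonal terminal at the arrested cone and start its SPs."""
    cell = _cell(state, ev)
    axon = cell.axon
    tip = ev.at or axon.tip
    axon.terminals.append(tip)
    axon.cone = "terminal-formed"
    for pid in ev.params.get("terminal_pathways", ()):
        cell.active_pathways.add(pid)
        schedule_pathway(state, cell.id, pid, state.tick + 1, at=tip)
    return "terminal-formed", {"at": list(tip)}


def handle_form_spine(state, ev, pw):
    """Dendrite side of the handshake: spine forms once TFF is in reach."""
    cell = _cell(state, ev)
    if cell.dendrite is None:
        return "no-dendrite", {}
    cell.spine_formed = True
    for pid in ev.params.get("activate", ()):
        if pid not in cell.active_pathways:
            cell.active_pathways.add(pid)
            schedule_pathway(state, cell.id, pid, state.tick + 1)
    cell.active_pathways.discard(ev.pathway_id)
    return "spine-formed", {}


def classify_connection(history: list[int], partner_id: int) -> str:
    """Repetition class of a new outgoing connection given the ordered
    history of the presynaptic cell's previous partners."""
    if history and history[-1] == partner_id:
        return "sequentially-repeated"
    if partner_id in history:
        return "non-sequentially-repeated"
    return "single"


def handle_form_synapse(state, ev, pw):
    """Close the handshake: record the connection, release the cone.

    Fires only when the spine-completion signal is present at the terminal
    (the pathway guard).  The postsynaptic partner is drawn uniformly from
    spine-bearing neurons of the configured target type within reach of the
    terminal.
    """
    cell = _cell(state, ev)
    terminal = ev.at
    radius = int(ev.params.get("search_radius", 2))
    target_type = ev.params["target_type"]
    lattice = state.lattice
    candidates = []
    for c in neighborhood(terminal, radius, lattice):
        oid = lattice.occupant(c)
        if oid is None or oid == cell.id:
            continue
        other = state.objects[oid]
        if getattr(other, "type", None) == target_type and other.spine_formed:
            candidates.append(other)
    occ = lattice.occupant(terminal)
    if occ is not None and occ != cell.id:
        other = state.objects[occ]
        if getattr(other, "type", None) == target_type and other.spine_formed:
            candidates.append(other)
    if not candidates:
        return "no-partner", {}
    partner = candidates[int(state.rng.integers(len(candidates)))]
    hist = state.out_history.setdefault(cell.id, [])
    category = classify_connection(hist, partner.id)
    hist.append(partner.id)
    state.connection_log.append(
        ConnectionRecord(
            pre_id=cell.id, post_id=partner.id, formed_tick=state.tick,
            category=category, pre_type=cell.type, post_type=partner.type,
        )
    )
    # retire the terminal's pathways; the cone retreats against the gradient
    for pid in ev.params.get("terminal_pathways", ()):
        cell.active_pathways.discard(pid)
    cell.active_pathways.discard(ev.pathway_id)
    cell.axon.cone = "reversing"
    return "synapse-formed", {"post": partner.id, "category": category}


# ---------------------------------------------------------------------------
# Registration
# ---------------------------------------------------------------------------

MECHANISM_HANDLERS.update(
    {
        "secrete_factor": handle_secrete,
        "transduce": handle_transduce,
        "move": handle_move,
        "divide_symmetric": handle_divide,
        "divide_asymmetric": handle_divide,
        "_divide_complete": handle_divide_complete,
        "differentiate": handle_differentiate,
        "apoptose": handle_kill,
        "necrose": handle_kill,
        "sprout_neurites": handle_sprout,
        "grow_axon": handle_grow_axon,
        "form_terminal": handle_form_terminal,
        "form_spine": handle_form_spine,
        "form_synapse": handle_form_synapse,
    }
)


def _fp_local(state, ev):
    owner = state.objects.get(ev.owner_id)
    c = ev.at or getattr(owner, "position", None) or getattr(
        owner, "coordinate", None
    )
    return frozenset({c}) if c is not None else frozenset()


def _fp_neighborhood(state, ev):
    owner = state.objects.get(ev.owner_id)
    c = getattr(owner, "position", None)
    if c is None:
        return frozenset()
    return frozenset(neighborhood(c, 1, state.lattice)) | {c}


MECHANISM_FOOTPRINTS.update(
    {
        "move": _fp_neighborhood,
        "divide_symmetric": _fp_neighborhood,
        "divide_asymmetric": _fp_neighborhood,
        "_divide_complete": _fp_neighborhood,
        "secrete_factor": _fp_local,
        "transduce": _fp_local,
        "differentiate": _fp_local,
        "apoptose": _fp_local,
        "necrose": _fp_local,
        "sprout_neurites": _fp_local,
        "grow_axon": _fp_local,
        "form_terminal": _fp_local,
        "form_spine": _fp_local,
        "form_synapse": _fp_local,
    }
)
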