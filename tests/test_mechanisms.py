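"""Built-in mechanisms: gates, division, differentiation, death, axons."""

import collections

import numpy as np
import pytest

from conftest import add_cell, make_state, simple_pathway, simple_type
from organoidsim.events import (
    Condition,
    ConfigurationError,
    Event,
    PredicateTree,
    schedule,
    step,
)
from organoidsim.mechanisms import (
    a_star,
    classify_connection,
    handle_form_synapse,
    handle_grow_axon,
    handle_kill,
    Neurite,
)
from organoidsim.signals import FactorDef
from organoidsim.space import Lattice, chebyshev_distance, neighborhood


# ---------------------------------------------------------------------------
# Stochastic gates
# ---------------------------------------------------------------------------


def gated_secretion_state(gate):
    # non-diffusing, non-degrading factor: total mass counts firings exactly
    state = make_state(
        factors=[FactorDef(id="F", emission_radius=5, signal_power=1.0,
                           propagation_rate=0.0)],
        cell_types={"C": simple_type("C", pathways=("sec",))},
        pathways={"sec": simple_pathway("sec", "secrete_factor", period=1,
                                        gate=gate, params={"factor": "F"})},
    )
    cell = add_cell(state, "C", (4, 4, 4))
    cell.active_pathways = {"sec"}
    schedule(state, Event(owner_id=cell.id, pathway_id="sec", due_tick=0,
                          priority=5, mechanism="secrete_factor",
                          params={"factor": "F"}))
    return state


@pytest.mark.parametrize("gate,lo,hi", [
    (0.0, 0, 0),        # degenerate: never fires
    (1.0, 1000, 1000),  # always fires
    (0.5, 485, 515),    # 3-sigma binomial band around p=0.5 (n=1e4 below)
])
def test_stochastic_gate_firing_fraction(gate, lo, hi):
    n = 10_000 if gate == 0.5 else 1000
    state = gated_secretion_state(gate)
    for _ in range(n):
        step(state)
    fired = round(state.fields["F"].total_mass())  # power 1 per firing, no decay
    if gate == 0.5:
        p, sigma = 0.5, (0.25 / n) ** 0.5
        assert abs(fired / n - p) < 3 * sigma
    else:
        assert fired == lo * n // 1000


# ---------------------------------------------------------------------------
# Division
# ---------------------------------------------------------------------------


def division_state(mechanism, daughter=None, parent_potency=2):
    params = {} if daughter is None else {"daughter": daughter}
    state = make_state(
        cell_types={
            "P": simple_type("P", potency=parent_potency, pathways=("div",)),
            "D": simple_type("D", potency=1, pathways=()),
        },
        pathways={"div": simple_pathway("div", mechanism, period=5,
                                        priority=1, params=params)},
    )
    cell = add_cell(state, "P", (4, 4, 4))
    cell.active_pathways = {"div"}
    schedule(state, Event(owner_id=cell.id, pathway_id="div", due_tick=0,
                          priority=1, mechanism=mechanism, params=params))
    return state, cell


def test_symmetric_division_adds_same_type():
    state, parent = division_state("divide_symmetric")
    step(state)
    step(state)  # completion
    assert state.census["P"] == 2
    assert state.birth_count == 2  # parent placement + daughter
    kinds = [o.type for o in state.objects.values()]
    assert kinds.count("P") == 2


def test_asymmetric_division_preserves_parent_census():
    state, parent = division_state("divide_asymmetric", daughter="D")
    step(state)
    step(state)
    assert state.census["P"] == 1 and state.census["D"] == 1
    daughter = next(o for o in state.objects.values() if o.type == "D")
    assert chebyshev_distance(daughter.position, parent.position) == 1


def test_asymmetric_division_requires_lower_potency():
    state, parent = division_state("divide_asymmetric", daughter="D",
                                   parent_potency=1)
    with pytest.raises(ConfigurationError):
        step(state)


def test_enclosed_cell_defers_division():
    state, parent = division_state("divide_symmetric")
    for c in neighborhood(parent.position, 1, state.lattice):
        add_cell(state, "D", c)
    before = dict(state.census)
    for _ in range(12):
        step(state)
    assert state.census == before, "no daughter until space opens"
    assert parent.status == "active"


# ---------------------------------------------------------------------------
# Differentiation
# ---------------------------------------------------------------------------


def diff_state(targets, conc):
    state = make_state(
        factors=[FactorDef(id="F", emission_radius=5)],
        cell_types={
            "P": simple_type("P", potency=3, pathways=("dif",)),
            "A": simple_type("A", potency=1),
            "B": simple_type("B", potency=1),
        },
        pathways={"dif": simple_pathway("dif", "differentiate", period=1,
                                        priority=2,
                                        params={"targets": targets})},
        lineage={("P", "A"), ("P", "B")},
    )
    cell = add_cell(state, "P", (4, 4, 4))
    cell.active_pathways = {"dif"}
    if conc:
        state.fields["F"].secrete((4, 4, 4), power=conc)
    schedule(state, Event(owner_id=cell.id, pathway_id="dif", due_tick=0,
                          priority=2, mechanism="differentiate",
                          params={"targets": targets}))
    return state, cell


def test_interval_selects_unique_target():
    targets = [{"type": "A", "factor": "F", "lo": 0.2, "hi": 0.6},
               {"type": "B", "factor": "F", "lo": 0.55, "hi": 1.0}]
    state, cell = diff_state(targets, conc=0.3)
    step(state)
    assert cell.type == "A"


def test_overlapping_intervals_choose_uniformly():
    """A concentration inside two intersecting intervals picks either target
    with equal probability (3-sigma binomial check over seeded repeats)."""
    targets = [{"type": "A", "factor": "F", "lo": 0.2, "hi": 0.6},
               {"type": "B", "factor": "F", "lo": 0.55, "hi": 1.0}]
    n, picks = 2000, collections.Counter()
    for seed in range(n):
        state, cell = diff_state(targets, conc=0.58)
        state.rng = np.random.default_rng(seed)
        step(state)
        picks[cell.type] += 1
    assert abs(picks["A"] / n - 0.5) < 3 * (0.25 / n) ** 0.5


def test_differentiation_outside_intervals_retries():
    targets = [{"type": "A", "factor": "F", "lo": 0.2, "hi": 0.6}]
    state, cell = diff_state(targets, conc=5.0)
    step(state)
    assert cell.type == "P"
    assert any(e[3].pathway_id == "dif" for e in state.queue), "retried"


def test_differentiation_outside_lineage_is_rejected():
    state, cell = diff_state([{"type": "A"}], conc=None)
    state.biology.lineage_edges.clear()
    with pytest.raises(ConfigurationError):
        step(state)


# ---------------------------------------------------------------------------
# Death
# ---------------------------------------------------------------------------


def kill_state(mechanism, payload=None):
    params = {} if payload is None else {"payload": payload}
    state = make_state(
        factors=[FactorDef(id="F", emission_radius=5)],
        cell_types={"C": simple_type("C", pathways=("die",))},
        pathways={"die": simple_pathway("die", mechanism, priority=0,
                                        params=params)},
    )
    cell = add_cell(state, "C", (4, 4, 4))
    ev = Event(owner_id=cell.id, pathway_id="die", due_tick=0, priority=0,
               mechanism=mechanism, params=params)
    return state, cell, ev


def test_apoptosis_leaves_environment_untouched():
    state, cell, ev = kill_state("apoptose")
    state.fields["F"].secrete((4, 4, 5), power=1.0)
    before = state.fields["F"].values.copy()
    handle_kill(state, ev, state.biology.pathways["die"])
    assert cell.status == "removed"
    assert state.lattice.is_vacant((4, 4, 4))
    assert np.array_equal(state.fields["F"].values, before)


def test_necrosis_deposits_payload():
    state, cell, ev = kill_state("necrose", payload={"F": 2.5})
    handle_kill(state, ev, state.biology.pathways["die"])
    assert state.fields["F"].concentration_at((4, 4, 4)) == 2.5


def test_double_kill_is_idempotent():
    state, cell, ev = kill_state("apoptose")
    pw = state.biology.pathways["die"]
    assert handle_kill(state, ev, pw)[0] == "apoptosed"
    assert handle_kill(state, ev, pw)[0] == "already-removed"
    assert state.death_count == 1


# ---------------------------------------------------------------------------
# Locomotion / A*
# ---------------------------------------------------------------------------


def bfs_shortest_path_length(lattice, start, goal):
    """Independent breadth-first oracle under the Chebyshev metric."""
    if start == goal:
        return 0
    seen = {start}
    frontier = [start]
    dist = 0
    while frontier:
        dist += 1
        nxt = []
        for c in frontier:
            for n in neighborhood(c, 1, lattice):
                if n == goal:
                    return dist
                if n not in seen and lattice.is_vacant(n):
                    seen.add(n)
                    nxt.append(n)
        frontier = nxt
    return None


def test_astar_unobstructed_is_chebyshev_geodesic():
    lat = Lattice(15)
    path = a_star(lat, (1, 2, 3), (9, 4, 13))
    assert path is not None
    assert len(path) - 1 == chebyshev_distance((1, 2, 3), (9, 4, 13))
    for a, b in zip(path, path[1:]):
        assert chebyshev_distance(a, b) == 1


def test_astar_through_wall_gap_matches_bfs():
    lat = Lattice(15)
    for x in range(15):
        for y in range(15):
            if (x, y) != (7, 7):
                lat.place(1000 + x * 15 + y, (x, y, 7))  # wall with one gap
    start, goal = (7, 7, 2), (7, 7, 12)
    path = a_star(lat, start, goal)
    assert len(path) - 1 == bfs_shortest_path_length(lat, start, goal)


def test_astar_matches_bfs_on_random_obstacle_grids():
    rng = np.random.default_rng(2024)
    for trial in range(100):
        lat = Lattice(15)
        blocked = rng.random((15, 15, 15)) < 0.35
        start = tuple(int(v) for v in rng.integers(0, 15, 3))
        goal = tuple(int(v) for v in rng.integers(0, 15, 3))
        blocked[start] = blocked[goal] = False
        oid = 1
        for idx in zip(*np.nonzero(blocked)):
            lat.place(oid, tuple(int(i) for i in idx))
            oid += 1
        expected = bfs_shortest_path_length(lat, start, goal)
        path = a_star(lat, start, goal)
        got = None if path is None else len(path) - 1
        assert got == expected


def test_walled_in_cell_cannot_move():
    lat = Lattice(5)
    lat.place(1, (2, 2, 2))
    for c in neighborhood((2, 2, 2), 1, lat):
        lat.place(10 + c[0] * 25 + c[1] * 5 + c[2], c)
    assert a_star(lat, (2, 2, 2), (0, 0, 0)) is None


# ---------------------------------------------------------------------------
# Axon growth and synaptogenesis
# ---------------------------------------------------------------------------


def axon_state():
    state = make_state(
        edge=15,
        factors=[FactorDef(id="AGF", emission_radius=8),
                 FactorDef(id="ACF", emission_radius=2)],
        cell_types={"N": simple_type("N", pathways=("gx",))},
        pathways={"gx": simple_pathway(
            "gx", "grow_axon", period=1, priority=4,
            params={"agf": "AGF", "acf": "ACF", "agf_threshold": 0.01,
                    "acf_threshold": 0.01, "sense_radius": 1,
                    "terminal_pathways": []})},
    )
    neuron = add_cell(state, "N", (5, 7, 7))
    neuron.axon = Neurite(owner_id=neuron.id, kind="axon",
                          path=[neuron.position])
    neuron.active_pathways = {"gx"}
    return state, neuron


def grow_event(state, neuron):
    pw = state.biology.pathways["gx"]
    return Event(owner_id=neuron.id, pathway_id="gx", due_tick=state.tick,
                 priority=4, mechanism="grow_axon", params=pw.params), pw


def set_point_source_field(state, factor, source, scale=1.0):
    field = state.fields[factor]
    for idx in np.ndindex(*field.values.shape):
        d = max(abs(idx[k] - source[k]) for k in range(3))
        if d <= field.factor.emission_radius:
            field.values[idx] = scale * np.exp(-0.05 * d * d)
    field.support[:] = True


def test_growth_climbs_guidance_gradient():
    state, neuron = axon_state()
    source = (12, 7, 7)
    set_point_source_field(state, "AGF", source)
    ev, pw = grow_event(state, neuron)
    for _ in range(9):
        before = chebyshev_distance(neuron.axon.tip, source)
        outcome, _ = handle_grow_axon(state, ev, pw)
        if neuron.axon.tip == source:
            break
        assert outcome == "extended"
        assert chebyshev_distance(neuron.axon.tip, source) < before


def test_connection_signal_arrests_growth():
    state, neuron = axon_state()
    set_point_source_field(state, "AGF", (12, 7, 7))
    state.fields["ACF"].secrete(neuron.axon.tip, power=1.0)
    ev, pw = grow_event(state, neuron)
    outcome, _ = handle_grow_axon(state, ev, pw)
    assert outcome == "growth-arrested"
    assert neuron.axon.cone == "terminal-pending"
    assert neuron.axon.length == 0
    assert any(e[3].mechanism == "form_terminal" for e in state.queue)


def test_no_guidance_signal_freezes_path():
    state, neuron = axon_state()
    ev, pw = grow_event(state, neuron)
    for _ in range(50):
        outcome, _ = handle_grow_axon(state, ev, pw)
        assert outcome == "no-signal"
    assert neuron.axon.length == 0


@pytest.mark.parametrize("history,partner,expected", [
    ([], "B", "single"),
    (["B"], "B", "sequentially-repeated"),
    (["B", "C"], "B", "non-sequentially-repeated"),
    (["B", "B", "C"], "B", "non-sequentially-repeated"),
    (["C"], "B", "single"),
])
def test_connection_repetition_classes(history, partner, expected):
    assert classify_connection(history, partner) == expected


def test_synapse_partner_must_be_target_type_with_spine():
    state = make_state(
        edge=9,
        factors=[FactorDef(id="DSFF", emission_radius=3)],
        cell_types={"A": simple_type("A", pathways=("syn",)),
                    "B": simple_type("B"), "C": simple_type("C")},
        pathways={"syn": simple_pathway(
            "syn", "form_synapse", period=1, priority=4,
            params={"target_type": "B", "search_radius": 2,
                    "terminal_pathways": []})},
    )
    pre = add_cell(state, "A", (4, 4, 4))
    pre.axon = Neurite(owner_id=pre.id, kind="axon", path=[(4, 4, 4)])
    wrong_type = add_cell(state, "C", (4, 4, 5))
    wrong_type.spine_formed = True
    no_spine = add_cell(state, "B", (4, 5, 4))
    partner = add_cell(state, "B", (5, 4, 4))
    partner.spine_formed = True
    pw = state.biology.pathways["syn"]
    ev = Event(owner_id=pre.id, pathway_id="syn", due_tick=0, priority=4,
               mechanism="form_synapse", params=pw.params, at=(4, 4, 4))
    outcome, details = handle_form_synapse(state, ev, pw)
    assert outcome == "synapse-formed"
    assert details["post"] == partner.id
    rec = state.connection_log[-1]
    assert (rec.pre_id, rec.post_id, rec.category) == (pre.id, partner.id,
                                                       "single")


def test_population_bookkeeping_on_organoid_run(organoid_run_I):
    """initial + births - deaths equals the live count at the end."""
    st = organoid_run_I.state
    live = sum(st.census.values())
    assert live == st.birth_count - st.death_count


def test_axon_paths_are_chebyshev_chains(organoid_run_I):
    checked = 0
    for obj in organoid_run_I.state.objects.values():
        axon = getattr(obj, "axon", None)
        if axon is None:
            continue
        assert axon.path[0] == obj.position
        for a, b in zip(axon.path, axon.path[1:]):
            assert chebyshev_distance(a, b) == 1
        checked += 1
    assert checked > 50
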