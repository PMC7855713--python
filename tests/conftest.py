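"""Shared fixtures: tiny hand-built states and full organoid runs.

The organoid runs are session-scoped because each takes tens of seconds;
every test that inspects the grown structure shares the same run.
"""

from __future__ import annotations

import numpy as np
import pytest

import organoidsim as osim
from organoidsim.configuration import BiologicalConfig
from organoidsim.events import ModelState
from organoidsim.mechanisms import Cell, CellType, SignalingPathway
from organoidsim.signals import FactorDef, FactorField
from organoidsim.space import Lattice


def make_state(edge=9, factors=(), cell_types=None, pathways=None,
               lineage=(), seed=0) -> ModelState:
    """A minimal model state for unit tests, bypassing document parsing."""
    fdefs = {}
    for f in factors:
        fdefs[f.id] = f
    biology = BiologicalConfig(
        factors=fdefs,
        cell_types=cell_types or {},
        pathways=pathways or {},
        lineage_edges=set(lineage),
    )
    state = ModelState(Lattice(edge), np.random.default_rng(seed), biology)
    for f in fdefs.values():
        state.fields[f.id] = FactorField(f, edge)
    return state


def add_cell(state: ModelState, type_name: str, at, status="active") -> Cell:
    cell = Cell(id=state.new_id(), type=type_name, position=tuple(at),
                status=status)
    state.objects[cell.id] = cell
    state.lattice.place(cell.id, cell.position)
    state.census[type_name] = state.census.get(type_name, 0) + 1
    state.birth_count += 1
    return cell


def simple_type(name, potency=1, pathways=(), initial=None):
    return CellType(name=name, potency=potency, pathways=tuple(pathways),
                    initial_pathways=tuple(initial if initial is not None
                                           else pathways))


def simple_pathway(pid, mechanism, **kw):
    return SignalingPathway(id=pid, mechanism=mechanism, **kw)


@pytest.fixture(scope="session")
def organoid_run_I():
    return osim.run_simulation(osim.make_organoid_config(1, "I", seed=1))


@pytest.fixture(scope="session")
def organoid_run_II():
    return osim.run_simulation(osim.make_organoid_config(1, "II", seed=1))


@pytest.fixture(scope="session")
def stage1_run():
    return osim.run_simulation(osim.make_stage_config(1, seed=1))


@pytest.fixture(scope="session")
def stage2_run():
    return osim.run_simulation(osim.make_stage_config(2, seed=1))


@pytest.fixture(scope="session")
def stage4_run():
    return osim.run_simulation(osim.make_stage_config(4, seed=1))
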