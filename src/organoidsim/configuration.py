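"""Declarative configuration: loading, validation, initial-state building.

A run is fully specified by three documents that never change during the
simulation: the model configuration (lattice edge, tick budget, seed), the
spatial configuration (initial object placement) and the biological
configuration (factors, cell types, signaling pathways, lineage).  The
on-disk format is YAML (JSON, being a YAML subset, is accepted too) with
the layout::

    model:   {edge, ticks, seed, ...}
    space:   {initial: [{type: NSC, at: [x, y, z]}, {mark: [NSCF], at: ...}]}
    biology:
      factors:    {NAME: {emission_radius, signal_power, ...}}
      cell_types: {NAME: {potency, emits, receives, pathways, initial_pathways}}
      pathways:   {ID: {mechanism, period, guard, gate, params, ...}}
      lineage:    [{from: A, to: B}, ...]

Guards are nested ``{all: [...]}`` / ``{any: [...]}`` lists with leaf
records ``{factor, op, threshold, threshold_hi, radius}``.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field as dc_field

import networkx as nx
import numpy as np
import yaml

from .space import Coord, Lattice, SpatialMark
from .signals import FactorDef, FactorField
from .events import (
    Condition,
    ConfigurationError,
    DEFAULT_PRIORITIES,
    ModelState,
    PredicateTree,
)
from .mechanisms import (
    Cell,
    CellType,
    SignalingPathway,
    launch_initial_pathways,
    register_birth,
)


@dataclass(frozen=True)
class ModelConfig:
    edge: int
    ticks: int
    seed: int = 0
    snapshot_every: int = 1000
    log_level: str = "summary"
    diffusion_every: int = 1

    def __post_init__(self):
        if self.edge < 3:
            raise ConfigurationError("lattice edge must be >= 3")
        # documents must declare a positive budget; a zero-tick override is
        # allowed at run time (initial snapshot only)
        if self.ticks < 0:
            raise ConfigurationError("tick budget must be >= 0")


@dataclass(frozen=True)
class InitialObject:
    kind: str  # "cell" | "mark"
    type_or_factors: object
    at: Coord


@dataclass(frozen=True)
class SpatialConfig:
    initial: tuple[InitialObject, ...]


@dataclass
class BiologicalConfig:
    factors: dict[str, FactorDef]
    cell_types: dict[str, CellType]
    pathways: dict[str, SignalingPathway]
    lineage_edges: set[tuple[str, str]]


# ---------------------------------------------------------------------------
# Parsing
# ---------------------------------------------------------------------------


def parse_guard(node) -> PredicateTree | None:
    if node is None:
        return None
    if isinstance(node, dict) and "all" in node:
        return PredicateTree(
            kind="and", children=tuple(parse_guard(ch) for ch in node["all"])
        )
    if isinstance(node, dict) and "any" in node:
        return PredicateTree(
            kind="or", children=tuple(parse_guard(ch) for ch in node["any"])
        )
    if isinstance(node, dict) and "factor" in node:
        cond = Condition(
            factor=node["factor"],
            op=node.get("op", "ge"),
            threshold=float(node["threshold"]),
            threshold_hi=(
                float(node["threshold_hi"]) if "threshold_hi" in node else None
            ),
            radius=int(node.get("radius", 0)),
        )
        return PredicateTree(kind="leaf", leaf=cond)
    raise ConfigurationError(f"cannot parse guard node {node!r}")


def guard_to_dict(tree: PredicateTree | None):
    if tree is None:
        return None
    if tree.kind == "leaf":
        c = tree.leaf
        out = {"factor": c.factor, "op": c.op, "threshold": c.threshold}
        if c.threshold_hi is not None:
            out["threshold_hi"] = c.threshold_hi
        if c.radius:
            out["radius"] = c.radius
        return out
    key = "all" if tree.kind == "and" else "any"
    return {key: [guard_to_dict(ch) for ch in tree.children]}


def _parse_pathway(pid: str, spec: dict) -> SignalingPathway:
    mechanism = spec["mechanism"]
    priority = spec.get("priority", DEFAULT_PRIORITIES.get(mechanism, 5))
    gate = spec.get("gate", None)
    if gate is not None and not isinstance(gate, (int, float)):
        raise ConfigurationError(f"pathway {pid}: gate must be a probability")
    return SignalingPathway(
        id=pid,
        mechanism=mechanism,
        period=int(spec.get("period", 1)),
        priority=int(priority),
        guard=parse_guard(spec.get("guard")),
        gate=gate,
        on_guard_fail=spec.get("on_guard_fail", "retry"),
        one_shot=bool(spec.get("one_shot", False)),
        params=dict(spec.get("params", {})),
    )


def load_config(document):
    """Parse and validate a configuration document.

    ``document`` is YAML text or an already-parsed mapping.  Returns
    ``(ModelConfig, SpatialConfig, BiologicalConfig)``; raises
    :class:`ConfigurationError` naming the offending identifier on dangling
    references, cyclic lineages, or placement collisions.
    """
    if isinstance(document, str):
        try:
            doc = yaml.safe_load(document)
        except yaml.YAMLError as exc:
            raise ConfigurationError(f"configuration syntax error: {exc}") from exc
    else:
        doc = document
    if not isinstance(doc, dict):
        raise ConfigurationError("configuration document must be a mapping")

    m = doc.get("model", {})
    if int(m.get("ticks", 100)) < 1:
        raise ConfigurationError("configured tick budget must be >= 1")
    model = ModelConfig(
        edge=int(m.get("edge", 16)),
        ticks=int(m.get("ticks", 100)),
        seed=int(m.get("seed", 0)),
        snapshot_every=int(m.get("snapshot_every", 1000)),
        log_level=m.get("log_level", "summary"),
        diffusion_every=int(m.get("diffusion_every", 1)),
    )

    bio = doc.get("biology", {})
    factors = {
        name: FactorDef(
            id=name,
            emission_radius=int(spec.get("emission_radius", 1)),
            signal_power=float(spec.get("signal_power", 1.0)),
            propagation_rate=float(spec.get("propagation_rate", 0.5)),
            degradation_rate=float(spec.get("degradation_rate", 0.0)),
        )
        for name, spec in (bio.get("factors") or {}).items()
    }
    pathways = {
        pid: _parse_pathway(pid, spec)
        for pid, spec in (bio.get("pathways") or {}).items()
    }
    cell_types = {}
    for name, spec in (bio.get("cell_types") or {}).items():
        pws = tuple(spec.get("pathways", ()))
        cell_types[name] = CellType(
            name=name,
            potency=int(spec.get("potency", 1)),
            receives=tuple(spec.get("receives", ())),
            emits=tuple(spec.get("emits", ())),
            pathways=pws,
            initial_pathways=tuple(spec.get("initial_pathways", pws)),
        )
    lineage_edges = {
        (e["from"], e["to"]) for e in (bio.get("lineage") or [])
    }
    biology = BiologicalConfig(
        factors=factors, cell_types=cell_types, pathways=pathways,
        lineage_edges=lineage_edges,
    )

    sp = doc.get("space", {})
    initial = []
    for item in sp.get("initial", ()):
        at = tuple(int(v) for v in item["at"])
        if "type" in item:
            initial.append(InitialObject("cell", item["type"], at))
        elif "mark" in item:
            initial.append(InitialObject("mark", tuple(item["mark"]), at))
        else:
            raise ConfigurationError(f"initial object {item!r} lacks type/mark")
    spatial = SpatialConfig(initial=tuple(initial))

    validate(model, spatial, biology)
    return model, spatial, biology


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------


def _pathway_factor_refs(pw: SignalingPathway):
    refs = set()
    if pw.guard is not None:
        refs |= pw.guard.factors()
    p = pw.params
    for key in ("factor", "agf", "acf"):
        if key in p:
            refs.add(p[key])
    for f in p.get("payload", {}):
        refs.add(f)
    for tgt in p.get("targets", ()):
        if tgt.get("factor"):
            refs.add(tgt["factor"])
    return refs


def validate(model: ModelConfig, spatial: SpatialConfig,
             biology: BiologicalConfig) -> None:
    """Reference closure, lineage acyclicity, potency monotonicity, bounds."""
    # reference closure: factors
    for pw in biology.pathways.values():
        for f in _pathway_factor_refs(pw):
            if f not in biology.factors:
                raise ConfigurationError(
                    f"pathway {pw.id!r} references undeclared factor {f!r}"
                )
    for ct in biology.cell_types.values():
        for f in (*ct.emits, *ct.receives):
            if f not in biology.factors:
                raise ConfigurationError(
                    f"cell type {ct.name!r} references undeclared factor {f!r}"
                )
        for pid in (*ct.pathways, *ct.initial_pathways):
            if pid not in biology.pathways:
                raise ConfigurationError(
                    f"cell type {ct.name!r} references undeclared pathway {pid!r}"
                )
    # pathway-internal references to pathways and cell types
    for pw in biology.pathways.values():
        for key in ("activate", "deactivate", "terminal_pathways"):
            for pid in pw.params.get(key, ()):
                if pid not in biology.pathways:
                    raise ConfigurationError(
                        f"pathway {pw.id!r} references undeclared pathway {pid!r}"
                    )
        if pw.mechanism == "divide_asymmetric":
            d = pw.params.get("daughter")
            if d not in biology.cell_types:
                raise ConfigurationError(
                    f"pathway {pw.id!r} references undeclared cell type {d!r}"
                )
        if pw.mechanism == "differentiate":
            for tgt in pw.params.get("targets", ()):
                if tgt["type"] not in biology.cell_types:
                    raise ConfigurationError(
                        f"pathway {pw.id!r} references undeclared cell type "
                        f"{tgt['type']!r}"
                    )
        if pw.mechanism == "form_synapse":
            t = pw.params.get("target_type")
            if t not in biology.cell_types:
                raise ConfigurationError(
                    f"pathway {pw.id!r} references undeclared cell type {t!r}"
                )
    # lineage: DAG over declared types with strictly decreasing potency
    g = nx.DiGraph()
    g.add_nodes_from(biology.cell_types)
    for a, b in biology.lineage_edges:
        for n in (a, b):
            if n not in biology.cell_types:
                raise ConfigurationError(
                    f"lineage references undeclared cell type {n!r}"
                )
        g.add_edge(a, b)
    if not nx.is_directed_acyclic_graph(g):
        cycle = nx.find_cycle(g)
        raise ConfigurationError(f"lineage contains a cycle: {cycle}")
    for a, b in biology.lineage_edges:
        if biology.cell_types[b].potency >= biology.cell_types[a].potency:
            raise ConfigurationError(
                f"lineage edge {a!r} -> {b!r} does not reduce potency"
            )
    # differentiation targets must be lineage edges
    for ct in biology.cell_types.values():
        for pid in ct.pathways:
            pw = biology.pathways[pid]
            if pw.mechanism == "differentiate":
                for tgt in pw.params.get("targets", ()):
                    if (ct.name, tgt["type"]) not in biology.lineage_edges:
                        raise ConfigurationError(
                            f"differentiation {ct.name!r} -> {tgt['type']!r} "
                            f"(pathway {pid!r}) is not a lineage edge"
                        )
            if pw.mechanism == "divide_asymmetric":
                d = pw.params["daughter"]
                if biology.cell_types[d].potency >= ct.potency:
                    raise ConfigurationError(
                        f"asymmetric division {ct.name!r} -> {d!r} does not "
                        "reduce potency"
                    )
    # placements
    seen: set[Coord] = set()
    for obj in spatial.initial:
        if not all(0 <= v < model.edge for v in obj.at):
            raise ConfigurationError(f"initial object at {obj.at} out of bounds")
        if obj.kind == "cell":
            if obj.type_or_factors not in biology.cell_types:
                raise ConfigurationError(
                    f"initial object references undeclared cell type "
                    f"{obj.type_or_factors!r}"
                )
            if obj.at in seen:
                raise ConfigurationError(
                    f"two cell bodies placed at coordinate {obj.at}"
                )
            seen.add(obj.at)
        else:
            for f in obj.type_or_factors:
                if f not in biology.factors:
                    raise ConfigurationError(
                        f"spatial mark references undeclared factor {f!r}"
                    )


# ---------------------------------------------------------------------------
# Serialization and initial state
# ---------------------------------------------------------------------------


def serialize_config(model: ModelConfig, spatial: SpatialConfig,
                     biology: BiologicalConfig) -> str:
    """Render the three configurations back to canonical YAML."""
    doc = {
        "model": {
            "edge": model.edge,
            "ticks": model.ticks,
            "seed": model.seed,
            "snapshot_every": model.snapshot_every,
            "log_level": model.log_level,
            "diffusion_every": model.diffusion_every,
        },
        "space": {
            "initial": [
                (
                    {"type": o.type_or_factors, "at": list(o.at)}
                    if o.kind == "cell"
                    else {"mark": list(o.type_or_factors), "at": list(o.at)}
                )
                for o in spatial.initial
            ]
        },
        "biology": {
            "factors": {
                f.id: {
                    "emission_radius": f.emission_radius,
                    "signal_power": f.signal_power,
                    "propagation_rate": f.propagation_rate,
                    "degradation_rate": f.degradation_rate,
                }
                for f in biology.factors.values()
            },
            "cell_types": {
                ct.name: {
                    "potency": ct.potency,
                    "receives": list(ct.receives),
                    "emits": list(ct.emits),
                    "pathways": list(ct.pathways),
                    "initial_pathways": list(ct.initial_pathways),
                }
                for ct in biology.cell_types.values()
            },
            "pathways": {
                pw.id: {
                    "mechanism": pw.mechanism,
                    "period": pw.period,
                    "priority": pw.priority,
                    "guard": guard_to_dict(pw.guard),
                    "gate": pw.gate,
                    "on_guard_fail": pw.on_guard_fail,
                    "one_shot": pw.one_shot,
                    "params": pw.params,
                }
                for pw in biology.pathways.values()
            },
            "lineage": [
                {"from": a, "to": b} for a, b in sorted(biology.lineage_edges)
            ],
        },
    }
    return yaml.safe_dump(doc, sort_keys=True)


def config_hash(model: ModelConfig, spatial: SpatialConfig,
                biology: BiologicalConfig) -> str:
    return hashlib.sha256(
        serialize_config(model, spatial, biology).encode()
    ).hexdigest()


def build_initial_state(model: ModelConfig, spatial: SpatialConfig,
                        biology: BiologicalConfig) -> ModelState:
    """Materialize the initial system state from validated configurations."""
    lattice = Lattice(model.edge)
    rng = np.random.default_rng(model.seed)
    state = ModelState(lattice, rng, biology, model_config=model)
    state.log_level = model.log_level
    for factor in biology.factors.values():
        state.fields[factor.id] = FactorField(factor, model.edge)
    for obj in spatial.initial:
        if obj.kind == "cell":
            cell = Cell(id=state.new_id(), type=obj.type_or_factors,
                        position=obj.at, born_tick=0)
            register_birth(state, cell)
            launch_initial_pathways(state, cell, due=0)
            state.log(
                # a synthetic placement record so censuses reconcile from logs
                __placement_event(cell), "placed", {"type": cell.type},
            )
        else:
            mark = SpatialMark(
                id=state.new_id(), coordinate=obj.at,
                emitted_factors=tuple(obj.type_or_factors),
            )
            state.objects[mark.id] = mark
            state.lattice.add_passthrough(mark.id, obj.at)
    state.census_history.append((0, dict(state.census)))
    return state


def __placement_event(cell: Cell):
    from .events import Event

    return Event(
        owner_id=cell.id, pathway_id="_initial", due_tick=0, priority=0,
        mechanism="_placement", at=cell.position,
    )
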