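"""Ready-made organoid configurations: four developmental stages at desk scale.

The configurations grow a layered, synaptically connected organoid-like
structure from a single neural stem cell:

Stage 1 (proliferation): the NSC divides asymmetrically at regular
intervals, shedding neural progenitor cells (NPC), and continuously emits
NSCF whose spherical gradient bounds the structure.  NPCs divide
symmetrically while NSCF is high; on the low-NSCF boundary they start
secreting NPCF, other NPCs sensing NPCF join in (a chain reaction), and
once NPCF passes a threshold NPCs differentiate probabilistically into
neuron- and glia-committed intermediates.  NPCs pushed below the minimal
NSCF boundary undergo apoptosis.

Stage 2 (differentiation): basal progenitors and radial glia keep NPCF up
and mature into neuron-restricted (NRPC) and glia-restricted (GRPC)
progenitors.  NRPCs map their local NSCF concentration onto intersecting
intervals to become L1-L4 neurons (outer layers match lower NSCF, so layers
order radially); GRPCs probabilistically yield astrocytes (type 1 centrally,
type 2 peripherally) and oligodendrocytes.

Stage 3 (compartments): a neuron lacking glial neurotrophic factor (GNF)
emits neuron factor (NF); glia sensing NF and insufficient GNF secrete GNF;
sufficient GNF triggers neurite sprouting and shuts NF emission off
(negative feedback).

Stage 4 (wiring): dendrite-bearing neurons emit type-specific axon-guidance
(AGF) and axon-connection (ACF) factors.  Growth cones climb the AGF
gradient of their configured target layer (L1->L3, L3->L2, L2->L4), arrest
on ACF, and run the terminal/spine handshake (TFF -> spine -> DSFF/DSCF ->
synapse); afterwards the cone retreats against the gradient and searches
again, which is what makes repeated connections possible.

All numeric thresholds, radii, probabilities and periods below are original
to this package (tuned to reproduce the qualitative structure at scale 1,
about a thousand cells); the two variants differ only in the L3/L4
differentiation intervals and in the AGF radii.
"""

from __future__ import annotations

import copy

# Steady-state NSCF landmarks at scale 1 (source power 50/tick, spread
# variance 0.465/tick/axis, decay 0.02/tick; a screened point-source
# profile): about 18 at the stem cell, 1.3 at radius 4, 0.5 at radius 6
# (the structure boundary) and 0.28 around radius 7.5 (the apoptosis
# boundary).
NSCF_DIVIDE_MIN = 0.50  # NPC symmetric division requires at least this
NSCF_APOPTOSIS_MAX = 0.28  # below this a cell has left the structure
NPCF_CHAIN_MIN = 0.15  # joining the NPCF chain reaction
NPCF_DIFF_MIN = 0.25  # NPC differentiation needs several nearby emitters
GNF_SPROUT_MIN = 0.15
NF_PRESENCE_MIN = 0.08
GNF_SATURATION = 1.0
AGF_PRESENCE_MIN = 0.004
ACF_PRESENCE_MIN = 0.004
TFF_PRESENCE_MIN = 0.01
DSFF_PRESENCE_MIN = 0.01

#: NSCF intervals (lo, hi) for neuron-restricted progenitor fate; the
#: intervals intersect so adjacent layers blend at their boundary.
LAYER_INTERVALS = {
    "I": {
        "L1N": (NSCF_APOPTOSIS_MAX, 0.72),
        "L2N": (0.64, 1.2),
        "L3N": (1.1, 2.6),
        "L4N": (2.4, None),
    },
    "II": {
        "L1N": (NSCF_APOPTOSIS_MAX, 0.72),
        "L2N": (0.64, 1.2),
        "L3N": (1.1, 2.0),
        "L4N": (1.85, None),
    },
}

#: Guidance-factor radii; variant I's L2NeuronAGF is 1.5x variant II's,
#: L4NeuronAGF 1.4x, and its L3NeuronAGF is smaller by one coordinate.
AGF_RADII = {
    "I": {"L2NeuronAGF": 6, "L3NeuronAGF": 6, "L4NeuronAGF": 7},
    "II": {"L2NeuronAGF": 4, "L3NeuronAGF": 7, "L4NeuronAGF": 5},
}

#: The wiring scheme: presynaptic layer -> postsynaptic layer.
WIRING_SCHEME = {"L1N": "L3N", "L3N": "L2N", "L2N": "L4N"}

NEURON_TYPES = ("L1N", "L2N", "L3N", "L4N")
GLIA_TYPES = ("T1A", "ODC", "T2A")
TRANSIENT_PROGENITORS = ("BPC", "RGC", "GRPC", "OT2APC")

#: Cell-type clusters used by the census analysis.
TYPE_CLUSTERS = {
    "MP": ("NSC", "NPC"),
    "NP": ("BPC", "NRPC"),
    "GP": ("RGC", "GRPC", "OT2APC"),
    "NC": NEURON_TYPES,
    "GC": GLIA_TYPES,
}


def _cube_root(scale: float) -> float:
    return float(scale) ** (1.0 / 3.0)


def _factors(scale: int, variant: str) -> dict:
    s = _cube_root(scale)
    r = lambda v: max(1, int(round(v * s)))
    factors = {
        "NSCF": {
            "emission_radius": r(14),
            "signal_power": 50.0 * s,
            "propagation_rate": 0.6,
            "degradation_rate": 0.02 / s**2,
        },
        "NPCF": {
            # short-ranged on purpose: the chain reaction then travels as an
            # inward wave from the boundary, which is what makes the layers
            # differentiate sequentially (L1 first, L4 last)
            "emission_radius": 2,
            "signal_power": 0.25,
            "propagation_rate": 0.4,
            "degradation_rate": 0.25,
        },
        "NF": {
            "emission_radius": 3,
            "signal_power": 0.5,
            "propagation_rate": 0.4,
            "degradation_rate": 0.2,
        },
        "GNF": {
            "emission_radius": 3,
            "signal_power": 0.5,
            "propagation_rate": 0.4,
            "degradation_rate": 0.2,
        },
        "TFF": {
            "emission_radius": 3,
            "signal_power": 1.0,
            "propagation_rate": 0.5,
            "degradation_rate": 0.15,
        },
        "DSFF": {
            "emission_radius": 3,
            "signal_power": 1.0,
            "propagation_rate": 0.5,
            "degradation_rate": 0.15,
        },
        "DSCF": {
            "emission_radius": 3,
            "signal_power": 1.0,
            "propagation_rate": 0.5,
            "degradation_rate": 0.15,
        },
    }
    for name, radius in AGF_RADII[variant].items():
        factors[name] = {
            "emission_radius": r(radius),
            "signal_power": 0.6,
            "propagation_rate": 0.6,
            "degradation_rate": 0.1,
        }
    for name in ("L2NeuronACF", "L3NeuronACF", "L4NeuronACF"):
        factors[name] = {
            "emission_radius": 2,
            "signal_power": 0.4,
            "propagation_rate": 0.3,
            "degradation_rate": 0.3,
        }
    return factors


def _progenitor_pathways(variant: str) -> dict:
    """Stages 1-2: proliferation, the NPCF chain, fate decisions."""
    intervals = LAYER_INTERVALS[variant]
    low_nscf_boundary = {
        "all": [
            {"factor": "NSCF", "op": "le", "threshold": NSCF_DIVIDE_MIN},
            {"factor": "NSCF", "op": "ge", "threshold": NSCF_APOPTOSIS_MAX},
        ]
    }
    pathways = {
        "nsc_secrete_nscf": {"mechanism": "secrete_factor", "period": 1,
                             "params": {"factor": "NSCF"}},
        "nsc_divide": {"mechanism": "divide_asymmetric", "period": 8,
                       "params": {"daughter": "NPC"}},
        "npc_divide": {
            "mechanism": "divide_symmetric", "period": 6,
            "guard": {"factor": "NSCF", "op": "ge",
                      "threshold": NSCF_DIVIDE_MIN},
        },
        "npc_join_chain": {
            "mechanism": "transduce", "period": 2,
            "guard": {"any": [
                low_nscf_boundary,
                {"factor": "NPCF", "op": "ge", "threshold": NPCF_CHAIN_MIN},
            ]},
            "params": {"activate": ["npc_secrete_npcf"],
                       "deactivate_self": True},
        },
        "npc_secrete_npcf": {"mechanism": "secrete_factor", "period": 1,
                             "params": {"factor": "NPCF"}},
        "npc_differentiate": {
            "mechanism": "differentiate", "period": 3, "gate": 0.5,
            "guard": {"all": [
                {"factor": "NPCF", "op": "ge", "threshold": NPCF_DIFF_MIN},
                {"factor": "NSCF", "op": "ge",
                 "threshold": NSCF_APOPTOSIS_MAX},
            ]},
            "params": {"targets": [
                {"type": "BPC", "weight": 0.16},
                {"type": "RGC", "weight": 0.84},
            ]},
        },
        "npc_apoptose": {
            "mechanism": "apoptose", "period": 2,
            "guard": {"factor": "NSCF", "op": "le",
                      "threshold": NSCF_APOPTOSIS_MAX},
        },
        "bpc_secrete_npcf": {"mechanism": "secrete_factor", "period": 1,
                             "params": {"factor": "NPCF"}},
        "bpc_differentiate": {
            "mechanism": "differentiate", "period": 2, "gate": 0.6,
            "guard": {"factor": "NSCF", "op": "ge",
                      "threshold": NSCF_APOPTOSIS_MAX},
            "params": {"targets": [{"type": "NRPC"}]},
        },
        "rgc_secrete_npcf": {"mechanism": "secrete_factor", "period": 1,
                             "params": {"factor": "NPCF"}},
        "rgc_differentiate": {
            "mechanism": "differentiate", "period": 2, "gate": 0.6,
            "guard": {"factor": "NSCF", "op": "ge",
                      "threshold": NSCF_APOPTOSIS_MAX},
            "params": {"targets": [{"type": "GRPC"}]},
        },
        "nrpc_differentiate": {
            "mechanism": "differentiate", "period": 3, "gate": 0.5,
            "guard": {"factor": "NSCF", "op": "ge",
                      "threshold": NSCF_APOPTOSIS_MAX},
            "params": {"targets": [
                {"type": name, "factor": "NSCF", "lo": lo,
                 **({"hi": hi} if hi is not None else {})}
                for name, (lo, hi) in intervals.items()
            ]},
        },
        "grpc_differentiate": {
            "mechanism": "differentiate", "period": 4, "gate": 0.3,
            "guard": {"factor": "NSCF", "op": "ge",
                      "threshold": NSCF_APOPTOSIS_MAX},
            "params": {"targets": [
                # graded type-1-astrocyte preference: strongest deep inside
                # the structure, so T1A density falls with radius
                {"type": "T1A", "factor": "NSCF", "lo": 1.3, "weight": 5.0},
                {"type": "T1A", "factor": "NSCF", "lo": 0.25, "weight": 2.2},
                {"type": "OT2APC", "weight": 1.0},
            ]},
        },
        "ot2apc_differentiate": {
            "mechanism": "differentiate", "period": 4, "gate": 0.4,
            "guard": {"factor": "NSCF", "op": "ge",
                      "threshold": NSCF_APOPTOSIS_MAX},
            "params": {"targets": [
                {"type": "ODC", "weight": 0.7},
                # type-2 astrocytes appear only in the low-NSCF periphery
                {"type": "T2A", "factor": "NSCF", "hi": 0.6, "weight": 1.5},
            ]},
        },
    }
    # every transient progenitor dies when pushed out of the structure
    for prefix in ("bpc", "rgc", "nrpc", "grpc", "ot2apc"):
        pathways[f"{prefix}_apoptose"] = {
            "mechanism": "apoptose", "period": 2,
            "guard": {"factor": "NSCF", "op": "le",
                      "threshold": NSCF_APOPTOSIS_MAX},
        }
    return pathways


def _neuron_pathways(layer: str) -> dict:
    """Stages 3-4 pathways for one neuron layer."""
    lx = layer.lower()
    has_axon = layer in WIRING_SCHEME
    has_dendrite = layer in WIRING_SCHEME.values()
    activate = []
    pathways = {}
    if has_axon:
        target = WIRING_SCHEME[layer]
        agf = f"{target[:2]}Neuron" + "AGF"
        acf = f"{target[:2]}Neuron" + "ACF"
        terminal_pathways = [f"{lx}_emit_tff", f"{lx}_form_synapse"]
        pathways[f"{lx}_grow_axon"] = {
            "mechanism": "grow_axon", "period": 2,
            "params": {
                "agf": agf, "acf": acf,
                "agf_threshold": AGF_PRESENCE_MIN,
                "acf_threshold": ACF_PRESENCE_MIN,
                "sense_radius": 1,
                "terminal_pathways": terminal_pathways,
            },
        }
        pathways[f"{lx}_emit_tff"] = {
            "mechanism": "secrete_factor", "period": 1,
            "params": {"factor": "TFF"},
        }
        pathways[f"{lx}_form_synapse"] = {
            "mechanism": "form_synapse", "period": 2,
            "guard": {"factor": "DSFF", "op": "ge",
                      "threshold": DSFF_PRESENCE_MIN, "radius": 1},
            "params": {"target_type": target, "search_radius": 3,
                       "terminal_pathways": terminal_pathways},
        }
        activate.append(f"{lx}_grow_axon")
    if has_dendrite:
        own_agf = f"{layer[:2]}Neuron" + "AGF"
        own_acf = f"{layer[:2]}Neuron" + "ACF"
        pathways[f"{lx}_emit_agf"] = {
            "mechanism": "secrete_factor", "period": 2,
            "params": {"factor": own_agf},
        }
        pathways[f"{lx}_emit_acf"] = {
            "mechanism": "secrete_factor", "period": 2,
            "params": {"factor": own_acf},
        }
        pathways[f"{lx}_form_spine"] = {
            "mechanism": "form_spine", "period": 2,
            "guard": {"factor": "TFF", "op": "ge",
                      "threshold": TFF_PRESENCE_MIN, "radius": 2},
            "params": {"activate": [f"{lx}_emit_dsff", f"{lx}_emit_dscf"]},
        }
        pathways[f"{lx}_emit_dsff"] = {
            "mechanism": "secrete_factor", "period": 1,
            "params": {"factor": "DSFF"},
        }
        pathways[f"{lx}_emit_dscf"] = {
            "mechanism": "secrete_factor", "period": 1,
            "params": {"factor": "DSCF"},
        }
        activate += [f"{lx}_emit_agf", f"{lx}_emit_acf", f"{lx}_form_spine"]
    pathways[f"{lx}_secrete_nf"] = {
        "mechanism": "secrete_factor", "period": 2,
        "guard": {"factor": "GNF", "op": "le", "threshold": GNF_SPROUT_MIN,
                  "radius": 2},
        "params": {"factor": "NF"},
    }
    pathways[f"{lx}_sprout"] = {
        "mechanism": "sprout_neurites", "period": 2,
        "guard": {"factor": "GNF", "op": "ge", "threshold": GNF_SPROUT_MIN,
                  "radius": 2},
        "params": {"axon": has_axon, "dendrite": has_dendrite,
                   "activate": activate, "deactivate": [f"{lx}_secrete_nf"]},
    }
    return pathways


def _stage34_shared_pathways() -> dict:
    return {
        "glia_secrete_gnf": {
            "mechanism": "secrete_factor", "period": 2,
            "guard": {"all": [
                {"factor": "NF", "op": "ge", "threshold": NF_PRESENCE_MIN,
                 "radius": 2},
                {"factor": "GNF", "op": "le", "threshold": GNF_SATURATION},
            ]},
            "params": {"factor": "GNF"},
        },
    }


def _cell_types(stage: int) -> dict:
    """Cell-type roster; later stages extend the earlier stages' behavior."""
    types = {
        "NSC": {
            "potency": 7, "emits": ["NSCF"],
            "pathways": ["nsc_secrete_nscf", "nsc_divide"],
        },
        "NPC": {
            "potency": 6, "receives": ["NSCF", "NPCF"], "emits": ["NPCF"],
            "pathways": ["npc_divide", "npc_join_chain", "npc_secrete_npcf",
                         "npc_differentiate", "npc_apoptose"],
            "initial_pathways": ["npc_divide", "npc_join_chain",
                                 "npc_differentiate", "npc_apoptose"],
        },
        "BPC": {
            "potency": 5, "receives": ["NSCF"], "emits": ["NPCF"],
            "pathways": ["bpc_secrete_npcf", "bpc_differentiate",
                         "bpc_apoptose"],
        },
        "RGC": {
            "potency": 5, "receives": ["NSCF"], "emits": ["NPCF"],
            "pathways": ["rgc_secrete_npcf", "rgc_differentiate",
                         "rgc_apoptose"],
        },
    }
    if stage == 1:
        # fate decisions stop at the committed-progenitor boundary
        for t in ("BPC", "RGC"):
            types[t]["pathways"] = [p for p in types[t]["pathways"]
                                    if not p.endswith("differentiate")]
            types[t].pop("initial_pathways", None)
        return types
    types.update(
        {
            "NRPC": {
                "potency": 4, "receives": ["NSCF"],
                "pathways": ["nrpc_differentiate", "nrpc_apoptose"],
            },
            "GRPC": {
                "potency": 4, "receives": ["NSCF"],
                "pathways": ["grpc_differentiate", "grpc_apoptose"],
            },
            "OT2APC": {
                "potency": 3, "receives": ["NSCF"],
                "pathways": ["ot2apc_differentiate", "ot2apc_apoptose"],
            },
        }
    )
    for layer in NEURON_TYPES:
        spec = {"potency": 1, "receives": ["GNF", "TFF", "DSFF"],
                "emits": ["NF"], "pathways": []}
        if stage >= 3:
            lx = layer.lower()
            initial = [f"{lx}_secrete_nf", f"{lx}_sprout"]
            all_pw = list(_neuron_pathways(layer))
            if stage == 3:
                # compartments form but wiring pathways stay off
                all_pw = [p for p in all_pw
                          if "axon" not in p and "tff" not in p
                          and "synapse" not in p and "agf" not in p
                          and "acf" not in p and "dsff" not in p
                          and "dscf" not in p and "spine" not in p]
                spec["pathways"] = all_pw
                spec["initial_pathways"] = initial
            else:
                spec["pathways"] = all_pw
                spec["initial_pathways"] = initial
        types[layer] = spec
    for g in GLIA_TYPES:
        spec = {"potency": 1, "receives": ["NF"], "emits": ["GNF"],
                "pathways": []}
        if stage >= 3:
            spec["pathways"] = ["glia_secrete_gnf"]
        types[g] = spec
    return types


def _lineage(stage: int) -> list:
    edges = [("NPC", "BPC"), ("NPC", "RGC")]
    if stage >= 2:
        edges += [("BPC", "NRPC"), ("RGC", "GRPC"), ("GRPC", "T1A"),
                  ("GRPC", "OT2APC"), ("OT2APC", "ODC"), ("OT2APC", "T2A")]
        edges += [("NRPC", n) for n in NEURON_TYPES]
    return [{"from": a, "to": b} for a, b in edges]


def _stage3_sprout_fixup(pathways: dict) -> dict:
    """Stage-3-only variant of the sprout pathways: no downstream wiring."""
    out = copy.deepcopy(pathways)
    for layer in NEURON_TYPES:
        lx = layer.lower()
        pid = f"{lx}_sprout"
        if pid in out:
            out[pid]["params"]["activate"] = []
    return out


def make_organoid_config(scale: int = 1, variant: str = "I",
                         seed: int = 0) -> dict:
    """Full four-stage organoid configuration document.

    ``scale`` 1 targets roughly a thousand cells on a 64-lattice; radii and
    the NSCF source scale with the cube root of ``scale`` so the structure
    radius grows accordingly.  ``variant`` selects between the two published
    wiring/differentiation parameterizations ("I" or "II").
    """
    if scale < 1:
        raise ValueError("scale must be >= 1")
    if variant not in ("I", "II"):
        raise ValueError("variant must be 'I' or 'II'")
    s = _cube_root(scale)
    edge = int(round(64 * s))
    center = edge // 2
    ticks = int(round(1200 * s))
    pathways = {}
    pathways.update(_progenitor_pathways(variant))
    pathways.update(_stage34_shared_pathways())
    for layer in NEURON_TYPES:
        pathways.update(_neuron_pathways(layer))
    return {
        "model": {"edge": edge, "ticks": ticks, "seed": int(seed),
                  "snapshot_every": 1000, "log_level": "summary"},
        "space": {"initial": [{"type": "NSC",
                               "at": [center, center, center]}]},
        "biology": {
            "factors": _factors(scale, variant),
            "cell_types": _cell_types(stage=4),
            "pathways": pathways,
            "lineage": _lineage(stage=4),
        },
    }


def make_stage_config(stage: int, scale: int = 1, seed: int = 0,
                      variant: str = "I") -> dict:
    """Isolated sub-experiment configuration for one developmental stage.

    Stages 1-3 grow from a single stem cell with later-stage rules removed;
    stage 4 starts from a pre-placed two-layer slab (L1 and L3 neurons with
    supporting glia) so wiring can be exercised without the growth phases.
    """
    if stage not in (1, 2, 3, 4):
        raise ValueError("stage must be 1..4")
    if stage == 4:
        return _stage4_slab_config(scale, seed, variant)
    s = _cube_root(scale)
    doc = make_organoid_config(scale=scale, variant=variant, seed=seed)
    bio = doc["biology"]
    bio["cell_types"] = _cell_types(stage)
    bio["lineage"] = _lineage(stage)
    if stage == 3:
        bio["pathways"] = _stage3_sprout_fixup(bio["pathways"])
    used = set()
    for spec in bio["cell_types"].values():
        used.update(spec.get("pathways", ()))
        used.update(spec.get("initial_pathways", ()))
    closure = set(used)
    for pid in used:
        p = bio["pathways"][pid].get("params", {})
        for key in ("activate", "deactivate", "terminal_pathways"):
            closure.update(p.get(key, ()))
    bio["pathways"] = {pid: pw for pid, pw in bio["pathways"].items()
                       if pid in closure}
    doc["model"]["ticks"] = int(round({1: 400, 2: 700, 3: 800}[stage] * s))
    return doc


def _stage4_slab_config(scale: int, seed: int, variant: str) -> dict:
    edge = 20
    doc = make_organoid_config(scale=1, variant=variant, seed=seed)
    doc["model"] = {"edge": edge, "ticks": 400, "seed": int(seed),
                    "snapshot_every": 1000, "log_level": "summary"}
    # two dense neuron planes with flanking glia so the GNF handshake
    # completes quickly; the gap between the planes is axon territory
    initial = []
    for x in range(6, 14):
        for y in range(6, 14):
            initial.append({"type": "T1A", "at": [x, y, 5]})
            initial.append({"type": "L1N", "at": [x, y, 6]})
            initial.append({"type": "L3N", "at": [x, y, 10]})
            initial.append({"type": "T1A", "at": [x, y, 11]})
    doc["space"] = {"initial": initial}
    return doc
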