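"""End-to-end orchestration: load, run, snapshot, analyze, reproduce.

A run is fully determined by (configuration, seed, tick budget); the
manifest records exactly that plus content hashes, so re-running from a
manifest reproduces every data artifact bit-identically (timestamps are
informational only and excluded from the contract).
"""

from __future__ import annotations

import dataclasses
import json
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .configuration import (
    ModelConfig,
    build_initial_state,
    config_hash,
    load_config,
    serialize_config,
)
from .events import ModelState, run as run_engine
from .mechanisms import Cell
from .fixtures import NEURON_TYPES, TYPE_CLUSTERS, WIRING_SCHEME
from . import analysis


@dataclasses.dataclass
class RunManifest:
    config_hash: str
    seed: int
    ticks: int
    software_version: str
    artifacts: dict[str, str]
    wall_start: float
    wall_end: float


@dataclasses.dataclass
class SimulationResult:
    state: ModelState
    model: ModelConfig
    manifest: RunManifest

    # -- tabular views ---------------------------------------------------

    def cells_df(self) -> pd.DataFrame:
        rows = []
        for obj in self.state.objects.values():
            if not isinstance(obj, Cell):
                continue
            x, y, z = obj.position
            rows.append({
                "id": obj.id, "type": obj.type, "x": x, "y": y, "z": z,
                "status": obj.status, "born_tick": obj.born_tick,
                "removed_tick": obj.removed_tick,
                "axon_formed": obj.axon is not None,
                "dendrite_formed": obj.dendrite is not None,
                "spine_formed": obj.spine_formed,
            })
        return pd.DataFrame(rows)

    def live_cells_df(self) -> pd.DataFrame:
        df = self.cells_df()
        return df[df["status"] != "removed"].reset_index(drop=True)

    def synapses_df(self) -> pd.DataFrame:
        rows = [dataclasses.asdict(r) for r in self.state.connection_log]
        cols = ["formed_tick", "pre_id", "pre_type", "post_id", "post_type",
                "category"]
        return pd.DataFrame(rows, columns=cols)

    def axons_df(self) -> pd.DataFrame:
        rows = []
        for obj in self.state.objects.values():
            if isinstance(obj, Cell) and obj.axon is not None:
                rows.append({
                    "cell_id": obj.id, "type": obj.type,
                    "path_length": obj.axon.length,
                    "terminal_count": len(obj.axon.terminals),
                    "cone_state": obj.axon.cone,
                })
        return pd.DataFrame(
            rows, columns=["cell_id", "type", "path_length",
                           "terminal_count", "cone_state"])

    def events_df(self) -> pd.DataFrame:
        recs = [json.loads(line) for line in self.state.records]
        cols = ["tick", "owner_id", "owner_type", "pathway", "outcome",
                "coordinate", "details"]
        return pd.DataFrame(recs, columns=cols)

    def events_jsonl(self) -> str:
        return "\n".join(self.state.records) + ("\n" if self.state.records else "")

    # -- metrics ---------------------------------------------------------

    def center(self):
        e = self.model.edge
        return (e // 2, e // 2, e // 2)

    def metrics(self) -> dict:
        cells = self.cells_df()
        live = cells[cells["status"] != "removed"]
        syn = self.synapses_df()
        cdf = analysis.census(self.state.census_history)
        center = self.center()
        counts = {t: int((live["type"] == t).sum())
                  for t in sorted(live["type"].unique())}
        clusters = {c: int(cdf[c].iloc[-1]) for c in TYPE_CLUSTERS
                    if c in cdf.columns}
        conn = {}
        if len(cells):
            for layer, lc in analysis.connectivity_summary(syn, cells).items():
                conn[layer] = {
                    "neuron_count": lc.neuron_count,
                    "axon_connection_rate": lc.axon_connection_rate,
                    "dendrite_connection_rate": lc.dendrite_connection_rate,
                    "interneuron_rate": lc.interneuron_rate,
                    "repeated_fractions": lc.repeated_fractions,
                }
        entropies = {}
        medians = {}
        for t in NEURON_TYPES:
            dist = analysis.radial_distribution(live, t, center)
            if not dist.empty:
                entropies[t] = analysis.distribution_entropy(dist)
                medians[t] = dist.median
        return {
            "final_tick": self.state.tick,
            "births": self.state.birth_count,
            "deaths": self.state.death_count,
            "live_cells": int(len(live)),
            "counts_by_type": counts,
            "counts_by_cluster": clusters,
            "n_synapses": int(len(syn)),
            "connectivity": conn,
            "radial_entropy": entropies,
            "radial_median": medians,
            "glia_neuron_ratio": analysis.glia_neuron_ratio(live, center),
        }


def run_simulation(document, seed: int | None = None, ticks: int | None = None,
                   out_dir: str | Path | None = None,
                   write_fields: bool = False) -> SimulationResult:
    """Execute a configuration document end to end.

    ``seed`` and ``ticks`` override the document's values.  When ``out_dir``
    is given, writes events.jsonl, cells.csv, synapses.csv, axons.csv,
    metrics.json, resolved_config.yaml, manifest.json (and fields.csv on
    request).
    """
    model, spatial, biology = load_config(document)
    if seed is not None or ticks is not None:
        model = dataclasses.replace(
            model,
            seed=model.seed if seed is None else int(seed),
            ticks=model.ticks if ticks is None else int(ticks),
        )
    t0 = time.time()
    state = build_initial_state(model, spatial, biology)
    run_engine(state, model.ticks)
    t1 = time.time()
    manifest = RunManifest(
        config_hash=config_hash(model, spatial, biology),
        seed=model.seed,
        ticks=model.ticks,
        software_version=__version__,
        artifacts={},
        wall_start=t0,
        wall_end=t1,
    )
    result = SimulationResult(state=state, model=model, manifest=manifest)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "events.jsonl").write_text(result.events_jsonl())
        result.cells_df().to_csv(out / "cells.csv", index=False)
        result.synapses_df().to_csv(out / "synapses.csv", index=False)
        result.axons_df().to_csv(out / "axons.csv", index=False)
        (out / "resolved_config.yaml").write_text(
            serialize_config(model, spatial, biology))
        (out / "metrics.json").write_text(
            json.dumps(result.metrics(), indent=2, default=float))
        if write_fields:
            rows = []
            for name, field in state.fields.items():
                for (x, y, z), v in field.nonzero_items():
                    rows.append((state.tick, name, x, y, z, v))
            pd.DataFrame(
                rows, columns=["tick", "factor", "x", "y", "z",
                               "concentration"]
            ).to_csv(out / "fields.csv", index=False)
        manifest.artifacts = {
            p.name: p.name for p in sorted(out.iterdir()) if p.is_file()
        }
        (out / "manifest.json").write_text(
            json.dumps(dataclasses.asdict(manifest), indent=2))
    return result


def run_replicates(document, seeds, ticks: int | None = None,
                   out_dir: str | Path | None = None) -> dict:
    """Run one configuration under several seeds and aggregate the metrics.

    Reports per-seed metrics plus mean and standard deviation (sample SD;
    reported as 0 with an ``n=1`` flag for a single replicate) for every
    scalar metric, plus a failure list for replicates that raised.
    """
    seeds = list(seeds)
    if not seeds:
        raise ValueError("at least one seed is required")
    per_seed: dict[int, dict] = {}
    failures: dict[int, str] = {}
    for s in seeds:
        try:
            per_seed[s] = run_simulation(document, seed=s, ticks=ticks).metrics()
        except Exception as exc:  # noqa: BLE001 - reported, not swallowed
            failures[s] = f"{type(exc).__name__}: {exc}"

    def _scalars(prefix: str, node, into: dict):
        if isinstance(node, dict):
            for k, v in node.items():
                _scalars(f"{prefix}.{k}" if prefix else str(k), v, into)
        elif isinstance(node, (int, float)) and node is not None:
            into[prefix] = float(node)

    tables: dict[str, list[float]] = {}
    for s, m in per_seed.items():
        flat: dict[str, float] = {}
        _scalars("", m, flat)
        for k, v in flat.items():
            tables.setdefault(k, []).append(v)
    n = len(per_seed)
    aggregate = {}
    for k, vals in tables.items():
        if len(vals) != n:
            continue
        arr = np.asarray(vals)
        aggregate[k] = {
            "mean": float(arr.mean()),
            "sd": 0.0 if n == 1 else float(arr.std(ddof=1)),
            "n": n,
        }
    out = {"per_seed": per_seed, "aggregate": aggregate,
           "failures": failures, "n_replicates": n}
    if out_dir is not None:
        outp = Path(out_dir)
        outp.mkdir(parents=True, exist_ok=True)
        (outp / "replicates.json").write_text(
            json.dumps(out, indent=2, default=float))
    return out
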