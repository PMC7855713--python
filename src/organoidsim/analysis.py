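"""Metrics over simulation outputs: censuses, layering, connectivity.

All operations take plain pandas DataFrames (the tables the runner writes)
so they work equally on in-memory results and on re-loaded CSV artifacts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .fixtures import GLIA_TYPES, NEURON_TYPES, TYPE_CLUSTERS

RADIAL_BINS = 20


# ---------------------------------------------------------------------------
# Census dynamics
# ---------------------------------------------------------------------------


def census(census_history: list[tuple[int, dict[str, int]]],
           clusters: dict[str, tuple[str, ...]] | None = None) -> pd.DataFrame:
    """Per-tick live counts per cell type, plus cluster and total columns."""
    if not census_history:
        raise ValueError("empty census history")
    clusters = TYPE_CLUSTERS if clusters is None else clusters
    rows = []
    for tick, counts in census_history:
        row = {"tick": tick}
        row.update(counts)
        rows.append(row)
    df = pd.DataFrame(rows).fillna(0).set_index("tick")
    df = df.astype(int)
    for cname, members in clusters.items():
        present = [m for m in members if m in df.columns]
        df[cname] = df[present].sum(axis=1) if present else 0
    df["total"] = df[[c for c in df.columns if c not in clusters]].sum(axis=1)
    return df


def check_census_conservation(df: pd.DataFrame, births: int, deaths: int,
                              initial: int) -> bool:
    """Live count must reconcile as initial + births - deaths."""
    final = int(df["total"].iloc[-1])
    return final == initial + births - deaths


def stem_progenitor_ratio(df: pd.DataFrame, at_ticks,
                          stem=("MP",), progenitor=("NP", "GP")) -> list:
    """Stem-pool to progenitor-pool ratio at the queried ticks.

    Returns one entry per tick; a zero denominator yields None (flagged
    undefined) rather than infinity.
    """
    out = []
    for t in at_ticks:
        row = df.loc[df.index.asof(t)] if t not in df.index else df.loc[t]
        num = float(sum(row.get(c, 0) for c in stem))
        den = float(sum(row.get(c, 0) for c in progenitor))
        out.append(None if den == 0 else num / den)
    return out


# ---------------------------------------------------------------------------
# Spatial distributions
# ---------------------------------------------------------------------------


@dataclass
class RadialDistribution:
    cell_type: str
    distances: np.ndarray  # normalized to [0, 1]
    histogram: np.ndarray  # RADIAL_BINS probabilities summing to 1
    empty: bool = False

    @property
    def median(self) -> float:
        return float(np.median(self.distances)) if not self.empty else math.nan


def _distances(cells: pd.DataFrame, center) -> np.ndarray:
    d = cells[["x", "y", "z"]].to_numpy(dtype=float) - np.asarray(center, float)
    return np.sqrt((d**2).sum(axis=1))


def radial_distribution(cells: pd.DataFrame, cell_type: str, center,
                        norm_types=NEURON_TYPES) -> RadialDistribution:
    """Normalized radial distances of one cell type, binned into a histogram.

    Distances are Euclidean from the structure center (the founding stem
    cell's coordinate) and normalized by the maximum over all ``norm_types``
    cells so that 1.0 is the outermost neuron.
    """
    live = cells[cells["removed_tick"].isna()] if "removed_tick" in cells else cells
    ref = live[live["type"].isin(norm_types)]
    sel = live[live["type"] == cell_type]
    if len(sel) == 0:
        return RadialDistribution(cell_type, np.array([]),
                                  np.zeros(RADIAL_BINS), empty=True)
    dmax = _distances(ref, center).max() if len(ref) else 1.0
    dmax = dmax if dmax > 0 else 1.0
    dist = np.minimum(_distances(sel, center) / dmax, 1.0)
    hist, _ = np.histogram(dist, bins=RADIAL_BINS, range=(0.0, 1.0))
    total = hist.sum()
    return RadialDistribution(cell_type, dist,
                              hist / total if total else hist.astype(float))


def distribution_entropy(dist: RadialDistribution) -> float:
    """Shannon entropy (natural log) of the binned radial distribution."""
    p = dist.histogram
    p = p[p > 0]
    return float(-(p * np.log(p)).sum()) if p.size else 0.0


# ---------------------------------------------------------------------------
# Connectivity
# ---------------------------------------------------------------------------


@dataclass
class LayerConnectivity:
    layer: str
    neuron_count: int
    axon_formed: int
    dendrite_formed: int
    axon_connection_rate: float | None
    dendrite_connection_rate: float | None
    interneuron_rate: float | None
    out_degrees: pd.Series
    in_degrees: pd.Series
    repeated_fractions: dict[str, float]


def connectivity_summary(synapses: pd.DataFrame, cells: pd.DataFrame,
                         layers=NEURON_TYPES) -> dict[str, LayerConnectivity]:
    """Per-layer connection rates, degree distributions, repetition classes.

    Rates follow the compartment-denominator convention: the proportion of
    neurons in a layer with at least one outgoing (incoming) connection
    among the neurons of that layer that successfully formed an axon
    (dendrite); the interneuron rate counts neurons with both, among those
    that formed both compartments.
    """
    known = set(cells["id"])
    if len(synapses):
        dangling = set(synapses["pre_id"]) | set(synapses["post_id"])
        dangling -= known
        if dangling:
            raise ValueError(f"synapse table references unknown cells: "
                             f"{sorted(dangling)}")
    out: dict[str, LayerConnectivity] = {}
    for layer in layers:
        sel = cells[(cells["type"] == layer)]
        ids = set(sel["id"])
        axon_formed = sel["axon_formed"].fillna(False).astype(bool)
        dend_formed = sel["dendrite_formed"].fillna(False).astype(bool)
        outgoing = synapses[synapses["pre_id"].isin(ids)] if len(synapses) \
            else synapses
        incoming = synapses[synapses["post_id"].isin(ids)] if len(synapses) \
            else synapses
        has_out = set(outgoing["pre_id"]) if len(outgoing) else set()
        has_in = set(incoming["post_id"]) if len(incoming) else set()
        n_axon = int(axon_formed.sum())
        n_dend = int(dend_formed.sum())
        axon_ids = set(sel[axon_formed]["id"])
        dend_ids = set(sel[dend_formed]["id"])
        both_ids = axon_ids & dend_ids
        rate = lambda hits, denom: (len(hits) / denom) if denom else None
        reps = {"single": 0.0, "sequentially-repeated": 0.0,
                "non-sequentially-repeated": 0.0}
        if len(outgoing):
            frac = outgoing["category"].value_counts(normalize=True)
            for k in reps:
                reps[k] = float(frac.get(k, 0.0))
        out[layer] = LayerConnectivity(
            layer=layer,
            neuron_count=len(sel),
            axon_formed=n_axon,
            dendrite_formed=n_dend,
            axon_connection_rate=rate(has_out & axon_ids, n_axon),
            dendrite_connection_rate=rate(has_in & dend_ids, n_dend),
            interneuron_rate=rate(has_out & has_in & both_ids, len(both_ids)),
            out_degrees=(outgoing.groupby("pre_id").size()
                         if len(outgoing) else pd.Series(dtype=int)),
            in_degrees=(incoming.groupby("post_id").size()
                        if len(incoming) else pd.Series(dtype=int)),
            repeated_fractions=reps,
        )
    return out


def pairing_conservation(synapses: pd.DataFrame,
                         wiring: dict[str, str]) -> bool:
    """Outgoing connections of each source layer equal the incoming of its
    target layer, exactly (each synapse is one ordered pair)."""
    for src, dst in wiring.items():
        n_out = int((synapses["pre_type"] == src).sum()) if len(synapses) else 0
        n_in = int((synapses["post_type"] == dst).sum()) if len(synapses) else 0
        if n_out != n_in:
            return False
    return True


# ---------------------------------------------------------------------------
# Axons and glia
# ---------------------------------------------------------------------------


def axon_length_stats(axons: pd.DataFrame,
                      layers=NEURON_TYPES) -> pd.DataFrame:
    """Per-layer axon count, total/mean length and length-to-count ratio."""
    rows = []
    for layer in layers:
        sel = axons[axons["type"] == layer]
        n = len(sel)
        total = float(sel["path_length"].sum()) if n else 0.0
        rows.append({
            "layer": layer,
            "axon_count": n,
            "total_length": total,
            "length_to_count_ratio": (total / n) if n else None,
        })
    return pd.DataFrame(rows).set_index("layer")


def glia_neuron_ratio(cells: pd.DataFrame, center,
                      layers=NEURON_TYPES,
                      glia_types=GLIA_TYPES) -> dict[str, float | None]:
    """Glia-to-neuron ratio per layer band.

    Glia are not assigned layers by the lineage, so each layer's band is the
    10th-90th percentile of that layer's neuron radial distances; the ratio
    is glia within the band over neurons of the layer.
    """
    live = cells[cells["removed_tick"].isna()] if "removed_tick" in cells else cells
    glia = live[live["type"].isin(glia_types)]
    gdist = _distances(glia, center) if len(glia) else np.array([])
    out: dict[str, float | None] = {}
    for layer in layers:
        sel = live[live["type"] == layer]
        if len(sel) == 0:
            out[layer] = None
            continue
        nd = _distances(sel, center)
        lo, hi = np.percentile(nd, [10, 90])
        n_glia = int(((gdist >= lo) & (gdist <= hi)).sum()) if gdist.size else 0
        out[layer] = n_glia / len(sel)
    return out


def first_appearance_ticks(events: pd.DataFrame,
                           types=NEURON_TYPES) -> dict[str, int | None]:
    """Tick of the first differentiation into each given type."""
    out: dict[str, int | None] = {}
    diff = events[events["outcome"] == "differentiated"]
    for t in types:
        sel = diff[diff["details"].apply(lambda d: d.get("to") == t)]
        out[t] = int(sel["tick"].min()) if len(sel) else None
    return out
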