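"""Analysis operations against hand-built tables and closed forms."""

import math

import numpy as np
import pandas as pd
import pytest

from organoidsim import analysis
from organoidsim.analysis import RADIAL_BINS, RadialDistribution


def make_history(rows):
    return [(t, dict(c)) for t, c in rows]


def cells_frame(rows):
    df = pd.DataFrame(rows, columns=["id", "type", "x", "y", "z",
                                     "axon_formed", "dendrite_formed"])
    df["removed_tick"] = np.nan
    return df


# ---------------------------------------------------------------------------
# Census
# ---------------------------------------------------------------------------


def test_census_counts_and_clusters():
    hist = make_history([(0, {"NSC": 1}), (1, {"NSC": 1, "NPC": 1})])
    df = analysis.census(hist)
    assert df.loc[0, "total"] == 1 and df.loc[1, "total"] == 2
    assert df.loc[1, "MP"] == 2  # NSC + NPC cluster


def test_census_conservation_with_divisions_and_deaths():
    initial, d, k = 5, 7, 3
    hist = make_history([(0, {"C": initial}), (9, {"C": initial + d - k})])
    df = analysis.census(hist, clusters={})
    assert analysis.check_census_conservation(df, births=initial + d,
                                              deaths=k, initial=0)


def test_stem_progenitor_ratio_cases():
    hist = make_history([
        (0, {"NSC": 4, "BPC": 2}),
        (1, {"NSC": 2, "BPC": 0}),
    ])
    df = analysis.census(hist)
    assert analysis.stem_progenitor_ratio(df, [0]) == [2.0]
    assert analysis.stem_progenitor_ratio(df, [1]) == [None], \
        "zero denominator is flagged undefined, not infinite"


def test_stem_progenitor_ratio_monotone_decline():
    rows = [(t, {"NSC": 40 - 3 * t, "BPC": 10 + 5 * t}) for t in range(5)]
    df = analysis.census(make_history(rows))
    ratios = analysis.stem_progenitor_ratio(df, range(5))
    assert all(a > b for a, b in zip(ratios, ratios[1:]))


# ---------------------------------------------------------------------------
# Radial distributions and entropy
# ---------------------------------------------------------------------------


def test_radial_point_mass_at_center():
    cells = cells_frame([(i, "L1N", 5, 5, 5, False, False) for i in range(4)])
    dist = analysis.radial_distribution(cells, "L1N", (5, 5, 5))
    assert dist.histogram[0] == 1.0
    assert analysis.distribution_entropy(dist) == 0.0


def test_radial_shell_concentrates_in_shell_bins():
    rows = []
    i = 0
    for dx, dy, dz in [(6, 0, 0), (-6, 0, 0), (0, 6, 0), (0, -6, 0)]:
        rows.append((i, "L1N", 8 + dx, 8 + dy, 8 + dz, False, False))
        i += 1
    rows.append((i, "L1N", 8 + 8, 8, 8))  # outermost neuron sets the scale
    cells = cells_frame([r + (False, False) if len(r) == 5 else r
                         for r in rows])
    dist = analysis.radial_distribution(cells, "L1N", (8, 8, 8))
    shell_bin = int((6 / 8) * RADIAL_BINS)
    assert dist.histogram[shell_bin] == 0.8


def test_radial_empty_type_is_flagged():
    cells = cells_frame([(0, "L1N", 5, 5, 5, False, False)])
    dist = analysis.radial_distribution(cells, "L4N", (5, 5, 5))
    assert dist.empty and math.isnan(dist.median)


def test_entropy_uniform_equals_log_bins():
    hist = np.full(RADIAL_BINS, 1.0 / RADIAL_BINS)
    dist = RadialDistribution("X", np.array([]), hist)
    assert analysis.distribution_entropy(dist) == pytest.approx(
        math.log(RADIAL_BINS))


def test_entropy_matches_direct_sum():
    rng = np.random.default_rng(5)
    p = rng.random(RADIAL_BINS)
    p /= p.sum()
    dist = RadialDistribution("X", np.array([]), p)
    expected = -sum(v * math.log(v) for v in p if v > 0)
    assert analysis.distribution_entropy(dist) == pytest.approx(expected)
    assert 0.0 <= expected <= math.log(RADIAL_BINS)


# ---------------------------------------------------------------------------
# Connectivity
# ---------------------------------------------------------------------------


def synapse_frame(rows):
    return pd.DataFrame(rows, columns=["formed_tick", "pre_id", "pre_type",
                                       "post_id", "post_type", "category"])


def test_axon_connection_rate_uses_compartment_denominator():
    cells = cells_frame(
        [(i, "L1N", i, 0, 0, True, False) for i in range(10)]
        + [(100, "L3N", 0, 5, 0, False, True)]
    )
    syn = synapse_frame([(5, i, "L1N", 100, "L3N", "single")
                         for i in range(9)])
    summary = analysis.connectivity_summary(syn, cells)
    assert summary["L1N"].axon_connection_rate == pytest.approx(0.9)
    assert summary["L3N"].dendrite_connection_rate == pytest.approx(1.0)
    assert summary["L3N"].in_degrees.iloc[0] == 9


def test_dangling_synapse_ids_rejected():
    cells = cells_frame([(1, "L1N", 0, 0, 0, True, False)])
    syn = synapse_frame([(5, 1, "L1N", 999, "L3N", "single")])
    with pytest.raises(ValueError, match="999"):
        analysis.connectivity_summary(syn, cells)


def test_repeated_connection_fractions():
    cells = cells_frame([(1, "L1N", 0, 0, 0, True, False),
                         (2, "L3N", 1, 0, 0, False, True),
                         (3, "L3N", 2, 0, 0, False, True)])
    # history B, B, C, B -> single, seq-repeated, single, non-seq-repeated
    syn = synapse_frame([
        (1, 1, "L1N", 2, "L3N", "single"),
        (2, 1, "L1N", 2, "L3N", "sequentially-repeated"),
        (3, 1, "L1N", 3, "L3N", "single"),
        (4, 1, "L1N", 2, "L3N", "non-sequentially-repeated"),
    ])
    reps = analysis.connectivity_summary(syn, cells)["L1N"].repeated_fractions
    assert reps["sequentially-repeated"] == pytest.approx(0.25)
    assert reps["non-sequentially-repeated"] == pytest.approx(0.25)


def test_pairing_conservation_on_organoid(organoid_run_I):
    syn = organoid_run_I.synapses_df()
    assert analysis.pairing_conservation(
        syn, {"L1N": "L3N", "L3N": "L2N", "L2N": "L4N"})
    # and exactly, per ordered pair
    for src, dst in (("L1N", "L3N"), ("L3N", "L2N"), ("L2N", "L4N")):
        assert (syn["pre_type"] == src).sum() == (syn["post_type"] == dst).sum()


# ---------------------------------------------------------------------------
# Axon lengths and glia ratios
# ---------------------------------------------------------------------------


def test_axon_length_ratio():
    axons = pd.DataFrame({"cell_id": [1, 2], "type": ["L1N", "L1N"],
                          "path_length": [3, 5]})
    stats = analysis.axon_length_stats(axons)
    assert stats.loc["L1N", "length_to_count_ratio"] == pytest.approx(4.0)
    assert pd.isna(stats.loc["L2N", "length_to_count_ratio"])


def test_glia_neuron_ratio_cases():
    rows = [(0, "L1N", 7, 5, 5, False, False)]
    rows += [(i, "T1A", 3, 5, 5, False, False) for i in range(1, 7)]
    cells = cells_frame(rows)
    ratios = analysis.glia_neuron_ratio(cells, (5, 5, 5))
    assert ratios["L1N"] == pytest.approx(6.0)  # 6 glia in the layer band
    assert ratios["L4N"] is None  # empty layer flagged
    no_glia = cells_frame([(0, "L1N", 7, 5, 5, False, False)])
    assert analysis.glia_neuron_ratio(no_glia, (5, 5, 5))["L1N"] == 0.0


def test_within_variant_axon_ratios_closer_than_between(organoid_run_I,
                                                        organoid_run_II):
    """The length-to-count ratio depends on the configuration more than on
    the seed: the two variants differ more than the same variant re-run."""
    import organoidsim as osim
    alt = osim.run_simulation(osim.make_organoid_config(1, "I", seed=2))
    runs = {"I@1": organoid_run_I, "I@2": alt, "II@1": organoid_run_II}
    ratios = {}
    for k, r in runs.items():
        stats = analysis.axon_length_stats(r.axons_df())
        ratios[k] = stats.loc["L1N", "length_to_count_ratio"]
    within = abs(ratios["I@1"] - ratios["I@2"])
    between = abs(ratios["I@1"] - ratios["II@1"])
    assert between > within
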