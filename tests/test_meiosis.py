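"""Meiosis simulator: crossover model, conversions, packaging, truth log."""

import math

import numpy as np
import pytest

from helpers import replay_truth_origins
from pseudobipolar.meiosis import (
    HET,
    P1,
    P2,
    Hotspot,
    MarkerMap,
    SimConfig,
    haldane_rf,
    package_teliospore,
    simulate_cross_experiment,
    simulate_meiosis,
)

NO_EVENTS = dict(conversion_rate_per_marker=0.0, p_diploid=0.0, p_recover_both_spores=0.0)


@pytest.fixture
def linear_map():
    return MarkerMap.from_records(
        [("s1", f"m{i}", 100.0 * i) for i in range(1, 6)]
    )


def test_marker_map_validation():
    with pytest.raises(ValueError):
        MarkerMap.from_records([("s", "a", 10.0), ("s", "b", 10.0)])  # not increasing
    with pytest.raises(ValueError):
        MarkerMap.from_records([("s", "a", 10.0), ("t", "a", 20.0)])  # duplicate name
    with pytest.raises(ValueError):
        simulate_meiosis(MarkerMap.from_records([]), SimConfig(), np.random.default_rng(0))


def test_no_event_meiosis_yields_pure_parental_products(linear_map):
    config = SimConfig(kb_per_cM_baseline=1e12, **NO_EVENTS)
    rng = np.random.default_rng(0)
    products, truth = simulate_meiosis(linear_map, config, rng)
    assert truth["crossovers"] == [] and truth["conversions"] == []
    pure = sorted("".join(sorted(set(p.origins.values()))) for p in products)
    assert pure == [P1, P1, P2, P2]


@pytest.mark.parametrize("seed", [0, 1, 2, 3])
def test_reciprocity_two_to_two_without_conversion(linear_map, seed):
    """Each marker carries exactly two P1 and two P2 alleles over the tetrad."""
    config = SimConfig(kb_per_cM_baseline=5.0, **NO_EVENTS)
    rng = np.random.default_rng(seed)
    products, _ = simulate_meiosis(linear_map, config, rng)
    for marker in linear_map.markers:
        calls = [p.origins[marker] for p in products]
        assert sorted(calls) == [P1, P1, P2, P2]


def test_conversion_breaks_reciprocity_three_to_one(linear_map):
    """Markers covered by exactly one logged tract show a 3:1 ratio."""
    config = SimConfig(
        kb_per_cM_baseline=1e12,
        conversion_rate_per_marker=0.2,
        conversion_tract_mean_kb=1.0,
        p_diploid=0.0,
        p_recover_both_spores=0.0,
    )
    rng = np.random.default_rng(42)
    saw_converted = False
    for _ in range(20):
        products, truth = simulate_meiosis(linear_map, config, rng)
        coverage = {m: 0 for m in linear_map.markers}
        for conv in truth["conversions"]:
            for m in conv["markers"]:
                coverage[m] += 1
        for marker, n_tracts in coverage.items():
            calls = sorted(p.origins[marker] for p in products)
            if n_tracts == 0:
                assert calls == [P1, P1, P2, P2]
            elif n_tracts == 1:
                saw_converted = True
                assert calls in ([P1, P1, P1, P2], [P1, P2, P2, P2])
    assert saw_converted


def test_products_match_truth_log_replay(linear_map):
    """Products are reconstructible from founders + logged events alone."""
    config = SimConfig(
        kb_per_cM_baseline=3.0,
        conversion_rate_per_marker=0.05,
        conversion_tract_mean_kb=1.0,
        p_diploid=0.0,
    )
    rng = np.random.default_rng(7)
    for _ in range(25):
        products, truth = simulate_meiosis(linear_map, config, rng)
        replayed = replay_truth_origins(truth, linear_map)
        for p in products:
            assert p.origins == replayed[p.product]


def test_recombinant_fraction_follows_haldane():
    """Two markers 320 kb apart at 32 kb/cM: RF ~ (1-e^(-0.2))/2 ~ 0.10."""
    marker_map = MarkerMap.from_records([("s", "a", 1.0), ("s", "b", 321.0)])
    config = SimConfig(kb_per_cM_baseline=32.0, **NO_EVENTS)
    rng = np.random.default_rng(11)
    recombinant = total = 0
    for _ in range(2500):
        products, _ = simulate_meiosis(marker_map, config, rng)
        for p in products:
            total += 1
            recombinant += p.origins["a"] != p.origins["b"]
    expected = haldane_rf(320.0, 32.0)
    assert expected == pytest.approx(0.0906, abs=1e-3)
    assert abs(recombinant / total - expected) < 0.015


def test_rf_increases_with_distance_and_caps_at_half():
    marker_map = MarkerMap.from_records(
        [("s", "a", 0.0), ("s", "b", 150.0), ("s", "c", 800.0), ("s", "d", 6000.0)]
    )
    config = SimConfig(kb_per_cM_baseline=32.0, **NO_EVENTS)
    rng = np.random.default_rng(2)
    counts = {pair: 0 for pair in [("a", "b"), ("a", "c"), ("a", "d")]}
    n = 0
    for _ in range(1500):
        products, _ = simulate_meiosis(marker_map, config, rng)
        for p in products:
            n += 1
            for x, y in counts:
                counts[(x, y)] += p.origins[x] != p.origins[y]
    rfs = {pair: c / n for pair, c in counts.items()}
    for (x, y), rf in rfs.items():
        d = marker_map.position(y) - marker_map.position(x)
        assert abs(rf - haldane_rf(d, 32.0)) < 0.02
    assert rfs[("a", "b")] < rfs[("a", "c")] <= rfs[("a", "d")] + 0.02
    assert all(rf <= 0.55 for rf in rfs.values())


def test_hotspot_concentrates_crossovers():
    marker_map = MarkerMap.from_records(
        [("s", "left", 10.0), ("s", "h1", 1200.0), ("s", "h2", 1227.0)]
    )
    config = SimConfig(
        kb_per_cM_baseline=32.0,
        hotspots=(Hotspot("s", 1200.0, 1227.0, 0.63),),
        **NO_EVENTS,
    )
    rng = np.random.default_rng(5)
    inside = outside = 0
    for _ in range(1000):
        _, truth = simulate_meiosis(marker_map, config, rng)
        for ev in truth["crossovers"]:
            if 1200.0 <= ev["pos_kb"] < 1227.0:
                inside += 1
            else:
                outside += 1
    density_in = inside / 27.0
    density_out = outside / (1227.0 - 27.0)
    assert density_in > 10 * density_out


def test_unlinked_scaffolds_assort_independently():
    marker_map = MarkerMap.from_records([("sA", "a", 0.0), ("sB", "b", 0.0)])
    config = SimConfig(kb_per_cM_baseline=1e12, **NO_EVENTS)
    rng = np.random.default_rng(3)
    parental_ditype = 0
    n = 400
    for _ in range(n):
        products, _ = simulate_meiosis(marker_map, config, rng)
        combos = {(p.origins["a"], p.origins["b"]) for p in products}
        assert len(combos) == 2  # whole-chromosome assortment: two classes per meiosis
        parental_ditype += combos == {(P1, P1), (P2, P2)}
    # MI orientation is a fair coin: parental and non-parental ditypes ~ 50:50
    assert 0.4 < parental_ditype / n < 0.6


def test_packaging_diploid_and_single_spore_recovery(linear_map):
    rng = np.random.default_rng(0)
    config = SimConfig(kb_per_cM_baseline=1e12, **NO_EVENTS)
    products, _ = simulate_meiosis(linear_map, config, rng)

    recovered, outcome = package_teliospore(
        products, SimConfig(p_diploid=1.0), np.random.default_rng(1)
    )
    assert outcome == "DIPLOID"
    assert all(v == HET for v in recovered[0].origins.values())

    recovered, outcome = package_teliospore(
        products, SimConfig(p_diploid=0.0, p_recover_both_spores=0.0), np.random.default_rng(1)
    )
    assert outcome == "HAPLOID_ONE_SPORE" and len(recovered) == 1

    with pytest.raises(ValueError):
        package_teliospore(products[:3], config, rng)


def test_both_spore_recovery_rate_matches_config(linear_map):
    """At p_recover_both_spores = 1/8, about one in eight teliospores yields both."""
    config = SimConfig(
        kb_per_cM_baseline=1e12,
        conversion_rate_per_marker=0.0,
        p_diploid=0.0,
        p_recover_both_spores=1 / 8,
    )
    rng = np.random.default_rng(9)
    both = 0
    n = 800
    for _ in range(n):
        products, _ = simulate_meiosis(linear_map, config, rng)
        _, outcome = package_teliospore(products, config, rng)
        both += outcome == "HAPLOID_BOTH_SPORES"
    se = math.sqrt(0.125 * 0.875 / n)
    assert abs(both / n - 0.125) < 4 * se


def test_cross_experiment_structure_and_clonality(linear_map):
    config = SimConfig(kb_per_cM_baseline=1e12, seed=1, **NO_EVENTS)
    table, truth = simulate_cross_experiment(linear_map, config, n_teliospores=8, colonies_per_teliospore=3)
    assert len(table) == 24
    assert list(table.columns) == ["teliospore", "colony", *linear_map.markers]
    markers = linear_map.markers
    for telio, sub in table.groupby("teliospore"):
        assert len(sub[markers].drop_duplicates()) <= 2
        # rate-0 config: every colony is pure parental
        assert set(np.unique(sub[markers].to_numpy())) <= {P1, P2}
    assert len(truth) == 8
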