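"""Segregation analysis: origin assignment, event calling, linkage, cohesion."""

import math

import numpy as np
import pandas as pd
import pytest

from helpers import replay_truth_origins
from pseudobipolar import fixtures as fx
from pseudobipolar.meiosis import HET, MISSING, P1, P2, MarkerMap, SimConfig, simulate_meiosis
from pseudobipolar.segregation import (
    EventKind,
    LinkageClass,
    assign_origin,
    call_events,
    collapse_products,
    detect_diploid,
    infer_scaffold_orientation,
    mat_cohesion_summary,
    recombination_fraction,
)


@pytest.fixture
def four_marker_map():
    return MarkerMap.from_records([("s", f"m{i}", 100.0 * i) for i in range(1, 5)])


def _origins(calls, markers=None):
    markers = markers or [f"m{i}" for i in range(1, len(calls) + 1)]
    return dict(zip(markers, calls))


# ---------------------------------------------------------------- assign_origin

def test_assign_origin_translates_allele_calls():
    parental = {"m1": ("a", "b"), "m2": ("c", "d")}
    raw = pd.DataFrame(
        {
            "teliospore": ["T1", "T1", "T2"],
            "colony": ["T1.1", "T1.2", "T2.1"],
            "m1": ["a", "b", "a/b"],
            "m2": ["c", "d", ""],
        }
    )
    out = assign_origin(raw, parental)
    assert list(out["m1"]) == [P1, P2, HET]
    assert list(out["m2"]) == [P1, P2, MISSING]


def test_assign_origin_drops_uninformative_markers_and_rejects_unknowns():
    parental = {"m1": ("a", "b"), "same": ("x", "x")}
    raw = pd.DataFrame({"colony": ["c1"], "m1": ["a"], "same": ["x"]})
    with pytest.warns(UserWarning, match="uninformative"):
        out = assign_origin(raw, parental)
    assert "same" not in out.columns
    with pytest.raises(KeyError):
        assign_origin(pd.DataFrame({"colony": ["c1"], "new": ["a"]}), parental)
    with pytest.raises(ValueError, match="neither parent"):
        assign_origin(pd.DataFrame({"colony": ["c1"], "m1": ["z"]}), parental)


def test_assign_origin_matches_simulator_truth(four_marker_map):
    """Raw alleles built from simulated origins round-trip exactly."""
    config = SimConfig(kb_per_cM_baseline=5.0, conversion_rate_per_marker=0.05,
                       conversion_tract_mean_kb=1.0, p_diploid=0.0)
    rng = np.random.default_rng(13)
    products, truth = simulate_meiosis(four_marker_map, config, rng)
    parental = {m: (f"{m}_1", f"{m}_2") for m in four_marker_map.markers}
    raw = pd.DataFrame(
        [
            {
                "colony": f"c{p.product}",
                **{
                    m: parental[m][0] if p.origins[m] == P1 else parental[m][1]
                    for m in four_marker_map.markers
                },
            }
            for p in products
        ]
    )
    out = assign_origin(raw, parental)
    replayed = replay_truth_origins(truth, four_marker_map)
    for i, p in enumerate(products):
        row = out.iloc[i]
        assert {m: row[m] for m in four_marker_map.markers} == replayed[p.product]


# --------------------------------------------------------------- detect_diploid

def test_detect_diploid_thresholds():
    assert detect_diploid(_origins([HET] * 5))
    assert not detect_diploid(_origins([P1] * 5))
    one_het = _origins([HET] + [P1] * 13)
    assert not detect_diploid(one_het)  # default requires HET everywhere
    assert detect_diploid(one_het, min_het_fraction=1 / 14)
    assert not detect_diploid(_origins([MISSING] * 3))
    with pytest.raises(ValueError):
        detect_diploid(_origins([P1]), min_het_fraction=0.0)


# ------------------------------------------------------------------ call_events

def test_single_switch_is_one_crossover(four_marker_map):
    events = call_events(_origins([P1, P1, P2, P2]), four_marker_map)
    assert [e.kind for e in events] == [EventKind.CROSSOVER]
    assert events[0].start_kb == 200.0 and events[0].end_kb == 300.0


def test_internal_single_marker_run_is_a_conversion(four_marker_map):
    events = call_events(_origins([P1, P2, P1, P1]), four_marker_map)
    assert [e.kind for e in events] == [EventKind.CONVERSION]
    assert events[0].markers == ("m2",)


def test_two_marker_internal_run_gives_two_crossovers(four_marker_map):
    events = call_events(_origins([P1, P2, P2, P1]), four_marker_map)
    assert [e.kind for e in events] == [EventKind.CROSSOVER, EventKind.CROSSOVER]


def test_conversion_span_limit(four_marker_map):
    # the intruding run spans 0 kb (single marker) but a 2-marker allowance
    # with a tight kb limit still rejects a wide run
    events = call_events(
        _origins([P1, P2, P2, P1]), four_marker_map,
        max_conversion_markers=2, max_conversion_kb=50.0,
    )
    assert [e.kind for e in events] == [EventKind.CROSSOVER, EventKind.CROSSOVER]
    events = call_events(
        _origins([P1, P2, P2, P1]), four_marker_map,
        max_conversion_markers=2, max_conversion_kb=150.0,
    )
    assert [e.kind for e in events] == [EventKind.CONVERSION]


def test_alternating_short_runs_do_not_overcall_conversions():
    marker_map = MarkerMap.from_records([("s", f"m{i}", 100.0 * i) for i in range(1, 6)])
    events = call_events(_origins([P1, P2, P1, P2, P1]), marker_map)
    kinds = sorted(e.kind for e in events)
    assert kinds == [EventKind.CONVERSION, EventKind.CONVERSION]
    assert sorted(e.markers for e in events) == [("m2",), ("m4",)]


def test_terminal_runs_not_conversions(four_marker_map):
    events = call_events(_origins([P2, P1, P1, P1]), four_marker_map)
    assert [e.kind for e in events] == [EventKind.CROSSOVER]
    events = call_events(
        _origins([P2, P1, P1, P1]), four_marker_map, terminal_ambiguous=True
    )
    assert [e.kind for e in events] == [EventKind.AMBIGUOUS]
    assert events[0].markers == ("m1",)


def test_missing_markers_widen_crossover_interval(four_marker_map):
    events = call_events(_origins([P1, MISSING, P2, P2]), four_marker_map)
    assert [e.kind for e in events] == [EventKind.CROSSOVER]
    assert (events[0].start_kb, events[0].end_kb) == (100.0, 300.0)


def test_call_events_invariant_under_parent_relabeling(four_marker_map):
    calls = [P1, P2, P1, P1]
    flipped = [P2 if c == P1 else P1 for c in calls]
    ev_a = call_events(_origins(calls), four_marker_map)
    ev_b = call_events(_origins(flipped), four_marker_map)
    assert [(e.kind, e.start_kb, e.end_kb, e.markers) for e in ev_a] == [
        (e.kind, e.start_kb, e.end_kb, e.markers) for e in ev_b
    ]
    # deterministic: calling twice yields identical events
    assert ev_a == call_events(_origins(calls), four_marker_map)


def test_call_events_rejects_het(four_marker_map):
    with pytest.raises(ValueError, match="detect_diploid"):
        call_events(_origins([P1, HET, P2, P2]), four_marker_map)


# ------------------------------------------------------- recombination_fraction

def test_hotspot_worked_example_yields_063_kb_per_cm():
    table, marker_map = fx.hotspot_fixture()
    res = recombination_fraction(table, "RecQ", "HD", marker_map=marker_map)
    assert (res.n_recombinant, res.n_informative) == (3, 7)
    assert res.rf == pytest.approx(3 / 7)
    assert res.map_distance_cM == pytest.approx(300 / 7)
    assert res.kb_per_cM == pytest.approx(0.63)


def test_zero_recombinants_leave_kb_per_cm_undefined():
    table, marker_map = fx.hotspot_fixture()
    concordant = table.copy()
    concordant["HD"] = concordant["RecQ"]
    res = recombination_fraction(concordant, "RecQ", "HD", marker_map=marker_map)
    assert res.rf == 0 and res.kb_per_cM is None
    assert res.linkage is LinkageClass.LINKED


def test_rf_errors_and_clone_collapse():
    table = pd.DataFrame(
        {
            "teliospore": ["T1"] * 3 + ["T2"],
            "colony": ["T1.1", "T1.2", "T1.3", "T2.1"],
            "a": [P1, P1, P1, P2],
            "b": [P1, P1, P1, P1],
        }
    )
    res = recombination_fraction(table, "a", "b")
    # T1's three clonal colonies collapse to one product
    assert res.n_informative == 2 and res.n_recombinant == 1
    het = table.copy()
    het[["a", "b"]] = HET
    with pytest.raises(ValueError, match="no informative"):
        recombination_fraction(het, "a", "b")
    with pytest.raises(KeyError):
        recombination_fraction(table, "a", "nope")


def test_rf_estimate_converges_to_simulator_expectation():
    """RF over ~1e4 simulated products within 0.01 of the Haldane value."""
    from pseudobipolar.meiosis import haldane_rf

    marker_map = MarkerMap.from_records([("s", "a", 1.0), ("s", "b", 161.0)])
    config = SimConfig(kb_per_cM_baseline=32.0, conversion_rate_per_marker=0.0,
                       p_diploid=0.0, p_recover_both_spores=0.0)
    rng = np.random.default_rng(21)
    rows = []
    for t in range(2600):
        products, _ = simulate_meiosis(marker_map, config, rng)
        for p in products:
            rows.append({"teliospore": f"T{t}p{p.product}", "colony": f"T{t}p{p.product}.1", **p.origins})
    table = pd.DataFrame(rows)
    res = recombination_fraction(table, "a", "b", marker_map=marker_map)
    assert res.n_informative >= 10_000
    assert abs(res.rf - haldane_rf(160.0, 32.0)) < 0.01
    assert res.linkage is LinkageClass.LINKED


# --------------------------------------------------------- mat_cohesion_summary

def test_cohesion_fixture_partitions_eight_teliospores():
    table, phase = fx.cohesion_fixture()
    summary = mat_cohesion_summary(table, "STE3", "HD", phase)
    assert summary["counts"] == {
        "parental": 6,
        "recombinant": 1,
        "diploid": 1,
        "both_types_recovered": 1,
    }
    assert summary["classes"]["T7"] == "RECOMBINANT"
    assert summary["classes"]["T8"] == "DIPLOID"
    assert summary["both_types_teliospores"] == ["T1"]
    counts = summary["counts"]
    assert counts["parental"] + counts["recombinant"] + counts["diploid"] == 8


def test_cohesion_all_parental_and_phase_validation():
    table, phase = fx.cohesion_fixture()
    parental_only = table[table["teliospore"].isin(["T2", "T3", "T4"])]
    summary = mat_cohesion_summary(parental_only, "STE3", "HD", phase)
    assert summary["counts"]["recombinant"] == 0
    with pytest.raises(ValueError, match="phase"):
        mat_cohesion_summary(table, "STE3", "HD", {"X": ("A1", "h")})


def test_cohesion_recombinant_count_tracks_simulated_r():
    """Recombinant teliospores ~ Binomial(n, r_eff) under the simulator."""
    marker_map = MarkerMap.from_records([("s", "STE3", 1.0), ("s", "HD", 641.0)])
    config = SimConfig(kb_per_cM_baseline=32.0, conversion_rate_per_marker=0.0,
                       p_diploid=0.0, p_recover_both_spores=0.0, seed=4)
    from pseudobipolar.meiosis import haldane_rf, simulate_cross_experiment

    n = 600
    table, _ = simulate_cross_experiment(marker_map, config, n_teliospores=n)
    summary = mat_cohesion_summary(table, "STE3", "HD", fx.PHASE)
    r_eff = haldane_rf(640.0, 32.0)
    observed = summary["counts"]["recombinant"] / n
    se = math.sqrt(r_eff * (1 - r_eff) / n)
    assert abs(observed - r_eff) < 4 * se


# -------------------------------------------------- infer_scaffold_orientation

def _product_table(rows):
    out = []
    for t, calls in enumerate(rows, start=1):
        out.append({"teliospore": f"T{t}", "colony": f"T{t}.1", **calls})
    return pd.DataFrame(out)


def test_orientation_recovered_from_hand_toy():
    marker_map = MarkerMap.from_records(
        [("A", "a1", 10.0), ("A", "a2", 20.0), ("B", "b1", 5.0), ("B", "b2", 15.0)]
    )
    table = _product_table(
        [
            {"a1": P1, "a2": P2, "b1": P2, "b2": P1},
            {"a1": P1, "a2": P1, "b1": P1, "b2": P2},
        ]
    )
    res = infer_scaffold_orientation(table, marker_map, "A", "B")
    assert res.resolved and res.best == (("+", "+"),)
    assert res.event_counts[("+", "+")] == min(res.event_counts.values())


def test_orientation_unresolved_for_all_parental_products():
    marker_map = MarkerMap.from_records(
        [("A", "a1", 10.0), ("A", "a2", 20.0), ("B", "b1", 5.0), ("B", "b2", 15.0)]
    )
    table = _product_table(
        [
            {"a1": P1, "a2": P1, "b1": P1, "b2": P1},
            {"a1": P2, "a2": P2, "b1": P2, "b2": P2},
        ]
    )
    res = infer_scaffold_orientation(table, marker_map, "A", "B")
    assert not res.resolved and len(res.best) == 4
    single = infer_scaffold_orientation(table.head(1), marker_map, "A", "B")
    assert not single.resolved and single.best == ()
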