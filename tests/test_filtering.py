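"""High-confidence selection: BFDR cut, partner rescue, control-bait exclusion."""

import pytest

from bioidkit import (
    FilterPlan,
    ScoredInteraction,
    ValidationError,
    build_high_confidence,
    compute_bfdr,
    exclude_control_enriched,
    filter_bfdr,
    rescue_by_partner,
)


def _rec(bait, prey, bfdr, avg_spec=10.0, avg_p=1.0):
    return ScoredInteraction(
        bait_id=bait, prey_id=prey, replicate_counts=[int(avg_spec)] * 2,
        replicate_probabilities=[avg_p] * 2, avg_p=avg_p, avg_spec=avg_spec,
        ctrl_counts=[0, 0, 0, 0], ctrl_avg=0.0, bfdr=bfdr,
    )


def test_bfdr_threshold_is_inclusive():
    recs = [_rec("B", f"P{i}", b) for i, b in enumerate([0.005, 0.01, 0.02])]
    assert filter_bfdr(recs, 0.01) == {"P0", "P1"}
    assert filter_bfdr(recs, 0.0) == set()
    zero = [_rec("B", "Z", 0.0)]
    assert filter_bfdr(zero, 0.0) == {"Z"}


def test_filter_bfdr_matches_comprehension_oracle(rng):
    recs = [_rec("B", f"P{i}", float(b)) for i, b in enumerate(rng.random(200))]
    thr = 0.3
    assert filter_bfdr(recs, thr) == {r.prey_id for r in recs if r.bfdr <= thr}


def test_rescue_only_applies_to_detected_preys():
    augmented, rescued = rescue_by_partner(
        {"A", "B"}, {"C", "X"}, {"A", "B", "C", "D"}
    )
    assert augmented == {"A", "B", "C"} and rescued == {"C"}
    # empty partner set rescues nothing
    assert rescue_by_partner({"A"}, set(), {"A", "B"})[0] == {"A"}
    # candidates already covering the partner: unchanged
    aug, resc = rescue_by_partner({"A", "C"}, {"C"}, {"A", "C"})
    assert aug == {"A", "C"} and resc == set()


def test_rescue_is_case_insensitive():
    aug, resc = rescue_by_partner({"a"}, {"SNAPIN"}, {"a", "Snapin"})
    assert resc == {"Snapin"}


@pytest.mark.parametrize(
    "bait_avg, ctrl_avg, excluded",
    [
        (2.0, 8.0, True),  # 8 >= 4 x 2: enriched in the control bait
        (5.0, 10.0, False),  # 10 < 20
        (0.0, 1.0, True),  # floored denominator: 1 >= 4 x 0.25
        (0.0, 0.9, False),  # below the floored cutoff
    ],
)
def test_control_enrichment_rule(bait_avg, ctrl_avg, excluded):
    kept, dropped = exclude_control_enriched(
        {"P"}, {"P": bait_avg}, {"P": ctrl_avg}, ratio=4.0
    )
    assert ("P" in dropped) is excluded


def _scored_three_baits():
    """PC1 with one sticky prey; PC2 partner; CD16 control bait."""
    recs = [
        _rec("PC1", "GOOD", 0.001, avg_spec=20),
        _rec("PC1", "STICKY", 0.001, avg_spec=2),
        _rec("PC1", "WEAK", 0.04, avg_spec=6, avg_p=0.9),
        _rec("PC1", "NOISE", 0.4, avg_spec=1, avg_p=0.3),
        _rec("PC2", "WEAK", 0.002, avg_spec=9),
        _rec("PC2", "OTHER", 0.003, avg_spec=7),
        _rec("CD16", "STICKY", 0.001, avg_spec=30),
        _rec("CD16", "GOOD", 0.9, avg_spec=1, avg_p=0.1),
    ]
    return recs


def test_build_high_confidence_applies_plan_in_order():
    plan = FilterPlan(
        rescue_partners={"PC1": "PC2"}, control_baits={"PC1": "CD16"}
    )
    kept, reports = build_high_confidence(_scored_three_baits(), plan)
    # WEAK rescued by the partner dataset, STICKY excluded 4x in the control bait
    assert kept["PC1"] == {"GOOD", "WEAK"}
    r = reports["PC1"]
    assert r.pass_bfdr == 2 and r.rescued_by_partner == 1
    assert r.excluded_by_control == 1 and r.final_n == 2
    assert r.terminal_decision("STICKY") == "drop"
    # unfiltered baits only get the BFDR cut
    assert kept["PC2"] == {"WEAK", "OTHER"}


def test_no_manual_filters_reduces_to_bfdr():
    recs = _scored_three_baits()
    kept, reports = build_high_confidence(recs, FilterPlan())
    for bait in kept:
        assert kept[bait] == filter_bfdr([r for r in recs if r.bait_id == bait], 0.01)
        reports[bait].reconcile()


def test_unknown_bait_in_plan_is_an_error():
    with pytest.raises(ValidationError, match="unknown bait"):
        build_high_confidence(
            _scored_three_baits(), FilterPlan(rescue_partners={"PC1": "NOPE"})
        )


def test_decision_trail_is_complete_and_reconciles():
    plan = FilterPlan(rescue_partners={"PC1": "PC2"}, control_baits={"PC1": "CD16"})
    recs = _scored_three_baits()
    kept, reports = build_high_confidence(recs, plan)
    for bait, r in reports.items():
        detected = {x.prey_id for x in recs if x.bait_id == bait}
        assert set(r.trail) == detected
        assert r.input_n == len(detected)
        assert all(steps[-1][0] == "final" for steps in r.trail.values())
        assert r.final_n == r.pass_bfdr + r.rescued_by_partner - r.excluded_by_control


def test_idempotence_of_the_filter_pipeline():
    plan = FilterPlan(rescue_partners={"PC1": "PC2"}, control_baits={"PC1": "CD16"})
    recs = _scored_three_baits()
    kept1, _ = build_high_confidence(recs, plan)
    # re-run on the records restricted to the kept preys
    kept_recs = [r for r in recs if r.bait_id not in kept1 or r.prey_id in kept1.get(r.bait_id, set()) or r.bait_id in ("PC2", "CD16")]
    sub = [r for r in recs if r.bait_id != "PC1" or r.prey_id in kept1["PC1"]]
    kept2, _ = build_high_confidence(sub, plan)
    assert kept2["PC1"] == kept1["PC1"]


def test_rescue_then_exclude_differs_from_exclude_then_rescue():
    # a prey that is partner-rescuable AND control-enriched must stay out:
    # the fixed order (rescue before exclude) removes it; the reverse order
    # would re-import it
    recs = [
        _rec("PC1", "TRAP", 0.2, avg_spec=2, avg_p=0.5),
        _rec("PC1", "OK", 0.001, avg_spec=10),
        _rec("PC2", "TRAP", 0.001, avg_spec=9),
        _rec("CD16", "TRAP", 0.001, avg_spec=40),
    ]
    plan = FilterPlan(rescue_partners={"PC1": "PC2"}, control_baits={"PC1": "CD16"})
    kept, _ = build_high_confidence(recs, plan)
    assert "TRAP" not in kept["PC1"]
    # reverse order by hand: exclude first (TRAP not yet present), rescue after
    bfdr_kept = filter_bfdr([r for r in recs if r.bait_id == "PC1"], 0.01)
    excl_first, _ = exclude_control_enriched(bfdr_kept, {"OK": 10.0, "TRAP": 2.0},
                                             {"TRAP": 40.0})
    reversed_kept, _ = rescue_by_partner(excl_first, {"TRAP"}, {"TRAP", "OK"})
    assert "TRAP" in reversed_kept  # demonstrates the order sensitivity


def test_sticky_preys_removed_only_for_planned_baits():
    recs = _scored_three_baits()
    kept_no_plan, _ = build_high_confidence(recs, FilterPlan())
    assert "STICKY" in kept_no_plan["PC1"]  # passes BFDR without the manual filter
    kept_planned, _ = build_high_confidence(
        recs, FilterPlan(control_baits={"PC1": "CD16"})
    )
    assert "STICKY" not in kept_planned["PC1"]
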