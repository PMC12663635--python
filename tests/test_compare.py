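"""Set overlaps, multi-database tallies, hypergeometric ORA, dot-plot encoding."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import hypergeom

from bioidkit import (
    ReferenceGeneSet,
    ScoredInteraction,
    ValidationError,
    compute_bfdr,
    dotplot_export,
    load_gene_set,
    multi_db_membership,
    overlap,
    overrepresentation,
    overrepresentation_table,
    packaged_gene_sets,
)
from bioidkit.compare import border_class

genes = st.sets(st.sampled_from([f"G{i}" for i in range(25)]), min_size=1, max_size=20)


def test_overlap_examples():
    s = overlap({"A", "B", "C"}, {"B", "C", "D"})
    assert s.intersection_n == 2
    assert s.jaccard_similarity == pytest.approx(0.5)
    assert s.jaccard_distance == pytest.approx(0.5)
    assert overlap({"A"}, {"a"}).jaccard_distance == 0.0  # case-insensitive
    with pytest.raises(ValidationError):
        overlap(set(), {"A"})


def test_percentages_round_to_nearest_whole():
    s = overlap({f"G{i}" for i in range(507)}, {f"G{i}" for i in range(266)})
    assert s.pct_of_a == round(100 * 266 / 507) == 52


@settings(max_examples=300, deadline=None)
@given(a=genes, b=genes)
def test_overlap_matches_brute_force_double_loop(a, b):
    s = overlap(a, b)
    inter = sum(1 for x in a for y in b if x == y)
    union = len(set(a) | set(b))
    assert s.intersection_n == inter
    assert s.jaccard_distance == pytest.approx(1 - inter / union)
    assert s.both + s.a_only == s.set_a_n
    assert s.both + s.b_only == s.set_b_n


def _dbs():
    return [
        ReferenceGeneSet("db1", frozenset({"P1", "P2", "P3"})),
        ReferenceGeneSet("db2", frozenset({"P2", "P3", "P4"})),
        ReferenceGeneSet("db3", frozenset({"P3", "P9"})),
    ]


def test_membership_tiers_and_exclusivity():
    per_prey, table = multi_db_membership(
        {"PC1": {"P1", "P2", "P3"}, "PC2": {"P2", "P5"}}, _dbs()
    )
    row = per_prey.set_index("prey")
    assert row.loc["P2", "n_databases"] == 2
    assert row.loc["P2", "exclusivity"] == "both"
    assert table.loc["ge2", "both"] == 1  # P2
    assert table.loc["ge2", "a_only"] == 1  # P3 (in all three DBs)
    assert table.loc["all", "a_only"] == 1
    assert table.loc["ge2", "b_only"] == 0


def test_membership_no_hits_gives_zero_tiers():
    _, table = multi_db_membership(
        {"A": {"X1"}, "B": {"X2"}},
        [ReferenceGeneSet("d1", frozenset({"Q"})), ReferenceGeneSet("d2", frozenset({"R"}))],
    )
    assert table.to_numpy().sum() == 0


@settings(max_examples=200, deadline=None)
@given(a=genes, b=genes, d1=genes, d2=genes, d3=genes)
def test_membership_matches_brute_force_enumeration(a, b, d1, d2, d3):
    dbs = [ReferenceGeneSet(f"d{i}", frozenset(g)) for i, g in enumerate((d1, d2, d3))]
    _, table = multi_db_membership({"A": a, "B": b}, dbs)
    for tier, cond in (("ge2", lambda n: n >= 2), ("all", lambda n: n == 3)):
        counts = {"both": 0, "a_only": 0, "b_only": 0}
        for prey in set(a) | set(b):
            n = sum(prey in db.genes for db in dbs)
            if cond(n):
                key = "both" if prey in a and prey in b else (
                    "a_only" if prey in a else "b_only")
                counts[key] += 1
        for cls, v in counts.items():
            assert table.loc[tier, cls] == v


def test_ora_limit_cases():
    ref = ReferenceGeneSet("ref", frozenset({f"G{i}" for i in range(20)}))
    p_same, fold_same = overrepresentation(ref.genes, ref, universe_n=1000)
    assert p_same < 1e-20 and fold_same == pytest.approx(50.0)
    disjoint = {f"H{i}" for i in range(10)}
    p_dis, fold_dis = overrepresentation(disjoint, ref, universe_n=1000)
    assert p_dis == pytest.approx(1.0)
    assert fold_dis == 0.0
    with pytest.raises(ValidationError):
        overrepresentation({"A"}, ref, universe_n=5)


def test_ora_matches_brute_force_pmf_summation():
    # 5-gene overlap of a 20-gene query with a 50-gene reference in a
    # 1000-gene universe
    query = {f"R{i}" for i in range(5)} | {f"Q{i}" for i in range(15)}
    ref = ReferenceGeneSet(
        "ref", frozenset({f"R{i}" for i in range(5)} | {f"S{i}" for i in range(45)})
    )
    p, _ = overrepresentation(query, ref, universe_n=1000)
    brute = sum(hypergeom.pmf(k, 1000, 50, 20) for k in range(5, 21))
    assert p == pytest.approx(brute, abs=1e-12)


@settings(max_examples=200, deadline=None)
@given(q=genes, r=genes)
def test_ora_equals_analytic_tail(q, r):
    ref = ReferenceGeneSet("ref", frozenset(r))
    universe = 200
    p, _ = overrepresentation(q, ref, universe)
    k = len({g.upper() for g in q} & ref.genes)
    exact = float(hypergeom.sf(k - 1, universe, len(ref.genes), len(set(q))))
    assert p == pytest.approx(exact, abs=1e-12)


def test_ora_table_has_bh_column():
    refs = [ReferenceGeneSet(f"r{i}", frozenset({f"G{j}" for j in range(i + 2)}))
            for i in range(4)]
    t = overrepresentation_table({"G0", "G1"}, refs, universe_n=500)
    assert (t["p_adj"] >= t["p_value"] - 1e-12).all()


def test_packaged_gene_sets_load():
    sets = packaged_gene_sets()
    assert len(sets) >= 3
    assert all(len(s) > 0 for s in sets.values())


def test_load_gene_set_skips_comments(tmp_path):
    p = tmp_path / "g.txt"
    p.write_text("# header\nTP53\n\nbrca1\n")
    gs = load_gene_set(p)
    assert gs.genes == frozenset({"TP53", "BRCA1"})


# ------------------------------------------------------------------ dot plot


def _scored(rng, n=200):
    recs = []
    for i in range(n):
        bait = f"B{rng.integers(1, 4)}"
        avg_spec = float(rng.uniform(0, 120))
        recs.append(
            ScoredInteraction(
                bait_id=bait, prey_id=f"P{rng.integers(0, 60):02d}",
                replicate_counts=[int(avg_spec)] * 2,
                replicate_probabilities=[1.0, 1.0],
                avg_p=float(rng.random()), avg_spec=avg_spec,
                ctrl_counts=[0, 0, 0, 0], ctrl_avg=float(rng.uniform(0, 30)),
            )
        )
    return compute_bfdr(recs)


def test_dotplot_encoding_rules(rng):
    records = dotplot_export(_scored(rng))
    assert ((records["color_value"] >= 0) & (records["color_value"] <= 50)).all()
    assert ((records["size_value"] >= 0) & (records["size_value"] <= 1)).all()
    # a prey's maximum dataset carries size exactly 1
    assert (records.groupby("prey_id")["size_value"].max() == 1.0).all()
    assert set(records["border_class"]) <= {"black", "blue", "light_blue"}


def test_dotplot_cap_and_border_examples():
    recs = compute_bfdr([
        ScoredInteraction("B", "P", [75, 75], [1.0, 1.0], 1.0, 75.0,
                          [0, 0, 0, 0], 0.0),
    ])
    rec = dotplot_export(recs).iloc[0]
    assert rec["color_value"] == 50.0  # capped
    assert rec["size_value"] == 1.0  # self-maximum for a single-bait prey
    assert border_class(0.005) == "black"
    assert border_class(0.03) == "blue"
    assert border_class(0.051) == "light_blue"


def test_dotplot_is_total_on_scored_input(rng):
    recs = _scored(rng)
    records = dotplot_export(recs)
    assert len(records) == len(recs)
    # every encoded field is defined (condition is legitimately optional)
    assert not records.drop(columns="condition").isna().any().any()
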