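from fractions import Fraction
from itertools import combinations
from math import comb

import numpy as np
import pytest

from diffppin.evaluation import (
    PathwayEdgeMap,
    direction_consistent_components,
    hypergeometric_enrichment,
    interactome_clustering,
    load_pathway_edge_file,
    load_transition_table,
    pathway_edge_enrichment,
    transition_table_statistics,
)
from diffppin.significance import RewiringEvent, benjamini_hochberg

from conftest import make_network


def enumerate_hypergeom_tail(m, n_target, n_query, k):
    """Oracle: P(overlap >= k) by exact rational counting."""
    total = Fraction(comb(m, n_query))
    hits = sum(
        Fraction(comb(n_target, i) * comb(m - n_target, n_query - i))
        for i in range(k, min(n_target, n_query) + 1)
    )
    return hits / total


def test_hypergeometric_worked_example_by_enumeration():
    background = set(range(10))
    target = set(range(4))
    query = {0, 1, 2, 8, 9}  # overlap 3
    res = hypergeometric_enrichment(query, target, background)
    assert res.overlap == 3
    assert res.p == pytest.approx(66 / 252)
    # exhaustive subset enumeration gives the same value
    count = sum(
        1
        for subset in combinations(background, 5)
        if len(set(subset) & target) >= 3
    )
    assert res.p == pytest.approx(count / comb(10, 5))


def test_hypergeometric_trivial_and_degenerate():
    bg = set(range(6))
    assert hypergeometric_enrichment({0, 1}, {2, 3}, bg).p == 1.0  # overlap 0
    res = hypergeometric_enrichment(bg, bg, bg)
    assert res.overlap == len(bg) and res.p == pytest.approx(1.0)
    with pytest.raises(ValueError):
        hypergeometric_enrichment({99}, {0}, bg)


def test_hypergeometric_matches_rational_enumeration_small_backgrounds():
    rng = np.random.default_rng(7)
    for _ in range(80):
        m = int(rng.integers(2, 21))
        n_t = int(rng.integers(0, m + 1))
        n_q = int(rng.integers(0, m + 1))
        bg = set(range(m))
        target = set(rng.choice(m, size=n_t, replace=False).tolist())
        query = set(rng.choice(m, size=n_q, replace=False).tolist())
        res = hypergeometric_enrichment(query, target, bg)
        exact = float(enumerate_hypergeom_tail(m, n_t, n_q, res.overlap))
        assert res.p == pytest.approx(exact, abs=1e-12)


def _e(i, j):
    return (f"P{i}", f"P{j}")


def test_pathway_enrichment_directions():
    background = {_e(i, i + 1) for i in range(0, 40, 2)}
    rewired = {_e(i, i + 1) for i in range(0, 10, 2)}
    enriched = PathwayEdgeMap("hit", "src", frozenset(rewired))
    disjoint = PathwayEdgeMap(
        "miss", "src", frozenset({_e(i, i + 1) for i in range(20, 30, 2)})
    )
    results = pathway_edge_enrichment(rewired, [enriched, disjoint], background)
    assert results[0].p < 1e-4
    assert results[1].p == 1.0


def test_bh_families_kept_separate_per_source():
    background = {_e(i, i + 1) for i in range(0, 60, 2)}
    bg_list = sorted(background)
    rewired = {_e(i, i + 1) for i in range(0, 12, 2)}
    maps = [
        PathwayEdgeMap("k1", "kegg", frozenset(bg_list[:10])),
        PathwayEdgeMap("k2", "kegg", frozenset(bg_list[10:16])),
        PathwayEdgeMap("r1", "reactome", frozenset(bg_list[5:12])),
    ]
    results = pathway_edge_enrichment(rewired, maps, background)
    raw = [r.p for r in results]
    kegg_adj = benjamini_hochberg(raw[:2])
    reactome_adj = benjamini_hochberg(raw[2:])
    assert [r.p_adj for r in results] == pytest.approx(kegg_adj + reactome_adj)
    pooled = benjamini_hochberg(raw)
    assert [r.p_adj for r in results] != pytest.approx(pooled)


def test_pathway_file_size_filter(tmp_path):
    lines = []
    for i in range(20):  # big enough pathway
        lines.append(f"kegg\tbig\tA{i}\tB{i}")
    lines.append("kegg\ttiny\tA0\tB0")  # below min_edges
    path = tmp_path / "pathways.tsv"
    path.write_text("\n".join(lines) + "\n")
    maps = load_pathway_edge_file(path, min_edges=15, max_edges=1000)
    assert [m.name for m in maps] == ["big"]


def _event(edge, direction):
    return RewiringEvent(edge, 3, direction, 3, 1e-4, 1e-4)


def test_direction_consistent_components():
    events = [_event(("A", "B"), 1), _event(("B", "C"), 1)]
    comps = direction_consistent_components({"A", "B", "C"}, events)
    assert len(comps) == 1
    assert comps[0].proteins == {"A", "B", "C"} and comps[0].direction == 1


def test_components_below_min_size_dropped():
    assert direction_consistent_components({"A", "B"}, [_event(("A", "B"), 1)]) == []
    mixed = [_event(("A", "B"), 1), _event(("B", "C"), -1)]
    assert direction_consistent_components({"A", "B", "C"}, mixed) == []


def test_components_restricted_to_reduced_set():
    events = [_event(("A", "B"), 1), _event(("B", "C"), 1), _event(("C", "D"), 1)]
    comps = direction_consistent_components({"A", "B", "C"}, events)
    assert len(comps) == 1 and comps[0].proteins == {"A", "B", "C"}


def test_clustering_identical_samples_merge_at_zero():
    edges = [("A", "B"), ("C", "D")]
    s1 = make_network("s1", edges)
    s2 = make_network("s2", edges)
    link, ids, dist = interactome_clustering([s1, s2], edges)
    assert ids == ["s1", "s2"]
    assert link[0, 2] == 0.0
    assert dist[0] == 0.0


def test_clustering_complement_vectors_distance_one():
    features = [("A", "B"), ("C", "D"), ("E", "F"), ("G", "H")]
    s1 = make_network("s1", features[:2], extra_proteins="EFGH")
    s2 = make_network("s2", features[2:], extra_proteins="ABCD")
    _, _, dist = interactome_clustering([s1, s2], features)
    assert dist[0] == 1.0


def test_clustering_hand_worked_upgma():
    # presence vectors 110, 100, 011 over three feature edges
    features = [("A", "B"), ("C", "D"), ("E", "F")]
    all_proteins = "ABCDEF"
    s1 = make_network("s1", features[:2], extra_proteins=all_proteins)
    s2 = make_network("s2", features[:1], extra_proteins=all_proteins)
    s3 = make_network("s3", features[1:], extra_proteins=all_proteins)
    link, _, dist = interactome_clustering([s1, s2, s3], features)
    assert dist == pytest.approx([1 / 3, 2 / 3, 1.0])
    # first merge joins s1, s2 at 1/3; s3 joins at mean(2/3, 1) = 5/6
    assert sorted(link[0, :2]) == [0, 1]
    assert link[0, 2] == pytest.approx(1 / 3)
    assert link[1, 2] == pytest.approx(5 / 6)
    # heights never decrease
    assert link[0, 2] <= link[1, 2]


def test_clustering_input_validation():
    s = make_network("s", [("A", "B")])
    with pytest.raises(ValueError):
        interactome_clustering([s, s], [])
    with pytest.raises(ValueError):
        interactome_clustering([s], [("A", "B")])


def test_transition_table_statistics_from_bundled_table():
    df = load_transition_table()
    assert len(df) == 10
    stats = transition_table_statistics(df)
    # the summary columns reproduce their published self-consistency values
    assert stats["pearson_obs_fraction_vs_p_rew"] == pytest.approx(0.30, abs=0.005)
    assert stats["pearson_obs_fraction_vs_obs_all"] == pytest.approx(-0.15, abs=0.005)
    # net significant change deviates from the mean net size difference by
    # at most 1.46 standard deviations (its published maximum)
    assert stats["max_sigma_deviation"] == pytest.approx(1.46, abs=0.005)
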