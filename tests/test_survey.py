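"""Survey parsing, completeness filtering, tier networks and metrics."""

from __future__ import annotations

import math

import numpy as np
import pytest

from gradenet.survey import (
    SurveyParseError,
    SurveyResponse,
    SurveyValidationError,
    TierNetwork,
    build_tier_network,
    filter_complete,
    network_metrics,
    read_survey,
)

from conftest import make_responses, random_network


class TestReadSurvey:
    def test_smallest_full_survey(self, three_student_survey):
        responses = read_survey(three_student_survey.splitlines(), ["A", "B", "C"])
        assert len(responses) == 3
        assert all(r.complete for r in responses)
        by_id = {r.respondent_id: r for r in responses}
        assert by_id["A"].ratings == {"B": "best_friend", "C": "friend"}

    def test_missing_rating_marks_incomplete(self, three_student_survey):
        lines = three_student_survey.splitlines()
        del lines[2]  # drop A,C,friend
        responses = read_survey(lines, ["A", "B", "C"])
        by_id = {r.respondent_id: r for r in responses}
        assert not by_id["A"].complete
        assert by_id["B"].complete and by_id["C"].complete

    def test_relations_case_insensitive(self):
        csv = "respondent_id,target_id,relation\nA,B,Best_Friend\nB,A,FRIEND\n"
        responses = read_survey(csv.splitlines(), ["A", "B"])
        by_id = {r.respondent_id: r for r in responses}
        assert by_id["A"].ratings["B"] == "best_friend"
        assert by_id["B"].ratings["A"] == "friend"

    @pytest.mark.parametrize(
        "row, exc, fragment",
        [
            ("A,B,enemy", SurveyParseError, "line 2"),
            ("A,A,friend", SurveyValidationError, "self"),
            ("A,Z,friend", SurveyValidationError, "roster"),
        ],
    )
    def test_bad_rows_rejected(self, row, exc, fragment):
        csv = f"respondent_id,target_id,relation\n{row}\n"
        with pytest.raises(exc, match=fragment):
            read_survey(csv.splitlines(), ["A", "B"])

    def test_duplicate_rating_is_error_not_overwrite(self):
        csv = (
            "respondent_id,target_id,relation\n"
            "A,B,friend\n"
            "A,B,best_friend\n"
        )
        with pytest.raises(SurveyValidationError, match="duplicate"):
            read_survey(csv.splitlines(), ["A", "B"])

    def test_bad_header_rejected(self):
        with pytest.raises(SurveyParseError, match="header"):
            read_survey(["a,b,c", "A,B,friend"], ["A", "B"])


class TestFilterComplete:
    def test_keeps_only_complete_preserving_order(self):
        rs = [
            SurveyResponse("A", {"B": "friend"}, True),
            SurveyResponse("B", {}, False),
            SurveyResponse("C", {"A": "friend"}, True),
        ]
        kept = filter_complete(rs)
        assert [r.respondent_id for r in kept] == ["A", "C"]

    def test_idempotent(self):
        rs = [SurveyResponse("A", {}, True), SurveyResponse("B", {}, False)]
        once = filter_complete(rs)
        assert filter_complete(once) == once

    def test_all_incomplete_gives_empty(self):
        assert filter_complete([SurveyResponse("A", {}, False)]) == []


class TestBuildTierNetwork:
    def test_hand_enumerated_edge_sets(self, five_node_responses):
        acq_plus = build_tier_network(five_node_responses, "acquaintance_plus", "cumulative")
        friend_plus = build_tier_network(five_node_responses, "friend_plus", "cumulative")
        best = build_tier_network(five_node_responses, "best_only", "cumulative")
        assert acq_plus.edge_set == {
            ("A", "B"), ("A", "C"), ("A", "D"),
            ("B", "A"), ("B", "E"),
            ("C", "A"),
            ("D", "E"),
            ("E", "A"), ("E", "D"),
        }
        assert friend_plus.edge_set == {
            ("A", "B"), ("A", "C"), ("B", "A"), ("B", "E"), ("D", "E"), ("E", "D")
        }
        assert best.edge_set == {("A", "B"), ("B", "E"), ("E", "D")}

    def test_best_rating_in_cumulative_friend_but_not_exclusive(self, five_node_responses):
        friend_plus = build_tier_network(five_node_responses, "friend_plus", "cumulative")
        friend_only = build_tier_network(five_node_responses, "friend_only", "exclusive")
        assert ("A", "B") in friend_plus.edge_set  # A rated B best_friend
        assert ("A", "B") not in friend_only.edge_set

    def test_unknown_and_related_never_produce_edges(self, five_node_responses):
        acq_plus = build_tier_network(five_node_responses, "acquaintance_plus", "cumulative")
        assert ("C", "B") not in acq_plus.edge_set  # related
        assert all(
            rel not in ("unknown", "related")
            for r in five_node_responses
            for t, rel in r.ratings.items()
            if (r.respondent_id, t) in acq_plus.edge_set
        )

    def test_cumulative_monotonicity_and_exclusive_partition(self):
        rng = np.random.default_rng(7)
        ids = [f"S{i}" for i in range(12)]
        levels = ["best_friend", "friend", "acquaintance", "unknown", "related"]
        ratings = {
            u: {v: levels[rng.integers(5)] for v in ids if v != u} for u in ids
        }
        responses = make_responses(ratings)
        cum = {
            t: build_tier_network(responses, t, "cumulative")
            for t in ("acquaintance_plus", "friend_plus", "best_only")
        }
        exc = {
            t: build_tier_network(responses, t, "exclusive")
            for t in ("acquaintance_only", "friend_only", "best_only")
        }
        assert cum["best_only"].edge_set <= cum["friend_plus"].edge_set
        assert cum["friend_plus"].edge_set <= cum["acquaintance_plus"].edge_set
        # exclusive tiers partition the widest cumulative tier
        union = exc["acquaintance_only"].edge_set | exc["friend_only"].edge_set | exc["best_only"].edge_set
        assert union == cum["acquaintance_plus"].edge_set
        total = sum(len(e.edge_set) for e in exc.values())
        assert total == len(cum["acquaintance_plus"].edge_set)

    def test_ratings_naming_dropped_students_are_dropped(self):
        rs = make_responses({"A": {"B": "friend"}, "B": {"A": "friend"}})
        # B also rated an excluded non-respondent Z
        rs[1].ratings["Z"] = "friend"
        net = build_tier_network(rs, "friend_plus", "cumulative")
        assert net.edge_set == {("A", "B"), ("B", "A")}

    def test_invalid_tier_or_mode(self, five_node_responses):
        with pytest.raises(ValueError, match="tier"):
            build_tier_network(five_node_responses, "unknown", "cumulative")
        with pytest.raises(ValueError, match="mode"):
            build_tier_network(five_node_responses, "friend_plus", "sideways")

    def test_incomplete_responses_rejected(self):
        rs = [SurveyResponse("A", {"B": "friend"}, False), SurveyResponse("B", {"A": "friend"}, True)]
        with pytest.raises(SurveyValidationError, match="incomplete"):
            build_tier_network(rs, "friend_plus", "cumulative")


def _brute_force_metrics(net: TierNetwork):
    """Independent triple/degree enumeration oracle for small networks."""
    nodes = list(net.nodes)
    n = len(nodes)
    e = net.edge_set
    density = len(e) / (n * (n - 1))
    paths = closed = 0
    for i in nodes:
        for j in nodes:
            for k in nodes:
                if i != j and j != k and i != k and (i, j) in e and (j, k) in e:
                    paths += 1
                    closed += (i, k) in e
    transitivity = closed / paths if paths else 0.0
    und = {frozenset(p) for p in e}
    nbrs = {u: {v for v in nodes if frozenset((u, v)) in und} for u in nodes}
    local = []
    for u in nodes:
        nb = sorted(nbrs[u])
        k = len(nb)
        if k < 2:
            local.append(0.0)
            continue
        links = sum(
            1
            for a in range(k)
            for b in range(a + 1, k)
            if frozenset((nb[a], nb[b])) in und
        )
        local.append(2 * links / (k * (k - 1)))
    out_deg = [sum(1 for v in nodes if (u, v) in e) for u in nodes]
    in_deg = [sum(1 for v in nodes if (v, u) in e) for u in nodes]
    out_ccdf = [sum(d >= kk for d in out_deg) / n for kk in range(max(out_deg) + 1)]
    in_ccdf = [sum(d >= kk for d in in_deg) / n for kk in range(max(in_deg) + 1)]
    # components via BFS on the undirected view
    seen: set[str] = set()
    comps = 0
    for u in nodes:
        if u in seen:
            continue
        comps += 1
        stack = [u]
        while stack:
            w = stack.pop()
            if w in seen:
                continue
            seen.add(w)
            stack.extend(nbrs[w] - seen)
    isolated = sum(1 for u in nodes if not nbrs[u])
    return density, transitivity, sum(local) / n, out_ccdf, in_ccdf, comps, isolated


class TestNetworkMetrics:
    def test_complete_digraph(self):
        nodes = ("A", "B", "C", "D")
        edges = tuple((u, v) for u in nodes for v in nodes if u != v)
        m = network_metrics(TierNetwork("friend_plus", "cumulative", nodes, edges))
        assert m.density == 1.0
        assert m.transitivity == 1.0
        assert m.n_components == 1
        assert m.n_isolated == 0

    def test_directed_three_cycle(self):
        net = TierNetwork(
            "friend_plus", "cumulative", ("A", "B", "C"), (("A", "B"), ("B", "C"), ("C", "A"))
        )
        m = network_metrics(net)
        assert m.density == pytest.approx(0.5)
        assert m.avg_clustering == pytest.approx(1.0)
        assert m.transitivity == 0.0  # no closed directed two-path

    def test_out_star(self):
        nodes = ("H", "A", "B", "C", "D")
        edges = tuple(("H", v) for v in nodes[1:])
        m = network_metrics(TierNetwork("friend_plus", "cumulative", nodes, edges))
        assert m.out_ccdf[4] == pytest.approx(0.2)
        assert m.out_ccdf[0] == 1.0
        assert m.n_isolated == 0
        assert m.n_components == 1

    def test_single_node_density_undefined(self):
        net = TierNetwork("friend_plus", "cumulative", ("A",), ())
        with pytest.raises(ValueError, match="undefined"):
            network_metrics(net)

    def test_ccdf_non_increasing_and_starts_at_one(self):
        rng = np.random.default_rng(3)
        net = random_network(rng, 10, 0.3)
        m = network_metrics(net)
        for ccdf in (m.out_ccdf, m.in_ccdf):
            assert ccdf[0] == 1.0
            assert all(a >= b for a, b in zip(ccdf, ccdf[1:]))

    @pytest.mark.parametrize("seed", range(8))
    def test_agrees_with_brute_force_on_small_random_graphs(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 9))
        net = random_network(rng, n, float(rng.uniform(0.1, 0.8)))
        m = network_metrics(net)
        density, trans, clust, out_ccdf, in_ccdf, comps, isolated = _brute_force_metrics(net)
        assert m.density == pytest.approx(density, abs=1e-12)
        assert m.transitivity == pytest.approx(trans, abs=1e-12)
        assert m.avg_clustering == pytest.approx(clust, abs=1e-12)
        assert list(m.out_ccdf) == pytest.approx(out_ccdf)
        assert list(m.in_ccdf) == pytest.approx(in_ccdf)
        assert m.n_components == comps
        assert m.n_isolated == isolated
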