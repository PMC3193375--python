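import pytest
from hypothesis import given, settings, strategies as st

from refogbench.metrics import (
    FusionThreshold,
    best_matching_og,
    evaluate_refog,
    gene_level_errors,
    group_level_events,
    rank_methods,
    summarize_comparisons,
    summarize_method,
)
from refogbench.model import RefOGSet

from conftest import G, make_predictions, make_refog


class TestBestMatch:
    def test_identity_prediction_matches_fully(self, identity_setup):
        refogs, preds = identity_setup
        for r in refogs:
            og, overlap = best_matching_og(r, preds)
            assert og == r.refog_id and overlap == r.size

    def test_largest_overlap_wins(self, toy_refog, toy_split_predictions):
        assert best_matching_og(toy_refog, toy_split_predictions) == ("OG1", 2)

    def test_tie_broken_by_fewer_non_members(self, toy_refog):
        preds = make_predictions({"OG1": ["a", "b"], "OG2": ["c", "d", "z"]})
        assert best_matching_og(toy_refog, preds) == ("OG1", 2)

    def test_tie_broken_by_smallest_og_id(self, toy_refog):
        preds = make_predictions({"OGB": ["a", "b"], "OGA": ["c", "d"]})
        assert best_matching_og(toy_refog, preds) == ("OGA", 2)

    def test_no_member_bearing_og_returns_null(self, toy_refog):
        preds = make_predictions({"OG1": ["x", "y"]})
        assert best_matching_og(toy_refog, preds) == (None, 0)


class TestGeneLevelErrors:
    def test_missing_and_erroneous_sets(self, toy_refog):
        missing, erroneous = gene_level_errors(
            toy_refog, {G("a"), G("b"), G("x")})
        assert {g.gene_id for g in missing} == {"c", "d"}
        assert {g.gene_id for g in erroneous} == {"x"}

    def test_exact_match_is_clean(self, toy_refog):
        missing, erroneous = gene_level_errors(toy_refog, set(toy_refog.members))
        assert not missing and not erroneous

    def test_null_match_makes_whole_refog_missing(self, toy_refog):
        missing, erroneous = gene_level_errors(toy_refog, set())
        assert missing == toy_refog.members and not erroneous


class TestGroupLevelEvents:
    def test_split_over_three_ogs_is_two_fissions(self, toy_refog, toy_split_predictions):
        fissions, fusions, bearing = group_level_events(toy_refog, toy_split_predictions)
        assert (fissions, fusions) == (2, 0)
        assert bearing == ("OG1", "OG2", "OG3")

    @pytest.mark.parametrize("n_aliens,expected_fusions", [(3, 0), (4, 1), (7, 1)])
    def test_fusion_needs_more_than_three_aliens(self, toy_refog, n_aliens, expected_fusions):
        preds = make_predictions(
            {"OG1": ["a", "b", "c", "d"] + [f"x{i}" for i in range(n_aliens)]})
        _, fusions, _ = group_level_events(toy_refog, preds)
        assert fusions == expected_fusions

    def test_perfect_prediction_has_no_events(self, toy_refog):
        preds = make_predictions({"OG1": ["a", "b", "c", "d"]})
        assert group_level_events(toy_refog, preds)[:2] == (0, 0)

    def test_threshold_one_counts_every_alien_bearing_og(self, toy_refog):
        preds = make_predictions({"OG1": ["a", "x"], "OG2": ["b"], "OG3": ["c", "d", "y"]})
        _, fusions, _ = group_level_events(toy_refog, preds, FusionThreshold(1))
        assert fusions == 2


class TestEvaluateRefOG:
    def test_identity_is_strict_and_group_accurate(self, identity_setup):
        refogs, preds = identity_setup
        for r in refogs:
            c = evaluate_refog(r, preds)
            assert c.gene_strict and c.group_accurate
            assert c.overlap_size + len(c.missing) == r.size

    def test_split_toy_fails_both_levels(self, toy_refog, toy_split_predictions):
        c = evaluate_refog(toy_refog, toy_split_predictions)
        assert not c.gene_strict and not c.group_accurate
        assert len(c.missing) == 2 and len(c.erroneous) == 1
        assert c.fission_events == 2

    def test_subthreshold_aliens_keep_group_accuracy(self, toy_refog):
        preds = make_predictions({"OG1": ["a", "b", "c", "d", "x1", "x2"]})
        c = evaluate_refog(toy_refog, preds)
        assert not c.gene_strict and c.group_accurate

    def test_strict_group_mode_rejects_any_alien(self, toy_refog):
        preds = make_predictions({"OG1": ["a", "b", "c", "d", "x1"]})
        assert evaluate_refog(toy_refog, preds).group_accurate
        assert not evaluate_refog(toy_refog, preds, strict_group_mode=True).group_accurate


class TestSummarize:
    def test_identity_scores_hundred_percent(self, identity_setup):
        refogs, preds = identity_setup
        s = summarize_method(refogs, preds)
        assert s.gene_strict_accuracy_pct == 100.0
        assert s.group_accuracy_pct == 100.0
        assert s.total_errors == 0
        assert s.pct_refogs_with_missing == 0.0
        assert s.pct_refogs_fused == 0.0

    def test_hand_aggregated_mixed_run(self):
        refogs = RefOGSet([make_refog("R1", ["a", "b", "c", "d"]),
                           make_refog("R2", ["e", "f"])])
        preds = make_predictions({
            "OG1": ["a", "b", "x"], "OG2": ["c", "y"], "OG3": ["d"],
            "OG4": ["e", "f"],
        })
        s = summarize_method(refogs, preds)
        assert s.gene_strict_accuracy_pct == 50.0
        assert s.total_missing == 2 and s.total_erroneous == 1
        assert s.total_fissions == 2 and s.total_fusions == 0
        assert s.pct_refogs_fissioned == 50.0

    def test_empty_refog_set_is_usage_error(self):
        preds = make_predictions({"OG1": ["a"]})
        with pytest.raises(ValueError):
            summarize_comparisons("m", [])

    def test_strict_never_exceeds_group_accuracy(self, toy_refog, toy_split_predictions):
        refogs = RefOGSet([toy_refog])
        s = summarize_method(refogs, toy_split_predictions)
        assert s.gene_strict_accuracy_pct <= s.group_accuracy_pct


class TestRanking:
    def _summary(self, name, missing, strict=0.0):
        refogs = RefOGSet([make_refog("R1", ["a"])])
        preds = make_predictions({"OG1": ["a"]}, method=name)
        s = summarize_method(refogs, preds)
        from dataclasses import replace
        return replace(s, total_missing=missing, gene_strict_accuracy_pct=strict)

    def test_ascending_by_total_errors(self):
        ranked = rank_methods([self._summary("A", 10), self._summary("B", 3),
                               self._summary("C", 7)])
        assert [s.total_errors for s in ranked] == [3, 7, 10]

    def test_tie_broken_by_strict_accuracy(self):
        ranked = rank_methods([self._summary("A", 5, 20.0), self._summary("B", 5, 40.0)])
        assert ranked[0].method_name == "B"

    def test_single_method(self):
        s = self._summary("A", 1)
        assert rank_methods([s]) == [s]


@st.composite
def scored_universe(draw):
    """A RefOG plus a random prediction partition over a shared gene pool."""
    member_ids = [f"m{i}" for i in range(draw(st.integers(1, 8)))]
    alien_ids = [f"x{i}" for i in range(draw(st.integers(0, 6)))]
    refog = make_refog("R", member_ids)
    pool = member_ids + alien_ids
    n_ogs = draw(st.integers(1, 4))
    ogs: dict[str, list[str]] = {}
    for gid in pool:
        if draw(st.booleans()):  # gene may be absent from the method entirely
            ogs.setdefault(f"OG{draw(st.integers(0, n_ogs - 1))}", []).append(gid)
    return refog, make_predictions(ogs) if ogs else make_predictions({})


@settings(max_examples=80, deadline=None)
@given(data=scored_universe())
def test_conservation_and_strict_implies_group(data):
    """overlap + |missing| = |RefOG|, and a strict RefOG is group-accurate."""
    refog, preds = data
    c = evaluate_refog(refog, preds)
    assert c.overlap_size + len(c.missing) == refog.size
    assert not c.erroneous & refog.members
    assert c.fission_events == max(0, len(c.member_bearing_ogs) - 1)
    if c.gene_strict:
        assert c.group_accurate


def test_adding_alien_never_decreases_erroneous(toy_refog):
    base = {"OG1": ["a", "b", "c"], "OG2": ["d"]}
    c0 = evaluate_refog(toy_refog, make_predictions(base))
    grown = {"OG1": base["OG1"] + ["alien"], "OG2": ["d"]}
    c1 = evaluate_refog(toy_refog, make_predictions(grown))
    assert len(c1.erroneous) >= len(c0.erroneous)


def test_removing_member_never_decreases_missing(toy_refog):
    c0 = evaluate_refog(toy_refog, make_predictions({"OG1": ["a", "b", "c", "d"]}))
    c1 = evaluate_refog(toy_refog, make_predictions({"OG1": ["a", "b", "c"]}))
    assert len(c1.missing) >= len(c0.missing)
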