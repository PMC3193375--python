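import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from refogbench.metrics import evaluate_all, summarize_method
from refogbench.model import RefOGSet
from refogbench.reconcile import (
    HistoryRow,
    IDHistoryTable,
    PROVENANCE_CATEGORIES,
    compare_runs,
    partition_error_genes,
    per_species_breakdown,
    read_history_table,
)

from conftest import G, make_predictions, make_refog


def history(rows):
    return IDHistoryTable(HistoryRow(*r) for r in rows)


class TestProvenance:
    def test_half_current_forty_retracted_ten_pseudogene(self):
        rows = [(f"c{i}", "current", 1, 60) for i in range(5)]
        rows += [(f"r{i}", "retracted", 1, 50) for i in range(4)]
        rows += [("p0", "pseudogene", 1, 60)]
        table = history(rows)
        prov = partition_error_genes([r[0] for r in rows], table, method_version=46)
        assert prov.fraction("mapped_current") == 0.5
        assert prov.fraction("retracted") == 0.4
        assert prov.fraction("pseudogene") == 0.1

    def test_empty_error_set(self):
        prov = partition_error_genes([], history([("a", "current", 1, 60)]), 46)
        assert prov.n_total == 0 and sum(prov.as_dict().values()) == 0

    def test_gene_introduced_after_method_version(self):
        table = history([("new", "current", 54, 60)])
        prov = partition_error_genes(["new"], table, method_version=46)
        assert prov.introduced_later == 1

    def test_absent_gene_is_unknown(self):
        prov = partition_error_genes(["ghost"], history([("a", "current", 1, 60)]), 46)
        assert prov.unknown == 1

    def test_superseded_with_replacement_maps_to_current(self):
        table = history([("old", "superseded", 1, 50, "newid")])
        prov = partition_error_genes(["old"], table, 46)
        assert prov.mapped_current == 1

    def test_same_gene_resolved_by_last_version(self):
        table = history([("g", "retracted", 1, 40), ("g", "current", 41, 60)])
        assert partition_error_genes(["g"], table, 46).mapped_current == 1

    def test_exact_last_version_tie_is_unknown(self):
        table = history([("g", "retracted", 1, 50), ("g", "current", 2, 50)])
        assert partition_error_genes(["g"], table, 46).unknown == 1

    def test_superseded_without_replacement_rejected(self):
        with pytest.raises(ValueError):
            HistoryRow("g", "superseded", 1, 5)

    def test_read_history_table(self, tmp_path):
        p = tmp_path / "hist.tsv"
        p.write_text(
            "gene_id\tstatus\tfirst_version\tlast_version\treplacement_id\n"
            "a\tcurrent\t1\t60\t\n"
            "b\tsuperseded\t1\t50\tc\n"
        )
        table = read_history_table(p)
        assert len(table) == 2
        assert table.lookup("b").replacement_id == "c"


@settings(max_examples=50, deadline=None)
@given(st.lists(
    st.tuples(st.sampled_from(["current", "retracted", "pseudogene"]),
              st.integers(1, 60)),
    min_size=0, max_size=30))
def test_provenance_categories_partition_the_error_set(specs):
    rows = [(f"g{i}", status, fv, 60) for i, (status, fv) in enumerate(specs)]
    table = history(rows)
    error_genes = [r[0] for r in rows] + ["absent1", "absent2"]
    prov = partition_error_genes(error_genes, table, method_version=30)
    assert sum(prov.as_dict().values()) == prov.n_total == len(error_genes)
    if prov.n_total:
        assert sum(prov.fraction(c) for c in PROVENANCE_CATEGORIES) == pytest.approx(1.0)


class TestSpeciesBreakdown:
    def test_identity_prediction_gives_full_coverage(self, identity_setup):
        refogs, preds = identity_setup
        rows = per_species_breakdown(evaluate_all(refogs, preds), refogs)
        assert rows and all(b.coverage_pct == 100.0 and b.n_missing == 0
                            and b.n_erroneous == 0 for b in rows)

    def test_two_of_four_human_members_missing_gives_half_coverage(self):
        refogs = RefOGSet([make_refog("R1", ["a", "b", "c", "d"], "hs")])
        preds = make_predictions({"OG1": ["a", "b"]}, species="hs")
        rows = per_species_breakdown(evaluate_all(refogs, preds), refogs)
        (hs,) = rows
        assert hs.n_refog_orthologs == 4 and hs.n_missing == 2
        assert hs.coverage_pct == 50.0

    def test_erroneous_gene_counts_to_its_species_without_touching_coverage(self):
        refogs = RefOGSet([make_refog("R1", ["a", "b"], "hs"),
                           make_refog("R2", ["e"], "dm")])
        preds = make_predictions({"OG1": [G("a", "hs"), G("b", "hs"), G("x", "dm")],
                                  "OG2": [G("e", "dm")]})
        rows = per_species_breakdown(evaluate_all(refogs, preds), refogs)
        by_sp = {b.species_id: b for b in rows}
        assert by_sp["dm"].n_erroneous == 1
        assert by_sp["hs"].coverage_pct == 100.0
        assert by_sp["dm"].coverage_pct == 100.0

    def test_species_without_orthologs_is_omitted_with_warning(self, caplog):
        import logging
        refogs = RefOGSet([make_refog("R1", ["a", "b"], "hs")])
        preds = make_predictions({"OG1": [G("a", "hs"), G("b", "hs"), G("x", "dm")]})
        with caplog.at_level(logging.WARNING):
            rows = per_species_breakdown(evaluate_all(refogs, preds), refogs)
        assert [b.species_id for b in rows] == ["hs"]
        assert "dm" in caplog.text

    def test_breakdown_totals_match_method_summary(self):
        refogs = RefOGSet([make_refog("R1", ["a", "b", "c", "d"], "hs"),
                           make_refog("R2", ["e", "f"], "dm")])
        preds = make_predictions({
            "OG1": [G("a", "hs"), G("b", "hs"), G("x", "dm")],
            "OG2": [G("c", "hs")],
            "OG4": [G("e", "dm")],
        })
        comparisons = evaluate_all(refogs, preds)
        summary = summarize_method(refogs, preds)
        rows = per_species_breakdown(comparisons, refogs)
        assert sum(b.n_missing for b in rows) == summary.total_missing
        assert sum(b.n_erroneous for b in rows) == summary.total_erroneous

    def test_any_og_mode_recovers_members_in_other_parts(self):
        refogs = RefOGSet([make_refog("R1", ["a", "b", "c", "d"], "hs")])
        preds = make_predictions({"OG1": ["a", "b", "c"], "OG2": ["d"]}, species="hs")
        comparisons = evaluate_all(refogs, preds)
        matched_only = per_species_breakdown(comparisons, refogs)
        any_og = per_species_breakdown(comparisons, refogs, any_og_mode=True,
                                       predictions=preds)
        assert matched_only[0].n_missing == 1
        assert any_og[0].n_missing == 0


class TestCompareRuns:
    def _summary(self, name, erroneous, missing=0):
        refogs = RefOGSet([make_refog("R1", ["a"])])
        preds = make_predictions({"OG1": ["a"]}, method=name)
        s = summarize_method(refogs, preds)
        from dataclasses import replace
        return replace(s, total_erroneous=erroneous, total_missing=missing)

    def test_identical_runs_have_zero_deltas(self):
        s = self._summary("A", 10)
        df = compare_runs(s, s)
        assert (df["delta"] == 0).all()

    def test_erroneous_reduction_pattern(self):
        old = self._summary("old", 271)
        new = self._summary("new", 149)
        df = compare_runs(old, new)
        row = df[df["metric"] == "total_erroneous"].iloc[0]
        assert row["pct_change"] == pytest.approx(-45.0, abs=0.1)

    def test_antisymmetry(self):
        a, b = self._summary("A", 100, 30), self._summary("B", 70, 21)
        fwd = compare_runs(a, b)
        rev = compare_runs(b, a)
        assert np.allclose(fwd["delta"].to_numpy(), -rev["delta"].to_numpy())

    def test_thirty_percent_fewer_missing(self):
        a, b = self._summary("A", 0, 100), self._summary("B", 0, 70)
        df = compare_runs(a, b)
        row = df[df["metric"] == "total_missing"].iloc[0]
        assert row["pct_change"] == pytest.approx(-30.0)

    def test_mismatched_refog_sets_rejected(self):
        a = self._summary("A", 1)
        from dataclasses import replace
        b = replace(self._summary("B", 1), n_refogs=2)
        with pytest.raises(ValueError):
            compare_runs(a, b)
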