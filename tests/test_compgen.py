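"""Presence/absence screen: matrix, funnel logic, keyword filter."""

import pandas as pd
import pytest

from salpipe.compgen import (
    CandidateReport,
    PhenotypePartition,
    build_og_matrix,
    core_ogs,
    filter_by_annotation,
    load_candidate_table,
    producer_unique_ogs,
    representative_annotations,
    run_screen,
)
from salpipe.simulate import simulate_genomes


def _records(rows):
    return pd.DataFrame(
        rows, columns=["gene_id", "genome_id", "og_id", "annotation", "cog_category"]
    )


class TestMatrix:
    def test_single_record(self):
        m = build_og_matrix(_records([("g1", "A", "OG1", "x", "S")]))
        assert m.genomes == ["A"] and m.ogs == ["OG1"]
        assert bool(m.presence.loc["A", "OG1"])

    def test_multiple_genes_collapse(self):
        m = build_og_matrix(
            _records([("g1", "A", "OG1", "x", "S"), ("g2", "A", "OG1", "x", "S")])
        )
        assert m.presence.shape == (1, 1)

    def test_synthetic_dimensions_match_truth(self):
        records, truth = simulate_genomes(n_background_ogs=200, seed=3)
        m = build_og_matrix(records)
        assert set(m.genomes) == set(
            truth.payload["producers"] + truth.payload["non_producers"]
        )
        assert truth.payload["causal_og"] in m.ogs

    def test_malformed_rows_rejected_with_position(self):
        records = _records([("g1", "A", "OG1", "x", "S"), ("", "A", "OG2", "x", "S")])
        with pytest.raises(ValueError, match="1"):
            build_og_matrix(records)


class TestFunnel:
    def _simple(self):
        rows = [
            ("g1", "P1", "X", "", ""), ("g2", "P2", "X", "", ""),
            ("g3", "P1", "Y", "", ""),
            ("g4", "N1", "X", "", ""),
        ]
        return build_og_matrix(_records(rows))

    def test_core_requires_every_producer(self):
        m = self._simple()
        part = PhenotypePartition({"P1", "P2"}, {"N1"})
        assert core_ogs(m, part) == {"X"}

    def test_single_producer_core_is_its_og_set(self):
        m = self._simple()
        part = PhenotypePartition({"P1"}, set())
        assert core_ogs(m, part) == {"X", "Y"}

    def test_unique_requires_absence_from_each_nonproducer(self):
        rows = [
            ("g1", "P1", "A", "", ""), ("g2", "P2", "A", "", ""),
            ("g3", "P1", "B", "", ""), ("g4", "P2", "B", "", ""),
            ("g5", "N1", "A", "", ""),
        ]
        m = build_og_matrix(_records(rows))
        part = PhenotypePartition({"P1", "P2"}, {"N1", "N2"})
        core = core_ogs(m, part)
        assert core == {"A", "B"}
        # A is in one of the two non-producers: excluded by strict absence
        assert producer_unique_ogs(core, m, part) == {"B"}

    def test_no_nonproducers_warns_and_returns_core(self):
        m = self._simple()
        part = PhenotypePartition({"P1", "P2"}, set())
        core = core_ogs(m, part)
        with pytest.warns(UserWarning):
            assert producer_unique_ogs(core, m, part) == core

    def test_empty_producer_set_rejected(self):
        with pytest.raises(ValueError):
            PhenotypePartition(set(), {"N1"})

    def test_nesting_invariant_on_synthetic_cohort(self):
        records, truth = simulate_genomes(n_background_ogs=300, seed=11)
        part = PhenotypePartition(
            truth.payload["producers"], truth.payload["non_producers"]
        )
        report = run_screen(records, part)
        candidate_ogs = {og for og, _a, _t in report.keyword_candidates}
        assert candidate_ogs <= report.producer_unique <= report.core_ogs
        assert report.shared_with_nonproducers == report.core_ogs - report.producer_unique

    def test_adding_nonproducer_never_grows_unique(self):
        records, truth = simulate_genomes(n_background_ogs=300, seed=12)
        producers = truth.payload["producers"]
        non_producers = truth.payload["non_producers"]
        m = build_og_matrix(records)
        part_small = PhenotypePartition(producers, non_producers[:1])
        part_full = PhenotypePartition(producers, non_producers)
        core = core_ogs(m, part_small)
        small = producer_unique_ogs(core, m, part_small)
        full = producer_unique_ogs(core_ogs(m, part_full), m, part_full)
        assert full <= small


class TestAnnotationFilter:
    def test_published_candidate_table_has_37_ogs_two_acyltransferases(self):
        table = load_candidate_table()
        assert len(table) == 37
        records = pd.DataFrame(
            {
                "gene_id": table["locus_tag"],
                "genome_id": "R_pomeroyi",
                "og_id": table["og_id"],
                "annotation": table["annotation"],
                "cog_category": table["cog_category"],
            }
        )
        hits = filter_by_annotation(set(table["og_id"]), records)
        assert sorted(og for og, _a, _t in hits) == ["05CDD", "08UX5"]
        annotations = {og: a for og, a, _t in hits}
        assert annotations["05CDD"] == "Phospholipid glycerol acyltransferase"
        assert annotations["08UX5"] == "Acetyltransferase, (GNAT) family"

    def test_empty_pattern_list_rejected(self):
        with pytest.raises(ValueError):
            filter_by_annotation({"OG1"}, _records([("g", "A", "OG1", "x", "")]), [])

    def test_invalid_regex_rejected(self):
        with pytest.raises(ValueError, match="regex"):
            filter_by_annotation(
                {"OG1"}, _records([("g", "A", "OG1", "x", "")]), ["(["]
            )

    def test_no_match_is_empty(self):
        out = filter_by_annotation(
            {"OG1"}, _records([("g", "A", "OG1", "kinase", "")]), ["acyltransferase"]
        )
        assert out == []

    def test_representative_annotation_majority_then_lexicographic(self):
        records = _records(
            [
                ("g1", "A", "OG1", "beta", ""),
                ("g2", "B", "OG1", "alpha", ""),
                ("g3", "C", "OG1", "beta", ""),
                ("g4", "A", "OG2", "zeta", ""),
                ("g5", "B", "OG2", "eta", ""),
            ]
        )
        reps = representative_annotations(records)
        assert reps.loc["OG1", "annotation"] == "beta"  # majority
        assert reps.loc["OG2", "annotation"] == "eta"  # tie -> lexicographic


class TestRunScreen:
    def test_planted_causal_og_is_sole_keyword_candidate(self):
        records, truth = simulate_genomes(n_background_ogs=500, seed=5)
        part = PhenotypePartition(
            truth.payload["producers"], truth.payload["non_producers"]
        )
        report = run_screen(records, part)
        assert [og for og, _a, _t in report.keyword_candidates] == [
            truth.payload["causal_og"]
        ]
        assert truth.payload["causal_og"] in report.producer_unique

    def test_degenerate_background_isolates_causal_og(self):
        records, truth = simulate_genomes(
            n_background_ogs=50, n_confounders=0, n_clade_markers=0,
            background_presence=1.0, seed=6,
        )
        part = PhenotypePartition(
            truth.payload["producers"], truth.payload["non_producers"]
        )
        report = run_screen(records, part)
        assert report.producer_unique == {truth.payload["causal_og"]}

    def test_report_is_candidate_report(self):
        records, truth = simulate_genomes(n_background_ogs=100, seed=7)
        part = PhenotypePartition(
            truth.payload["producers"], truth.payload["non_producers"]
        )
        report = run_screen(records, part)
        assert isinstance(report, CandidateReport)
        sizes = report.venn_sizes
        assert sizes["core"] >= sizes["producer_unique"] >= sizes["keyword_candidates"]
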