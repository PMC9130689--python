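import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import geocna as g
from geocna.errors import (
    DegeneracyError,
    DomainError,
    SchemaError,
    SearchExhaustedError,
    UndefinedMetricError,
)
from conftest import random_case_table
from oracles import brute_msc, ext_of, outcome_ext, row_key


class TestLiteralsAndGrammar:
    def test_empty_level_set_forbidden(self):
        with pytest.raises(DomainError):
            g.Literal("A", [])

    def test_duplicate_factor_forbidden(self):
        with pytest.raises(DomainError):
            g.Conjunction([g.Literal("A", [0]), g.Literal("A", [1])])

    def test_complement(self):
        lit = g.Literal("ICEBLACK", [0, 1])
        assert lit.complement({0, 1, 2}) == g.Literal("ICEBLACK", [2])
        with pytest.raises(DomainError):
            g.Literal("A", [0, 1]).complement({0, 1})

    @pytest.mark.parametrize(
        "text",
        ["EDU=0", "ICEBLACK=0|1", "EDU=0*ICEBLACK=0|1", "A=1*B=0|2*C=2"],
    )
    def test_parse_print_round_trip(self, text):
        if "*" in text:
            assert str(g.parse_conjunction(text)) == text
        else:
            assert str(g.parse_literal(text)) == text

    def test_disjunction_grammar(self):
        disj = g.parse_disjunction("EDU=1|2 + ICEBLACK=2")
        assert [str(c) for c in disj] == ["EDU=1|2", "ICEBLACK=2"]

    def test_canonical_ordering(self):
        conj = g.Conjunction([g.Literal("B", [0]), g.Literal("A", [1])])
        assert str(conj) == "A=1*B=0"


class TestExtensionAndMetrics:
    def test_extension_matches_direct_filter(self, toy_table):
        ext = g.extension(g.parse_conjunction("A=1*B=0"), toy_table)
        direct = {
            cid for cid, row in toy_table.levels.iterrows()
            if row["A"] == 1 and row["B"] == 0
        }
        assert ext == direct == {"c0", "c1"}

    def test_unknown_factor_rejected(self, toy_table):
        with pytest.raises(SchemaError):
            g.extension(g.Literal("Z", [0]), toy_table)

    def test_fixture_reproduces_printed_ratios(self, study_fixture):
        y = g.Literal("PLOW", [1])
        ny = g.Literal("PLOW", [0])
        pos = g.parse_conjunction("EDU=0*ICEBLACK=0|1")
        neg = g.parse_disjunction("EDU=1|2 + ICEBLACK=2")
        assert g.consistency(pos, y, study_fixture) == pytest.approx(11 / 12)
        assert g.coverage(pos, y, study_fixture) == pytest.approx(11 / 13)
        assert g.consistency(neg, ny, study_fixture) == pytest.approx(28 / 30)
        assert g.coverage(neg, ny, study_fixture) == pytest.approx(28 / 29)

    def test_subset_extension_gives_perfect_consistency(self, toy_table):
        # extension of A=1*B=0 is exactly the outcome set
        assert g.consistency(g.parse_conjunction("A=1*B=0"),
                             g.Literal("Y", [1]), toy_table) == 1.0

    def test_empty_extension_is_undefined_not_zero(self, toy_table):
        # no case has A=0 and B=0 and C=2
        conj = g.parse_conjunction("A=0*B=0*C=2")
        with pytest.raises(UndefinedMetricError):
            g.consistency(conj, g.Literal("Y", [1]), toy_table)

    def test_empty_outcome_is_undefined(self, toy_table):
        never_instantiated = g.Literal("C", [5])
        with pytest.raises(UndefinedMetricError):
            g.coverage(g.Literal("A", [1]), never_instantiated, toy_table)

    @given(seed=st.integers(0, 200))
    @settings(max_examples=25)
    def test_duality_coverage_is_reverse_consistency(self, seed):
        """coverage(X -> Y) == consistency(Y -> X) on random tables."""
        table = random_case_table(np.random.default_rng(seed), 4, 25)
        y = g.Literal("Y", [1])
        x = g.Literal("A", [0])
        if not g.extension(x, table) or not g.extension(y, table):
            return
        assert g.coverage(x, y, table) == pytest.approx(
            g.consistency(y, x, table))

    @given(seed=st.integers(0, 200))
    @settings(max_examples=25)
    def test_adding_literal_never_increases_coverage(self, seed):
        table = random_case_table(np.random.default_rng(seed), 4, 25)
        y = g.Literal("Y", [1])
        base = g.Conjunction([g.Literal("A", [0])])
        bigger = g.Conjunction([g.Literal("A", [0]), g.Literal("B", [0])])
        ext_base = g.extension(base, table)
        ext_big = g.extension(bigger, table)
        assert ext_big <= ext_base
        assert g.coverage(bigger, y, table) <= g.coverage(base, y, table)


class TestEnumerateMsc:
    def test_planted_conjunction_toy_table(self, toy_table):
        """On the 8-case table with Y=1 iff A=1 and B=0 the MSC set at
        threshold 1.0 matches the brute-force oracle exactly."""
        y = g.Literal("Y", [1])
        ct = g.enumerate_msc(toy_table, y, max_order=3, threshold=1.0)
        assert {row_key(r) for r in ct.rows} == brute_msc(toy_table, y, 3, 1.0)
        assert "A=1*B=0" in ct.configurations()

    def test_single_literal_rule_no_superset_retained(self):
        levels = pd.DataFrame(
            {
                "C": [2, 2, 2, 0, 1, 0, 1, 2],
                "D": [0, 1, 2, 0, 1, 2, 0, 1],
            },
            index=[f"c{i}" for i in range(8)],
        )
        levels["Y"] = (levels["C"] == 2).astype(int)
        table = g.CaseTable(levels=levels, outcome_name="Y")
        y = g.Literal("Y", [1])
        ct = g.enumerate_msc(table, y, max_order=2, threshold=1.0)
        # the planted literal ranks first (full coverage); no superset of it
        # survives minimality, and the table agrees with the oracle
        assert ct.configurations()[0] == "C=2"
        assert not any(
            r.conjunction.order > 1 and "C=2" in str(r.conjunction)
            for r in ct.rows
        )
        assert {row_key(r) for r in ct.rows} == brute_msc(table, y, 2, 1.0)

    def test_value_set_enlargement_minimality(self):
        """A specific literal is dropped when a larger accepted set keeps
        the threshold (canonical value-set form)."""
        levels = pd.DataFrame(
            {"A": [0, 0, 1, 1, 2, 2, 2, 0], "B": [0, 1, 2, 0, 1, 2, 0, 2]},
            index=[f"c{i}" for i in range(8)],
        )
        levels["Y"] = levels["A"].isin([0, 1]).astype(int)
        table = g.CaseTable(levels=levels, outcome_name="Y")
        ct = g.enumerate_msc(table, g.Literal("Y", [1]), max_order=2,
                             threshold=1.0)
        assert ct.configurations() == ["A=0|1"]

    def test_degenerate_outcome_rejected(self, toy_table):
        levels = toy_table.levels.copy()
        levels["Y"] = 1
        table = g.CaseTable(levels=levels, outcome_name="Y")
        with pytest.raises(DegeneracyError):
            g.enumerate_msc(table, g.Literal("Y", [1]), 2, 1.0)

    def test_rows_respect_stored_counts(self, study_fixture):
        y = g.Literal("PLOW", [1])
        ct = g.enumerate_msc(study_fixture, y, max_order=2, threshold=0.9)
        n_y = len(g.extension(y, study_fixture))
        for row in ct.rows:
            ext = g.extension(row.conjunction, study_fixture)
            assert row.n_instantiating == len(ext)
            assert row.n_overlap == len(ext & g.extension(y, study_fixture))
            assert row.consistency == pytest.approx(row.n_overlap / row.n_instantiating)
            assert row.coverage == pytest.approx(row.n_overlap / n_y)

    @given(seed=st.integers(0, 500))
    @settings(max_examples=40)
    def test_agrees_with_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        table = random_case_table(rng, 4, 30)
        threshold = float(rng.choice([1.0, 0.9, 0.8, 0.75]))
        y = g.Literal("Y", [1])
        ct = g.enumerate_msc(table, y, max_order=2, threshold=threshold)
        assert {row_key(r) for r in ct.rows} == brute_msc(table, y, 2, threshold)

    def test_lower_threshold_reminimized_against_oracle(self, toy_table):
        y = g.Literal("Y", [1])
        for threshold in (1.0, 0.75, 0.5):
            ct = g.enumerate_msc(toy_table, y, max_order=3, threshold=threshold)
            assert {row_key(r) for r in ct.rows} == \
                brute_msc(toy_table, y, 3, threshold)


class TestThresholdSearch:
    def test_stops_at_start_when_enough_rows(self, toy_table):
        y = g.Literal("Y", [1])
        t, ct, trail = g.threshold_search(toy_table, y, max_order=2,
                                          min_rows=1)
        assert t == 1.0
        assert trail == [(1.0, len(ct))]
        assert len(ct) >= 1

    def test_trail_matches_oracle_recounts(self):
        rng = np.random.default_rng(99)
        table = random_case_table(rng, 4, 40)
        y = g.Literal("Y", [1])
        t, ct, trail = g.threshold_search(table, y, max_order=2, min_rows=3)
        for threshold, n_rows in trail:
            assert n_rows == len(brute_msc(table, y, 2, threshold))
        assert trail[-1][0] == t
        assert trail[-1][1] >= 3
        assert all(n < 3 for _, n in trail[:-1])

    def test_exhaustion_error(self):
        levels = pd.DataFrame(
            {"A": [0, 1, 2, 0, 1, 2], "Y": [1, 0, 1, 0, 1, 0]},
            index=[f"c{i}" for i in range(6)],
        )
        table = g.CaseTable(levels=levels, outcome_name="Y")
        with pytest.raises(SearchExhaustedError):
            g.threshold_search(table, g.Literal("Y", [1]), max_order=1,
                               min_rows=50)
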