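"""Expression input, linear transforms and Booleanization."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from lineagespec.expression import (
    BooleanProfile,
    ExpressionError,
    ExpressionMatrix,
    StageDesign,
    booleanize,
    impute_missing,
    rank_sum_p_greater,
    read_expression,
    subset_tfs,
)
from oracles import exact_rank_sum_p_greater


def _write_matrix(tmp_path, table: pd.DataFrame, labels: dict):
    expr_path = tmp_path / "expr.tsv"
    table.to_csv(expr_path, sep="\t")
    label_path = tmp_path / "labels.tsv"
    with open(label_path, "w") as fh:
        for c, sp in labels.items():
            fh.write(f"{c}\t{sp}\n")
    return expr_path, label_path


class TestReadExpression:
    def test_ct_transform_reverses_ranks(self, tmp_path):
        table = pd.DataFrame({"c1": [10.0, 11.0], "c2": [11.0, 10.0]}, index=["g1", "g2"])
        paths = _write_matrix(tmp_path, table, {"c1": "X", "c2": "X"})
        m = read_expression(*paths, assay="ct")
        assert m.values.loc["g1", "c1"] == pytest.approx(2.0**-10)
        assert m.values.loc["g2", "c1"] == pytest.approx(2.0**-11)
        # higher C_T means lower expression
        assert m.values.loc["g1", "c1"] > m.values.loc["g2", "c1"]

    def test_equal_ct_gives_equal_expression(self, tmp_path):
        table = pd.DataFrame({"c1": [12.0], "c2": [12.0]}, index=["g1"])
        m = read_expression(*_write_matrix(tmp_path, table, {"c1": "X", "c2": "X"}), assay="ct")
        assert m.values.loc["g1", "c1"] == m.values.loc["g1", "c2"]

    def test_fpkm_missing_imputed_with_global_minimum(self, tmp_path):
        expr_path = tmp_path / "expr.tsv"
        expr_path.write_text("gene\tc1\tc2\ng1\t5.0\tNA\ng2\t2.0\t7.0\n")
        label_path = tmp_path / "labels.tsv"
        label_path.write_text("c1\tX\nc2\tX\n")
        m = read_expression(expr_path, label_path, assay="fpkm")
        assert m.values.loc["g1", "c2"] == 2.0

    def test_unlabeled_cell_rejected(self, tmp_path):
        table = pd.DataFrame({"c1": [1.0], "c2": [2.0]}, index=["g1"])
        paths = _write_matrix(tmp_path, table, {"c1": "X"})
        with pytest.raises(ExpressionError, match="without"):
            read_expression(*paths, assay="fpkm")

    def test_non_numeric_entry_rejected(self, tmp_path):
        expr_path = tmp_path / "expr.tsv"
        expr_path.write_text("gene\tc1\ng1\tnot_a_number\n")
        label_path = tmp_path / "labels.tsv"
        label_path.write_text("c1\tX\n")
        with pytest.raises(ExpressionError, match="non-numeric"):
            read_expression(expr_path, label_path, assay="fpkm")


class TestImputeMissing:
    @pytest.mark.parametrize(
        "data, expected",
        [
            ([[1.0, np.nan], [3.0, 4.0]], [[1.0, 1.0], [3.0, 4.0]]),
            ([[1.0, 2.0], [3.0, 4.0]], [[1.0, 2.0], [3.0, 4.0]]),
            ([[np.nan, 5.0]], [[5.0, 5.0]]),
        ],
    )
    def test_missing_replaced_by_minimum(self, data, expected):
        np.testing.assert_allclose(impute_missing(np.array(data)), expected)

    def test_never_changes_minimum(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            data = rng.exponential(size=(4, 6))
            data[rng.random(data.shape) < 0.3] = np.nan
            if np.isnan(data).all():
                continue
            assert np.nanmin(impute_missing(data)) == np.nanmin(data)

    def test_all_missing_rejected(self):
        with pytest.raises(ExpressionError):
            impute_missing(np.full((2, 2), np.nan))


class TestSubsetTfs:
    def _matrix(self, genes):
        values = pd.DataFrame(np.ones((len(genes), 2)), index=genes, columns=["c1", "c2"])
        return ExpressionMatrix(values=values, cell_labels={"c1": "X", "c2": "X"})

    def test_restricts_rows_preserving_order(self):
        m = self._matrix([f"g{i}" for i in range(10)])
        sub = subset_tfs(m, {"g7", "g2", "g5", "g0"})
        assert sub.gene_ids == ["g0", "g2", "g5", "g7"]

    def test_superset_is_identity(self):
        m = self._matrix(["g1", "g2"])
        assert subset_tfs(m, {"g1", "g2", "g3"}).gene_ids == m.gene_ids

    def test_disjoint_list_rejected(self):
        with pytest.raises(ExpressionError):
            subset_tfs(self._matrix(["g1"]), {"zzz"})


class TestRankSumExactness:
    def test_matches_enumeration_oracle_small_n(self):
        rng = np.random.default_rng(42)
        for _ in range(30):
            n1 = int(rng.integers(2, 5))
            n2 = int(rng.integers(2, 6))
            # integer draws force ties into the comparison
            x = rng.integers(0, 5, size=n1).astype(float)
            y = rng.integers(0, 5, size=n2).astype(float)
            assert rank_sum_p_greater(x, y) == pytest.approx(exact_rank_sum_p_greater(x, y), abs=1e-9)

    def test_maximal_shift_is_significant(self):
        x = np.arange(20.0, 30.0)
        y = np.arange(0.0, 20.0)
        assert rank_sum_p_greater(x, y) < 0.01

    def test_identical_samples_not_significant(self):
        x = np.arange(10.0)
        y = np.concatenate([np.arange(10.0), np.arange(10.0)])
        assert rank_sum_p_greater(x, y) > 0.4

    @settings(deadline=None, max_examples=25)
    @given(
        st.lists(st.floats(0.1, 100.0), min_size=3, max_size=5),
        st.lists(st.floats(0.1, 100.0), min_size=3, max_size=6),
        st.floats(0.5, 3.0),
    )
    def test_invariant_under_monotone_transform(self, x, y, power):
        """A rank test cannot see strictly monotone rescaling."""
        p1 = rank_sum_p_greater(np.array(x), np.array(y))
        p2 = rank_sum_p_greater(np.array(x) ** power, np.array(y) ** power)
        assert p1 == pytest.approx(p2, abs=1e-9)


class TestBooleanize:
    def _design(self):
        return StageDesign(stages=[("s1", frozenset({"X", "Y"}))])

    def _matrix(self, x_vals, y_vals, gene="g1"):
        cells = [f"x{i}" for i in range(len(x_vals))] + [f"y{i}" for i in range(len(y_vals))]
        values = pd.DataFrame([list(x_vals) + list(y_vals)], index=[gene], columns=cells)
        labels = {c: ("X" if c.startswith("x") else "Y") for c in cells}
        return ExpressionMatrix(values=values, cell_labels=labels)

    def test_clear_overexpression_is_active(self):
        m = self._matrix(np.arange(100, 110.0), np.arange(0, 20.0))
        profile = booleanize(m, self._design(), "X")
        assert profile.states["g1"] == 1
        assert profile.pvalues["g1"] < 0.01

    def test_no_shift_is_inactive(self):
        m = self._matrix(np.arange(10.0), np.arange(10.0))
        profile = booleanize(m, self._design(), "X")
        assert profile.states["g1"] == 0

    def test_decision_flips_correctly_around_the_cutoff(self):
        # two constructed 3-cell cases whose exact p against the union
        # background straddles the 0.4 cutoff: 33/84 just below (active) and
        # 34/84 just above (inactive)
        cases = [
            ([1.0, 3.0, 4.0], [1.0, 2.0, 2.0], 33 / 84, 1),
            ([1.0, 2.0, 2.0], [1.0, 1.0, 1.0], 34 / 84, 0),
        ]
        for x, y, exact_p, expected in cases:
            m = self._matrix(x, y)
            profile = booleanize(m, self._design(), "X")
            assert profile.pvalues["g1"] == pytest.approx(exact_p, abs=1e-12)
            assert profile.states["g1"] == expected

    def test_background_includes_own_cells(self):
        # X cells high, Y cells low: X's background is the union of both, so
        # the p-value reflects X against X+Y, not X against Y alone
        m = self._matrix([10.0, 11.0, 12.0, 13.0], [1.0, 2.0, 3.0, 4.0])
        profile = booleanize(m, self._design(), "X")
        p_vs_union = rank_sum_p_greater(
            np.array([10.0, 11, 12, 13]), np.array([10.0, 11, 12, 13, 1, 2, 3, 4])
        )
        assert profile.pvalues["g1"] == pytest.approx(p_vs_union)
        assert profile.states["g1"] == 1

    def test_too_few_cells_rejected(self):
        m = self._matrix([1.0], [2.0, 3.0])
        with pytest.raises(ExpressionError, match="<2 cells"):
            booleanize(m, self._design(), "X")

    def test_unknown_subpopulation_rejected(self):
        m = self._matrix([1.0, 2.0], [2.0, 3.0])
        with pytest.raises(ExpressionError):
            booleanize(m, self._design(), "Z")


class TestStageDesign:
    def test_yaml_round_trip(self, tmp_path):
        design = StageDesign(
            stages=[("early", frozenset({"P", "O"})), ("late", frozenset({"A", "B"}))],
            lineage_triples=[("P", "A", "B")],
        )
        path = tmp_path / "design.yaml"
        design.to_yaml(path)
        loaded = StageDesign.from_yaml(path)
        assert loaded.stages == design.stages
        assert loaded.lineage_triples == design.lineage_triples

    def test_triple_members_must_appear_in_a_stage(self):
        with pytest.raises(ExpressionError):
            StageDesign(stages=[("s", frozenset({"A", "B"}))], lineage_triples=[("P", "A", "B")])

    def test_identical_daughters_rejected(self):
        with pytest.raises(ExpressionError):
            StageDesign(stages=[("s", frozenset({"P", "A"}))], lineage_triples=[("P", "A", "A")])
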