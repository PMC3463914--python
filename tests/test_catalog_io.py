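"""Expression-table and catalogue IO: parsing, merging, fixtures."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

import leafcoex as lx
from leafcoex.errors import (
    DimensionError,
    DuplicateConflictError,
    DuplicateGeneError,
    ExpressionFormatError,
)


def _write(tmp_path, text, name="expr.tsv"):
    p = tmp_path / name
    p.write_text(text)
    return p


class TestReadExpressionTable:
    def test_table1_fixture_loads_as_printed(self, table1):
        assert table1.n_genes == 24
        assert table1.zones == ("basal", "transitional", "maturing", "mature")
        assert table1.values.loc["GRMZM2G174807", "basal"] == 1373.24
        # the three below-detection cells of the printed table
        flagged = table1.below_detection
        assert flagged.to_numpy().sum() == 3
        assert flagged.loc["GRMZM2G305446", ["maturing", "mature"]].all()
        assert table1.values.loc["GRMZM2G305446", "maturing"] == 0.0

    def test_empty_file_is_a_format_error(self, tmp_path):
        with pytest.raises(ExpressionFormatError):
            lx.read_expression_table(_write(tmp_path, ""))

    def test_single_gene_uniform_row_accepted(self, tmp_path):
        p = _write(tmp_path, "gene_id\tname\tz1\tz2\tz3\tz4\nG1\tg\t1\t1\t1\t1\n")
        t = lx.read_expression_table(p)
        assert t.n_genes == 1
        assert list(t.values.iloc[0]) == [1.0, 1.0, 1.0, 1.0]

    def test_missing_header_is_a_format_error(self, tmp_path):
        p = _write(tmp_path, "G1\tg\t1\t2\t3\t4\nG2\tg\t1\t2\t3\t4\n")
        with pytest.raises(ExpressionFormatError):
            lx.read_expression_table(p)

    def test_fewer_than_two_zones_is_a_dimension_error(self, tmp_path):
        p = _write(tmp_path, "gene_id\tname\tbasal\nG1\tg\t1\n")
        with pytest.raises(DimensionError):
            lx.read_expression_table(p)

    @pytest.mark.parametrize("cell", ["abc", "-1.5"])
    def test_bad_cell_error_names_row_and_column(self, tmp_path, cell):
        p = _write(tmp_path, f"gene_id\tname\tz1\tz2\nG1\tg\t1\t{cell}\n")
        with pytest.raises(ExpressionFormatError, match="'G1'.*'z2'"):
            lx.read_expression_table(p)

    def test_strict_mode_refuses_any_duplicate(self, tmp_path):
        p = _write(tmp_path, "gene_id\tname\tz1\tz2\nG1\ta\t1\t2\nG1\tb\t1\t2\n")
        with pytest.raises(DuplicateGeneError, match="collapse_duplicates"):
            lx.read_expression_table(p, on_duplicate="raise")
        assert lx.read_expression_table(p).n_genes == 2

    def test_conflicting_duplicate_rows_always_refused(self, tmp_path):
        p = _write(tmp_path, "gene_id\tname\tz1\tz2\nG1\ta\t1\t2\nG1\tb\t9\t2\n")
        with pytest.raises(DuplicateConflictError):
            lx.read_expression_table(p)


class TestRoundTrip:
    def test_table1_round_trip_is_bit_exact(self, tmp_path, table1):
        out = tmp_path / "t1.tsv"
        lx.write_expression_table(table1, out)
        back = lx.read_expression_table(out)
        pd.testing.assert_frame_equal(back.values, table1.values)
        pd.testing.assert_frame_equal(back.below_detection, table1.below_detection)
        assert back.names == table1.names

    @given(
        rows=st.lists(
            st.lists(
                st.floats(min_value=0, max_value=1e6, allow_nan=False),
                min_size=3,
                max_size=3,
            ),
            min_size=1,
            max_size=6,
        )
    )
    def test_round_trip_reproduces_arbitrary_values(self, tmp_path_factory, rows):
        tmp = tmp_path_factory.mktemp("rt")
        df = pd.DataFrame(
            rows, index=[f"G{i}" for i in range(len(rows))], columns=["a", "b", "c"]
        )
        table = lx.ExpressionTable.from_frame(df)
        out = tmp / "m.tsv"
        lx.write_expression_table(table, out)
        back = lx.read_expression_table(out)
        assert (back.values.to_numpy() == df.to_numpy()).all()


class TestCollapseDuplicates:
    def test_table1_collapses_to_23_gene_models(self, table1, catalogue):
        collapsed, report = lx.collapse_duplicates(table1, catalogue)
        assert collapsed.n_genes == 23
        assert len(report) == 1
        assert report[0].gene_id == "GRMZM2G392975"
        assert report[0].names == ("ZmPIP1;3", "ZmPIP1;4")
        assert "ZmPIP1;4" in catalogue["GRMZM2G392975"].names

    def test_idempotent_and_identity_without_duplicates(self, table1):
        once, _ = lx.collapse_duplicates(table1)
        twice, report = lx.collapse_duplicates(once)
        assert report == []
        pd.testing.assert_frame_equal(once.values, twice.values)

    def test_conflicting_rows_raise_instead_of_averaging(self):
        df = pd.DataFrame(
            [[1.0, 2.0], [3.0, 2.0]], index=["G1", "G1"], columns=["a", "b"]
        )
        with pytest.raises(DuplicateConflictError):
            lx.collapse_duplicates(lx.ExpressionTable.from_frame(df))


@pytest.mark.parametrize(
    "name,expected",
    [
        ("ZmPIP2;5", "PIP2"),
        ("ZmPIP1;1", "PIP1"),
        ("ZmNIP5;1", "NIP"),
        ("ZmTIP4;2", "TIP"),
        ("ZmSIP1;1", "SIP"),
        ("GRMZM2G455124", "other"),
        ("", "other"),
    ],
)
def test_classify_by_name(name, expected):
    assert lx.classify_by_name(name) == expected


class TestCatalogue:
    def test_aquaporin_family_counts(self, catalogue):
        assert catalogue.n_names == 33
        counts = catalogue.subfamily_counts()
        assert counts == {"PIP1": 6, "PIP2": 7, "TIP": 11, "NIP": 6, "SIP": 3}
        # PIPs quoted as a single family of 13
        assert counts["PIP1"] + counts["PIP2"] == 13

    def test_shared_gene_model_is_one_record_with_two_names(self, catalogue):
        rec = catalogue["GRMZM2G392975"]
        assert rec.names == ("ZmPIP1;3", "ZmPIP1;4")
        assert len(catalogue) == 32

    def test_never_printed_member_carries_flagged_placeholder(self, catalogue):
        placeholders = [r for r in catalogue if r.placeholder]
        assert [r.names for r in placeholders] == [("ZmPIP1;2",)]

    def test_gene_class_must_match_symbol_prefix(self):
        with pytest.raises(ValueError, match="contradicts"):
            lx.GeneRecord("G1", names=("ZmPIP1;9",), gene_class="TIP")

    def test_catalogue_round_trip(self, tmp_path, catalogue):
        out = tmp_path / "cat.tsv"
        lx.write_catalogue(catalogue, out)
        back = lx.read_catalogue(out)
        assert back.n_names == catalogue.n_names
        assert back.subfamily_counts() == catalogue.subfamily_counts()
        assert back["GRMZM2G392975"].names == ("ZmPIP1;3", "ZmPIP1;4")
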