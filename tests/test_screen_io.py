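import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import pairscreen as ps
from pairscreen.screen_io import (
    RESULT_COLUMNS,
    ResultTable,
    ScreenFormatError,
    ScreenTable,
    ScreenValidationError,
    trimmed_mean,
    write_screen_csv,
)


def _write(tmp_path, text, name="screen.csv"):
    path = tmp_path / name
    path.write_text(text)
    return path


class TestReadScreenCsv:
    def test_duplicate_rows_become_replicates(self, tmp_path):
        path = _write(tmp_path, "X;d1;10\nX;d1;12\nY;d1;5\nX;d2;7\nY;d2;3\n")
        table = ps.read_screen_csv(path)
        sub = table.data[(table.data.pert_a == "X") & (table.data.pert_b == "d1")]
        assert list(sub.rep2) == [1, 2]
        assert list(sub.score) == [10.0, 12.0]

    def test_five_column_lossless_order_preserved(self, tmp_path):
        lines = [f"a{i % 3};b{i % 2};{i + 1}.5;h{i % 2};{i // 6 + 1}" for i in range(6)]
        path = _write(tmp_path, "\n".join(lines))
        table = ps.read_screen_csv(path)
        assert len(table) == 6
        assert list(table.data.score) == [i + 1.5 for i in range(6)]

    def test_header_detected_and_skipped(self, tmp_path):
        path = _write(tmp_path, "pertA;pertB;score\nX;d1;10\nY;d1;2\nX;d2;3\nY;d2;4\n")
        table = ps.read_screen_csv(path)
        assert len(table) == 4
        assert table.meta["header"] is True

    def test_non_numeric_score_names_line(self, tmp_path):
        path = _write(
            tmp_path, "X;d1;10\nY;d1;2\nX;d2;3\nY;d2;4\nX;d3;5\nY;d3;6\nX;d4;NA\n"
        )
        with pytest.raises(ScreenFormatError, match="line 7"):
            ps.read_screen_csv(path)

    def test_empty_file_errors(self, tmp_path):
        with pytest.raises(ScreenFormatError, match="empty"):
            ps.read_screen_csv(_write(tmp_path, ""))

    def test_single_axis_level_rejected(self, tmp_path):
        path = _write(tmp_path, "X;d1;10\nX;d2;12\n")
        with pytest.raises(ScreenValidationError, match="2 distinct"):
            ps.read_screen_csv(path)

    @pytest.mark.parametrize(
        "dialect,sep", [("comma", ","), ("tab", "\t"), ("semicolon", ";")]
    )
    def test_dialects(self, tmp_path, dialect, sep):
        text = "\n".join(sep.join(p) for p in
                         [("X", "d1", "1"), ("Y", "d1", "2"),
                          ("X", "d2", "3"), ("Y", "d2", "4")])
        table = ps.read_screen_csv(_write(tmp_path, text), dialect=dialect)
        assert len(table) == 4

    def test_reimport_is_stable(self, tmp_path):
        path = _write(tmp_path, "X;d1;10\nX;d1;12\nY;d1;5\nY;d2;3\nX;d2;7\nX;d1;9\n")
        t1 = ps.read_screen_csv(path)
        t2 = ps.read_screen_csv(path)
        pd.testing.assert_frame_equal(t1.data, t2.data)

    def test_write_read_round_trip(self, tmp_path, small_screen):
        path = tmp_path / "out.csv"
        write_screen_csv(small_screen, path)
        back = ps.read_screen_csv(path)
        pd.testing.assert_frame_equal(
            back.data.astype({"rep2": int}), small_screen.data.astype({"rep2": int})
        )


class TestTrimmedMean:
    def test_hand_example(self):
        assert trimmed_mean(np.array([1, 2, 3, 4, 100]), 0.2) == 3.0

    def test_zero_trim_is_mean(self):
        v = np.array([1.0, 5.0, 9.0, 2.0])
        assert trimmed_mean(v, 0.0) == pytest.approx(v.mean())

    @given(
        beads=st.lists(st.floats(0, 1e6, allow_nan=False), min_size=1, max_size=30),
        trim=st.floats(0, 0.49),
    )
    @settings(max_examples=100, deadline=None)
    def test_permutation_invariant_and_bounded(self, beads, trim):
        v = np.array(beads)
        m = trimmed_mean(v, trim)
        assert trimmed_mean(v[::-1], trim) == m
        assert v.min() - 1e-9 <= m <= v.max() + 1e-9

    def test_constant_invariance(self):
        for trim in (0.0, 0.1, 0.25, 0.4):
            assert trimmed_mean(np.full(7, 3.25), trim) == 3.25


class TestImportLuminex:
    def test_beads_reduced_per_pair(self, tmp_path):
        lines = []
        for cell in ("c1", "c2"):
            for drug in ("d1", "d2"):
                for bead in (1, 2, 3, 4, 100):
                    lines.append(f"{cell};{drug};{bead}")
        path = _write(tmp_path, "\n".join(lines))
        table = ps.import_luminex(path, trim_fraction=0.2)
        assert len(table) == 4
        assert set(table.data.score) == {3.0}

    def test_negative_bead_errors(self, tmp_path):
        path = _write(tmp_path, "c1;d1;5\nc1;d1;-2\nc2;d1;1\nc1;d2;1\nc2;d2;1\n")
        with pytest.raises(ScreenFormatError, match="line 2"):
            ps.import_luminex(path)

    def test_replicate_column_splits_groups(self, tmp_path):
        lines = []
        for rep in ("r1", "r2"):
            for bead in (10, 20, 30):
                lines.append(f"c1;d1;{bead};{rep}")
                lines.append(f"c2;d1;{bead};{rep}")
                lines.append(f"c1;d2;{bead};{rep}")
                lines.append(f"c2;d2;{bead};{rep}")
        table = ps.import_luminex(_write(tmp_path, "\n".join(lines)), trim_fraction=0)
        sub = table.data[(table.data.pert_a == "c1") & (table.data.pert_b == "d1")]
        assert list(sub.rep2) == [1, 2]
        assert list(sub.score) == [20.0, 20.0]


class TestImportMps:
    def test_gene_parsed_from_hairpin_name(self, tmp_path):
        path = _write(
            tmp_path,
            "c1;USP7_sh1;500\nc1;USP7_sh2;300\nc2;USP7_sh1;100\nc2;USP7_sh2;200\n"
            "c1;BAP1_sh1;50\nc2;BAP1_sh1;60\n",
        )
        table = ps.import_mps(path)
        assert set(table.data.pert_b) == {"USP7", "BAP1"}
        usp7 = table.data[table.data.pert_b == "USP7"]
        assert set(usp7.rep1) == {"USP7_sh1", "USP7_sh2"}

    def test_no_delimiter_fallback(self, tmp_path):
        path = _write(tmp_path, "c1;USP7;500\nc2;USP7;300\nc1;UCHL5;10\nc2;UCHL5;20\n")
        table = ps.import_mps(path)
        row = table.data[table.data.rep1 == "USP7"].iloc[0]
        assert row.pert_b == "USP7"

    def test_repeated_rows_autonumber(self, tmp_path):
        path = _write(
            tmp_path,
            "\n".join(["c1;USP7_sh1;500"] * 4 + ["c2;USP7_sh1;100", "c1;X_sh1;2", "c2;X_sh1;3"]),
        )
        table = ps.import_mps(path)
        sub = table.data[(table.data.pert_a == "c1") & (table.data.rep1 == "USP7_sh1")]
        assert list(sub.rep2) == [1, 2, 3, 4]

    def test_zero_counts_retained_negative_rejected(self, tmp_path):
        table = ps.import_mps(
            _write(tmp_path, "c1;A_sh1;0\nc2;A_sh1;5\nc1;B_sh1;1\nc2;B_sh1;2\n")
        )
        assert (table.data.score == 0).sum() == 1
        with pytest.raises(ScreenFormatError, match="line 1"):
            ps.import_mps(_write(tmp_path, "c1;A_sh1;-3\nc2;B_sh1;5\n", "neg.csv"))


class TestResultsFile:
    def test_round_trip_close_to_machine_precision(self, tmp_path, results_fixture):
        path = tmp_path / "res.csv"
        ps.write_results(results_fixture, path)
        back = ps.read_results(path)
        a = results_fixture.data[RESULT_COLUMNS[2:]].to_numpy(dtype=float)
        b = back.data[RESULT_COLUMNS[2:]].to_numpy(dtype=float)
        mask = ~np.isnan(a)
        assert np.allclose(a[mask], b[mask], rtol=1e-12, atol=0)
        assert list(back.data.pertA) == list(results_fixture.data.pertA)

    def test_wrong_column_count_names_format(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("a;b;c;d;e;f;g;h\n1;2;3;4;5;6;7;8\n")
        with pytest.raises(ScreenFormatError, match="9 semicolon-separated"):
            ps.read_results(path)

    def test_external_file_imported_with_source(self, tmp_path):
        path = tmp_path / "external.csv"
        header = ";".join(RESULT_COLUMNS)
        path.write_text(f"{header}\ng1;d1;0.5;0.6;100;200;0.01;0.02;0.005\n")
        res = ps.read_results(path)
        assert res.meta["source"] == "external"
        assert len(res) == 1

    def test_out_of_range_p_warns_but_keeps_row(self, tmp_path):
        path = tmp_path / "warn.csv"
        header = ";".join(RESULT_COLUMNS)
        path.write_text(f"{header}\ng1;d1;0.5;0.6;100;200;1.5;0.02;0.005\n")
        with pytest.warns(UserWarning, match="outside"):
            res = ps.read_results(path)
        assert len(res) == 1


class TestScreenArithmetic:
    def test_measurement_count(self):
        assert ps.n_measurements(100, 100, 4) == 40_000

    def test_sequencing_depth(self):
        assert ps.reads_per_barcode(1e8, 100, 100) == 10_000
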