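import numpy as np
import pandas as pd
import pytest

from forestbpr.table import (
    COLUMNS,
    PlotTable,
    PlotTableError,
    derive_productivity,
    filter_complete,
    read_plot_table,
    require_nonempty,
    write_plot_table,
)

from conftest import make_table


class TestReadWrite:
    def test_round_trip_preserves_values_and_order(self, tmp_path):
        table = make_table(n=7)
        table.df.loc[2, "soil_cn"] = np.nan
        path = tmp_path / "plots.tsv"
        write_plot_table(table, path)
        back = read_plot_table(path)
        assert len(back) == 7
        assert list(back.df["plot_id"]) == list(table.df["plot_id"])
        for col in COLUMNS[2:]:
            np.testing.assert_allclose(
                back.df[col].to_numpy(float), table.df[col].to_numpy(float),
                rtol=1e-9, equal_nan=True,
            )

    def test_csv_dialect_inferred_from_suffix(self, tmp_path):
        table = make_table(n=3)
        path = tmp_path / "plots.csv"
        write_plot_table(table, path)
        assert read_plot_table(path).df.shape[0] == 3

    def test_missing_mandatory_column_is_named(self, tmp_path):
        table = make_table(n=3)
        path = tmp_path / "bad.tsv"
        table.df.drop(columns=["stand_age"]).to_csv(path, sep="\t", index=False)
        with pytest.raises(PlotTableError, match="stand_age"):
            read_plot_table(path)

    def test_malformed_cell_cites_line_number(self, tmp_path):
        table = make_table(n=8)
        path = tmp_path / "bad.tsv"
        write_plot_table(table, path)
        lines = path.read_text().splitlines()
        cols = lines[0].split("\t")
        row = lines[6].split("\t")  # file line 7 = data row 6
        row[cols.index("mat")] = "abc"
        lines[6] = "\t".join(row)
        path.write_text("\n".join(lines) + "\n")
        with pytest.raises(PlotTableError, match=r"mat.*line 7"):
            read_plot_table(path)

    def test_na_tokens_parse_as_missing(self, tmp_path):
        table = make_table(n=3)
        path = tmp_path / "plots.tsv"
        write_plot_table(table, path)
        text = path.read_text().replace(
            f"{table.df['soil_cn'].iloc[0]:.10g}", "NaN", 1
        )
        path.write_text(text)
        back = read_plot_table(path)
        assert back.df["soil_cn"].isna().iloc[0]

    def test_unforested_rows_dropped_with_warning(self, tmp_path):
        table = make_table(n=5, richness=[3.0, 0.0, 2.0, 0.0, 4.0])
        path = tmp_path / "plots.tsv"
        write_plot_table(table, path)
        with pytest.warns(UserWarning, match="richness == 0"):
            back = read_plot_table(path)
        assert len(back) == 3
        assert back.notes["n_unforested_dropped"] == 2

    def test_duplicate_plot_id_rejected(self):
        with pytest.raises(PlotTableError, match="duplicate"):
            make_table(n=3, plot_id=["a", "a", "b"])


class TestDeriveProductivity:
    def test_definitional_ratio(self):
        table = make_table(n=3, agb=[100.0, 0.0, 50.0], stand_age=[50.0, 10.0, 25.0])
        out = derive_productivity(table)
        np.testing.assert_allclose(out.df["productivity"], [2.0, 0.0, 2.0])

    def test_nonpositive_age_flagged_not_fatal(self):
        table = make_table(n=3, stand_age=[0.0, 10.0, np.nan])
        out = derive_productivity(table)
        assert out.df["productivity"].isna().tolist() == [True, False, True]
        assert out.notes["productivity_flagged"] == 2

    def test_commutes_with_filtering(self):
        table = make_table(n=12)
        table.df.loc[[1, 5], "soil_cn"] = np.nan
        a, _ = filter_complete(derive_productivity(table), COLUMNS)
        b = derive_productivity(filter_complete(table, COLUMNS)[0])
        pd.testing.assert_frame_equal(a.df, b.df)


class TestFilterComplete:
    def test_counts_per_column(self):
        table = make_table(n=10)
        table.df.loc[[2, 7], "soil_cn"] = np.nan
        out, report = filter_complete(table)
        assert len(out) == 8
        assert report.removed_per_column == {"soil_cn": 2}
        assert report.n_input == 10 and report.n_kept == 8

    def test_no_missing_is_identity(self):
        table = make_table(n=6)
        out, report = filter_complete(table)
        pd.testing.assert_frame_equal(out.df, table.df)
        assert report.n_removed == 0

    def test_idempotent(self):
        table = make_table(n=10)
        table.df.loc[[0, 3, 4], "mat"] = np.nan
        once, _ = filter_complete(table)
        twice, rep2 = filter_complete(once)
        pd.testing.assert_frame_equal(once.df, twice.df)
        assert rep2.n_removed == 0

    def test_empty_result_refused_downstream(self):
        table = make_table(n=4, mat=[np.nan] * 4)
        out, _ = filter_complete(table)
        assert len(out) == 0
        with pytest.raises(PlotTableError, match="empty"):
            require_nonempty(out, "bin")

    def test_unknown_required_column_raises(self, small_table):
        with pytest.raises(PlotTableError, match="nope"):
            filter_complete(small_table, ["nope"])
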