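import numpy as np
import pandas as pd
import pytest

from morphosize import (
    filter_complete,
    filter_mature,
    merge_tables,
    read_table,
    write_table,
)

from conftest import make_table


def write_csv(tmp_path, rows, name="table.csv"):
    path = tmp_path / name
    pd.DataFrame(rows).to_csv(path, index=False)
    return path


def full_row(i, **overrides):
    row = {
        "specimen_id": f"sp{i}",
        "maturity": "mature",
        "BL": 500.0, "SBL": 330.0, "PL": 270.0, "MDL": 100.0, "PW": 70.0,
        "SI": 165.0, "CRL": 240.0, "FL": 330.0, "SW": 145.0,
    }
    row.update(overrides)
    return row


class TestReadTable:
    def test_complete_csv_roundtrip(self, tmp_path, cranium_catalog):
        path = write_csv(tmp_path, [full_row(i) for i in range(3)])
        table = read_table(path, cranium_catalog)
        assert table.n_specimens == 3
        assert table.n_missing == 0

    def test_blank_cell_becomes_missing(self, tmp_path, cranium_catalog):
        rows = [full_row(0), full_row(1, SW="")]
        path = write_csv(tmp_path, rows)
        table = read_table(path, cranium_catalog)
        assert table.n_missing == 1
        assert np.isnan(table.values.loc["sp1", "SW"])

    def test_missing_column_names_it(self, tmp_path, cranium_catalog):
        rows = [{k: v for k, v in full_row(0).items() if k != "SW"}]
        path = write_csv(tmp_path, rows)
        with pytest.raises(ValueError, match="SW"):
            read_table(path, cranium_catalog)

    def test_duplicate_specimen_id_rejected(self, tmp_path, cranium_catalog):
        path = write_csv(tmp_path, [full_row(0), full_row(0)])
        with pytest.raises(ValueError, match="duplicate"):
            read_table(path, cranium_catalog)

    def test_nonpositive_length_coerced_to_missing(self, tmp_path, cranium_catalog):
        path = write_csv(tmp_path, [full_row(0, BL=-3.0)])
        with pytest.warns(UserWarning, match="non-positive"):
            table = read_table(path, cranium_catalog)
        assert np.isnan(table.values.loc["sp0", "BL"])

    def test_column_map_resolves_renamed_headers(self, tmp_path, cranium_catalog):
        rows = [full_row(0)]
        rows[0]["BasilarLength"] = rows[0].pop("BL")
        path = write_csv(tmp_path, rows)
        table = read_table(path, cranium_catalog, column_map={"BL": "BasilarLength"})
        assert table.values.loc["sp0", "BL"] == 500.0

    def test_write_read_roundtrip_bit_exact(self, tmp_path, cranium_catalog):
        rng = np.random.default_rng(11)
        values = rng.lognormal(5.0, 0.4, size=(6, 9))
        table = make_table(cranium_catalog, values)
        table.values.iloc[2, 4] = np.nan
        out = tmp_path / "roundtrip.csv"
        write_table(table, out)
        again = read_table(out, cranium_catalog)
        assert np.array_equal(
            table.values.to_numpy(), again.values.to_numpy(), equal_nan=True
        )
        assert list(again.specimen_ids) == list(table.specimen_ids)


class TestFilters:
    def test_incomplete_specimen_dropped(self, tiny_catalog):
        table = make_table(tiny_catalog, [[1, 2, 3], [4, np.nan, 6], [7, 8, 9]])
        kept, report = filter_complete(table)
        assert kept.n_specimens == 2
        assert report.dropped_ids == ("sp2",)

    def test_filter_complete_idempotent(self, tiny_catalog):
        table = make_table(tiny_catalog, [[1, 2, 3], [4, np.nan, 6]])
        once, _ = filter_complete(table)
        twice, report = filter_complete(once)
        assert twice.specimen_ids == once.specimen_ids
        assert report.n_dropped == 0

    def test_all_missing_raises(self, tiny_catalog):
        table = make_table(tiny_catalog, [[np.nan] * 3, [np.nan] * 3])
        with pytest.raises(ValueError, match="complete"):
            filter_complete(table)

    def test_mature_only_with_unknown_dropped(self, tiny_catalog):
        table = make_table(
            tiny_catalog,
            np.full((4, 3), 5.0),
            maturity=["mature", "immature", "unknown", "mature"],
        )
        kept, report = filter_mature(table)
        assert kept.specimen_ids == ["sp1", "sp4"]
        assert set(report.dropped_ids) == {"sp2", "sp3"}

    def test_unknown_maturity_retained_on_request(self, tiny_catalog):
        table = make_table(
            tiny_catalog, np.full((2, 3), 5.0), maturity=["unknown", "mature"]
        )
        kept, _ = filter_mature(table, drop_unknown=False)
        assert kept.n_specimens == 2

    def test_all_mature_table_unchanged(self, random_table):
        kept, report = filter_mature(random_table)
        assert kept.specimen_ids == random_table.specimen_ids
        assert report.n_dropped == 0

    def test_mixed_ontogeny_sample_counts(self, tiny_catalog):
        # 17 specimens of mixed ontogeny, 9 confirmed mature: the mature
        # subsample alone enters the analyses
        maturity = ["mature"] * 9 + ["immature"] * 6 + ["unknown"] * 2
        table = make_table(tiny_catalog, np.full((17, 3), 4.0), maturity=maturity)
        kept, _ = filter_mature(table)
        assert kept.n_specimens == 9


class TestMerge:
    def test_merge_lengths_add(self, tiny_catalog):
        rng = np.random.default_rng(3)
        a = make_table(tiny_catalog, rng.lognormal(2, 0.2, (5, 3)),
                       ids=[f"a{i}" for i in range(5)])
        b = make_table(tiny_catalog, rng.lognormal(2, 0.2, (4, 3)),
                       ids=[f"b{i}" for i in range(4)])
        merged = merge_tables(a, b)
        assert merged.n_specimens == 9
        assert merged.specimen_ids == a.specimen_ids + b.specimen_ids

    def test_merge_with_empty_is_identity(self, tiny_catalog, random_table):
        empty = make_table(tiny_catalog, np.empty((0, 3)), ids=[])
        merged = merge_tables(random_table, empty)
        assert merged.specimen_ids == random_table.specimen_ids

    def test_id_collision_rejected(self, tiny_catalog):
        a = make_table(tiny_catalog, [[1, 2, 3]])
        b = make_table(tiny_catalog, [[4, 5, 6]])
        with pytest.raises(ValueError, match="collision"):
            merge_tables(a, b)

    def test_catalog_mismatch_rejected(self, tiny_catalog, mixed_catalog):
        a = make_table(tiny_catalog, [[1, 2, 3]])
        b = make_table(mixed_catalog, [[1, 2, 90]], ids=["other"])
        with pytest.raises(ValueError, match="catalog"):
            merge_tables(a, b)

    def test_study_sized_merge_and_completeness(self, tiny_catalog):
        # 29 new + 6 literature + 138 comparative = 173 specimens, one of
        # which is incomplete: 172 enter the analyses
        rng = np.random.default_rng(42)
        parts = []
        for name, n in (("new", 29), ("lit", 6), ("comp", 138)):
            parts.append(
                make_table(
                    tiny_catalog,
                    rng.lognormal(3, 0.2, (n, 3)),
                    ids=[f"{name}{i}" for i in range(n)],
                    source=name,
                )
            )
        merged = merge_tables(merge_tables(parts[0], parts[1]), parts[2])
        assert merged.n_specimens == 173
        merged.values.loc["lit3", "B"] = np.nan
        complete, report = filter_complete(merged)
        assert complete.n_specimens == 172
        assert report.dropped_ids == ("lit3",)
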