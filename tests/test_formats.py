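"""Interchange-format parsing, validation and round trips."""

import gzip

import numpy as np
import pandas as pd
import pytest

from subspec.formats import (
    CoverageSummary,
    FormatError,
    PositionKey,
    read_coverage_summary,
    read_frequency_table,
    read_model,
    write_frequency_table,
    write_model,
    AbundanceTable,
    SampleMetadata,
)
from subspec.genotype import GenotypingPosition, GenotypingPositionSet

from conftest import make_ft, make_model, make_positions


class TestPositionKey:
    def test_parse_round_trip(self):
        pk = PositionKey.parse("specI_v2_0001:contigA:42:A>G")
        assert pk == PositionKey("specI_v2_0001", "contigA", 42, "A", "G")
        assert PositionKey.parse(str(pk)) == pk

    @pytest.mark.parametrize(
        "bad",
        ["noseparators", "sp:c:0:A>G", "sp:c:x:A>G", "sp:c:5:A>A", "sp:c:5:AA>G", "sp:c:5:A-G"],
    )
    def test_malformed_or_invalid_ids_rejected(self, bad):
        with pytest.raises(FormatError):
            PositionKey.parse(bad)


class TestFrequencyTableIO:
    def _write(self, tmp_path, rows, samples=("s1", "s2")):
        path = tmp_path / "freq.tsv"
        lines = ["\t".join(["id", *samples])]
        for rid, vals in rows:
            lines.append("\t".join([rid, *map(str, vals)]))
        path.write_text("\n".join(lines) + "\n")
        return path

    def test_sentinel_becomes_missing(self, tmp_path):
        path = self._write(tmp_path, [("sp1:c1:1:A>C", [-1, 0.5])])
        ft = read_frequency_table(path)
        assert np.isnan(ft.freq[0, 0]) and ft.freq[0, 1] == 0.5

    def test_percent_scale_autodetected(self, tmp_path):
        # any value above 1 marks the table as percent-scaled
        path = self._write(
            tmp_path,
            [("sp1:c1:1:A>C", [87, 12]), ("sp1:c1:2:A>C", [0.5, 3])],
        )
        ft = read_frequency_table(path, scale_hint="auto")
        assert np.allclose(ft.freq, [[0.87, 0.12], [0.005, 0.03]])

    def test_fraction_rereading_is_idempotent(self, tmp_path):
        ft = make_ft([[0.9, 0.2], [np.nan, 0.8]])
        p1 = tmp_path / "a.tsv"
        write_frequency_table(ft, p1)
        again = read_frequency_table(p1)
        p2 = tmp_path / "b.tsv"
        write_frequency_table(again, p2)
        assert again.equals(read_frequency_table(p2))
        assert np.nanmax(again.freq) == 0.9  # never rescaled

    def test_round_trip_with_depth(self, tmp_path):
        depth = np.array([[5, 9], [0, 20]])
        ft = make_ft([[0.9, 0.2], [np.nan, 0.8]], depth=depth)
        write_frequency_table(ft, tmp_path / "f.tsv", depth_path=tmp_path / "d.tsv")
        back = read_frequency_table(tmp_path / "f.tsv", depth_path=tmp_path / "d.tsv")
        assert back.equals(ft)

    def test_gzip_input_accepted(self, tmp_path):
        path = tmp_path / "freq.tsv.gz"
        with gzip.open(path, "wt") as fh:
            fh.write("id\ts1\nsp1:c1:1:A>C\t0.25\n")
        assert read_frequency_table(path).freq[0, 0] == 0.25

    def test_malformed_row_id_names_line(self, tmp_path):
        path = self._write(tmp_path, [("sp1:c1:1:A>C", [0.1, 0.1]), ("garbage", [0, 0])])
        with pytest.raises(FormatError, match="line 3"):
            read_frequency_table(path)

    @pytest.mark.parametrize("bad", [150, -0.5, -2])
    def test_out_of_range_values_rejected(self, tmp_path, bad):
        path = self._write(tmp_path, [("sp1:c1:1:A>C", [bad, 0.1])])
        with pytest.raises(FormatError):
            read_frequency_table(path)


class TestCoverageSummary:
    def test_valid_row_accepted(self, tmp_path):
        p = tmp_path / "cov.tsv"
        p.write_text("sample\tspecies\tvertical\thorizontal\ns1\tspA\t5.0\t0.4\n")
        cov = read_coverage_summary(p)
        assert cov.table.iloc[0]["vertical"] == 5.0

    def test_breadth_bound_enforced(self):
        with pytest.raises(FormatError):
            CoverageSummary(
                pd.DataFrame(
                    {"sample_id": ["s1"], "species_id": ["spA"],
                     "vertical": [5.0], "horizontal": [1.3]}
                )
            )

    def test_duplicate_pairs_rejected(self):
        with pytest.raises(FormatError, match="duplicate"):
            CoverageSummary(
                pd.DataFrame(
                    {"sample_id": ["s1", "s1"], "species_id": ["spA", "spA"],
                     "vertical": [5.0, 6.0], "horizontal": [0.5, 0.6]}
                )
            )


class TestOtherTables:
    def test_negative_abundance_rejected(self):
        with pytest.raises(FormatError):
            AbundanceTable(pd.DataFrame({"s1": [-0.1]}, index=["g1"]))

    def test_metadata_requires_unique_samples(self):
        df = pd.DataFrame(
            {"sample_id": ["a", "a"], "subject_id": ["x", "x"],
             "collection_day": [0, 1], "country": ["DE", "DE"], "study": ["s", "s"]}
        )
        with pytest.raises(FormatError, match="duplicate"):
            SampleMetadata(df)


class TestModelSerialization:
    def _model_with_gps(self):
        model = make_model({"s1": "MGSS1", "s2": "MGSS1", "s3": "MGSS2"})
        pos = make_positions(3)
        model.genotyping_positions = GenotypingPositionSet(
            species_id="sp1",
            by_label={
                "MGSS1": [GenotypingPosition(pos[2], 0.95, 0.02),
                          GenotypingPosition(pos[0], 0.99, 0.01)],
                "MGSS2": [GenotypingPosition(pos[1], 0.9, 0.05)],
            },
        )
        return model

    def test_round_trip_identity(self, tmp_path):
        model = self._model_with_gps()
        write_model(model, tmp_path / "m.json")
        back = read_model(tmp_path / "m.json")
        assert back.to_dict() == model.to_dict()

    def test_genotyping_position_order_preserved(self, tmp_path):
        model = self._model_with_gps()
        write_model(model, tmp_path / "m.json")
        back = read_model(tmp_path / "m.json")
        orig = [str(g.position) for g in model.genotyping_positions.by_label["MGSS1"]]
        got = [str(g.position) for g in back.genotyping_positions.by_label["MGSS1"]]
        assert got == orig

    def test_truncated_file_is_explicit_error(self, tmp_path):
        model = self._model_with_gps()
        write_model(model, tmp_path / "m.json")
        full = (tmp_path / "m.json").read_text()
        (tmp_path / "t.json").write_text(full[: len(full) // 2])
        with pytest.raises(FormatError):
            read_model(tmp_path / "t.json")

    def test_schema_version_mismatch_rejected(self, tmp_path):
        (tmp_path / "v.json").write_text('{"schema_version": 999, "model": {}}')
        with pytest.raises(FormatError, match="schema version"):
            read_model(tmp_path / "v.json")
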