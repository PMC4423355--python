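"""Layout paths and the three deposited CSV schemas."""

import io

import pytest

from blastoquant.core import ValidationError
from blastoquant.dataio import (
    BatchID,
    BoundaryRow,
    IntegratedRow,
    SchemaError,
    TimeclassBandRow,
    layout_path,
    parse_layout_path,
    read_boundary_data,
    read_integrated,
    read_timeclasses_bands,
    validate_tree,
    write_boundary_data,
    write_integrated,
    write_timeclasses_bands,
)

BAND_ROWS = [
    TimeclassBandRow(
        embryo="ish/megaselia/ma_gt_260911/proc/001",
        timeclass="C14_T3",
        spline_height=24,
        spline_x=(10.0, 160.0, 310.0, 460.0, 610.0),
        spline_y=(125.0, 129.867, 130.0, 130.0, 129.467),
    ),
    TimeclassBandRow(
        embryo="ish/megaselia/ma_gt_260911/proc/002",
        timeclass="C13",
        spline_height=23,
        spline_x=(11.0, 160.5, 310.0, 459.5, 609.0),
        spline_y=(120.0, 121.0, 122.0, 121.5, 120.25),
    ),
]

BOUNDARY_ROWS = [
    BoundaryRow(
        embryo="ish/megaselia/ma_gt_260911/proc/001",
        boundary_id=2,
        facing="posterior",
        gene="gt",
        channel="purple",
        boundary_x=(160.0, 190.25, 220.5),
        boundary_y=(64.0, 137.0, 210.0),
    ),
]

INTEGRATED_ROWS = [
    IntegratedRow(
        gene="gt", timeclass="C14_T3", boundary_id=2,
        mean=29.948, median=29.951, standard_deviation=0.034, mad=0.024,
    ),
]


class TestLayout:
    def test_worked_example_path(self):
        assert (
            layout_path("ma_gt_260911", "001", "_ch00")
            == "ish/megaselia/ma_gt_260911/proc/001_ch00.png"
        )

    def test_rnai_batches_rooted_at_rnai(self):
        assert layout_path("ma_gt_260911", "002", "_embmsk", "rnai").startswith(
            "RNAi/megaselia/"
        )

    def test_prof_dat_has_no_png_extension(self):
        assert layout_path("ma_gt_260911", "001", "_prof.dat").endswith(
            "/001_prof.dat"
        )

    def test_unknown_suffix_rejected(self):
        with pytest.raises(ValidationError):
            layout_path("ma_gt_260911", "001", "_foo")

    @pytest.mark.parametrize(
        "suffix", ["_ch00", "_dic_ch00", "_nuc_ch00", "_memb_ch00",
                   "_embmsk", "_band", "_stband", "_prof.dat"]
    )
    def test_parse_inverts_layout(self, suffix):
        path = layout_path("ma_kni_010212", "007", suffix)
        batch, embryo_id, got_suffix, background = parse_layout_path(path)
        assert (str(batch), embryo_id, got_suffix, background) == (
            "ma_kni_010212", "007", suffix, "wt"
        )

    def test_parse_accepts_figure_legend_profile_name(self):
        batch, embryo_id, suffix, _ = parse_layout_path(
            "ish/megaselia/ma_gt_260911/proc/001_ch00_prof.dat"
        )
        assert embryo_id == "001" and suffix == "_prof.dat"

    def test_batch_id_roundtrip_and_validation(self):
        b = BatchID.parse("ma_gt_260911")
        assert (b.species, b.stain, b.date) == ("ma", "gt", "260911")
        assert str(b) == "ma_gt_260911"
        with pytest.raises(ValidationError):
            BatchID.parse("ma_gt")
        with pytest.raises(ValidationError):
            BatchID("ma", "gt", "26091")


@pytest.mark.parametrize(
    "rows,write,read",
    [
        (BAND_ROWS, write_timeclasses_bands, read_timeclasses_bands),
        (BOUNDARY_ROWS, write_boundary_data, read_boundary_data),
        (INTEGRATED_ROWS, write_integrated, read_integrated),
    ],
    ids=["timeclasses_bands", "boundary_data", "integrated"],
)
class TestRoundTrip:
    def test_write_read_write_is_byte_identical(self, tmp_path, rows, write,
                                                read):
        path = tmp_path / "table.csv"
        write(path, rows)
        first = path.read_bytes()
        buf = io.StringIO()
        write(buf, read(path))
        assert buf.getvalue().encode() == first

    def test_writers_are_deterministic(self, rows, write, read):
        a, b = io.StringIO(), io.StringIO()
        write(a, rows)
        write(b, rows)
        assert a.getvalue() == b.getvalue()


class TestValidation:
    def test_invalid_timeclass_names_line_number(self, tmp_path):
        path = tmp_path / "bands.csv"
        write_timeclasses_bands(path, BAND_ROWS)
        text = path.read_text().replace("C14_T3", "C14_T9")
        path.write_text(text)
        with pytest.raises(SchemaError, match="line 2"):
            read_timeclasses_bands(path)

    def test_header_only_file_gives_empty_list(self, tmp_path):
        path = tmp_path / "bands.csv"
        write_timeclasses_bands(path, [])
        assert read_timeclasses_bands(path) == []

    def test_unknown_facing_rejected(self):
        with pytest.raises(ValidationError, match="facing"):
            BoundaryRow(
                embryo="e", boundary_id=1, facing="dorsal", gene="gt",
                channel="purple", boundary_x=(1.0, 2.0, 3.0),
                boundary_y=(0.0, 0.0, 0.0),
            )

    def test_unknown_channel_rejected(self):
        with pytest.raises(ValidationError, match="channel"):
            BoundaryRow(
                embryo="e", boundary_id=1, facing="anterior", gene="gt",
                channel="green", boundary_x=(1.0, 2.0, 3.0),
                boundary_y=(0.0, 0.0, 0.0),
            )

    def test_unordered_control_points_rejected(self):
        with pytest.raises(ValidationError, match="x1 < x2 < x3"):
            BoundaryRow(
                embryo="e", boundary_id=1, facing="anterior", gene="gt",
                channel="purple", boundary_x=(3.0, 2.0, 1.0),
                boundary_y=(0.0, 0.0, 0.0),
            )

    def test_wrong_column_count_names_line(self, tmp_path):
        path = tmp_path / "bad.csv"
        write_boundary_data(path, BOUNDARY_ROWS)
        path.write_text(path.read_text() + "too,few,columns\n")
        with pytest.raises(SchemaError, match="line 3"):
            read_boundary_data(path)

    def test_wrong_header_rejected(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("not,the,right,header\n")
        with pytest.raises(SchemaError, match="line 1"):
            read_integrated(path)


class TestTreeValidation:
    def test_synthetic_batch_validates_clean(self, tmp_path):
        from blastoquant.synthgen import BatchSpec, generate_batch

        generate_batch(BatchSpec(n_embryos=2), tmp_path, seed=1)
        report = validate_tree(tmp_path)
        assert report.ok
        assert report.n_batches == 1
        assert report.n_embryos == 2
        assert report.n_complete == 2

    def test_missing_image_is_reported(self, tmp_path):
        from blastoquant.synthgen import BatchSpec, generate_batch

        spec = BatchSpec(n_embryos=2)
        generate_batch(spec, tmp_path, seed=1)
        proc = tmp_path / "ish" / "megaselia" / spec.batch_id / "proc"
        (proc / "002_nuc_ch00.png").unlink()
        report = validate_tree(tmp_path)
        assert not report.ok
        assert any("missing images" in p for p in report.problems)
        assert report.n_complete == 1
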