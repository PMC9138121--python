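"""File I/O: fixture JPEG parsing, byte order, parameter tables, CSV rasters."""

import hashlib
import io

import numpy as np
import pytest
from PIL import Image

from irproc import flir_io, fixtures
from irproc.flir_io import (
    FormatError,
    MetadataIncompleteError,
    ParameterRecord,
    RawMissingError,
    SchemaError,
    extract_metadata,
    extract_raw_frame,
    read_parameter_table,
    read_temperature_csv,
    resolve_byte_order,
    write_parameter_table,
    write_temperature_csv,
)
from irproc.radiometry import RawFrame, TemperatureFrame

from .conftest import make_scene


def checkerboard(h=16, w=24):
    dn = np.indices((h, w)).sum(axis=0) % 2
    return (dn * 30000 + 10000 + np.arange(w)[None, :]).astype(np.uint16)


@pytest.fixture
def fixture_jpeg(tmp_path):
    spec = make_scene()
    raw = RawFrame(dn=checkerboard())
    path = fixtures.write_fixture_jpeg(raw, spec, tmp_path / "cam.jpg")
    return path, spec, raw


class TestByteOrder:
    # the rule is a pure function of (payload type, model, exception list)
    @pytest.mark.parametrize(
        "raw_type, model, exceptions, expected",
        [
            ("PNG", "ModelA", [], "little"),
            ("png", "ModelA", [], "little"),
            ("PNG", "Quirky1", ["Quirky1", "Quirky2"], "big"),
            ("TIFF", "ModelA", [], "big"),
            ("TIFF", "Quirky1", ["Quirky1"], "little"),
        ],
    )
    def test_resolution_table(self, raw_type, model, exceptions, expected):
        assert resolve_byte_order(raw_type, model, exceptions) == expected


class TestFixtureJpeg:
    def test_metadata_round_trip(self, fixture_jpeg):
        path, spec, _ = fixture_jpeg
        meta = extract_metadata(path)
        assert meta.cal == spec.cal
        assert meta.atm == spec.atm
        assert meta.user == spec.params
        assert meta.camera_model == spec.camera_model
        assert meta.raw_image_type == "PNG"

    def test_raw_round_trip(self, fixture_jpeg):
        path, spec, raw = fixture_jpeg
        order = resolve_byte_order("PNG", spec.camera_model)
        out = extract_raw_frame(path, order)
        np.testing.assert_array_equal(out.dn, raw.dn)

    def test_wrong_byte_order_gives_swapped_values(self, fixture_jpeg):
        path, _, raw = fixture_jpeg
        out = extract_raw_frame(path, "big")  # correct order is "little"
        np.testing.assert_array_equal(out.dn, raw.dn.byteswap())

    def test_tiff_payload_round_trip(self, tmp_path):
        spec = make_scene()
        raw = RawFrame(dn=checkerboard())
        path = fixtures.write_fixture_jpeg(raw, spec, tmp_path / "t.jpg", raw_type="TIFF")
        meta = extract_metadata(path)
        assert meta.raw_image_type == "TIFF"
        out = extract_raw_frame(path, resolve_byte_order("TIFF", spec.camera_model))
        np.testing.assert_array_equal(out.dn, raw.dn)

    def test_extraction_is_read_only(self, fixture_jpeg):
        path, spec, _ = fixture_jpeg
        before = hashlib.sha256(path.read_bytes()).hexdigest()
        extract_metadata(path)
        extract_raw_frame(path, "little")
        assert hashlib.sha256(path.read_bytes()).hexdigest() == before

    def test_plain_photo_has_no_metadata(self, tmp_path):
        p = tmp_path / "photo.jpg"
        Image.new("RGB", (32, 32), (80, 120, 40)).save(p, format="JPEG")
        with pytest.raises(MetadataIncompleteError):
            extract_metadata(p)
        with pytest.raises(RawMissingError):
            extract_raw_frame(p, "little")

    def test_not_a_jpeg(self, tmp_path):
        p = tmp_path / "x.jpg"
        p.write_bytes(b"not an image at all")
        with pytest.raises(FormatError):
            extract_metadata(p)

    def test_truncated_payload(self, fixture_jpeg, tmp_path):
        path, _, _ = fixture_jpeg
        data = bytearray(path.read_bytes())
        # corrupt the embedded PNG payload bytes inside the raw segment
        idx = data.find(flir_io._RAW_MAGIC)
        assert idx > 0
        data[idx + 20 : idx + 40] = b"\x00" * 20
        bad = tmp_path / "trunc.jpg"
        bad.write_bytes(bytes(data))
        with pytest.raises(FormatError):
            extract_raw_frame(bad, "little")


def _records():
    spec = make_scene()
    recs = []
    for i, eps in enumerate((0.90, 0.95, 1.0)):
        r = fixtures._parameter_record(spec, f"img{i}.jpg")
        r.objEmissivity = eps
        recs.append(r)
    return recs


class TestParameterTable:
    def test_round_trip(self, tmp_path):
        recs = _records()
        p = tmp_path / "parameters.csv"
        write_parameter_table(recs, p)
        back = read_parameter_table(p)
        assert back == recs

    def test_missing_column_is_schema_error(self, tmp_path):
        recs = _records()
        p = tmp_path / "parameters.csv"
        write_parameter_table(recs, p)
        text = p.read_text().splitlines()
        cols = text[0].split(",")
        drop = cols.index("objEmissivity")
        stripped = "\n".join(
            ",".join(t for i, t in enumerate(line.split(",")) if i != drop) for line in text
        )
        p.write_text(stripped)
        with pytest.raises(SchemaError, match="objEmissivity"):
            read_parameter_table(p)

    def test_unparseable_numeric_names_row_and_column(self, tmp_path):
        recs = _records()
        p = tmp_path / "parameters.csv"
        write_parameter_table(recs, p)
        p.write_text(p.read_text().replace("0.95", "oops", 1))
        with pytest.raises(FormatError, match=r"row \d+"):
            read_parameter_table(p)

    def test_humidity_percent_normalized(self):
        rec = _records()[0]
        rec.airRelHumidity_perc = 50.0
        assert rec.acquisition().rel_humidity == pytest.approx(0.5)

    def test_unknown_columns_preserved(self, tmp_path):
        recs = _records()
        recs[0].extra["note"] = "sunny"
        recs[1].extra["note"] = "cloudy"
        recs[2].extra["note"] = "night"
        p = tmp_path / "parameters.csv"
        write_parameter_table(recs, p)
        back = read_parameter_table(p)
        assert [r.extra["note"] for r in back] == ["sunny", "cloudy", "night"]


class TestTemperatureCsv:
    def test_round_trip_to_printed_precision(self, tmp_path):
        frame = TemperatureFrame(temp_C=np.array([[20.123, 40.567], [-5.25, 0.0]]))
        p = tmp_path / "t.csv"
        write_temperature_csv(frame, p)
        back = read_temperature_csv(p)
        np.testing.assert_allclose(back.temp_C, frame.temp_C, atol=0.005)

    def test_nan_sentinel_token(self, tmp_path):
        frame = TemperatureFrame(temp_C=np.array([[20.0, np.nan], [21.0, 22.0]]))
        p = tmp_path / "t.csv"
        write_temperature_csv(frame, p)
        assert "NaN" in p.read_text()
        back = read_temperature_csv(p)
        assert np.isnan(back.temp_C[0, 1])
        assert np.isfinite(back.temp_C).sum() == 3

    def test_empty_file_is_error(self, tmp_path):
        p = tmp_path / "empty.csv"
        p.write_text("")
        with pytest.raises(FormatError):
            read_temperature_csv(p)

    def test_ragged_rows_error(self, tmp_path):
        p = tmp_path / "ragged.csv"
        p.write_text("1.0,2.0\n3.0\n")
        with pytest.raises(FormatError):
            read_temperature_csv(p)
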