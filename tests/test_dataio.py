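"""I/O round-trips and manifest validation."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from PIL import Image

from mammopart import dataio
from mammopart.detector import DetectionSet, Instance
from mammopart.errors import FormatError, ValidationError

from conftest import build_manifest, census_manifest_410


class TestManifest:
    def test_parse_small_csv(self, tmp_path):
        path = tmp_path / "m.csv"
        path.write_text(
            "image_id,case_id,laterality,view,image_path,mask_path,pixel_spacing_mm\n"
            "a,case1,L,CC,a.png,a_m.png,0.07\n"
            "b,case1,L,MLO,b.png,,0.07\n"
            "c,case2,R,CC,c.png,c_m.png,0.07\n"
        )
        manifest = dataio.read_manifest(path)
        assert len(manifest) == 3
        assert len(manifest.case_ids) == 2
        assert manifest.record("b").mask_path is None

    def test_duplicate_image_id_rejected(self, tmp_path):
        path = tmp_path / "m.csv"
        path.write_text(
            "image_id,case_id,laterality,view,image_path,mask_path,pixel_spacing_mm\n"
            "a,case1,L,CC,a.png,,0.07\n"
            "a,case1,L,MLO,b.png,,0.07\n"
        )
        with pytest.raises(ValidationError, match="duplicate"):
            dataio.read_manifest(path)

    def test_missing_column_is_format_error(self, tmp_path):
        path = tmp_path / "m.csv"
        path.write_text("image_id,case_id\na,case1\n")
        with pytest.raises(FormatError, match="missing column"):
            dataio.read_manifest(path)

    def test_census_manifest_roundtrip(self, tmp_path):
        manifest = census_manifest_410()
        assert len(manifest) == 410 and len(manifest.case_ids) == 115
        path = tmp_path / "census.csv"
        dataio.write_manifest(manifest, path)
        back = dataio.read_manifest(path)
        assert back.records == manifest.records

    @pytest.mark.parametrize(
        "mutation",
        ["five_images_one_case", "repeated_view_pair", "zero_spacing"],
    )
    def test_invariant_violations(self, mutation):
        records = list(build_manifest(2).records)
        r = records[0]
        if mutation == "five_images_one_case":
            bad = [
                dataio.ManifestRecord(f"x{i}", "caseX", "L", "CC", "x.png", None, 0.1)
                for i in range(5)
            ]
            # 5 images also necessarily repeats a view pair; both are invalid
            records = records + bad
        elif mutation == "repeated_view_pair":
            records.append(
                dataio.ManifestRecord("dup", r.case_id, r.laterality, r.view, "d.png", None, 0.1)
            )
        else:
            records.append(
                dataio.ManifestRecord("zsp", "caseZ", "L", "CC", "z.png", None, 0.0)
            )
        with pytest.raises(ValidationError):
            dataio.Manifest(records)

    def test_leakage_risk_report_counts_multi_image_cases(self):
        manifest = build_manifest(3, views_per_case=[4, 2, 1])
        report = dataio.leakage_risk_report(manifest)
        assert report["n_multi_image_cases"] == 2


class TestImageIO:
    def test_16bit_png_ramp_lossless(self, tmp_path):
        ramp = (np.arange(64 * 64, dtype=np.uint16) % 65535).reshape(64, 64)
        path = tmp_path / "ramp.png"
        dataio.write_image_16bit(ramp, path)
        image = dataio.read_image(path)
        assert image.pixels.shape == (64, 64)
        np.testing.assert_array_equal(image.pixels, ramp)
        assert image.bit_depth == 16

    def test_dicom_roundtrip_with_pixel_spacing(self, tmp_path):
        import pydicom
        from pydicom.dataset import FileDataset, FileMetaDataset
        from pydicom.uid import ExplicitVRLittleEndian, SecondaryCaptureImageStorage, generate_uid

        pixels = np.arange(32 * 24, dtype=np.uint16).reshape(32, 24)
        meta = FileMetaDataset()
        meta.MediaStorageSOPClassUID = SecondaryCaptureImageStorage
        meta.MediaStorageSOPInstanceUID = generate_uid()
        meta.TransferSyntaxUID = ExplicitVRLittleEndian
        ds = FileDataset(None, {}, file_meta=meta, preamble=b"\0" * 128)
        ds.SOPClassUID = meta.MediaStorageSOPClassUID
        ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
        ds.Rows, ds.Columns = pixels.shape
        ds.SamplesPerPixel = 1
        ds.PhotometricInterpretation = "MONOCHROME2"
        ds.BitsAllocated = 16
        ds.BitsStored = 12
        ds.HighBit = 11
        ds.PixelRepresentation = 0
        ds.PixelSpacing = [0.07, 0.07]
        ds.PixelData = pixels.tobytes()
        path = tmp_path / "img.dcm"
        ds.save_as(str(path), enforce_file_format=True)

        image = dataio.read_image(path)
        np.testing.assert_array_equal(image.pixels, pixels)
        assert image.pixel_spacing_mm == pytest.approx(0.07)
        assert image.bit_depth == 12

    def test_jpeg_rejected(self, tmp_path):
        path = tmp_path / "img.jpg"
        Image.fromarray(np.zeros((8, 8), dtype=np.uint8)).save(path)
        with pytest.raises(FormatError, match="unsupported"):
            dataio.read_image(path)

    def test_rgb_png_rejected(self, tmp_path):
        path = tmp_path / "img.png"
        Image.fromarray(np.zeros((8, 8, 3), dtype=np.uint8)).save(path)
        with pytest.raises(FormatError, match="single-channel"):
            dataio.read_image(path)

    def test_8bit_png_rejected(self, tmp_path):
        path = tmp_path / "img.png"
        Image.fromarray(np.zeros((8, 8), dtype=np.uint8)).save(path)
        with pytest.raises(FormatError, match="16-bit"):
            dataio.read_image(path)

    def test_mask_roundtrip_preserves_instances(self, tmp_path):
        labels = np.zeros((16, 16), dtype=np.int32)
        labels[2:5, 2:5] = 1
        labels[10:14, 9:12] = 2
        mask = dataio.LesionMask("m", labels > 0, labels)
        path = tmp_path / "m.png"
        dataio.write_mask(mask, path)
        back = dataio.read_mask(path, image_id="m")
        np.testing.assert_array_equal(back.instance_labels, labels)
        assert len(back.instances()) == 2


class TestDetectionIO:
    def _random_detections(self, rng, n):
        out = []
        for i in range(n):
            shape = (24, 24)
            instances = []
            for _ in range(int(rng.integers(0, 4))):
                r0, c0 = int(rng.integers(0, 16)), int(rng.integers(0, 16))
                r1, c1 = r0 + int(rng.integers(2, 8)), c0 + int(rng.integers(2, 8))
                mask = np.zeros(shape, dtype=bool)
                mask[r0:r1, c0:c1] = rng.random((r1 - r0, c1 - c0)) > 0.3
                if not mask.any():
                    mask[r0, c0] = True
                instances.append(
                    Instance(box=(r0, c0, r1, c1), mask=mask, score=float(rng.random()))
                )
            out.append(DetectionSet(image_id=f"img{i}", instances=instances))
        return out

    def test_empty_list_roundtrip(self, tmp_path):
        path = tmp_path / "det.json"
        dataio.write_detections([], path)
        assert dataio.read_detections(path) == []

    def test_empty_detection_set_roundtrip(self, tmp_path):
        path = tmp_path / "det.json"
        dataio.write_detections([DetectionSet("img0", [])], path)
        back = dataio.read_detections(path)
        assert back[0].image_id == "img0" and len(back[0]) == 0

    def test_random_detections_roundtrip_bit_exact(self, tmp_path, rng):
        detections = self._random_detections(rng, 100)
        path = tmp_path / "det.json"
        dataio.write_detections(detections, path)
        back = dataio.read_detections(path)
        assert len(back) == len(detections)
        for a, b in zip(detections, back):
            assert a.image_id == b.image_id
            assert len(a) == len(b)
            for ia, ib in zip(a.instances, b.instances):
                assert ia.box == ib.box
                assert ia.score == ib.score
                np.testing.assert_array_equal(ia.mask, ib.mask)

    def test_out_of_bounds_box_rejected(self, tmp_path):
        mask = np.zeros((8, 8), dtype=bool)
        mask[0, 0] = True
        det = DetectionSet("x", [Instance(box=(0, 0, 9, 4), mask=mask, score=0.5)])
        with pytest.raises(ValidationError, match="outside image bounds"):
            dataio.write_detections([det], tmp_path / "det.json")


@settings(deadline=None, max_examples=50)
@given(
    st.lists(st.booleans(), min_size=1, max_size=200),
    st.integers(min_value=1, max_value=20),
)
def test_rle_roundtrip_property(flat, width):
    arr = np.array(flat, dtype=bool)
    n = (len(arr) // width) * width
    if n == 0:
        return
    mask = arr[:n].reshape(-1, width)
    np.testing.assert_array_equal(dataio.rle_decode(dataio.rle_encode(mask)), mask)
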