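import json

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from edemaseg.errors import (
    AlignmentError,
    FormatError,
    UnsupportedFormatError,
    ValidationError,
)
from edemaseg.volumes_io import (
    MaskVolume,
    PolygonAnnotation,
    Volume,
    load_labelme,
    rasterize_polygons,
    read_mask,
    read_volume,
    write_mask,
    write_volume,
)

from _oracles import rasterize_bruteforce


# ---------------------------------------------------------------------------
# container invariants
# ---------------------------------------------------------------------------


def test_volume_rejects_bad_geometry():
    vox = np.zeros((3, 4, 4))
    with pytest.raises(ValidationError):
        Volume(vox, pixel_spacing=(0.0, 1.0))
    with pytest.raises(ValidationError):
        Volume(vox, slice_positions=np.array([0.0, 0.0, 1.0]))
    with pytest.raises(ValidationError):
        Volume(vox, slice_positions=np.array([0.0, 1.0]))
    with pytest.raises(ValidationError):
        Volume(np.zeros((4, 4)))


def test_mask_rejects_nonbinary_values():
    with pytest.raises(ValidationError):
        MaskVolume(np.full((2, 3, 3), 2))


# ---------------------------------------------------------------------------
# round trips
# ---------------------------------------------------------------------------


def test_nifti_roundtrip_preserves_voxels_and_spacing(tmp_path, rng):
    vox = rng.integers(0, 1000, size=(5, 7, 6)).astype(np.int16)
    v = Volume(vox, (0.7211, 0.7211), np.arange(5) * 0.625)
    path = tmp_path / "v.nii.gz"
    write_volume(v, path, "nifti")
    back = read_volume(path, "nifti")
    np.testing.assert_array_equal(back.voxels, vox)
    assert back.pixel_spacing == pytest.approx((0.7211, 0.7211), abs=1e-4)
    np.testing.assert_allclose(back.slice_positions, v.slice_positions, atol=1e-4)


def test_png_stack_roundtrip_16bit(tmp_path, rng):
    vox = rng.integers(0, 65536, size=(3, 8, 8)).astype(np.uint16)
    v = Volume(vox, (1.0, 1.0), np.arange(3.0))
    write_volume(v, tmp_path / "stack", "png_stack")
    back = read_volume(tmp_path / "stack", "png_stack")
    np.testing.assert_array_equal(back.voxels, vox)
    np.testing.assert_allclose(back.slice_positions, v.slice_positions)


def test_png_stack_without_metadata_warns_and_uses_defaults(tmp_path):
    import imageio.v3 as iio

    for i in range(3):
        iio.imwrite(tmp_path / f"slice_{i:04d}.png", np.zeros((4, 4), np.uint8))
    with pytest.warns(UserWarning, match="no spatial metadata"):
        v = read_volume(tmp_path, "png_stack")
    assert v.shape == (3, 4, 4)
    assert v.pixel_spacing == pytest.approx((0.7211, 0.7211))
    assert v.slice_thickness() == pytest.approx(0.625)


def test_png_stack_rejects_float_and_inconsistent_shapes(tmp_path):
    import imageio.v3 as iio

    v = Volume(np.zeros((2, 4, 4), dtype=float))
    with pytest.raises(ValidationError, match="quantize"):
        write_volume(v, tmp_path / "s", "png_stack")

    iio.imwrite(tmp_path / "slice_0000.png", np.zeros((4, 4), np.uint8))
    iio.imwrite(tmp_path / "slice_0001.png", np.zeros((5, 5), np.uint8))
    with pytest.raises(FormatError, match="inconsistent"):
        read_volume(tmp_path, "png_stack")


def test_dicom_is_read_only(tmp_path):
    v = Volume(np.zeros((2, 4, 4), dtype=np.int16))
    with pytest.raises(UnsupportedFormatError):
        write_volume(v, tmp_path / "d", "dicom_series")


def _write_dicom_slice(path, arr, z, spacing=(0.7, 0.7)):
    import pydicom
    from pydicom.dataset import FileDataset, FileMetaDataset
    from pydicom.uid import ExplicitVRLittleEndian, generate_uid

    meta = FileMetaDataset()
    meta.MediaStorageSOPClassUID = pydicom.uid.SecondaryCaptureImageStorage
    meta.MediaStorageSOPInstanceUID = generate_uid()
    meta.TransferSyntaxUID = ExplicitVRLittleEndian
    ds = FileDataset(str(path), {}, file_meta=meta, preamble=b"\0" * 128)
    ds.SOPClassUID = meta.MediaStorageSOPClassUID
    ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
    ds.Rows, ds.Columns = arr.shape
    ds.BitsAllocated = 16
    ds.BitsStored = 16
    ds.HighBit = 15
    ds.PixelRepresentation = 0
    ds.SamplesPerPixel = 1
    ds.PhotometricInterpretation = "MONOCHROME2"
    ds.PixelSpacing = [str(spacing[0]), str(spacing[1])]
    ds.ImagePositionPatient = ["0", "0", str(z)]
    ds.PixelData = arr.astype(np.uint16).tobytes()
    ds.save_as(str(path), enforce_file_format=True)


def test_dicom_series_read_sorted_by_position(tmp_path, rng):
    arrs = [rng.integers(0, 100, (6, 6)).astype(np.uint16) for _ in range(3)]
    # write out of order; positions should drive the final stacking order
    for name, (arr, z) in zip("bca", zip(arrs, (5.0, 10.0, 0.0))):
        _write_dicom_slice(tmp_path / f"{name}.dcm", arr, z)
    v = read_volume(tmp_path, "dicom_series")
    assert v.shape == (3, 6, 6)
    np.testing.assert_allclose(v.slice_positions, [0.0, 5.0, 10.0])
    np.testing.assert_array_equal(v.voxels[0], arrs[2])
    np.testing.assert_array_equal(v.voxels[2], arrs[1])


def test_dicom_series_mixed_shapes_rejected(tmp_path):
    _write_dicom_slice(tmp_path / "a.dcm", np.zeros((4, 4), np.uint16), 0.0)
    _write_dicom_slice(tmp_path / "b.dcm", np.zeros((5, 5), np.uint16), 1.0)
    with pytest.raises(FormatError, match="shapes"):
        read_volume(tmp_path, "dicom_series")


# ---------------------------------------------------------------------------
# masks
# ---------------------------------------------------------------------------


def test_mask_binarization_and_roundtrip(tmp_path):
    raw = np.zeros((2, 4, 4), dtype=np.uint8)
    raw[0, 1, 1] = 255
    write_volume(Volume(raw), tmp_path / "m.nii", "nifti")
    m = read_mask(tmp_path / "m.nii", "nifti")
    assert set(np.unique(m.labels)) <= {0, 1}
    assert m.labels[0, 1, 1] == 1 and m.labels.sum() == 1

    write_mask(m, tmp_path / "m2", "png_stack")
    back = read_mask(tmp_path / "m2", "png_stack")
    np.testing.assert_array_equal(back.labels, m.labels)


def test_empty_mask_file_reads_empty(tmp_path):
    write_volume(Volume(np.zeros((2, 4, 4), np.uint8)), tmp_path / "z.nii", "nifti")
    assert read_mask(tmp_path / "z.nii", "nifti").labels.sum() == 0


def test_mask_alignment_error(tmp_path):
    write_volume(Volume(np.ones((3, 4, 4), np.uint8)), tmp_path / "m.nii", "nifti")
    ref = Volume(np.zeros((3, 5, 5)))
    with pytest.raises(AlignmentError):
        read_mask(tmp_path / "m.nii", "nifti", reference=ref)


# ---------------------------------------------------------------------------
# polygon rasterization
# ---------------------------------------------------------------------------


def _ref(shape=(1, 8, 8)):
    return Volume(np.zeros(shape), (1.0, 1.0), np.arange(float(shape[0])))


def test_rectangle_matches_bruteforce_center_rule():
    verts = [(1, 1), (1, 3), (3, 3), (3, 1)]
    ann = PolygonAnnotation("edema", 0, verts)
    mask = rasterize_polygons([ann], _ref())
    expected = rasterize_bruteforce(verts, (8, 8))
    np.testing.assert_array_equal(mask.labels[0].astype(bool), expected)
    # left/top edges in, right/bottom out: the enclosed centers form a 2x2 block
    assert mask.labels.sum() == 4


def test_empty_annotation_list_gives_zero_mask():
    mask = rasterize_polygons([], _ref())
    assert mask.labels.sum() == 0


def test_disjoint_triangles_union_adds_areas():
    t1 = PolygonAnnotation("a", 0, [(0.5, 0.5), (3.5, 0.5), (0.5, 3.5)])
    t2 = PolygonAnnotation("b", 0, [(4.5, 4.5), (7.2, 4.5), (4.5, 7.2)])
    ref = _ref()
    both = rasterize_polygons([t1, t2], ref).labels.sum()
    alone = (
        rasterize_polygons([t1], ref).labels.sum()
        + rasterize_polygons([t2], ref).labels.sum()
    )
    assert both == alone > 0


def test_degenerate_polygon_rejected():
    with pytest.raises(ValidationError):
        PolygonAnnotation("bad", 0, [(0, 0), (1, 1)])


def test_out_of_range_slice_rejected():
    ann = PolygonAnnotation("edema", 5, [(1, 1), (3, 1), (2, 3)])
    with pytest.raises(ValidationError):
        rasterize_polygons([ann], _ref())


@given(st.integers(0, 2**32 - 1))
def test_rasterization_invariant_to_vertex_order_reversal(seed):
    rng = np.random.default_rng(seed)
    n = int(rng.integers(3, 8))
    verts = [tuple(v) for v in rng.uniform(0.3, 14.7, size=(n, 2))]
    ref = _ref((1, 15, 15))
    fwd = rasterize_polygons([PolygonAnnotation("p", 0, verts)], ref)
    rev = rasterize_polygons([PolygonAnnotation("p", 0, verts[::-1])], ref)
    np.testing.assert_array_equal(fwd.labels, rev.labels)


@given(st.integers(0, 2**32 - 1))
def test_convex_polygon_matches_shapely_containment(seed):
    from shapely.geometry import Point, Polygon

    rng = np.random.default_rng(seed)
    n = int(rng.integers(3, 9))
    # convex polygon: points sorted by angle around their centroid,
    # off-grid vertices so no pixel center sits exactly on an edge
    pts = rng.uniform(1.3, 30.1, size=(n, 2))
    center = pts.mean(axis=0)
    order = np.argsort(np.arctan2(*(pts - center).T[::-1]))
    hull = pts[order]
    poly = Polygon(hull)
    if not poly.is_valid or poly.area < 1.0:
        return
    mask = rasterize_polygons(
        [PolygonAnnotation("p", 0, [tuple(v) for v in hull])], _ref((1, 32, 32))
    )
    for r in range(32):
        for c in range(32):
            p = Point(float(c), float(r))
            if poly.boundary.distance(p) < 1e-9:
                continue  # center exactly on an edge: rule is tie-break only
            assert bool(mask.labels[0, r, c]) == poly.contains(p)


def test_load_labelme_roundtrip(tmp_path):
    payload = {
        "shapes": [
            {"label": "edema", "points": [[1, 1], [5, 1], [3, 4]]},
            {"label": "other", "points": [[0, 0], [1, 0], [0, 1]]},
        ]
    }
    path = tmp_path / "ann.json"
    path.write_text(json.dumps(payload))
    anns = load_labelme(path, slice_index=2, label="edema")
    assert len(anns) == 1
    assert anns[0].slice_index == 2
    assert anns[0].vertices == [(1, 1), (5, 1), (3, 4)]
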