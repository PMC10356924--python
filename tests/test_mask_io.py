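"""Mask and annotation I/O: RLE dialect, rasterization, vectorization."""

import json

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

import ftuseg
from ftuseg.errors import (
    DegeneratePolygonError,
    MaskFormatError,
    UnsupportedGeometryError,
)
from ftuseg.mask_io import (
    Annotation,
    AnnotationSet,
    BinaryMask,
    LabeledMask,
    RLERecord,
    rasterize,
    read_annotations,
    read_label_tiff,
    read_rle_csv,
    rle_decode,
    rle_encode,
    vectorize,
    write_annotations,
    write_label_tiff,
    write_rle_csv,
)


class TestRLE:
    def test_all_false_gives_empty_runs(self):
        rec = rle_encode(BinaryMask(np.zeros((4, 4), bool)))
        assert rec.runs == ()

    def test_all_true_gives_single_run(self):
        rec = rle_encode(BinaryMask(np.ones((4, 4), bool)))
        assert rec.runs == ((1, 16),)

    def test_column_major_numbering(self):
        # pixels (r0,c0), (r1,c1), (r2,c1): column-major 1-based indices 1, 5, 6
        m = np.zeros((3, 3), bool)
        m[0, 0] = m[1, 1] = m[2, 1] = True
        rec = rle_encode(BinaryMask(m))
        assert rec.runs == ((1, 1), (5, 2))

    def test_decode_empty_and_full(self):
        assert not rle_decode(RLERecord("w", (4, 4), ())).grid.any()
        assert rle_decode(RLERecord("w", (4, 4), ((1, 16),))).grid.all()

    def test_run_out_of_bounds_rejected(self):
        with pytest.raises(MaskFormatError):
            RLERecord("w", (3, 3), ((8, 3),))

    def test_overlapping_runs_rejected(self):
        with pytest.raises(MaskFormatError):
            RLERecord("w", (4, 4), ((1, 5), (3, 2)))

    @given(
        hnp.arrays(
            bool,
            st.tuples(st.integers(1, 12), st.integers(1, 12)),
            elements=st.booleans(),
        )
    )
    def test_roundtrip_identity(self, grid):
        mask = BinaryMask(grid)
        out = rle_decode(rle_encode(mask))
        assert np.array_equal(out.grid, mask.grid)

    def test_roundtrip_200_random_masks(self, rng):
        for _ in range(200):
            shape = (int(rng.integers(1, 40)), int(rng.integers(1, 40)))
            mask = BinaryMask(rng.random(shape) < rng.uniform(0, 1))
            assert np.array_equal(rle_decode(rle_encode(mask)).grid, mask.grid)

    def test_csv_roundtrip(self, tmp_path, rng):
        recs = [
            rle_encode(BinaryMask(rng.random((9, 7)) < 0.4), wsi_id=f"w{i}")
            for i in range(3)
        ]
        write_rle_csv(recs, tmp_path / "preds.csv")
        back = read_rle_csv(tmp_path / "preds.csv")
        assert back == recs


def random_annotation_set(rng, n=5):
    anns = []
    for i in range(n):
        cx, cy = rng.uniform(20, 80, 2)
        r = rng.uniform(3, 12)
        theta = np.linspace(0, 2 * np.pi, 12, endpoint=False)
        ring = tuple(
            (float(cx + r * np.cos(t)), float(cy + r * np.sin(t))) for t in theta
        )
        cat = ("glomerulus", "crypt", "cortex")[i % 3]
        anns.append(Annotation(id=i, category=cat, ring=ring))
    return AnnotationSet("wsi-1", (100, 100), 0.5, anns)


class TestAnnotationFiles:
    def test_read_two_categories(self, tmp_path):
        aset = AnnotationSet(
            "w",
            (20, 20),
            0.5,
            [
                Annotation(0, "glomerulus", ((1, 1), (5, 1), (5, 5), (1, 5))),
                Annotation(1, "cortex", ((0, 0), (19, 0), (19, 19), (0, 19))),
            ],
        )
        write_annotations(aset, tmp_path / "a.json")
        back = read_annotations(tmp_path / "a.json")
        assert [a.category for a in back.annotations] == ["glomerulus", "cortex"]

    def test_point_geometry_rejected(self, tmp_path):
        doc = {
            "type": "FeatureCollection",
            "features": [
                {
                    "type": "Feature",
                    "id": "pt1",
                    "properties": {},
                    "geometry": {"type": "Point", "coordinates": [1, 2]},
                }
            ],
        }
        (tmp_path / "bad.json").write_text(json.dumps(doc))
        with pytest.raises(UnsupportedGeometryError, match="pt1"):
            read_annotations(tmp_path / "bad.json")

    def test_malformed_json_rejected(self, tmp_path):
        (tmp_path / "broken.json").write_text("{not json")
        with pytest.raises(MaskFormatError):
            read_annotations(tmp_path / "broken.json")

    def test_empty_collection_roundtrip(self, tmp_path):
        aset = AnnotationSet("empty", (10, 10), 0.5, [])
        write_annotations(aset, tmp_path / "e.json")
        back = read_annotations(tmp_path / "e.json")
        assert back.annotations == [] and back.wsi_id == "empty"

    def test_roundtrip_bit_exact(self, tmp_path, rng):
        for trial in range(5):
            aset = random_annotation_set(rng)
            write_annotations(aset, tmp_path / "r.json")
            back = read_annotations(tmp_path / "r.json")
            assert back.wsi_id == aset.wsi_id
            assert back.image_shape == aset.image_shape
            assert back.pixel_size_um == aset.pixel_size_um
            for a, b in zip(aset.annotations, back.annotations):
                assert a.ring == b.ring  # bit-exact float round-trip
                assert a.category == b.category

    def test_holes_preserved(self, tmp_path):
        outer = ((0.0, 0.0), (20.0, 0.0), (20.0, 20.0), (0.0, 20.0))
        hole = ((5.0, 5.0), (15.0, 5.0), (15.0, 15.0), (5.0, 15.0))
        aset = AnnotationSet(
            "h", (30, 30), 0.5, [Annotation(0, "cortex", outer, holes=(hole,))]
        )
        write_annotations(aset, tmp_path / "h.json")
        back = read_annotations(tmp_path / "h.json")
        assert back.annotations[0].holes == (hole,)


class TestRasterize:
    def test_axis_aligned_square_exact(self):
        ann = Annotation(0, "glomerulus", ((0, 0), (10, 0), (10, 10), (0, 10)))
        assert rasterize(ann, (16, 16)).grid.sum() == 100

    def test_degenerate_ring_rejected(self):
        with pytest.raises(DegeneratePolygonError):
            Annotation(0, "glomerulus", ((0, 0), (5, 5)))

    def test_circle_area_within_2pct(self):
        r = 50
        theta = np.linspace(0, 2 * np.pi, 256, endpoint=False)
        ring = tuple((60 + r * np.cos(t), 60 + r * np.sin(t)) for t in theta)
        ann = Annotation(0, "glomerulus", ring)
        n = rasterize(ann, (120, 120)).grid.sum()
        assert abs(n - np.pi * r**2) / (np.pi * r**2) < 0.02

    def test_hole_subtracted(self):
        outer = ((0, 0), (10, 0), (10, 10), (0, 10))
        hole = ((2, 2), (8, 2), (8, 8), (2, 8))
        ann = Annotation(0, "cortex", outer, holes=(hole,))
        assert rasterize(ann, (12, 12)).grid.sum() == 100 - 36

    def test_monotone_under_containment(self, rng):
        # a polygon contained in another rasterizes to a pixel subset
        for _ in range(10):
            cx, cy = rng.uniform(20, 30, 2)
            r_out = rng.uniform(8, 15)
            r_in = r_out * rng.uniform(0.3, 0.9)
            theta = np.linspace(0, 2 * np.pi, 32, endpoint=False)
            big = Annotation(
                0, "other", tuple((cx + r_out * np.cos(t), cy + r_out * np.sin(t)) for t in theta)
            )
            small = Annotation(
                1, "other", tuple((cx + r_in * np.cos(t), cy + r_in * np.sin(t)) for t in theta)
            )
            gb = rasterize(big, (50, 50)).grid
            gs = rasterize(small, (50, 50)).grid
            assert not (gs & ~gb).any()


class TestVectorize:
    def test_one_annotation_per_label(self, rng):
        grid = np.zeros((30, 30), np.int32)
        grid[2:8, 2:8] = 1
        grid[15:25, 10:20] = 2
        assert len(vectorize(LabeledMask(grid))) == 2

    def test_rectilinear_roundtrip_exact(self):
        grid = np.zeros((9, 9), np.int32)
        grid[3:6, 3:6] = 1
        anns = vectorize(LabeledMask(grid))
        back = rasterize(anns[0], (9, 9))
        assert ftuseg.dice(back.grid, grid == 1) == 1.0

    def test_empty_mask_gives_empty_list(self):
        assert vectorize(LabeledMask(np.zeros((5, 5), np.int32))) == []

    def test_generator_blob_roundtrip(self, small_scene):
        anns = vectorize(small_scene.truth)
        assert len(anns) == small_scene.truth.n_labels
        for k, ann in enumerate(anns, start=1):
            back = rasterize(ann, small_scene.truth.shape)
            assert ftuseg.dice(back.grid, small_scene.truth.grid == k) >= 0.99

    def test_blob_with_hole_roundtrip(self):
        grid = np.zeros((20, 20), np.int32)
        grid[2:18, 2:18] = 1
        grid[8:12, 8:12] = 0  # interior hole
        anns = vectorize(LabeledMask(grid))
        back = rasterize(anns[0], (20, 20))
        assert ftuseg.dice(back.grid, grid == 1) == 1.0


def test_label_tiff_roundtrip(tmp_path, small_scene):
    write_label_tiff(small_scene.truth, tmp_path / "lab.tif")
    back = read_label_tiff(tmp_path / "lab.tif", small_scene.truth.pixel_size_um)
    assert np.array_equal(back.grid, small_scene.truth.grid)


def test_annotation_set_rejects_out_of_bounds():
    with pytest.raises(ValueError, match="outside"):
        AnnotationSet(
            "w", (10, 10), 0.5,
            [Annotation(0, "glomerulus", ((0, 0), (15, 0), (15, 5)))],
        )
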