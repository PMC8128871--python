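"""Marker I/O round-trips, cropping exactness, splits and pooling."""

import numpy as np
import pandas as pd
import pytest

from trapvision.annotations import (
    DEFAULT_TAXONOMY,
    MarkerParseError,
    MarkerValidationError,
    PoolingScheme,
    SubImageRecord,
    apply_pooling,
    crop_subimages,
    empty_marker_table,
    read_markers,
    split_train_opt,
    whitefly_pooling,
    write_markers,
)

_SHARED_PATCH = np.zeros((201, 201, 3), dtype=np.uint8)


def _rec(label, tag="Lab0d"):
    # records share one patch buffer; these tests exercise bookkeeping only
    return SubImageRecord(
        patch=_SHARED_PATCH, label=label, source=("img", 100, 100), dataset_tag=tag
    )


def make_table(rows):
    return pd.DataFrame(rows, columns=["image_id", "x", "y", "label", "dataset_tag"])


class TestMarkerIO:
    def test_round_trip_identity(self, tmp_path):
        table = make_table(
            [
                ("img1", 120, 300, "BEMITA", "Lab0d"),
                ("img1", 10, 20, "BKGRND", "Lab0d"),
                ("img2", 55, 66, "MACRPY", "Lab7d"),
            ]
        )
        path = tmp_path / "markers.tsv"
        write_markers(table, path)
        back = read_markers(path)
        assert back.equals(table)

    def test_empty_table_round_trip(self, tmp_path):
        path = tmp_path / "empty.tsv"
        write_markers(empty_marker_table(), path)
        back = read_markers(path)
        assert len(back) == 0
        assert list(back.columns) == ["image_id", "x", "y", "label", "dataset_tag"]

    def test_unknown_label_rejected(self, tmp_path):
        path = tmp_path / "bad.tsv"
        write_markers(make_table([("i", 1, 2, "APHID", "Lab0d")]), path)
        with pytest.raises(MarkerValidationError, match="APHID"):
            read_markers(path, taxonomy=DEFAULT_TAXONOMY)

    def test_malformed_row_reports_line_number(self, tmp_path):
        path = tmp_path / "mangled.tsv"
        path.write_text(
            "image_id\tx\ty\tlabel\tdataset_tag\n"
            "i\t1\t2\tBEMITA\tLab0d\n"
            "i\t1\tBEMITA\tLab0d\n"
        )
        with pytest.raises(MarkerParseError, match="line 3"):
            read_markers(path)

    def test_out_of_bounds_marker_rejected(self, tmp_path):
        path = tmp_path / "oob.tsv"
        write_markers(make_table([("i", 500, 2, "BEMITA", "Lab0d")]), path)
        with pytest.raises(MarkerValidationError, match="outside"):
            read_markers(path, image_shape=(300, 400))


class TestCropping:
    def test_exact_fit_patch_equals_image(self):
        image = np.random.default_rng(0).integers(0, 255, (201, 201, 3), np.uint8)
        table = make_table([("i", 100, 100, "BEMITA", "Lab0d")])
        (rec,) = crop_subimages(image, table)
        assert np.array_equal(rec.patch, image)

    def test_interior_crops_are_exact(self):
        """patch[i, j] == image[y-100+i, x-100+j] — direct indexing oracle."""
        rng = np.random.default_rng(1)
        image = rng.integers(0, 255, (600, 700, 3), np.uint8)
        pts = [(150, 200), (350, 420), (101, 101)]
        table = make_table([("i", x, y, "TRIAVA", "Lab0d") for x, y in pts])
        recs = crop_subimages(image, table)
        assert len(recs) == 3
        for rec, (x, y) in zip(recs, pts):
            assert rec.patch.shape == (201, 201, 3)
            assert np.array_equal(rec.patch, image[y - 100 : y + 101, x - 100 : x + 101])
            assert np.array_equal(rec.patch[100, 100], image[y, x])

    def test_skip_policy_drops_border_markers(self, caplog):
        image = np.zeros((400, 400, 3), np.uint8)
        table = make_table(
            [("i", 5, 5, "BEMITA", "Lab0d"), ("i", 200, 200, "BEMITA", "Lab0d")]
        )
        with caplog.at_level("WARNING"):
            recs = crop_subimages(image, table, edge_policy="skip")
        assert len(recs) == 1
        assert "skipping border marker" in caplog.text

    def test_reflect_policy_keeps_counts_and_size(self):
        image = np.random.default_rng(2).integers(0, 255, (400, 400, 3), np.uint8)
        table = make_table([("i", 5, 5, "BEMITA", "Lab0d")])
        (rec,) = crop_subimages(image, table, edge_policy="reflect")
        assert rec.patch.shape == (201, 201, 3)
        # centre pixel is still the marker pixel
        assert np.array_equal(rec.patch[100, 100], image[5, 5])

    def test_even_size_rejected(self):
        image = np.zeros((300, 300, 3), np.uint8)
        with pytest.raises(ValueError, match="odd"):
            crop_subimages(image, empty_marker_table(), size=200)


class TestSplit:
    def test_stratified_75_25(self):
        recs = [_rec(c) for c in DEFAULT_TAXONOMY for _ in range(100)]
        fit, opt = split_train_opt(recs, fraction=0.75, rng_seed=0)
        assert len(fit) == 375 and len(opt) == 125
        for c in DEFAULT_TAXONOMY:
            assert sum(r.label == c for r in fit) == 75
            assert sum(r.label == c for r in opt) == 25

    def test_small_class_floor_keeps_one_out(self):
        recs = [_rec("BEMITA") for _ in range(4)]
        fit, opt = split_train_opt(recs, fraction=0.75, rng_seed=0)
        assert (len(fit), len(opt)) == (3, 1)

    def test_singleton_class_stays_in_fit(self, caplog):
        recs = [_rec("BEMITA")] + [_rec("TRIAVA") for _ in range(10)]
        with caplog.at_level("WARNING"):
            fit, opt = split_train_opt(recs, rng_seed=1)
        assert sum(r.label == "BEMITA" for r in fit) == 1
        assert sum(r.label == "BEMITA" for r in opt) == 0

    def test_split_determinism_and_disjointness(self):
        recs = [_rec(c, tag=f"t{i}") for i, c in enumerate(["BEMITA", "TRIAVA"] * 20)]
        a = split_train_opt(recs, rng_seed=7)
        b = split_train_opt(recs, rng_seed=7)
        ids = lambda part: [(r.label, r.dataset_tag) for r in part]
        assert ids(a[0]) == ids(b[0]) and ids(a[1]) == ids(b[1])
        assert len(a[0]) + len(a[1]) == len(recs)
        assert not set(map(id, a[0])) & set(map(id, a[1]))

    def test_bad_fraction(self):
        with pytest.raises(ValueError):
            split_train_opt([], fraction=1.0)


class TestPooling:
    def test_categorical_count_additivity(self):
        recs = [_rec("BEMITA") for _ in range(10)] + [_rec("TRIAVA") for _ in range(20)]
        pooled = apply_pooling(recs, whitefly_pooling())
        assert len(pooled) == 30
        assert all(r.label == "BEM-TRI" for r in pooled)

    def test_identity_scheme_is_noop(self):
        recs = [_rec("ENCAFO"), _rec("MACRPY", tag="Lab7d")]
        scheme = PoolingScheme(categorical={c: c for c in DEFAULT_TAXONOMY})
        out = apply_pooling(recs, scheme)
        assert [(r.label, r.dataset_tag) for r in out] == [
            ("ENCAFO", "Lab0d"),
            ("MACRPY", "Lab7d"),
        ]

    def test_temporal_pooling_merges_study_sized_sets(self):
        """Merging a 5866-record fresh set with a 1435-record aged set gives
        one 7301-record set under a single tag."""
        recs = [_rec("BEMITA", tag="Lab0d") for _ in range(5866)] + [
            _rec("BEMITA", tag="Lab7d") for _ in range(1435)
        ]
        pooled = apply_pooling(recs, PoolingScheme(temporal=True))
        assert len(pooled) == 7301
        assert {r.dataset_tag for r in pooled} == {"Lab0d-7d"}

    def test_label_outside_scheme_domain(self):
        with pytest.raises(MarkerValidationError):
            whitefly_pooling().map_label("APHID")

    def test_pooled_taxonomy(self):
        assert whitefly_pooling().pooled_taxonomy == (
            "BEM-TRI",
            "ENCAFO",
            "MACRPY",
            "BKGRND",
        )
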