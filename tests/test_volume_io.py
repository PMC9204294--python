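"""Intensity preprocessing, patch cropping, and cohort loading."""

import numpy as np
import pandas as pd
import pytest

from varcnn.synthetic import PhantomConfig, save_cohort
from varcnn.volume_io import (Volume, crop_patch, load_cohort, load_volume,
                              normalize_and_clip, save_volume)


def test_zscore_matches_hand_computation_then_clips():
    # 3x3x3 volume of 1..27: mean 14, SD from the definition
    data = np.arange(1, 28, dtype=float).reshape(3, 3, 3)
    mean, sd = 14.0, np.sqrt(np.sum((np.arange(1, 28) - 14.0) ** 2) / 27)
    out = normalize_and_clip(Volume(data), -1.0, 2.5)
    expected = np.clip((data - mean) / sd, -1.0, 2.5)
    np.testing.assert_allclose(out.data, expected, atol=1e-12)


def test_clip_bounds_respected_with_outliers(rng):
    data = rng.normal(size=(6, 6, 6))
    data[0, 0, 0] = -1e4  # a -10 sigma style outlier
    data[5, 5, 5] = 1e4
    out = normalize_and_clip(Volume(data))
    assert out.data.min() >= -1.0 and out.data.max() <= 2.5


def test_normalize_is_identity_on_standardized_data_with_inactive_clip():
    # exact mean-0, SD-1 data within the clip range: the map is the identity
    data = np.array([-1.0] * 14 + [1.0] * 13 + [0.0]).reshape(2, 2, 7)
    data = (data - data.mean()) / data.std()
    out = normalize_and_clip(Volume(data), -10.0, 10.0)
    np.testing.assert_allclose(out.data, data, atol=1e-6)
    # and idempotent: applying it twice changes nothing further
    again = normalize_and_clip(out, -10.0, 10.0)
    np.testing.assert_allclose(again.data, out.data, atol=1e-6)


def test_constant_volume_raises():
    with pytest.raises(ValueError, match="constant"):
        normalize_and_clip(Volume(np.full((3, 3, 3), 7.0)))


def test_bad_clip_range_raises():
    with pytest.raises(ValueError):
        normalize_and_clip(Volume(np.zeros((2, 2, 2)) + np.arange(2)), 2.0, -1.0)


class TestCropPatch:
    def test_identity_crop_returns_whole_volume(self, rng):
        vol = Volume(rng.normal(size=(4, 5, 6)))
        patch = crop_patch(vol, (0, 0, 0), (4, 5, 6))
        np.testing.assert_array_equal(patch.data, vol.data)
        assert patch.origin == (0, 0, 0)

    def test_template_grid_crop_shape(self):
        vol = Volume(np.zeros((181, 217, 181), dtype=np.float32) +
                     np.arange(181, dtype=np.float32)[:, None, None])
        patch = crop_patch(vol, (50, 58, 50), (80, 100, 80))
        assert patch.shape == (80, 100, 80)

    def test_marked_voxel_lands_at_offset_coordinates(self):
        vol = Volume(np.zeros((100, 120, 100)))
        vol.data[60, 70, 60] = 42.0
        patch = crop_patch(vol, (50, 58, 50), (40, 50, 40))
        assert patch.data[10, 12, 10] == 42.0
        assert np.count_nonzero(patch.data) == 1

    def test_out_of_bounds_names_offending_axis(self):
        vol = Volume(np.zeros((10, 10, 10)) + np.arange(10))
        with pytest.raises(ValueError, match="axis 1"):
            crop_patch(vol, (0, 5, 0), (10, 6, 10))

    def test_crop_copies_no_outside_voxels(self, rng):
        vol = Volume(rng.normal(size=(8, 8, 8)))
        patch = crop_patch(vol, (2, 3, 1), (4, 4, 4))
        np.testing.assert_array_equal(patch.data, vol.data[2:6, 3:7, 1:5])
        vol.data[...] = 0  # patch owns its memory
        assert np.any(patch.data != 0)


def test_nifti_round_trip_bitwise(tmp_path, rng):
    vol = Volume(rng.normal(size=(5, 6, 7)).astype(np.float32))
    path = tmp_path / "phantom.nii.gz"
    save_volume(vol, path)
    back = load_volume(path)
    np.testing.assert_array_equal(back.data.astype(np.float32), vol.data)
    patch = crop_patch(back, (0, 0, 0), back.shape)
    np.testing.assert_array_equal(patch.data.astype(np.float32), vol.data)


class TestLoadCohort:
    @pytest.fixture()
    def cohort_dir(self, tmp_path):
        cfg = PhantomConfig(shape=(8, 12, 8), n_per_class=2, signal_radius_nc=1.5,
                            n_redundant_blobs=1, seed=3)
        save_cohort(cfg, tmp_path)
        return tmp_path

    def test_counts_and_row_order_preserved(self, cohort_dir):
        records, rejects = load_cohort(cohort_dir / "images", cohort_dir / "cohort.csv")
        assert len(records) == 4 and not rejects
        table = pd.read_csv(cohort_dir / "cohort.csv")
        assert [r.subject_id for r in records] == list(table["subject_id"])
        assert all(r.patch.data.min() >= -1.0 and r.patch.data.max() <= 2.5
                   for r in records)

    def test_metric_columns_in_stated_order(self, cohort_dir):
        records, _ = load_cohort(cohort_dir / "images", cohort_dir / "cohort.csv",
                                 metric_columns=["gmv", "wmv", "csf"])
        table = pd.read_csv(cohort_dir / "cohort.csv")
        np.testing.assert_allclose(records[0].morph,
                                   table.iloc[0][["gmv", "wmv", "csf"]].to_numpy(float))
        assert records[0].morph.size == 3

    def test_missing_image_goes_to_rejects(self, cohort_dir):
        table = pd.read_csv(cohort_dir / "cohort.csv")
        table.loc[0, "subject_id"] = "sub-ghost"
        table.to_csv(cohort_dir / "cohort.csv", index=False)
        records, rejects = load_cohort(cohort_dir / "images", cohort_dir / "cohort.csv")
        assert len(records) == 3
        assert rejects == [{"subject_id": "sub-ghost", "reason": "image not found"}]

    def test_malformed_label_goes_to_rejects(self, cohort_dir):
        table = pd.read_csv(cohort_dir / "cohort.csv")
        table["label"] = table["label"].astype(object)
        table.loc[1, "label"] = "maybe"
        table.to_csv(cohort_dir / "cohort.csv", index=False)
        records, rejects = load_cohort(cohort_dir / "images", cohort_dir / "cohort.csv")
        assert len(records) == 3 and len(rejects) == 1

    def test_duplicate_subject_raises(self, cohort_dir):
        table = pd.read_csv(cohort_dir / "cohort.csv")
        table.loc[1, "subject_id"] = table.loc[0, "subject_id"]
        table.to_csv(cohort_dir / "cohort.csv", index=False)
        with pytest.raises(ValueError, match="duplicate"):
            load_cohort(cohort_dir / "images", cohort_dir / "cohort.csv")

    def test_empty_table_raises(self, tmp_path):
        (tmp_path / "empty.csv").write_text("subject_id,label,gmv\n")
        with pytest.raises(ValueError, match="empty"):
            load_cohort(tmp_path, tmp_path / "empty.csv")
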