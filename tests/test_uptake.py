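"""SUV normalization and blood-pool-subtracted statistics."""

import dataclasses

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from aaaquant import phantom, segmentation, uptake
from aaaquant.errors import ConfigError, DataError
from aaaquant.imaging_io import ImageVolume


class TestSUVNormalize:
    def test_textbook_arithmetic(self):
        vol = ImageVolume(np.full((2, 2, 2), 5.0), (1, 1, 1))
        subj = phantom.SubjectCovariates(body_weight_kg=70.0,
                                         injected_dose_MBq=350.0)
        suv = uptake.suv_normalize(vol, subj)
        np.testing.assert_allclose(suv.data, 1.0)

    def test_zero_activity(self):
        vol = ImageVolume(np.zeros((2, 2, 2)), (1, 1, 1))
        suv = uptake.suv_normalize(vol, phantom.SubjectCovariates())
        assert np.all(suv.data == 0)

    @settings(max_examples=20, deadline=None)
    @given(st.floats(10, 200), st.floats(50, 900))
    def test_dose_scaling_property(self, weight, dose):
        vol = ImageVolume(np.full((2, 2, 2), 3.0), (1, 1, 1))
        s1 = uptake.suv_normalize(vol, phantom.SubjectCovariates(
            body_weight_kg=weight, injected_dose_MBq=dose))
        s2 = uptake.suv_normalize(vol, phantom.SubjectCovariates(
            body_weight_kg=weight, injected_dose_MBq=2 * dose))
        np.testing.assert_allclose(s1.data, 2 * s2.data, rtol=1e-12)

    def test_nonpositive_dose_rejected(self):
        vol = ImageVolume(np.zeros((2, 2, 2)), (1, 1, 1))
        bad = phantom.SubjectCovariates()
        bad.injected_dose_MBq = 0.0
        with pytest.raises(ConfigError):
            uptake.suv_normalize(vol, bad)


class TestSUVDiffStats:
    def brute_force_region_stats(self, data, mask, blood_mask):
        """Independent voxel-list oracle."""
        vals = [data[i, j, k] for i, j, k in zip(*np.nonzero(mask))]
        blood = [data[i, j, k] for i, j, k in zip(*np.nonzero(blood_mask))]
        bm = sum(blood) / len(blood)
        return (sum(vals) / len(vals), max(vals), bm)

    def test_exact_on_noiseless_phantom_vs_voxel_list_oracle(
            self, small_geometry, clean_spec, small_segmentation):
        labels, _ = small_geometry
        sim = phantom.simulate_pet(labels, clean_spec)
        seg = small_segmentation
        table = uptake.suv_diff_stats(sim.volume, seg)
        for _, row in table.iterrows():
            if row["missing"]:
                continue
            if row["region_type"] == "segment":
                k0, k1 = seg.segment_slabs[row["region"]]
                m = np.zeros_like(seg.wall_mask)
                m[:, :, k0:k1] = seg.wall_mask[:, :, k0:k1]
            else:
                qi = segmentation.QUADRANTS.index(row["region"])
                mas = seg.mas_region_mask()
                m = (seg.quadrant_labels == qi) & seg.wall_mask & mas[None, None, :]
            mean_w, max_w, blood = self.brute_force_region_stats(
                sim.volume.data, m, seg.blood_mask)
            assert row["mean_suv_wall"] == pytest.approx(mean_w, rel=1e-12)
            assert row["max_suv_wall"] == pytest.approx(max_w, rel=1e-12)
            assert row["mean_suv_diff"] == pytest.approx(mean_w - blood, rel=1e-12)
            assert row["max_suv_diff"] == pytest.approx(max_w - blood, rel=1e-12)

    def test_uniform_wall_minus_blood(self, small_geometry, clean_spec):
        labels, _ = small_geometry
        spec = dataclasses.replace(
            clean_spec, uptake_wall_by_quadrant={q: 0.8 for q in segmentation.QUADRANTS},
            uptake_blood=0.3)
        sim = phantom.simulate_pet(labels, spec)
        seg = segmentation.segment(labels, spec.landmark_z_mm, 1.5, 1.5)
        table = uptake.suv_diff_stats(sim.volume, seg)
        seg_rows = table[(table["region_type"] == "segment") & ~table["missing"]]
        np.testing.assert_allclose(seg_rows["mean_suv_diff"], 0.5, atol=1e-12)

    def test_wall_equal_blood_vanishes_under_blur(self, small_geometry, small_spec):
        labels, _ = small_geometry
        spec = dataclasses.replace(
            small_spec, noise_sd=0.0,
            uptake_wall_by_quadrant={q: 0.9 for q in segmentation.QUADRANTS},
            uptake_blood=0.9, uptake_background=0.9)
        sim = phantom.simulate_pet(labels, spec)
        seg = segmentation.segment(labels, spec.landmark_z_mm, 1.5, 1.5)
        table = uptake.suv_diff_stats(sim.volume, seg)
        ok = table[~table["missing"]]
        np.testing.assert_allclose(ok["mean_suv_diff"], 0.0, atol=1e-9)

    def test_quadrant_ranking_recovered(self, small_geometry, small_spec):
        """Posterior > left > right > anterior generative ranking survives
        blur and noise (single-seed check; the ensemble rate is asserted in
        the acceptance suite)."""
        labels, _ = small_geometry
        sim = phantom.simulate_pet(labels, small_spec)
        seg = segmentation.segment(labels, small_spec.landmark_z_mm, 1.5, 1.5)
        table = uptake.suv_diff_stats(sim.volume, seg)
        q = table[table["region_type"] == "quadrant"].set_index("region")
        order = q["mean_suv_diff"].sort_values(ascending=False).index.tolist()
        assert order == ["posterior", "left", "right", "anterior"]

    def test_empty_blood_mask_hard_error(self, small_segmentation, small_geometry):
        labels, _ = small_geometry
        import copy
        seg = small_segmentation
        broken = copy.copy(seg)
        broken.blood_mask = np.zeros_like(seg.blood_mask)
        vol = ImageVolume(np.ones(labels.shape), labels.spacing, labels.origin)
        with pytest.raises(DataError, match="blood"):
            uptake.suv_diff_stats(vol, broken)


class TestMASCumulative:
    def make_table(self, rows):
        recs = []
        for region, n, v in rows:
            recs.append({"subject": "s", "region_type": "segment", "region": region,
                         "voxel_count": n, "mean_suv_wall": np.nan,
                         "max_suv_wall": np.nan, "mean_suv_blood": np.nan,
                         "mean_suv_diff": v, "max_suv_diff": np.nan,
                         "missing": n == 0})
        return pd.DataFrame(recs, columns=uptake.UPTAKE_COLUMNS)

    def test_equal_weights_arithmetic(self):
        t = self.make_table([("Ab MAS", 10, 0.4), ("MAS", 10, 0.6),
                             ("Be MAS", 10, 0.5)])
        assert uptake.mas_cumulative_uptake(t) == pytest.approx(0.5)

    def test_single_surviving_slab(self):
        t = self.make_table([("Ab MAS", 0, np.nan), ("MAS", 25, 0.37),
                             ("Be MAS", 0, np.nan)])
        assert uptake.mas_cumulative_uptake(t) == pytest.approx(0.37)

    def test_all_missing_raises(self):
        t = self.make_table([("Ab MAS", 0, np.nan), ("MAS", 0, np.nan),
                             ("Be MAS", 0, np.nan)])
        with pytest.raises(DataError):
            uptake.mas_cumulative_uptake(t)

    def test_weighting_matches_pooled_voxel_mean(self, small_geometry, clean_spec,
                                                 small_segmentation):
        labels, _ = small_geometry
        sim = phantom.simulate_pet(labels, clean_spec)
        seg = small_segmentation
        table = uptake.suv_diff_stats(sim.volume, seg)
        # oracle: direct mean over the concatenated MAS-region wall voxels
        mas = seg.mas_region_mask()
        m = seg.wall_mask & mas[None, None, :]
        blood = sim.volume.data[seg.blood_mask].mean()
        oracle = sim.volume.data[m].mean() - blood
        assert uptake.mas_cumulative_uptake(table) == pytest.approx(oracle, rel=1e-12)


class TestClassification:
    def test_boundary_is_high(self):
        assert uptake.classify_high_low(0.53, 0.53) == "high"
        assert uptake.classify_high_low(0.529999, 0.53) == "low"

    @settings(max_examples=30, deadline=None)
    @given(st.floats(-5, 5), st.floats(-5, 5), st.floats(0, 1))
    def test_monotonicity(self, v, thr, bump):
        lo = uptake.classify_high_low(v, thr)
        hi = uptake.classify_high_low(v + bump, thr)
        assert not (lo == "high" and hi == "low")
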