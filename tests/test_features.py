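import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from deltarad import features as F
from deltarad.errors import DegenerateInputError, SchemaError


class TestTaxonomy:
    def test_feature_count_partition(self):
        assert F.N_FEATURES == 536
        assert len(F.SHAPE_NAMES) == 14
        assert len(F.FIRSTORDER_NAMES) == 18
        assert len(F.GLCM_NAMES) + len(F.GLRLM_NAMES) == 40
        assert len(F.WAVELET_BANDS) == 8
        wavelet = [n for n in F.FEATURE_NAMES if n.startswith("wavelet-")]
        assert len(wavelet) == 464
        assert len(set(F.FEATURE_NAMES)) == 536

    def test_extract_all_returns_full_vector(self, small_imaging_pair):
        (base, _post), _ = small_imaging_pair
        vec = F.extract_all(base.t2w, base.roi_mask, spacing=base.t2w_spacing)
        assert len(vec) == 536
        assert list(vec.index) == F.FEATURE_NAMES
        assert vec.notna().all()


class TestDiscretize:
    def test_bin_edge_arithmetic(self):
        lv = F.discretize(np.array([0.0, 16.0, 31.999]), n_bins=32)
        assert lv.tolist() == [1, 17, 32]

    def test_constant_roi_single_level(self):
        assert set(F.discretize(np.full(10, 3.3)).tolist()) == {1}

    def test_uniform_fill_balanced(self):
        vals = np.arange(0, 32, 0.25)  # uniform on [0, 32)
        counts = np.bincount(F.discretize(vals, 32), minlength=33)[1:]
        assert counts.min() >= 3 and counts.max() <= 5

    @given(st.integers(2, 64), st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_levels_always_in_range(self, n_bins, seed):
        vals = np.random.default_rng(seed).normal(0, 100, size=200)
        lv = F.discretize(vals, n_bins)
        assert lv.min() >= 1 and lv.max() <= n_bins
        assert lv[np.argmax(vals)] == n_bins


class TestShape:
    def test_digitized_sphere(self, sphere_mask):
        f = F.shape_features(sphere_mask, (1.0, 1.0, 1.0))
        analytic = 4.0 / 3.0 * np.pi * 1000.0  # 4188.8 mm^3
        assert abs(f["shape_MeshVolume"] - analytic) / analytic < 0.02
        assert 0.97 <= f["shape_Sphericity"] <= 1.0

    def test_single_voxel_volume(self):
        m = np.zeros((3, 3, 3), dtype=np.uint8)
        m[1, 1, 1] = 1
        f = F.shape_features(m, (2.0, 2.0, 2.0))
        assert f["shape_VoxelVolume"] == pytest.approx(8.0)

    def test_prolate_ellipsoid_elongation(self):
        n = 51
        x, y, z = np.meshgrid(*[np.arange(n) - 25.0] * 3, indexing="ij")
        mask = (x / 20.0) ** 2 + (y / 10.0) ** 2 + (z / 10.0) ** 2 <= 1.0
        f = F.shape_features(mask, (1.0, 1.0, 1.0))
        assert f["shape_Elongation"] == pytest.approx(0.5, abs=0.03)
        assert f["shape_Flatness"] == pytest.approx(0.5, abs=0.03)
        assert f["shape_Maximum3DDiameter"] == pytest.approx(40.0, rel=0.05)

    def test_empty_mask_rejected(self):
        with pytest.raises(DegenerateInputError):
            F.shape_features(np.zeros((4, 4, 4)), (1, 1, 1))


class TestFirstOrder:
    def test_hand_arithmetic_oracle(self):
        f = F.first_order_features(np.array([1.0, 2.0, 3.0, 4.0]))
        assert f["firstorder_Mean"] == pytest.approx(2.5)
        assert f["firstorder_Range"] == pytest.approx(3.0)
        assert f["firstorder_RootMeanSquared"] == pytest.approx(np.sqrt(7.5))
        assert f["firstorder_Energy"] == pytest.approx(30.0)
        assert f["firstorder_Variance"] == pytest.approx(1.25)

    def test_constant_roi(self):
        f = F.first_order_features(np.full(50, 4.2))
        assert f["firstorder_Mean"] == pytest.approx(4.2)
        assert f["firstorder_Variance"] == 0.0
        assert f["firstorder_Entropy"] == pytest.approx(0.0, abs=1e-12)
        assert f["firstorder_Uniformity"] == pytest.approx(1.0)

    def test_symmetric_distribution_zero_skew(self):
        vals = np.concatenate([np.linspace(-3, 3, 101)])
        f = F.first_order_features(vals)
        assert abs(f["firstorder_Skewness"]) < 1e-10


class TestTexture:
    @staticmethod
    def _checkerboard(n=8):
        x, y, z = np.meshgrid(*[np.arange(n)] * 3, indexing="ij")
        return ((x + y + z) % 2 + 1).astype(np.int64)

    def test_checkerboard_glcm_closed_form(self):
        """Two-level checkerboard: of the 13 offsets, the 7 with odd parity sum
        see only (1,2)/(2,1) pairs (contrast 1, correlation -1) and the 6 even
        ones only (1,1)/(2,2) (contrast 0, correlation +1)."""
        lv = self._checkerboard()
        mask = np.ones_like(lv, dtype=bool)
        f = F.glcm_features(lv, mask, n_levels=2)
        assert f["glcm_Contrast"] == pytest.approx(7.0 / 13.0)
        assert f["glcm_Correlation"] == pytest.approx(-1.0 / 13.0)

    def test_constant_roi_glrlm_long_runs(self):
        lv = np.ones((6, 6, 6), dtype=np.int64)
        f = F.glrlm_features(lv, np.ones_like(lv, dtype=bool), n_levels=32)
        # a constant ROI has one maximal run per line -> long-run emphasis huge
        assert f["glrlm_LongRunEmphasis"] > 10.0
        assert f["glrlm_RunPercentage"] < 0.5

    def test_permutation_changes_texture_not_histogram(self):
        rng = np.random.default_rng(0)
        vol = rng.normal(size=(7, 7, 7))
        vol_s = np.sort(vol.ravel()).reshape(vol.shape)  # extreme spatial reorder
        mask = np.ones(vol.shape, dtype=bool)
        fo1 = F.first_order_features(vol[mask])
        fo2 = F.first_order_features(vol_s[mask])
        for k in ("firstorder_Mean", "firstorder_Variance", "firstorder_Entropy"):
            assert fo1[k] == pytest.approx(fo2[k])
        g1 = F.glcm_features(np.where(mask, F.discretize(vol), 0), mask)
        g2 = F.glcm_features(np.where(mask, F.discretize(vol_s), 0), mask)
        assert abs(g1["glcm_Contrast"] - g2["glcm_Contrast"]) > 1e-3

    def test_single_voxel_roi_flagged_missing(self):
        lv = np.zeros((3, 3, 3), dtype=np.int64)
        mask = np.zeros((3, 3, 3), dtype=bool)
        mask[1, 1, 1] = True
        lv[1, 1, 1] = 1
        f = F.glcm_features(lv, mask)
        assert all(np.isnan(v) for v in f.values())

    def test_intensity_shift_covariance(self):
        """Adding a constant shifts the mean but leaves variance/entropy/GLCM alone."""
        rng = np.random.default_rng(4)
        vol = rng.normal(100, 10, size=(9, 9, 9))
        mask = np.ones(vol.shape, dtype=bool)
        a = F.first_order_features(vol[mask])
        b = F.first_order_features(vol[mask] + 55.5)
        assert b["firstorder_Mean"] - a["firstorder_Mean"] == pytest.approx(55.5)
        assert b["firstorder_Variance"] == pytest.approx(a["firstorder_Variance"])
        assert b["firstorder_Entropy"] == pytest.approx(a["firstorder_Entropy"])
        ga = F.glcm_features(np.where(mask, F.discretize(vol), 0), mask)
        gb = F.glcm_features(np.where(mask, F.discretize(vol + 55.5), 0), mask)
        for k in F.GLCM_NAMES:
            assert ga[k] == pytest.approx(gb[k], rel=1e-9)


class TestWavelet:
    def test_eight_subbands_on_original_grid(self):
        vol = np.random.default_rng(1).normal(size=(10, 11, 9))
        bands = F.wavelet_bands(vol)
        assert sorted(bands) == sorted(F.WAVELET_BANDS)
        assert all(b.shape == vol.shape for b in bands.values())

    def test_constant_volume_detail_bands_vanish(self):
        bands = F.wavelet_bands(np.full((8, 8, 8), 7.0))
        for name, band in bands.items():
            if "H" in name:
                assert band.var() < 1e-10
        assert bands["LLL"].var() < 1e-10


class TestDelta:
    def test_identical_timepoints_zero(self, feature_cohort):
        _, tables, _, _ = feature_cohort
        t = tables["t1w"].iloc[:5]
        d = F.delta(t, t)
        assert (d.to_numpy() == 0).all()

    def test_voxel_volume_delta_linearity(self, small_imaging_pair):
        (base, post), _ = small_imaging_pair
        fb = F.extract_all(base.t2w, base.roi_mask, spacing=base.t2w_spacing)
        fp = F.extract_all(post.t2w, post.roi_mask, spacing=post.t2w_spacing)
        d = F.delta(fp.to_frame("p").T, fb.to_frame("p").T)
        assert d.loc["p", "shape_VoxelVolume"] == pytest.approx(
            fp["shape_VoxelVolume"] - fb["shape_VoxelVolume"]
        )

    def test_column_mismatch_rejected(self):
        a = pd.DataFrame({"x": [1.0]}, index=["p"])
        b = pd.DataFrame({"y": [1.0]}, index=["p"])
        with pytest.raises(SchemaError):
            F.delta(a, b)

    def test_patients_missing_a_timepoint_dropped(self):
        cols = ["x", "y"]
        post = pd.DataFrame([[1.0, 2.0], [3.0, 4.0]], index=["a", "b"], columns=cols)
        pre = pd.DataFrame([[1.0, 1.0]], index=["a"], columns=cols)
        d = F.delta(post, pre)
        assert list(d.index) == ["a"]
        assert d.loc["a"].tolist() == [0.0, 1.0]
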