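"""First-order, shape and texture feature extraction."""

import math

import numpy as np
import pytest

from fistulomics._texture import (
    GLCM_FEATURES,
    GLDM_FEATURES,
    GLRLM_FEATURES,
    GLSZM_FEATURES,
    N_TEXTURE_FEATURES,
    NGTDM_FEATURES,
    texture_features,
)
from fistulomics.imaging_core import FilterConfig, VOIMask, VolumeGrid
from fistulomics.radiomics_features import (
    FIRST_ORDER_FEATURES,
    SHAPE_FEATURES,
    extract_first_order,
    extract_radiomics_profile,
    extract_shape,
    extract_texture,
    n_profile_features,
)

from .conftest import make_mask


def first_order_oracle(values, voxel_volume, n_bins):
    """Literal-formula re-implementation of the 18 first-order statistics,
    written directly from the definitions (python scalar arithmetic)."""
    v = sorted(float(x) for x in values)
    n = len(v)
    mean = sum(v) / n
    var = sum((x - mean) ** 2 for x in v) / n
    energy = sum(x * x for x in v)
    p10, p25, p50, p75, p90 = (float(np.percentile(v, q)) for q in (10, 25, 50, 75, 90))
    lo, hi = v[0], v[-1]
    if hi > lo:
        levels = [min(n_bins, math.floor(n_bins * (x - lo) / (hi - lo)) + 1) for x in v]
    else:
        levels = [1] * n
    probs = [levels.count(k) / n for k in sorted(set(levels))]
    robust = [x for x in v if p10 <= x <= p90]
    rmean = sum(robust) / len(robust)
    return {
        "Energy": energy,
        "TotalEnergy": voxel_volume * energy,
        "Entropy": -sum(p * math.log2(p) for p in probs),
        "Minimum": lo,
        "Percentile10": p10,
        "Percentile90": p90,
        "Maximum": hi,
        "Mean": mean,
        "Median": p50,
        "InterquartileRange": p75 - p25,
        "Range": hi - lo,
        "MeanAbsoluteDeviation": sum(abs(x - mean) for x in v) / n,
        "RobustMeanAbsoluteDeviation": sum(abs(x - rmean) for x in robust) / len(robust),
        "RootMeanSquared": math.sqrt(energy / n),
        "Skewness": sum((x - mean) ** 3 for x in v) / n / var**1.5 if var else 0.0,
        "Kurtosis": sum((x - mean) ** 4 for x in v) / n / var**2 if var else 0.0,
        "Variance": var,
        "Uniformity": sum(p * p for p in probs),
    }


class TestFirstOrder:
    def test_constant_roi_degenerate_values(self):
        grid = VolumeGrid(np.full((3, 3, 3), 5.0), (1, 1, 1))
        mask = VOIMask(np.ones((3, 3, 3), bool))
        out = extract_first_order(grid, mask, 10)
        assert out["Energy"] == pytest.approx(27 * 25.0)
        assert out["Entropy"] == 0.0
        assert out["Variance"] == 0.0
        assert out["Uniformity"] == 1.0

    def test_direct_definitions_small_roi(self):
        vals = np.zeros((1, 1, 4))
        vals[0, 0, :] = [1.0, 2.0, 3.0, 4.0]
        out = extract_first_order(
            VolumeGrid(vals, (1, 1, 1)), VOIMask(np.ones((1, 1, 4), bool)), 4
        )
        assert out["Mean"] == pytest.approx(2.5)
        assert out["Range"] == pytest.approx(3.0)

    def test_matches_literal_formula_oracle(self, rng):
        """All 18 statistics agree with an independent brute-force oracle."""
        vals = rng.normal(10.0, 5.0, size=(5, 5, 5))
        grid = VolumeGrid(vals, (1.152, 1.152, 3.0))
        mask = VOIMask(np.ones((5, 5, 5), bool))
        for n_bins in (8, 25):
            got = extract_first_order(grid, mask, n_bins)
            expected = first_order_oracle(vals.ravel(), grid.voxel_volume, n_bins)
            assert set(got) == set(FIRST_ORDER_FEATURES)
            for key in expected:
                assert got[key] == pytest.approx(expected[key], rel=1e-9), key

    def test_empty_mask_rejected(self, random_grid):
        with pytest.raises(ValueError, match="non-empty"):
            extract_first_order(random_grid, VOIMask(np.zeros((10, 11, 12), bool)), 10)

    def test_mean_variance_invariant_to_mask_geometry(self, rng):
        """First-order stats depend on the value multiset, not voxel layout."""
        vals = rng.normal(size=(6, 6, 6))
        scattered = VOIMask(rng.random((6, 6, 6)) > 0.5)
        grid = VolumeGrid(vals, (1, 1, 1))
        out = extract_first_order(grid, scattered, 10)
        expected = first_order_oracle(
            vals[scattered.indicator], grid.voxel_volume, 10
        )
        assert out["Mean"] == pytest.approx(expected["Mean"])
        assert out["Variance"] == pytest.approx(expected["Variance"])


class TestShape:
    def test_single_voxel_volume_and_degenerate_axes(self):
        mask = make_mask((5, 5, 5), (2, 2, 2))
        out = extract_shape(mask, (1, 1, 1))
        assert out["VoxelVolume"] == pytest.approx(1.0)
        assert out["Maximum3DDiameter"] == 0.0
        assert out["Elongation"] == 1.0 and out["Flatness"] == 1.0
        assert set(out) == set(SHAPE_FEATURES)

    def test_digitized_sphere_near_unit_sphericity(self):
        n, r = 45, 20
        x, y, z = np.mgrid[:n, :n, :n]
        mask = VOIMask((x - 22) ** 2 + (y - 22) ** 2 + (z - 22) ** 2 <= r * r)
        out = extract_shape(mask, (1, 1, 1))
        assert 0.97 < out["Sphericity"] <= 1.0
        assert out["VoxelVolume"] == pytest.approx(4 / 3 * np.pi * r**3, rel=0.02)
        assert out["Maximum3DDiameter"] == pytest.approx(2 * r, rel=0.05)

    def test_dimensional_scaling_with_spacing(self):
        x, y, z = np.mgrid[:12, :12, :12]
        mask = VOIMask((x - 6) ** 2 + (y - 6) ** 2 / 4 + (z - 6) ** 2 / 9 <= 9)
        small = extract_shape(mask, (1, 1, 1))
        big = extract_shape(mask, (2, 2, 2))
        assert big["MeshVolume"] / small["MeshVolume"] == pytest.approx(8.0, rel=1e-3)
        assert big["SurfaceArea"] / small["SurfaceArea"] == pytest.approx(4.0, rel=1e-3)
        assert big["Sphericity"] == pytest.approx(small["Sphericity"], abs=1e-3)
        assert big["Maximum3DDiameter"] == pytest.approx(
            2 * small["Maximum3DDiameter"]
        )
        assert big["MajorAxisLength"] == pytest.approx(2 * small["MajorAxisLength"])


class TestTexture:
    def test_returns_73_features(self, random_grid, box_mask):
        out = extract_texture(random_grid, box_mask, 10)
        assert len(out) == N_TEXTURE_FEATURES == 73
        by_family = {
            "glcm": GLCM_FEATURES, "glrlm": GLRLM_FEATURES,
            "glszm": GLSZM_FEATURES, "gldm": GLDM_FEATURES,
            "ngtdm": NGTDM_FEATURES,
        }
        for fam, names in by_family.items():
            assert sum(k.startswith(fam + "_") for k in out) == len(names)

    def test_constant_roi_zero_entropy_and_contrast(self):
        grid = VolumeGrid(np.full((4, 4, 4), 9.0), (1, 1, 1))
        mask = VOIMask(np.ones((4, 4, 4), bool))
        out = extract_texture(grid, mask, 10)
        assert out["glcm_JointEntropy"] == 0.0
        assert out["ngtdm_Contrast"] == 0.0
        assert out["glcm_MaximumProbability"] == 1.0

    def test_hand_enumerated_glcm_line(self):
        """A 3-voxel line with levels (1,2,1): symmetric counts {(1,2):2,
        (2,1):2} in the only populated direction, so contrast = 1."""
        vals = np.zeros((3, 1, 1))
        vals[1, 0, 0] = 10.0
        out = texture_features(vals, np.ones((3, 1, 1), bool), 2, families=("glcm",))
        assert out["glcm_Contrast"] == pytest.approx(1.0)
        assert out["glcm_MaximumProbability"] == pytest.approx(0.5)
        assert out["glcm_JointEntropy"] == pytest.approx(1.0)  # two equal cells

    def test_single_voxel_mask_defined_not_crash(self):
        out = texture_features(np.ones((3, 3, 3)), make_mask((3, 3, 3), (1, 1, 1)).indicator, 8)
        assert len(out) == 73
        assert all(np.isfinite(v) for v in out.values())

    def test_intensity_shift_invariance(self, rng):
        """Fixed-bin-number discretization absorbs affine intensity maps."""
        vals = rng.normal(size=(6, 6, 6))
        mask = np.ones((6, 6, 6), bool)
        a = texture_features(vals, mask, 12)
        b = texture_features(3.0 * vals + 150.0, mask, 12)
        for k in a:
            assert a[k] == pytest.approx(b[k], rel=1e-9), k

    def test_hand_enumerated_run_lengths(self):
        """Levels (1,1,2,2,2) on a line: runs {1:len2, 2:len3} along the
        line direction; 5 runs of length 1 in every other direction."""
        vals = np.zeros((5, 1, 1))
        vals[2:, 0, 0] = 1.0
        out = texture_features(vals, np.ones((5, 1, 1), bool), 2, families=("glrlm",))
        # 12 of 13 directions see 5 unit runs (RP=1); the line direction
        # sees 2 runs of lengths 2 and 3 (RP=2/5)
        expected_rp = (12 * 1.0 + 2.0 / 5.0) / 13
        assert out["glrlm_RunPercentage"] == pytest.approx(expected_rp)

    def test_hand_enumerated_zones(self):
        """Two 26-connected zones of level 2 (sizes 1 and 2) + one zone of
        level 1."""
        vals = np.zeros((1, 1, 7))
        vals[0, 0, 0] = 10.0       # zone A: level 2, size 1
        vals[0, 0, 3:5] = 10.0     # zone B: level 2, size 2
        out = texture_features(vals, np.ones((1, 1, 7), bool), 2, families=("glszm",))
        # zones: level1 sizes {2,2} (voxels 1-2 and 5-6)... enumerate:
        # level1 occupies z=1,2,5,6 -> two zones of size 2; level2: sizes 1,2
        assert out["glszm_SizeZoneNonUniformity"] == pytest.approx((3**2 + 1**2) / 4)
        assert out["glszm_GrayLevelNonUniformity"] == pytest.approx((2**2 + 2**2) / 4)


class TestProfile:
    def test_default_configuration_counting_identity(self):
        assert n_profile_features(FilterConfig()) == 5474

    def test_minimal_config_counts_and_determinism(self, rng):
        grid = VolumeGrid(rng.normal(size=(6, 6, 8)), (1, 1, 1))
        mask = VOIMask(np.ones((6, 6, 8), bool))
        cfg = FilterConfig(log_sigmas=(), wavelet_subbands=(), bin_numbers=(10,))
        p1 = extract_radiomics_profile(grid, mask, cfg)
        p2 = extract_radiomics_profile(grid, mask, cfg)
        assert len(p1) == 14 + 91 == 105
        assert p1 == p2
        assert list(p1) == list(p2)  # deterministic ordering

    def test_count_identity_arbitrary_config(self, rng):
        from fistulomics.imaging_core import WAVELET_SUBBANDS

        grid = VolumeGrid(rng.normal(size=(6, 6, 6)), (1, 1, 1))
        mask = VOIMask(np.ones((6, 6, 6), bool))
        cfg = FilterConfig(
            log_sigmas=(2.0,), wavelet_subbands=WAVELET_SUBBANDS[:3],
            bin_numbers=(8, 16),
        )
        prof = extract_radiomics_profile(grid, mask, cfg)
        assert len(prof) == 14 + (1 + 1 + 3) * 2 * 91 == n_profile_features(cfg)
        assert len(set(prof)) == len(prof)  # unique names
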