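import numpy as np
import pytest

import oracles
from radsem.features import (
    DIRECTIONS_3D,
    RadiomicFeatureExtractor,
    discretize,
    extract_features,
    feature_names,
    glcm_features,
    glszm_size_zone_variability,
    intensity_statistics,
    rlgl_features,
    shape_features,
)
from radsem.filters import FilterBankConfig
from radsem.volume import RegionMask, VoxelVolume


def _region(values, mask=None, spacing=(1.0, 1.0, 1.0)):
    values = np.asarray(values, dtype=float)
    vol = VoxelVolume(values, spacing)
    m = np.ones(values.shape, bool) if mask is None else np.asarray(mask, bool)
    return vol, RegionMask(m, spacing)


def _random_discretized(rng, shape=(4, 4, 4), ng=4, density=0.8):
    """Random small labeled region for oracle comparisons."""
    levels = rng.integers(1, ng + 1, size=shape).astype(np.int32)
    levels[rng.random(shape) > density] = 0
    if not (levels > 0).any():
        levels[0, 0, 0] = 1
    vol = VoxelVolume(levels.astype(float) * 25.0, (1, 1, 1))
    mask = RegionMask(levels > 0, (1, 1, 1))
    return discretize(vol, mask, 25.0), levels


class TestDiscretize:
    def test_floor_rule_on_worked_example(self):
        vol, mask = _region(np.array([0.0, 24.9, 25.0, 60.0]).reshape(4, 1, 1))
        disc = discretize(vol, mask, 25.0)
        np.testing.assert_array_equal(disc.levels.ravel(), [1, 1, 2, 3])
        assert disc.n_levels == 3

    def test_constant_region_is_single_level(self):
        vol, mask = _region(np.full((3, 1, 1), -100.0))
        disc = discretize(vol, mask, 25.0)
        assert disc.n_levels == 1

    def test_hu_shift_leaves_levels_unchanged(self):
        rng = np.random.default_rng(3)
        base = rng.normal(0, 80, (5, 5, 5))
        vol, mask = _region(base)
        vol2, _ = _region(base + 137.0)
        a = discretize(vol, mask, 25.0)
        b = discretize(vol2, mask, 25.0)
        np.testing.assert_array_equal(a.levels, b.levels)

    def test_out_of_mask_voxels_are_sentinel(self):
        m = np.zeros((3, 3, 3), bool)
        m[1, 1, 1] = True
        vol, mask = _region(np.ones((3, 3, 3)), m)
        disc = discretize(vol, mask, 25.0)
        assert disc.levels[0, 0, 0] == 0 and disc.levels[1, 1, 1] == 1


class TestShapeFeatures:
    def test_single_voxel_volume(self):
        m = np.zeros((5, 5, 5), bool)
        m[2, 2, 2] = True
        sf = shape_features(RegionMask(m, (1, 1, 1)))
        assert sf["volume"] == pytest.approx(1.0)
        assert sf["max_3d_diameter"] == 0.0

    def test_digital_ball_sphericity_near_one(self, digital_ball):
        sf = shape_features(digital_ball)
        assert 0.95 <= sf["sphericity"] <= 1.005
        # 1 mm voxels: digital volume close to (4/3) pi r^3
        assert sf["volume"] == pytest.approx(4 / 3 * np.pi * 20**3, rel=0.01)

    def test_rotation_invariance_on_isotropic_grid(self):
        """90-degree rotations leave voxel-count and PCA features bit-equal;
        mesh-surface features move only at the triangulation level (<2%)."""
        rng = np.random.default_rng(1)
        m = np.pad(rng.random((7, 8, 9)) > 0.6, 3)
        a = shape_features(RegionMask(m, (1, 1, 1)))
        b = shape_features(RegionMask(np.rot90(m, axes=(0, 1)).copy(), (1, 1, 1)))
        exact = ["volume", "max_3d_diameter", "major_axis_length",
                 "minor_axis_length", "least_axis_length", "elongation", "flatness"]
        for k in exact:
            assert a[k] == pytest.approx(b[k], abs=1e-9), k
        for k in set(a) - set(exact):
            # compactness2 cubes the area ratio, so give it 3x the slack
            rel = 0.06 if k == "compactness2" else 0.02
            assert a[k] == pytest.approx(b[k], rel=rel), k

    def test_sphericity_never_exceeds_one_plus_epsilon(self):
        rng = np.random.default_rng(8)
        for trial in range(10):
            m = np.pad(rng.random((6, 6, 6)) > rng.uniform(0.3, 0.9), 2)
            if not m.any():
                continue
            sf = shape_features(RegionMask(m, (1, 1, 1)))
            assert sf["sphericity"] <= 1.01

    def test_anisotropic_spacing_scales_volume(self):
        m = np.zeros((4, 4, 4), bool)
        m[1:3, 1:3, 1:3] = True
        sf = shape_features(RegionMask(m, (0.5, 0.5, 2.0)))
        assert sf["volume"] == pytest.approx(8 * 0.5 * 0.5 * 2.0)


class TestIntensityStatistics:
    def test_closed_form_example(self):
        vol, mask = _region(np.arange(1.0, 6.0).reshape(5, 1, 1))
        st = intensity_statistics(vol, mask)
        assert st["mean"] == pytest.approx(3.0)
        assert st["median"] == pytest.approx(3.0)
        assert st["range"] == pytest.approx(4.0)
        assert st["standard_deviation"] == pytest.approx(np.sqrt(2.0))
        assert st["energy"] == pytest.approx(55.0)
        assert st["root_mean_square"] == pytest.approx(np.sqrt(11.0))

    def test_symmetric_sample_has_zero_skewness(self):
        vol, mask = _region(np.array([-5.0, 0.0, 5.0]).reshape(3, 1, 1))
        assert intensity_statistics(vol, mask)["skewness"] == pytest.approx(0.0)

    def test_constant_region_declares_moments_undefined(self):
        vol, mask = _region(np.full((4, 1, 1), 7.0))
        st = intensity_statistics(vol, mask)
        assert np.isnan(st["skewness"]) and np.isnan(st["kurtosis"])
        assert st["entropy"] == 0.0

    def test_matches_direct_formula_oracle(self, noisy_region):
        """Every statistic agrees with a naive direct-formula recomputation."""
        vol, mask = noisy_region
        st = intensity_statistics(vol, mask)
        v = vol.intensities[mask.voxels]
        n = v.size
        mean = v.sum() / n
        sd = np.sqrt(((v - mean) ** 2).sum() / n)
        expected = {
            "energy": (v**2).sum(),
            "kurtosis": ((v - mean) ** 4).sum() / n / sd**4 - 3,
            "maximum": v.max(),
            "mean": mean,
            "mean_absolute_deviation": np.abs(v - mean).sum() / n,
            "median": np.sort(v)[n // 2] if n % 2 else np.sort(v)[n // 2 - 1 : n // 2 + 1].mean(),
            "minimum": v.min(),
            "range": v.max() - v.min(),
            "root_mean_square": np.sqrt((v**2).sum() / n),
            "skewness": ((v - mean) ** 3).sum() / n / sd**3,
            "standard_deviation": sd,
        }
        for k, val in expected.items():
            assert st[k] == pytest.approx(val, rel=1e-10), k


class TestGLCM:
    def test_constant_region_limits(self):
        vol, mask = _region(np.full((3, 3, 3), 40.0))
        disc = discretize(vol, mask, 25.0)
        f = glcm_features(disc)
        assert f["energy"] == pytest.approx(1.0)
        assert f["entropy"] == pytest.approx(0.0)
        assert f["contrast"] == pytest.approx(0.0)
        assert np.isnan(f["correlation"])

    def test_two_by_two_slab_matches_exhaustive_pairs(self):
        levels = np.array([[1, 2], [1, 2]], dtype=np.int32).reshape(2, 2, 1)
        vol = VoxelVolume(levels * 25.0, (1, 1, 1))
        disc = discretize(vol, RegionMask(levels > 0, (1, 1, 1)), 25.0)
        mine = glcm_features(disc)
        ref = oracles.glcm_features_bruteforce(levels)
        for k, v in ref.items():
            assert mine[k] == pytest.approx(v, abs=1e-10), k

    def test_gray_level_flip_preserves_symmetric_features(self):
        rng = np.random.default_rng(2)
        disc, levels = _random_discretized(rng, ng=4)
        flipped = levels.copy()
        flipped[levels > 0] = disc.n_levels + 1 - levels[levels > 0]
        vol = VoxelVolume(flipped.astype(float) * 25.0, (1, 1, 1))
        disc_f = discretize(vol, RegionMask(flipped > 0, (1, 1, 1)), 25.0)
        a, b = glcm_features(disc), glcm_features(disc_f)
        for k in ("energy", "entropy", "contrast", "dissimilarity",
                  "homogeneity", "inverse_difference_moment"):
            assert a[k] == pytest.approx(b[k], abs=1e-12), k


class TestGLSZM:
    def test_constant_region_single_zone(self):
        vol, mask = _region(np.full((2, 2, 2), 10.0))
        assert glszm_size_zone_variability(discretize(vol, mask, 25.0)) == 1.0

    def test_eight_isolated_singletons(self):
        """8 single-voxel zones of size 1: SZV = 8^2 / 8 = 8."""
        levels = np.zeros((5, 5, 5))
        for i, (x, y, z) in enumerate([(0, 0, 0), (0, 0, 4), (0, 4, 0), (4, 0, 0),
                                       (0, 4, 4), (4, 0, 4), (4, 4, 0), (4, 4, 4)]):
            levels[x, y, z] = 25.0
        mask = levels != 0
        vol = VoxelVolume(levels, (1, 1, 1))
        disc = discretize(vol, RegionMask(mask, (1, 1, 1)), 25.0)
        assert glszm_size_zone_variability(disc) == pytest.approx(8.0)

    def test_checkerboard_matches_flood_fill_oracle(self):
        x, y = np.meshgrid(np.arange(4), np.arange(4), indexing="ij")
        levels = (((x + y) % 2) + 1).astype(np.int32).reshape(4, 4, 1)
        vol = VoxelVolume(levels * 25.0, (1, 1, 1))
        disc = discretize(vol, RegionMask(levels > 0, (1, 1, 1)), 25.0)
        assert glszm_size_zone_variability(disc) == pytest.approx(
            oracles.szv_bruteforce(levels), abs=1e-12)


class TestRLGL:
    def test_single_line_run(self):
        """A constant 1x1xN line is one run of length N along z, so run
        percentage along that direction is 1/N."""
        n = 6
        levels = np.ones((1, 1, n), dtype=np.int32)
        runs = oracles.runs_bruteforce(levels, (0, 0, 1))
        assert runs == [(1, n)]
        vol = VoxelVolume(levels * 25.0, (1, 1, 1))
        disc = discretize(vol, RegionMask(levels > 0, (1, 1, 1)), 25.0)
        f = rlgl_features(disc)
        assert f == pytest.approx(oracles.rlgl_features_bruteforce(levels), abs=1e-12)

    def test_alternating_levels_maximize_short_run_emphasis(self):
        levels = np.array([1, 2] * 4, dtype=np.int32).reshape(1, 1, 8)
        vol = VoxelVolume(levels * 25.0, (1, 1, 1))
        disc = discretize(vol, RegionMask(levels > 0, (1, 1, 1)), 25.0)
        f = rlgl_features(disc)
        # every run has length 1 in every direction
        assert f["short_run_emphasis"] == pytest.approx(1.0)
        assert f["long_run_emphasis"] == pytest.approx(1.0)


class TestExtraction:
    def test_original_inventory_is_exactly_48(self, noisy_region):
        vol, mask = noisy_region
        fv = extract_features(vol, mask)
        assert len(fv) == 48
        families = {}
        for name in fv.index:
            families.setdefault(name.split(".")[1], []).append(name)
        assert len(families["shape"]) == 13
        assert len(families["stats"]) == 12
        assert len(families["glcm"]) == 17
        assert len(families["glszm"]) == 1
        assert len(families["rlgl"]) == 5

    def test_filtered_inventory_arithmetic(self):
        assert len(feature_names(FilterBankConfig())) == 48 + 13 * 35
        cfg = FilterBankConfig(log_sigmas_mm=(2.0,), subbands=("LLL",))
        assert len(feature_names(cfg)) == 48 + 2 * 35

    def test_extraction_is_deterministic(self, noisy_region):
        vol, mask = noisy_region
        a = extract_features(vol, mask)
        b = extract_features(vol, mask)
        assert (a == b).all() or ((a.isna() == b.isna()).all()
                                  and np.array_equal(a.dropna(), b.dropna()))

    def test_translation_invariance(self):
        """Embedding the same region elsewhere in the grid changes nothing."""
        rng = np.random.default_rng(9)
        block = rng.normal(0, 100, (5, 5, 5))
        bmask = rng.random((5, 5, 5)) > 0.3
        out = {}
        for offset in ((1, 1, 1), (6, 4, 2)):
            grid = np.zeros((14, 14, 14))
            m = np.zeros((14, 14, 14), bool)
            sl = tuple(slice(o, o + 5) for o in offset)
            grid[sl], m[sl] = block, bmask
            vol = VoxelVolume(grid, (1, 1, 1))
            out[offset] = extract_features(vol, RegionMask(m, (1, 1, 1)))
        a, b = out.values()
        mask_ok = ~(a.isna() & b.isna())
        np.testing.assert_allclose(a[mask_ok], b[mask_ok], rtol=1e-9)

    def test_hu_shift_invariance_of_texture_features(self, noisy_region):
        vol, mask = noisy_region
        shifted = VoxelVolume(vol.intensities + 212.0, vol.spacing)
        a = extract_features(vol, mask)
        b = extract_features(shifted, mask)
        texture = [n for n in a.index if n.split(".")[1] in ("glcm", "glszm", "rlgl")]
        np.testing.assert_allclose(a[texture].astype(float),
                                   b[texture].astype(float), rtol=1e-9)

    def test_estimator_interface(self, noisy_region):
        from sklearn.base import clone
        vol, mask = noisy_region
        est = RadiomicFeatureExtractor(bin_width_hu=25.0)
        est2 = clone(est).fit()
        table = est2.transform([(vol, mask), (vol, mask)])
        assert table.shape == (2, 48)
        assert list(est2.get_feature_names_out()) == list(table.columns)
        with pytest.raises(ValueError):
            RadiomicFeatureExtractor(bin_width_hu=-1).fit()


def test_thirteen_unique_directions_cover_all_neighbor_pairs():
    assert len(DIRECTIONS_3D) == 13
    assert len({d for d in DIRECTIONS_3D} | {tuple(-c for c in d) for d in DIRECTIONS_3D}) == 26
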