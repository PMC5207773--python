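"""Volume types, morphology primitives, and IO round trips."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import striomap as sm
from striomap.core_volumes import l1_ball

from conftest import VS, flood_fill_components, mask, random_mask


class TestErosion:
    def test_solid_cube_erodes_to_inner_cube(self):
        cube = np.zeros((9, 9, 9), dtype=bool)
        cube[2:7, 2:7, 2:7] = True
        eroded = sm.erode_mask(mask(cube), 100.0)
        expected = np.zeros_like(cube)
        expected[3:6, 3:6, 3:6] = True
        assert np.array_equal(eroded.values, expected)

    def test_empty_mask_and_zero_distance(self):
        empty = mask(np.zeros((4, 4, 4)))
        assert sm.erode_mask(empty, 250.0).count() == 0
        m = random_mask(np.random.default_rng(0))
        assert np.array_equal(sm.erode_mask(m, 0.0).values, m.values)

    def test_negative_distance_rejected(self):
        with pytest.raises(sm.VolumeError):
            sm.erode_mask(mask(np.ones((3, 3, 3))), -1.0)

    def test_matches_per_voxel_oracle(self):
        rng = np.random.default_rng(1)
        m = mask(rng.random((7, 7, 7)) < 0.7)
        eroded = sm.erode_mask(m, 100.0)
        ball = np.argwhere(l1_ball(100.0, VS)) - 1  # offsets
        for idx in np.ndindex(m.values.shape):
            keep = all(
                0 <= idx[0] + o[0] < 7
                and 0 <= idx[1] + o[1] < 7
                and 0 <= idx[2] + o[2] < 7
                and m.values[idx[0] + o[0], idx[1] + o[1], idx[2] + o[2]]
                for o in ball
            )
            assert eroded.values[idx] == (m.values[idx] and keep)

    def test_composition_of_distances(self):
        # eroding by d1 then d2 equals eroding by d1 + d2 (L1 unit balls)
        rng = np.random.default_rng(2)
        for _ in range(5):
            m = mask(rng.random((9, 9, 9)) < 0.8)
            two_step = sm.erode_mask(sm.erode_mask(m, 100.0), 200.0)
            one_step = sm.erode_mask(m, 300.0)
            assert np.array_equal(two_step.values, one_step.values)

    def test_anisotropic_voxels_honored_per_axis(self):
        cube = np.zeros((9, 9, 9), dtype=bool)
        cube[2:7, 2:7, 2:7] = True
        m = sm.BinaryMask(cube, (100.0, 50.0, 50.0))
        eroded = sm.erode_mask(m, 100.0)
        # 100 um = 1 voxel along axis 0 but 2 voxels along axes 1 and 2
        assert eroded.values[:, 4, 4].sum() == 3
        assert eroded.values[4, :, 4].sum() == 1
        assert eroded.values[4, 4, :].sum() == 1


class TestCoverage:
    def test_basic_fractions(self):
        a = np.zeros((4, 4, 4), dtype=bool)
        a[0, 0, :4] = True
        a[0, 1, :4] = True  # 8 voxels
        b = np.zeros_like(a)
        b[0, 0, :2] = True  # overlaps 2
        assert sm.coverage_fraction(mask(a), mask(a)) == 1.0
        assert sm.coverage_fraction(mask(a), mask(~a)) == 0.0
        assert sm.coverage_fraction(mask(a), mask(b)) == pytest.approx(0.25)

    def test_empty_target_is_an_error(self):
        with pytest.raises(sm.VolumeError):
            sm.coverage_fraction(mask(np.zeros((3, 3, 3))), mask(np.ones((3, 3, 3))))

    def test_monotone_in_probe(self):
        rng = np.random.default_rng(3)
        target = random_mask(rng, p=0.5)
        probe = random_mask(rng, p=0.3)
        bigger = mask(probe.values | random_mask(rng, p=0.3).values)
        assert sm.coverage_fraction(target, bigger) >= sm.coverage_fraction(target, probe)


class TestSubtractAndDownsample:
    def test_subtract_mask_cases(self):
        vol = sm.ProjectionVolume(np.full((3, 3, 3), 0.7), VS)
        everywhere = mask(np.ones((3, 3, 3)))
        nowhere = mask(np.zeros((3, 3, 3)))
        assert sm.subtract_mask(vol, everywhere).values.sum() == 0
        assert np.array_equal(sm.subtract_mask(vol, nowhere).values, vol.values)
        one = mask(np.zeros((3, 3, 3)))
        one.values[1, 1, 1] = True
        out = sm.subtract_mask(vol, one)
        assert out.values[1, 1, 1] == 0.0
        assert out.values[0, 1, 1] == 0.7

    def test_downsample_fraction_examples(self):
        fine = np.zeros((2, 2, 2), dtype=bool)
        fine[0, 0, 0] = fine[0, 0, 1] = fine[0, 1, 0] = fine[1, 0, 0] = True  # 4 of 8
        coarse = sm.downsample_fraction(sm.BinaryMask(fine, (50.0, 50.0, 50.0)), 100.0)
        assert coarse.values.shape == (1, 1, 1)
        assert coarse.values[0, 0, 0] == pytest.approx(0.5)
        full = sm.downsample_fraction(sm.BinaryMask(np.ones((4, 4, 4), bool), (50.0,) * 3), 100.0)
        assert np.all(full.values == 1.0)

    def test_downsample_matches_mean_pool_oracle_and_conserves_mass(self):
        rng = np.random.default_rng(4)
        fine = rng.random((6, 6, 6)) < 0.5
        m = sm.BinaryMask(fine, (50.0, 50.0, 50.0))
        coarse = sm.downsample_fraction(m, 100.0)
        for i, j, k in np.ndindex(coarse.values.shape):
            block = fine[2 * i : 2 * i + 2, 2 * j : 2 * j + 2, 2 * k : 2 * k + 2]
            assert coarse.values[i, j, k] == pytest.approx(block.mean())
        assert coarse.values.sum() * 8 == pytest.approx(fine.sum())

    def test_non_integral_factor_rejected(self):
        with pytest.raises(sm.VolumeError):
            sm.downsample_fraction(sm.BinaryMask(np.ones((4, 4, 4), bool), (60.0,) * 3), 100.0)


class TestConnectedComponents:
    def test_two_separated_cubes(self):
        v = np.zeros((8, 8, 8), dtype=bool)
        v[0:2, 0:2, 0:2] = True
        v[5:7, 5:7, 5:7] = True
        _, count = sm.connected_components(mask(v))
        assert count == 2

    def test_empty(self):
        _, count = sm.connected_components(mask(np.zeros((3, 3, 3))))
        assert count == 0

    def test_matches_flood_fill_oracle_on_random_masks(self):
        rng = np.random.default_rng(5)
        for _ in range(100):
            m = random_mask(rng, shape=(7, 7, 7), p=float(rng.uniform(0.1, 0.6)))
            _, count = sm.connected_components(m)
            assert count == flood_fill_components(m.values)


class TestInvariantsAndIO:
    @given(st.integers(0, 2**32 - 1))
    @settings(max_examples=20, deadline=None)
    def test_projection_volume_bounds_enforced(self, seed):
        rng = np.random.default_rng(seed)
        vals = rng.random((3, 3, 3))
        sm.ProjectionVolume(vals, VS)  # valid
        with pytest.raises(sm.VolumeError):
            sm.ProjectionVolume(vals + 1.0, VS)

    def test_atlas_names_must_match_labels(self):
        labels = np.zeros((3, 3, 3), dtype=np.int32)
        labels[0, 0, 0] = 1
        sm.AtlasPartition(labels, {1: "a"})
        with pytest.raises(sm.VolumeError):
            sm.AtlasPartition(labels, {1: "a", 2: "phantom"})

    def test_injection_core_subset_enforced(self):
        full = mask(np.zeros((4, 4, 4)))
        full.values[1:3, 1:3, 1:3] = True
        bad_core = mask(np.ones((4, 4, 4)))
        with pytest.raises(sm.VolumeError):
            sm.Injection("x", "thalamic", full, bad_core, full)

    def test_nifti_round_trip(self, tmp_path):
        rng = np.random.default_rng(6)
        vol = sm.ProjectionVolume(rng.random((4, 5, 6)), VS)
        sm.save_nifti(vol, tmp_path / "v.nii.gz")
        back = sm.load_nifti(tmp_path / "v.nii.gz", "volume")
        assert np.allclose(back.values, vol.values, atol=1e-6)
        assert back.voxel_size_um == pytest.approx(VS)
        m = random_mask(rng)
        sm.save_nifti(m, tmp_path / "m.nii.gz")
        assert np.array_equal(sm.load_nifti(tmp_path / "m.nii.gz", "mask").values, m.values)

    def test_tiff_round_trip(self, tmp_path):
        rng = np.random.default_rng(7)
        m = random_mask(rng)
        sm.save_tiff(m, tmp_path / "m.tiff")
        back = sm.load_tiff(tmp_path / "m.tiff")
        assert np.array_equal(back.values, m.values)
        assert back.voxel_size_um == pytest.approx(VS)
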