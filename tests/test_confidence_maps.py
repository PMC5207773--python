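"""Criteria evaluation and confidence-map construction."""

import numpy as np
import pytest

import striomap as sm
from striomap.confidence_maps import Criterion, CriteriaSet

from conftest import VS, confidence_oracle, mask, random_injection_scene, sphere_mask


def _perfect_setup(shape=(12, 12, 12)):
    """One injection whose projection exactly matches the target, no rivals."""
    thal = mask(np.ones(shape))
    full = sphere_mask(shape, (6, 6, 6), 4)
    core = sm.erode_mask(full, 100.0)
    target = mask(np.zeros(shape))
    target.values[0:4, 0:4, 0:4] = True
    proj = mask(target.values.copy())
    inj = sm.Injection("perfect", "thalamic", full, core, proj)
    return thal, target, inj


class TestEvaluateCriteria:
    def test_superset_projection_satisfies_coverage(self):
        thal, target, inj = _perfect_setup()
        res = sm.evaluate_criteria([inj], {"diffuse": target, "dense": target}, sm.GRADED_CRITERIA)
        assert res.loc["perfect"].all()

    def test_empty_projection_fails_everything(self):
        thal, target, inj = _perfect_setup()
        empty = sm.Injection("empty", "thalamic", inj.full, inj.core,
                             mask(np.zeros(target.values.shape)))
        res = sm.evaluate_criteria([empty], target, sm.BINARY_CRITERIA)
        assert not res.loc["empty"].any()

    @pytest.mark.parametrize("frac, expected", [(0.07, False), (0.12, True)])
    def test_ten_percent_coverage_boundary(self, frac, expected):
        shape = (10, 10, 10)
        target = mask(np.zeros(shape))
        target.values[0] = True  # 100 voxels
        proj = mask(np.zeros(shape))
        proj.values[0, 0, : int(frac * 100)] = True
        full = sphere_mask(shape, (5, 5, 5), 3)
        inj = sm.Injection("x", "thalamic", full, sm.erode_mask(full, 100.0), proj)
        crit = CriteriaSet([Criterion("target_covered", 0.10),
                            Criterion("target_covered", 0.50)])
        res = sm.evaluate_criteria([inj], target, crit)
        assert bool(res.iloc[0, 0]) is expected

    def test_projection_inside_but_small_coverage(self):
        # projection entirely within the target but covering only 5% of it
        shape = (10, 10, 10)
        target = mask(np.zeros(shape))
        target.values[0:4, :, :] = True  # 400 voxels
        proj = mask(np.zeros(shape))
        proj.values[0, 0, :20] = True  # 20 voxels, all inside
        full = sphere_mask(shape, (5, 5, 5), 3)
        inj = sm.Injection("x", "thalamic", full, sm.erode_mask(full, 100.0), proj)
        res = sm.evaluate_criteria([inj], target, sm.BINARY_CRITERIA)
        assert list(res.iloc[0]) == [False, True, False, True]

    def test_empty_target_tier_rejected(self):
        thal, target, inj = _perfect_setup()
        with pytest.raises(sm.VolumeError):
            sm.evaluate_criteria([inj], {"diffuse": target,
                                         "dense": mask(np.zeros(target.values.shape))},
                                 sm.GRADED_CRITERIA)


class TestBuildConfidenceMap:
    def test_perfect_injection_levels(self):
        thal, target, inj = _perfect_setup()
        res = sm.evaluate_criteria([inj], {"diffuse": target, "dense": target}, sm.GRADED_CRITERIA)
        cm = sm.build_confidence_map([inj], res, sm.GRADED_CRITERIA, thal)
        assert cm.max_level == 6
        assert np.all(cm.values[inj.core.values] == 6)
        shell = inj.full.values & ~inj.core.values
        assert np.all(cm.values[shell] == 3)
        assert cm.values[~inj.full.values].max() == 0

    def test_eight_level_variant(self):
        thal, target, inj = _perfect_setup()
        cm = sm.build_confidence_map_binary_target([inj], target, thal)
        assert cm.max_level == 8
        assert np.all(cm.values[inj.core.values] == 8)

    def test_never_satisfying_core_zeroed(self):
        thal, target, inj = _perfect_setup()
        bad = sm.Injection("bad", "thalamic", inj.full, inj.core,
                           mask(np.zeros(target.values.shape)))
        cm = sm.build_confidence_map_binary_target([bad], target, thal)
        assert cm.values[bad.core.values].max() == 0

    def test_matches_per_voxel_oracle(self):
        rng = np.random.default_rng(21)
        for _ in range(10):
            thal, target, injections = random_injection_scene(rng)
            res = sm.evaluate_criteria(injections, target, sm.BINARY_CRITERIA)
            cm = sm.build_confidence_map(injections, res, sm.BINARY_CRITERIA, thal)
            oracle = confidence_oracle(injections, res, sm.BINARY_CRITERIA, thal)
            assert np.array_equal(cm.values, oracle)

    def test_adding_perfect_injection_never_decreases(self):
        rng = np.random.default_rng(22)
        thal, target, injections = random_injection_scene(rng)
        res = sm.evaluate_criteria(injections, target, sm.BINARY_CRITERIA)
        base = sm.build_confidence_map(injections, res, sm.BINARY_CRITERIA, thal)
        extra = sm.Injection(
            "extra", "thalamic",
            sphere_mask(thal.values.shape, (5, 5, 5), 3),
            sm.erode_mask(sphere_mask(thal.values.shape, (5, 5, 5), 3), 100.0),
            mask(target.values.copy()),
        )
        all_inj = injections + [extra]
        res2 = sm.evaluate_criteria(all_inj, target, sm.BINARY_CRITERIA)
        assert res2.loc["extra"].all()
        cm2 = sm.build_confidence_map(all_inj, res2, sm.BINARY_CRITERIA, thal)
        zeroed = np.zeros(thal.values.shape, dtype=bool)
        sat2 = res2.to_numpy(bool)
        for i, inj in enumerate(all_inj):
            if not sat2[i].any():
                zeroed |= inj.core.values
        outside = ~zeroed
        assert np.all(cm2.values[outside] >= base.values[outside])

    def test_support_shrinks_with_harder_cutoffs(self):
        rng = np.random.default_rng(23)
        thal, target, injections = random_injection_scene(rng, n_inj=6)
        supports = []
        for cut in (0.05, 0.15, 0.30):
            crit = CriteriaSet([Criterion("target_covered", cut),
                                Criterion("projection_within", cut)])
            res = sm.evaluate_criteria(injections, target, crit)
            cm = sm.build_confidence_map(injections, res, crit, thal)
            supports.append(cm.values > 0)
        assert np.all(~supports[1] | supports[0])
        assert np.all(~supports[2] | supports[1])

    def test_too_few_criteria_rejected(self):
        thal, target, inj = _perfect_setup()
        crit = CriteriaSet([Criterion("target_covered", 0.1)])
        res = sm.evaluate_criteria([inj], target, crit)
        with pytest.raises(sm.VolumeError):
            sm.build_confidence_map([inj], res, crit, thal)


class TestNuclearCoverageAndOverlay:
    def _atlas(self, shape=(12, 12, 12)):
        labels = np.zeros(shape, dtype=np.int32)
        labels[0:6] = 1
        labels[6:] = 2
        return sm.AtlasPartition(labels, {1: "nuc_a", 2: "nuc_b"}, VS)

    def test_uniform_max_and_zero_maps(self):
        atlas = self._atlas()
        full = sm.ConfidenceMap(np.full((12, 12, 12), 6, dtype=np.int32), 6, VS)
        cov = sm.nuclear_coverage(full, atlas)
        assert np.allclose(cov[["level_1", "level_3", "level_5", "average"]], 1.0)
        zero = sm.ConfidenceMap(np.zeros((12, 12, 12), dtype=np.int32), 6, VS)
        assert np.allclose(sm.nuclear_coverage(zero, atlas).to_numpy(), 0.0)

    def test_levels_are_nested(self):
        rng = np.random.default_rng(24)
        cm = sm.ConfidenceMap(rng.integers(0, 7, (12, 12, 12)).astype(np.int32), 6, VS)
        cov = sm.nuclear_coverage(cm, self._atlas())
        assert np.all(cov["level_1"] >= cov["level_3"])
        assert np.all(cov["level_3"] >= cov["level_5"])

    def test_overlay_categories(self):
        rng = np.random.default_rng(25)
        a = sm.ConfidenceMap(rng.integers(0, 7, (8, 8, 8)).astype(np.int32), 6, VS)
        labels, counts = sm.overlay_confidence(a, a, 1, 1)
        assert counts["ts_only"] == 0 and counts["tc_only"] == 0
        b_vals = np.where(a.values >= 1, 0, 3).astype(np.int32)
        b = sm.ConfidenceMap(b_vals, 6, VS)
        labels, counts = sm.overlay_confidence(a, b, 1, 1)
        assert counts["both"] == 0
        # tally oracle
        c = sm.ConfidenceMap(rng.integers(0, 7, (8, 8, 8)).astype(np.int32), 6, VS)
        labels, counts = sm.overlay_confidence(a, c, 2, 3)
        expect = {"neither": 0, "ts_only": 0, "tc_only": 0, "both": 0}
        for idx in np.ndindex(a.values.shape):
            ia, ic = a.values[idx] >= 2, c.values[idx] >= 3
            key = ("both" if ia and ic else "ts_only" if ia else "tc_only" if ic else "neither")
            expect[key] += 1
        assert counts == expect
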