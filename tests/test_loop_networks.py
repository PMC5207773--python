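"""Thresholded circuit-graph extraction and export round trips."""

import numpy as np
import pandas as pd
import pytest

import striomap as sm
from striomap.loop_networks import CORTICAL, SUBDIVISION, THALAMIC

from conftest import mask


class TestPrimaryInputs:
    def _subdivision(self, shape=(6, 6, 6)):
        s = mask(np.zeros(shape))
        s.values[0:3] = True  # 108 voxels
        return s

    def test_field_filling_subdivision_qualifies_both_routes(self):
        sub = self._subdivision()
        field = mask(sub.values.copy())
        out = sm.primary_inputs(sub, {"a": field})
        assert bool(out.loc["a", "route_1"]) and bool(out.loc["a", "route_2"])

    def test_small_but_contained_field_qualifies_route_two_only(self):
        sub = self._subdivision()
        field = mask(np.zeros(sub.values.shape))
        field.values[0, 0, :5] = True  # ~5% of subdivision, 100% within
        out = sm.primary_inputs(sub, {"a": field})
        assert not bool(out.loc["a", "route_1"])
        assert bool(out.loc["a", "route_2"]) and bool(out.loc["a", "primary"])

    def test_fractions_match_brute_force(self):
        rng = np.random.default_rng(1)
        sub = mask(rng.random((6, 6, 6)) < 0.5)
        fields = {f"s{i}": mask(rng.random((6, 6, 6)) < 0.3) for i in range(5)}
        out = sm.primary_inputs(sub, fields)
        for name, f in fields.items():
            inter = np.count_nonzero(sub.values & f.values)
            assert out.loc[name, "occupancy"] == pytest.approx(inter / sub.count())
            assert out.loc[name, "within"] == pytest.approx(inter / f.count())

    def test_empty_subdivision_rejected(self):
        with pytest.raises(sm.VolumeError):
            sm.primary_inputs(mask(np.zeros((3, 3, 3))), {"a": mask(np.ones((3, 3, 3)))})

    def test_broad_source_is_primary_to_every_subdivision(self, small_scene, small_classmaps):
        # a source projecting densely everywhere qualifies for all subdivisions
        broad = mask(small_scene.striatum_ipsi.values.copy())
        dense_fields = {n: m.tier_mask("dense") for n, m in small_classmaps.items()}
        dense_fields["broad"] = broad
        vs = small_scene.striatum.voxel_size_um
        for sub_id in small_scene.truth.signatures:
            sub = sm.BinaryMask(small_scene.truth.subdivision_labels == sub_id, vs)
            out = sm.primary_inputs(sub, dense_fields)
            assert bool(out.loc["broad", "primary"])


class TestTableEdges:
    def test_corticocortical_strict_boundary(self):
        table = pd.DataFrame(
            [[0.0, 0.16], [0.15, 0.0]], index=["a", "b"], columns=["a", "b"]
        )
        edges = sm.corticocortical_edges(table, cutoff=0.15)
        assert edges == [("a", "b", 0.16)]

    def test_zero_table_and_count_oracle(self):
        names = [f"s{i}" for i in range(6)]
        zero = pd.DataFrame(0.0, index=names, columns=names)
        assert sm.corticocortical_edges(zero) == []
        rng = np.random.default_rng(2)
        table = pd.DataFrame(rng.random((6, 6)), index=names, columns=names)
        edges = sm.corticocortical_edges(table, cutoff=0.5)
        expect = sum(
            1 for a in names for b in names if a != b and table.loc[a, b] > 0.5
        )
        assert len(edges) == expect

    def test_thalamic_edges_boundary_and_direction(self):
        cov = pd.DataFrame([[0.25, 0.2]], index=["nuc"], columns=["ctx_a", "ctx_b"])
        ts = sm.thalamic_edges(cov, "thalamostriatal", cutoff=0.2)
        assert ts == [("nuc", "ctx_a", 0.25)]
        ct = sm.thalamic_edges(cov, "corticothalamic", cutoff=0.2)
        assert ct == [("ctx_a", "nuc", 0.25)]


class TestPrimaryConvergent:
    def _tier_fields(self, specs):
        return {
            tier: {name: mask(vals) for name, vals in fields.items()}
            for tier, fields in specs.items()
        }

    def test_identical_and_disjoint(self):
        a = np.zeros((4, 4, 4), dtype=bool)
        a[0] = True
        b = np.zeros_like(a)
        b[2] = True
        tiers = self._tier_fields(
            {t: {"a": a, "b": b} for t in ("dense", "moderate", "diffuse")}
        )
        conv, edges = sm.primary_convergent(tiers)
        assert conv.loc["a", "a"] == pytest.approx(1.0)
        assert conv.loc["a", "b"] == pytest.approx(0.0)
        assert edges == []

    def test_tier_mean_qualification(self):
        # coverage fractions 0.9 / 0.6 / 0.3 across tiers -> mean 0.6 > 0.5
        target = {}
        source = {}
        for tier, frac in (("dense", 0.9), ("moderate", 0.6), ("diffuse", 0.3)):
            tvals = np.zeros((10, 10, 1), dtype=bool)
            tvals[0, :10] = True
            svals = np.zeros_like(tvals)
            svals[0, : int(frac * 10)] = True
            target[tier] = tvals
            source[tier] = svals
        tiers = {
            tier: {"tgt": mask(target[tier]), "src": mask(source[tier])}
            for tier in target
        }
        conv, edges = sm.primary_convergent(tiers)
        assert conv.loc["src", "tgt"] == pytest.approx(0.6)
        assert ("src", "tgt", pytest.approx(0.6)) in [
            (a, b, pytest.approx(w)) for a, b, w in edges
        ]

    def test_empty_tier_omitted_from_mean(self):
        a = np.zeros((4, 4, 4), dtype=bool)
        a[0] = True
        tiers = {
            "dense": {"a": mask(a), "b": mask(a)},
            "moderate": {"a": mask(np.zeros_like(a)), "b": mask(a)},
            "diffuse": {"a": mask(a), "b": mask(a)},
        }
        conv, _ = sm.primary_convergent(tiers)
        # target a has an empty moderate field: mean over dense+diffuse only
        assert conv.loc["b", "a"] == pytest.approx(1.0)


class TestGraphExportAndMonotonicity:
    def _graph(self):
        g = sm.CircuitGraph()
        g.add_node("ctx_a", CORTICAL)
        g.add_node("ctx_b", CORTICAL)
        g.add_node("nuc_a", THALAMIC)
        g.add_node("sub_1", SUBDIVISION)
        g.add_edge("ctx_a", "ctx_b", "corticocortical", 0.3)
        g.add_edge("nuc_a", "sub_1", "thalamostriatal", 0.4)
        g.add_edge("ctx_a", "nuc_a", "corticothalamic", 0.25)
        g.add_edge("ctx_a", "sub_1", "corticostriatal_convergent", 0.6)
        return g

    def test_round_trip_csv_and_graphml(self, tmp_path):
        g = self._graph()
        sm.export_graph(g, tmp_path / "g.csv")
        assert sm.load_graph(tmp_path / "g.csv") == g
        sm.export_graph(g, tmp_path / "g.graphml")
        assert sm.load_graph(tmp_path / "g.graphml") == g

    def test_empty_graph_round_trip(self, tmp_path):
        g = sm.CircuitGraph()
        sm.export_graph(g, tmp_path / "e.csv")
        assert sm.load_graph(tmp_path / "e.csv") == g

    def test_illegal_edge_class_pair_rejected(self):
        g = sm.CircuitGraph()
        g.add_node("nuc", THALAMIC)
        g.add_node("ctx", CORTICAL)
        with pytest.raises(sm.VolumeError):
            g.add_edge("ctx", "nuc", "thalamocortical", 0.5)

    def test_raising_cutoffs_never_adds_edges(self):
        rng = np.random.default_rng(3)
        names = [f"s{i}" for i in range(8)]
        table = pd.DataFrame(rng.random((8, 8)), index=names, columns=names)
        prev = None
        for cutoff in (0.1, 0.3, 0.5, 0.7, 0.9):
            edges = {(a, b) for a, b, _ in sm.corticocortical_edges(table, cutoff)}
            if prev is not None:
                assert edges <= prev
            prev = edges
        cov = pd.DataFrame(rng.random((6, 4)),
                           index=[f"n{i}" for i in range(6)],
                           columns=[f"c{i}" for i in range(4)])
        prev = None
        for cutoff in (0.1, 0.3, 0.5, 0.7):
            edges = {(a, b) for a, b, _ in sm.thalamic_edges(cov, "thalamocortical", cutoff)}
            if prev is not None:
                assert edges <= prev
            prev = edges
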