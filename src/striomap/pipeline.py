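"""End-to-end orchestration: simulate -> align -> density -> converge ->
confmap -> cluster -> network, with a provenance manifest.

Each stage writes its artifacts into the run directory and contributes
content checksums (computed from in-memory arrays/tables, so the manifest
of two runs with the same config is byte-identical regardless of file
timestamps) to ``manifest.json`` together with the config hash and
library versions.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .alignment import align_stack
from .config import RunConfig
from .confidence_maps import (
    BINARY_CRITERIA,
    GRADED_CRITERIA,
    build_confidence_map,
    build_confidence_map_binary_target,
    evaluate_criteria,
    nuclear_coverage,
)
from .convergence import convergence_count, pairwise_convergence, split_high_low
from .core_volumes import BinaryMask, dice, save_nifti
from .loop_networks import (
    CircuitGraph,
    CORTICAL,
    SUBDIVISION,
    THALAMIC,
    corticocortical_edges,
    export_graph,
    primary_convergent,
    primary_inputs,
    thalamic_edges,
)
from .parcellation import build_feature_matrix, cluster_voxels, cut_dendrogram, report_contiguity
from .projection_density import classify_density, max_density_map
from .synthetic_data import (
    make_alignment_experiment,
    make_alignment_stack,
    make_connectivity_tables,
    make_scene,
    write_scene,
)

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failure, tagged with the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


def _checksum_array(arr: np.ndarray) -> str:
    h = hashlib.sha256()
    h.update(str(arr.shape).encode())
    h.update(np.ascontiguousarray(arr).tobytes())
    return h.hexdigest()


def _checksum_df(df: pd.DataFrame) -> str:
    return hashlib.sha256(df.to_csv().encode()).hexdigest()


def run_pipeline(config: RunConfig, out_dir) -> Path:
    """Execute all stages; returns the run directory (with manifest.json)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {
        "config_hash": config.digest(),
        "versions": {
            "striomap": __version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
        "stages": {},
    }
    config.save(out / "config.json")

    def stage(name):
        logger.info("stage %s", name)
        manifest["stages"][name] = {"checksums": {}}
        return manifest["stages"][name]["checksums"]

    try:
        cs = stage("simulate")
        scene = make_scene(config.scene)
        write_scene(scene, out / "scene")
        cs["striatum"] = _checksum_array(scene.striatum.values)
        cs["subdivision_truth"] = _checksum_array(scene.truth.subdivision_labels)
    except Exception as e:  # noqa: BLE001
        raise PipelineError("simulate", e) from e

    try:
        cs = stage("align")
        if config.scene.misalignment is not None and not config.scene.misalignment.is_identity():
            template, template_lm = make_alignment_stack(config.scene)
            misaligned, lm_mis = make_alignment_experiment(
                config.scene, config.scene.misalignment
            )
            aligned, est = align_stack(
                misaligned,
                template,
                landmark=lm_mis,
                template_landmark=template_lm,
                n_rounds=config.alignment_rounds,
            )
            save_nifti(aligned, out / "aligned_striatum.nii.gz")
            manifest["stages"]["align"]["dice_recovered"] = dice(aligned, template)
            manifest["stages"]["align"]["estimated"] = {
                "roll_deg": est.roll_deg,
                "pitch_deg": est.pitch_deg,
                "yaw_deg": est.yaw_deg,
                "scales": list(est.scales),
            }
            cs["aligned"] = _checksum_array(aligned.values)
        else:
            manifest["stages"]["align"]["skipped"] = True
    except Exception as e:  # noqa: BLE001
        raise PipelineError("align", e) from e

    try:
        cs = stage("density")
        classmaps = {
            name: classify_density(vol, scene.striatum_ipsi, config.density_thresholds)
            for name, vol in scene.cortical_fields.items()
        }
        combined = max_density_map(list(classmaps.values()))
        np.save(out / "max_density_classes.npy", combined.classes)
        cs["max_density"] = _checksum_array(combined.classes)
    except Exception as e:  # noqa: BLE001
        raise PipelineError("density", e) from e

    try:
        cs = stage("converge")
        diffuse_fields = {n: m.tier_mask("diffuse") for n, m in classmaps.items()}
        dense_fields = {n: m.tier_mask("dense") for n, m in classmaps.items()}
        conv = pairwise_convergence(diffuse_fields)
        conv.to_csv(out / "pairwise_convergence_diffuse.csv")
        counts = convergence_count(diffuse_fields)
        split = split_high_low(counts, scene.striatum_ipsi)
        (out / "convergence_split.json").write_text(json.dumps(split.as_dict(), indent=2))
        cs["pairwise"] = _checksum_df(conv)
        cs["split_high"] = _checksum_array(split.high.values)
    except Exception as e:  # noqa: BLE001
        raise PipelineError("converge", e) from e

    try:
        cs = stage("confmap")
        # graded six-level map for the first subregion's projection field
        first = scene.subregion_names[0]
        targets = {
            "diffuse": classmaps[first].tier_mask("diffuse"),
            "dense": classmaps[first].tier_mask("dense"),
        }
        results = evaluate_criteria(scene.thalamic_injections, targets, GRADED_CRITERIA)
        graded = build_confidence_map(
            scene.thalamic_injections, results, GRADED_CRITERIA, scene.thalamus
        )
        nuclear_coverage(graded, scene.atlas).to_csv(out / f"nuclear_coverage_{first}.csv")
        cs[f"graded_{first}"] = _checksum_array(graded.values)
        # binary eight-level maps per planted subdivision
        binary_maps = {}
        vs = scene.striatum.voxel_size_um
        for sub_id in sorted(scene.truth.signatures):
            target = BinaryMask(scene.truth.subdivision_labels == sub_id, vs)
            cm = build_confidence_map_binary_target(
                scene.thalamic_injections, target, scene.thalamus, BINARY_CRITERIA
            )
            binary_maps[sub_id] = cm
            nuclear_coverage(cm, scene.atlas, levels=(3, 5, 7)).to_csv(
                out / f"nuclear_coverage_subdivision_{sub_id}.csv"
            )
            cs[f"binary_subdivision_{sub_id}"] = _checksum_array(cm.values)
    except Exception as e:  # noqa: BLE001
        raise PipelineError("confmap", e) from e

    try:
        cs = stage("cluster")
        features = build_feature_matrix(classmaps, scene.striatum_ipsi, config.cluster_voxel_um)
        result = cluster_voxels(features, metric=config.cluster_metric)
        k = config.n_clusters or config.scene.n_planted_subdivisions
        parc = cut_dendrogram(result, k=k)
        labels_vol = features.labels_to_volume(parc.labels)
        np.save(out / "parcellation_labels.npy", labels_vol)
        report_contiguity(parc, features).to_csv(out / "cluster_contiguity.csv", index=False)
        pd.DataFrame(result.linkage, columns=["left", "right", "height", "size"]).to_csv(
            out / "voxel_linkage.csv", index=False
        )
        cs["parcellation"] = _checksum_array(labels_vol)
    except Exception as e:  # noqa: BLE001
        raise PipelineError("cluster", e) from e

    try:
        cs = stage("network")
        graph = CircuitGraph()
        for name in scene.subregion_names:
            graph.add_node(name, CORTICAL)
        for nid in scene.atlas.ids():
            graph.add_node(scene.atlas.names[nid], THALAMIC)
        cc_table, ct_table = make_connectivity_tables(scene)
        for u, v, w in corticocortical_edges(cc_table, config.corticocortical_cutoff):
            graph.add_edge(u, v, "corticocortical", w)
        for u, v, w in thalamic_edges(ct_table, "corticothalamic", config.thalamic_cutoff):
            graph.add_edge(u, v, "corticothalamic", w)
        tier_fields = {
            t: {n: m.tier_mask(t) for n, m in classmaps.items()}
            for t in ("dense", "moderate", "diffuse")
        }
        _, conv_edges = primary_convergent(tier_fields, config.convergent_cutoff)
        for u, v, w in conv_edges:
            graph.add_edge(u, v, "corticostriatal_convergent", w)
        for sub_id, cm in binary_maps.items():
            node = f"subdivision_{sub_id}"
            graph.add_node(node, SUBDIVISION)
            target = BinaryMask(scene.truth.subdivision_labels == sub_id, vs)
            prim = primary_inputs(
                target,
                dense_fields,
                config.primary_occupancy_cutoff,
                config.primary_within_cutoff,
            )
            for name, row in prim[prim["primary"]].iterrows():
                graph.add_edge(name, node, "corticostriatal_convergent", row["occupancy"])
            cov = nuclear_coverage(cm, scene.atlas, levels=(3, 5, 7))
            ts_table = cov[["average"]].rename(columns={"average": node})
            for u, v, w in thalamic_edges(ts_table, "thalamostriatal", config.thalamic_cutoff):
                graph.add_edge(u, v, "thalamostriatal", w)
        export_graph(graph, out / "circuit_graph.csv")
        export_graph(graph, out / "circuit_graph.graphml")
        edge_df = pd.read_csv(out / "circuit_graph.csv")
        cs["edges"] = _checksum_df(edge_df)
        manifest["stages"]["network"]["n_edges"] = int(len(edge_df))
    except Exception as e:  # noqa: BLE001
        raise PipelineError("network", e) from e

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return out
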