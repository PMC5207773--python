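"""Thresholded extraction of the cortico-thalamo-basal ganglia circuit graph.

Edges are drawn between cortical subregions, thalamic nuclei, and
clustered striatal subdivisions using strict (>) cutoffs on measured
fractions:

* corticocortical: projection density > 15% in the target area,
* corticostriatal convergence: the tier-matched coverage of one
  subregion's striatal projection field by another's, averaged over the
  dense / moderate / diffuse tiers, > 50%,
* primary inputs to a striatal subdivision: a dense projection field
  occupying > 20% of the subdivision (route 1) or > 50% of the dense
  projections falling within it (route 2),
* thalamostriatal / thalamocortical / corticothalamic: > 20% of the
  thalamic nucleus volume involved.

The graph is a typed, weighted ``networkx.DiGraph``; rendering is out of
scope — edge lists (CSV) and GraphML are exported instead.
"""

from __future__ import annotations

import logging
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .core_volumes import BinaryMask, VolumeError, coverage_fraction

logger = logging.getLogger(__name__)

CORTICAL, THALAMIC, SUBDIVISION = "cortical", "thalamic", "striatal_subdivision"

#: legal (source class, target class) pairs per edge type
LEGAL_EDGES = {
    "corticocortical": {(CORTICAL, CORTICAL)},
    "corticostriatal_convergent": {(CORTICAL, CORTICAL), (CORTICAL, SUBDIVISION)},
    "thalamostriatal": {(THALAMIC, CORTICAL), (THALAMIC, SUBDIVISION)},
    "thalamocortical": {(THALAMIC, CORTICAL)},
    "corticothalamic": {(CORTICAL, THALAMIC)},
}

DEFAULT_CUTOFFS = {
    "corticocortical": 0.15,
    "corticostriatal_convergent": 0.50,
    "thalamic": 0.20,
    "primary_occupancy": 0.20,
    "primary_within": 0.50,
}


class CircuitGraph:
    """Typed weighted digraph over cortical / thalamic / subdivision nodes."""

    def __init__(self):
        self.g = nx.DiGraph()

    def add_node(self, name: str, node_class: str):
        if node_class not in (CORTICAL, THALAMIC, SUBDIVISION):
            raise VolumeError(f"unknown node class {node_class!r}")
        existing = self.g.nodes.get(name)
        if existing and existing["node_class"] != node_class:
            raise VolumeError(f"node {name} already has class {existing['node_class']}")
        self.g.add_node(name, node_class=node_class)

    def add_edge(self, source: str, target: str, edge_type: str, weight: float):
        if edge_type not in LEGAL_EDGES:
            raise VolumeError(f"unknown edge type {edge_type!r}")
        if not 0 <= weight <= 1:
            raise VolumeError(f"edge weight must lie in [0, 1], got {weight}")
        sc = self.g.nodes[source]["node_class"]
        tc = self.g.nodes[target]["node_class"]
        if (sc, tc) not in LEGAL_EDGES[edge_type]:
            raise VolumeError(
                f"edge type {edge_type} cannot connect {sc} -> {tc} ({source} -> {target})"
            )
        self.g.add_edge(source, target, edge_type=edge_type, weight=float(weight))

    def edges_of_type(self, edge_type: str):
        return [
            (u, v, d["weight"])
            for u, v, d in self.g.edges(data=True)
            if d["edge_type"] == edge_type
        ]

    def __eq__(self, other):
        if not isinstance(other, CircuitGraph):
            return NotImplemented
        if set(self.g.nodes(data="node_class")) != set(other.g.nodes(data="node_class")):
            return False
        a = {(u, v, d["edge_type"], round(d["weight"], 12)) for u, v, d in self.g.edges(data=True)}
        b = {(u, v, d["edge_type"], round(d["weight"], 12)) for u, v, d in other.g.edges(data=True)}
        return a == b


# ---------------------------------------------------------------------------
# Edge extraction
# ---------------------------------------------------------------------------

def primary_inputs(
    subdivision: BinaryMask,
    dense_fields: dict[str, BinaryMask],
    occupancy_cutoff: float = DEFAULT_CUTOFFS["primary_occupancy"],
    within_cutoff: float = DEFAULT_CUTOFFS["primary_within"],
) -> pd.DataFrame:
    """Cortical subregions qualifying as primary inputs to a striatal subdivision.

    Route 1: the subregion's dense projection field occupies more than
    ``occupancy_cutoff`` of the subdivision's voxels.  Route 2: more than
    ``within_cutoff`` of the subregion's dense projections lie within the
    subdivision.  Returns the per-subregion fractions, per-route booleans,
    and the union qualification.
    """
    if subdivision.count() == 0:
        raise VolumeError("subdivision mask is empty")
    rows = []
    for name, field in dense_fields.items():
        n_field = field.count()
        occupancy = coverage_fraction(subdivision, field)
        within = (
            np.count_nonzero(field.values & subdivision.values) / n_field
            if n_field
            else np.nan
        )
        r1 = occupancy > occupancy_cutoff
        r2 = bool(n_field) and within > within_cutoff
        rows.append(
            {
                "subregion": name,
                "occupancy": occupancy,
                "within": within,
                "route_1": r1,
                "route_2": r2,
                "primary": r1 or r2,
            }
        )
    return pd.DataFrame(rows).set_index("subregion")


def corticocortical_edges(
    density_table: pd.DataFrame,
    cutoff: float = DEFAULT_CUTOFFS["corticocortical"],
):
    """Directed edges where projection density strictly exceeds the cutoff.

    ``density_table``: square source x target fractions in [0, 1];
    self-projections are ignored.
    """
    vals = density_table.to_numpy(dtype=float)
    if np.nanmin(vals) < 0 or np.nanmax(vals) > 1:
        raise VolumeError("density table entries must lie in [0, 1]")
    edges = []
    for src in density_table.index:
        for tgt in density_table.columns:
            if src == tgt:
                continue
            w = density_table.loc[src, tgt]
            if np.isfinite(w) and w > cutoff:
                edges.append((src, tgt, float(w)))
    return edges


def primary_convergent(
    tier_fields: dict[str, dict[str, BinaryMask]],
    cutoff: float = DEFAULT_CUTOFFS["corticostriatal_convergent"],
):
    """Tier-averaged striatal convergence between subregion projection fields.

    ``tier_fields`` maps tier name ('dense', 'moderate', 'diffuse') to the
    per-subregion fields of that tier.  For an ordered pair (source,
    target), convergence is the mean over tiers of the fraction of the
    target's tier field covered by the source's tier field; tiers in which
    the target's field is empty are omitted from the mean (and logged).
    Returns ``(convergence DataFrame, qualifying edge list)``.
    """
    tiers = list(tier_fields)
    names = list(tier_fields[tiers[0]])
    conv = pd.DataFrame(np.nan, index=names, columns=names, dtype=float)
    for tgt in names:
        for src in names:
            fracs = []
            for tier in tiers:
                target_field = tier_fields[tier][tgt]
                if target_field.count() == 0:
                    logger.info("tier %s empty for target %s; omitted from mean", tier, tgt)
                    continue
                fracs.append(coverage_fraction(target_field, tier_fields[tier][src]))
            if fracs:
                conv.loc[src, tgt] = float(np.mean(fracs))
    edges = [
        (src, tgt, float(conv.loc[src, tgt]))
        for src in names
        for tgt in names
        if src != tgt and np.isfinite(conv.loc[src, tgt]) and conv.loc[src, tgt] > cutoff
    ]
    return conv, edges


def thalamic_edges(
    coverage_table: pd.DataFrame,
    edge_type: str,
    cutoff: float = DEFAULT_CUTOFFS["thalamic"],
):
    """Edges from a nucleus x target coverage table, typed by relation.

    Rows are thalamic nuclei, columns targets, entries the fraction of the
    nucleus volume involved; strict > cutoff.  For 'corticothalamic' the
    edge runs target -> nucleus (cortical feedback onto the thalamus);
    for 'thalamostriatal' / 'thalamocortical' it runs nucleus -> target.
    """
    if edge_type not in ("thalamostriatal", "thalamocortical", "corticothalamic"):
        raise VolumeError(f"unsupported thalamic edge type {edge_type!r}")
    edges = []
    for nucleus in coverage_table.index:
        for target in coverage_table.columns:
            w = coverage_table.loc[nucleus, target]
            if not np.isfinite(w) or w <= cutoff:
                continue
            if edge_type == "corticothalamic":
                edges.append((target, nucleus, float(w)))
            else:
                edges.append((nucleus, target, float(w)))
    return edges


# ---------------------------------------------------------------------------
# Export / import
# ---------------------------------------------------------------------------

def export_graph(graph: CircuitGraph, path, fmt: str | None = None) -> None:
    """Write the graph as an edge-list CSV or GraphML (lossless round trip)."""
    path = Path(path)
    if fmt is None:
        fmt = "graphml" if path.suffix == ".graphml" else "csv"
    if fmt == "csv":
        rows = [
            {
                "source": u,
                "target": v,
                "type": d["edge_type"],
                "weight": d["weight"],
                "source_class": graph.g.nodes[u]["node_class"],
                "target_class": graph.g.nodes[v]["node_class"],
            }
            for u, v, d in graph.g.edges(data=True)
        ]
        df = pd.DataFrame(rows, columns=["source", "target", "type", "weight",
                                         "source_class", "target_class"])
        df.to_csv(path, index=False)
        nodes = pd.DataFrame(
            [{"node": n, "node_class": c} for n, c in graph.g.nodes(data="node_class")],
            columns=["node", "node_class"],
        )
        nodes.to_csv(path.with_suffix(".nodes.csv"), index=False)
    elif fmt == "graphml":
        nx.write_graphml(graph.g, str(path))
    else:
        raise VolumeError(f"unknown export format {fmt!r}")


def load_graph(path, fmt: str | None = None) -> CircuitGraph:
    path = Path(path)
    if fmt is None:
        fmt = "graphml" if path.suffix == ".graphml" else "csv"
    out = CircuitGraph()
    if fmt == "csv":
        nodes = pd.read_csv(path.with_suffix(".nodes.csv"))
        for _, row in nodes.iterrows():
            out.add_node(row["node"], row["node_class"])
        df = pd.read_csv(path)
        for _, row in df.iterrows():
            out.add_edge(row["source"], row["target"], row["type"], row["weight"])
    elif fmt == "graphml":
        g = nx.read_graphml(str(path))
        for n, d in g.nodes(data=True):
            out.add_node(n, d["node_class"])
        for u, v, d in g.edges(data=True):
            out.add_edge(u, v, d["edge_type"], float(d["weight"]))
    else:
        raise VolumeError(f"unknown format {fmt!r}")
    return out
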