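"""Pairwise projection-field convergence and per-voxel convergence counts.

Convergence of field B onto field A is the fraction of A's voxels also
covered by B (rows = covered field, columns = covering field; not
symmetric).  The per-voxel convergence count — how many subregion fields
cover each striatal voxel — splits the striatum into a high- and a
low-convergence compartment at the mean count over striatal voxels
(a voxel exactly at the mean goes to "low").
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .core_volumes import BinaryMask, ProjectionVolume, VolumeError, coverage_fraction


def pairwise_convergence(fields: dict[str, BinaryMask]) -> pd.DataFrame:
    """M[r, c] = fraction of field r covered by field c (NaN row for empty fields)."""
    names = list(fields)
    if not names:
        raise VolumeError("need at least one field")
    first = fields[names[0]]
    for m in fields.values():
        if m.values.shape != first.values.shape:
            raise VolumeError("fields must share a grid")
    M = pd.DataFrame(np.nan, index=names, columns=names, dtype=float)
    for r in names:
        if fields[r].count() == 0:
            continue  # marked missing, never silently 0
        for c in names:
            M.loc[r, c] = coverage_fraction(fields[r], fields[c])
    return M


def convergence_count(fields: dict[str, BinaryMask]) -> ProjectionVolume:
    """Per-voxel count of fields covering that voxel, as a fraction-scaled volume.

    The raw integer counts (range [0, n_fields]) are stored scaled by
    1 / n_fields to satisfy the ProjectionVolume [0, 1] invariant; use
    :func:`counts_array` for the integers.
    """
    if not fields:
        raise VolumeError("need at least one field")
    masks = list(fields.values())
    counts = np.zeros(masks[0].values.shape, dtype=np.int64)
    for m in masks:
        counts += m.values
    vol = ProjectionVolume(
        counts / len(masks), masks[0].voxel_size_um, origin_label=f"count/{len(masks)}"
    )
    return vol


def counts_array(count_volume: ProjectionVolume) -> np.ndarray:
    """Recover integer convergence counts from a scaled count volume."""
    n = int(count_volume.origin_label.split("/")[1])
    return np.rint(count_volume.values * n).astype(np.int64)


@dataclasses.dataclass
class ConvergenceSplit:
    high: BinaryMask
    low: BinaryMask
    threshold: float
    high_mean: float
    high_sd: float
    low_mean: float
    low_sd: float

    def as_dict(self) -> dict:
        return {
            "threshold": self.threshold,
            "high_mean": self.high_mean,
            "high_sd": self.high_sd,
            "low_mean": self.low_mean,
            "low_sd": self.low_sd,
            "high_voxels": self.high.count(),
            "low_voxels": self.low.count(),
        }


def split_high_low(
    count_volume: ProjectionVolume,
    striatum: BinaryMask,
    threshold: float | None = None,
) -> ConvergenceSplit:
    """Partition the striatum into high (> threshold) and low (<= threshold) masks.

    The default threshold is the mean convergence count over striatal
    voxels (of the analyzed hemisphere mask passed in).  High and low
    masks partition the striatum exactly.
    """
    if striatum.count() == 0:
        raise VolumeError("striatum mask is empty")
    counts = counts_array(count_volume)
    inside = counts[striatum.values]
    if threshold is None:
        threshold = float(inside.mean())
    high_vals = (counts > threshold) & striatum.values
    low_vals = striatum.values & ~high_vals
    def _stats(mask_vals):
        sel = counts[mask_vals]
        if sel.size == 0:
            return float("nan"), float("nan")
        return float(sel.mean()), float(sel.std())
    hm, hs = _stats(high_vals)
    lm, ls = _stats(low_vals)
    return ConvergenceSplit(
        high=striatum.with_values(high_vals),
        low=striatum.with_values(low_vals),
        threshold=float(threshold),
        high_mean=hm,
        high_sd=hs,
        low_mean=lm,
        low_sd=ls,
    )
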