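"""Graded density classification and axis coverage profiles.

Voxelized projection fractions are split into three ordinal tiers —
dense, moderate and diffuse — at fractions of fluorescence-positive
imaging sub-voxels of over 20%, 5% and 0.5% respectively (strict
greater-than at every boundary).  Tier *fields* are cumulative by default:
the diffuse projection field includes moderate and dense voxels, matching
the outer-envelope reading used throughout the analysis (switchable to
exclusive tiers).
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .core_volumes import BinaryMask, ProjectionVolume, VolumeError

#: ordinal class codes
NONE, DIFFUSE, MODERATE, DENSE = 0, 1, 2, 3
TIER_NAMES = {NONE: "none", DIFFUSE: "diffuse", MODERATE: "moderate", DENSE: "dense"}
TIER_CODES = {v: k for k, v in TIER_NAMES.items()}

DEFAULT_THRESHOLDS = (0.2, 0.05, 0.005)  # dense, moderate, diffuse


@dataclasses.dataclass
class DensityClassMap:
    """Ordinal density classes {0=none, 1=diffuse, 2=moderate, 3=dense}."""

    classes: np.ndarray
    thresholds: tuple[float, float, float]
    voxel_size_um: tuple[float, float, float]

    def __post_init__(self):
        self.classes = np.asarray(self.classes, dtype=np.uint8)
        if self.classes.max(initial=0) > DENSE:
            raise VolumeError("density classes must lie in {0, 1, 2, 3}")

    @property
    def shape(self):
        return self.classes.shape

    def tier_mask(self, tier, cumulative: bool = True) -> BinaryMask:
        """Binary field of a tier; cumulative means class >= tier."""
        code = TIER_CODES[tier] if isinstance(tier, str) else int(tier)
        if not DIFFUSE <= code <= DENSE:
            raise VolumeError(f"tier must be diffuse/moderate/dense, got {tier!r}")
        vals = self.classes >= code if cumulative else self.classes == code
        return BinaryMask(vals, self.voxel_size_um)


def classify_density(
    volume: ProjectionVolume,
    striatum: BinaryMask,
    thresholds: tuple[float, float, float] = DEFAULT_THRESHOLDS,
) -> DensityClassMap:
    """Classify per-voxel fractions into graded density tiers within the striatum.

    v > thresholds[0] -> dense, v > thresholds[1] -> moderate,
    v > thresholds[2] -> diffuse, else none; voxels outside the striatum
    mask are always none.
    """
    t_dense, t_mod, t_diff = thresholds
    if not (0 < t_diff < t_mod < t_dense < 1):
        raise VolumeError(f"thresholds must be strictly decreasing in (0, 1), got {thresholds}")
    if volume.values.shape != striatum.values.shape:
        raise VolumeError("volume and striatum mask must share a grid")
    v = volume.values
    classes = np.zeros(v.shape, dtype=np.uint8)
    classes[v > t_diff] = DIFFUSE
    classes[v > t_mod] = MODERATE
    classes[v > t_dense] = DENSE
    classes[~striatum.values] = NONE
    return DensityClassMap(classes, thresholds, volume.voxel_size_um)


def max_density_map(maps: list[DensityClassMap]) -> DensityClassMap:
    """Voxelwise ordinal maximum across class maps (cumulative per-subregion map)."""
    if not maps:
        raise VolumeError("max_density_map requires at least one class map")
    first = maps[0]
    out = first.classes.copy()
    for m in maps[1:]:
        if m.shape != first.shape:
            raise VolumeError("class maps must share a grid")
        np.maximum(out, m.classes, out=out)
    return DensityClassMap(out, first.thresholds, first.voxel_size_um)


_AXES = {"A-P": 0, "D-V": 1, "M-L": 2, "AP": 0, "DV": 1, "ML": 2}


def axis_distribution(
    class_map: DensityClassMap,
    striatum: BinaryMask,
    axis: str,
    step_um: float = 100.0,
    tier: str = "dense",
    cumulative: bool = True,
) -> pd.DataFrame:
    """Tier coverage profile along an anatomical axis in fixed-width slabs.

    For each slab of width ``step_um``: (tier-covered striatal voxels in
    slab) / (striatal voxels in slab), normalizing each slab by its own
    striatal volume.  Slabs containing no striatal voxel get NaN (marked
    missing rather than zero).  Returns a DataFrame with columns
    ``slab_position_um`` (slab start) and ``fraction``.
    """
    if tier not in ("dense", "diffuse", "moderate"):
        raise VolumeError(f"tier must be dense/moderate/diffuse, got {tier!r}")
    ax = _AXES.get(axis)
    if ax is None:
        raise VolumeError(f"axis must be one of {sorted(set(_AXES))}, got {axis!r}")
    vs = class_map.voxel_size_um[ax]
    if step_um < vs:
        raise VolumeError(f"step ({step_um} um) must be >= voxel size ({vs} um)")
    stride = int(round(step_um / vs))
    tier_vals = class_map.tier_mask(tier, cumulative=cumulative).values & striatum.values
    str_vals = striatum.values
    n = class_map.shape[ax]
    tier_counts = np.moveaxis(tier_vals, ax, 0).reshape(n, -1).sum(axis=1)
    str_counts = np.moveaxis(str_vals, ax, 0).reshape(n, -1).sum(axis=1)
    rows = []
    for start in range(0, n, stride):
        sl = slice(start, min(start + stride, n))
        denom = str_counts[sl].sum()
        frac = tier_counts[sl].sum() / denom if denom > 0 else np.nan
        rows.append({"slab_position_um": start * vs, "fraction": frac})
    return pd.DataFrame(rows)
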