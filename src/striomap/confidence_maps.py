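"""Sub-injection localization of thalamic projection origins: confidence maps.

Overlapping thalamic injections are individually tested against graded
inclusion criteria on their striatal projection fields (e.g. "covers 10%
of the diffuse target volume").  For each criterion the injections are
combined into union masks that vote on thalamic voxels:

* the union of full volumes of satisfying injections adds +1, and the
  union of their eroded cores adds a further +1,
* the union of cores of failing injections subtracts 1 for every
  criterion; the union of their full volumes additionally subtracts 1 —
  but only for the two easiest-to-meet criteria ("easiest" is determined
  empirically per run as the descending count of satisfying injections,
  ties broken by the declared criteria order),
* after summing over criteria, voxels inside the cores of injections that
  satisfied no criterion at all are set to zero, negative values are
  clipped to zero, and the map is restricted to the thalamus.

With L criteria the result is a 2L-level integer confidence map: 6 levels
for the graded (diffuse/dense) target criteria, 8 levels for the binary
target variant.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import pandas as pd

from .core_volumes import AtlasPartition, BinaryMask, Injection, VolumeError

#: number of easiest criteria whose failing full volumes are also subtracted
N_FULL_SUBTRACT = 2

MEASURES = ("target_covered", "projection_within")


@dataclasses.dataclass(frozen=True)
class Criterion:
    """One inclusion criterion.

    measure 'target_covered': fraction of the (tier) target volume covered
    by the projection; 'projection_within': fraction of the projection
    volume lying within the target.  ``tier`` selects the target variant
    (e.g. 'diffuse' / 'dense') when targets are tiered, or None for a
    single binary target.
    """

    measure: str
    cutoff: float
    tier: str | None = None

    def __post_init__(self):
        if self.measure not in MEASURES:
            raise VolumeError(f"unknown measure {self.measure!r}")
        if not 0 < self.cutoff <= 1:
            raise VolumeError(f"cutoff must lie in (0, 1], got {self.cutoff}")

    def label(self) -> str:
        t = f"{self.tier}_" if self.tier else ""
        return f"{self.measure}:{t}{self.cutoff:g}"


@dataclasses.dataclass
class CriteriaSet:
    """An explicitly ordered list of criteria (declared order breaks ties)."""

    criteria: list[Criterion]

    def __post_init__(self):
        if not self.criteria:
            raise VolumeError("criteria set must be nonempty")

    def __len__(self):
        return len(self.criteria)

    def __iter__(self):
        return iter(self.criteria)

    def labels(self) -> list[str]:
        return [c.label() for c in self.criteria]


#: six-level map: graded corticostriatal target (diffuse/dense tiers)
GRADED_CRITERIA = CriteriaSet(
    [
        Criterion("target_covered", 0.10, tier="diffuse"),
        Criterion("target_covered", 0.05, tier="dense"),
        Criterion("target_covered", 0.50, tier="dense"),
    ]
)

#: eight-level map: binary striatal target volume
BINARY_CRITERIA = CriteriaSet(
    [
        Criterion("target_covered", 0.10),
        Criterion("projection_within", 0.10),
        Criterion("target_covered", 0.25),
        Criterion("projection_within", 0.25),
    ]
)


@dataclasses.dataclass
class ConfidenceMap:
    """Non-negative integer confidence levels over the thalamus."""

    values: np.ndarray
    max_level: int
    voxel_size_um: tuple

    def __post_init__(self):
        self.values = np.asarray(self.values)
        if self.values.min(initial=0) < 0 or self.values.max(initial=0) > self.max_level:
            raise VolumeError(f"confidence values must lie in [0, {self.max_level}]")

    def level_mask(self, level: int, mode: str = "ge") -> BinaryMask:
        """Voxels covered by confidence level ``level`` (>= by default)."""
        vals = self.values >= level if mode == "ge" else self.values == level
        return BinaryMask(vals, self.voxel_size_um)


def _measure(projection: BinaryMask, target: BinaryMask, criterion: Criterion) -> float:
    n_target = target.count()
    if n_target == 0:
        raise VolumeError(f"empty target for criterion {criterion.label()}")
    n_proj = projection.count()
    if n_proj == 0:
        return 0.0
    inter = int(np.count_nonzero(projection.values & target.values))
    if criterion.measure == "target_covered":
        return inter / n_target
    return inter / n_proj


def _target_for(targets, criterion: Criterion) -> BinaryMask:
    if isinstance(targets, BinaryMask):
        if criterion.tier is not None:
            raise VolumeError(
                f"criterion {criterion.label()} needs tiered targets but got a single mask"
            )
        return targets
    try:
        return targets[criterion.tier]
    except KeyError:
        raise VolumeError(f"no target field for tier {criterion.tier!r}") from None


def evaluate_criteria(
    injections: Sequence[Injection],
    targets,
    criteria: CriteriaSet,
) -> pd.DataFrame:
    """Boolean table (injection x criterion): measure meets (>=) its cutoff.

    ``targets`` is a single BinaryMask for tier-less criteria, or a dict
    tier -> BinaryMask for graded criteria.
    """
    rows = {}
    for inj in injections:
        rows[inj.id] = [
            _measure(inj.projection, _target_for(targets, c), c) >= c.cutoff for c in criteria
        ]
    return pd.DataFrame.from_dict(rows, orient="index", columns=criteria.labels())


def rank_by_easiness(criteria_results: pd.DataFrame) -> list[int]:
    """Criterion column indices ordered easiest (most satisfiers) first.

    Ties are broken by the declared criteria order.
    """
    counts = criteria_results.sum(axis=0).to_numpy()
    return sorted(range(len(counts)), key=lambda j: (-counts[j], j))


def build_confidence_map(
    injections: Sequence[Injection],
    criteria_results: pd.DataFrame,
    criteria: CriteriaSet,
    thalamus: BinaryMask,
) -> ConfidenceMap:
    """Accumulate injection votes into a 2L-level confidence map.

    Requires at least ``N_FULL_SUBTRACT`` criteria, since the
    full-volume-subtraction exception distinguishes the two easiest.
    """
    if len(criteria) < N_FULL_SUBTRACT:
        raise VolumeError(
            f"need at least {N_FULL_SUBTRACT} criteria for the full-subtraction exception"
        )
    if list(criteria_results.index) != [inj.id for inj in injections]:
        criteria_results = criteria_results.loc[[inj.id for inj in injections]]
    sat = criteria_results.to_numpy(dtype=bool)
    easiest = set(rank_by_easiness(criteria_results)[:N_FULL_SUBTRACT])
    shape = thalamus.values.shape
    acc = np.zeros(shape, dtype=np.int32)
    # per criterion, injections are combined into union masks before voting,
    # so each criterion contributes at most +2 / -2 at a voxel and the map
    # is bounded by 2 x |criteria|
    for j in range(len(criteria)):
        sat_full = np.zeros(shape, dtype=bool)
        sat_core = np.zeros(shape, dtype=bool)
        fail_full = np.zeros(shape, dtype=bool)
        fail_core = np.zeros(shape, dtype=bool)
        for i, inj in enumerate(injections):
            if sat[i, j]:
                sat_full |= inj.full.values
                sat_core |= inj.core.values
            else:
                fail_full |= inj.full.values
                fail_core |= inj.core.values
        acc += sat_full
        acc += sat_core
        acc -= fail_core
        if j in easiest:
            acc -= fail_full
    never = ~sat.any(axis=1)
    for i, inj in enumerate(injections):
        if never[i]:
            acc[inj.core.values] = 0
    np.clip(acc, 0, None, out=acc)
    acc[~thalamus.values] = 0
    return ConfidenceMap(acc, 2 * len(criteria), thalamus.voxel_size_um)


def build_confidence_map_binary_target(
    injections: Sequence[Injection],
    target: BinaryMask,
    thalamus: BinaryMask,
    criteria: CriteriaSet = BINARY_CRITERIA,
) -> ConfidenceMap:
    """Convenience wrapper: evaluate the binary-target criteria and build the map."""
    results = evaluate_criteria(injections, target, criteria)
    return build_confidence_map(injections, results, criteria, thalamus)


def nuclear_coverage(
    confmap: ConfidenceMap,
    atlas: AtlasPartition,
    levels: Sequence[int] = (1, 3, 5),
    mode: str = "ge",
) -> pd.DataFrame:
    """Fraction of each atlas nucleus covered by each confidence level.

    Coverage at level l means confidence >= l (nested by construction);
    the across-levels average is appended.  Nuclei with no voxels on the
    grid are marked missing (NaN).
    """
    if atlas.labels.shape != confmap.values.shape:
        raise VolumeError("atlas and confidence map must share a grid")
    rows = []
    for nid in atlas.ids():
        nucleus = atlas.mask_of(nid)
        n = int(nucleus.sum())
        row = {"nucleus": atlas.names[nid]}
        if n == 0:
            for lv in levels:
                row[f"level_{lv}"] = np.nan
            row["average"] = np.nan
        else:
            vals = confmap.values[nucleus]
            for lv in levels:
                covered = vals >= lv if mode == "ge" else vals == lv
                row[f"level_{lv}"] = float(np.count_nonzero(covered)) / n
            row["average"] = float(np.mean([row[f"level_{lv}"] for lv in levels]))
        rows.append(row)
    return pd.DataFrame(rows).set_index("nucleus")


NEITHER, TS_ONLY, TC_ONLY, BOTH = 0, 1, 2, 3
OVERLAY_NAMES = {NEITHER: "neither", TS_ONLY: "ts_only", TC_ONLY: "tc_only", BOTH: "both"}


def overlay_confidence(
    ts: ConfidenceMap,
    tc: ConfidenceMap,
    ts_cutoff: int = 1,
    tc_cutoff: int = 1,
):
    """Categorical overlay of thalamostriatal vs thalamocortical maps.

    Per voxel: 0 neither, 1 ts only, 2 tc only, 3 both, by confidence >=
    the per-map cutoff.  Returns ``(label array, counts dict)``.
    """
    if ts.values.shape != tc.values.shape:
        raise VolumeError("confidence maps must share a grid")
    a = ts.values >= ts_cutoff
    b = tc.values >= tc_cutoff
    labels = np.zeros(ts.values.shape, dtype=np.uint8)
    labels[a & ~b] = TS_ONLY
    labels[~a & b] = TC_ONLY
    labels[a & b] = BOTH
    counts = {name: int(np.count_nonzero(labels == code)) for code, name in OVERLAY_NAMES.items()}
    return labels, counts
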