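"""Synthetic tracing "experiments" with planted ground truth.

Every downstream stage of the pipeline (density classification, convergence,
confidence maps, parcellation, alignment, circuit graphs, EPSC metrics) is
exercised on scenes produced here, so no external dataset is required.

A scene emulates, at 100 um voxel resolution, the geometry of a bilateral
mouse striatum and a unilateral thalamus:

* the striatum is a pair of mirrored ellipsoids; a small anterior blob
  plays the role of the anterior commissure landmark used to align
  anterior sections,
* the analyzed (ipsilateral) striatal hemisphere is partitioned into
  ``n_planted_subdivisions`` contiguous Voronoi cells, each assigned a
  distinct subset of cortical subregions that innervate it densely
  (the recoverable target of the parcellation stage),
* each cortical subregion paints a compact dense projection core on its
  signature subdivisions, wrapped in a moderate ring and a wider diffuse
  halo, emulating the dense-core-plus-diffuse-field structure of real
  corticostriatal projections; optional i.i.d. Gaussian noise (truncated
  to [0, 1]) stresses the density thresholds,
* thalamic injections are overlapping spheres on a jittered lattice
  (grown until their union covers the configured fraction of the
  thalamus, default >93%); each injection carries a full mask, a core
  eroded by 100 um, and the striatal projection field of the planted
  thalamic zone it falls in,
* the thalamus also carries a synthetic nuclear atlas (Voronoi cells)
  for nuclear-coverage tables.

Scenes are deterministic functions of their :class:`SceneConfig`
(including the seed).
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from .alignment import SectionTransform, sectioning_matrix, apply_affine, shift_sections
from .core_volumes import (
    AtlasPartition,
    BinaryMask,
    Injection,
    ProjectionVolume,
    coverage_fraction,
    erode_mask,
    save_nifti,
)
from .ephys_metrics import EPSCTrace

MAX_MISALIGNMENT_DEG = 15.0


class SceneConfigError(ValueError):
    pass


@dataclasses.dataclass
class SceneConfig:
    """Parameters of a synthetic scene (identical config => identical scene)."""

    seed: int = 0
    grid_shape: tuple[int, int, int] = (40, 36, 48)
    voxel_size_um: float = 100.0
    n_cortical_subregions: int = 15
    n_thalamic_injections: int | None = None  # None: all lattice sites
    n_planted_subdivisions: int = 4
    n_thalamic_nuclei: int = 8
    dense_level: float = 0.5
    moderate_level: float = 0.1
    diffuse_level: float = 0.02
    noise_sd: float = 0.02
    min_thalamic_coverage: float = 0.93
    injection_radius_um: float = 350.0
    injection_lattice_um: float = 300.0
    core_erosion_um: float = 100.0
    misalignment: SectionTransform | None = None

    def __post_init__(self):
        if self.n_planted_subdivisions > self.n_cortical_subregions:
            raise SceneConfigError(
                "cannot plant more subdivisions than there are cortical subregions "
                "to build distinct dense-input signatures from"
            )
        if self.n_planted_subdivisions < 1:
            raise SceneConfigError("need at least one planted subdivision")
        for lvl in (self.dense_level, self.moderate_level, self.diffuse_level):
            if not 0 <= lvl <= 1:
                raise SceneConfigError("painting levels must lie in [0, 1]")
        if self.misalignment is not None:
            for a in (
                self.misalignment.roll_deg,
                self.misalignment.pitch_deg,
                self.misalignment.yaw_deg,
            ):
                if abs(a) > MAX_MISALIGNMENT_DEG:
                    raise SceneConfigError(
                        f"misalignment angles must satisfy |angle| <= {MAX_MISALIGNMENT_DEG} deg"
                    )


@dataclasses.dataclass
class SceneTruth:
    """Planted ground truth of a scene."""

    subdivision_labels: np.ndarray  # 3D int array, 0 = outside analyzed striatum
    signatures: dict[int, tuple[str, ...]]  # subdivision -> dense subregions
    thalamic_zone_labels: np.ndarray  # 3D int, planted thalamus->subdivision zones
    injection_zone: dict[str, int]  # injection id -> zone it projects for
    transform: SectionTransform | None


@dataclasses.dataclass
class Scene:
    config: SceneConfig
    striatum: BinaryMask  # bilateral
    striatum_ipsi: BinaryMask  # analyzed hemisphere
    landmark: BinaryMask  # anterior-commissure surrogate
    thalamus: BinaryMask
    atlas: AtlasPartition  # synthetic thalamic nuclei
    cortical_fields: dict[str, ProjectionVolume]
    thalamic_injections: list[Injection]
    truth: SceneTruth

    @property
    def subregion_names(self) -> list[str]:
        return list(self.cortical_fields)


# ---------------------------------------------------------------------------
# Geometry helpers
# ---------------------------------------------------------------------------

def _ellipsoid(shape, center, semi_axes, grids=None) -> np.ndarray:
    if grids is None:
        grids = np.ogrid[tuple(slice(0, s) for s in shape)]
    val = sum(((g - c) / a) ** 2 for g, c, a in zip(grids, center, semi_axes))
    return val <= 1.0


def _scene_geometry(cfg: SceneConfig, grids=None):
    """Striatum / landmark / thalamus masks scaled to the configured grid.

    ``grids`` may supply alternative (possibly transformed) coordinate
    arrays in index units, enabling analytic rasterization of misaligned
    anatomy; by default the grid's own coordinates are used.
    """
    shape = cfg.grid_shape
    # proportions chosen so the default (40, 36, 48) grid leaves a margin
    # for misalignment without clipping
    ap, dv, ml = shape
    mid = ml / 2.0
    str_c_ap, str_c_dv = 0.40 * ap, 0.47 * dv
    str_ax = (0.33 * ap, 0.28 * dv, 0.17 * ml)
    offset_ml = 0.25 * ml
    striatum = np.zeros(shape, dtype=bool)
    for side in (-1, +1):
        striatum |= _ellipsoid(
            shape, (str_c_ap, str_c_dv, mid + side * offset_ml), str_ax, grids=grids
        )
    ipsi = striatum.copy()
    ipsi[:, :, : int(mid)] = False
    landmark = np.zeros(shape, dtype=bool)
    lm_ap = max(2.0, str_c_ap - str_ax[0] + 1.0)
    for side in (-1, +1):
        landmark |= _ellipsoid(
            shape,
            (lm_ap + 1.0, 0.65 * dv, mid + side * 0.12 * ml),
            (0.055 * ap, 0.05 * dv, 0.0375 * ml),
            grids=grids,
        )
    thal_c = (0.76 * ap, 0.5 * dv, mid + 0.18 * ml)
    thal_ax = (0.15 * ap, 0.20 * dv, 0.15 * ml)
    thalamus = _ellipsoid(shape, thal_c, thal_ax, grids=grids)
    return striatum, ipsi, landmark, thalamus


def _voronoi_partition(mask: np.ndarray, n_cells: int, rng: np.random.Generator) -> np.ndarray:
    """Contiguous partition of a convex-ish mask into Voronoi cells of seeds.

    Seeds are drawn with a minimum-separation rejection rule so no cell is
    degenerate.
    """
    coords = np.argwhere(mask)
    if coords.shape[0] < n_cells:
        raise SceneConfigError("mask too small to partition")
    span = coords.max(axis=0) - coords.min(axis=0) + 1
    min_sep = max(2.0, 0.5 * float(span.max()) / n_cells)
    seeds = []
    order = rng.permutation(coords.shape[0])
    for idx in order:
        p = coords[idx]
        if all(np.linalg.norm(p - s) >= min_sep for s in seeds):
            seeds.append(p)
        if len(seeds) == n_cells:
            break
    while len(seeds) < n_cells:  # relax separation if rejection exhausted
        seeds.append(coords[rng.integers(coords.shape[0])])
    seeds = np.asarray(seeds, dtype=float)
    d2 = ((coords[:, None, :] - seeds[None, :, :]) ** 2).sum(axis=2)
    labels = np.zeros(mask.shape, dtype=np.int32)
    labels[tuple(coords.T)] = d2.argmin(axis=1) + 1
    return _enforce_contiguity(labels)


def _enforce_contiguity(labels: np.ndarray, max_rounds: int = 20) -> np.ndarray:
    """Reassign stray voxels so every label is one 6-connected component.

    Voxelizing a convex Voronoi cell can pinch off small fragments along
    thin diagonal wedges; fragments beyond the largest component of each
    label are absorbed into the dominant neighbouring label.
    """
    structure = ndimage.generate_binary_structure(3, 1)
    labels = labels.copy()
    for _ in range(max_rounds):
        changed = False
        for lab in np.unique(labels[labels > 0]):
            comp, n = ndimage.label(labels == lab, structure=structure)
            if n <= 1:
                continue
            sizes = ndimage.sum_labels(np.ones_like(comp), comp, index=range(1, n + 1))
            keep = int(np.argmax(sizes)) + 1
            for c in range(1, n + 1):
                if c == keep:
                    continue
                frag = comp == c
                ring = ndimage.binary_dilation(frag, structure=structure) & ~frag
                neigh = labels[ring]
                neigh = neigh[(neigh > 0) & (neigh != lab)]
                if neigh.size == 0:
                    continue  # isolated; picked up in a later round via donors
                labels[frag] = np.bincount(neigh).argmax()
                changed = True
        if not changed:
            break
    return labels


# ---------------------------------------------------------------------------
# Scene construction
# ---------------------------------------------------------------------------

def subregion_name(i: int) -> str:
    return f"ctx_{i + 1:02d}"


def _paint_cortical_fields(cfg, striatum_ipsi, subdivision_labels, signatures, rng):
    fields = {}
    for i in range(cfg.n_cortical_subregions):
        name = subregion_name(i)
        dense = np.zeros(cfg.grid_shape, dtype=bool)
        for sub_id, sig in signatures.items():
            if name in sig:
                dense |= subdivision_labels == sub_id
        moderate = ndimage.binary_dilation(dense, iterations=2) & striatum_ipsi & ~dense
        halo = (
            ndimage.binary_dilation(dense, iterations=5)
            & striatum_ipsi
            & ~dense
            & ~moderate
        )
        values = np.zeros(cfg.grid_shape, dtype=np.float64)
        values[halo] = cfg.diffuse_level
        values[moderate] = cfg.moderate_level
        values[dense] = cfg.dense_level
        if cfg.noise_sd > 0:
            values = values + rng.normal(0.0, cfg.noise_sd, size=values.shape)
        fields[name] = ProjectionVolume(
            np.clip(values, 0.0, 1.0), (cfg.voxel_size_um,) * 3, origin_label=name
        )
    return fields


def _place_injections(cfg, thalamus_mask: BinaryMask, zone_labels, subdivision_labels, rng):
    vs = cfg.voxel_size_um
    spacing = max(1, int(round(cfg.injection_lattice_um / vs)))
    radius_vox = cfg.injection_radius_um / vs
    coords = np.argwhere(thalamus_mask.values)
    lo, hi = coords.min(axis=0), coords.max(axis=0)
    centers = []
    for a in range(lo[0], hi[0] + 1, spacing):
        for d in range(lo[1], hi[1] + 1, spacing):
            for m in range(lo[2], hi[2] + 1, spacing):
                c = np.array([a, d, m]) + rng.integers(-1, 2, size=3)
                c = np.clip(c, 0, np.array(cfg.grid_shape) - 1)
                if thalamus_mask.values[tuple(c)]:
                    centers.append(c)
    if cfg.n_thalamic_injections is not None:
        extra = cfg.n_thalamic_injections - len(centers)
        for _ in range(max(0, extra)):
            centers.append(coords[rng.integers(coords.shape[0])])
        centers = centers[: cfg.n_thalamic_injections]
    if not centers:
        raise SceneConfigError("no thalamic injection centers could be placed")

    # striatal projection field per planted zone
    zone_projection = {}
    for z in np.unique(zone_labels[zone_labels > 0]):
        zone_projection[int(z)] = subdivision_labels == z

    def build(radius):
        injections = []
        zone_of = {}
        union = np.zeros(cfg.grid_shape, dtype=bool)
        for k, c in enumerate(centers):
            full_vals = _ellipsoid(cfg.grid_shape, tuple(c), (radius,) * 3)
            union |= full_vals
            full = BinaryMask(full_vals, (vs,) * 3)
            core = erode_mask(full, cfg.core_erosion_um)
            zone = int(zone_labels[tuple(c)])
            proj = BinaryMask(zone_projection[zone], (vs,) * 3)
            inj_id = f"thal_{k + 1:03d}"
            injections.append(Injection(inj_id, "thalamic", full, core, proj))
            zone_of[inj_id] = zone
        cov = coverage_fraction(thalamus_mask, BinaryMask(union, (vs,) * 3))
        return injections, zone_of, cov

    for _ in range(8):
        injections, zone_of, cov = build(radius_vox)
        if cov >= cfg.min_thalamic_coverage:
            break
        radius_vox += 1.0
    return injections, zone_of


def make_scene(config: SceneConfig) -> Scene:
    """Build a complete deterministic scene from its config."""
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    vs = (cfg.voxel_size_um,) * 3
    striatum_vals, ipsi_vals, landmark_vals, thalamus_vals = _scene_geometry(cfg)

    subdivision_labels = _voronoi_partition(ipsi_vals, cfg.n_planted_subdivisions, rng)
    # distinct dense-input signatures: round-robin assignment of subregions
    signatures: dict[int, tuple[str, ...]] = {
        d + 1: tuple(
            subregion_name(i)
            for i in range(cfg.n_cortical_subregions)
            if i % cfg.n_planted_subdivisions == d
        )
        for d in range(cfg.n_planted_subdivisions)
    }
    cortical_fields = _paint_cortical_fields(cfg, ipsi_vals, subdivision_labels, signatures, rng)

    thalamus = BinaryMask(thalamus_vals, vs)
    zone_labels = _voronoi_partition(thalamus_vals, cfg.n_planted_subdivisions, rng)
    nucleus_labels = _voronoi_partition(thalamus_vals, cfg.n_thalamic_nuclei, rng)
    atlas = AtlasPartition(
        nucleus_labels,
        {int(k): f"nucleus_{int(k):02d}" for k in np.unique(nucleus_labels) if k > 0},
        vs,
    )
    injections, zone_of = _place_injections(cfg, thalamus, zone_labels, subdivision_labels, rng)

    truth = SceneTruth(
        subdivision_labels=subdivision_labels,
        signatures=signatures,
        thalamic_zone_labels=zone_labels,
        injection_zone=zone_of,
        transform=cfg.misalignment,
    )
    return Scene(
        config=cfg,
        striatum=BinaryMask(striatum_vals, vs),
        striatum_ipsi=BinaryMask(ipsi_vals, vs),
        landmark=BinaryMask(landmark_vals, vs),
        thalamus=thalamus,
        atlas=atlas,
        cortical_fields=cortical_fields,
        thalamic_injections=injections,
        truth=truth,
    )


# ---------------------------------------------------------------------------
# Misalignment
# ---------------------------------------------------------------------------

def make_alignment_stack(config: SceneConfig, inplane_factor: int = 4):
    """Striatum + landmark stacks at fine in-plane resolution for alignment.

    Section stacks are physically thick along A-P but imaged at much finer
    in-plane resolution, and alignment needs that in-plane precision for
    degree-scale angles to be observable.  This rasterizes the scene's
    striatum and anterior-commissure surrogate on a grid with the same
    sections but ``inplane_factor`` finer D-V / M-L voxels (100 um
    sections with 25 um in-plane pixels at the default factor).

    Returns ``(striatum, landmark)`` as :class:`BinaryMask` objects.
    """
    f = int(inplane_factor)
    if f < 1:
        raise SceneConfigError("inplane_factor must be >= 1")
    fine_cfg = dataclasses.replace(
        config,
        grid_shape=(
            config.grid_shape[0],
            config.grid_shape[1] * f,
            config.grid_shape[2] * f,
        ),
    )
    striatum_vals, _, landmark_vals, _ = _scene_geometry(fine_cfg)
    vs = (config.voxel_size_um, config.voxel_size_um / f, config.voxel_size_um / f)
    return BinaryMask(striatum_vals, vs), BinaryMask(landmark_vals, vs)


def make_alignment_experiment(
    config: SceneConfig, transform: SectionTransform, inplane_factor: int = 4
):
    """Misaligned striatum + landmark stacks rasterized from continuous geometry.

    A real experimental stack is sectioned and imaged *after* the
    misalignment happens, so the rasterized masks carry sub-voxel boundary
    information about the sectioning angle.  Resampling an already
    voxelized mask cannot reproduce that (a nearest-neighbour shear of a
    binary stack is literally indistinguishable from integer per-section
    jitter), so here the scale+shear+roll map is applied analytically to
    the scene's ellipsoid geometry and the transformed shapes are
    rasterized directly on the fine-in-plane grid; the integer jitter is
    applied afterwards.

    Returns ``(striatum, landmark)`` BinaryMasks on the same grid as
    :func:`make_alignment_stack`.
    """
    f = int(inplane_factor)
    fine_cfg = dataclasses.replace(
        config,
        grid_shape=(
            config.grid_shape[0],
            config.grid_shape[1] * f,
            config.grid_shape[2] * f,
        ),
    )
    shape = fine_cfg.grid_shape
    vs = np.array([config.voxel_size_um, config.voxel_size_um / f, config.voxel_size_um / f])
    R = sectioning_matrix(transform.roll_deg, transform.pitch_deg, transform.yaw_deg)
    M = np.diag(transform.scales) @ R
    A = np.diag(1.0 / vs) @ np.linalg.inv(M) @ np.diag(vs)  # index-space pullback
    center = (np.asarray(shape) - 1) / 2.0
    idx = np.indices(shape, dtype=np.float64).reshape(3, -1)
    back = A @ (idx - center[:, None]) + center[:, None]
    grids = [back[k].reshape(shape) for k in range(3)]
    striatum_vals, _, landmark_vals, _ = _scene_geometry(fine_cfg, grids=grids)
    if transform.per_section_shifts is not None:
        striatum_vals = shift_sections(striatum_vals, transform.per_section_shifts)
        landmark_vals = shift_sections(landmark_vals, transform.per_section_shifts)
    vs_t = tuple(vs)
    return BinaryMask(striatum_vals, vs_t), BinaryMask(landmark_vals, vs_t)


def apply_misalignment(
    stack: BinaryMask, transform: SectionTransform, supersample: int = 1
) -> BinaryMask:
    """Apply roll/pitch/yaw, per-axis scaling and per-section jitter to a stack.

    Rotation and scale are applied about the grid center in a single
    nearest-neighbour resampling; the integer per-section (D-V, M-L)
    jitter is applied afterwards.  For coarse-grid masks, ``supersample``
    can upsample the mask before resampling and mean-pool/re-binarize it
    afterwards, emulating that real misalignment happens before
    voxelization (sub-voxel boundary displacement survives rasterization).
    The exact transform should be recorded in the scene truth by the
    caller.
    """
    for a in (transform.roll_deg, transform.pitch_deg, transform.yaw_deg):
        if abs(a) > MAX_MISALIGNMENT_DEG:
            raise SceneConfigError(f"|angles| must be <= {MAX_MISALIGNMENT_DEG} deg")
    if transform.is_identity():
        return stack.with_values(stack.values.copy())
    R = sectioning_matrix(transform.roll_deg, transform.pitch_deg, transform.yaw_deg)
    M = np.diag(transform.scales) @ R
    f = max(1, int(supersample))
    fine = stack.values
    for ax in range(3):
        fine = np.repeat(fine, f, axis=ax)
    fine_vs = tuple(v / f for v in stack.voxel_size_um)
    out = apply_affine(fine.astype(np.float64), M, fine_vs, order=0)
    sh = [d // f for d in fine.shape]
    out = out.reshape(sh[0], f, sh[1], f, sh[2], f).mean(axis=(1, 3, 5)) > 0.5
    if transform.per_section_shifts is not None:
        shifts = np.asarray(transform.per_section_shifts, dtype=int)
        if shifts.shape != (stack.shape[0], 2):
            raise SceneConfigError(
                f"per_section_shifts must have shape ({stack.shape[0]}, 2)"
            )
        out = shift_sections(out, shifts)
    return stack.with_values(out)


def random_transform(
    rng: np.random.Generator,
    n_sections: int,
    max_angle_deg: float = 5.0,
    scale_range: tuple[float, float] = (0.9, 1.1),
    jitter_voxels: int = 4,
) -> SectionTransform:
    """Draw a plausible sectioning misalignment for round-trip experiments.

    Defaults emulate realistic histology: sectioning-angle aberrations of a
    few degrees, up to 10% per-axis shrinkage/stretch, and per-section
    mounting jitter of up to ``jitter_voxels`` voxels (+-100 um at the
    25 um in-plane resolution of the alignment stacks).
    """
    return SectionTransform(
        roll_deg=float(rng.uniform(-max_angle_deg, max_angle_deg)),
        pitch_deg=float(rng.uniform(-max_angle_deg, max_angle_deg)),
        yaw_deg=float(rng.uniform(-max_angle_deg, max_angle_deg)),
        scale_ap=float(rng.uniform(*scale_range)),
        scale_dv=float(rng.uniform(*scale_range)),
        scale_ml=float(rng.uniform(*scale_range)),
        per_section_shifts=rng.integers(-jitter_voxels, jitter_voxels + 1, size=(n_sections, 2)),
    )


# ---------------------------------------------------------------------------
# EPSC trace generation
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class EPSCParams:
    """Generator parameters for a synthetic EPSC trace.

    Per-stimulus amplitudes follow, in order of precedence: an explicit
    ``relative_amplitudes`` list; a paired-pulse ratio ``ppr`` (second
    stimulus scaled by it); or a geometric ``depression_factor`` f with
    stimulus k scaled by f**(k-1).  ``slow_fraction`` adds a sustained
    plateau current of that fraction of the first EPSC peak, building with
    ``slow_tau_ms`` from the first stimulus.
    """

    amplitude_pa: float = -200.0
    rise_ms: float = 1.0
    decay_ms: float = 5.0
    n_stimuli: int = 2
    interval_ms: float = 50.0
    ppr: float | None = None
    depression_factor: float | None = None
    relative_amplitudes: list[float] | None = None
    slow_fraction: float = 0.0
    slow_tau_ms: float = 15.0
    sampling_khz: float = 10.0
    noise_sd_pa: float = 0.0
    baseline_ms: float = 100.0
    tail_ms: float = 200.0
    seed: int = 0

    def relative(self) -> np.ndarray:
        if self.relative_amplitudes is not None:
            rel = np.asarray(self.relative_amplitudes, dtype=float)
            if rel.size != self.n_stimuli:
                raise SceneConfigError("relative_amplitudes length must equal n_stimuli")
            return rel
        if self.ppr is not None:
            rel = np.ones(self.n_stimuli)
            if self.n_stimuli >= 2:
                rel[1] = self.ppr
            return rel
        if self.depression_factor is not None:
            return self.depression_factor ** np.arange(self.n_stimuli)
        return np.ones(self.n_stimuli)


def epsc_waveform(t_ms: np.ndarray, rise_ms: float, decay_ms: float) -> np.ndarray:
    """Unit-peak difference-of-exponentials kernel (0 before onset)."""
    if rise_ms <= 0 or decay_ms <= rise_ms:
        raise SceneConfigError("need 0 < rise < decay time constants")
    t = np.maximum(t_ms, 0.0)
    raw = np.exp(-t / decay_ms) - np.exp(-t / rise_ms)
    t_peak = rise_ms * decay_ms / (decay_ms - rise_ms) * np.log(decay_ms / rise_ms)
    peak = np.exp(-t_peak / decay_ms) - np.exp(-t_peak / rise_ms)
    out = raw / peak
    out[t_ms < 0] = 0.0
    return out


def make_epsc_trace(params: EPSCParams) -> EPSCTrace:
    """Synthesize an EPSC trace with stored ground truth."""
    p = params
    if p.sampling_khz <= 0:
        raise SceneConfigError("sampling rate must be positive")
    duration = p.baseline_ms + (p.n_stimuli - 1) * p.interval_ms + p.tail_ms
    n = int(round(duration * p.sampling_khz))
    t = np.arange(n) / p.sampling_khz
    stim_times = [p.baseline_ms + k * p.interval_ms for k in range(p.n_stimuli)]
    rel = p.relative()
    current = np.zeros(n)
    for k, t0 in enumerate(stim_times):
        current += p.amplitude_pa * rel[k] * epsc_waveform(t - t0, p.rise_ms, p.decay_ms)
    if p.slow_fraction != 0.0:
        dt0 = t - stim_times[0]
        slow = p.slow_fraction * p.amplitude_pa * (1.0 - np.exp(-np.maximum(dt0, 0) / p.slow_tau_ms))
        slow[dt0 < 0] = 0.0
        current += slow
    if p.noise_sd_pa > 0:
        rng = np.random.default_rng(p.seed)
        current += rng.normal(0.0, p.noise_sd_pa, size=n)
    truth = {
        "amplitude_pa": p.amplitude_pa,
        "rise_ms": p.rise_ms,
        "decay_ms": p.decay_ms,
        "relative_amplitudes": rel.tolist(),
        "ppr": float(rel[1] / rel[0]) if p.n_stimuli >= 2 else None,
        "slow_fraction": p.slow_fraction,
    }
    return EPSCTrace(current, p.sampling_khz, stim_times, ground_truth=truth)


# ---------------------------------------------------------------------------
# Fabricated long-range connectivity tables
# ---------------------------------------------------------------------------

def make_connectivity_tables(scene: Scene, strong: float = 0.30, weak: float = 0.05,
                             jitter_sd: float = 0.02):
    """Corticocortical and corticothalamic density tables with planted structure.

    These tables enter the circuit-graph stage preprocessed (in a real
    workflow they come from an atlas API, not from the image pipeline).
    Corticocortical density is ``strong`` between subregions sharing a
    planted subdivision signature and ``weak`` otherwise; corticothalamic
    density is ``strong`` from a subregion onto nuclei whose dominant
    planted thalamic zone maps to a subdivision the subregion innervates
    densely, ``weak`` elsewhere.  A small seeded jitter avoids exact ties.
    """
    cfg = scene.config
    rng = np.random.default_rng(cfg.seed + 1)
    names = scene.subregion_names
    group = {}
    for sub_id, sig in scene.truth.signatures.items():
        for n in sig:
            group[n] = sub_id
    cc = pd.DataFrame(weak, index=names, columns=names, dtype=float)
    for a in names:
        for b in names:
            if a != b and group[a] == group[b]:
                cc.loc[a, b] = strong
    cc += rng.normal(0.0, jitter_sd, size=cc.shape)
    cc = cc.clip(0.0, 1.0)
    np.fill_diagonal(cc.values, 0.0)

    nuclei = [scene.atlas.names[i] for i in scene.atlas.ids()]
    ct = pd.DataFrame(weak, index=nuclei, columns=names, dtype=float)
    for nid in scene.atlas.ids():
        in_nucleus = scene.atlas.mask_of(nid)
        zones = scene.truth.thalamic_zone_labels[in_nucleus]
        zones = zones[zones > 0]
        if zones.size == 0:
            continue
        dominant = int(np.bincount(zones).argmax())
        for n in scene.truth.signatures.get(dominant, ()):
            ct.loc[scene.atlas.names[nid], n] = strong
    ct += rng.normal(0.0, jitter_sd, size=ct.shape)
    ct = ct.clip(0.0, 1.0)
    return cc, ct


# ---------------------------------------------------------------------------
# Scene export
# ---------------------------------------------------------------------------

def write_scene(scene: Scene, out_dir) -> None:
    """Write all scene volumes (NIfTI), truth tables (CSV) and config (JSON)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    save_nifti(scene.striatum, out / "striatum.nii.gz")
    save_nifti(scene.striatum_ipsi, out / "striatum_ipsi.nii.gz")
    save_nifti(scene.landmark, out / "landmark.nii.gz")
    save_nifti(scene.thalamus, out / "thalamus.nii.gz")
    save_nifti(scene.atlas, out / "thalamic_atlas.nii.gz")
    for name, vol in scene.cortical_fields.items():
        save_nifti(vol, out / f"field_{name}.nii.gz")
    for inj in scene.thalamic_injections:
        save_nifti(inj.full, out / f"{inj.id}_full.nii.gz")
        save_nifti(inj.core, out / f"{inj.id}_core.nii.gz")
        save_nifti(inj.projection, out / f"{inj.id}_projection.nii.gz")
    coords = np.argwhere(scene.truth.subdivision_labels > 0)
    labels = scene.truth.subdivision_labels[tuple(coords.T)]
    pd.DataFrame(
        {"ap": coords[:, 0], "dv": coords[:, 1], "ml": coords[:, 2], "subdivision": labels}
    ).to_csv(out / "truth_subdivisions.csv", index=False)
    pd.DataFrame(
        [
            {"subdivision": d, "dense_subregions": ";".join(sig)}
            for d, sig in scene.truth.signatures.items()
        ]
    ).to_csv(out / "truth_signatures.csv", index=False)
    cfg = dataclasses.asdict(scene.config)
    if cfg["misalignment"] is not None and cfg["misalignment"]["per_section_shifts"] is not None:
        cfg["misalignment"]["per_section_shifts"] = np.asarray(
            cfg["misalignment"]["per_section_shifts"]
        ).tolist()
    (out / "scene_config.json").write_text(json.dumps(cfg, indent=2))
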