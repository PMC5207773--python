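"""Shared 3D volume types and morphology primitives.

All volumes in the pipeline live on coarse voxel grids (default 100 um
isotropic) with a fixed anatomical axis convention:

* axis 0 -- anterior -> posterior (coronal section index),
* axis 1 -- dorsal -> superior-to-inferior (D-V),
* axis 2 -- medial -> lateral across the midline (M-L).

Voxels are 0-indexed with centers at ``(i + 0.5) * voxel_size_um``.

:class:`ProjectionVolume` holds per-voxel fluorescence fractions in [0, 1]
(the fraction of fine imaging sub-voxels within a coarse voxel that contained
positive fluorescence); :class:`BinaryMask` holds anatomical or projection
masks; :class:`AtlasPartition` holds integer nucleus/subregion labels; and
:class:`Injection` bundles the full / eroded-core / striatal-projection masks
of one tracer injection.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Mapping

import numpy as np
import nibabel as nib
import tifffile
from scipy import ndimage

AXIS_ORDER = "AP:DV:ML"

#: Face-adjacency (6-connectivity) structuring element used as the default
#: for erosion and connected components on coarse voxel grids.
STRUCTURE_6 = ndimage.generate_binary_structure(3, 1)


class VolumeError(ValueError):
    """Raised on invalid volume parameters or incompatible grids."""


def _as_voxel_size(voxel_size_um) -> tuple[float, float, float]:
    vs = np.broadcast_to(np.asarray(voxel_size_um, dtype=float), (3,))
    if not np.all(np.isfinite(vs)) or np.any(vs <= 0):
        raise VolumeError(f"voxel_size_um must be positive and finite, got {voxel_size_um!r}")
    return (float(vs[0]), float(vs[1]), float(vs[2]))


@dataclasses.dataclass
class ProjectionVolume:
    """3D grid of per-voxel fluorescence fractions in [0, 1]."""

    values: np.ndarray
    voxel_size_um: tuple[float, float, float]
    axis_order: str = AXIS_ORDER
    origin_label: str = ""

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 3:
            raise VolumeError("ProjectionVolume values must be 3D")
        if np.any(self.values < 0) or np.any(self.values > 1):
            raise VolumeError("ProjectionVolume values must lie in [0, 1]")
        self.voxel_size_um = _as_voxel_size(self.voxel_size_um)

    @property
    def shape(self):
        return self.values.shape


@dataclasses.dataclass
class BinaryMask:
    """3D boolean mask on the shared grid convention."""

    values: np.ndarray
    voxel_size_um: tuple[float, float, float]
    axis_order: str = AXIS_ORDER

    def __post_init__(self):
        self.values = np.asarray(self.values).astype(bool)
        if self.values.ndim != 3:
            raise VolumeError("BinaryMask values must be 3D")
        self.voxel_size_um = _as_voxel_size(self.voxel_size_um)

    @property
    def shape(self):
        return self.values.shape

    def count(self) -> int:
        return int(self.values.sum())

    def with_values(self, values: np.ndarray) -> "BinaryMask":
        return BinaryMask(values, self.voxel_size_um, self.axis_order)


@dataclasses.dataclass
class AtlasPartition:
    """Integer-labeled partition (0 = background, k > 0 = nucleus id)."""

    labels: np.ndarray
    names: Mapping[int, str]
    voxel_size_um: tuple[float, float, float] = (100.0, 100.0, 100.0)

    def __post_init__(self):
        self.labels = np.asarray(self.labels)
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise VolumeError("AtlasPartition labels must be integers")
        self.voxel_size_um = _as_voxel_size(self.voxel_size_um)
        present = set(np.unique(self.labels).tolist()) - {0}
        named = set(int(k) for k in self.names)
        if present != named:
            raise VolumeError(
                f"atlas names table ({sorted(named)}) does not match labels present ({sorted(present)})"
            )

    def ids(self) -> list[int]:
        return sorted(int(k) for k in self.names)

    def mask_of(self, label: int) -> np.ndarray:
        return self.labels == label


@dataclasses.dataclass
class Injection:
    """One tracer injection: full volume, eroded core, striatal projection.

    ``projection`` is the binary striatal projection field with traveling
    (fasciculated) axons already excluded upstream.
    """

    id: str
    source: str  # {"thalamic", "cortical"}
    full: BinaryMask
    core: BinaryMask
    projection: BinaryMask

    def __post_init__(self):
        if self.source not in ("thalamic", "cortical"):
            raise VolumeError(f"unknown injection source {self.source!r}")
        if np.any(self.core.values & ~self.full.values):
            raise VolumeError(f"injection {self.id}: core is not a subset of full")


def _check_same_grid(a, b, what="operands"):
    if a.values.shape != b.values.shape:
        raise VolumeError(f"{what} have mismatched shapes {a.values.shape} vs {b.values.shape}")
    if not np.allclose(a.voxel_size_um, b.voxel_size_um):
        raise VolumeError(
            f"{what} have mismatched voxel sizes {a.voxel_size_um} vs {b.voxel_size_um}"
        )


# ---------------------------------------------------------------------------
# Morphology / coverage operations
# ---------------------------------------------------------------------------

def l1_ball(distance_um: float, voxel_size_um) -> np.ndarray:
    """Discrete unit-ball structuring element for a physical distance.

    An offset ``(i, j, k)`` belongs to the element iff its L1 distance in
    micrometres, ``|i|*vs0 + |j|*vs1 + |k|*vs2``, does not exceed
    ``distance_um``.  On an isotropic grid with ``distance = n * voxel`` this
    is exactly the n-fold dilation of the 6-connected cross, so eroding by
    d1 then d2 equals eroding by d1 + d2.
    """
    vs = _as_voxel_size(voxel_size_um)
    radii = [int(np.floor(distance_um / v + 1e-9)) for v in vs]
    grids = np.meshgrid(*[np.arange(-r, r + 1) for r in radii], indexing="ij")
    dist = sum(np.abs(g) * v for g, v in zip(grids, vs))
    return dist <= distance_um + 1e-9


def erode_mask(mask: BinaryMask, distance_um: float) -> BinaryMask:
    """Morphological erosion by a physical distance (default injection-core rule).

    The structuring element is the discrete L1 (6-connected) unit ball whose
    radius corresponds to ``distance_um`` at the mask's voxel size;
    anisotropic voxel sizes are honored per axis.  The result is always a
    subset of the input.
    """
    if distance_um < 0:
        raise VolumeError(f"erosion distance must be >= 0, got {distance_um}")
    elem = l1_ball(distance_um, mask.voxel_size_um)
    if elem.size == 1:
        return mask.with_values(mask.values.copy())
    eroded = ndimage.binary_erosion(mask.values, structure=elem, border_value=0)
    return mask.with_values(eroded)


def coverage_fraction(target: BinaryMask, probe: BinaryMask) -> float:
    """|target AND probe| / |target|.

    Raises :class:`VolumeError` for an empty target rather than silently
    returning 0, since downstream inclusion criteria divide by this count.
    """
    _check_same_grid(target, probe, "coverage_fraction operands")
    n_target = target.count()
    if n_target == 0:
        raise VolumeError("coverage_fraction is undefined for an empty target mask")
    return float(np.count_nonzero(target.values & probe.values)) / n_target


def subtract_mask(volume: ProjectionVolume, exclusion: BinaryMask) -> ProjectionVolume:
    """Zero the volume inside an exclusion mask (traveling-axon removal)."""
    if volume.values.shape != exclusion.values.shape:
        raise VolumeError(
            f"volume shape {volume.values.shape} != exclusion shape {exclusion.values.shape}"
        )
    out = volume.values.copy()
    out[exclusion.values] = 0.0
    return ProjectionVolume(out, volume.voxel_size_um, volume.axis_order, volume.origin_label)


def downsample_fraction(mask: BinaryMask, target_voxel_um: float) -> ProjectionVolume:
    """Bin a fine binary mask into coarse voxels holding the true-fraction.

    Each coarse voxel holds the fraction of its fine sub-voxels that are
    true, emulating the voxelization of segmented fluorescence images.  The
    binning factor must be an integer on every axis; ragged trailing edges
    are padded with false sub-voxels so that mass is conserved exactly:
    ``sum(coarse) * bin_voxel_count == count(true fine voxels)``.
    """
    factors = []
    for v in mask.voxel_size_um:
        f = target_voxel_um / v
        if abs(f - round(f)) > 1e-9 or round(f) < 1:
            raise VolumeError(
                f"target voxel {target_voxel_um} um is not an integer multiple of source voxel {v} um"
            )
        factors.append(int(round(f)))
    arr = mask.values
    pad = [(0, (-s) % f) for s, f in zip(arr.shape, factors)]
    arr = np.pad(arr, pad, mode="constant", constant_values=False)
    shape = []
    for s, f in zip(arr.shape, factors):
        shape.extend([s // f, f])
    coarse = arr.reshape(shape).astype(np.float64).mean(axis=(1, 3, 5))
    return ProjectionVolume(coarse, (target_voxel_um,) * 3, mask.axis_order)


def connected_components(mask: BinaryMask, connectivity: int = 6):
    """Label connected components (default face adjacency).

    Returns ``(AtlasPartition, count)``; labeling is deterministic
    (scipy's raster-scan order).
    """
    if connectivity == 6:
        structure = ndimage.generate_binary_structure(3, 1)
    elif connectivity == 18:
        structure = ndimage.generate_binary_structure(3, 2)
    elif connectivity == 26:
        structure = ndimage.generate_binary_structure(3, 3)
    else:
        raise VolumeError(f"connectivity must be one of 6, 18, 26; got {connectivity}")
    labels, count = ndimage.label(mask.values, structure=structure)
    names = {int(k): f"component_{int(k)}" for k in range(1, count + 1)}
    return AtlasPartition(labels, names, mask.voxel_size_um), int(count)


def dice(a: BinaryMask, b: BinaryMask) -> float:
    """Dice overlap coefficient of two masks (1.0 for two empty masks)."""
    _check_same_grid(a, b, "dice operands")
    na, nb = a.count(), b.count()
    if na + nb == 0:
        return 1.0
    return 2.0 * np.count_nonzero(a.values & b.values) / (na + nb)


# ---------------------------------------------------------------------------
# IO: NIfTI and TIFF-with-sidecar
# ---------------------------------------------------------------------------

def _nifti_affine(voxel_size_um):
    # store voxel size in mm in the header affine
    vs_mm = np.asarray(voxel_size_um, dtype=float) / 1000.0
    aff = np.diag(list(vs_mm) + [1.0])
    return aff


def save_nifti(obj, path) -> None:
    """Write a ProjectionVolume (float32), BinaryMask or AtlasPartition (uint8)."""
    path = Path(path)
    if isinstance(obj, ProjectionVolume):
        data = obj.values.astype(np.float32)
    elif isinstance(obj, BinaryMask):
        data = obj.values.astype(np.uint8)
    elif isinstance(obj, AtlasPartition):
        data = obj.labels.astype(np.uint8 if obj.labels.max(initial=0) < 256 else np.int32)
    else:
        raise VolumeError(f"cannot save object of type {type(obj).__name__} as NIfTI")
    img = nib.Nifti1Image(data, _nifti_affine(obj.voxel_size_um))
    nib.save(img, str(path))


def load_nifti(path, kind: str = "volume", names: Mapping[int, str] | None = None):
    """Load a NIfTI file as ``kind`` in {"volume", "mask", "atlas"}."""
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    vs_um = tuple(float(z) * 1000.0 for z in img.header.get_zooms()[:3])
    if kind == "volume":
        return ProjectionVolume(data.astype(np.float64), vs_um)
    if kind == "mask":
        return BinaryMask(data > 0, vs_um)
    if kind == "atlas":
        labels = data.astype(np.int32)
        if names is None:
            names = {int(k): f"region_{int(k)}" for k in np.unique(labels) if k != 0}
        return AtlasPartition(labels, names, vs_um)
    raise VolumeError(f"unknown kind {kind!r}")


def save_tiff(obj, path) -> None:
    """Write a multi-page TIFF stack (axis 0 = pages) plus a JSON sidecar."""
    path = Path(path)
    if isinstance(obj, ProjectionVolume):
        data = obj.values.astype(np.float32)
    elif isinstance(obj, BinaryMask):
        data = obj.values.astype(np.uint8)
    else:
        raise VolumeError(f"cannot save object of type {type(obj).__name__} as TIFF")
    tifffile.imwrite(str(path), data)
    sidecar = {
        "voxel_size_um": list(obj.voxel_size_um),
        "axis_order": obj.axis_order,
        "kind": "volume" if isinstance(obj, ProjectionVolume) else "mask",
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=2))


def load_tiff(path):
    """Load a TIFF stack written by :func:`save_tiff` (reads the sidecar)."""
    path = Path(path)
    sidecar = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    data = tifffile.imread(str(path))
    vs = tuple(sidecar["voxel_size_um"])
    if sidecar["kind"] == "mask":
        return BinaryMask(data > 0, vs, sidecar["axis_order"])
    return ProjectionVolume(data.astype(np.float64), vs, sidecar["axis_order"])
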