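"""Section-stack alignment by iterative center-of-mass registration.

Histological section stacks are misaligned by an aberrant sectioning angle
(roll about the A-P axis, pitch about the M-L axis, yaw about the D-V
axis), per-axis shrinkage/stretch, and independent integer in-plane jitter
of individual sections.  Alignment operates on binary striatum stacks kept
at fine in-plane resolution (sections are physically thick, but the
in-plane pixel size is much smaller than a section), which is what makes
degree-scale angles observable; the analysis stages downstream run on
coarser voxel grids.

The correction chain:

1. per-section jitter, template-free: the per-section center-of-mass curve
   of the underlying anatomy is smooth (linear under a small rotation), so
   the integer jitter is read off as the rounded residuals of a weighted
   linear fit (D-V from the whole-mask curve, M-L from the mean of the two
   per-hemisphere curves, which is immune to hemisphere-asymmetry
   artifacts at the A-P tips),
2. rotation: roll from the within-section row-wise M-L center-of-mass
   trend per hemisphere; yaw from the A-P trend of the per-hemisphere M-L
   centers of mass; pitch from the A-P trend of the whole-mask D-V center
   of mass.  Slicing a rotated ellipsoidal body moves slice centers along
   the conjugate diameter, which attenuates every such slope by
   (1 - sigma_b^2 / sigma_a^2) for the two axes involved; the raw slopes
   are divided by that moment-derived gain, and the estimate is iterated
   on linearly-resampled float volumes until the residual vanishes,
3. per-axis scales against the template: first from second-moment ratios
   (a normalization applied before angle estimation), then refined from
   the half-peak-area A-P span ratio and averaged anatomical distances,
4. per-section D-V / M-L shifts from center-of-mass differences with the
   template (M-L from the top half of the mask; anterior tip sections from
   the anterior-commissure surrogate landmark), iterated a fixed number of
   rounds.

Angles follow the right-handed convention of :func:`rotation_matrix`
applied in physical (micrometre) coordinates with axes (A-P, D-V, M-L).
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import ndimage

from .core_volumes import BinaryMask, ProjectionVolume, dice

# Sections whose mask area falls below this fraction of the peak section
# area are treated as unstable tip sections: they are excluded from trend
# fits and aligned on the anterior-commissure surrogate landmark when one
# is available.
ANTERIOR_AREA_FRACTION = 0.25


class AlignmentError(RuntimeError):
    """Raised when an estimation step lacks the geometry it needs."""


@dataclasses.dataclass
class SectionTransform:
    """Rigid + scale + per-section-jitter misalignment description."""

    roll_deg: float = 0.0
    pitch_deg: float = 0.0
    yaw_deg: float = 0.0
    scale_ap: float = 1.0
    scale_dv: float = 1.0
    scale_ml: float = 1.0
    #: integer (d_dv, d_ml) offsets per section, or None for no jitter
    per_section_shifts: np.ndarray | None = None

    def __post_init__(self):
        for s in (self.scale_ap, self.scale_dv, self.scale_ml):
            if not np.isfinite(s) or s <= 0:
                raise ValueError(f"scales must be positive, got {s}")
        for a in (self.roll_deg, self.pitch_deg, self.yaw_deg):
            if not np.isfinite(a):
                raise ValueError("angles must be finite")
        if self.per_section_shifts is not None:
            self.per_section_shifts = np.asarray(self.per_section_shifts, dtype=int)

    @property
    def scales(self) -> np.ndarray:
        return np.array([self.scale_ap, self.scale_dv, self.scale_ml])

    @property
    def angles_deg(self) -> np.ndarray:
        return np.array([self.roll_deg, self.pitch_deg, self.yaw_deg])

    def is_identity(self) -> bool:
        return (
            self.roll_deg == self.pitch_deg == self.yaw_deg == 0.0
            and np.allclose(self.scales, 1.0)
            and (self.per_section_shifts is None or not self.per_section_shifts.any())
        )


def rotation_matrix(roll_deg: float, pitch_deg: float, yaw_deg: float) -> np.ndarray:
    """Composite rotation R = R_roll @ R_pitch @ R_yaw on (AP, DV, ML) axes.

    roll rotates in the (D-V, M-L) section plane about A-P; pitch rotates
    in the (A-P, D-V) plane about M-L; yaw rotates in the (A-P, M-L) plane
    about D-V.
    """
    r, p, y = np.deg2rad([roll_deg, pitch_deg, yaw_deg])
    cr, sr = np.cos(r), np.sin(r)
    cp, sp = np.cos(p), np.sin(p)
    cy, sy = np.cos(y), np.sin(y)
    R_roll = np.array([[1, 0, 0], [0, cr, -sr], [0, sr, cr]])
    R_pitch = np.array([[cp, -sp, 0], [sp, cp, 0], [0, 0, 1]])
    R_yaw = np.array([[cy, 0, -sy], [0, 1, 0], [sy, 0, cy]])
    return R_roll @ R_pitch @ R_yaw


def sectioning_matrix(roll_deg: float, pitch_deg: float, yaw_deg: float) -> np.ndarray:
    """Misalignment matrix of a reconstructed section stack.

    A stack cut at an aberrant angle and restacked orthogonally carries the
    anatomy *sheared* along A-P, not rotated: each section is a rigid slab
    displaced in-plane in proportion to its A-P position (pitch shears D-V,
    yaw shears M-L).  A mounting-angle roll, by contrast, is a true
    in-plane rotation of every section.  The composite forward map is
    R_roll @ Shear(pitch, yaw) in physical (AP, DV, ML) coordinates.
    """
    r = np.deg2rad(roll_deg)
    cr, sr = np.cos(r), np.sin(r)
    R_roll = np.array([[1, 0, 0], [0, cr, -sr], [0, sr, cr]])
    shear = np.eye(3)
    shear[1, 0] = np.tan(np.deg2rad(pitch_deg))
    shear[2, 0] = np.tan(np.deg2rad(yaw_deg))
    return R_roll @ shear


def apply_affine(values: np.ndarray, matrix: np.ndarray, voxel_size_um, order: int) -> np.ndarray:
    """Resample under the forward map T(x) = M (x - c) + c about the grid center.

    ``matrix`` acts in physical coordinates; anisotropic voxel sizes are
    folded into the index-space matrix.  ``order=0`` gives
    nearest-neighbour resampling; higher orders interpolate.
    """
    vs = np.asarray(voxel_size_um, dtype=float)
    inv_phys = np.linalg.inv(matrix)
    A = np.diag(1.0 / vs) @ inv_phys @ np.diag(vs)  # index-space pullback
    center = (np.asarray(values.shape) - 1) / 2.0
    offset = center - A @ center
    return ndimage.affine_transform(
        values.astype(np.float64), A, offset=offset, order=order, mode="constant", cval=0.0
    )


def transform_mask(
    mask: BinaryMask,
    transform: SectionTransform,
    inverse: bool = False,
    interpolation: str = "linear",
) -> BinaryMask:
    """Apply (or undo) the rotation+scale part of a transform to a mask.

    The mask is resampled as a float volume and re-binarized at 0.5
    (``interpolation='nearest'`` switches to nearest-neighbour);
    per-section jitter is not applied here.
    """
    R = sectioning_matrix(transform.roll_deg, transform.pitch_deg, transform.yaw_deg)
    M = np.diag(transform.scales) @ R
    if inverse:
        M = np.linalg.inv(M)
    order = 0 if interpolation == "nearest" else 1
    out = apply_affine(mask.values.astype(np.float64), M, mask.voxel_size_um, order=order)
    return mask.with_values(out > 0.5)


def shift_sections(values: np.ndarray, shifts: np.ndarray) -> np.ndarray:
    """Shift each A-P section in-plane by integer (d_dv, d_ml) with zero fill."""
    out = np.zeros_like(values)
    n_dv, n_ml = values.shape[1], values.shape[2]
    for i, (ddv, dml) in enumerate(np.asarray(shifts, dtype=int)):
        src = values[i]
        dst = out[i]
        sd0, sd1 = max(ddv, 0), max(-ddv, 0)
        sm0, sm1 = max(dml, 0), max(-dml, 0)
        h = n_dv - abs(ddv)
        w = n_ml - abs(dml)
        if h > 0 and w > 0:
            dst[sd0 : sd0 + h, sm0 : sm0 + w] = src[sd1 : sd1 + h, sm1 : sm1 + w]
    return out


# ---------------------------------------------------------------------------
# Weighted center-of-mass machinery (works on float volumes)
# ---------------------------------------------------------------------------

def _wcom_table(values: np.ndarray) -> np.ndarray:
    """(index, dv_com, ml_com, mass) per section with nonzero mass."""
    v = values.astype(np.float64, copy=False)
    mass = v.sum(axis=(1, 2))
    dv_idx = np.arange(v.shape[1])
    ml_idx = np.arange(v.shape[2])
    rows = []
    for i in np.nonzero(mass > 1e-9)[0]:
        sec = v[i]
        m = mass[i]
        rows.append(
            (i, (sec.sum(axis=1) @ dv_idx) / m, (sec.sum(axis=0) @ ml_idx) / m, m)
        )
    return np.asarray(rows, dtype=float)


def _float_vars(values: np.ndarray) -> np.ndarray:
    idx = np.argwhere(values > 1e-9)
    if idx.shape[0] < 2:
        raise AlignmentError("volume too small for moment estimation")
    w = values[values > 1e-9]
    mean = np.average(idx, axis=0, weights=w)
    return np.average((idx - mean) ** 2, axis=0, weights=w)


def _weighted_slope(x, y, w):
    w = np.asarray(w, dtype=float)
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    xm = np.average(x, weights=w)
    ym = np.average(y, weights=w)
    denom = np.average((x - xm) ** 2, weights=w)
    if denom < 1e-12:
        raise AlignmentError("degenerate extent for slope estimation")
    return np.average((x - xm) * (y - ym), weights=w) / denom


def _weighted_fit(x, y, w):
    slope = _weighted_slope(x, y, w)
    intercept = np.average(y, weights=w) - slope * np.average(x, weights=w)
    return slope, intercept


def _keep_big(tab: np.ndarray) -> np.ndarray:
    return tab[tab[:, 3] >= ANTERIOR_AREA_FRACTION * tab[:, 3].max()]


def _rotation_components(values: np.ndarray, voxel_size_um) -> np.ndarray:
    """One-shot (roll, pitch, yaw) degrees from a float volume.

    Under the sectioning (shear) model, pitch and yaw displace each
    section rigidly in proportion to its A-P position, so the A-P trend of
    the per-section centers of mass recovers tan(angle) directly.  Roll is
    a true in-plane rotation; the within-section row-wise center-of-mass
    slope is attenuated by the conjugate-diameter factor
    (1 - sigma_ML^2 / sigma_DV^2) and divided by that moment-derived gain.
    """
    vs = np.asarray(voxel_size_um, dtype=float)
    mid = values.shape[2] // 2
    halves = (values[:, :, :mid], values[:, :, mid:])

    # yaw: per-hemisphere M-L center of mass vs A-P (shear: unit gain)
    slopes = []
    for h in halves:
        tab = _wcom_table(h)
        if tab.shape[0] < 3:
            raise AlignmentError("hemisphere present in fewer than 3 sections")
        t = _keep_big(tab)
        slopes.append(_weighted_slope(t[:, 0] * vs[0], t[:, 2] * vs[2], t[:, 3]))
    yaw = np.degrees(np.arctan(float(np.mean(slopes))))

    # pitch: whole-mask D-V center of mass vs A-P (shear: unit gain)
    tab = _wcom_table(values)
    t = _keep_big(tab)
    pitch = np.degrees(np.arctan(_weighted_slope(t[:, 0] * vs[0], t[:, 1] * vs[1], t[:, 3])))

    # roll: within-section row-wise M-L center of mass vs D-V, per hemisphere
    slopes, weights, gains = [], [], []
    ml_idx = np.arange(values.shape[2] - mid, dtype=float)  # max hemi width
    for h in halves:
        var = _float_vars(h)
        gains.append(1.0 - (var[2] * vs[2] ** 2) / (var[1] * vs[1] ** 2))
        tab = _wcom_table(h)
        good = set(_keep_big(tab)[:, 0].astype(int))
        cols = np.arange(h.shape[2], dtype=float)
        for i in good:
            sec = h[i]
            row_mass = sec.sum(axis=1)
            rows = np.nonzero(row_mass > 1e-9)[0]
            if rows.size < 3:
                continue
            mlc = (sec[rows] @ cols) / row_mass[rows]
            slopes.append(
                _weighted_slope(rows * vs[1], mlc * vs[2], row_mass[rows])
            )
            weights.append(row_mass[rows].sum())
    gain_roll = float(np.mean(gains))
    if gain_roll <= 0.05 or not slopes:
        raise AlignmentError("mask too isotropic in D-V/M-L for roll estimation")
    roll = np.degrees(np.arctan(float(np.average(slopes, weights=weights)) / gain_roll))
    return np.array([roll, pitch, yaw])


def _iterate_rotation(
    values: np.ndarray, voxel_size_um, n_passes: int = 3, tol_deg: float = 0.05
) -> np.ndarray:
    """Accumulate rotation estimates over linearly-resampled float volumes."""
    est = np.zeros(3)
    vals0 = values.astype(np.float64)
    for k in range(max(1, n_passes)):
        if k == 0:
            work = vals0
        else:
            R = sectioning_matrix(*est)
            work = apply_affine(vals0, np.linalg.inv(R), voxel_size_um, order=1)
        resid = _rotation_components(work, voxel_size_um)
        est += resid
        if np.abs(resid).max() < tol_deg:
            break
    return est


# ---------------------------------------------------------------------------
# Jitter
# ---------------------------------------------------------------------------

def _lattice_fit(x: np.ndarray, y: np.ndarray, w: np.ndarray, slope_bound: float,
                 n_grid: int = 401):
    """Fit y ~ a + s*x + integer jitter by exploiting the integer lattice.

    An ordinary least-squares fit confounds a linear trend with integer
    jitter (part of the trend leaks into the rounded residuals).  Here the
    slope is chosen to minimize the weighted squared distance of the
    residuals to the *integer lattice*: for the true slope the residuals
    are integers plus center-of-mass noise, for a wrong slope their
    fractional parts drift systematically.  The fractional offset for a
    candidate slope has a closed form via the circular mean of
    exp(2*pi*i*(y - s*x)).  Returns ``(slope, offset, integer jitter)``.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    w = np.asarray(w, float)
    w = w / w.sum()

    def score(s):
        r = y - s * x
        z = np.sum(w * np.exp(2j * np.pi * r))
        a = np.angle(z) / (2 * np.pi)
        d = r - a
        frac = d - np.round(d)
        return float(np.sum(w * frac**2)), a

    grid = np.linspace(-slope_bound, slope_bound, n_grid)
    scores = [score(s)[0] for s in grid]
    k = int(np.argmin(scores))
    lo = grid[max(k - 1, 0)]
    hi = grid[min(k + 1, n_grid - 1)]
    fine = np.linspace(lo, hi, 101)
    fscores = [score(s)[0] for s in fine]
    s_best = float(fine[int(np.argmin(fscores))])
    _, a_best = score(s_best)
    resid = y - s_best * x - a_best
    j = np.round(resid).astype(int)
    # the circular offset is defined only mod 1: fold the integer part of
    # the baseline into the offset, keeping jitter centered on zero
    baseline = int(np.round(np.average(j, weights=w)))
    return s_best, a_best + baseline, j - baseline


def estimate_section_jitter(stack: BinaryMask, max_angle_deg: float = 8.0) -> np.ndarray:
    """Template-free recovery of integer per-section (D-V, M-L) jitter.

    The per-section center-of-mass curve of the anatomy is linear under
    the sectioning (shear) model, while mounting jitter shifts whole
    sections by integer voxels; slope and jitter are separated with the
    integer-lattice fit of :func:`_lattice_fit` (searching slopes up to
    ``max_angle_deg`` of sectioning angle).  The D-V curve uses the whole
    mask; the M-L curve uses the mean of the two per-hemisphere centers of
    mass (the bilateral-union M-L center is distorted where one hemisphere
    ends before the other).  Tip sections below the area threshold keep
    jitter 0 (they are aligned later by the landmark stage).
    """
    jitter = np.zeros((stack.shape[0], 2), dtype=int)
    mid = stack.shape[2] // 2
    vs = stack.voxel_size_um
    vals = stack.values.astype(np.float64)
    tab = _wcom_table(vals)
    if tab.shape[0] < 4:
        return jitter
    t = _keep_big(tab)
    # slope bound: sectioning angle plus scale distortion, hard-capped below
    # 0.5 voxel/section — slopes an integer apart are aliases on the lattice
    bound_dv = min(0.49, 1.5 * np.tan(np.radians(max_angle_deg)) * vs[0] / vs[1])
    s, a, j = _lattice_fit(t[:, 0], t[:, 1], t[:, 3], bound_dv)
    jitter[t[:, 0].astype(int), 0] = j

    left = {int(r[0]): r for r in _wcom_table(vals[:, :, :mid])}
    right = {int(r[0]): r for r in _wcom_table(vals[:, :, mid:])}
    common = np.asarray([i for i in t[:, 0].astype(int) if i in left and i in right])
    if common.size >= 4:
        ml = np.array([(left[i][2] + right[i][2]) / 2.0 for i in common])
        w = np.array([left[i][3] + right[i][3] for i in common])
        bound_ml = min(0.49, 1.5 * np.tan(np.radians(max_angle_deg)) * vs[0] / vs[2])
        s, a, j = _lattice_fit(common.astype(float), ml, w, bound_ml)
        jitter[common, 1] = j
    return jitter


def dejitter(stack: BinaryMask, jitter: np.ndarray | None = None):
    """Remove estimated integer per-section jitter; returns (stack, jitter)."""
    if jitter is None:
        jitter = estimate_section_jitter(stack)
    return stack.with_values(shift_sections(stack.values, -jitter)), jitter


# ---------------------------------------------------------------------------
# Rotation estimation (public API)
# ---------------------------------------------------------------------------

def find_midline_points(stack: BinaryMask):
    """Per-section midline point pairs (a stand-in for manual selection).

    For each section containing both hemispheres, the midline is sampled at
    two D-V levels: the midpoint between the hemisphere centers of mass in
    the dorsal half of the section and in the ventral half.  Returns a dict
    section_index -> ((dv, ml) top, (dv, ml) bottom).
    """
    mid = stack.shape[2] // 2
    points = {}
    for i in range(stack.shape[0]):
        sec = stack.values[i]
        rows = np.nonzero(sec.any(axis=1))[0]
        if rows.size < 4:
            continue
        dv_split = (rows[0] + rows[-1] + 1) // 2
        pair = []
        for offset, half in ((0, sec[:dv_split]), (dv_split, sec[dv_split:])):
            idx_l = np.nonzero(half[:, :mid])
            idx_r = np.nonzero(half[:, mid:])
            if idx_l[0].size == 0 or idx_r[0].size == 0:
                pair = None
                break
            dv = (idx_l[0].mean() + idx_r[0].mean()) / 2.0 + offset
            ml = (idx_l[1].mean() + idx_r[1].mean() + mid) / 2.0
            pair.append((dv, ml))
        if pair is not None:
            points[i] = (tuple(pair[0]), tuple(pair[1]))
    return points


def estimate_roll(stack: BinaryMask, midpoints=None) -> float:
    """Roll angle (degrees) that verticalizes the midline.

    With explicit ``midpoints`` (section -> ((dv, ml), (dv, ml)) pairs),
    the angle of each midline segment from vertical is averaged directly.
    Otherwise the stack is de-jittered and the roll comes from the
    iterative within-section center-of-mass trend estimator.
    """
    if midpoints is not None:
        if len(midpoints) == 0:
            raise AlignmentError("no midline point pairs supplied")
        vs = stack.voxel_size_um
        angles = []
        for (top, bot) in midpoints.values():
            d_dv = (bot[0] - top[0]) * vs[1]
            d_ml = (bot[1] - top[1]) * vs[2]
            if abs(d_dv) < 1e-9 and abs(d_ml) < 1e-9:
                raise AlignmentError("degenerate (coincident) midline points")
            angles.append(np.degrees(np.arctan2(-d_ml, d_dv)) + 180.0)
        ang = float(np.mean([((a + 90) % 180) - 90 for a in angles]))
        return ang
    work, _ = dejitter(stack)
    return float(_iterate_rotation(work.values, stack.voxel_size_um)[0])


def estimate_pitch_yaw(stack: BinaryMask) -> tuple[float, float]:
    """(pitch, yaw) in degrees from A-P center-of-mass trends.

    The stack is de-jittered internally; the trends are gain-corrected for
    the conjugate-diameter attenuation and iterated on resampled float
    volumes (see module docstring).  Requires both hemispheres present in
    at least 3 sections.
    """
    mid = stack.shape[2] // 2
    n_bilateral = sum(
        1
        for i in range(stack.shape[0])
        if stack.values[i, :, :mid].any() and stack.values[i, :, mid:].any()
    )
    if n_bilateral < 3:
        raise AlignmentError("need both hemispheres present in >= 3 sections")
    work, _ = dejitter(stack)
    est = _iterate_rotation(work.values, stack.voxel_size_um)
    return float(est[1]), float(est[2])


# ---------------------------------------------------------------------------
# Scaling against the template
# ---------------------------------------------------------------------------

def moment_scales(stack: BinaryMask, template: BinaryMask) -> np.ndarray:
    """Per-axis scale of stack relative to template from second-moment ratios.

    Rotation affects per-axis variances only at second order in the angle,
    so this is a robust normalization before angle estimation.
    """
    vs = _float_vars(stack.values.astype(np.float64))
    vt = _float_vars(template.values.astype(np.float64))
    return np.sqrt(vs / vt)


def _half_area_span(stack_values: np.ndarray) -> float:
    """A-P span between the interpolated half-peak crossings of the area profile.

    The crossings of the per-section mask area through half its peak are
    steep, reproducible landmark positions (a sub-section surrogate for
    first/last anatomical landmark sections).
    """
    area = stack_values.reshape(stack_values.shape[0], -1).sum(axis=1).astype(float)
    if area.max() <= 0:
        raise AlignmentError("empty stack has no A-P span")
    half = area.max() / 2.0
    above = np.nonzero(area >= half)[0]
    first, last = above[0], above[-1]
    lo = float(first)
    if first > 0:
        lo = first - (area[first] - half) / (area[first] - area[first - 1])
    hi = float(last)
    if last < area.size - 1:
        hi = last + (area[last] - half) / (area[last] - area[last + 1])
    return hi - lo


def _dv_and_ml_distances(stack_values: np.ndarray):
    """Averaged per-section anatomical distances for D-V / M-L scaling.

    D-V: distance from the top (dorsal border) of the mask to its D-V
    center of mass.  M-L: average width of the dorsal mask, i.e. of rows
    above the D-V center of mass.  Averaged over sections with at least
    half-peak area.
    """
    area = stack_values.reshape(stack_values.shape[0], -1).sum(axis=1)
    if area.max() <= 0:
        raise AlignmentError("empty stack")
    keep = area >= area.max() / 2.0
    dv_d, ml_d = [], []
    for i in np.nonzero(keep)[0]:
        sec = stack_values[i]
        rows = np.nonzero(sec.any(axis=1))[0]
        dv_com = np.nonzero(sec)[0].mean()
        dv_d.append(dv_com - rows[0])
        top = sec[: int(np.ceil(dv_com))]
        widths = top.sum(axis=1)
        widths = widths[widths > 0]
        if widths.size:
            ml_d.append(widths.mean())
    if not dv_d or not ml_d:
        raise AlignmentError("missing landmarks for D-V / M-L scaling")
    return float(np.mean(dv_d)), float(np.mean(ml_d))


def estimate_scales(stack: BinaryMask, template: BinaryMask) -> tuple[float, float, float]:
    """Per-axis scale factors of stack relative to template (>1 = stretched).

    A-P from the half-peak-area span ratio; D-V and M-L from averaged
    anatomical distances (top-of-striatum to center of mass, and dorsal
    width, respectively).
    """
    ap = _half_area_span(stack.values) / _half_area_span(template.values)
    dv_s, ml_s = _dv_and_ml_distances(stack.values)
    dv_t, ml_t = _dv_and_ml_distances(template.values)
    return float(ap), float(dv_s / dv_t), float(ml_s / ml_t)


def scale_to_template(stack: BinaryMask, template: BinaryMask, landmarks=None):
    """Rescale a (rotation-corrected) stack onto the template's scale.

    Returns ``(scaled stack, (scale_ap, scale_dv, scale_ml))`` where the
    scales describe the input stack relative to the template.
    ``landmarks`` may pre-specify the scales; by default they are estimated
    with :func:`estimate_scales`.
    """
    scales = tuple(landmarks) if landmarks is not None else estimate_scales(stack, template)
    t = SectionTransform(scale_ap=scales[0], scale_dv=scales[1], scale_ml=scales[2])
    scaled = transform_mask(stack, t, inverse=True, interpolation="linear")
    return scaled, scales


# ---------------------------------------------------------------------------
# Iterative per-section alignment
# ---------------------------------------------------------------------------

def _section_com(section: np.ndarray):
    idx = np.nonzero(section)
    if idx[0].size == 0:
        return None
    return float(idx[0].mean()), float(idx[1].mean())


def _top_half_ml_com(sec: np.ndarray):
    rows = np.nonzero(sec.any(axis=1))[0]
    if rows.size == 0:
        return None
    median_row = int(np.median(np.nonzero(sec)[0]))
    top = sec[:median_row] if median_row > rows[0] else sec[: rows[0] + 1]
    cols = np.nonzero(top)[1]
    if cols.size == 0:
        cols = np.nonzero(sec)[1]
    return float(cols.mean())


def _section_shift(sec, tmp_sec, use_landmark, lm_sec, tmp_lm_sec):
    if use_landmark:
        cs, ct = _section_com(lm_sec), _section_com(tmp_lm_sec)
        if cs is None or ct is None:
            return None
        return ct[0] - cs[0], ct[1] - cs[1]
    cs, ct = _section_com(sec), _section_com(tmp_sec)
    if cs is None or ct is None:
        return None
    d_dv = ct[0] - cs[0]
    ms, mt = _top_half_ml_com(sec), _top_half_ml_com(tmp_sec)
    d_ml = mt - ms if (ms is not None and mt is not None) else ct[1] - cs[1]
    return d_dv, d_ml


def iterative_com_align(
    stack: BinaryMask,
    template: BinaryMask,
    n_rounds: int = 2,
    landmark: BinaryMask | None = None,
    template_landmark: BinaryMask | None = None,
):
    """Per-section D-V / M-L alignment to the template by center of mass.

    Each round computes a (d_dv, d_ml) shift per section: D-V from the
    center-of-mass difference with the template section, M-L from the
    center of mass of the top half of the mask (rows above the per-section
    D-V median row).  Anterior tip sections, where the striatum outline is
    small and variable, use the anterior-commissure surrogate landmark when
    one is supplied.  Shifts for sections empty in the stack but not the
    template are interpolated from flanking sections.  Rounds that would
    decrease the whole-stack Dice against the template are discarded, so
    Dice is nondecreasing in the number of rounds.

    Returns ``(aligned stack, cumulative per-section integer shifts)``.
    """
    if stack.shape != template.shape:
        raise AlignmentError("stack and template must share a grid after scaling")
    n_sec = stack.shape[0]
    tmp_area = template.values.reshape(n_sec, -1).sum(axis=1)
    anterior = tmp_area < ANTERIOR_AREA_FRACTION * max(tmp_area.max(), 1)
    current = stack.values.copy()
    lm_values = landmark.values if landmark is not None else None
    total = np.zeros((n_sec, 2), dtype=int)
    best_dice = dice(stack.with_values(current), template)
    for _ in range(n_rounds):
        shifts = np.full((n_sec, 2), np.nan)
        for i in range(n_sec):
            use_lm = (
                anterior[i]
                and lm_values is not None
                and template_landmark is not None
                and lm_values[i].any()
                and template_landmark.values[i].any()
            )
            if not current[i].any() and not use_lm:
                if tmp_area[i] == 0:
                    shifts[i] = (0.0, 0.0)
                continue  # interpolated below
            s = _section_shift(
                current[i],
                template.values[i],
                use_lm,
                lm_values[i] if lm_values is not None else None,
                template_landmark.values[i] if template_landmark is not None else None,
            )
            if s is not None:
                shifts[i] = s
        missing = np.nonzero(np.isnan(shifts[:, 0]))[0]
        known = np.nonzero(~np.isnan(shifts[:, 0]))[0]
        if known.size == 0:
            raise AlignmentError("no section yielded an alignment shift")
        for i in missing:
            before = known[known < i]
            after = known[known > i]
            if before.size and after.size:
                b, a = before[-1], after[0]
                frac = (i - b) / (a - b)
                shifts[i] = shifts[b] * (1 - frac) + shifts[a] * frac
            elif before.size or after.size:
                shifts[i] = shifts[before[-1] if before.size else after[0]]
            else:
                raise AlignmentError(f"empty section {i} has no flanking sections with shifts")
        step = np.round(shifts).astype(int)
        candidate = shift_sections(current, step)
        d = dice(stack.with_values(candidate), template)
        if d < best_dice:
            break
        best_dice = d
        current = candidate
        total += step
        if lm_values is not None:
            lm_values = shift_sections(lm_values, step)
    return stack.with_values(current), total


def repair_damaged_section(stack, section_index: int):
    """Replace a damaged section with the voxelwise mean of its neighbours.

    Masks are re-binarized at a strict > 0.5 threshold (the mean of a
    present and an absent neighbour does not survive).  Works on
    :class:`BinaryMask` and :class:`ProjectionVolume` stacks.
    """
    n = stack.values.shape[0]
    if section_index <= 0 or section_index >= n - 1:
        raise AlignmentError("cannot repair a boundary section (no flanking sections)")
    mean = (
        stack.values[section_index - 1].astype(np.float64)
        + stack.values[section_index + 1].astype(np.float64)
    ) / 2.0
    out = stack.values.copy()
    if isinstance(stack, BinaryMask):
        out[section_index] = mean > 0.5
        return stack.with_values(out)
    out = out.astype(np.float64)
    out[section_index] = mean
    return ProjectionVolume(out, stack.voxel_size_um, stack.axis_order, stack.origin_label)


def align_stack(
    stack: BinaryMask,
    template: BinaryMask,
    landmark: BinaryMask | None = None,
    template_landmark: BinaryMask | None = None,
    n_rounds: int = 2,
):
    """Full correction chain: de-jitter -> scales -> rotation -> shifts.

    The per-section jitter is removed first (template-free integer
    recovery), the stack is pre-normalized to the template's scale via
    second-moment ratios, the rotation is estimated iteratively on the
    normalized stack, the landmark-based scale estimate refines the
    moment-based one, the combined scale+rotation correction is applied to
    the de-jittered stack in a single resampling, and the final
    per-section shifts come from iterative center-of-mass alignment.

    Returns ``(aligned stack, estimated SectionTransform)``; the transform
    records the estimated misalignment (the applied correction is its
    inverse), with ``per_section_shifts`` holding the recovered jitter.
    """
    dejit, jitter = dejitter(stack)
    # alternate scale normalization and rotation estimation: the first
    # moment-scale estimate is slightly contaminated by the shear and
    # jitter, which biases the roll through the residual in-plane
    # anisotropy; one refinement on the rotation-corrected stack removes it
    s0 = moment_scales(dejit, template)
    for _ in range(2):
        pre = SectionTransform(scale_ap=s0[0], scale_dv=s0[1], scale_ml=s0[2])
        normalized = transform_mask(dejit, pre, inverse=True)
        angles = _iterate_rotation(normalized.values, stack.voxel_size_um)
        rot = SectionTransform(roll_deg=angles[0], pitch_deg=angles[1], yaw_deg=angles[2])
        rot_corrected = transform_mask(normalized, rot, inverse=True)
        s0 = s0 * moment_scales(rot_corrected, template)

    refine = np.asarray(estimate_scales(rot_corrected, template))
    total_scales = s0 * refine
    est = SectionTransform(
        roll_deg=angles[0],
        pitch_deg=angles[1],
        yaw_deg=angles[2],
        scale_ap=total_scales[0],
        scale_dv=total_scales[1],
        scale_ml=total_scales[2],
    )
    corrected = transform_mask(dejit, est, inverse=True)
    lm_corr = None
    if landmark is not None:
        lm_dejit = landmark.with_values(shift_sections(landmark.values, -jitter))
        lm_corr = transform_mask(lm_dejit, est, inverse=True)
    aligned, com_shifts = iterative_com_align(
        corrected,
        template,
        n_rounds=n_rounds,
        landmark=lm_corr,
        template_landmark=template_landmark,
    )
    est.per_section_shifts = jitter - com_shifts
    return aligned, est
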