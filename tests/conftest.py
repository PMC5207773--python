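"""Shared fixtures: small synthetic scenes and independent oracles."""

from __future__ import annotations

import numpy as np
import pytest

import striomap as sm

VS = (100.0, 100.0, 100.0)

#: compact scene used by suites that loop over many seeds
SMALL_GRID = (30, 26, 36)


@pytest.fixture(scope="session")
def small_scene():
    return sm.make_scene(sm.SceneConfig(seed=0, grid_shape=SMALL_GRID))


@pytest.fixture(scope="session")
def small_classmaps(small_scene):
    return {
        name: sm.classify_density(vol, small_scene.striatum_ipsi)
        for name, vol in small_scene.cortical_fields.items()
    }


def mask(values) -> sm.BinaryMask:
    return sm.BinaryMask(np.asarray(values, dtype=bool), VS)


def random_mask(rng, shape=(8, 8, 8), p=0.4) -> sm.BinaryMask:
    return mask(rng.random(shape) < p)


def sphere_mask(shape, center, radius) -> sm.BinaryMask:
    g = np.ogrid[tuple(slice(0, s) for s in shape)]
    return mask(sum((gg - c) ** 2 for gg, c in zip(g, center)) <= radius**2)


# ---------------------------------------------------------------------------
# Independent oracles
# ---------------------------------------------------------------------------

def flood_fill_components(values: np.ndarray) -> int:
    """BFS flood fill under 6-connectivity, independent of scipy labeling."""
    values = np.asarray(values, dtype=bool)
    seen = np.zeros_like(values)
    count = 0
    for start in np.argwhere(values):
        start = tuple(start)
        if seen[start]:
            continue
        count += 1
        queue = [start]
        seen[start] = True
        while queue:
            x, y, z = queue.pop()
            for dx, dy, dz in ((1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)):
                n = (x + dx, y + dy, z + dz)
                if all(0 <= n[i] < values.shape[i] for i in range(3)):
                    if values[n] and not seen[n]:
                        seen[n] = True
                        queue.append(n)
    return count


def naive_average_linkage(D: np.ndarray) -> np.ndarray:
    """Set-based O(n^3) average-linkage agglomeration with lowest-id tie break.

    Recomputes every cluster-pair distance as the mean over all member
    pairs at each step — no Lance-Williams update — so it is an
    independent check of the production implementation.
    """
    D = np.asarray(D, dtype=float)
    n = D.shape[0]
    clusters = {i: [i] for i in range(n)}
    Z = np.zeros((n - 1, 4))
    next_id = n
    for step in range(n - 1):
        best = None
        for a in sorted(clusters):
            for b in sorted(clusters):
                if a >= b:
                    continue
                d = np.mean([D[i, j] for i in clusters[a] for j in clusters[b]])
                if best is None or d < best[0] - 1e-15 or (
                    abs(d - best[0]) <= 1e-15 and (a, b) < (best[1], best[2])
                ):
                    best = (d, a, b)
        d, a, b = best
        Z[step] = (a, b, d, len(clusters[a]) + len(clusters[b]))
        clusters[next_id] = clusters.pop(a) + clusters.pop(b)
        next_id += 1
    return Z


def confidence_oracle(injections, results, criteria, thalamus) -> np.ndarray:
    """Per-voxel re-evaluation of the confidence rule, union semantics.

    Walks every voxel and criterion independently of the vectorized
    accumulation in the package.
    """
    from striomap.confidence_maps import N_FULL_SUBTRACT, rank_by_easiness

    sat = results.to_numpy(dtype=bool)
    easiest = set(rank_by_easiness(results)[:N_FULL_SUBTRACT])
    shape = thalamus.values.shape
    out = np.zeros(shape, dtype=np.int64)
    for idx in np.ndindex(shape):
        v = 0
        for j in range(len(criteria)):
            in_sat_full = any(sat[i, j] and inj.full.values[idx] for i, inj in enumerate(injections))
            in_sat_core = any(sat[i, j] and inj.core.values[idx] for i, inj in enumerate(injections))
            in_fail_full = any(
                (not sat[i, j]) and inj.full.values[idx] for i, inj in enumerate(injections)
            )
            in_fail_core = any(
                (not sat[i, j]) and inj.core.values[idx] for i, inj in enumerate(injections)
            )
            v += int(in_sat_full) + int(in_sat_core) - int(in_fail_core)
            if j in easiest:
                v -= int(in_fail_full)
        for i, inj in enumerate(injections):
            if not sat[i].any() and inj.core.values[idx]:
                v = 0
        out[idx] = max(v, 0) if thalamus.values[idx] else 0
    return out


def random_injection_scene(rng, shape=(10, 10, 10), n_inj=5):
    """Tiny random thalamus / target / injections for confidence-map tests."""
    thal = np.zeros(shape, dtype=bool)
    thal[1:-1, 1:-1, 1:-1] = True
    target = np.zeros(shape, dtype=bool)
    target[tuple(rng.integers(0, shape[0], (30, 3)).T)] = True
    if not target.any():
        target[0, 0, 0] = True
    injections = []
    for k in range(n_inj):
        c = rng.integers(2, shape[0] - 2, 3)
        r = int(rng.integers(2, 4))
        full = sphere_mask(shape, c, r)
        core = sm.erode_mask(full, 100)
        proj = np.zeros(shape, dtype=bool)
        npts = int(rng.integers(0, 50))
        if npts:
            proj[tuple(rng.integers(0, shape[0], (npts, 3)).T)] = True
        injections.append(sm.Injection(f"inj_{k}", "thalamic", full, core, mask(proj)))
    return sm.BinaryMask(thal, VS), mask(target), injections


def coarse_truth_labels(scene, features) -> np.ndarray:
    """Plurality-vote ground-truth subdivision label per clustering voxel."""
    fine_idx = np.argwhere(scene.striatum_ipsi.values)
    vs = scene.striatum_ipsi.voxel_size_um[0]
    coarse_idx = np.floor(fine_idx * vs / features.voxel_um + 1e-9).astype(int)
    groups: dict[tuple, list] = {}
    for f, c in zip(fine_idx, coarse_idx):
        groups.setdefault(tuple(c), []).append(scene.truth.subdivision_labels[tuple(f)])
    return np.array([np.bincount(groups[tuple(c)]).argmax() for c in features.coords])
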