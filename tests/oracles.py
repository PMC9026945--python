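"""Independent brute-force oracles used by the test suite.

Deliberately avoids scipy.ndimage (which the implementation uses):
dilation is done with explicit numpy slice-shifts and the per-threshold
region is recomputed from scratch as the connected component of the
supra-threshold set containing the seed.
"""

from __future__ import annotations

import itertools

import numpy as np


def neighbor_offsets(connectivity: int):
    offs = []
    for off in itertools.product((-1, 0, 1), repeat=3):
        dist = sum(abs(o) for o in off)
        if dist == 0:
            continue
        if connectivity == 6 and dist > 1:
            continue
        if connectivity == 18 and dist > 2:
            continue
        offs.append(off)
    return offs


def _shift(mask: np.ndarray, off) -> np.ndarray:
    """Shift a boolean mask by an integer offset, zero-filling the border."""
    out = np.zeros_like(mask)
    src = []
    dst = []
    for o, n in zip(off, mask.shape):
        if o >= 0:
            src.append(slice(0, n - o))
            dst.append(slice(o, n))
        else:
            src.append(slice(-o, n))
            dst.append(slice(0, n + o))
    out[tuple(dst)] = mask[tuple(src)]
    return out


def dilate(mask: np.ndarray, connectivity: int) -> np.ndarray:
    out = mask.copy()
    for off in neighbor_offsets(connectivity):
        out |= _shift(mask, off)
    return out


def flood_from_seed(allowed: np.ndarray, seed, connectivity: int) -> np.ndarray:
    """Connected component of ``allowed`` containing ``seed`` (seed always kept)."""
    region = np.zeros_like(allowed)
    region[seed] = True
    while True:
        grown = region | (dilate(region, connectivity) & allowed)
        if np.array_equal(grown, region):
            return region
        region = grown


def window_max(data: np.ndarray, center, radius: int) -> float:
    """Exhaustive scan of the clipped window for the maximum value."""
    best = -np.inf
    for off in itertools.product(range(-radius, radius + 1), repeat=3):
        idx = tuple(c + o for c, o in zip(center, off))
        if all(0 <= v < n for v, n in zip(idx, data.shape)):
            best = max(best, data[idx])
    return float(best)


def window_argmax(data: np.ndarray, center, radius: int):
    """Exhaustive scan: lexicographically-lowest voxel attaining the window max."""
    best_val = -np.inf
    best_idx = None
    lo = [max(0, c - radius) for c in center]
    hi = [min(n, c + radius + 1) for c, n in zip(center, data.shape)]
    for idx in itertools.product(*[range(a, b) for a, b in zip(lo, hi)]):
        val = data[idx]
        if val > best_val:
            best_val = val
            best_idx = idx
    return best_idx


def grow_oracle(
    data: np.ndarray,
    seed,
    *,
    window_radius: int = 3,
    connectivity: int = 26,
    threshold_step: float = 1.0,
    doubling_factor: float = 2.0,
    doubling_min_size: int = 10,
    threshold_floor=None,
):
    """Per-threshold flood-fill reference for the region grower.

    For each threshold in the decrement sequence the region is rebuilt
    from scratch as the seed's connected component of ``{v > t}`` (with
    the seed itself always included), then the same three stop rules are
    applied. Returns ``(mask, stop_reason, counts)``.
    """
    data = np.asarray(data, dtype=float)
    t0 = window_max(data, seed, window_radius)
    floor = float(data.min()) if threshold_floor is None else float(threshold_floor)
    tol = 1e-9 * max(1.0, abs(t0), abs(floor))

    region = np.zeros(data.shape, dtype=bool)
    region[seed] = True
    prev_count = 1
    counts = []
    k = 0
    while True:
        t = t0 - k * threshold_step
        if t < floor - tol:
            return region, "floor_reached", counts
        new_region = flood_from_seed(data > t, seed, connectivity)
        new_count = int(new_region.sum())
        counts.append(new_count)
        if prev_count >= doubling_min_size and new_count > doubling_factor * prev_count:
            return region, "volume_doubled", counts
        region = new_region
        if new_count == prev_count:
            frontier = dilate(region, connectivity) & ~region
            if not np.any(data[frontier] > floor):
                return region, "no_new_voxels", counts
        prev_count = new_count
        k += 1
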