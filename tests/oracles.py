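"""Independent brute-force reference implementations used only by tests.

These are deliberately written as naive loops / enumerations, sharing no
code with the package, so they can serve as oracles for the vectorised
implementations.
"""

from __future__ import annotations

import numpy as np


def naive_curl(u: np.ndarray, v: np.ndarray, w: np.ndarray,
               spacing: tuple[float, float, float]) -> tuple[np.ndarray, ...]:
    """Triple-loop curl with central interior / one-sided boundary stencils."""
    nx, ny, nz = u.shape
    hx, hy, hz = spacing

    def d(f, i, j, k, axis):
        idx = [i, j, k]
        n = f.shape[axis]
        h = (hx, hy, hz)[axis]
        if idx[axis] == 0:
            lo, hi, denom = 0, 1, h
        elif idx[axis] == n - 1:
            lo, hi, denom = n - 2, n - 1, h
        else:
            lo, hi, denom = idx[axis] - 1, idx[axis] + 1, 2 * h
        a = list(idx)
        b = list(idx)
        a[axis], b[axis] = hi, lo
        return (f[tuple(a)] - f[tuple(b)]) / denom

    cx = np.empty_like(u)
    cy = np.empty_like(u)
    cz = np.empty_like(u)
    for i in range(nx):
        for j in range(ny):
            for k in range(nz):
                cx[i, j, k] = d(w, i, j, k, 1) - d(v, i, j, k, 2)
                cy[i, j, k] = d(u, i, j, k, 2) - d(w, i, j, k, 0)
                cz[i, j, k] = d(v, i, j, k, 0) - d(u, i, j, k, 1)
    return cx, cy, cz


def sort_based_stats(values: np.ndarray) -> dict:
    """Order-statistics reference for min/max/mean/p99."""
    flat = np.sort(np.ravel(values))
    n = flat.size
    # linear interpolation between order statistics at rank q*(n-1)
    pos = 0.99 * (n - 1)
    lo = int(np.floor(pos))
    frac = pos - lo
    p99 = flat[lo] if lo == n - 1 else flat[lo] * (1 - frac) + flat[lo + 1] * frac
    return {
        "min": flat[0],
        "max": flat[-1],
        "mean": flat.sum() / n,
        "p99": p99,
        "n_voxels": n,
    }


def enumerate_suprathreshold(values: np.ndarray, threshold: float) -> set:
    """All voxel indices strictly above the threshold."""
    return {
        tuple(idx) for idx in np.argwhere(values > threshold)
    }


def brute_force_surface_distance(point_mm: np.ndarray, mask: np.ndarray,
                                 spacing: tuple[float, float, float]) -> float:
    """Minimum distance from a physical point to any mask voxel centre."""
    coords = np.argwhere(mask) * np.asarray(spacing)
    return float(np.sqrt(((coords - point_mm) ** 2).sum(axis=1)).min())
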