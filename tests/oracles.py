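"""Independent brute-force oracles used only by the tests.

These deliberately avoid the library code paths they check: connected
components by explicit breadth-first flood fill over neighbor offsets, and
rigid registration by exhaustive grid search over (theta, tx, ty).
"""

from collections import deque
from itertools import product

import numpy as np

NEIGHBOR_OFFSETS = {
    6: [o for o in product((-1, 0, 1), repeat=3) if sum(abs(v) for v in o) == 1],
    18: [
        o
        for o in product((-1, 0, 1), repeat=3)
        if 1 <= sum(abs(v) for v in o) <= 2
    ],
    26: [o for o in product((-1, 0, 1), repeat=3) if any(o)],
}


def flood_fill_components(mask: np.ndarray, connectivity: int = 26):
    """BFS connected components of a 3D boolean mask.

    Returns (component_map, sizes) with components numbered in discovery
    order; sizes unsorted.
    """
    offsets = NEIGHBOR_OFFSETS[connectivity]
    comp = np.zeros(mask.shape, dtype=np.int32)
    sizes = []
    nz, ny, nx = mask.shape
    next_id = 0
    for start in zip(*np.nonzero(mask)):
        if comp[start]:
            continue
        next_id += 1
        comp[start] = next_id
        size = 1
        queue = deque([start])
        while queue:
            z, y, x = queue.popleft()
            for dz, dy, dx in offsets:
                zz, yy, xx = z + dz, y + dy, x + dx
                if 0 <= zz < nz and 0 <= yy < ny and 0 <= xx < nx:
                    if mask[zz, yy, xx] and not comp[zz, yy, xx]:
                        comp[zz, yy, xx] = next_id
                        size += 1
                        queue.append((zz, yy, xx))
        sizes.append(size)
    return comp, np.array(sizes, dtype=np.int64)


def bfs_reachable_components(stain_mask, ref_mask, connectivity: int = 26):
    """Which stain components (by BFS numbering) are reachable from the
    reference region: BFS outward from every reference voxel, one step into
    the stain, then flood within the stain."""
    offsets = NEIGHBOR_OFFSETS[connectivity]
    comp, sizes = flood_fill_components(stain_mask, connectivity)
    nz, ny, nx = stain_mask.shape
    touched = set()
    for z, y, x in zip(*np.nonzero(ref_mask)):
        if stain_mask[z, y, x]:
            touched.add(int(comp[z, y, x]))
        for dz, dy, dx in offsets:
            zz, yy, xx = z + dz, y + dy, x + dx
            if 0 <= zz < nz and 0 <= yy < ny and 0 <= xx < nx and stain_mask[zz, yy, xx]:
                touched.add(int(comp[zz, yy, xx]))
    return comp, sizes, touched


def grid_search_rigid(fixed, moving, theta_range, t_range, n_theta=81, n_t=41):
    """Exhaustive search over (theta, tx, ty) minimizing the sum of squared
    landmark distances, with the rotation taken about the moving centroid
    (where the translation is small and decoupled from the angle).

    Returns (theta, tx, ty) at the grid resolution, translation expressed
    about the moving centroid.
    """
    cm = moving.mean(axis=0)
    centered = moving - cm
    best = None
    thetas = np.linspace(-theta_range, theta_range, n_theta)
    ts = np.linspace(-t_range, t_range, n_t)
    for theta in thetas:
        c, s = np.cos(theta), np.sin(theta)
        rot = centered @ np.array([[c, s], [-s, c]]) + cm  # (R @ x.T).T + cm
        for tx in ts:
            for ty in ts:
                d = rot + np.array([tx, ty]) - fixed
                cost = float((d**2).sum())
                if best is None or cost < best[0]:
                    best = (cost, theta, tx, ty)
    return best[1], best[2], best[3]
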