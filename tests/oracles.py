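"""Independent brute-force oracles used by the test suite only.

These deliberately use different algorithms from the implementation:
pairwise O(n^2) link enumeration with BFS components for the merge, and a
per-pixel distance test for the density raster.
"""

from collections import deque

import numpy as np


def merge_oracle(frames, x, y, radius: float, window: int):
    """Single-linkage components: link iff dist <= radius and 1 <= gap <= window.

    Returns (count, list of component row-index sets).
    """
    frames = np.asarray(frames)
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = frames.size
    adj = [[] for _ in range(n)]
    for i in range(n):
        for j in range(i + 1, n):
            gap = abs(int(frames[i]) - int(frames[j]))
            if gap < 1 or gap > window:
                continue
            if (x[i] - x[j]) ** 2 + (y[i] - y[j]) ** 2 <= radius**2:
                adj[i].append(j)
                adj[j].append(i)
    seen = [False] * n
    comps = []
    for i in range(n):
        if seen[i]:
            continue
        comp = set()
        queue = deque([i])
        seen[i] = True
        while queue:
            k = queue.popleft()
            comp.add(k)
            for m in adj[k]:
                if not seen[m]:
                    seen[m] = True
                    queue.append(m)
        comps.append(comp)
    return len(comps), comps


def density_oracle(x, y, nx, ny, pixel_size_nm, disk_diameter_nm=1000.0):
    """Per-pixel brute force: count emitters within disk radius of each center."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    r2 = (disk_diameter_nm / 2.0) ** 2
    values = np.zeros((ny, nx), dtype=int)
    for iy in range(ny):
        cy = (iy + 0.5) * pixel_size_nm
        for ix in range(nx):
            cx = (ix + 0.5) * pixel_size_nm
            values[iy, ix] = int(np.sum((x - cx) ** 2 + (y - cy) ** 2 <= r2))
    return values


def point_in_mask_oracle(x, y, mask, pixel_size_nm):
    """Floor-convention membership test, one point at a time."""
    keep = []
    ny, nx = mask.shape
    for xi, yi in zip(np.asarray(x, float), np.asarray(y, float)):
        ix = int(np.floor(xi / pixel_size_nm))
        iy = int(np.floor(yi / pixel_size_nm))
        keep.append(0 <= ix < nx and 0 <= iy < ny and bool(mask[iy, ix]))
    return np.asarray(keep, dtype=bool)
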