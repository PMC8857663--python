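"""Independent brute-force oracles used to cross-check the implementation.

These deliberately avoid the code paths (and, where feasible, the libraries)
they validate: flood fill instead of labeling, exhaustive voxel counting
instead of set arithmetic, all-pairs distances instead of KD-trees.
"""

from collections import deque

import numpy as np


def flood_fill_components(grid, connectivity):
    """BFS connected components; returns a list of frozensets of voxel tuples."""
    offsets = []
    for dx in (-1, 0, 1):
        for dy in (-1, 0, 1):
            for dz in (-1, 0, 1):
                if (dx, dy, dz) == (0, 0, 0):
                    continue
                order = abs(dx) + abs(dy) + abs(dz)
                if (connectivity == 6 and order == 1) or connectivity == 26:
                    offsets.append((dx, dy, dz))
    grid = np.asarray(grid, bool)
    seen = np.zeros_like(grid, bool)
    components = []
    for start in zip(*np.nonzero(grid)):
        if seen[start]:
            continue
        comp = set()
        q = deque([start])
        seen[start] = True
        while q:
            p = q.popleft()
            comp.add(p)
            for off in offsets:
                nb = tuple(c + o for c, o in zip(p, off))
                if all(0 <= c < s for c, s in zip(nb, grid.shape)) and grid[nb] and not seen[nb]:
                    seen[nb] = True
                    q.append(nb)
        components.append(frozenset(comp))
    return components


def brute_force_dice(a, b):
    """Voxel-by-voxel counting of 2|A∩B| / (|A| + |B|)."""
    na = nb = ni = 0
    for pa, pb in zip(a.ravel(), b.ravel()):
        na += bool(pa)
        nb += bool(pb)
        ni += bool(pa) and bool(pb)
    return 1.0 if na + nb == 0 else 2 * ni / (na + nb)


def brute_force_hausdorff(a, b, spacing=(1.0, 1.0, 1.0)):
    """All-pairs surface distance; surface = foreground voxel with a
    background 6-neighbour (out-of-grid counts as background)."""

    def surface(m):
        pts = []
        for p in zip(*np.nonzero(m)):
            for ax in range(3):
                for d in (-1, 1):
                    q = list(p)
                    q[ax] += d
                    if not (0 <= q[ax] < m.shape[ax]) or not m[tuple(q)]:
                        pts.append(np.array(p) * np.asarray(spacing))
                        break
                else:
                    continue
                break
        return np.array(pts)

    pa, pb = surface(a), surface(b)
    d = np.sqrt(((pa[:, None, :] - pb[None, :, :]) ** 2).sum(-1))
    return max(d.min(axis=1).max(), d.min(axis=0).max())
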