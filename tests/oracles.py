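"""Independent brute-force oracles for the property and acceptance tests.

Kept deliberately separate from the package: strict polygon interiors are
checked with shapely's exact predicates, clustering with a plain union-find
over the full pairwise distance matrix, diameters with an all-pairs scan.
"""

import numpy as np
from shapely import contains_xy
from shapely.geometry import Polygon


def strict_interior_oracle(points, shape):
    """Pixels strictly inside the closed polygon (boundary excluded)."""
    poly = Polygon(points)
    rows, cols = shape
    yy, xx = np.mgrid[0:rows, 0:cols]
    return contains_xy(poly, xx.ravel().astype(float), yy.ravel().astype(float)).reshape(
        rows, cols
    )


def mask_oracle(included, excluded, shape):
    """Include-minus-exclude strict-interior set arithmetic on one slice."""
    mask = np.zeros(shape, dtype=bool)
    for pts in included:
        mask |= strict_interior_oracle(pts, shape)
    for pts in excluded:
        mask &= ~strict_interior_oracle(pts, shape)
    return mask


def union_find_clusters(n, distance, tol):
    """Connected components of the thresholded pairwise distance graph.

    Returns frozensets of member indices.
    """
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            if distance(i, j) <= tol:
                ri, rj = find(i), find(j)
                if ri != rj:
                    parent[rj] = ri
    groups = {}
    for i in range(n):
        groups.setdefault(find(i), set()).add(i)
    return {frozenset(members) for members in groups.values()}


def brute_force_diameter(mask_volume):
    """All-pairs maximum in-plane distance over every foreground pixel."""
    g = mask_volume.geometry
    row_sp, col_sp = g.pixel_spacing
    best = 0.0
    for k in mask_volume.nonempty_slices:
        sl = mask_volume.slice_mask(k)
        pts = np.argwhere(sl).astype(float)
        if len(pts) < 2:
            continue
        xy = np.column_stack([pts[:, 1] * col_sp, pts[:, 0] * row_sp])
        d2 = ((xy[:, None, :] - xy[None, :, :]) ** 2).sum(-1)
        best = max(best, float(np.sqrt(d2.max())))
    return best
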