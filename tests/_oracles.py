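"""Independent brute-force oracles used by the test suite.

Each oracle is a deliberately naive re-statement of the operation it
checks, written without vectorization or shared code with the package,
so that agreement pins down the semantics rather than the implementation.
"""

import numpy as np


def point_in_polygon(x, y, vertices):
    """Scalar even-odd crossing test for one point against one polygon."""
    inside = False
    n = len(vertices)
    for i in range(n):
        x0, y0 = vertices[i]
        x1, y1 = vertices[(i + 1) % n]
        if (y0 > y) != (y1 > y):
            x_at = x0 + (y - y0) * (x1 - x0) / (y1 - y0)
            if x < x_at:
                inside = not inside
    return inside


def rasterize_bruteforce(vertices, shape):
    """Evaluate the point-in-polygon rule at every pixel center."""
    rows, cols = shape
    out = np.zeros(shape, dtype=bool)
    for r in range(rows):
        for c in range(cols):
            out[r, c] = point_in_polygon(float(c), float(r), vertices)
    return out


def grow_fixed_point(img, seed_rc, fraction=0.2, connectivity=8,
                     init_window=3, range_floor=0.0, mode="dynamic"):
    """Region growing iterated to fixed point by repeated full scans.

    Every pass examines *all* pixels adjacent to the accepted set and
    admits any satisfying |I(P) - I(S)| <= max(f*(max-min), tau0) under
    the current extrema; passes repeat until nothing changes.  Repeated
    scanning removes any queue-order effects.
    """
    img = np.asarray(img, dtype=float)
    rows, cols = img.shape
    sr, sc = seed_rc
    half = init_window // 2
    accepted = set()
    for r in range(max(0, sr - half), min(rows, sr + half + 1)):
        for c in range(max(0, sc - half), min(cols, sc + half + 1)):
            accepted.add((r, c))
    s_val = img[sr, sc]
    vals = [img[p] for p in accepted]
    mn, mx = min(vals), max(vals)
    if mode == "fixed":
        frozen_t = max(fraction * (mx - mn), range_floor)
    if connectivity == 8:
        nbrs = [(dr, dc) for dr in (-1, 0, 1) for dc in (-1, 0, 1)
                if (dr, dc) != (0, 0)]
    else:
        nbrs = [(-1, 0), (1, 0), (0, -1), (0, 1)]

    changed = True
    while changed:
        changed = False
        for r in range(rows):
            for c in range(cols):
                if (r, c) in accepted:
                    continue
                if not any((r + dr, c + dc) in accepted for dr, dc in nbrs):
                    continue
                t = frozen_t if mode == "fixed" else max(
                    fraction * (mx - mn), range_floor)
                if abs(img[r, c] - s_val) <= t:
                    accepted.add((r, c))
                    mn = min(mn, img[r, c])
                    mx = max(mx, img[r, c])
                    changed = True
    out = np.zeros(img.shape, dtype=np.uint8)
    for r, c in accepted:
        out[r, c] = 1
    return out


def overlap_by_sets(a, b):
    """(dice, iou, voe) by explicit coordinate-set counting."""
    sa = {tuple(idx) for idx in np.argwhere(np.asarray(a) != 0)}
    sb = {tuple(idx) for idx in np.argwhere(np.asarray(b) != 0)}
    inter = len(sa & sb)
    union = len(sa | sb)
    if union == 0:
        return 1.0, 1.0, 0.0
    iou = inter / union
    dice = 2 * inter / (len(sa) + len(sb))
    return dice, iou, 1.0 - iou
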