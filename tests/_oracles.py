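"""Independent brute-force oracles used to validate the fast implementations.

Everything here is deliberately naive: per-pixel distance scans, explicit
moment sums, O(n^4) circumcircle tests.  Nothing imports the code paths it
checks.
"""

from __future__ import annotations

import itertools

import numpy as np


def brute_force_voronoi(labels: np.ndarray, region_labels: np.ndarray) -> np.ndarray:
    """Nearest-region assignment by exhaustive scan.

    For every tissue pixel (labels 1-3), measure the squared Euclidean
    distance to every region's pixel set; assign the nearest, ties to the
    lowest region label.  Background pixels stay 0.
    """
    n = int(region_labels.max())
    region_pixels = {
        lab: np.argwhere(region_labels == lab) for lab in range(1, n + 1)}
    assign = np.zeros(labels.shape, dtype=np.int32)
    for r, c in np.argwhere(labels > 0):
        best_d2, best_lab = None, 0
        for lab in range(1, n + 1):
            pix = region_pixels[lab]
            d2 = int(np.min((pix[:, 0] - r) ** 2 + (pix[:, 1] - c) ** 2))
            if best_d2 is None or d2 < best_d2:
                best_d2, best_lab = d2, lab
        assign[r, c] = best_lab
    return assign


def brute_force_eccentricity(mask: np.ndarray) -> float:
    """Eccentricity of the moment-equivalent ellipse by explicit moment sums."""
    pts = np.argwhere(mask).astype(float)
    r_bar, c_bar = pts.mean(axis=0)
    n = len(pts)
    mu20 = np.sum((pts[:, 0] - r_bar) ** 2) / n
    mu02 = np.sum((pts[:, 1] - c_bar) ** 2) / n
    mu11 = np.sum((pts[:, 0] - r_bar) * (pts[:, 1] - c_bar)) / n
    common = np.sqrt(4 * mu11 ** 2 + (mu20 - mu02) ** 2)
    lam1 = (mu20 + mu02 + common) / 2.0
    lam2 = (mu20 + mu02 - common) / 2.0
    if lam1 == 0:
        return 0.0
    return float(np.sqrt(1.0 - lam2 / lam1))


def _circumcircle(p1, p2, p3):
    """Centre and squared radius of the circle through three points."""
    ax, ay = p1
    bx, by = p2
    cx, cy = p3
    d = 2.0 * (ax * (by - cy) + bx * (cy - ay) + cx * (ay - by))
    if abs(d) < 1e-12:
        return None
    ux = ((ax ** 2 + ay ** 2) * (by - cy) + (bx ** 2 + by ** 2) * (cy - ay)
          + (cx ** 2 + cy ** 2) * (ay - by)) / d
    uy = ((ax ** 2 + ay ** 2) * (cx - bx) + (bx ** 2 + by ** 2) * (ax - cx)
          + (cx ** 2 + cy ** 2) * (bx - ax)) / d
    r2 = (ax - ux) ** 2 + (ay - uy) ** 2
    return (ux, uy), r2


def brute_force_delaunay_degrees(points: np.ndarray) -> np.ndarray:
    """Delaunay degrees via the empty-circumcircle test over all triples."""
    n = len(points)
    edges = set()
    for i, j, k in itertools.combinations(range(n), 3):
        cc = _circumcircle(points[i], points[j], points[k])
        if cc is None:
            continue
        (ux, uy), r2 = cc
        empty = True
        for m in range(n):
            if m in (i, j, k):
                continue
            if (points[m][0] - ux) ** 2 + (points[m][1] - uy) ** 2 < r2 - 1e-9:
                empty = False
                break
        if empty:
            edges.update({(i, j), (i, k), (j, k)})
    deg = np.zeros(n, dtype=int)
    for a, b in edges:
        deg[a] += 1
        deg[b] += 1
    return deg


def sort_based_summary(values, stat: str) -> float:
    """Summary statistics computed from first principles on sorted data."""
    v = sorted(float(x) for x in values)
    n = len(v)
    if n == 0:
        return 0.0
    if stat == "mean":
        return sum(v) / n
    if stat == "median":
        mid = n // 2
        return v[mid] if n % 2 else (v[mid - 1] + v[mid]) / 2.0
    if stat == "sd":
        m = sum(v) / n
        return (sum((x - m) ** 2 for x in v) / n) ** 0.5
    if stat == "max":
        return v[-1]
    if stat == "iq":
        def quantile(q):
            h = (n - 1) * q
            lo = int(np.floor(h))
            hi = min(lo + 1, n - 1)
            return v[lo] + (h - lo) * (v[hi] - v[lo])
        return quantile(0.75) - quantile(0.25)
    raise ValueError(stat)


def mann_whitney_auc(scores, truth) -> float:
    """AUC as the concordance probability over all case-control pairs."""
    scores = np.asarray(scores, dtype=float)
    truth = np.asarray(truth)
    pos = scores[truth == 1]
    neg = scores[truth == 0]
    total = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                total += 1.0
            elif p == q:
                total += 0.5
    return total / (len(pos) * len(neg))
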