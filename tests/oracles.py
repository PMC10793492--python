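"""Independent brute-force oracles used to validate the pipeline.

Everything here is deliberately naive — O(n^2) union-find clustering,
gift-wrapping hulls with the shoelace formula, Sutherland-Hodgman polygon
clipping, exhaustive kNN and pairwise concordance, per-gene running-sum
walks, BFS flood fill — and shares no code with the implementation paths
it checks.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.stats import rankdata


# ---------------------------------------------------------------------------
# clustering


def clusters_bruteforce(coords: np.ndarray, tau: float) -> list[frozenset]:
    """Connected components of the <=tau proximity graph via union-find."""
    n = len(coords)
    parent = list(range(n))

    def find(a):
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    for i in range(n):
        for j in range(i + 1, n):
            d = math.dist(coords[i], coords[j])
            if d <= tau:
                ra, rb = find(i), find(j)
                if ra != rb:
                    parent[ra] = rb
    comps: dict[int, set] = {}
    for i in range(n):
        comps.setdefault(find(i), set()).add(i)
    return [frozenset(c) for c in comps.values()]


# ---------------------------------------------------------------------------
# convex hulls


def gift_wrap_hull(points: np.ndarray) -> np.ndarray:
    """Convex hull vertices (counterclockwise) by Jarvis march."""
    pts = np.unique(np.asarray(points, float), axis=0)
    n = len(pts)
    if n <= 2:
        return pts
    start = min(range(n), key=lambda i: (pts[i][0], pts[i][1]))
    hull = [start]
    while True:
        cur = hull[-1]
        cand = (cur + 1) % n
        for j in range(n):
            if j == cur:
                continue
            u = pts[cand] - pts[cur]
            v = pts[j] - pts[cur]
            cross = u[0] * v[1] - u[1] * v[0]
            if cross < 0 or (cross == 0 and
                             math.dist(pts[cur], pts[j]) > math.dist(pts[cur], pts[cand])):
                cand = j
        if cand == start:
            break
        hull.append(cand)
        if len(hull) > n:
            break
    return pts[hull]


def shoelace_area(vertices: np.ndarray) -> float:
    v = np.asarray(vertices, float)
    if len(v) < 3:
        return 0.0
    x, y = v[:, 0], v[:, 1]
    return float(abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1))) / 2)


def hull_area_bruteforce(points: np.ndarray) -> float:
    return shoelace_area(gift_wrap_hull(points))


def _clip_polygon(subject: np.ndarray, clip: np.ndarray) -> np.ndarray:
    """Sutherland-Hodgman clipping of a convex subject by a convex clip."""
    def inside(p, a, b):
        return (b[0] - a[0]) * (p[1] - a[1]) - (b[1] - a[1]) * (p[0] - a[0]) >= -1e-12

    def intersect(p1, p2, a, b):
        x1, y1 = p1
        x2, y2 = p2
        x3, y3 = a
        x4, y4 = b
        den = (x1 - x2) * (y3 - y4) - (y1 - y2) * (x3 - x4)
        if den == 0:
            return p2
        t = ((x1 - x3) * (y3 - y4) - (y1 - y3) * (x3 - x4)) / den
        return (x1 + t * (x2 - x1), y1 + t * (y2 - y1))

    output = [tuple(p) for p in subject]
    m = len(clip)
    for i in range(m):
        a, b = tuple(clip[i]), tuple(clip[(i + 1) % m])
        inp, output = output, []
        if not inp:
            break
        s = inp[-1]
        for p in inp:
            if inside(p, a, b):
                if not inside(s, a, b):
                    output.append(intersect(s, p, a, b))
                output.append(p)
            elif inside(s, a, b):
                output.append(intersect(s, p, a, b))
            s = p
    return np.array(output) if output else np.empty((0, 2))


def _ccw(vertices: np.ndarray) -> np.ndarray:
    v = np.asarray(vertices, float)
    if len(v) < 3:
        return v
    signed = np.dot(v[:, 0], np.roll(v[:, 1], -1)) - np.dot(v[:, 1], np.roll(v[:, 0], -1))
    return v if signed >= 0 else v[::-1]


def hull_iou_bruteforce(points_a: np.ndarray, points_b: np.ndarray) -> float:
    """IoU of the convex hulls of two point sets (degenerate rule included)."""
    ha, hb = gift_wrap_hull(points_a), gift_wrap_hull(points_b)
    area_a, area_b = shoelace_area(ha), shoelace_area(hb)
    if area_a == 0 and area_b == 0:
        same = len(ha) == len(hb) and np.allclose(
            np.sort(ha, axis=0), np.sort(hb, axis=0))
        return 1.0 if same else 0.0
    inter = shoelace_area(_clip_polygon(_ccw(ha), _ccw(hb))) \
        if area_a > 0 and area_b > 0 else 0.0
    union = area_a + area_b - inter
    return inter / union if union > 0 else 0.0


# ---------------------------------------------------------------------------
# kNN mixing


def mixing_bruteforce(xy: np.ndarray, is_til: np.ndarray, k: int) -> np.ndarray:
    """Per-cell fraction of k nearest neighbors from the other family."""
    n = len(xy)
    out = np.full(n, np.nan)
    for i in range(n):
        d = [(math.dist(xy[i], xy[j]), j) for j in range(n) if j != i]
        if not d:
            continue
        d.sort()
        keff = min(k, len(d))
        nbrs = [j for _, j in d[:keff]]
        out[i] = float(np.mean([is_til[j] != is_til[i] for j in nbrs]))
    return out


# ---------------------------------------------------------------------------
# concordance


def cindex_bruteforce(time: np.ndarray, event: np.ndarray,
                      score: np.ndarray) -> float:
    """Harrell's C by exhaustive enumeration of comparable pairs.

    A pair is comparable when the earlier time is an event and the times
    differ; tied scores count one half.
    """
    num = den = 0.0
    n = len(time)
    for i in range(n):
        for j in range(n):
            if time[i] < time[j] and event[i] == 1:
                den += 1
                if score[i] > score[j]:
                    num += 1
                elif score[i] == score[j]:
                    num += 0.5
    return num / den


# ---------------------------------------------------------------------------
# ssGSEA


def ssgsea_oracle(values: np.ndarray, gene_ids: list[str],
                  members: set[str], alpha: float) -> float:
    """Normalized running-sum integral for one sample, computed stepwise."""
    n = len(values)
    order = sorted(range(n), key=lambda i: (-values[i], i))
    ranks = rankdata(values)  # ascending average ranks

    def walk(member_flags, weights):
        wsum = sum(w for w, m in zip(weights, member_flags) if m)
        n_mem = sum(member_flags)
        total = running = 0.0
        for w, m in zip(weights, member_flags):
            if m:
                running += (w / wsum) if wsum else 0.0
            else:
                running -= 1.0 / (n - n_mem)
            total += running
        return total

    flags = [gene_ids[i] in members for i in order]
    weights = [ranks[i] ** alpha for i in order]
    es = walk(flags, weights)

    n_mem = sum(flags)
    ref = [float(n - i) for i in range(n)]  # tie-free descending ranks
    top = walk([i < n_mem for i in range(n)], [r ** alpha for r in ref])
    bot = walk([i >= n - n_mem for i in range(n)], [r ** alpha for r in ref])
    denom = (top - bot) or 1.0
    return es / denom


# ---------------------------------------------------------------------------
# raster labeling


def floodfill_components(binary: np.ndarray, connectivity: int = 2) -> list[set]:
    """BFS connected components of a binary raster (8-conn by default)."""
    h, w = binary.shape
    seen = np.zeros_like(binary, dtype=bool)
    if connectivity == 2:
        nbrs = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]
    else:
        nbrs = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    comps = []
    for r in range(h):
        for c in range(w):
            if binary[r, c] and not seen[r, c]:
                comp = set()
                stack = [(r, c)]
                seen[r, c] = True
                while stack:
                    y, x = stack.pop()
                    comp.add((y, x))
                    for dy, dx in nbrs:
                        ny, nx = y + dy, x + dx
                        if 0 <= ny < h and 0 <= nx < w and \
                                binary[ny, nx] and not seen[ny, nx]:
                            seen[ny, nx] = True
                            stack.append((ny, nx))
                comps.append(comp)
    return comps


def tile_coverage_bruteforce(mask: np.ndarray, tile: int, frac: float) -> set:
    """(row, col) grid tiles whose coverage meets the fraction, by counting."""
    h, w = mask.shape
    out = set()
    for r in range(h // tile):
        for c in range(w // tile):
            count = 0
            for y in range(r * tile, (r + 1) * tile):
                for x in range(c * tile, (c + 1) * tile):
                    count += bool(mask[y, x])
            if count / tile ** 2 >= frac:
                out.add((r, c))
    return out
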