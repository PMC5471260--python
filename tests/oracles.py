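"""Independent brute-force oracles used to validate the fast implementations.

Everything here is deliberately written with explicit Python loops and
textbook formulas, sharing no code with the package internals.
"""

from __future__ import annotations

import math

import numpy as np

# the 13 unique 3D pair directions, written out explicitly
DIRECTIONS = [
    (1, 0, 0), (0, 1, 0), (0, 0, 1),
    (1, 1, 0), (1, -1, 0), (1, 0, 1), (1, 0, -1),
    (0, 1, 1), (0, 1, -1),
    (1, 1, 1), (1, 1, -1), (1, -1, 1), (1, -1, -1),
]


def _in_grid(shape, p):
    return all(0 <= c < n for c, n in zip(p, shape))


def glcm_counts_bruteforce(levels: np.ndarray, offset) -> np.ndarray:
    """Symmetric GLCM by exhaustive voxel-pair enumeration (0 = outside)."""
    ng = int(levels.max())
    counts = np.zeros((ng, ng))
    shape = levels.shape
    for x in range(shape[0]):
        for y in range(shape[1]):
            for z in range(shape[2]):
                a = levels[x, y, z]
                if a == 0:
                    continue
                q = (x + offset[0], y + offset[1], z + offset[2])
                if not _in_grid(shape, q):
                    continue
                b = levels[q]
                if b == 0:
                    continue
                counts[a - 1, b - 1] += 1
                counts[b - 1, a - 1] += 1
    return counts


def glcm_features_bruteforce(levels: np.ndarray, distance: int = 1) -> dict:
    """The 17 co-occurrence features, averaged over directions with pairs."""
    per_dir = []
    for d in DIRECTIONS:
        off = tuple(distance * c for c in d)
        counts = glcm_counts_bruteforce(levels, off)
        if counts.sum() == 0:
            continue
        p = counts / counts.sum()
        per_dir.append(_glcm_from_matrix(p))
    agg = {}
    for key in per_dir[0]:
        vals = [f[key] for f in per_dir if not math.isnan(f[key])]
        agg[key] = sum(vals) / len(vals) if vals else float("nan")
    return agg


def _glcm_from_matrix(p: np.ndarray) -> dict:
    ng = p.shape[0]
    mu = 0.0
    for i in range(ng):
        for j in range(ng):
            mu += (i + 1) * p[i, j]
    var = 0.0
    for i in range(ng):
        for j in range(ng):
            var += ((i + 1) - mu) ** 2 * p[i, j]

    pxpy = {}
    pxmy = {}
    for i in range(ng):
        for j in range(ng):
            pxpy[i + j + 2] = pxpy.get(i + j + 2, 0.0) + p[i, j]
            pxmy[abs(i - j)] = pxmy.get(abs(i - j), 0.0) + p[i, j]

    f = dict.fromkeys([
        "autocorrelation", "cluster_prominence", "cluster_shade",
        "cluster_tendency", "contrast", "dissimilarity", "energy", "entropy",
        "homogeneity", "inverse_difference_moment", "inverse_variance",
        "maximum_probability",
    ], 0.0)
    for i in range(ng):
        for j in range(ng):
            v = p[i, j]
            ii, jj = i + 1, j + 1
            f["autocorrelation"] += ii * jj * v
            f["cluster_prominence"] += (ii + jj - 2 * mu) ** 4 * v
            f["cluster_shade"] += (ii + jj - 2 * mu) ** 3 * v
            f["cluster_tendency"] += (ii + jj - 2 * mu) ** 2 * v
            f["contrast"] += (ii - jj) ** 2 * v
            f["dissimilarity"] += abs(ii - jj) * v
            f["energy"] += v * v
            if v > 0:
                f["entropy"] -= v * math.log2(v)
            f["homogeneity"] += v / (1 + abs(ii - jj))
            f["inverse_difference_moment"] += v / (1 + (ii - jj) ** 2)
            if ii != jj:
                f["inverse_variance"] += v / (ii - jj) ** 2
            f["maximum_probability"] = max(f["maximum_probability"], v)
    f["correlation"] = (f["autocorrelation"] - mu * mu) / var if var > 0 else float("nan")
    sa = sum(k * q for k, q in pxpy.items())
    f["sum_average"] = sa
    f["sum_entropy"] = -sum(q * math.log2(q) for q in pxpy.values() if q > 0)
    f["sum_variance"] = sum((k - sa) ** 2 * q for k, q in pxpy.items())
    f["difference_entropy"] = -sum(q * math.log2(q) for q in pxmy.values() if q > 0)
    return f


def zones_bruteforce(levels: np.ndarray) -> list[int]:
    """26-connected equal-level zone sizes via BFS flood fill."""
    shape = levels.shape
    seen = np.zeros(shape, dtype=bool)
    sizes = []
    neigh = [(dx, dy, dz) for dx in (-1, 0, 1) for dy in (-1, 0, 1)
             for dz in (-1, 0, 1) if (dx, dy, dz) != (0, 0, 0)]
    for x in range(shape[0]):
        for y in range(shape[1]):
            for z in range(shape[2]):
                if levels[x, y, z] == 0 or seen[x, y, z]:
                    continue
                g = levels[x, y, z]
                stack = [(x, y, z)]
                seen[x, y, z] = True
                size = 0
                while stack:
                    cx, cy, cz = stack.pop()
                    size += 1
                    for dx, dy, dz in neigh:
                        q = (cx + dx, cy + dy, cz + dz)
                        if _in_grid(shape, q) and not seen[q] and levels[q] == g:
                            seen[q] = True
                            stack.append(q)
                sizes.append(size)
    return sizes


def szv_bruteforce(levels: np.ndarray) -> float:
    sizes = zones_bruteforce(levels)
    nz = len(sizes)
    per_size = {}
    for s in sizes:
        per_size[s] = per_size.get(s, 0) + 1
    return sum(c * c for c in per_size.values()) / nz


def runs_bruteforce(levels: np.ndarray, direction) -> list[tuple[int, int]]:
    """(level, length) of maximal in-mask same-level runs along a direction,
    found by walking every line voxel by voxel."""
    shape = levels.shape
    d = direction
    runs = []
    for x in range(shape[0]):
        for y in range(shape[1]):
            for z in range(shape[2]):
                prev = (x - d[0], y - d[1], z - d[2])
                # start of a run: previous voxel missing, off-mask, or other level
                here = levels[x, y, z]
                if here == 0:
                    continue
                if _in_grid(shape, prev) and levels[prev] == here:
                    continue
                length = 0
                p = (x, y, z)
                while _in_grid(shape, p) and levels[p] == here:
                    length += 1
                    p = (p[0] + d[0], p[1] + d[1], p[2] + d[2])
                runs.append((int(here), length))
    return runs


def rlgl_features_bruteforce(levels: np.ndarray) -> dict:
    n_vox = int((levels > 0).sum())
    acc = {k: [] for k in ["short_run_emphasis", "long_run_emphasis",
                           "gray_level_nonuniformity",
                           "run_length_nonuniformity", "run_percentage"]}
    for d in DIRECTIONS:
        runs = runs_bruteforce(levels, d)
        nr = len(runs)
        by_level, by_length = {}, {}
        for g, r in runs:
            by_level[g] = by_level.get(g, 0) + 1
            by_length[r] = by_length.get(r, 0) + 1
        acc["short_run_emphasis"].append(sum(1.0 / r**2 for _, r in runs) / nr)
        acc["long_run_emphasis"].append(sum(float(r**2) for _, r in runs) / nr)
        acc["gray_level_nonuniformity"].append(sum(c * c for c in by_level.values()) / nr)
        acc["run_length_nonuniformity"].append(sum(c * c for c in by_length.values()) / nr)
        acc["run_percentage"].append(nr / n_vox)
    return {k: sum(v) / len(v) for k, v in acc.items()}


def auc_paircount(values, labels) -> float:
    """AUC = fraction of (class1, class0) pairs won, half credit for ties."""
    pos = [v for v, y in zip(values, labels) if y == 1]
    neg = [v for v, y in zip(values, labels) if y == 0]
    wins = 0.0
    for a in pos:
        for b in neg:
            if a > b:
                wins += 1.0
            elif a == b:
                wins += 0.5
    return wins / (len(pos) * len(neg))


def bh_stepup(pvalues) -> list[float]:
    """Benjamini-Hochberg step-up by the hand procedure."""
    m = len(pvalues)
    order = sorted(range(m), key=lambda i: pvalues[i])
    q = [0.0] * m
    prev = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        val = min(prev, pvalues[i] * m / rank_from_top)
        q[i] = val
        prev = val
    return q


def midranks(x) -> list[float]:
    order = sorted(range(len(x)), key=lambda i: x[i])
    ranks = [0.0] * len(x)
    i = 0
    while i < len(x):
        j = i
        while j + 1 < len(x) and x[order[j + 1]] == x[order[i]]:
            j += 1
        avg = (i + j) / 2.0 + 1.0
        for k in range(i, j + 1):
            ranks[order[k]] = avg
        i = j + 1
    return ranks


def spearman_rank_pearson(x, y) -> float:
    """Spearman rho = Pearson correlation of midranks."""
    rx, ry = midranks(list(x)), midranks(list(y))
    mx, my = sum(rx) / len(rx), sum(ry) / len(ry)
    num = sum((a - mx) * (b - my) for a, b in zip(rx, ry))
    den = math.sqrt(sum((a - mx) ** 2 for a in rx) * sum((b - my) ** 2 for b in ry))
    return num / den


def kruskal_wallis_handformula(groups) -> float:
    """Tie-corrected Kruskal-Wallis H by the direct formula."""
    pooled = [v for g in groups for v in g]
    n = len(pooled)
    ranks = midranks(pooled)
    h = 0.0
    start = 0
    for g in groups:
        rsum = sum(ranks[start:start + len(g)])
        h += rsum**2 / len(g)
        start += len(g)
    h = 12.0 / (n * (n + 1)) * h - 3 * (n + 1)
    # tie correction
    counts = {}
    for v in pooled:
        counts[v] = counts.get(v, 0) + 1
    correction = 1.0 - sum(t**3 - t for t in counts.values()) / (n**3 - n)
    return h / correction


def noether_p_erfc(auc: float, n0: int, n1: int) -> float:
    """Two-sided normal p via math.erfc, independent of scipy."""
    z = (auc - 0.5) / math.sqrt((n0 + n1 + 1) / (12.0 * n0 * n1))
    return math.erfc(abs(z) / math.sqrt(2.0))
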