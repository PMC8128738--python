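"""Independent brute-force reference implementations used only by tests.

Everything here is written with plain Python loops and first-principles
formulas, deliberately sharing no code with the package, so agreement
between the two routes is informative.
"""

from __future__ import annotations

import math
from itertools import combinations


def brute_force_weight(max_hu: float) -> int:
    if max_hu < 130:
        raise ValueError("below threshold")
    for upper, w in ((200, 1), (300, 2), (400, 3)):
        if max_hu < upper:
            return w
    return 4


def brute_force_macs(
    voxels,
    region_mask,
    pixel_spacing,
    slice_thickness,
    threshold=130.0,
    min_area=1.0,
):
    """Per-slice flood-fill Agatston scorer: python loops only.

    voxels / region_mask are (z, y, x) nested-indexable arrays.
    """
    nz = len(voxels)
    ny = len(voxels[0])
    nx = len(voxels[0][0])
    pixel_area = pixel_spacing[0] * pixel_spacing[1]
    total = 0.0
    lesion_count = 0
    for k in range(nz):
        seen = [[False] * nx for _ in range(ny)]
        for j0 in range(ny):
            for i0 in range(nx):
                if seen[j0][i0]:
                    continue
                if not (region_mask[k][j0][i0] and voxels[k][j0][i0] >= threshold):
                    continue
                # flood fill with 8-connectivity
                stack = [(j0, i0)]
                seen[j0][i0] = True
                component = []
                while stack:
                    j, i = stack.pop()
                    component.append((j, i))
                    for dj in (-1, 0, 1):
                        for di in (-1, 0, 1):
                            jj, ii = j + dj, i + di
                            if 0 <= jj < ny and 0 <= ii < nx and not seen[jj][ii]:
                                if region_mask[k][jj][ii] and voxels[k][jj][ii] >= threshold:
                                    seen[jj][ii] = True
                                    stack.append((jj, ii))
                area = len(component) * pixel_area
                if area < min_area:
                    continue
                max_hu = max(voxels[k][j][i] for j, i in component)
                weight = brute_force_weight(max_hu)
                total += area * weight * (slice_thickness / 3.0)
                lesion_count += 1
    return total, lesion_count


def pairwise_auc(scores, labels):
    """AUC as the fraction of (diseased, healthy) pairs ranked correctly,
    ties counting one half."""
    pos = [s for s, l in zip(scores, labels) if l]
    neg = [s for s, l in zip(scores, labels) if not l]
    wins = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                wins += 1.0
            elif p == q:
                wins += 0.5
    return wins / (len(pos) * len(neg))


def exhaustive_cutoff(scores, labels):
    """Best cutoff by exhaustive search over observed unique scores.

    Positivity is score >= cutoff; Youden's J is maximised; ties go to
    the cutoff with higher sensitivity (the lower cutoff); the returned
    value is the midpoint between the winning score and the next lower
    observed score.
    """
    pos = [s for s, l in zip(scores, labels) if l]
    neg = [s for s, l in zip(scores, labels) if not l]
    unique = sorted(set(scores))
    best = None
    for v in unique:
        sens = sum(1 for s in pos if s >= v) / len(pos)
        spec = sum(1 for s in neg if s < v) / len(neg)
        j = sens + spec - 1.0
        # strictly better J wins; ties go to higher sensitivity which,
        # scanning ascending, is the earlier (lower) cutoff
        if best is None or j > best[0] + 1e-12:
            best = (j, sens, v)
    _, _, v = best
    lower = [u for u in unique if u < v]
    if lower:
        return (v + lower[-1]) / 2.0
    return v


def anova_icc2(ratings):
    """ICC(2,1) from first-principles two-way ANOVA sums of squares."""
    n = len(ratings)
    k = len(ratings[0])
    grand = sum(sum(row) for row in ratings) / (n * k)
    row_means = [sum(row) / k for row in ratings]
    col_means = [sum(ratings[i][j] for i in range(n)) / n for j in range(k)]
    ss_rows = k * sum((rm - grand) ** 2 for rm in row_means)
    ss_cols = n * sum((cm - grand) ** 2 for cm in col_means)
    ss_total = sum((ratings[i][j] - grand) ** 2 for i in range(n) for j in range(k))
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    return (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)


def point_in_polygon_even_odd(py, px, vertices):
    """Even-odd ray casting: vertices are (y, x) pairs."""
    inside = False
    m = len(vertices)
    for a in range(m):
        y1, x1 = vertices[a]
        y2, x2 = vertices[(a + 1) % m]
        if (y1 > py) != (y2 > py):
            x_cross = x1 + (py - y1) * (x2 - x1) / (y2 - y1)
            if px < x_cross:
                inside = not inside
    return inside


def two_sided_binomial_p(k_successes, n, p=0.5):
    """Exact two-sided binomial p-value: sum of all outcome
    probabilities not exceeding the observed one."""
    def pmf(i):
        return math.comb(n, i) * p ** i * (1 - p) ** (n - i)

    observed = pmf(k_successes)
    return sum(pmf(i) for i in range(n + 1) if pmf(i) <= observed * (1 + 1e-12))


def rank_sum_exact_p(a, b):
    """Two-sided exact Wilcoxon rank-sum p by full enumeration of group
    assignments (tie-free samples only)."""
    pooled = sorted(a + b)
    assert len(set(pooled)) == len(pooled), "oracle requires no ties"
    ranks = {v: i + 1 for i, v in enumerate(pooled)}
    observed = sum(ranks[v] for v in a)
    n_a = len(a)
    total = 0
    at_least = 0
    mean_stat = n_a * (len(pooled) + 1) / 2.0
    obs_dev = abs(observed - mean_stat)
    for combo in combinations(range(1, len(pooled) + 1), n_a):
        total += 1
        if abs(sum(combo) - mean_stat) >= obs_dev - 1e-12:
            at_least += 1
    return at_least / total
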