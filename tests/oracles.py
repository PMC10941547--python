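"""Independent brute-force oracles used to cross-check the implementation.

Everything here is written from first principles (explicit loops, direct
textbook summations) and deliberately shares no code with the package.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


def brute_glcm(levels: np.ndarray, mask: np.ndarray, offset: tuple[int, int, int],
               G: int) -> np.ndarray:
    """Symmetric normalized GLCM by explicit enumeration of voxel pairs."""
    counts = np.zeros((G, G))
    nz, ny, nx = levels.shape
    dz, dy, dx = offset
    for z in range(nz):
        for y in range(ny):
            for x in range(nx):
                z2, y2, x2 = z + dz, y + dy, x + dx
                if not (0 <= z2 < nz and 0 <= y2 < ny and 0 <= x2 < nx):
                    continue
                if mask[z, y, x] and mask[z2, y2, x2]:
                    i, j = levels[z, y, x] - 1, levels[z2, y2, x2] - 1
                    counts[i, j] += 1
                    counts[j, i] += 1
    total = counts.sum()
    return counts / total if total > 0 else counts


def _ent2(ps) -> float:
    return -sum(p * math.log2(p) for p in ps if p > 0)


def textbook_haralick(P: np.ndarray) -> dict[str, float]:
    """The 13 Haralick statistics by direct double-loop summation."""
    G = P.shape[0]
    idx = range(1, G + 1)
    px = [sum(P[i - 1, j - 1] for j in idx) for i in idx]
    py = [sum(P[i - 1, j - 1] for i in idx) for j in idx]
    mu_x = sum(i * px[i - 1] for i in idx)
    mu_y = sum(j * py[j - 1] for j in idx)
    sd_x = math.sqrt(sum((i - mu_x) ** 2 * px[i - 1] for i in idx))
    sd_y = math.sqrt(sum((j - mu_y) ** 2 * py[j - 1] for j in idx))

    p_sum = {k: 0.0 for k in range(2, 2 * G + 1)}
    p_diff = {k: 0.0 for k in range(0, G)}
    for i in idx:
        for j in idx:
            p_sum[i + j] += P[i - 1, j - 1]
            p_diff[abs(i - j)] += P[i - 1, j - 1]

    energy = sum(P[i - 1, j - 1] ** 2 for i in idx for j in idx)
    contrast = sum((i - j) ** 2 * P[i - 1, j - 1] for i in idx for j in idx)
    if sd_x > 0 and sd_y > 0:
        correlation = (sum(i * j * P[i - 1, j - 1] for i in idx for j in idx)
                       - mu_x * mu_y) / (sd_x * sd_y)
    else:
        correlation = 0.0
    variance = sum((i - mu_x) ** 2 * P[i - 1, j - 1] for i in idx for j in idx)
    idm = sum(P[i - 1, j - 1] / (1 + (i - j) ** 2) for i in idx for j in idx)
    sum_avg = sum(k * v for k, v in p_sum.items())
    sum_var = sum((k - sum_avg) ** 2 * v for k, v in p_sum.items())
    sum_ent = _ent2(p_sum.values())
    entropy = _ent2(P.ravel())
    diff_avg = sum(k * v for k, v in p_diff.items())
    diff_var = sum((k - diff_avg) ** 2 * v for k, v in p_diff.items())
    diff_ent = _ent2(p_diff.values())

    hxy1 = -sum(P[i - 1, j - 1] * math.log2(px[i - 1] * py[j - 1])
                for i in idx for j in idx
                if P[i - 1, j - 1] > 0 and px[i - 1] * py[j - 1] > 0)
    hxy2 = _ent2([px[i - 1] * py[j - 1] for i in idx for j in idx])
    hx, hy = _ent2(px), _ent2(py)
    imc1 = (entropy - hxy1) / max(hx, hy) if max(hx, hy) > 0 else 0.0
    imc2 = math.sqrt(max(0.0, 1.0 - math.exp(-2.0 * (hxy2 - entropy))))

    return {
        "Energy": energy, "Contrast": contrast, "Correlation": correlation,
        "Variance": variance, "Inverse Difference Moment": idm,
        "Sum Average": sum_avg, "Sum Variance": sum_var, "Sum Entropy": sum_ent,
        "Entropy": entropy, "Difference Variance": diff_var,
        "Difference Entropy": diff_ent,
        "Information Measure of Correlation 1": imc1,
        "Information Measure of Correlation 2": imc2,
    }


def pairwise_auc(scores, labels) -> float:
    """AUC as the all-pairs concordance fraction (ties count half)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    total = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                total += 1.0
            elif p == q:
                total += 0.5
    return total / (len(pos) * len(neg))


def naive_complete_linkage(X: np.ndarray) -> list[float]:
    """Merge heights of complete-linkage agglomeration, O(n^3), from scratch."""
    clusters: list[list[int]] = [[i] for i in range(len(X))]
    D = np.sqrt(((X[:, None, :] - X[None, :, :]) ** 2).sum(-1))
    heights = []
    while len(clusters) > 1:
        best = (None, None, np.inf)
        for a in range(len(clusters)):
            for b in range(a + 1, len(clusters)):
                d = max(D[i, j] for i in clusters[a] for j in clusters[b])
                if d < best[2]:
                    best = (a, b, d)
        a, b, d = best
        heights.append(d)
        clusters[a] = clusters[a] + clusters[b]
        del clusters[b]
    return heights


def exact_mannwhitney_p(a, b) -> float:
    """Two-sided exact Mann-Whitney p by full enumeration of assignments."""
    a = list(a)
    b = list(b)
    pooled = a + b
    na = len(a)

    def u_stat(sample_a, sample_b):
        u = 0.0
        for x in sample_a:
            for y in sample_b:
                if x > y:
                    u += 1
                elif x == y:
                    u += 0.5
        return u

    u_obs = u_stat(a, b)
    mu = na * len(b) / 2.0
    count = 0
    total = 0
    for comb in itertools.combinations(range(len(pooled)), na):
        sa = [pooled[i] for i in comb]
        sb = [pooled[i] for i in range(len(pooled)) if i not in comb]
        if abs(u_stat(sa, sb) - mu) >= abs(u_obs - mu) - 1e-12:
            count += 1
        total += 1
    return count / total


def kruskal_h_no_ties(samples) -> float:
    """Kruskal-Wallis H from rank arithmetic (assumes no ties)."""
    pooled = np.concatenate([np.asarray(s, dtype=float) for s in samples])
    ranks = {v: r + 1 for r, v in enumerate(sorted(pooled))}
    N = len(pooled)
    h = 0.0
    for s in samples:
        rbar = np.mean([ranks[v] for v in s])
        h += len(s) * (rbar - (N + 1) / 2.0) ** 2
    return 12.0 / (N * (N + 1)) * h
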