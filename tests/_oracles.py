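"""Independent brute-force reference implementations.

Deliberately naive: explicit Python loops, dictionary counting and
from-scratch formulas, sharing no code with the package, so they can
serve as oracles for the vectorized implementations on small inputs.
"""

from __future__ import annotations

import itertools
import math
from collections import Counter

import numpy as np
from scipy import stats


def quantize_oracle(values, n_levels):
    values = [float(v) for v in values]
    lo, hi = min(values), max(values)
    if hi == lo:
        return [1 for _ in values]
    out = []
    for v in values:
        q = int(math.floor((v - lo) / (hi - lo) * n_levels)) + 1
        out.append(min(max(q, 1), n_levels))
    return out


def first_order_oracle(image, roi_mask, n_levels=32):
    xs = [float(image[i][j]) for i in range(len(image)) for j in range(len(image[0]))
          if roi_mask[i][j]]
    n = len(xs)
    mean = sum(xs) / n
    var = sum((v - mean) ** 2 for v in xs) / n
    sd = math.sqrt(var)
    srt = sorted(xs)
    median = (srt[n // 2] if n % 2 else 0.5 * (srt[n // 2 - 1] + srt[n // 2]))
    levels = quantize_oracle(xs, n_levels)
    counts = Counter(levels)
    probs = [c / n for c in counts.values()]
    return {
        "fo_energy": sum(v * v for v in xs),
        "fo_entropy": -sum(p * math.log2(p) for p in probs),
        "fo_kurtosis": (sum((v - mean) ** 4 for v in xs) / n / var ** 2) if var > 0 else 0.0,
        "fo_maximum": max(xs),
        "fo_mean": mean,
        "fo_mad": sum(abs(v - mean) for v in xs) / n,
        "fo_median": median,
        "fo_minimum": min(xs),
        "fo_range": max(xs) - min(xs),
        "fo_rms": math.sqrt(sum(v * v for v in xs) / n),
        "fo_skewness": (sum((v - mean) ** 3 for v in xs) / n / sd ** 3) if var > 0 else 0.0,
        "fo_std": sd,
        "fo_uniformity": sum(p * p for p in probs),
        "fo_variance": var,
    }


def glcm_oracle(qimg, n_levels, directions):
    """Direction-averaged symmetric normalized GLCM by explicit pair listing."""
    h, w = len(qimg), len(qimg[0])
    mats = []
    for dy, dx in directions:
        c = Counter()
        for y in range(h):
            for x in range(w):
                y2, x2 = y + dy, x + dx
                if 0 <= y2 < h and 0 <= x2 < w and qimg[y][x] > 0 and qimg[y2][x2] > 0:
                    c[(qimg[y][x], qimg[y2][x2])] += 1
                    c[(qimg[y2][x2], qimg[y][x])] += 1
        total = sum(c.values())
        if total:
            mats.append({k: v / total for k, v in c.items()})
    p = Counter()
    for m in mats:
        for k, v in m.items():
            p[k] += v / len(mats)
    return dict(p)


def glcm_features_oracle(qimg, n_levels, directions):
    p = glcm_oracle(qimg, n_levels, directions)
    px = Counter()
    for (i, j), v in p.items():
        px[i] += v
    mu = sum(i * v for i, v in px.items())
    var = sum((i - mu) ** 2 * v for i, v in px.items())
    sd = math.sqrt(var)
    pdiff = Counter()
    psum = Counter()
    for (i, j), v in p.items():
        pdiff[abs(i - j)] += v
        psum[i + j] += v
    hxy = -sum(v * math.log2(v) for v in p.values() if v > 0)
    hx = -sum(v * math.log2(v) for v in px.values() if v > 0)
    hxy1 = -sum(v * math.log2(px[i] * px[j]) for (i, j), v in p.items()
                if px[i] * px[j] > 0)
    hxy2 = -sum(px[i] * px[j] * math.log2(px[i] * px[j])
                for i in px for j in px if px[i] * px[j] > 0)
    sum_avg = sum(k * v for k, v in psum.items())
    return {
        "glcm_autocorrelation": sum(i * j * v for (i, j), v in p.items()),
        "glcm_cluster_prominence": sum((i + j - 2 * mu) ** 4 * v for (i, j), v in p.items()),
        "glcm_cluster_shade": sum((i + j - 2 * mu) ** 3 * v for (i, j), v in p.items()),
        "glcm_contrast": sum((i - j) ** 2 * v for (i, j), v in p.items()),
        "glcm_correlation": ((sum(i * j * v for (i, j), v in p.items()) - mu * mu) / var
                             if var > 0 else 0.0),
        "glcm_difference_entropy": -sum(v * math.log2(v) for v in pdiff.values() if v > 0),
        "glcm_dissimilarity": sum(abs(i - j) * v for (i, j), v in p.items()),
        "glcm_energy": sum(v * v for v in p.values()),
        "glcm_entropy": hxy,
        "glcm_homogeneity": sum(v / (1 + abs(i - j)) for (i, j), v in p.items()),
        "glcm_imc1": (hxy - hxy1) / hx if hx > 0 else 0.0,
        "glcm_imc2": math.sqrt(max(1 - math.exp(-2 * (hxy2 - hxy)), 0.0)),
        "glcm_idmn": sum(v / (1 + (i - j) ** 2 / n_levels ** 2) for (i, j), v in p.items()),
        "glcm_max_probability": max(p.values()),
        "glcm_sum_average": sum_avg,
        "glcm_sum_entropy": -sum(v * math.log2(v) for v in psum.values() if v > 0),
        "glcm_sum_variance": sum((k - sum_avg) ** 2 * v for k, v in psum.items()),
        "glcm_variance": var,
        "glcm_inverse_variance": sum(v / (i - j) ** 2 for (i, j), v in p.items() if i != j),
    }


def glrlm_runs_oracle(qimg, directions):
    """All maximal constant runs, listed by explicit line walking."""
    h, w = len(qimg), len(qimg[0])
    all_runs = []
    for dy, dx in directions:
        runs = []
        # starting points: cells with no valid predecessor along (dy, dx)
        for y in range(h):
            for x in range(w):
                py, px_ = y - dy, x - dx
                if 0 <= py < h and 0 <= px_ < w:
                    continue
                line = []
                cy, cx = y, x
                while 0 <= cy < h and 0 <= cx < w:
                    line.append(qimg[cy][cx])
                    cy += dy
                    cx += dx
                i = 0
                while i < len(line):
                    j = i
                    while j < len(line) and line[j] == line[i]:
                        j += 1
                    if line[i] > 0:
                        runs.append((line[i], j - i))
                    i = j
        all_runs.append(runs)
    return all_runs


def glrlm_features_oracle(qimg, n_levels, directions, n_roi_pixels):
    per_dir = glrlm_runs_oracle(qimg, directions)
    r = Counter()
    for runs in per_dir:
        for level, length in runs:
            r[(level, length)] += 1 / len(per_dir)
    n_runs = sum(r.values())
    gl = Counter()
    rl = Counter()
    for (i, j), v in r.items():
        gl[i] += v
        rl[j] += v
    return {
        "glrlm_SRE": sum(v / j ** 2 for (i, j), v in r.items()) / n_runs,
        "glrlm_LRE": sum(v * j ** 2 for (i, j), v in r.items()) / n_runs,
        "glrlm_GLN": sum(v ** 2 for v in gl.values()) / n_runs,
        "glrlm_RLN": sum(v ** 2 for v in rl.values()) / n_runs,
        "glrlm_RP": n_runs / n_roi_pixels,
        "glrlm_LGLRE": sum(v / i ** 2 for (i, j), v in r.items()) / n_runs,
        "glrlm_HGLRE": sum(v * i ** 2 for (i, j), v in r.items()) / n_runs,
        "glrlm_SRLGLE": sum(v / (i ** 2 * j ** 2) for (i, j), v in r.items()) / n_runs,
        "glrlm_SRHGLE": sum(v * i ** 2 / j ** 2 for (i, j), v in r.items()) / n_runs,
        "glrlm_LRLGLE": sum(v * j ** 2 / i ** 2 for (i, j), v in r.items()) / n_runs,
        "glrlm_LRHGLE": sum(v * i ** 2 * j ** 2 for (i, j), v in r.items()) / n_runs,
    }


def ccc_oracle(x, y):
    n = len(x)
    mx, my = sum(x) / n, sum(y) / n
    vx = sum((v - mx) ** 2 for v in x) / n
    vy = sum((v - my) ** 2 for v in y) / n
    cov = sum((a - mx) * (b - my) for a, b in zip(x, y)) / n
    denom = vx + vy + (mx - my) ** 2
    return 1.0 if denom == 0 else 2 * cov / denom


def _avg_ranks(values):
    order = sorted(range(len(values)), key=lambda i: values[i])
    ranks = [0.0] * len(values)
    i = 0
    while i < len(order):
        j = i
        while j < len(order) and values[order[j]] == values[order[i]]:
            j += 1
        avg = (i + j + 1) / 2.0
        for k in range(i, j):
            ranks[order[k]] = avg
        i = j
    return ranks


def kruskal_oracle(groups):
    """H statistic with tie correction; chi-square p-value."""
    pooled = [v for g in groups for v in g]
    n = len(pooled)
    ranks = _avg_ranks(pooled)
    h = 0.0
    idx = 0
    for g in groups:
        rsum = sum(ranks[idx:idx + len(g)])
        h += rsum ** 2 / len(g)
        idx += len(g)
    h = 12.0 / (n * (n + 1)) * h - 3 * (n + 1)
    ties = Counter(pooled)
    correction = 1 - sum(t ** 3 - t for t in ties.values()) / (n ** 3 - n)
    h /= correction
    return h, float(stats.chi2.sf(h, len(groups) - 1))


def quade_oracle(table):
    """Quade F statistic and p-value from first principles."""
    n = len(table)
    k = len(table[0])
    r = [_avg_ranks(row) for row in table]
    ranges = [max(row) - min(row) for row in table]
    q = _avg_ranks(ranges)
    s = [[q[i] * (r[i][j] - (k + 1) / 2) for j in range(k)] for i in range(n)]
    a = sum(s[i][j] ** 2 for i in range(n) for j in range(k))
    b = sum(sum(s[i][j] for i in range(n)) ** 2 for j in range(k)) / n
    if a == 0:
        return 0.0, 1.0
    if a == b:
        return math.inf, 0.0
    f = (n - 1) * b / (a - b)
    return f, float(stats.f.sf(f, k - 1, (n - 1) * (k - 1)))


def wilson_oracle(successes, n, level=0.95):
    """Numeric inversion of the score test: the interval endpoints are the
    p where the score statistic equals the critical z."""
    from scipy.optimize import brentq

    z = stats.norm.ppf(0.5 + level / 2)
    phat = successes / n

    def score(p):
        return (phat - p) / math.sqrt(p * (1 - p) / n)

    eps = 1e-12
    lo = 0.0 if phat == 0 else brentq(lambda p: score(p) - z, eps, phat - eps if phat < 1 else 1 - eps)
    if phat == 0:
        lo = 0.0
    hi = 1.0 if phat == 1 else brentq(lambda p: score(p) + z, phat + eps if phat > 0 else eps, 1 - eps)
    if phat == 1:
        hi = 1.0
    return lo, hi


def multinomial_oracle(observed, probs):
    """Exact multinomial p by recursive enumeration with factorial pmf."""
    n = sum(observed)
    k = len(observed)

    def pmf(counts):
        coef = math.factorial(n)
        for c in counts:
            coef //= math.factorial(c)
        pr = float(coef)
        for c, p in zip(counts, probs):
            pr *= p ** c
        return pr

    p_obs = pmf(observed)
    total = 0.0
    for counts in itertools.product(range(n + 1), repeat=k - 1):
        if sum(counts) > n:
            continue
        full = list(counts) + [n - sum(counts)]
        pr = pmf(full)
        if pr <= p_obs * (1 + 1e-9):
            total += pr
    return min(total, 1.0)
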