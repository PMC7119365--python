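"""Independent brute-force oracles, deliberately written as literal
transcriptions of the defining formulas (no shared code with the package)."""

from __future__ import annotations

import math

import numpy as np


def tmm_factor_oracle(y_s, y_r, trim_m=0.30, trim_a=0.05):
    """Literal trimmed-mean-of-M-values factor of sample s against reference r.

    Explicit sorting-based trimming; returns the unscaled 2**weighted-mean.
    """
    y_s = np.asarray(y_s, float)
    y_r = np.asarray(y_r, float)
    n_s, n_r = y_s.sum(), y_r.sum()
    keep = (y_s > 0) & (y_r > 0)
    ys, yr = y_s[keep], y_r[keep]
    m = np.log2((ys / n_s) / (yr / n_r))
    a = 0.5 * np.log2((ys / n_s) * (yr / n_r))
    var = (n_s - ys) / (n_s * ys) + (n_r - yr) / (n_r * yr)
    n = len(m)
    lo_m = math.floor(n * trim_m) + 1
    hi_m = n + 1 - lo_m
    lo_a = math.floor(n * trim_a) + 1
    hi_a = n + 1 - lo_a
    # ranks via explicit sorting (1-based, ties broken by sort order)
    rank_m = np.empty(n)
    rank_m[np.argsort(m, kind="mergesort")] = np.arange(1, n + 1)
    rank_a = np.empty(n)
    rank_a[np.argsort(a, kind="mergesort")] = np.arange(1, n + 1)
    kept = (rank_m >= lo_m) & (rank_m <= hi_m) & (rank_a >= lo_a) & (rank_a <= hi_a)
    w = 1.0 / var[kept]
    return 2.0 ** (np.sum(w * m[kept]) / np.sum(w))


def tom_oracle(adj):
    """Naive O(n^3) unsigned topological overlap."""
    a = np.asarray(adj, float).copy()
    n = a.shape[0]
    for i in range(n):
        a[i, i] = 0.0
    k = a.sum(axis=1)
    tom = np.eye(n)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            l_ij = 0.0
            for u in range(n):
                if u != i and u != j:
                    l_ij += a[i, u] * a[u, j]
            tom[i, j] = (l_ij + a[i, j]) / (min(k[i], k[j]) + 1.0 - a[i, j])
    return tom


def bh_oracle(p):
    """Brute-force step-up adjustment: sort, scale by m/rank, enforce
    monotonicity from the largest p downward."""
    p = list(map(float, p))
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    scaled = [p[order[i]] * m / (i + 1) for i in range(m)]
    for i in range(m - 2, -1, -1):
        scaled[i] = min(scaled[i], scaled[i + 1])
    out = [0.0] * m
    for i, idx in enumerate(order):
        out[idx] = min(scaled[i], 1.0)
    return out


def hypergeom_sf_oracle(k, n_universe, n_term, n_study):
    """P(X >= k) by full pmf enumeration with exact integer binomials."""
    denom = math.comb(n_universe, n_study)
    total = 0
    for j in range(k, min(n_term, n_study) + 1):
        if n_study - j <= n_universe - n_term:
            total += math.comb(n_term, j) * math.comb(n_universe - n_term, n_study - j)
    return total / denom


def site_pi_oracle(alt_count, n_alleles):
    """Pairwise-difference fraction: differing pairs / all C(n,2) pairs."""
    a, n = int(alt_count), int(n_alleles)
    if n < 2:
        return float("nan")
    return a * (n - a) / (n * (n - 1) / 2)


def wc_fst_site_oracle(n1, p1, h1, n2, p2, h2):
    """Weir & Cockerham two-population a, b, c components for one site,
    written as explicit scalar arithmetic."""
    r = 2
    nbar = (n1 + n2) / r
    nc = (r * nbar - (n1 * n1 + n2 * n2) / (r * nbar)) / (r - 1)
    pbar = (n1 * p1 + n2 * p2) / (r * nbar)
    s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1) * nbar)
    hbar = (n1 * h1 + n2 * h2) / (r * nbar)
    a = (nbar / nc) * (
        s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4) / (nbar - 1)
    )
    b = (nbar / (nbar - 1)) * (
        pbar * (1 - pbar)
        - (r - 1) / r * s2
        - (2 * nbar - 1) / (4 * nbar) * hbar
    )
    c = hbar / 2
    return a, b, c


def hudson_fst_site_oracle(n1, p1, n2, p2):
    """Bhatia-form Hudson estimator numerator and denominator for one site."""
    num = (
        (p1 - p2) ** 2
        - p1 * (1 - p1) / (n1 - 1)
        - p2 * (1 - p2) / (n2 - 1)
    )
    den = p1 * (1 - p2) + p2 * (1 - p1)
    return num, den


def scale_free_fit_oracle(k, n_bins=10):
    """Independent log-log fit of the connectivity histogram (equal-width
    bins, least squares by normal equations)."""
    k = np.asarray(k, float)
    lo, hi = k.min(), k.max() + 1e-12
    width = (hi - lo) / n_bins
    xs, ys = [], []
    for b in range(n_bins):
        mask = (k >= lo + b * width) & (k < lo + (b + 1) * width)
        if b == n_bins - 1:
            mask = (k >= lo + b * width) & (k <= hi)
        if mask.sum() == 0:
            continue
        mk = k[mask].mean()
        if mk <= 0:
            continue
        xs.append(math.log10(mk))
        ys.append(math.log10(mask.mean()))
    if len(xs) < 3:
        return 0.0, 0.0
    xs, ys = np.asarray(xs), np.asarray(ys)
    xbar, ybar = xs.mean(), ys.mean()
    slope = ((xs - xbar) * (ys - ybar)).sum() / ((xs - xbar) ** 2).sum()
    intercept = ybar - slope * xbar
    resid = ys - (slope * xs + intercept)
    ss_tot = ((ys - ybar) ** 2).sum()
    r2 = 1.0 - (resid**2).sum() / ss_tot if ss_tot > 0 else 0.0
    if slope > 0:
        r2 = 0.0
    return r2, slope
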