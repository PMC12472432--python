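"""Independent brute-force oracles used to cross-check the implementation.

Everything here is written straight from the defining formulas with plain
loops (or, for spectra, a direct FFT), deliberately avoiding the code
paths of the package itself.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
from scipy.stats import f as f_dist


# ---------------------------------------------------------------- features

def tod_oracle(ap, ml):
    am = sum(ap) / len(ap)
    mm = sum(ml) / len(ml)
    return sum(
        math.sqrt((a - am) ** 2 + (m - mm) ** 2) for a, m in zip(ap, ml)
    )


def std_oracle(x):
    n = len(x)
    mean = sum(x) / n
    return math.sqrt(sum((v - mean) ** 2 for v in x) / (n - 1))


def rms_oracle(x):
    return math.sqrt(sum(v**2 for v in x) / len(x))


def amplitude_oracle(x):
    return max(x) - min(x)


def velocity_oracle(x, fs):
    total = sum(abs(x[i + 1] - x[i]) for i in range(len(x) - 1))
    return total * fs / (len(x) - 1)


def total_velocity_oracle(ap, ml, fs):
    total = sum(
        math.sqrt((ap[i + 1] - ap[i]) ** 2 + (ml[i + 1] - ml[i]) ** 2)
        for i in range(len(ap) - 1)
    )
    return total * fs / (len(ap) - 1)


def ellipse_area_oracle(ap, ml, multiplier):
    n = len(ap)
    am = sum(ap) / n
    mm = sum(ml) / n
    saa = sum((a - am) ** 2 for a in ap) / (n - 1)
    smm = sum((m - mm) ** 2 for m in ml) / (n - 1)
    sam = sum((a - am) * (m - mm) for a, m in zip(ap, ml)) / (n - 1)
    det = saa * smm - sam**2
    if det <= 0:
        return 0.0
    return math.pi * multiplier * math.sqrt(det)


def band_powers_oracle(x, fs):
    """LF/MF/HF density sums from a raw one-sided FFT periodogram."""
    x = np.asarray(x, dtype=float)
    n = len(x)
    X = np.fft.rfft(x)
    p = (np.abs(X) ** 2) / (fs * n)
    p[1:] *= 2
    if n % 2 == 0:
        p[-1] /= 2
    f = np.fft.rfftfreq(n, d=1 / fs)
    lf = p[(f >= 0.01) & (f <= 0.1)].sum()
    mf = p[(f > 0.1) & (f <= 0.5)].sum()
    hf = p[(f > 0.5) & (f <= 1.0)].sum()
    return lf, mf, hf


# ------------------------------------------------------------------- stats

def median_iqr_oracle(values):
    """Sort-and-interpolate median and IQR (linear interpolation)."""
    s = sorted(values)
    n = len(s)

    def quantile(q):
        pos = q * (n - 1)
        lo = int(math.floor(pos))
        hi = min(lo + 1, n - 1)
        frac = pos - lo
        return s[lo] * (1 - frac) + s[hi] * frac

    return quantile(0.5), quantile(0.75) - quantile(0.25)


def mann_whitney_enumeration(x, y):
    """Exact two-sided Mann-Whitney p by full enumeration (no ties)."""
    pooled = list(x) + list(y)
    order = sorted(range(len(pooled)), key=lambda i: pooled[i])
    ranks = [0.0] * len(pooled)
    for r, i in enumerate(order, start=1):
        ranks[i] = float(r)
    nx = len(x)
    u_obs = sum(ranks[:nx]) - nx * (nx + 1) / 2
    us = []
    for combo in itertools.combinations(range(len(pooled)), nx):
        u = sum(ranks[i] for i in combo) - nx * (nx + 1) / 2
        us.append(u)
    n_le = sum(1 for u in us if u <= u_obs)
    n_ge = sum(1 for u in us if u >= u_obs)
    p = 2 * min(n_le, n_ge) / len(us)
    return u_obs, min(1.0, p)


def bh_step_up_oracle(p):
    """Benjamini-Hochberg adjusted values by the literal step-up recipe."""
    p = list(p)
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    adjusted = [0.0] * m
    running_min = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        val = min(1.0, p[i] * m / rank_from_top)
        running_min = min(running_min, val)
        adjusted[i] = running_min
    return adjusted


def levene_oracle(x, y):
    """Levene W (mean-centred |deviations| one-way ANOVA) and p."""
    groups = [list(x), list(y)]
    k = len(groups)
    z = []
    for g in groups:
        mean = sum(g) / len(g)
        z.append([abs(v - mean) for v in g])
    n_total = sum(len(g) for g in z)
    zbar = sum(sum(g) for g in z) / n_total
    zbar_i = [sum(g) / len(g) for g in z]
    num = sum(len(g) * (zi - zbar) ** 2 for g, zi in zip(z, zbar_i))
    den = sum(
        sum((v - zi) ** 2 for v in g) for g, zi in zip(z, zbar_i)
    )
    w = (n_total - k) / (k - 1) * num / den
    p = float(f_dist.sf(w, k - 1, n_total - k))
    return w, p


# ---------------------------------------------------------------- classify

def auc_pairwise_oracle(y_true, scores):
    """AUC as the fraction of (pos, neg) pairs ranked correctly (ties 1/2)."""
    pos = [s for t, s in zip(y_true, scores) if t == 1]
    neg = [s for t, s in zip(y_true, scores) if t == 0]
    wins = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                wins += 1.0
            elif p == q:
                wins += 0.5
    return wins / (len(pos) * len(neg))


def percentile_bootstrap_oracle(values, B, seed):
    """Percentile bootstrap with the same index stream, loop-computed.

    The resample index draw is shared with the implementation (one
    ``integers`` call of shape (B, n)); the mean/percentile summary is
    recomputed from scratch with sorted-list interpolation.
    """
    values = list(map(float, values))
    n = len(values)
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, n, size=(B, n))
    means = sorted(
        sum(values[j] for j in row) / n for row in idx
    )

    def quantile(q):
        pos = q * (B - 1)
        lo = int(math.floor(pos))
        hi = min(lo + 1, B - 1)
        frac = pos - lo
        return means[lo] * (1 - frac) + means[hi] * frac

    return sum(values) / n, quantile(0.025), quantile(0.975)


def spearman_closed_form(a, b):
    """Tie-free Spearman rho: 1 - 6*sum(d^2) / (n(n^2-1))."""
    n = len(a)
    ra = {i: r for r, i in enumerate(sorted(range(n), key=lambda i: a[i]), 1)}
    rb = {i: r for r, i in enumerate(sorted(range(n), key=lambda i: b[i]), 1)}
    d2 = sum((ra[i] - rb[i]) ** 2 for i in range(n))
    return 1 - 6 * d2 / (n * (n**2 - 1))


def point_segment_distance(p, a, b):
    """Euclidean distance from point p to segment [a, b]."""
    p, a, b = (np.asarray(v, dtype=float) for v in (p, a, b))
    ab = b - a
    denom = float(ab @ ab)
    if denom == 0:
        return float(np.linalg.norm(p - a))
    t = float(np.clip((p - a) @ ab / denom, 0.0, 1.0))
    return float(np.linalg.norm(p - (a + t * ab)))
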