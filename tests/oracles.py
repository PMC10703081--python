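"""Independent brute-force reference implementations used as test oracles.

Everything here is written from the definitions, not from the package code:
loops over explicit formulas, no shared helpers with src/.
"""

from __future__ import annotations

import math

import numpy as np
from scipy import stats


def ivw_oracle(bx, sx, by, sy):
    """IVW as the inverse-variance weighted mean of Wald ratios
    (first-order weights), with multiplicative SE inflation floored at 1."""
    ratios = [b / a for a, b in zip(bx, by)]
    weights = [(a / s) ** 2 for a, s in zip(bx, sy)]
    est = sum(w * r for w, r in zip(weights, ratios)) / sum(weights)
    se = 1.0 / math.sqrt(sum(weights))
    q = sum(w * (r - est) ** 2 for w, r in zip(weights, ratios))
    df = len(ratios) - 1
    if df > 0:
        se *= max(1.0, math.sqrt(q / df))
    return est, se, q


def egger_oracle(bx, sx, by, sy):
    """Weighted least squares with intercept via explicit normal equations
    (no orientation; see :func:`egger_oracle_oriented`)."""
    w = [1.0 / s**2 for s in sy]
    sw = sum(w)
    swx = sum(wi * xi for wi, xi in zip(w, bx))
    swxx = sum(wi * xi * xi for wi, xi in zip(w, bx))
    swy = sum(wi * yi for wi, yi in zip(w, by))
    swxy = sum(wi * xi * yi for wi, xi, yi in zip(w, bx, by))
    det = sw * swxx - swx**2
    intercept = (swxx * swy - swx * swxy) / det
    slope = (sw * swxy - swx * swy) / det
    return slope, intercept


def egger_oracle_oriented(bx, by, sy):
    """Egger slope/intercept after SNP-wise orientation (sign of bx)."""
    bx2, by2 = [], []
    for x, y in zip(bx, by):
        if x < 0:
            bx2.append(-x)
            by2.append(-y)
        else:
            bx2.append(x)
            by2.append(y)
    return egger_oracle(bx2, None, by2, sy)


def weighted_median_oracle(values, weights):
    """Interpolated weighted median by a literal cumulative-weight scan."""
    pairs = sorted(zip(values, weights))
    values = [v for v, _ in pairs]
    total = sum(w for _, w in pairs)
    weights = [w / total for _, w in pairs]
    cum = []
    running = 0.0
    for w in weights:
        cum.append(running + w / 2.0)
        running += w
    if 0.5 <= cum[0]:
        return values[0]
    if 0.5 >= cum[-1]:
        return values[-1]
    for i in range(len(cum) - 1):
        if cum[i] <= 0.5 <= cum[i + 1]:
            frac = (0.5 - cum[i]) / (cum[i + 1] - cum[i])
            return values[i] + frac * (values[i + 1] - values[i])
    raise AssertionError("unreachable")


def contamination_oracle(ratios, ratio_ses, psi, grid):
    """Profile log-likelihood over an explicit double loop."""
    best_theta, best_ll = None, -math.inf
    lls = []
    for theta in grid:
        ll = 0.0
        for r, s in zip(ratios, ratio_ses):
            valid = stats.norm.logpdf(r, loc=theta, scale=s)
            invalid = stats.norm.logpdf(r, loc=0.0, scale=math.sqrt(s**2 + psi**2))
            ll += max(valid, invalid)
        lls.append(ll)
        if ll > best_ll:
            best_theta, best_ll = theta, ll
    return best_theta, np.array(lls)


def clump_oracle(rows, r2_lookup, r2_threshold, window_bp):
    """Literal greedy clumping over (variant_id, chrom, pos, p) tuples.

    ``r2_lookup(a, b)`` returns r^2 or None when unknown.
    """
    remaining = sorted(rows, key=lambda r: (r[3], r[1], r[2], r[0]))
    kept = []
    while remaining:
        index = remaining.pop(0)
        kept.append(index[0])
        survivors = []
        for row in remaining:
            r2 = r2_lookup(index[0], row[0])
            close = row[1] == index[1] and abs(row[2] - index[2]) <= window_bp
            if r2 is not None and r2 >= r2_threshold and close:
                continue
            survivors.append(row)
        remaining = survivors
    return kept


def bh_oracle(p_values):
    """Literal Benjamini-Hochberg step-up: adjusted_(i) = min_{j>=i} p_(j) m / j."""
    m = len(p_values)
    indexed = sorted(range(m), key=lambda i: p_values[i])
    adjusted = [0.0] * m
    for rank_pos, i in enumerate(indexed, start=1):
        candidates = []
        for j_pos in range(rank_pos, m + 1):
            pj = p_values[indexed[j_pos - 1]]
            candidates.append(pj * m / j_pos)
        adjusted[i] = min(1.0, min(candidates))
    return adjusted
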