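"""Independent brute-force oracles used to validate the implementations.

Everything here is deliberately naive: exact rational arithmetic and
explicit enumeration, sharing no code with the package.
"""

from __future__ import annotations

import itertools
from fractions import Fraction
from math import comb

import numpy as np


def fisher2x2_oracle(table) -> Fraction:
    """Two-sided Fisher p by exhaustive enumeration with exact rationals."""
    (a, b), (c, d) = table
    r0, r1 = a + b, c + d
    c0 = a + c
    n = r0 + r1

    def prob(x: int) -> Fraction:
        return Fraction(comb(r0, x) * comb(r1, c0 - x), comb(n, c0))

    p_obs = prob(a)
    total = Fraction(0)
    for x in range(max(0, c0 - r1), min(r0, c0) + 1):
        p = prob(x)
        if p <= p_obs:
            total += p
    return total


def freeman_halton_oracle(table) -> Fraction:
    """R×C exact test by full enumeration with exact rationals."""
    arr = np.asarray(table, dtype=int)
    rows = arr.sum(axis=1)
    cols = arr.sum(axis=0)
    n = int(arr.sum())

    def multinom(ks) -> int:
        out, rem = 1, sum(ks)
        for k in ks:
            out *= comb(rem, k)
            rem -= k
        return out

    def prob(t: np.ndarray) -> Fraction:
        num = 1
        for r in t:
            num *= multinom(list(r))
        den = multinom(list(cols))
        return Fraction(num, den)

    def row_fills(total, col_rem):
        if len(col_rem) == 1:
            if total <= col_rem[0]:
                yield (total,)
            return
        for v in range(min(total, col_rem[0]) + 1):
            for rest in row_fills(total - v, col_rem[1:]):
                yield (v,) + rest

    def tables(row_idx, col_rem):
        if row_idx == len(rows):
            if all(x == 0 for x in col_rem):
                yield ()
            return
        for fill in row_fills(int(rows[row_idx]), tuple(col_rem)):
            new_rem = tuple(c - f for c, f in zip(col_rem, fill))
            if any(x < 0 for x in new_rem):
                continue
            for rest in tables(row_idx + 1, new_rem):
                yield (fill,) + rest

    p_obs = prob(arr)
    total = Fraction(0)
    for t in tables(0, tuple(int(c) for c in cols)):
        p = prob(np.asarray(t))
        if p <= p_obs:
            total += p
    return total


def auc_pairs_oracle(scores, labels) -> float:
    """AUC as explicit all-pairs concordance with ties counting one half."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    total = 0.0
    for sp, sn in itertools.product(pos, neg):
        if sp > sn:
            total += 1.0
        elif sp == sn:
            total += 0.5
    return total / (len(pos) * len(neg))


def tukey_fences_oracle(values):
    """Outlier labels by direct fence arithmetic (type-7 quartiles)."""
    arr = np.sort(np.asarray(values, dtype=float))
    n = len(arr)

    def quantile(q):
        h = (n - 1) * q
        lo = int(np.floor(h))
        hi = min(lo + 1, n - 1)
        return arr[lo] + (h - lo) * (arr[hi] - arr[lo])

    q1, q3 = quantile(0.25), quantile(0.75)
    iqr = q3 - q1
    out = []
    for v in np.asarray(values, dtype=float):
        if v < q1 - 3 * iqr or v > q3 + 3 * iqr:
            out.append("extreme")
        elif v < q1 - 1.5 * iqr or v > q3 + 1.5 * iqr:
            out.append("mild")
        else:
            out.append("inlier")
    return out
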