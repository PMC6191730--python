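"""Independent brute-force oracles used to validate the statistics code.

These deliberately use exact rational arithmetic or naive enumeration and
share no code with the implementations they check.
"""

from fractions import Fraction
from math import comb

import numpy as np


def fisher_p_exact(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher p by exact rational enumeration of all tables
    with the observed margins (sum of probabilities <= observed)."""
    n = a + b + c + d
    r1, c1 = a + b, a + c
    denom = comb(n, c1)
    p_obs = Fraction(comb(r1, a) * comb(n - r1, c1 - a), denom)
    total = Fraction(0)
    for k in range(max(0, c1 - (n - r1)), min(r1, c1) + 1):
        p_k = Fraction(comb(r1, k) * comb(n - r1, c1 - k), denom)
        if p_k <= p_obs:
            total += p_k
    return float(total)


def auc_pairwise(scores, labels) -> float:
    """AUC by exhaustive pair counting; ties count one half."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    pos = scores[labels]
    neg = scores[~labels]
    wins = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                wins += 1.0
            elif p == q:
                wins += 0.5
    return wins / (len(pos) * len(neg))


def slope_se_closed_form(x, y):
    """Least-squares slope and SE from the direct textbook sums."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    xbar, ybar = x.mean(), y.mean()
    sxx = ((x - xbar) ** 2).sum()
    slope = ((x - xbar) * (y - ybar)).sum() / sxx
    intercept = ybar - slope * xbar
    resid = y - intercept - slope * x
    s2 = (resid**2).sum() / (n - 2)
    return slope, np.sqrt(s2 / sxx)
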