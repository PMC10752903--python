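"""Independent oracles used by the test suite.

Everything here is deliberately brute-force and kept independent of the
package's implementation paths: exact rational-arithmetic enumeration of the
rank-statistic permutation moments, closed-form spherical cell areas, and an
explicit normal-equations least-squares solver.
"""

from __future__ import annotations

from fractions import Fraction
from itertools import combinations

import numpy as np

EARTH_RADIUS_M = 6.371e6


def exact_midranks(values) -> list:
    """Midranks of a sequence as exact Fractions."""
    n = len(values)
    order = sorted(range(n), key=lambda i: values[i])
    ranks = [Fraction(0)] * n
    i = 0
    while i < n:
        j = i
        while j + 1 < n and values[order[j + 1]] == values[order[i]]:
            j += 1
        avg = Fraction((i + 1) + (j + 1), 2)
        for k in range(i, j + 1):
            ranks[order[k]] = avg
        i = j + 1
    return ranks


def ansari_scores(ranks, n) -> list:
    return [min(r, Fraction(n + 1) - r) for r in ranks]


def enumeration_moments(values, n1):
    """Exact mean and variance of W and A over all C(n, n1) label
    assignments (rational arithmetic).

    Returns (E_W, V_W, E_A, V_A) as Fractions.
    """
    n = len(values)
    ranks = exact_midranks(values)
    ab = ansari_scores(ranks, n)

    def moments(scores):
        sums = [sum(scores[i] for i in combo) for combo in combinations(range(n), n1)]
        m = len(sums)
        mean = sum(sums, Fraction(0)) / m
        var = sum((s - mean) ** 2 for s in sums) / m
        return mean, var

    e_w, v_w = moments(ranks)
    e_a, v_a = moments(ab)
    return e_w, v_w, e_a, v_a


def hk_oracle(sample1, sample2) -> float:
    """Lepage HK computed entirely from the enumeration oracle."""
    pooled = list(sample1) + list(sample2)
    n1 = len(sample1)
    n = len(pooled)
    ranks = exact_midranks(pooled)
    ab = ansari_scores(ranks, n)
    w = sum(ranks[:n1], Fraction(0))
    a = sum(ab[:n1], Fraction(0))
    e_w, v_w, e_a, v_a = enumeration_moments(pooled, n1)
    return float((w - e_w) ** 2 / v_w + (a - e_a) ** 2 / v_a)


def exhaustive_hk_pvalue(sample1, sample2) -> float:
    """Exact permutation p-value of HK by full enumeration of splits."""
    pooled = list(sample1) + list(sample2)
    n1 = len(sample1)
    n = len(pooled)
    ranks = exact_midranks(pooled)
    ab = ansari_scores(ranks, n)
    e_w, v_w, e_a, v_a = enumeration_moments(pooled, n1)

    def hk(indices):
        w = sum(ranks[i] for i in indices)
        a = sum(ab[i] for i in indices)
        return (w - e_w) ** 2 / v_w + (a - e_a) ** 2 / v_a

    observed = hk(range(n1))
    splits = list(combinations(range(n), n1))
    count = sum(1 for c in splits if hk(c) >= observed)
    return count / len(splits)


def textbook_tie_free_moments(n1, n2):
    """Published closed forms for untied data (even/odd n for A)."""
    n = n1 + n2
    e_w = Fraction(n1 * (n + 1), 2)
    v_w = Fraction(n1 * n2 * (n + 1), 12)
    if n % 2 == 0:
        e_a = Fraction(n1 * (n + 2), 4)
        v_a = Fraction(n1 * n2 * (n + 2) * (n - 2), 48 * (n - 1))
    else:
        e_a = Fraction(n1 * (n + 1) ** 2, 4 * n)
        v_a = Fraction(n1 * n2 * (n + 1) * (3 + n ** 2), 48 * n ** 2)
    return e_w, v_w, e_a, v_a


def spherical_cell_area(lat_center, dlat, dlon) -> float:
    """Closed-form area (m^2) of a lat-lon cell centered at lat_center."""
    lat1 = np.deg2rad(lat_center - dlat / 2)
    lat2 = np.deg2rad(lat_center + dlat / 2)
    return EARTH_RADIUS_M ** 2 * np.deg2rad(dlon) * (np.sin(lat2) - np.sin(lat1))


def normal_equations_fit(x_matrix, y):
    """OLS with intercept via explicit normal equations."""
    design = np.column_stack([np.ones(len(y)), x_matrix])
    return np.linalg.solve(design.T @ design, design.T @ y)


def pearson_oracle(x, y) -> float:
    """Correlation via the explicit covariance formula."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    xm = x - x.mean()
    ym = y - y.mean()
    return float(np.sum(xm * ym) / np.sqrt(np.sum(xm ** 2) * np.sum(ym ** 2)))
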