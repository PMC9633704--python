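"""Independent oracle implementations used to cross-check the package.

Everything here is deliberately written from first principles (explicit
loops, recursion, exhaustive enumeration) and stays independent of the
code paths it validates.
"""

from __future__ import annotations

import math
from itertools import combinations


def sample_entropy_bruteforce(x, m: int = 1, r_coeff: float = 0.2) -> float:
    """SampEn by explicit double loop over all template pairs.

    B counts ordered pairs of length-m templates within Chebyshev
    tolerance r = r_coeff * sd; A the same for length m+1; result is
    -ln(A/B). NaN when either count is zero.
    """
    n = len(x)
    mu = sum(x) / n
    sd = math.sqrt(sum((v - mu) ** 2 for v in x) / n)
    if sd == 0:
        return 0.0
    r = r_coeff * sd

    def count(length):
        total = 0
        n_tpl = n - length + 1
        for i in range(n_tpl):
            for j in range(n_tpl):
                if i == j:
                    continue
                dist = max(abs(x[i + k] - x[j + k]) for k in range(length))
                if dist <= r:
                    total += 1
        return total

    b = count(m)
    a = count(m + 1)
    if a == 0 or b == 0:
        return float("nan")
    return -math.log(a / b)


def nsrps_recursive(seq: list[int], alphabet: int | None = None) -> int:
    """Effort-to-compress by an independently coded recursive NSRPS.

    Counts pair frequencies with a plain dictionary scan, substitutes the
    most frequent pair (earliest occurrence breaking ties) and recurses
    until the sequence is constant or a single symbol.
    """
    if alphabet is None:
        alphabet = max(seq) + 1
    if len(seq) <= 1 or all(s == seq[0] for s in seq):
        return 0
    pairs: dict[tuple[int, int], list[int]] = {}
    for i in range(len(seq) - 1):
        pairs.setdefault((seq[i], seq[i + 1]), []).append(i)
    best = None
    for pair, pos in pairs.items():
        key = (-len(pos), pos[0])
        if best is None or key < best[0]:
            best = (key, pair)
    target = best[1]
    out = []
    i = 0
    while i < len(seq):
        if i + 1 < len(seq) and (seq[i], seq[i + 1]) == target:
            out.append(alphabet)
            i += 2
        else:
            out.append(seq[i])
            i += 1
    return 1 + nsrps_recursive(out, alphabet + 1)


def weighted_pearson_sums(x, y, w) -> float:
    """Weighted Pearson by explicit accumulation of weighted moments."""
    sw = sum(w)
    mx = sum(wi * xi for wi, xi in zip(w, x)) / sw
    my = sum(wi * yi for wi, yi in zip(w, y)) / sw
    cov = sum(wi * (xi - mx) * (yi - my) for wi, xi, yi in zip(w, x, y)) / sw
    vx = sum(wi * (xi - mx) ** 2 for wi, xi in zip(w, x)) / sw
    vy = sum(wi * (yi - my) ** 2 for wi, yi in zip(w, y)) / sw
    return cov / math.sqrt(vx * vy)


def ranksum_exact_z(a, b) -> float:
    """z statistic of the rank-sum test from exhaustive permutation.

    The mean and sd of the first group's rank sum are computed over all
    C(n1+n2, n1) assignments (exact, ties included).
    """
    combined = list(a) + list(b)
    n1 = len(a)
    order = sorted(range(len(combined)), key=lambda i: combined[i])
    ranks = [0.0] * len(combined)
    i = 0
    while i < len(order):
        j = i
        while j + 1 < len(order) and combined[order[j + 1]] == combined[order[i]]:
            j += 1
        avg = (i + j) / 2.0 + 1.0
        for k in range(i, j + 1):
            ranks[order[k]] = avg
        i = j + 1
    sums = [sum(ranks[i] for i in idx)
            for idx in combinations(range(len(combined)), n1)]
    mean = sum(sums) / len(sums)
    var = sum((s - mean) ** 2 for s in sums) / len(sums)
    w = sum(ranks[:n1])
    if var == 0:
        return 0.0
    return (w - mean) / math.sqrt(var)


def logistic_newton(x, y, max_iter: int = 200, tol: float = 1e-12):
    """Plain-Newton MLE of binary logistic regression with intercept.

    Returns (intercept, slope) for P(y=1) = logistic(a + b*x).
    """
    a, b = 0.0, 0.0
    for _ in range(max_iter):
        g_a = g_b = 0.0
        h_aa = h_ab = h_bb = 0.0
        for xi, yi in zip(x, y):
            p = 1.0 / (1.0 + math.exp(-(a + b * xi)))
            g_a += yi - p
            g_b += (yi - p) * xi
            w = p * (1 - p)
            h_aa += w
            h_ab += w * xi
            h_bb += w * xi * xi
        det = h_aa * h_bb - h_ab * h_ab
        da = (h_bb * g_a - h_ab * g_b) / det
        db = (h_aa * g_b - h_ab * g_a) / det
        a += da
        b += db
        if abs(da) < tol and abs(db) < tol:
            break
    return a, b
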