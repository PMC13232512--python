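"""Independent brute-force oracles used to cross-check the implementation.

Everything here is deliberately written from first principles (plain Python,
``math.comb``, explicit loops) and never calls into the package, so a test
comparing the two routes genuinely checks the implementation.
"""

from __future__ import annotations

import math


def wc_theta(n1: int, ac1: int, het1: int, n2: int, ac2: int, het2: int) -> float:
    """Scalar Weir & Cockerham (1984) theta from the published equations."""
    r = 2
    n = [n1, n2]
    p = [ac1 / (2 * n1), ac2 / (2 * n2)]
    h = [het1 / n1, het2 / n2]
    nbar = sum(n) / r
    nc = (r * nbar - sum(ni * ni for ni in n) / (r * nbar)) / (r - 1)
    pbar = sum(ni * pi for ni, pi in zip(n, p)) / (r * nbar)
    s2 = sum(ni * (pi - pbar) ** 2 for ni, pi in zip(n, p)) / ((r - 1) * nbar)
    hbar = sum(ni * hi for ni, hi in zip(n, h)) / (r * nbar)
    a = nbar / nc * (
        s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4) / (nbar - 1)
    )
    b = nbar / (nbar - 1) * (
        pbar * (1 - pbar) - (r - 1) / r * s2 - (2 * nbar - 1) / (4 * nbar) * hbar
    )
    c = hbar / 2
    den = a + b + c
    return a / den if den != 0 else float("nan")


def binom_upper_tail(k: int, n: int, p: float) -> float:
    """P(X >= k) for X ~ Binomial(n, p) by term-by-term summation."""
    return sum(
        math.comb(n, i) * p**i * (1 - p) ** (n - i) for i in range(k, n + 1)
    )


def _hypergeom_pmf(a: int, r1: int, r2: int, c1: int) -> float:
    """P(top-left cell = a) for fixed margins (r1, r2 rows; c1 first column)."""
    n = r1 + r2
    return math.comb(r1, a) * math.comb(r2, c1 - a) / math.comb(n, c1)


def fisher_two_sided(table) -> float:
    """Two-sided Fisher exact P by enumerating all tables with fixed margins.

    Uses the standard convention: sum the probabilities of every table whose
    point probability is at most that of the observed table (with a small
    relative tolerance for floating-point ties).
    """
    (a, b), (c, d) = table
    r1, r2, c1 = a + b, c + d, a + c
    lo = max(0, c1 - r2)
    hi = min(r1, c1)
    p_obs = _hypergeom_pmf(a, r1, r2, c1)
    total = 0.0
    for x in range(lo, hi + 1):
        p = _hypergeom_pmf(x, r1, r2, c1)
        if p <= p_obs * (1 + 1e-9):
            total += p
    return min(total, 1.0)


def _ranks(values) -> list[float]:
    """Average ranks (1-based) with midrank ties."""
    order = sorted(range(len(values)), key=lambda i: values[i])
    ranks = [0.0] * len(values)
    i = 0
    while i < len(order):
        j = i
        while j + 1 < len(order) and values[order[j + 1]] == values[order[i]]:
            j += 1
        avg = (i + j) / 2 + 1
        for k in range(i, j + 1):
            ranks[order[k]] = avg
        i = j + 1
    return ranks


def pearson_r(x, y) -> float:
    """Pearson correlation from raw moment sums."""
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    sxy = sum((xi - mx) * (yi - my) for xi, yi in zip(x, y))
    sxx = sum((xi - mx) ** 2 for xi in x)
    syy = sum((yi - my) ** 2 for yi in y)
    return sxy / math.sqrt(sxx * syy)


def spearman_rho(x, y) -> float:
    """Spearman correlation as the Pearson correlation of average ranks."""
    return pearson_r(_ranks(list(x)), _ranks(list(y)))


def welch_t(a, b) -> float:
    """Welch two-sample t statistic from the textbook formula."""
    na, nb = len(a), len(b)
    ma = sum(a) / na
    mb = sum(b) / nb
    va = sum((x - ma) ** 2 for x in a) / (na - 1)
    vb = sum((x - mb) ** 2 for x in b) / (nb - 1)
    return (ma - mb) / math.sqrt(va / na + vb / nb)


def mean_pairwise_diff(haplotypes) -> float:
    """Average pairwise difference per site over a list of 0/1 haplotypes."""
    n = len(haplotypes)
    n_sites = len(haplotypes[0])
    total = 0
    pairs = 0
    for i in range(n):
        for j in range(i + 1, n):
            total += sum(
                1 for s in range(n_sites) if haplotypes[i][s] != haplotypes[j][s]
            )
            pairs += 1
    return total / pairs / n_sites
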