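"""Independent, loop-based reference implementations used as test oracles.

Everything here is deliberately written as slow per-site Python loops, kept
separate from the vectorized library code paths it checks.
"""

from __future__ import annotations

import math
from collections import Counter


def naive_d(py, pz, pw, px):
    num = den = 0.0
    n = 0
    for a, b, c, d in zip(py, pz, pw, px):
        if any(math.isnan(v) for v in (a, b, c, d)):
            continue
        num += (a - b) * (c - d)
        den += (a + b - 2 * a * b) * (c + d - 2 * c * d)
        n += 1
    if n == 0 or den == 0:
        return float("nan")
    return num / den


def naive_fd(py, pz, pw, px):
    d = naive_d(py, pz, pw, px)
    if math.isnan(d):
        return float("nan")
    if d == 0:
        return 0.0
    num = den = 0.0
    for a, b, c, dd in zip(py, pz, pw, px):
        if any(math.isnan(v) for v in (a, b, c, dd)):
            continue
        num += (a - b) * (c - dd)
        if d > 0:
            den += max((dd - a) * (dd - c), (b - a) * (b - c))
        else:
            den += max((dd - b) * (dd - c), (a - b) * (a - c))
    if den == 0:
        return float("nan")
    return num / den


def naive_f3(pz, px, py):
    terms = [
        (z - x) * (z - y)
        for z, x, y in zip(pz, px, py)
        if not any(math.isnan(v) for v in (z, x, y))
    ]
    return sum(terms) / len(terms)


def naive_f4(py, pz, pw, px):
    terms = [
        (y - z) * (w - x)
        for y, z, w, x in zip(py, pz, pw, px)
        if not any(math.isnan(v) for v in (y, z, w, x))
    ]
    return sum(terms) / len(terms)


def naive_window_pi(genotypes_by_site, window_bp):
    """pi from explicit allele pairs: mean pairwise mismatch per site / bp."""
    total = 0.0
    for genos in genotypes_by_site:
        alleles = []
        for g in genos:
            if g < 0:
                continue
            alleles += [1] * g + [0] * (2 - g)
        n = len(alleles)
        if n < 2:
            continue
        mismatches = sum(
            1
            for i in range(n)
            for j in range(i + 1, n)
            if alleles[i] != alleles[j]
        )
        total += mismatches / (n * (n - 1) / 2)
    return total / window_bp


def naive_window_theta(genotypes_by_site, window_bp):
    """Watterson's theta with modal allele count and a loop-built harmonic sum."""
    s = 0
    ns = []
    for genos in genotypes_by_site:
        called = [g for g in genos if g >= 0]
        n = 2 * len(called)
        if n < 2:
            continue
        ns.append(n)
        x = sum(called)
        if 0 < x < n:
            s += 1
    if s == 0:
        return 0.0
    tally = Counter(ns)
    top = max(tally.values())
    modal = max(n for n, c in tally.items() if c == top)
    a = 0.0
    for i in range(1, modal):
        a += 1.0 / i
    return s / a / window_bp


def naive_wc_site(g1, g2):
    """Weir & Cockerham (1984) per-site components a, b, c for two samples of
    diploid genotypes (alt dosages, -1 missing); None when not computable."""
    pops = []
    for g in (g1, g2):
        called = [x for x in g if x >= 0]
        if len(called) < 2:
            return None
        n = len(called)
        p = sum(called) / (2.0 * n)
        h = sum(1 for x in called if x == 1) / n
        pops.append((n, p, h))
    r = 2
    nbar = sum(n for n, _, _ in pops) / r
    nc = (r * nbar - sum(n * n for n, _, _ in pops) / (r * nbar)) / (r - 1)
    pbar = sum(n * p for n, p, _ in pops) / (r * nbar)
    s2 = sum(n * (p - pbar) ** 2 for n, p, _ in pops) / ((r - 1) * nbar)
    hbar = sum(n * h for n, _, h in pops) / (r * nbar)
    a = (nbar / nc) * (
        s2 - (pbar * (1 - pbar) - s2 * (r - 1) / r - hbar / 4.0) / (nbar - 1)
    )
    b = (nbar / (nbar - 1)) * (
        pbar * (1 - pbar) - s2 * (r - 1) / r - hbar * (2 * nbar - 1) / (4 * nbar)
    )
    c = hbar / 2.0
    return a, b, c


def naive_wc_fst(geno_rows_1, geno_rows_2):
    """Ratio-of-sums W&C Fst over per-site genotype rows of two populations."""
    num = den = 0.0
    for g1, g2 in zip(geno_rows_1, geno_rows_2):
        comp = naive_wc_site(list(g1), list(g2))
        if comp is None:
            continue
        a, b, c = comp
        num += a
        den += a + b + c
    return num / den if den != 0 else float("nan")


def naive_ld_prune(geno_rows, window_size, step, r2_threshold):
    """Greedy windowed pruning with pairwise-complete r^2, all in loops."""

    def r2(a, b):
        pairs = [(x, y) for x, y in zip(a, b) if x >= 0 and y >= 0]
        if len(pairs) < 2:
            return 0.0
        xs = [p[0] for p in pairs]
        ys = [p[1] for p in pairs]
        n = len(pairs)
        mx, my = sum(xs) / n, sum(ys) / n
        vx = sum((x - mx) ** 2 for x in xs) / n
        vy = sum((y - my) ** 2 for y in ys) / n
        if vx == 0 or vy == 0:
            return 0.0
        cov = sum((x - mx) * (y - my) for x, y in pairs) / n
        return cov * cov / (vx * vy)

    n = len(geno_rows)
    kept = set(range(n))
    for start in range(0, max(n - 1, 1), step):
        idx = [i for i in range(start, min(start + window_size, n)) if i in kept]
        while True:
            worst, worst_pair = r2_threshold, None
            for a in range(len(idx)):
                for b in range(a + 1, len(idx)):
                    v = r2(geno_rows[idx[a]], geno_rows[idx[b]])
                    if v > worst:
                        worst, worst_pair = v, (idx[a], idx[b])
            if worst_pair is None:
                break
            kept.discard(worst_pair[1])
            idx.remove(worst_pair[1])
    return sorted(kept)
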