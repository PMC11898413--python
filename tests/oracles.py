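"""Independent brute-force oracles for the windowed statistics.

Scalar, enumeration-based implementations written directly from the
published formulas; deliberately kept separate from (and slower than)
the vectorized kernels they are used to verify.
"""

import itertools
import math

import numpy as np

from popsweep import MISSING


def oracle_site_pi(genotypes):
    """Mean pairwise difference among allele copies at one site."""
    alleles = []
    for g in genotypes:
        if g != MISSING:
            alleles.extend([1] * g + [0] * (2 - g))
    n = len(alleles)
    if n < 2:
        return 0.0
    pairs = list(itertools.combinations(alleles, 2))
    return sum(a != b for a, b in pairs) / len(pairs)


def oracle_window_pi(dosage, window_len):
    return sum(oracle_site_pi(col) for col in np.asarray(dosage).T) / window_len


def oracle_site_wc(ga, gb):
    """Weir & Cockerham (1984) a, b, c for one biallelic site and two
    populations of diploids, written directly from the published
    formulas with r = 2."""
    ga = [g for g in ga if g != MISSING]
    gb = [g for g in gb if g != MISSING]
    n1, n2 = len(ga), len(gb)
    if n1 < 1 or n2 < 1 or (n1 + n2) / 2 <= 1:
        return None
    r = 2
    p1 = sum(ga) / (2 * n1)
    p2 = sum(gb) / (2 * n2)
    h1 = sum(1 for g in ga if g == 1) / n1
    h2 = sum(1 for g in gb if g == 1) / n2
    nbar = (n1 + n2) / r
    nc = (r * nbar - (n1 ** 2 + n2 ** 2) / (r * nbar)) / (r - 1)
    pbar = (n1 * p1 + n2 * p2) / (r * nbar)
    s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1) * nbar)
    hbar = (n1 * h1 + n2 * h2) / (r * nbar)
    a = (nbar / nc) * (
        s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4) / (nbar - 1))
    b = (nbar / (nbar - 1)) * (
        pbar * (1 - pbar) - (r - 1) / r * s2
        - (2 * nbar - 1) / (4 * nbar) * hbar)
    c = hbar / 2
    return a, b, c


def oracle_global_wc_fst(dosA, dosB):
    num = den = 0.0
    for ca, cb in zip(np.asarray(dosA).T, np.asarray(dosB).T):
        res = oracle_site_wc(ca, cb)
        if res is None:
            continue
        a, b, c = res
        if a + b + c != 0:
            num += a
            den += a + b + c
    return num / den if den else float("nan")


def oracle_tajima_d(dosage):
    """Tajima (1989) D for one population, no missing data."""
    dos = np.asarray(dosage)
    n = 2 * dos.shape[0]
    counts = dos.sum(axis=0)
    seg = (counts > 0) & (counts < n)
    S = int(seg.sum())
    if S == 0:
        return float("nan")
    pi_hat = sum(oracle_site_pi(dos[:, j]) for j in np.flatnonzero(seg))
    a1 = sum(1 / i for i in range(1, n))
    a2 = sum(1 / i ** 2 for i in range(1, n))
    b1 = (n + 1) / (3 * (n - 1))
    b2 = 2 * (n ** 2 + n + 3) / (9 * n * (n - 1))
    c1 = b1 - 1 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1 ** 2
    e1, e2 = c1 / a1, c2 / (a1 ** 2 + a2)
    return (pi_hat - S / a1) / math.sqrt(e1 * S + e2 * S * (S - 1))


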