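"""Sliding-window population-genetic statistics.

Implements the three windowed summaries used by the sweep scan:

- nucleotide diversity pi: per site the unbiased heterozygosity
  ``2*p*q * n/(n-1)`` (n = non-missing allele copies), summed over the
  window and divided by the window length in bp, so monomorphic and
  unsequenced positions contribute zero to the numerator but full
  length to the denominator (the VCFtools ``--window-pi`` convention);
- pairwise Weir & Cockerham (1984) F_st with ratio-of-sums window
  aggregation ``sum(a) / sum(a+b+c)``, negative estimates returned
  unclamped;
- Tajima's D from the window's segregating-site count and mean pairwise
  differences, with the canonical a1..e2 constants.

Windows tile each chromosome on a fixed step (default 100 kb windows,
10 kb step) in 1-based, half-open ``[start, start+size)`` coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .matrix import MISSING, GenotypeMatrix

NAN = float("nan")


@dataclass(frozen=True)
class WindowSpec:
    """Sliding-window geometry in base pairs."""

    window_size: int = 100_000
    step: int = 10_000

    def __post_init__(self) -> None:
        if self.window_size <= 0 or self.step <= 0:
            raise ValueError("window_size and step must be positive")
        if self.step > self.window_size:
            raise ValueError("step must not exceed window_size")


@dataclass
class WindowStat:
    """One window's statistics.  ``pi``/``tajima_d`` are keyed by
    population, ``fst`` by (popA, popB) pair; NaN marks an undefined
    value (e.g. Tajima's D with no segregating sites)."""

    chrom: str
    start: int          # 1-based, inclusive
    end: int            # half-open
    n_sites: int = 0
    partial: bool = False
    pi: dict[str, float] = field(default_factory=dict)
    fst: dict[tuple[str, str], float] = field(default_factory=dict)
    tajima_d: dict[str, float] = field(default_factory=dict)


def window_grid(chrom_length: int, spec: WindowSpec) -> list[tuple[int, int, bool]]:
    """Window (start, end, is_partial) tuples covering ``[1, chrom_length]``.

    Starts run 1, 1+step, 2*step+1, ...; trailing windows whose nominal
    end exceeds the chromosome are clipped and flagged partial.
    """
    out = []
    start = 1
    while start <= chrom_length:
        nominal_end = start + spec.window_size
        end = min(nominal_end, chrom_length + 1)
        out.append((start, end, nominal_end > chrom_length + 1))
        start += spec.step
    return out


def _window_sums(pos: np.ndarray, starts: np.ndarray, ends: np.ndarray,
                 *value_tracks: np.ndarray) -> list[np.ndarray]:
    """Sum each value track over [start, end) position windows via
    cumulative sums (positions must be sorted)."""
    lo = np.searchsorted(pos, starts, side="left")
    hi = np.searchsorted(pos, ends, side="left")
    out = []
    for vals in value_tracks:
        cs = np.concatenate([[0.0], np.cumsum(vals, dtype=np.float64)])
        out.append(cs[hi] - cs[lo])
    return out


# ---------------------------------------------------------------------------
# per-site kernels
# ---------------------------------------------------------------------------

def _site_allele_counts(dos: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(allele copies n, alt-allele count) per site for one population's
    dosage block, counting non-missing genotypes only."""
    called = dos != MISSING
    n = 2 * called.sum(axis=0)
    alt = np.where(called, dos, 0).sum(axis=0)
    return n.astype(np.int64), alt.astype(np.int64)


def site_pi_terms(dos: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-site unbiased heterozygosity ``2*p*q*n/(n-1)``.

    Returns (terms, usable) where sites with fewer than 2 allele copies
    are unusable and contribute 0.
    """
    n, alt = _site_allele_counts(dos)
    usable = n >= 2
    nf = n.astype(np.float64)
    with np.errstate(divide="ignore", invalid="ignore"):
        p = np.where(usable, alt / np.maximum(nf, 1), 0.0)
        terms = np.where(usable, 2.0 * p * (1.0 - p) * nf / np.maximum(nf - 1, 1), 0.0)
    return terms, usable


def site_wc_components(dosA: np.ndarray, dosB: np.ndarray
                       ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Weir & Cockerham (1984) per-site variance components for two
    populations.

    Returns ``(a, abc, usable)`` with ``a`` the among-population
    component and ``abc = a + b + c`` the total; ``usable`` excludes
    sites where either population has no calls or the finite-sample
    corrections are undefined (mean sample size <= 1).
    """
    r = 2.0
    calledA = dosA != MISSING
    calledB = dosB != MISSING
    nA = calledA.sum(axis=0).astype(np.float64)   # individuals, not copies
    nB = calledB.sum(axis=0).astype(np.float64)

    altA = np.where(calledA, dosA, 0).sum(axis=0).astype(np.float64)
    altB = np.where(calledB, dosB, 0).sum(axis=0).astype(np.float64)
    hetA = np.where(calledA, dosA == 1, False).sum(axis=0).astype(np.float64)
    hetB = np.where(calledB, dosB == 1, False).sum(axis=0).astype(np.float64)

    usable = (nA >= 1) & (nB >= 1) & ((nA + nB) / 2.0 > 1.0)
    nA_s = np.maximum(nA, 1e-12)
    nB_s = np.maximum(nB, 1e-12)

    with np.errstate(divide="ignore", invalid="ignore"):
        pA = altA / (2.0 * nA_s)
        pB = altB / (2.0 * nB_s)
        hA = hetA / nA_s
        hB = hetB / nB_s

        nbar = (nA + nB) / r
        nc = (r * nbar - (nA ** 2 + nB ** 2) / (r * nbar)) / (r - 1.0)
        pbar = (nA * pA + nB * pB) / (r * nbar)
        s2 = (nA * (pA - pbar) ** 2 + nB * (pB - pbar) ** 2) / ((r - 1.0) * nbar)
        hbar = (nA * hA + nB * hB) / (r * nbar)

        inner = pbar * (1.0 - pbar) - ((r - 1.0) / r) * s2 - hbar / 4.0
        a = (nbar / nc) * (s2 - inner / (nbar - 1.0))
        b = (nbar / (nbar - 1.0)) * (
            pbar * (1.0 - pbar) - ((r - 1.0) / r) * s2
            - ((2.0 * nbar - 1.0) / (4.0 * nbar)) * hbar
        )
        c = hbar / 2.0

    a = np.where(usable, a, 0.0)
    abc = np.where(usable, a + b + c, 0.0)
    # ratio-of-sums: a zero total variance carries no information; skip
    usable = usable & (abc != 0.0)
    a = np.where(usable, a, 0.0)
    abc = np.where(usable, abc, 0.0)
    return a, abc, usable


def tajima_constants(n: int) -> dict[str, float]:
    """Tajima (1989) normalization constants for ``n`` allele copies."""
    if n < 2:
        raise ValueError("Tajima constants need n >= 2 allele copies")
    i = np.arange(1, n)
    a1 = float(np.sum(1.0 / i))
    a2 = float(np.sum(1.0 / i ** 2))
    b1 = (n + 1.0) / (3.0 * (n - 1.0))
    b2 = 2.0 * (n ** 2 + n + 3.0) / (9.0 * n * (n - 1.0))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2.0) / (a1 * n) + a2 / a1 ** 2
    e1 = c1 / a1
    e2 = c2 / (a1 ** 2 + a2)
    return {"a1": a1, "a2": a2, "b1": b1, "b2": b2,
            "c1": c1, "c2": c2, "e1": e1, "e2": e2}


def tajima_d_from_counts(S: int, pi_hat: float, n: int) -> float:
    """Tajima's D from segregating sites S, mean pairwise differences
    ``pi_hat`` (count scale) and n allele copies; NaN when S == 0."""
    if S == 0:
        return NAN
    k = tajima_constants(n)
    var = k["e1"] * S + k["e2"] * S * (S - 1.0)
    if var <= 0:
        return NAN
    return (pi_hat - S / k["a1"]) / np.sqrt(var)


# ---------------------------------------------------------------------------
# windowed operations
# ---------------------------------------------------------------------------

def _chrom_blocks(geno: GenotypeMatrix,
                  chrom_lengths: dict[str, int] | None):
    lengths = chrom_lengths or geno.chrom_lengths()
    chrom_str = geno.chrom.astype(str)
    for c in sorted(lengths):
        idx = np.flatnonzero(chrom_str == c)
        yield c, lengths[c], idx


def windowed_pi(
    geno: GenotypeMatrix,
    pop: str,
    spec: WindowSpec = WindowSpec(),
    chrom_lengths: dict[str, int] | None = None,
) -> list[WindowStat]:
    """Per-window nucleotide diversity for one population.

    Window pi is the sum of per-site unbiased heterozygosities divided
    by the window length in bp; windows without usable variants get 0.
    """
    dos = geno.pop_dosage(pop)
    terms, usable = site_pi_terms(dos)
    out: list[WindowStat] = []
    for c, length, idx in _chrom_blocks(geno, chrom_lengths):
        grid = window_grid(length, spec)
        starts = np.array([g[0] for g in grid])
        ends = np.array([g[1] for g in grid])
        sums, counts = _window_sums(
            geno.pos[idx], starts, ends, terms[idx], usable[idx].astype(float))
        for (s, e, part), tot, cnt in zip(grid, sums, counts):
            out.append(WindowStat(
                chrom=c, start=int(s), end=int(e), n_sites=int(cnt), partial=part,
                pi={pop: float(tot) / (e - s)},
            ))
    return out


def global_pi(
    geno: GenotypeMatrix,
    pop: str,
    chrom_lengths: dict[str, int] | None = None,
) -> float:
    """Genome-wide per-site nucleotide diversity: summed per-site
    heterozygosity over the total assayed length."""
    terms, _ = site_pi_terms(geno.pop_dosage(pop))
    lengths = chrom_lengths or geno.chrom_lengths()
    return float(terms.sum()) / float(sum(lengths.values()))


def pairwise_fst(
    geno: GenotypeMatrix,
    popA: str,
    popB: str,
    spec: WindowSpec = WindowSpec(),
    chrom_lengths: dict[str, int] | None = None,
) -> list[WindowStat]:
    """Windowed Weir-Cockerham F_st between two populations
    (ratio-of-sums aggregation, negatives unclamped, symmetric in the
    population order; windows with no usable sites get NaN)."""
    if popA == popB:
        raise ValueError("pairwise_fst needs two distinct populations")
    a, abc, usable = site_wc_components(geno.pop_dosage(popA), geno.pop_dosage(popB))
    key = (popA, popB)
    out: list[WindowStat] = []
    for c, length, idx in _chrom_blocks(geno, chrom_lengths):
        grid = window_grid(length, spec)
        starts = np.array([g[0] for g in grid])
        ends = np.array([g[1] for g in grid])
        a_sum, abc_sum, counts = _window_sums(
            geno.pos[idx], starts, ends, a[idx], abc[idx], usable[idx].astype(float))
        for (s, e, part), an, dn, cnt in zip(grid, a_sum, abc_sum, counts):
            val = float(an) / float(dn) if dn != 0.0 else NAN
            out.append(WindowStat(chrom=c, start=int(s), end=int(e),
                                  n_sites=int(cnt), partial=part, fst={key: val}))
    return out


def global_fst(geno: GenotypeMatrix, popA: str, popB: str) -> float:
    """Genome-wide Weir-Cockerham F_st (ratio of summed components)."""
    a, abc, _ = site_wc_components(geno.pop_dosage(popA), geno.pop_dosage(popB))
    denom = abc.sum()
    return float(a.sum() / denom) if denom != 0.0 else NAN


def hudson_fst(geno: GenotypeMatrix, popA: str, popB: str) -> float:
    """Hudson (1992) F_st estimator (Bhatia et al. ratio-of-averages),
    kept as a labelled cross-check alternative to Weir-Cockerham."""
    nA, altA = _site_allele_counts(geno.pop_dosage(popA))
    nB, altB = _site_allele_counts(geno.pop_dosage(popB))
    usable = (nA >= 2) & (nB >= 2)
    nA, altA = nA[usable].astype(float), altA[usable].astype(float)
    nB, altB = nB[usable].astype(float), altB[usable].astype(float)
    pA, pB = altA / nA, altB / nB
    num = (pA - pB) ** 2 - pA * (1 - pA) / (nA - 1) - pB * (1 - pB) / (nB - 1)
    den = pA * (1 - pB) + pB * (1 - pA)
    dsum = den.sum()
    return float(num.sum() / dsum) if dsum != 0.0 else NAN


def windowed_tajima_d(
    geno: GenotypeMatrix,
    pop: str,
    spec: WindowSpec = WindowSpec(),
    chrom_lengths: dict[str, int] | None = None,
) -> list[WindowStat]:
    """Windowed Tajima's D for one population.

    S and the mean pairwise-difference count are accumulated per window
    over its segregating sites; the normalization constants use the
    median non-missing allele-copy count among those sites (equal to
    2 x sample size when no genotypes are missing).  Windows with S = 0
    get NaN.
    """
    dos = geno.pop_dosage(pop)
    if 2 * dos.shape[0] < 4:
        raise ValueError("Tajima's D needs at least 4 allele copies")
    n, alt = _site_allele_counts(dos)
    seg = (n >= 2) & (alt > 0) & (alt < n)
    nf = n.astype(np.float64)
    with np.errstate(divide="ignore", invalid="ignore"):
        p = np.where(seg, alt / np.maximum(nf, 1), 0.0)
        k_terms = np.where(seg, 2.0 * p * (1.0 - p) * nf / np.maximum(nf - 1, 1), 0.0)

    out: list[WindowStat] = []
    for c, length, idx in _chrom_blocks(geno, chrom_lengths):
        grid = window_grid(length, spec)
        starts = np.array([g[0] for g in grid])
        ends = np.array([g[1] for g in grid])
        pos_c = geno.pos[idx]
        S_sum, k_sum = _window_sums(pos_c, starts, ends,
                                    seg[idx].astype(float), k_terms[idx])
        lo = np.searchsorted(pos_c, starts, side="left")
        hi = np.searchsorted(pos_c, ends, side="left")
        for (s, e, part), S, k, l, h in zip(grid, S_sum, k_sum, lo, hi):
            S = int(round(S))
            if S > 0:
                site_n = n[idx][l:h]
                site_n = site_n[seg[idx][l:h]]
                n_win = int(np.median(site_n))
                d = tajima_d_from_counts(S, float(k), n_win) if n_win >= 4 else NAN
            else:
                d = NAN
            out.append(WindowStat(chrom=c, start=int(s), end=int(e),
                                  n_sites=S, partial=part, tajima_d={pop: d}))
    return out


# ---------------------------------------------------------------------------
# tabular export
# ---------------------------------------------------------------------------

def pi_frame(stats: list[WindowStat], pop: str) -> pd.DataFrame:
    """VCFtools-style windowed-pi table (CHROM, BIN_START, BIN_END,
    N_VARIANTS, PI)."""
    return pd.DataFrame({
        "CHROM": [w.chrom for w in stats],
        "BIN_START": [w.start for w in stats],
        "BIN_END": [w.end - 1 for w in stats],
        "N_VARIANTS": [w.n_sites for w in stats],
        "PI": [w.pi[pop] for w in stats],
    })


def fst_frame(stats: list[WindowStat], pair: tuple[str, str]) -> pd.DataFrame:
    return pd.DataFrame({
        "CHROM": [w.chrom for w in stats],
        "BIN_START": [w.start for w in stats],
        "BIN_END": [w.end - 1 for w in stats],
        "N_VARIANTS": [w.n_sites for w in stats],
        "WEIR_AND_COCKERHAM_FST": [w.fst[pair] for w in stats],
    })


def tajima_frame(stats: list[WindowStat], pop: str) -> pd.DataFrame:
    return pd.DataFrame({
        "CHROM": [w.chrom for w in stats],
        "BIN_START": [w.start for w in stats],
        "BIN_END": [w.end - 1 for w in stats],
        "N_SEG_SITES": [w.n_sites for w in stats],
        "TAJIMA_D": [w.tajima_d[pop] for w in stats],
    })
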