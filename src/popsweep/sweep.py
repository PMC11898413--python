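"""Reduction-of-diversity (ROD) selective-sweep scan.

For each non-reference population, every window's diversity is compared
with the same window in the reference population:

    ROD = |1 - pi_pop / pi_ref|

Windows in the top 5% of both the windowed F_st (population vs
reference) and ROD distributions are called outliers, merged into
candidate sweep regions, and annotated with overlapping genes.  The
absolute value makes ROD two-sided exactly as defined; a one-sided
variant ranking the signed value 1 - pi_pop/pi_ref (sweeps only reduce
diversity) is available via ``side="loss"``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .matrix import GenotypeMatrix
from .vcfio import Gene
from .windows import WindowSpec, WindowStat, pairwise_fst, windowed_pi

log = logging.getLogger(__name__)

NAN = float("nan")

#: Windows with fewer usable sites than this are excluded from ROD
#: ranking: the ratio of two small noisy pi values is unstable.
DEFAULT_MIN_SITES = 10


@dataclass
class RodValue:
    """ROD for one window and population; ``rod = |signed_rod|`` where
    ``signed_rod = 1 - pi_pop/pi_ref`` (positive = diversity loss)."""

    chrom: str
    start: int
    end: int
    population: str
    rod: float
    signed_rod: float
    n_sites: int


@dataclass
class SweepRegion:
    """A merged run of outlier windows with its peak statistics."""

    chrom: str
    start: int     # 1-based inclusive
    end: int       # half-open
    population: str
    n_windows: int
    peak_rod: float
    peak_fst: float
    gene_ids: list[str] = field(default_factory=list)


def rod(pi_pop: float, pi_ref: float) -> tuple[float, float]:
    """(|1 - pi_pop/pi_ref|, 1 - pi_pop/pi_ref); NaN when pi_ref = 0."""
    if not pi_ref > 0:
        return NAN, NAN
    signed = 1.0 - pi_pop / pi_ref
    return abs(signed), signed


def window_rod(
    geno: GenotypeMatrix,
    population: str,
    spec: WindowSpec = WindowSpec(),
    min_sites: int = DEFAULT_MIN_SITES,
    chrom_lengths: dict[str, int] | None = None,
) -> list[RodValue]:
    """Per-window ROD of ``population`` against the matrix's reference
    population.  Windows where the reference pi is 0 or either
    population has fewer than ``min_sites`` usable sites get NaN and are
    excluded from downstream ranking.
    """
    ref = geno.reference_pop
    pi_pop = windowed_pi(geno, population, spec, chrom_lengths)
    pi_ref = windowed_pi(geno, ref, spec, chrom_lengths)
    out = []
    for wp, wr in zip(pi_pop, pi_ref):
        assert (wp.chrom, wp.start) == (wr.chrom, wr.start)
        if min(wp.n_sites, wr.n_sites) < min_sites:
            r = s = NAN
        else:
            r, s = rod(wp.pi[population], wr.pi[ref])
        out.append(RodValue(chrom=wp.chrom, start=wp.start, end=wp.end,
                            population=population, rod=r, signed_rod=s,
                            n_sites=min(wp.n_sites, wr.n_sites)))
    return out


def scan_table(
    geno: GenotypeMatrix,
    population: str,
    spec: WindowSpec = WindowSpec(),
    min_sites: int = DEFAULT_MIN_SITES,
    chrom_lengths: dict[str, int] | None = None,
) -> pd.DataFrame:
    """Joint per-window table (ROD + F_st vs reference) on one grid."""
    ref = geno.reference_pop
    if population == ref:
        raise ValueError("scan population must differ from the reference")
    rods = window_rod(geno, population, spec, min_sites, chrom_lengths)
    fsts = pairwise_fst(geno, population, ref, spec, chrom_lengths)
    rows = []
    for rv, wf in zip(rods, fsts):
        assert (rv.chrom, rv.start) == (wf.chrom, wf.start)
        rows.append({
            "CHROM": rv.chrom, "BIN_START": rv.start, "BIN_END": rv.end - 1,
            "N_SITES": rv.n_sites, "ROD": rv.rod, "SIGNED_ROD": rv.signed_rod,
            "FST": wf.fst[(population, ref)],
        })
    return pd.DataFrame(rows)


def call_outlier_windows(
    table: pd.DataFrame,
    top_frac: float = 0.05,
    mode: str = "intersection",
    side: str = "abs",
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Call top-``top_frac`` joint F_st/ROD outlier windows.

    Thresholds are the genome-wide (1 - top_frac) quantiles of the two
    statistics over defined windows; windows at or above both thresholds
    are returned (``mode="union"`` gives either).  Ties at a threshold
    are included.  Returns the outlier rows plus the thresholds and the
    per-statistic outlier flags (added as columns ``FST_OUTLIER`` /
    ``ROD_OUTLIER`` on the returned full table copy).
    """
    if mode not in ("intersection", "union"):
        raise ValueError(f"unknown mode {mode!r}")
    if side not in ("abs", "loss"):
        raise ValueError(f"unknown side {side!r}")
    rod_col = "ROD" if side == "abs" else "SIGNED_ROD"
    t = table.copy()
    ranked = t.dropna(subset=[rod_col, "FST"])
    if len(ranked) < 20:
        log.warning("only %d ranked windows: top-%% thresholds are unstable",
                    len(ranked))
    if ranked.empty:
        raise ValueError("no window has both ROD and FST defined")
    q = 1.0 - top_frac
    fst_thr = float(np.quantile(ranked["FST"], q))
    rod_thr = float(np.quantile(ranked[rod_col], q))
    if ranked["FST"].nunique() == 1 or ranked[rod_col].nunique() == 1:
        log.warning("degenerate statistic distribution: all ranked windows tie "
                    "at the outlier threshold")
    t["FST_OUTLIER"] = t["FST"] >= fst_thr
    t["ROD_OUTLIER"] = t[rod_col] >= rod_thr
    if mode == "intersection":
        sel = t["FST_OUTLIER"] & t["ROD_OUTLIER"]
    else:
        sel = t["FST_OUTLIER"] | t["ROD_OUTLIER"]
    return t[sel], {"fst_threshold": fst_thr, "rod_threshold": rod_thr,
                    "n_ranked": len(ranked), "table": t}


def merge_regions(
    outliers: pd.DataFrame,
    population: str,
    max_gap: int = 0,
) -> list[SweepRegion]:
    """Merge outlier windows on the same chromosome that overlap or are
    separated by at most ``max_gap`` bp into sweep regions."""
    regions: list[SweepRegion] = []
    if outliers.empty:
        return regions
    o = outliers.sort_values(["CHROM", "BIN_START"])
    cur = None
    for row in o.itertuples():
        start, end = int(row.BIN_START), int(row.BIN_END) + 1
        if (cur is not None and row.CHROM == cur.chrom
                and start <= cur.end + max_gap):
            cur.end = max(cur.end, end)
            cur.n_windows += 1
            cur.peak_rod = max(cur.peak_rod, row.ROD)
            cur.peak_fst = max(cur.peak_fst, row.FST)
        else:
            cur = SweepRegion(chrom=row.CHROM, start=start, end=end,
                              population=population, n_windows=1,
                              peak_rod=float(row.ROD), peak_fst=float(row.FST))
            regions.append(cur)
    return regions


def annotate_genes(regions: list[SweepRegion], genes: list[Gene]) -> list[SweepRegion]:
    """Attach every gene whose (1-based inclusive) span overlaps a
    region's half-open interval by at least one bp; strand ignored."""
    for reg in regions:
        reg.gene_ids = sorted(
            g.gene_id for g in genes
            if g.chrom == reg.chrom and g.start < reg.end and g.end >= reg.start
        )
    return regions


def sweep_scan(
    geno: GenotypeMatrix,
    population: str,
    spec: WindowSpec = WindowSpec(),
    top_frac: float = 0.05,
    max_gap: int = 0,
    min_sites: int = DEFAULT_MIN_SITES,
    genes: list[Gene] | None = None,
    mode: str = "intersection",
    side: str = "abs",
    chrom_lengths: dict[str, int] | None = None,
) -> tuple[list[SweepRegion], pd.DataFrame]:
    """Full scan for one population: window table -> joint outliers ->
    merged, gene-annotated sweep regions.  Returns (regions, full
    window table with outlier flags)."""
    table = scan_table(geno, population, spec, min_sites, chrom_lengths)
    outliers, info = call_outlier_windows(table, top_frac, mode, side)
    regions = merge_regions(outliers, population, max_gap)
    if genes:
        regions = annotate_genes(regions, genes)
    return regions, info["table"]


def regions_to_bed(regions: list[SweepRegion]) -> pd.DataFrame:
    """BED-style frame (0-based half-open) for emitted sweep regions."""
    return pd.DataFrame({
        "chrom": [r.chrom for r in regions],
        "chromStart": [r.start - 1 for r in regions],
        "chromEnd": [r.end - 1 for r in regions],
        "name": [f"{r.population}_sweep_{i + 1}" for i, r in enumerate(regions)],
        "peak_rod": [r.peak_rod for r in regions],
        "peak_fst": [r.peak_fst for r in regions],
        "genes": [",".join(r.gene_ids) for r in regions],
    })
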