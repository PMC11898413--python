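"""VCF / GFF3 / population-table I/O and site-level variant filtering.

Reading goes through :mod:`cyvcf2`; only biallelic SNP records are kept
(multi-allelic and indel records are skipped and counted).  Writing
produces plain-text VCF v4.2 with GT and per-genotype DP, sorted by
(chromosome, position), so that a written cohort round-trips through
:func:`read_vcf` to the identical dosage matrix.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import gffutils
import numpy as np
import pandas as pd
from cyvcf2 import VCF

from .matrix import MISSING, FilterThresholds, GenotypeMatrix

log = logging.getLogger(__name__)

_GT_STRING = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def read_pop_table(path: str | Path) -> dict[str, str]:
    """Read a two-column (sample, population) TSV without header."""
    df = pd.read_csv(path, sep="\t", header=None, names=["sample", "population"],
                     dtype=str, comment="#")
    return dict(zip(df["sample"], df["population"]))


def read_vcf(
    path: str | Path,
    pop_labels: dict[str, str],
    reference_pop: str,
) -> GenotypeMatrix:
    """Load a multi-sample VCF into a :class:`GenotypeMatrix`.

    Only biallelic SNPs are retained; skipped records are logged with a
    count.  GT is parsed to dosage (``./.`` -> missing) and FORMAT/DP to
    per-genotype depth when present on every kept record.
    """
    vcf = VCF(str(path), gts012=True)
    samples = list(vcf.samples)
    missing_labels = [s for s in samples if s not in pop_labels]
    if missing_labels:
        raise ValueError(
            f"VCF samples absent from the population table: {missing_labels}"
        )

    chroms: list[str] = []
    positions: list[int] = []
    dosage_cols: list[np.ndarray] = []
    depth_cols: list[np.ndarray] = []
    n_skipped = 0
    any_dp = False
    for var in vcf:
        if len(var.ALT) != 1 or not var.is_snp:
            n_skipped += 1
            continue
        gt = np.asarray(var.gt_types, dtype=np.int8)  # gts012: 3 == unknown
        gt[gt == 3] = MISSING
        chroms.append(var.CHROM)
        positions.append(var.POS)
        dosage_cols.append(gt)
        try:
            dp = var.format("DP")
        except KeyError:
            dp = None
        if dp is not None:
            dp = dp.reshape(-1).astype(np.int64)
            dp[dp < 0] = 0  # cyvcf2 encodes missing DP as a negative sentinel
            depth_cols.append(dp)
            any_dp = True
        else:
            depth_cols.append(np.zeros(len(samples), dtype=np.int64))
    if n_skipped:
        log.info("read_vcf: skipped %d non-biallelic-SNP records", n_skipped)
    if not positions:
        raise ValueError(f"no biallelic SNP records found in {path}")

    dosage = np.column_stack(dosage_cols)
    depth = np.column_stack(depth_cols) if any_dp else None
    return GenotypeMatrix(
        sample_ids=samples,
        pop_labels={s: pop_labels[s] for s in samples},
        reference_pop=reference_pop,
        chrom=np.array(chroms, dtype=object),
        pos=np.array(positions, dtype=np.int64),
        dosage=dosage,
        depth=depth,
    )


def write_vcf(geno: GenotypeMatrix, path: str | Path) -> None:
    """Serialize to VCF v4.2 with GT and DP FORMAT fields.

    Allele symbols are synthetic (REF=A, ALT=G): the matrix stores
    dosages, not sequences, and every downstream statistic is invariant
    to the base letters.
    """
    if geno.n_variants == 0:
        raise ValueError("refusing to write an empty genotype matrix")
    path = Path(path)
    has_dp = geno.depth is not None
    fmt = "GT:DP" if has_dp else "GT"
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=popsweep\n")
        for c, ln in geno.chrom_lengths().items():
            fh.write(f"##contig=<ID={c},length={ln}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        if has_dp:
            fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(geno.sample_ids) + "\n")
        for j in range(geno.n_variants):
            cells = []
            for i in range(geno.n_samples):
                gt = _GT_STRING[int(geno.dosage[i, j])]
                if has_dp:
                    cells.append(f"{gt}:{int(geno.depth[i, j])}")
                else:
                    cells.append(gt)
            fh.write(
                f"{geno.chrom[j]}\t{int(geno.pos[j])}\t.\tA\tG\t.\tPASS\t.\t{fmt}\t"
                + "\t".join(cells) + "\n"
            )


def write_pop_table(geno: GenotypeMatrix, path: str | Path) -> None:
    with open(path, "w") as fh:
        for s in geno.sample_ids:
            fh.write(f"{s}\t{geno.pop_labels[s]}\n")


# ---------------------------------------------------------------------------
# GFF3 gene annotation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Gene:
    """A gene feature: 1-based inclusive span, as in GFF3."""

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str = "+"


def write_gff(genes: list[Gene], path: str | Path) -> None:
    """Write gene features as GFF3 (1-based inclusive coordinates)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in sorted(genes, key=lambda g: (g.chrom, g.start)):
            fh.write(
                f"{g.chrom}\tpopsweep\tgene\t{g.start}\t{g.end}\t.\t{g.strand}\t.\t"
                f"ID={g.gene_id};Name={g.gene_id}\n"
            )


def read_gff(path: str | Path) -> list[Gene]:
    """Parse gene features from a GFF3 file via :mod:`gffutils`."""
    db = gffutils.create_db(
        str(path), dbfn=":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    genes = []
    for feat in db.features_of_type("gene"):
        gene_id = feat.attributes.get("ID", [feat.id])[0]
        genes.append(Gene(gene_id=gene_id, chrom=feat.seqid,
                          start=feat.start, end=feat.end, strand=feat.strand or "+"))
    return genes


# ---------------------------------------------------------------------------
# Variant filtering
# ---------------------------------------------------------------------------

@dataclass
class FilterReport:
    """Per-criterion failure counts from one :func:`filter_variants` call.

    A variant may fail several criteria, so the failure counts can sum
    to more than ``n_input - n_retained``.
    """

    n_input: int
    n_retained: int
    n_fail_maf: int
    n_fail_depth: int
    n_fail_missing: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(self)])


def pooled_maf(geno: GenotypeMatrix) -> np.ndarray:
    """Minor allele frequency per variant over all non-missing genotypes
    pooled across samples; sites with no calls get MAF 0."""
    called = geno.dosage != MISSING
    n_copies = 2 * called.sum(axis=0)
    alt = np.where(called, geno.dosage, 0).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(n_copies > 0, alt / np.maximum(n_copies, 1), 0.0)
    return np.minimum(p, 1.0 - p)


def filter_variants(
    geno: GenotypeMatrix,
    thresholds: FilterThresholds = FilterThresholds(),
    depth_mode: str = "site_mean",
) -> tuple[GenotypeMatrix, FilterReport]:
    """Apply the cohort-level site filters (all inequalities strict):

    - pooled minor allele frequency > ``min_maf``;
    - depth > ``min_depth`` — by default the mean per-genotype DP at the
      site (``depth_mode="site_mean"``, VCFtools-style site filtering);
      with ``depth_mode="mask_genotypes"`` individual genotypes at or
      below the threshold are set missing first instead;
    - missing-genotype fraction < ``max_missing``.

    When the matrix carries no depth information the depth criterion is
    vacuously satisfied.  Removing every variant yields an empty matrix
    with a warning, not an error.
    """
    if geno.n_variants == 0:
        raise ValueError("cannot filter an empty genotype matrix")
    if depth_mode not in ("site_mean", "mask_genotypes"):
        raise ValueError(f"unknown depth_mode {depth_mode!r}")

    if depth_mode == "mask_genotypes" and geno.depth is not None:
        masked = geno.dosage.copy()
        masked[geno.depth <= thresholds.min_depth] = MISSING
        geno = GenotypeMatrix(
            sample_ids=geno.sample_ids, pop_labels=geno.pop_labels,
            reference_pop=geno.reference_pop, chrom=geno.chrom, pos=geno.pos,
            dosage=masked, depth=geno.depth,
        )

    maf = pooled_maf(geno)
    pass_maf = maf > thresholds.min_maf

    if geno.depth is not None and depth_mode == "site_mean":
        mean_dp = geno.depth.mean(axis=0)
        pass_depth = mean_dp > thresholds.min_depth
    else:
        pass_depth = np.ones(geno.n_variants, dtype=bool)

    miss_frac = (geno.dosage == MISSING).mean(axis=0)
    pass_missing = miss_frac < thresholds.max_missing

    keep = pass_maf & pass_depth & pass_missing
    report = FilterReport(
        n_input=geno.n_variants,
        n_retained=int(keep.sum()),
        n_fail_maf=int((~pass_maf).sum()),
        n_fail_depth=int((~pass_depth).sum()),
        n_fail_missing=int((~pass_missing).sum()),
    )
    if report.n_retained == 0:
        log.warning("filter_variants removed every variant")
    return geno.take_variants(keep), report
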