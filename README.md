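# popsweep

Selective-sweep scanning and population-structure inference for
multi-population SNP cohorts, with a seeded synthetic-data generator so
the whole pipeline is verifiable at desk scale.

The package targets the analysis that follows joint variant calling in
a wild-population resequencing study: several coastal populations of a
marine fish are sequenced, one of them (a marine-protected-area
population, here called `XM`) experiences no fishing pressure and
serves as the baseline, and the question is whether the exploited
populations carry local signatures of selection despite essentially
zero genome-wide differentiation. It is aimed at population geneticists
who have a multi-sample VCF and a sample→population table and want the
standard windowed statistics, the sweep screen and the structure
analyses in one reproducible, tested toolchain.

## What it computes

**Site filtering** — keep biallelic SNPs with pooled minor allele
frequency > 0.01, mean per-genotype depth > 3 and missing-genotype
fraction < 0.2 (all thresholds configurable).

**Windowed statistics** (default 100 kb windows, 10 kb step):

- nucleotide diversity π: per site the unbiased heterozygosity
  2p̂q̂·n/(n−1) (n = non-missing allele copies), summed over the window
  and divided by the window length;
- pairwise F_st: the Weir & Cockerham (1984) estimator with
  ratio-of-sums aggregation Σa / Σ(a+b+c); negative finite-sample
  estimates are reported unclamped (they are the expected outcome for
  truly undifferentiated populations);
- Tajima's D = (π̂ − S/a₁) / √(e₁S + e₂S(S−1)) per window.

**Sweep scan** — for each population, every window's reduction of
diversity against the reference population,

&nbsp;&nbsp;&nbsp;&nbsp;ROD = |1 − π_pop / π_ref|,

is ranked together with the windowed F_st (population vs reference);
windows in the top 5% of *both* statistics are called outliers, merged
into candidate sweep regions, and annotated with overlapping genes from
a GFF3.

**Structure inference** — identity-by-state distances, a Saitou–Nei
neighbor-joining tree (exact on additive matrices), and the admixture
model g_il ~ Binomial(2, Σ_k q_ik p_kl) fitted by EM, with the number of
ancestral populations K chosen by masked-genotype cross-validation.

**Synthetic cohorts** — the Balding–Nichols generator draws population
allele frequencies Beta(p(1−F)/F, (1−p)(1−F)/F) around a uniform
ancestral spectrum, giving closed-form control of F_st, diversity,
implanted sweep footprints, admixture proportions, read depth and
missingness — with the ground truth recorded for every cohort.

## Worked example

```python
import popsweep as ps

cfg = ps.SimulationConfig(
    seed=42, n_pops=2, samples_per_pop=10, n_chroms=2, chrom_length=2_000_000,
    sweep_intervals=[ps.SweepInterval("chr1", 800_001, 1_200_000, 0.8)],
)
geno, truth = ps.simulate_cohort(cfg)
kept, report = ps.filter_variants(geno)
lengths = {c: cfg.chrom_length for c in cfg.chrom_names()}
print(ps.global_pi(kept, "XM", lengths), ps.global_fst(kept, "XM", "BH"))
regions, table = ps.sweep_scan(kept, "BH", genes=ps.simulate_genes(cfg),
                               chrom_lengths=lengths)
```

prints (exactly, for this seed):

```
simulated 20 samples x 34006 SNPs; 33113 retained after filtering
genome-wide pi: XM=3.0569e-03  BH=2.8019e-03
global Weir-Cockerham Fst(XM, BH) = 0.04090
sweep region chr1:830001-1140001  windows=15  peak ROD=0.817  peak Fst=0.427  genes=['gene_chr1_005', 'gene_chr1_006']
```

Reading the numbers: both populations sit near the target diversity of
3.1 × 10⁻³, but the 400 kb interval implanted on chr1 removed 80% of
`BH`'s heterozygosity there, so the scan recovers a single region
overlapping the implant whose peak ROD (0.817) matches the implanted
reduction, with elevated F_st confined to the same windows, and reports
the two genes the region overlaps. The genome-wide F_st (0.041) is
inflated above the background precisely because the sweep region
contributes strong local differentiation.

The same pipeline is available from the shell:

```bash
popsweep simulate --out run/sim
popsweep filter --vcf run/sim/cohort.vcf --pops run/sim/populations.tsv \
    --reference-pop XM --out run/filtered
popsweep sweep --vcf run/filtered/filtered.vcf --pops run/filtered/populations.tsv \
    --reference-pop XM --gff run/sim/genes.gff3 --out run/sweep
popsweep nj  --vcf run/filtered/filtered.vcf --pops run/filtered/populations.tsv \
    --reference-pop XM --out run/tree.nwk
popsweep admix --vcf run/filtered/filtered.vcf --pops run/filtered/populations.tsv \
    --reference-pop XM --k-max 6 --repeats 20 --out run/admix
```

Each run directory carries a `manifest.json` with input hashes, seeds
and stage outputs; identical configurations reproduce byte-identical
outputs.

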