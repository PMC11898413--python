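"""Seeded multi-population genotype simulator with known truth.

The generator emulates the statistical structure that the sweep scan
and structure inference assume, at desk scale:

- ancestral allele frequencies drawn from a uniform spectrum;
- per-population frequencies from the Balding-Nichols model
  ``Beta(p(1-F)/F, (1-p)(1-F)/F)``, giving closed-form control of the
  expected differentiation F;
- diploid genotypes as ``Binomial(2, p_pop)`` draws, sites independent
  (no linkage disequilibrium);
- selective-sweep footprints implanted by pushing affected populations'
  frequencies to fixation at a rate chosen so window diversity drops by
  a requested fraction;
- optional K-source admixture (individual ancestry ~ Dirichlet);
- overdispersed per-genotype read depth (negative binomial) and
  independent missing genotypes.

Variant density is set analytically so that the realized genome-wide
per-site nucleotide diversity matches ``target_pi``.  The same seed
always produces a byte-identical cohort (and VCF).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

from .matrix import MISSING, GenotypeMatrix
from .vcfio import Gene, write_gff, write_pop_table, write_vcf

#: Default population codes; the first is the reference (no-pressure)
#: population the reduction-of-diversity scan is anchored on.
DEFAULT_POP_NAMES = ("XM", "BH", "DS", "QZ", "WA", "ZJ")


@dataclass(frozen=True)
class SweepInterval:
    """A genomic interval whose diversity is reduced in some populations.

    ``populations=None`` means every non-reference population is
    affected.  ``diversity_reduction`` is the fraction of heterozygosity
    removed inside the interval (1.0 = complete fixation).
    """

    chrom: str
    start: int            # 1-based inclusive
    end: int              # half-open
    diversity_reduction: float
    populations: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        if not 0.0 < self.diversity_reduction <= 1.0:
            raise ValueError("diversity_reduction must lie in (0, 1]")
        if self.start < 1 or self.end <= self.start:
            raise ValueError("sweep interval must satisfy 1 <= start < end")


@dataclass
class SimulationConfig:
    """Scenario definition; the seed fully determines the cohort.

    Defaults emulate a six-population coastal cohort of 10 diploid
    individuals each with genome-wide pi around 3.1e-3 and essentially
    no between-population differentiation.
    """

    seed: int = 0
    n_pops: int = 6
    samples_per_pop: int = 10
    n_chroms: int = 2
    chrom_length: int = 2_000_000
    target_pi: float = 3.1e-3
    divergence_F: float | list[float] = 1e-3
    sweep_intervals: list[SweepInterval] = field(default_factory=list)
    admixture_spec: tuple[int, float] | None = None   # (K, Dirichlet alpha)
    depth_mean: float = 12.0
    depth_dispersion: float = 5.0
    missing_rate: float = 0.05
    maf_low: float = 0.05
    maf_high: float = 0.95
    pop_names: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        if self.n_pops < 1 or self.samples_per_pop < 1:
            raise ValueError("need at least one population and one sample")
        if self.n_chroms < 1 or self.chrom_length < 1:
            raise ValueError("need at least one chromosome of positive length")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must lie in [0, 1)")
        if not 0.0 < self.maf_low < self.maf_high < 1.0:
            raise ValueError("need 0 < maf_low < maf_high < 1")
        for f in self.pop_F():
            if not 0.0 <= f < 1.0:
                raise ValueError("divergence_F values must lie in [0, 1)")
        for iv in self.sweep_intervals:
            if iv.chrom not in self.chrom_names():
                raise ValueError(f"sweep interval on unknown chromosome {iv.chrom}")
            if iv.end > self.chrom_length + 1:
                raise ValueError("sweep interval exceeds chromosome bounds")
        if self.admixture_spec is not None:
            K, alpha = self.admixture_spec
            if K < 2 or alpha <= 0:
                raise ValueError("admixture_spec needs K >= 2 and alpha > 0")

    # -- naming ---------------------------------------------------------
    def resolved_pop_names(self) -> list[str]:
        if self.pop_names is not None:
            if len(self.pop_names) != self.n_pops:
                raise ValueError("pop_names length must equal n_pops")
            return list(self.pop_names)
        names = list(DEFAULT_POP_NAMES[: self.n_pops])
        names += [f"P{i + 1}" for i in range(len(names), self.n_pops)]
        return names

    @property
    def reference_pop(self) -> str:
        return self.resolved_pop_names()[0]

    def chrom_names(self) -> list[str]:
        return [f"chr{i + 1}" for i in range(self.n_chroms)]

    def pop_F(self) -> list[float]:
        if isinstance(self.divergence_F, (int, float)):
            return [float(self.divergence_F)] * self.n_pops
        if len(self.divergence_F) != self.n_pops:
            raise ValueError("divergence_F list length must equal n_pops")
        return [float(f) for f in self.divergence_F]

    # -- calibration ----------------------------------------------------
    def expected_site_heterozygosity(self) -> float:
        """E[2p(1-p)] under the uniform ancestral spectrum, times the
        Balding-Nichols within-population factor (1 - mean F)."""
        a, b = self.maf_low, self.maf_high
        m = (a + b) / 2.0
        second_moment = (b - a) ** 2 / 12.0 + m ** 2
        e2pq = 2.0 * (m - second_moment)
        return e2pq * (1.0 - float(np.mean(self.pop_F())))

    def sites_per_chrom(self) -> int:
        """Variant count per chromosome so that expected genome-wide
        per-site pi equals ``target_pi``."""
        density = self.target_pi / self.expected_site_heterozygosity()
        n = int(round(density * self.chrom_length))
        if n < 1:
            raise ValueError("configuration yields zero variant sites")
        if n > self.chrom_length:
            raise ValueError("target_pi demands more sites than base pairs")
        return n


@dataclass
class TruthRecord:
    """Ground truth stored alongside every simulated cohort."""

    pop_F: dict[str, float]
    sweep_intervals: list[SweepInterval]
    Q: np.ndarray | None = None                      # samples x K, rows sum to 1
    ancestral_freq: dict[str, np.ndarray] = field(default_factory=dict)
    pop_freq: dict[str, np.ndarray] = field(default_factory=dict)  # chrom -> pops x sites

    def to_json(self, path: str | Path) -> None:
        """Scalar truth as JSON (per-site frequency arrays omitted)."""
        payload = {
            "pop_F": self.pop_F,
            "sweep_intervals": [asdict(iv) for iv in self.sweep_intervals],
            "Q": None if self.Q is None else np.asarray(self.Q).round(6).tolist(),
        }
        Path(path).write_text(json.dumps(payload, indent=2))


def simulate_cohort(config: SimulationConfig) -> tuple[GenotypeMatrix, TruthRecord]:
    """Draw one cohort; identical configs give identical output."""
    rng = np.random.default_rng(config.seed)
    pops = config.resolved_pop_names()
    pop_F = config.pop_F()
    n_per = config.samples_per_pop
    n_samples = config.n_pops * n_per
    sample_ids = [f"{p}_{i + 1:02d}" for p in pops for i in range(n_per)]
    pop_labels = {s: s.rsplit("_", 1)[0] for s in sample_ids}
    pop_slices = {p: slice(k * n_per, (k + 1) * n_per) for k, p in enumerate(pops)}

    n_sites = config.sites_per_chrom()
    chroms_out, pos_out, dos_out = [], [], []
    anc_freq: dict[str, np.ndarray] = {}
    pop_freq: dict[str, np.ndarray] = {}
    Q_true: np.ndarray | None = None

    if config.admixture_spec is not None:
        K, alpha = config.admixture_spec
        Q_true = rng.dirichlet([alpha] * K, size=n_samples)

    for chrom in config.chrom_names():
        positions = np.sort(rng.choice(config.chrom_length, size=n_sites,
                                       replace=False)) + 1
        p_anc = rng.uniform(config.maf_low, config.maf_high, size=n_sites)
        anc_freq[chrom] = p_anc

        if config.admixture_spec is not None:
            K, _ = config.admixture_spec
            P_src = _balding_nichols(rng, np.tile(p_anc, (K, 1)),
                                     np.full(K, float(np.mean(pop_F))))
            x = Q_true @ P_src                      # per-individual site freqs
            dosage = rng.binomial(2, x).astype(np.int8)
            pop_freq[chrom] = P_src
        else:
            freqs = _balding_nichols(rng, np.tile(p_anc, (config.n_pops, 1)),
                                     np.asarray(pop_F))
            freqs = _implant_sweeps(rng, config, chrom, positions, p_anc, freqs, pops)
            pop_freq[chrom] = freqs
            dosage = np.empty((n_samples, n_sites), dtype=np.int8)
            for k, p in enumerate(pops):
                dosage[pop_slices[p], :] = rng.binomial(
                    2, np.tile(freqs[k], (n_per, 1)))
        chroms_out.append(np.full(n_sites, chrom, dtype=object))
        pos_out.append(positions)
        dos_out.append(dosage)

    dosage = np.concatenate(dos_out, axis=1)
    total_sites = dosage.shape[1]

    k = config.depth_dispersion
    depth = rng.negative_binomial(
        n=k, p=k / (k + config.depth_mean), size=dosage.shape).astype(np.int64)
    if config.missing_rate > 0:
        miss = rng.random(dosage.shape) < config.missing_rate
        dosage = np.where(miss, np.int8(MISSING), dosage)

    geno = GenotypeMatrix(
        sample_ids=sample_ids,
        pop_labels=pop_labels,
        reference_pop=config.reference_pop,
        chrom=np.concatenate(chroms_out),
        pos=np.concatenate(pos_out),
        dosage=dosage,
        depth=depth,
    )
    truth = TruthRecord(
        pop_F={p: f for p, f in zip(pops, pop_F)},
        sweep_intervals=list(config.sweep_intervals),
        Q=Q_true,
        ancestral_freq=anc_freq,
        pop_freq=pop_freq,
    )
    assert total_sites == geno.n_variants
    return geno, truth


def _balding_nichols(rng: np.random.Generator, p: np.ndarray,
                     F: np.ndarray) -> np.ndarray:
    """Population frequencies around ancestral ``p`` (pops x sites) with
    per-population divergence ``F``; F = 0 returns ``p`` unchanged."""
    out = np.empty_like(p)
    for k in range(p.shape[0]):
        if F[k] == 0.0:
            out[k] = p[k]
        else:
            shape = (1.0 - F[k]) / F[k]
            out[k] = rng.beta(p[k] * shape, (1.0 - p[k]) * shape)
    return out


def _implant_sweeps(rng, config: SimulationConfig, chrom: str,
                    positions: np.ndarray, p_anc: np.ndarray,
                    freqs: np.ndarray, pops: list[str]) -> np.ndarray:
    """Push affected populations' frequencies to fixation inside sweep
    intervals.  Each site fixes independently with probability equal to
    ``diversity_reduction`` (fixing to the alt allele with probability
    p_anc), so expected heterozygosity drops by exactly that fraction.
    """
    freqs = freqs.copy()
    for iv in config.sweep_intervals:
        if iv.chrom != chrom:
            continue
        in_iv = (positions >= iv.start) & (positions < iv.end)
        affected = iv.populations
        if affected is None:
            affected = tuple(p for p in pops if p != config.reference_pop)
        for p in affected:
            k = pops.index(p)
            fix = in_iv & (rng.random(len(positions)) < iv.diversity_reduction)
            fixed_allele = (rng.random(len(positions)) < p_anc).astype(float)
            freqs[k] = np.where(fix, fixed_allele, freqs[k])
    return freqs


def simulate_genes(config: SimulationConfig, n_per_chrom: int = 10,
                   gene_length: int = 20_000, seed: int | None = None) -> list[Gene]:
    """Place non-overlapping gene features evenly spaced with random
    offsets, for sweep-region annotation demos and tests."""
    rng = np.random.default_rng(config.seed + 7_919 if seed is None else seed)
    genes = []
    slot = config.chrom_length // n_per_chrom
    if slot <= gene_length:
        raise ValueError("genes would overlap: reduce n_per_chrom or gene_length")
    for chrom in config.chrom_names():
        for i in range(n_per_chrom):
            offset = int(rng.integers(0, slot - gene_length))
            start = i * slot + offset + 1
            genes.append(Gene(gene_id=f"gene_{chrom}_{i + 1:03d}", chrom=chrom,
                              start=start, end=start + gene_length - 1))
    return genes


# ---------------------------------------------------------------------------
# scenario serialization
# ---------------------------------------------------------------------------

def config_from_yaml(path: str | Path) -> SimulationConfig:
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if "sweep_intervals" in raw:
        raw["sweep_intervals"] = [
            SweepInterval(**{**iv, "populations": tuple(iv["populations"])
                             if iv.get("populations") else None})
            for iv in raw["sweep_intervals"]
        ]
    if raw.get("admixture_spec") is not None:
        raw["admixture_spec"] = tuple(raw["admixture_spec"])
    if raw.get("pop_names") is not None:
        raw["pop_names"] = tuple(raw["pop_names"])
    return SimulationConfig(**raw)


def config_to_yaml(config: SimulationConfig, path: str | Path) -> None:
    raw = asdict(config)
    raw["sweep_intervals"] = [asdict(iv) for iv in config.sweep_intervals]
    Path(path).write_text(yaml.safe_dump(raw, sort_keys=False))


def write_cohort(geno: GenotypeMatrix, truth: TruthRecord,
                 outdir: str | Path) -> dict[str, Path]:
    """Serialize a simulated cohort (VCF, population table, truth JSON)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "vcf": outdir / "cohort.vcf",
        "pops": outdir / "populations.tsv",
        "truth": outdir / "truth.json",
    }
    write_vcf(geno, paths["vcf"])
    write_pop_table(geno, paths["pops"])
    truth.to_json(paths["truth"])
    return paths
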