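import numpy as np
import pytest
from hypothesis import settings

from popsweep import GenotypeMatrix, SimulationConfig, simulate_cohort

settings.register_profile("default", deadline=None, derandomize=True,
                          max_examples=25)
settings.load_profile("default")


def build_matrix(dosage, pops, reference_pop=None, pos=None, chrom="chr1",
                 depth=None):
    """Assemble a GenotypeMatrix from a dense dosage array and a list of
    per-sample population labels."""
    dosage = np.asarray(dosage, dtype=np.int8)
    n_samples, n_variants = dosage.shape
    sample_ids = [f"s{i}" for i in range(n_samples)]
    pop_labels = dict(zip(sample_ids, pops))
    if pos is None:
        pos = np.arange(1, n_variants + 1) * 100
    if isinstance(chrom, str):
        chrom = np.full(n_variants, chrom, dtype=object)
    return GenotypeMatrix(
        sample_ids=sample_ids,
        pop_labels=pop_labels,
        reference_pop=reference_pop or pops[0],
        chrom=np.asarray(chrom, dtype=object),
        pos=np.asarray(pos),
        dosage=dosage,
        depth=None if depth is None else np.asarray(depth),
    )


@pytest.fixture(scope="session")
def small_cohort():
    """A three-population cohort small enough for every statistic."""
    cfg = SimulationConfig(seed=11, n_pops=3, samples_per_pop=8, n_chroms=1,
                           chrom_length=400_000, divergence_F=0.02)
    geno, truth = simulate_cohort(cfg)
    return cfg, geno, truth
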