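"""Core genotype container shared by every analysis stage.

Genotypes are stored as alt-allele dosages (0, 1, 2) in a dense
samples x variants int8 array, with :data:`MISSING` (-1) marking
uncalled genotypes.  Coordinates are 1-based base pairs, as in VCF;
variants are kept sorted by (chromosome, position).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

#: Sentinel dosage for a missing genotype call.
MISSING: int = -1


@dataclass
class GenotypeMatrix:
    """Diploid genotype dosages for a multi-population cohort.

    Parameters
    ----------
    sample_ids
        Sample names, one per dosage row.
    pop_labels
        Mapping sample id -> population name.  Every sample must be
        labelled.
    reference_pop
        The population used as the baseline for reduction-of-diversity
        scans (in the motivating study design, a marine-protected-area
        population assumed to sit at zero fishing pressure).
    chrom, pos
        Per-variant chromosome identifier and 1-based position.
    dosage
        ``(n_samples, n_variants)`` int8 array of alt-allele counts in
        {0, 1, 2} with ``MISSING`` for uncalled genotypes.
    depth
        Optional per-genotype read depth, same shape as ``dosage``.
    """

    sample_ids: list[str]
    pop_labels: dict[str, str]
    reference_pop: str
    chrom: np.ndarray
    pos: np.ndarray
    dosage: np.ndarray
    depth: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.dosage = np.asarray(self.dosage, dtype=np.int8)
        if self.dosage.shape != (len(self.sample_ids), len(self.pos)):
            raise ValueError(
                f"dosage shape {self.dosage.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.pos)} variants"
            )
        if self.depth is not None:
            self.depth = np.asarray(self.depth)
            if self.depth.shape != self.dosage.shape:
                raise ValueError("depth shape must match dosage shape")
        unlabelled = [s for s in self.sample_ids if s not in self.pop_labels]
        if unlabelled:
            raise ValueError(f"samples without a population label: {unlabelled}")
        if self.reference_pop not in set(self.pop_labels.values()):
            raise ValueError(
                f"reference population {self.reference_pop!r} has no samples"
            )
        bad = ~np.isin(self.dosage, (0, 1, 2, MISSING))
        if bad.any():
            raise ValueError("dosage values must be in {0, 1, 2, MISSING}")
        order = self._sort_order()
        if not np.array_equal(order, np.arange(len(self.pos))):
            self.chrom = self.chrom[order]
            self.pos = self.pos[order]
            self.dosage = self.dosage[:, order]
            if self.depth is not None:
                self.depth = self.depth[:, order]

    def _sort_order(self) -> np.ndarray:
        return np.lexsort((self.pos, self.chrom.astype(str)))

    # -- basic geometry -------------------------------------------------
    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_variants(self) -> int:
        return len(self.pos)

    @property
    def populations(self) -> list[str]:
        """Population names in first-appearance order of their samples."""
        seen: dict[str, None] = {}
        for s in self.sample_ids:
            seen.setdefault(self.pop_labels[s], None)
        return list(seen)

    def sample_indices(self, pop: str) -> np.ndarray:
        idx = np.array(
            [i for i, s in enumerate(self.sample_ids) if self.pop_labels[s] == pop],
            dtype=np.intp,
        )
        if idx.size == 0:
            raise KeyError(f"no samples belong to population {pop!r}")
        return idx

    def pop_dosage(self, pop: str) -> np.ndarray:
        """Dosage rows for one population (view, samples x variants)."""
        return self.dosage[self.sample_indices(pop), :]

    def chrom_lengths(self) -> dict[str, int]:
        """Largest observed position per chromosome (used as its length
        when no explicit assembly lengths are supplied)."""
        out: dict[str, int] = {}
        for c in np.unique(self.chrom.astype(str)):
            out[c] = int(self.pos[self.chrom.astype(str) == c].max())
        return out

    # -- subsetting -----------------------------------------------------
    def take_variants(self, mask_or_index: np.ndarray) -> "GenotypeMatrix":
        """New matrix restricted to the selected variants (order kept)."""
        return replace(
            self,
            chrom=self.chrom[mask_or_index],
            pos=self.pos[mask_or_index],
            dosage=self.dosage[:, mask_or_index],
            depth=None if self.depth is None else self.depth[:, mask_or_index],
        )


@dataclass(frozen=True)
class FilterThresholds:
    """Site-level variant filters: keep a variant iff pooled minor allele
    frequency > ``min_maf``, mean per-genotype depth > ``min_depth`` and
    missing-genotype fraction < ``max_missing`` (all strict)."""

    min_maf: float = 0.01
    min_depth: float = 3.0
    max_missing: float = 0.2

    def __post_init__(self) -> None:
        if not 0.0 <= self.min_maf <= 0.5:
            raise ValueError("min_maf must lie in [0, 0.5]")
        if not 0.0 <= self.max_missing <= 1.0:
            raise ValueError("max_missing must lie in [0, 1]")
        if self.min_depth < 0:
            raise ValueError("min_depth must be non-negative")
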