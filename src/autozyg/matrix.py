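"""In-memory genotype container: sites x individuals with per-genotype
sequencing evidence.

Genotypes are coded 0 (hom ref), 1 (het), 2 (hom alt) and -1 (missing) in
an int8 array. Per-genotype depth, genotype quality, allele depths and
strand-resolved supporting read counts are carried when the source VCF
provides them and are ``None`` otherwise; filters that need an absent field
skip that criterion.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .genome import GenomeSpec

MISSING = -1

__all__ = ["GenotypeMatrix", "MISSING"]


@dataclass
class GenotypeMatrix:
    """Biallelic SNP genotypes ordered by (chromosome, position).

    Attributes
    ----------
    genome : GenomeSpec
    chrom_idx : (n_sites,) int32
        Index into ``genome.names`` per site; non-decreasing.
    pos : (n_sites,) int64
        0-based positions, strictly increasing within a chromosome.
    ref, alt : (n_sites,) arrays of single-base strings
    samples : list of str
    gt : (n_sites, n_samples) int8
    dp, gq : (n_sites, n_samples) int32 or None
        Per-genotype read depth and genotype quality.
    ad : (n_sites, n_samples, 2) int32 or None
        Ref/alt allele depths.
    dp4 : (n_sites, n_samples, 4) int32 or None
        Forward-ref, reverse-ref, forward-alt, reverse-alt read counts.
    """

    genome: GenomeSpec
    chrom_idx: np.ndarray
    pos: np.ndarray
    ref: np.ndarray
    alt: np.ndarray
    samples: list[str]
    gt: np.ndarray
    dp: np.ndarray | None = None
    gq: np.ndarray | None = None
    ad: np.ndarray | None = None
    dp4: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.chrom_idx = np.asarray(self.chrom_idx, dtype=np.int32)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.gt = np.asarray(self.gt, dtype=np.int8)
        if self.gt.shape != (self.n_sites, self.n_samples):
            raise ValueError("gt shape mismatch")
        if np.any(np.diff(self.chrom_idx) < 0):
            raise ValueError("sites not ordered by chromosome")
        same = np.diff(self.chrom_idx) == 0
        if np.any(np.diff(self.pos)[same] <= 0):
            raise ValueError("positions not strictly increasing within chromosome")
        lengths = np.asarray(self.genome.lengths)[self.chrom_idx]
        if self.pos.size and (np.any(self.pos < 0) or np.any(self.pos >= lengths)):
            raise ValueError("position outside chromosome bounds")

    @property
    def n_sites(self) -> int:
        return len(self.pos)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def take_sites(self, index: np.ndarray) -> "GenotypeMatrix":
        """Subset to sites selected by boolean mask or index array (order kept)."""
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)

        def sub(a):
            return a[index] if a is not None else None

        return replace(
            self,
            chrom_idx=self.chrom_idx[index],
            pos=self.pos[index],
            ref=self.ref[index],
            alt=self.alt[index],
            gt=self.gt[index],
            dp=sub(self.dp),
            gq=sub(self.gq),
            ad=sub(self.ad),
            dp4=sub(self.dp4),
        )

    def copy(self) -> "GenotypeMatrix":
        def cp(a):
            return a.copy() if a is not None else None

        return replace(
            self,
            chrom_idx=self.chrom_idx.copy(),
            pos=self.pos.copy(),
            ref=self.ref.copy(),
            alt=self.alt.copy(),
            gt=self.gt.copy(),
            dp=cp(self.dp),
            gq=cp(self.gq),
            ad=cp(self.ad),
            dp4=cp(self.dp4),
        )

    def sample_index(self, name: str) -> int:
        try:
            return self.samples.index(name)
        except ValueError:
            raise KeyError(f"sample {name!r} not in matrix") from None

    def sites_of(self, chrom: str) -> slice:
        """Contiguous slice of site rows on one chromosome."""
        ci = self.genome.index_of(chrom)
        lo = int(np.searchsorted(self.chrom_idx, ci, side="left"))
        hi = int(np.searchsorted(self.chrom_idx, ci, side="right"))
        return slice(lo, hi)

    def missing_fraction_per_sample(self) -> np.ndarray:
        if self.n_sites == 0:
            return np.zeros(self.n_samples)
        return (self.gt == MISSING).mean(axis=0)

    def missing_fraction_per_site(self) -> np.ndarray:
        if self.n_samples == 0:
            return np.zeros(self.n_sites)
        return (self.gt == MISSING).mean(axis=1)
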