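import numpy as np
import pytest

from autozyg.genome import GenomeSpec
from autozyg.matrix import MISSING, GenotypeMatrix


@pytest.fixture
def small_genome() -> GenomeSpec:
    return GenomeSpec(("chr1", "chr2", "chr3"), (1_000_000, 600_000, 300_000))


def random_matrix(
    genome: GenomeSpec,
    n_per_chrom: int,
    n_samples: int,
    rng: np.random.Generator,
    hom_runs: bool = True,
    geno_probs=(0.45, 0.15, 0.3, 0.1),
) -> GenotypeMatrix:
    """Random genotype fixture; optionally plants long homozygous stretches
    in half the individuals so ROH callers have something to find."""
    chrom_idx, pos = [], []
    for ci, length in enumerate(genome.lengths):
        n = min(n_per_chrom, length // 2)
        p = np.sort(rng.choice(length, size=n, replace=False))
        chrom_idx.append(np.full(n, ci, dtype=np.int32))
        pos.append(p.astype(np.int64))
    chrom_idx = np.concatenate(chrom_idx)
    pos = np.concatenate(pos)
    m = len(pos)
    gt = rng.choice(
        np.array([0, 1, 2, MISSING], dtype=np.int8),
        size=(m, n_samples),
        p=list(geno_probs),
    )
    if hom_runs and m > 0:
        for j in range(0, n_samples, 2):
            a = rng.integers(0, max(1, m // 2))
            b = min(m, a + rng.integers(m // 4, m))
            gt[a:b, j] = rng.choice(np.array([0, 2], dtype=np.int8), size=b - a)
    return GenotypeMatrix(
        genome=genome,
        chrom_idx=chrom_idx,
        pos=pos,
        ref=np.full(m, "A", dtype="U1"),
        alt=np.full(m, "G", dtype="U1"),
        samples=[f"ind{j}" for j in range(n_samples)],
        gt=gt,
    )
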