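"""Independent brute-force oracles used by the test suite.

These deliberately materialise every window / enumerate every case rather
than sharing any code path with the package implementation.
"""

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from autozyg.matrix import MISSING, GenotypeMatrix
from autozyg.roh import ROHParams, ROHSegment


def brute_force_roh(
    matrix: GenotypeMatrix, params: ROHParams
) -> dict[str, list[ROHSegment]]:
    """Literal window-enumeration ROH caller (the slow reference)."""
    out: dict[str, list[ROHSegment]] = {s: [] for s in matrix.samples}
    W = params.window_snp
    gap_bp = params.homozyg_gap * 1000.0
    for chrom in matrix.genome.names:
        sl = matrix.sites_of(chrom)
        pos = matrix.pos[sl]
        m = len(pos)
        if m < W:
            continue
        for si, sample in enumerate(matrix.samples):
            g = matrix.gt[sl, si]
            windows = sliding_window_view(g, W)  # every window, materialised
            passing = ((windows == 1).sum(axis=1) <= params.window_het) & (
                (windows == MISSING).sum(axis=1) <= params.window_missing
            )
            n_win = len(passing)
            eligible = np.zeros(m, dtype=bool)
            for j in range(m):
                lo = max(0, j - W + 1)
                hi = min(j, n_win - 1)
                frac = passing[lo : hi + 1].sum() / (hi - lo + 1)
                eligible[j] = frac >= params.hit_threshold
            j = 0
            while j < m:
                if not eligible[j]:
                    j += 1
                    continue
                k = j
                while k + 1 < m and eligible[k + 1]:
                    k += 1
                # split run at oversized gaps
                pieces, start = [], j
                for t in range(j, k):
                    if pos[t + 1] - pos[t] > gap_bp:
                        pieces.append((start, t))
                        start = t + 1
                pieces.append((start, k))
                for f, l in pieces:
                    seg = _finalize(g, pos, f, l, params, sample, chrom)
                    if seg is not None:
                        out[sample].append(seg)
                j = k + 1
    return out


def _finalize(g, pos, f, l, params, sample, chrom):
    while f <= l and g[f] not in (0, 2):
        f += 1
    while l >= f and g[l] not in (0, 2):
        l -= 1
    if l < f:
        return None
    n_snps = l - f + 1
    span = int(pos[l] - pos[f]) + 1
    n_het = int((g[f : l + 1] == 1).sum())
    if n_snps < params.homozyg_snp:
        return None
    if span < params.homozyg_kb * 1000.0:
        return None
    if span / 1000.0 / n_snps > params.homozyg_density:
        return None
    if n_het > params.homozyg_het:
        return None
    return ROHSegment(
        individual=sample,
        chrom=chrom,
        start=int(pos[f]),
        end=int(pos[l]) + 1,
        n_snps=n_snps,
        n_het=n_het,
    )


def random_roh_params(rng: np.random.Generator) -> ROHParams:
    """Random caller parameterisation on the scale of the fuzz fixtures
    (positions spaced ~1 kb)."""
    return ROHParams(
        homozyg_snp=int(rng.integers(2, 26)),
        homozyg_kb=float(rng.choice([1.0, 5.0, 20.0, 50.0])),
        homozyg_density=float(rng.choice([5.0, 20.0, 100.0, 1000.0])),
        homozyg_gap=float(rng.choice([5.0, 20.0, 100.0, 1000.0])),
        homozyg_het=int(rng.integers(0, 4)),
        window_snp=int(rng.integers(2, 16)),
        window_het=int(rng.integers(0, 3)),
        window_missing=int(rng.integers(0, 3)),
        hit_threshold=float(rng.choice([0.05, 0.3, 0.5, 1.0])),
    )


def mendel_error_enumeration() -> np.ndarray:
    """27-combination trio truth table by explicit allele enumeration:
    True where the child genotype is impossible."""
    table = np.zeros((3, 3, 3), dtype=bool)
    geno_alleles = {0: (0, 0), 1: (0, 1), 2: (1, 1)}
    for gs in range(3):
        for gd in range(3):
            reachable = {
                sa + da
                for sa in geno_alleles[gs]
                for da in geno_alleles[gd]
            }
            for gc in range(3):
                table[gs, gd, gc] = gc not in reachable
    return table
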