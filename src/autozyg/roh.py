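"""Sliding-window detection of runs of homozygosity (ROH).

Re-implements the windowed caller popularised by PLINK ``--homozyg``: a
window of fixed SNP count slides along each chromosome, each SNP is scored
by the fraction of overlapping windows that look homozygous, and maximal
stretches of high-scoring SNPs become segments subject to length, SNP-count,
density and heterozygote limits. Two parameter presets are provided, one
tuned for dense whole-genome (WGS) panels and one for sparse
reduced-representation (RRS) panels.

Also provides the L-parameter calculation (the minimum homozygous-SNP count
that bounds the expected number of false-positive runs at rate alpha), the
genome-coverage parameter used to tune caller settings, SNP density
evaluation, and a grid optimiser over parameter combinations.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .genome import GenomeSpec
from .matrix import MISSING, GenotypeMatrix

log = logging.getLogger(__name__)

__all__ = [
    "ROHParams",
    "ROHSegment",
    "WGS_PRESET",
    "RRS_PRESET",
    "compute_l_parameter",
    "mean_heterozygosity",
    "detect_roh",
    "meyermans_coverage",
    "snp_density",
    "optimize_parameters",
]


@dataclass(frozen=True)
class ROHParams:
    """Full parameterisation of the windowed caller.

    Attributes
    ----------
    homozyg_snp : int
        Minimum SNPs per emitted segment (the L-parameter).
    homozyg_kb : float
        Minimum segment span in kb.
    homozyg_density : float
        Maximum kb per SNP within a segment (minimum density).
    homozyg_gap : float
        Maximum gap between neighbouring SNPs in kb; larger gaps split runs.
    homozyg_het : int
        Maximum heterozygous calls tolerated inside a segment.
    window_snp : int
        Sliding-window size in SNPs.
    window_het : int
        Maximum heterozygous calls for a window to pass.
    window_missing : int
        Maximum missing calls for a window to pass.
    hit_threshold : float
        Minimum fraction of passing windows containing a SNP for the SNP to
        be run-eligible (PLINK default 0.05).
    """

    homozyg_snp: int = 40
    homozyg_kb: float = 300.0
    homozyg_density: float = 100.0
    homozyg_gap: float = 1000.0
    homozyg_het: int = 3
    window_snp: int = 50
    window_het: int = 3
    window_missing: int = 5
    hit_threshold: float = 0.05

    def __post_init__(self) -> None:
        if self.window_snp < 1:
            raise ValueError("window size must be >= 1")
        if not (0.0 < self.hit_threshold <= 1.0):
            raise ValueError("hit threshold must be in (0, 1]")
        for name in ("homozyg_snp", "homozyg_het", "window_het", "window_missing"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.homozyg_kb < 0 or self.homozyg_density <= 0 or self.homozyg_gap <= 0:
            raise ValueError("kb/density/gap parameters must be positive")


# The two published parameterisations: dense WGS panels and sparse RRS panels.
WGS_PRESET = ROHParams(
    homozyg_snp=40,
    homozyg_kb=300.0,
    homozyg_density=100.0,
    homozyg_gap=1000.0,
    homozyg_het=3,
    window_snp=50,
    window_het=3,
    window_missing=5,
)
RRS_PRESET = replace(WGS_PRESET, homozyg_snp=37, homozyg_density=130.0, window_snp=25)

PRESETS = {"wgs": WGS_PRESET, "rrs": RRS_PRESET}


@dataclass(frozen=True)
class ROHSegment:
    """One homozygous run. ``start``/``end`` are 0-based half-open; the
    1-based inclusive interval written to ``.hom`` files is
    (start+1, end) with bp length end - start."""

    individual: str
    chrom: str
    start: int
    end: int
    n_snps: int
    n_het: int

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("segment end must exceed start")

    @property
    def length_bp(self) -> int:
        return self.end - self.start


def compute_l_parameter(
    alpha: float,
    n_snps: int,
    n_individuals: int,
    mean_het: float,
    rounding: str = "nearest",
) -> int:
    """Minimum homozygous-SNP count L bounding expected false-positive runs.

    L = ln(alpha / (n_s * n_i)) / ln(1 - het): the run length at which the
    chance of observing a purely random stretch of homozygous calls anywhere
    in the dataset falls below the false-positive rate ``alpha``.
    Monotone: increases with n_s * n_i, decreases with het.
    """
    if not (0.0 < alpha < 1.0):
        raise ValueError("alpha must be in (0, 1)")
    if n_snps < 1 or n_individuals < 1:
        raise ValueError("n_snps and n_individuals must be >= 1")
    if not (0.0 < mean_het < 1.0):
        raise ValueError("mean heterozygosity must be strictly inside (0, 1)")
    raw = math.log(alpha / (n_snps * n_individuals)) / math.log(1.0 - mean_het)
    if rounding == "nearest":
        return int(round(raw))
    if rounding == "floor":
        return int(math.floor(raw))
    if rounding == "ceil":
        return int(math.ceil(raw))
    raise ValueError(f"unknown rounding mode {rounding!r}")


def mean_heterozygosity(matrix: GenotypeMatrix) -> float:
    """Mean across sites of (het calls / non-missing calls); sites where all
    calls are missing are excluded."""
    called = matrix.gt != MISSING
    n_called = called.sum(axis=1)
    keep = n_called > 0
    if not keep.any():
        return 0.0
    het = (matrix.gt == 1).sum(axis=1)
    with np.errstate(invalid="ignore"):
        frac = het[keep] / n_called[keep]
    return float(frac.mean())


def _runs_of(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of True as (first, last) index pairs, inclusive."""
    if not mask.any():
        return []
    padded = np.concatenate(([False], mask, [False]))
    d = np.diff(padded.astype(np.int8))
    starts = np.flatnonzero(d == 1)
    ends = np.flatnonzero(d == -1) - 1
    return list(zip(starts.tolist(), ends.tolist()))


def detect_roh(
    matrix: GenotypeMatrix, params: ROHParams
) -> dict[str, list[ROHSegment]]:
    """Call ROH segments per individual with the sliding-window algorithm.

    For each individual and chromosome: (1) slide a window of
    ``window_snp`` consecutive SNPs one SNP at a time; a window passes iff
    its het calls <= ``window_het`` and missing calls <= ``window_missing``;
    (2) score each SNP by passing windows containing it / windows containing
    it; (3) SNPs scoring >= ``hit_threshold`` are run-eligible; (4) maximal
    consecutive eligible stretches are split where the gap to the next SNP
    exceeds ``homozyg_gap`` kb and trimmed to start and end on homozygous
    calls; (5) a candidate is emitted iff its SNP count >= ``homozyg_snp``,
    span >= ``homozyg_kb``, kb-per-SNP <= ``homozyg_density`` and het calls
    <= ``homozyg_het``.

    Chromosomes with fewer SNPs than the window yield no segments (logged).
    Windows never span chromosomes.
    """
    out: dict[str, list[ROHSegment]] = {s: [] for s in matrix.samples}
    W = params.window_snp
    gap_bp = params.homozyg_gap * 1000.0
    for ci, chrom in enumerate(matrix.genome.names):
        sl = matrix.sites_of(chrom)
        m = sl.stop - sl.start
        if m == 0:
            continue
        if m < W:
            log.info("detect_roh: %s has %d < %d SNPs; no windows", chrom, m, W)
            continue
        G = matrix.gt[sl]
        pos = matrix.pos[sl]
        het = G == 1
        miss = G == MISSING
        # window het/missing counts via cumulative sums, all samples at once
        het_cs = np.zeros((m + 1, matrix.n_samples), dtype=np.int32)
        np.cumsum(het, axis=0, out=het_cs[1:])
        miss_cs = np.zeros_like(het_cs)
        np.cumsum(miss, axis=0, out=miss_cs[1:])
        win_het = het_cs[W:] - het_cs[:-W]
        win_miss = miss_cs[W:] - miss_cs[:-W]
        passing = (win_het <= params.window_het) & (win_miss <= params.window_missing)
        n_win = m - W + 1
        pass_cs = np.zeros((n_win + 1, matrix.n_samples), dtype=np.int32)
        np.cumsum(passing, axis=0, out=pass_cs[1:])
        j = np.arange(m)
        lo = np.maximum(0, j - W + 1)
        hi = np.minimum(j, n_win - 1)
        n_containing = (hi - lo + 1)[:, None]
        n_passing = pass_cs[hi + 1] - pass_cs[lo]
        eligible = n_passing / n_containing >= params.hit_threshold
        gap_after = np.diff(pos) > gap_bp  # split between j and j+1
        for si, sample in enumerate(matrix.samples):
            segs = out[sample]
            for first, last in _runs_of(eligible[:, si]):
                # split candidate run at oversized gaps
                cuts = np.flatnonzero(gap_after[first:last]) + first
                bounds = [first] + [c + 1 for c in cuts] + [last + 1]
                for a, b in zip(bounds[:-1], bounds[1:]):
                    seg = _finalize_candidate(
                        G[:, si], pos, a, b - 1, params, sample, chrom
                    )
                    if seg is not None:
                        segs.append(seg)
    return out


def _finalize_candidate(
    g: np.ndarray,
    pos: np.ndarray,
    first: int,
    last: int,
    params: ROHParams,
    sample: str,
    chrom: str,
) -> ROHSegment | None:
    # trim so the segment starts and ends on homozygous calls
    while first <= last and g[first] in (1, MISSING):
        first += 1
    while last >= first and g[last] in (1, MISSING):
        last -= 1
    if last < first:
        return None
    n_snps = last - first + 1
    span_bp = int(pos[last] - pos[first]) + 1
    n_het = int(np.count_nonzero(g[first : last + 1] == 1))
    if n_snps < params.homozyg_snp:
        return None
    if span_bp < params.homozyg_kb * 1000.0:
        return None
    if span_bp / 1000.0 / n_snps > params.homozyg_density:
        return None
    if n_het > params.homozyg_het:
        return None
    return ROHSegment(
        individual=sample,
        chrom=chrom,
        start=int(pos[first]),
        end=int(pos[last]) + 1,
        n_snps=n_snps,
        n_het=n_het,
    )


def meyermans_coverage(matrix: GenotypeMatrix, params: ROHParams) -> float:
    """Genome-coverage parameter: percentage of the autosomal genome lying
    in ROH-callable territory under ``params``.

    Callable territory is the union, over chromosomes, of maximal runs of
    consecutive SNPs whose adjacent gaps are <= ``homozyg_gap`` kb and that
    satisfy the SNP-count, span and density requirements — i.e., intervals
    where a fully homozygous individual could have a segment called. Used to
    compare parameter combinations and SNP panels; denser panels cover more
    of the genome.
    """
    gap_bp = params.homozyg_gap * 1000.0
    callable_bp = 0
    for chrom in matrix.genome.names:
        sl = matrix.sites_of(chrom)
        pos = matrix.pos[sl]
        if pos.size == 0:
            continue
        cuts = np.flatnonzero(np.diff(pos) > gap_bp)
        bounds = [0] + [c + 1 for c in cuts.tolist()] + [pos.size]
        for a, b in zip(bounds[:-1], bounds[1:]):
            n = b - a
            span_bp = int(pos[b - 1] - pos[a]) + 1
            if (
                n >= params.homozyg_snp
                and span_bp >= params.homozyg_kb * 1000.0
                and span_bp / 1000.0 / n <= params.homozyg_density
            ):
                callable_bp += span_bp
    return 100.0 * callable_bp / matrix.genome.autosomal_length


def snp_density(matrix: GenotypeMatrix, genome: GenomeSpec) -> pd.DataFrame:
    """SNPs per Mb per chromosome plus an overall row (total SNPs / total length)."""
    rows = []
    for ci, (name, length) in enumerate(zip(genome.names, genome.lengths)):
        n = int(np.count_nonzero(matrix.chrom_idx == ci))
        rows.append({"chrom": name, "n_snps": n, "snps_per_mb": n / (length / 1e6)})
    total_n = matrix.n_sites
    total_len = sum(genome.lengths)
    rows.append(
        {
            "chrom": "overall",
            "n_snps": total_n,
            "snps_per_mb": total_n / (total_len / 1e6),
        }
    )
    return pd.DataFrame(rows)


def optimize_parameters(
    matrix: GenotypeMatrix, grid: list[ROHParams]
) -> tuple[ROHParams, pd.DataFrame]:
    """Evaluate genome coverage over a parameter grid and return the argmax
    (ties broken by grid order) plus the full coverage table."""
    if not grid:
        raise ValueError("empty parameter grid")
    coverages = [meyermans_coverage(matrix, p) for p in grid]
    table = pd.DataFrame(
        [{**vars(p), "coverage_pct": c} for p, c in zip(grid, coverages)]
    )
    best = grid[int(np.argmax(coverages))]
    return best, table
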