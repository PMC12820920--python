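"""Inbreeding coefficients and concordance statistics from ROH segments.

F_ROH is the fraction of the autosomal genome covered by ROH:
F_ROH = sum(L_ROH) / L_Auto, with L_Auto the configured total autosomal
length (not the SNP-spanned length — this choice changes absolute values
and is therefore fixed and documented). F_ROH_CHR applies the same ratio
per chromosome; its chromosome-length-weighted mean over autosomes equals
genome-wide F_ROH exactly.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .genome import GenomeSpec
from .matrix import GenotypeMatrix
from .roh import ROHSegment

log = logging.getLogger(__name__)

__all__ = [
    "froh",
    "froh_per_chromosome",
    "size_class_spectrum",
    "profile_table",
    "concordance",
    "missingness_check",
    "SIZE_CLASS_EDGES_MB",
]

# half-open bins in Mb; boundary values go to the upper class
SIZE_CLASS_EDGES_MB = (0.0, 2.0, 4.0, 8.0, 16.0, np.inf)


def _check_segments(segments: list[ROHSegment], genome: GenomeSpec) -> None:
    for s in segments:
        if s.end > genome.length_of(s.chrom):
            raise ValueError(
                f"segment {s.individual} {s.chrom}:{s.start}-{s.end} "
                "beyond chromosome end"
            )


def froh(
    segments: list[ROHSegment],
    genome: GenomeSpec,
    individuals: list[str] | None = None,
) -> pd.Series:
    """Genome-wide F_ROH per individual (autosomal ROH length / L_Auto).

    ``individuals`` fixes the output index (individuals without segments get
    0); by default only individuals appearing in ``segments`` are reported.
    """
    _check_segments(segments, genome)
    if individuals is None:
        individuals = sorted({s.individual for s in segments})
    total = dict.fromkeys(individuals, 0)
    auto = {genome.names[i] for i in genome.autosome_indices}
    for s in segments:
        if s.chrom in auto and s.individual in total:
            total[s.individual] += s.length_bp
    l_auto = genome.autosomal_length
    return pd.Series({i: total[i] / l_auto for i in individuals}, name="froh")


def froh_per_chromosome(
    segments: list[ROHSegment],
    genome: GenomeSpec,
    individuals: list[str] | None = None,
) -> pd.DataFrame:
    """F_ROH_CHR: individuals x chromosomes matrix of per-chromosome ROH
    fractions (autosomes only)."""
    _check_segments(segments, genome)
    if individuals is None:
        individuals = sorted({s.individual for s in segments})
    auto_idx = genome.autosome_indices
    chroms = [genome.names[i] for i in auto_idx]
    mat = pd.DataFrame(0.0, index=list(individuals), columns=chroms)
    for s in segments:
        if s.chrom in mat.columns and s.individual in mat.index:
            mat.loc[s.individual, s.chrom] += s.length_bp
    lengths = np.array([genome.lengths[i] for i in auto_idx], dtype=float)
    return mat / lengths


def size_class_spectrum(
    segments: list[ROHSegment],
    edges_mb: tuple[float, ...] = SIZE_CLASS_EDGES_MB,
) -> pd.Series:
    """Segment counts per length class; bins are half-open [lo, hi) Mb."""
    lengths_mb = np.array([s.length_bp / 1e6 for s in segments])
    counts, _ = np.histogram(lengths_mb, bins=np.asarray(edges_mb))
    labels = [
        f"[{lo:g}-{hi:g})" if np.isfinite(hi) else f">={lo:g}"
        for lo, hi in zip(edges_mb[:-1], edges_mb[1:])
    ]
    return pd.Series(counts, index=labels, name="n_segments")


def profile_table(
    segments: list[ROHSegment],
    genome: GenomeSpec,
    matrix: GenotypeMatrix | None = None,
    individuals: list[str] | None = None,
) -> pd.DataFrame:
    """Per-individual inbreeding profile: F_ROH, segment count, total ROH
    length, size-class counts and (when a matrix is given) per-individual
    missing-call fraction."""
    if individuals is None:
        if matrix is not None:
            individuals = list(matrix.samples)
        else:
            individuals = sorted({s.individual for s in segments})
    f = froh(segments, genome, individuals)
    by_ind: dict[str, list[ROHSegment]] = {i: [] for i in individuals}
    for s in segments:
        if s.individual in by_ind:
            by_ind[s.individual].append(s)
    rows = []
    for ind in individuals:
        segs = by_ind[ind]
        spectrum = size_class_spectrum(segs)
        rows.append(
            {
                "individual": ind,
                "froh": f[ind],
                "n_segments": len(segs),
                "total_roh_bp": int(sum(s.length_bp for s in segs)),
                **{f"n_{k}_mb": int(v) for k, v in spectrum.items()},
            }
        )
    out = pd.DataFrame(rows).set_index("individual")
    if matrix is not None:
        miss = pd.Series(
            matrix.missing_fraction_per_sample(), index=matrix.samples
        )
        out["missing_fraction"] = miss.reindex(out.index)
    return out


def concordance(
    profile_a: pd.Series | pd.DataFrame,
    profile_b: pd.Series | pd.DataFrame,
    level: str = "genome",
) -> pd.DataFrame:
    """Pearson correlation between two F_ROH profiles over shared individuals.

    ``level="genome"`` correlates genome-wide values (one row); with
    per-chromosome DataFrames and ``level="chromosome"`` each chromosome is
    correlated separately, with undefined correlations (constant columns)
    reported as NaN and flagged in the log. Returns columns (level, r, p, n).
    """
    shared = profile_a.index.intersection(profile_b.index)
    dropped = len(profile_a.index.union(profile_b.index)) - len(shared)
    if dropped:
        log.info("concordance: %d individuals not shared; excluded", dropped)
    if len(shared) < 3:
        raise ValueError("need at least 3 shared individuals")
    a, b = profile_a.loc[shared], profile_b.loc[shared]
    rows = []
    if level == "genome":
        if isinstance(a, pd.DataFrame):
            raise ValueError("genome-level concordance expects Series inputs")
        r, p = stats.pearsonr(a, b)
        rows.append({"level": "genome", "r": r, "p": p, "n": len(shared)})
    elif level == "chromosome":
        for chrom in a.columns:
            x, y = a[chrom], b[chrom]
            if x.std(ddof=0) == 0 or y.std(ddof=0) == 0:
                log.info("concordance: %s constant; correlation undefined", chrom)
                rows.append(
                    {"level": chrom, "r": np.nan, "p": np.nan, "n": len(shared)}
                )
            else:
                r, p = stats.pearsonr(x, y)
                rows.append({"level": chrom, "r": r, "p": p, "n": len(shared)})
    else:
        raise ValueError(f"unknown level {level!r}")
    return pd.DataFrame(rows)


def missingness_check(matrix: GenotypeMatrix, f: pd.Series) -> tuple[float, float]:
    """Pearson correlation between per-individual missing-call fraction and
    F_ROH — a confounding check; a strong correlation would indicate that
    missing data, not autozygosity, drives the inbreeding estimates."""
    miss = pd.Series(matrix.missing_fraction_per_sample(), index=matrix.samples)
    shared = miss.index.intersection(f.index)
    if len(shared) < 3:
        raise ValueError("need at least 3 shared individuals")
    r, p = stats.pearsonr(miss.loc[shared], f.loc[shared])
    return float(r), float(p)
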