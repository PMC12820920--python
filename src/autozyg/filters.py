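"""Genotype- and site-level filtering plus Mendelian-error removal.

Genotype calls failing depth, quality, heterozygous allelic-balance or
strand-support criteria are blanked to missing; sites are then dropped for
excess missingness, masked (repeat) positions or non-autosomal location, in
that fixed order so missingness reflects blanked genotypes. No minor-allele
frequency or linkage filtering is applied anywhere: monomorphic sites are
deliberately retained, since frequency pruning biases homozygosity-based
inbreeding estimates in small populations.

Two presets mirror the published pipelines: a stringent one for deep WGS
data (DP > 4, GQ > 20, >= 5 supporting reads, <= 10% site missingness) and
a permissive one for shallow RRS data (DP > 1, >= 2 reads, <= 20%
missingness).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .genome import MaskSet
from .matrix import MISSING, GenotypeMatrix

log = logging.getLogger(__name__)

__all__ = [
    "FilterThresholds",
    "WGS_FILTERS",
    "RRS_FILTERS",
    "filter_genotypes",
    "filter_sites",
    "apply_filters",
    "find_mendelian_errors",
    "remove_mendelian_errors",
]


@dataclass(frozen=True)
class FilterThresholds:
    """Thresholds for genotype- and site-level filtering.

    A genotype passes iff DP > ``min_depth``, GQ > ``min_quality``, its
    heterozygous allelic balance (alt reads / ref+alt reads) lies inside
    ``het_ab_bounds`` and its supporting reads total >= ``min_read_support``
    (with ``strict_strand`` additionally requiring every forward/reverse
    ref/alt stratum to be covered by at least one read). Criteria whose
    evidence field is absent from the matrix are skipped and logged.
    """

    min_depth: int = 4
    min_quality: int = 20
    het_ab_bounds: tuple[float, float] = (0.2, 0.8)
    min_read_support: int = 5
    strict_strand: bool = False
    max_site_missing: float = 0.10
    biallelic_only: bool = True
    exclude_sex_chromosomes: bool = True
    mask: MaskSet | None = None

    def __post_init__(self) -> None:
        lo, hi = self.het_ab_bounds
        if not (0.0 <= lo < hi <= 1.0):
            raise ValueError("het allelic-balance bounds must satisfy 0 <= lo < hi <= 1")
        if not (0.0 <= self.max_site_missing <= 1.0):
            raise ValueError("max site missing fraction must be in [0, 1]")


WGS_FILTERS = FilterThresholds()
RRS_FILTERS = replace(
    WGS_FILTERS, min_depth=1, min_read_support=2, max_site_missing=0.20
)
PRESETS = {"wgs": WGS_FILTERS, "rrs": RRS_FILTERS}


def filter_genotypes(
    matrix: GenotypeMatrix, thresholds: FilterThresholds
) -> GenotypeMatrix:
    """Blank genotype calls failing the per-genotype criteria.

    Returns a new matrix; per-criterion failure counts are logged and stored
    under ``meta["genotype_filter_counts"]``.
    """
    out = matrix.copy()
    gt = out.gt
    called = gt != MISSING
    counts: dict[str, int] = {}

    def fail(mask: np.ndarray, name: str) -> None:
        mask = mask & called
        counts[name] = int(mask.sum())
        gt[mask] = MISSING

    if matrix.dp is not None:
        fail(matrix.dp <= thresholds.min_depth, "depth")
    else:
        log.info("filter_genotypes: no DP field; depth criterion skipped")
    if matrix.gq is not None:
        fail(matrix.gq <= thresholds.min_quality, "quality")
    else:
        log.info("filter_genotypes: no GQ field; quality criterion skipped")
    if matrix.ad is not None:
        lo, hi = thresholds.het_ab_bounds
        denom = matrix.ad.sum(axis=2)
        with np.errstate(invalid="ignore", divide="ignore"):
            ab = np.where(denom > 0, matrix.ad[:, :, 1] / np.maximum(denom, 1), np.nan)
        het = gt == 1
        bad_ab = het & ((ab < lo) | (ab > hi))
        fail(bad_ab, "het_allelic_balance")
    else:
        log.info("filter_genotypes: no AD field; allelic-balance criterion skipped")
    support = None
    if matrix.dp4 is not None:
        support = matrix.dp4.sum(axis=2)
        if thresholds.strict_strand:
            uncovered = (matrix.dp4 < 1).any(axis=2)
            fail(uncovered, "strand_coverage")
    elif matrix.ad is not None:
        support = matrix.ad.sum(axis=2)
        log.info("filter_genotypes: no DP4 field; read support taken from AD")
    if support is not None:
        fail(support < thresholds.min_read_support, "read_support")
    else:
        log.info("filter_genotypes: no DP4/AD field; read-support criterion skipped")
    for name, c in counts.items():
        log.info("filter_genotypes: %s removed %d calls", name, c)
    out.meta = dict(out.meta, genotype_filter_counts=counts)
    return out


def filter_sites(
    matrix: GenotypeMatrix, thresholds: FilterThresholds
) -> GenotypeMatrix:
    """Drop sites failing missingness, mask or sex-chromosome rules.

    Site order is preserved; per-rule drop counts go to
    ``meta["site_filter_counts"]``. There is no MAF rule: monomorphic sites
    are retained.
    """
    drop = np.zeros(matrix.n_sites, dtype=bool)
    counts: dict[str, int] = {}
    miss = matrix.missing_fraction_per_site()
    m = miss > thresholds.max_site_missing
    counts["missingness"] = int(m.sum())
    drop |= m
    if thresholds.exclude_sex_chromosomes:
        auto = np.asarray(matrix.genome.is_autosome)[matrix.chrom_idx]
        counts["sex_chromosome"] = int((~auto & ~drop).sum())
        drop |= ~auto
    if thresholds.mask is not None:
        masked = np.zeros(matrix.n_sites, dtype=bool)
        for ci, chrom in enumerate(matrix.genome.names):
            rows = matrix.chrom_idx == ci
            if rows.any():
                masked[rows] = thresholds.mask.contains(chrom, matrix.pos[rows])
        counts["masked_region"] = int((masked & ~drop).sum())
        drop |= masked
    for name, c in counts.items():
        log.info("filter_sites: %s dropped %d sites", name, c)
    out = matrix.take_sites(~drop)
    out.meta = dict(out.meta, site_filter_counts=counts)
    return out


def apply_filters(
    matrix: GenotypeMatrix, thresholds: FilterThresholds
) -> GenotypeMatrix:
    """Genotype-level filtering first, then site-level (fixed order)."""
    return filter_sites(filter_genotypes(matrix, thresholds), thresholds)


# ---------------------------------------------------------------------------
# Mendelian errors


def _mendel_lut() -> np.ndarray:
    """lut[gs, gd, gc] True iff child genotype gc is impossible given
    parent genotypes gs, gd (codes 0/1/2 = alt-allele dose)."""
    lut = np.zeros((3, 3, 3), dtype=bool)
    alleles = {0: [(0, 0)], 1: [(0, 1)], 2: [(1, 1)]}
    for gs in range(3):
        for gd in range(3):
            possible = set()
            for sa in set(sum(alleles[gs], ())):
                for da in set(sum(alleles[gd], ())):
                    possible.add(sa + da)
            for gc in range(3):
                lut[gs, gd, gc] = gc not in possible
    return lut


_MENDEL_LUT = _mendel_lut()


def find_mendelian_errors(
    matrix: GenotypeMatrix, trios: pd.DataFrame
) -> pd.DataFrame:
    """Flag genotype combinations impossible under Mendelian transmission.

    ``trios`` needs columns child, sire, dam (sample names). A combination
    is an error iff the child genotype cannot be assembled from one allele
    of each parent; combinations with any missing member are never flagged.
    Returns a table (site, child, sire, dam, reason).
    """
    for col in ("child", "sire", "dam"):
        if col not in trios.columns:
            raise ValueError(f"trio table missing column {col!r}")
    records = []
    for t in trios.itertuples():
        ic = matrix.sample_index(str(t.child))
        isire = matrix.sample_index(str(t.sire))
        idam = matrix.sample_index(str(t.dam))
        gc_, gs, gd = matrix.gt[:, ic], matrix.gt[:, isire], matrix.gt[:, idam]
        ok = (gc_ != MISSING) & (gs != MISSING) & (gd != MISSING)
        bad = np.zeros(matrix.n_sites, dtype=bool)
        bad[ok] = _MENDEL_LUT[gs[ok], gd[ok], gc_[ok]]
        for site in np.flatnonzero(bad):
            records.append(
                {
                    "site": int(site),
                    "child": str(t.child),
                    "sire": str(t.sire),
                    "dam": str(t.dam),
                    "reason": f"child {gc_[site]} impossible from "
                    f"{gs[site]} x {gd[site]}",
                }
            )
    return pd.DataFrame(
        records, columns=["site", "child", "sire", "dam", "reason"]
    )


def remove_mendelian_errors(
    matrix: GenotypeMatrix, errors: pd.DataFrame, mode: str = "genotype"
) -> GenotypeMatrix:
    """Remove flagged Mendelian errors.

    ``mode="genotype"`` (default) blanks the trio members' genotypes at each
    flagged site; ``mode="site"`` drops flagged sites entirely.
    """
    if mode not in ("genotype", "site"):
        raise ValueError(f"unknown mode {mode!r}")
    if len(errors) == 0:
        return matrix.copy()
    if mode == "site":
        drop = np.zeros(matrix.n_sites, dtype=bool)
        drop[errors["site"].to_numpy()] = True
        return matrix.take_sites(~drop)
    out = matrix.copy()
    for r in errors.itertuples():
        for name in (r.child, r.sire, r.dam):
            out.gt[r.site, matrix.sample_index(str(name))] = MISSING
    return out
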