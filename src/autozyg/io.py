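"""Readers and writers for the formats the pipeline touches.

VCF is read through cyvcf2 and written by a plain-text serializer covering
the subset of VCF 4.2 this package produces (biallelic SNPs with GT and
optional DP/GQ/AD/DP4 per genotype). ROH segments interoperate with PLINK
``--homozyg`` output via a ``.hom``-style whitespace table. Pedigree and
phenotype tables are tab-delimited with fixed headers. All on-disk
coordinates are 1-based inclusive (VCF, ``.hom``) or 0-based half-open
(BED); in memory everything is 0-based half-open.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from cyvcf2 import VCF

from .genome import GenomeSpec, MaskSet
from .matrix import MISSING, GenotypeMatrix
from .roh import ROHSegment

log = logging.getLogger(__name__)

PEDIGREE_COLUMNS = ["id", "sire", "dam", "sex", "generation"]
PHENOTYPE_COLUMNS = [
    "female_id",
    "year",
    "clutch_id",
    "egg_id",
    "clutch_size",
    "eggs_hatched",
    "egg_length_mm",
    "egg_width_mm",
    "egg_volume_ml",
    "age",
    "generation",
]
HOM_COLUMNS = ["IID", "CHR", "POS1", "POS2", "KB", "NSNP", "NHET"]


# ---------------------------------------------------------------------------
# VCF


def _format_present(vcf: VCF, tag: str) -> bool:
    return f"##FORMAT=<ID={tag}," in vcf.raw_header


def read_vcf(path: str | Path, genome: GenomeSpec) -> GenotypeMatrix:
    """Read biallelic SNPs from a VCF into a GenotypeMatrix.

    Non-SNP and multiallelic records are skipped (count logged). Records
    must be sorted by (chromosome, position) in the order of ``genome``;
    unknown chromosomes and unsorted input raise ``ValueError``.
    """
    vcf = VCF(str(path), gts012=True)
    samples = list(vcf.samples)
    has = {t: _format_present(vcf, t) for t in ("DP", "GQ", "AD", "DP4")}

    chrom_idx: list[int] = []
    pos: list[int] = []
    ref: list[str] = []
    alt: list[str] = []
    gts: list[np.ndarray] = []
    dps, gqs, ads, dp4s = [], [], [], []
    n_skipped = 0
    last = (-1, -1)
    for v in vcf:
        if len(v.ALT) != 1 or len(v.REF) != 1 or len(v.ALT[0]) != 1:
            n_skipped += 1
            continue
        ci = genome.index_of(v.CHROM)
        key = (ci, v.POS)
        if key <= last:
            raise ValueError(
                f"VCF not sorted at {v.CHROM}:{v.POS} (expected order of genome table)"
            )
        last = key
        chrom_idx.append(ci)
        pos.append(v.POS - 1)
        ref.append(v.REF)
        alt.append(v.ALT[0])
        g = np.asarray(v.gt_types, dtype=np.int8)
        g[g == 3] = MISSING
        gts.append(g)
        if has["DP"]:
            dps.append(_clean_int(v.format("DP"), (len(samples),)))
        if has["GQ"]:
            gqs.append(_clean_int(v.format("GQ"), (len(samples),)))
        if has["AD"]:
            ads.append(_clean_int(v.format("AD"), (len(samples), 2)))
        if has["DP4"]:
            dp4s.append(_clean_int(v.format("DP4"), (len(samples), 4)))
    if n_skipped:
        log.info("read_vcf: skipped %d non-SNP/multiallelic records", n_skipped)

    n = len(pos)
    mat = GenotypeMatrix(
        genome=genome,
        chrom_idx=np.asarray(chrom_idx, dtype=np.int32),
        pos=np.asarray(pos, dtype=np.int64),
        ref=np.asarray(ref, dtype="U1"),
        alt=np.asarray(alt, dtype="U1"),
        samples=samples,
        gt=(np.vstack(gts) if n else np.zeros((0, len(samples)), dtype=np.int8)),
        dp=np.vstack(dps).reshape(n, -1) if dps else None,
        gq=np.vstack(gqs).reshape(n, -1) if gqs else None,
        ad=np.asarray(ads) if ads else None,
        dp4=np.asarray(dp4s) if dp4s else None,
        meta={"skipped_records": n_skipped},
    )
    return mat


def _clean_int(a, shape) -> np.ndarray:
    if a is None:
        return np.full(shape, MISSING, dtype=np.int32)
    a = np.asarray(a, dtype=np.int64).reshape(shape)
    a = np.where((a < 0) | (a > 2**31 - 2), MISSING, a)
    return a.astype(np.int32)


_GT_STR = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def write_vcf(matrix: GenotypeMatrix, path: str | Path) -> None:
    """Write the matrix as an uncompressed VCF 4.2 file."""
    fmt_tags = ["GT"]
    if matrix.dp is not None:
        fmt_tags.append("DP")
    if matrix.gq is not None:
        fmt_tags.append("GQ")
    if matrix.ad is not None:
        fmt_tags.append("AD")
    if matrix.dp4 is not None:
        fmt_tags.append("DP4")
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=autozyg\n")
        for name, length in zip(matrix.genome.names, matrix.genome.lengths):
            fh.write(f"##contig=<ID={name},length={length}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        if "DP" in fmt_tags:
            fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        if "GQ" in fmt_tags:
            fh.write('##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">\n')
        if "AD" in fmt_tags:
            fh.write('##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allele depths">\n')
        if "DP4" in fmt_tags:
            fh.write(
                '##FORMAT=<ID=DP4,Number=4,Type=Integer,'
                'Description="Fwd ref, rev ref, fwd alt, rev alt reads">\n'
            )
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(matrix.samples)
            + "\n"
        )
        fmt = ":".join(fmt_tags)
        for i in range(matrix.n_sites):
            chrom = matrix.genome.names[matrix.chrom_idx[i]]
            fields = [
                chrom,
                str(int(matrix.pos[i]) + 1),
                ".",
                str(matrix.ref[i]),
                str(matrix.alt[i]),
                ".",
                "PASS",
                ".",
                fmt,
            ]
            for j in range(matrix.n_samples):
                parts = [_GT_STR[int(matrix.gt[i, j])]]
                if matrix.dp is not None:
                    parts.append(_int_or_dot(matrix.dp[i, j]))
                if matrix.gq is not None:
                    parts.append(_int_or_dot(matrix.gq[i, j]))
                if matrix.ad is not None:
                    parts.append(",".join(_int_or_dot(x) for x in matrix.ad[i, j]))
                if matrix.dp4 is not None:
                    parts.append(",".join(_int_or_dot(x) for x in matrix.dp4[i, j]))
                fields.append(":".join(parts))
            fh.write("\t".join(fields) + "\n")


def _int_or_dot(x) -> str:
    return "." if int(x) == MISSING else str(int(x))


# ---------------------------------------------------------------------------
# PLINK .hom


def write_hom(segments: list[ROHSegment], path: str | Path) -> None:
    """Write ROH segments as a PLINK ``.hom``-style table.

    One row per segment with individual, chromosome, first/last SNP position
    (1-based inclusive), length in kb, SNP count and het count, sorted by
    (individual, chromosome, start).
    """
    rows = sorted(segments, key=lambda s: (s.individual, s.chrom, s.start))
    with open(path, "w") as fh:
        fh.write("\t".join(HOM_COLUMNS) + "\n")
        for s in rows:
            kb = (s.end - s.start) / 1000.0  # half-open span == 1-based inclusive bp
            fh.write(
                f"{s.individual}\t{s.chrom}\t{s.start + 1}\t{s.end}\t"
                f"{kb:.3f}\t{s.n_snps}\t{s.n_het}\n"
            )


def read_hom(path: str | Path) -> list[ROHSegment]:
    df = pd.read_csv(path, sep=r"\s+")
    missing = set(HOM_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f".hom file missing columns: {sorted(missing)}")
    return [
        ROHSegment(
            individual=str(r.IID),
            chrom=str(r.CHR),
            start=int(r.POS1) - 1,
            end=int(r.POS2),
            n_snps=int(r.NSNP),
            n_het=int(r.NHET),
        )
        for r in df.itertuples()
    ]


# ---------------------------------------------------------------------------
# Tables


def read_bed(path: str | Path, genome: GenomeSpec | None = None) -> MaskSet:
    """Read a BED3 file (0-based half-open) into a MaskSet."""
    items = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("track", "browser", "#")):
                continue
            parts = line.split()
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: expected >=3 BED columns")
            try:
                items.append((parts[0], int(parts[1]), int(parts[2])))
            except ValueError as e:
                raise ValueError(f"{path}:{lineno}: {e}") from None
    try:
        return MaskSet.from_intervals(items, genome)
    except ValueError as e:
        raise ValueError(f"{path}: {e}") from None


def read_pedigree(path: str | Path) -> pd.DataFrame:
    """Read a tab-delimited pedigree (id, sire, dam, sex, generation).

    Founders have empty or ``0`` parent fields. Every named parent must
    itself appear as an individual, and parents must precede offspring.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = set(PEDIGREE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"pedigree missing columns: {sorted(missing)}")
    df["generation"] = df["generation"].astype(int)
    df = df.fillna({"sire": "0", "dam": "0"})
    seen: set[str] = set()
    for lineno, row in enumerate(df.itertuples(), start=2):
        if row.id in seen:
            raise ValueError(f"pedigree line {lineno}: duplicate id {row.id!r}")
        for parent in (row.sire, row.dam):
            if parent not in ("0", "") and parent not in seen:
                raise ValueError(
                    f"pedigree line {lineno}: parent {parent!r} unknown or "
                    "does not precede offspring"
                )
        seen.add(row.id)
    return df


def read_phenotypes(path: str | Path) -> pd.DataFrame:
    """Read the per-egg reproductive phenotype table.

    Keys are (female_id, year, clutch_id, egg_id); duplicates, hatched
    counts above clutch size and non-positive volumes are validation errors.
    """
    df = pd.read_csv(path, sep="\t")
    missing = set(PHENOTYPE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"phenotype table missing columns: {sorted(missing)}")
    key = ["female_id", "year", "clutch_id", "egg_id"]
    dup = df.duplicated(subset=key)
    if dup.any():
        first = df[dup].iloc[0]
        raise ValueError(
            f"duplicate phenotype row for {tuple(first[k] for k in key)}"
        )
    bad = df["eggs_hatched"] > df["clutch_size"]
    if bad.any():
        raise ValueError(
            f"eggs_hatched exceeds clutch_size on {int(bad.sum())} rows"
        )
    if (df["egg_volume_ml"] <= 0).any():
        raise ValueError("non-positive egg volume")
    return df


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Config


def load_config(path: str | Path) -> dict:
    """Load a YAML run configuration and echo it to the log so a run can be
    reproduced from its log alone."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    for line in yaml.safe_dump(cfg, sort_keys=True).splitlines():
        log.info("config: %s", line)
    return cfg
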