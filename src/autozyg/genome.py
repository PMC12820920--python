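"""Genome coordinate frame: chromosome table and interval masks.

Internal coordinates are 0-based half-open throughout the package; the
1-based inclusive convention of VCF and PLINK ``.hom`` files is converted
at the I/O boundary only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["GenomeSpec", "MaskSet", "default_genome"]


@dataclass(frozen=True)
class GenomeSpec:
    """Ordered chromosome table with lengths in base pairs.

    Parameters
    ----------
    names : tuple of str
        Chromosome labels, unique, in analysis order.
    lengths : tuple of int
        Chromosome lengths in bp, positive.
    is_autosome : tuple of bool, optional
        Autosome flag per chromosome; defaults to all-autosomal.
    """

    names: tuple[str, ...]
    lengths: tuple[int, ...]
    is_autosome: tuple[bool, ...] = ()

    def __post_init__(self) -> None:
        if len(set(self.names)) != len(self.names):
            raise ValueError("chromosome names must be unique")
        if len(self.lengths) != len(self.names):
            raise ValueError("names and lengths differ in length")
        if any(l <= 0 for l in self.lengths):
            raise ValueError("chromosome lengths must be positive")
        if not self.is_autosome:
            object.__setattr__(self, "is_autosome", tuple(True for _ in self.names))
        elif len(self.is_autosome) != len(self.names):
            raise ValueError("is_autosome flag length mismatch")

    @property
    def n_chromosomes(self) -> int:
        return len(self.names)

    @property
    def autosome_indices(self) -> np.ndarray:
        return np.flatnonzero(np.asarray(self.is_autosome))

    @property
    def autosomal_length(self) -> int:
        """L_Auto: total autosomal genome length in bp (the F_ROH denominator)."""
        return int(sum(l for l, a in zip(self.lengths, self.is_autosome) if a))

    def index_of(self, name: str) -> int:
        try:
            return self.names.index(name)
        except ValueError:
            raise KeyError(f"unknown chromosome {name!r}") from None

    def length_of(self, name: str) -> int:
        return self.lengths[self.index_of(name)]

    @classmethod
    def from_table(cls, df) -> "GenomeSpec":
        """Build from a DataFrame with columns chrom, length[, autosome]."""
        names = tuple(str(c) for c in df["chrom"])
        lengths = tuple(int(l) for l in df["length"])
        if "autosome" in df.columns:
            auto = tuple(bool(a) for a in df["autosome"])
        else:
            auto = ()
        return cls(names, lengths, auto)


def default_genome(
    n_autosomes: int = 23, total_mb: float = 200.0, decay: float = 0.88
) -> GenomeSpec:
    """Synthetic avian-style karyotype: lengths decay geometrically from
    macro- to micro-chromosomes so that the shortest chromosomes may be too
    short to harbour any callable run of homozygosity.

    With the defaults, chromosome 1 is ~25 Mb and chromosome 23 ~1.5 Mb on a
    200 Mb genome.
    """
    if n_autosomes < 1:
        raise ValueError("need at least one autosome")
    w = decay ** np.arange(n_autosomes)
    lengths = np.round(w / w.sum() * total_mb * 1e6).astype(int)
    lengths = np.maximum(lengths, 1)
    names = tuple(f"chr{i + 1}" for i in range(n_autosomes))
    return GenomeSpec(names, tuple(int(l) for l in lengths))


def _merge_intervals(iv: np.ndarray) -> np.ndarray:
    if iv.size == 0:
        return iv.reshape(0, 2)
    iv = iv[np.argsort(iv[:, 0], kind="stable")]
    out = [list(iv[0])]
    for s, e in iv[1:]:
        if s <= out[-1][1]:
            out[-1][1] = max(out[-1][1], e)
        else:
            out.append([s, e])
    return np.asarray(out, dtype=np.int64)


@dataclass
class MaskSet:
    """Per-chromosome masked intervals, 0-based half-open, stored merged."""

    intervals: dict[str, np.ndarray] = field(default_factory=dict)

    @classmethod
    def from_intervals(
        cls, items: list[tuple[str, int, int]], genome: GenomeSpec | None = None
    ) -> "MaskSet":
        by_chrom: dict[str, list[tuple[int, int]]] = {}
        for chrom, start, end in items:
            if end <= start or start < 0:
                raise ValueError(f"invalid interval {chrom}:{start}-{end}")
            if genome is not None and end > genome.length_of(chrom):
                raise ValueError(
                    f"interval {chrom}:{start}-{end} beyond chromosome end"
                )
            by_chrom.setdefault(chrom, []).append((start, end))
        ivs = {
            c: _merge_intervals(np.asarray(v, dtype=np.int64))
            for c, v in by_chrom.items()
        }
        return cls(ivs)

    def contains(self, chrom: str, positions: np.ndarray) -> np.ndarray:
        """Boolean mask: which of ``positions`` (0-based) fall in a masked interval."""
        positions = np.asarray(positions)
        iv = self.intervals.get(chrom)
        if iv is None or iv.size == 0:
            return np.zeros(positions.shape, dtype=bool)
        idx = np.searchsorted(iv[:, 0], positions, side="right") - 1
        ok = idx >= 0
        hit = np.zeros(positions.shape, dtype=bool)
        hit[ok] = positions[ok] < iv[idx[ok], 1]
        return hit

    @property
    def total_masked(self) -> int:
        return int(
            sum((iv[:, 1] - iv[:, 0]).sum() for iv in self.intervals.values())
        )
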