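"""Synthetic genotype and phenotype data with known ground truth.

The generator emulates the study system end to end: a small managed
population with pedigree-driven consanguinity (including a lek mating
system in which few dominant males sire most offspring), gene dropping of
founder haplotypes with Poisson crossovers to obtain genotypes *and* the
true identical-by-descent (IBD) tracts behind them, thinning of the dense
panel to a sparse clustered reduced-representation panel, and repeated
female reproductive measures (clutch size, eggs hatched, egg volume) with
a planted genome-wide inbreeding effect on the standardized scale.

Every operation takes an explicit seed and is reproducible from it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from scipy.special import gammaln

import numpy as np
import pandas as pd

from .genome import GenomeSpec, default_genome
from .matrix import MISSING, GenotypeMatrix
from .pheno import egg_volume, invert_egg_volume

__all__ = [
    "Pedigree",
    "IBDTrack",
    "simulate_pedigree",
    "pedigree_inbreeding",
    "simulate_genomes",
    "emulate_rrs",
    "add_genotype_errors",
    "PhenotypeEffects",
    "simulate_phenotypes",
]


@dataclass
class Pedigree:
    """Ordered pedigree: parents always precede offspring.

    ``sire``/``dam`` hold row indices into ``ids`` or -1 for founders;
    ``sex`` is "M"/"F"; ``generation`` is 0 for founders.
    """

    ids: list[str]
    sire: np.ndarray
    dam: np.ndarray
    sex: np.ndarray
    generation: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.ids)
        self.sire = np.asarray(self.sire, dtype=np.int64)
        self.dam = np.asarray(self.dam, dtype=np.int64)
        for p in (self.sire, self.dam):
            if np.any(p >= np.arange(n)):
                raise ValueError("parents must precede offspring")
        if np.any((self.sire == -1) != (self.dam == -1)):
            raise ValueError("individuals must have both parents or neither")

    @property
    def n(self) -> int:
        return len(self.ids)

    def is_founder(self, i: int) -> bool:
        return self.sire[i] < 0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "id": self.ids,
                "sire": ["0" if s < 0 else self.ids[s] for s in self.sire],
                "dam": ["0" if d < 0 else self.ids[d] for d in self.dam],
                "sex": self.sex,
                "generation": self.generation,
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "Pedigree":
        index = {str(r): i for i, r in enumerate(df["id"])}

        def parent(x):
            return -1 if str(x) in ("0", "", "nan") else index[str(x)]

        return cls(
            ids=[str(x) for x in df["id"]],
            sire=np.array([parent(x) for x in df["sire"]]),
            dam=np.array([parent(x) for x in df["dam"]]),
            sex=np.asarray(df["sex"], dtype="U1"),
            generation=np.asarray(df["generation"], dtype=int),
        )


def simulate_pedigree(
    n_founders: int,
    n_generations: int,
    mating_scheme: str = "random",
    seed: int = 0,
    offspring_per_generation: int | None = None,
    n_dominant_males: int = 2,
) -> Pedigree:
    """Simulate a pedigree under a consanguinity-controlling mating scheme.

    Schemes
    -------
    ``random``
        Each offspring draws an independent sire and dam from the previous
        generation.
    ``halfsib``
        Sires are drawn from a small pool (a quarter of available males),
        biasing toward paternal half-sib relationships.
    ``lek``
        Sires come from ``n_dominant_males`` dominant males per generation,
        mimicking a lek in which few males father most offspring.
    ``fullsib_line``
        Deterministic brother-sister chain: one pair per generation, always
        full sibs; pedigree inbreeding rises 0, 1/4, 3/8, ...

    ``n_generations = 0`` returns founders only (no parent links).
    """
    if n_founders < 2:
        raise ValueError("need at least two founders")
    if n_generations < 0:
        raise ValueError("n_generations must be >= 0")
    rng = np.random.default_rng(seed)
    ids = [f"F{i}" for i in range(n_founders)]
    sex = ["M" if i % 2 == 0 else "F" for i in range(n_founders)]
    sire = [-1] * n_founders
    dam = [-1] * n_founders
    gen = [0] * n_founders
    per_gen = offspring_per_generation or n_founders
    if mating_scheme == "fullsib_line":
        per_gen = 2
    prev = list(range(n_founders))
    counter = 0
    for g in range(1, n_generations + 1):
        males = [i for i in prev if sex[i] == "M"]
        females = [i for i in prev if sex[i] == "F"]
        if not males or not females:
            raise ValueError(f"generation {g - 1} lacks one sex; cannot mate")
        if mating_scheme == "random":
            sire_pool = males
        elif mating_scheme == "halfsib":
            k = max(1, len(males) // 4)
            sire_pool = list(rng.choice(males, size=k, replace=False))
        elif mating_scheme == "lek":
            k = min(n_dominant_males, len(males))
            sire_pool = list(rng.choice(males, size=k, replace=False))
        elif mating_scheme == "fullsib_line":
            sire_pool = males[:1]
            females = females[:1]
        else:
            raise ValueError(f"unknown mating scheme {mating_scheme!r}")
        cur = []
        for j in range(per_gen):
            s = int(rng.choice(sire_pool))
            d = int(rng.choice(females))
            ids.append(f"G{g}_{counter}")
            counter += 1
            sex.append("M" if j % 2 == 0 else "F")
            sire.append(s)
            dam.append(d)
            gen.append(g)
            cur.append(len(ids) - 1)
        prev = cur
    return Pedigree(
        ids=ids,
        sire=np.array(sire),
        dam=np.array(dam),
        sex=np.array(sex, dtype="U1"),
        generation=np.array(gen),
    )


def pedigree_inbreeding(ped: Pedigree) -> np.ndarray:
    """Wright's pedigree inbreeding coefficient per individual, computed via
    the tabular kinship recursion (F_i = kinship(sire_i, dam_i))."""
    n = ped.n
    phi = np.zeros((n, n))
    for i in range(n):
        s, d = ped.sire[i], ped.dam[i]
        if s < 0:
            phi[i, i] = 0.5
        else:
            phi[i, i] = 0.5 * (1.0 + phi[s, d])
        for j in range(i):
            if s < 0:
                val = 0.0
            else:
                val = 0.5 * (phi[s, j] + phi[d, j])
            phi[i, j] = phi[j, i] = val
    F = np.zeros(n)
    for i in range(n):
        s, d = ped.sire[i], ped.dam[i]
        F[i] = phi[s, d] if s >= 0 else 0.0
    return F


@dataclass
class IBDTrack:
    """True autozygosity per individual: IBD intervals (0-based half-open)
    per chromosome, and the realized genome-wide autozygous fraction."""

    tracts: dict[str, dict[str, np.ndarray]]
    f_true: pd.Series

    def total_ibd_bp(self, individual: str) -> int:
        return int(
            sum(
                (iv[:, 1] - iv[:, 0]).sum()
                for iv in self.tracts[individual].values()
                if iv.size
            )
        )


# --- gene dropping ----------------------------------------------------------


def _meiosis(
    hap_a: tuple[np.ndarray, np.ndarray],
    hap_b: tuple[np.ndarray, np.ndarray],
    length: int,
    rate_cm_per_mb: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Recombine a parent's two ancestry mosaics into one gamete.

    A mosaic is (starts, ids): segment start positions (starts[0] == 0) and
    the founder-haplotype id carried from each start to the next. Crossover
    count is Poisson(genetic length in Morgans), positions uniform, no
    interference.
    """
    n_x = rng.poisson(length / 1e6 * rate_cm_per_mb / 100.0)
    cuts = np.sort(rng.integers(1, length, size=n_x)) if n_x else np.empty(0, int)
    cur = int(rng.integers(2))
    sources = (hap_a, hap_b)
    starts_out: list[int] = []
    ids_out: list[int] = []
    block_edges = np.concatenate(([0], cuts, [length]))
    for a, b in zip(block_edges[:-1], block_edges[1:]):
        if a == b:
            continue
        starts, ids = sources[cur]
        lo = int(np.searchsorted(starts, a, side="right")) - 1
        hi = int(np.searchsorted(starts, b, side="left"))
        for k in range(lo, hi):
            s = max(int(starts[k]), int(a))
            fid = int(ids[k])
            if ids_out and ids_out[-1] == fid:
                pass  # merge contiguous same-ancestry blocks
            else:
                starts_out.append(s)
                ids_out.append(fid)
        cur = 1 - cur
    return np.asarray(starts_out, dtype=np.int64), np.asarray(ids_out, dtype=np.int64)


def _ibd_intervals(
    hap1: tuple[np.ndarray, np.ndarray],
    hap2: tuple[np.ndarray, np.ndarray],
    length: int,
) -> np.ndarray:
    """Intervals where the two mosaics carry the same founder haplotype."""
    edges = np.unique(np.concatenate((hap1[0], hap2[0], [0, length])))
    edges = edges[edges < length]
    out = []
    for a, b in zip(edges, np.append(edges[1:], length)):
        id1 = hap1[1][np.searchsorted(hap1[0], a, side="right") - 1]
        id2 = hap2[1][np.searchsorted(hap2[0], a, side="right") - 1]
        if id1 == id2:
            if out and out[-1][1] == a:
                out[-1][1] = int(b)
            else:
                out.append([int(a), int(b)])
    return np.asarray(out, dtype=np.int64).reshape(-1, 2)


def simulate_genomes(
    pedigree: Pedigree,
    genome: GenomeSpec | None = None,
    maf_distribution=None,
    recomb_rate_cM_per_Mb: float = 1.0,
    snp_density_per_Mb: float = 1000.0,
    seed: int = 0,
) -> tuple[GenotypeMatrix, IBDTrack]:
    """Gene-drop founder haplotypes through the pedigree.

    Founder haplotypes are mutually distinct by construction (founders are
    unrelated and non-inbred), carry alleles drawn per site from
    ``maf_distribution`` (default Uniform(0.05, 0.5) allele frequency), and
    are transmitted with Poisson crossovers at ``recomb_rate_cM_per_Mb``.
    Returns the genotype matrix at the requested SNP density together with
    the exact IBD tracts (where both haplotypes descend from the same
    founder haplotype) and realized autozygous fraction F_true.
    """
    if genome is None:
        genome = default_genome()
    if snp_density_per_Mb <= 0:
        raise ValueError("SNP density must be positive")
    if genome.autosomal_length <= 0:
        raise ValueError("zero-length genome")
    rng = np.random.default_rng(seed)

    # site map: fixed count per chromosome, uniform random positions
    chrom_idx, pos = [], []
    for ci, length in enumerate(genome.lengths):
        n_c = max(1, min(int(round(snp_density_per_Mb * length / 1e6)), length))
        # draw-with-replacement + unique (collisions negligible at these
        # densities); top up the rare shortfall
        p = np.unique(rng.integers(0, length, size=n_c))
        while p.size < n_c:
            p = np.unique(
                np.concatenate([p, rng.integers(0, length, size=n_c - p.size)])
            )
        chrom_idx.append(np.full(p.size, ci, dtype=np.int32))
        pos.append(p.astype(np.int64))
    chrom_idx = np.concatenate(chrom_idx)
    pos = np.concatenate(pos)
    n_sites = pos.size

    # founder haplotype alleles
    n_f = int(np.count_nonzero(pedigree.sire < 0))
    if maf_distribution is None:
        freqs = rng.uniform(0.05, 0.5, size=n_sites)
    else:
        freqs = np.asarray(maf_distribution(rng, n_sites))
    alleles = (rng.random((2 * n_f, n_sites)) < freqs).astype(np.int8)

    # drop ancestry mosaics through the pedigree
    n_chrom = genome.n_chromosomes
    mosaics: list[list[tuple]] = []  # [individual][chrom] -> (hap1, hap2)
    founder_count = 0
    for i in range(pedigree.n):
        per_chrom = []
        if pedigree.is_founder(i):
            h1, h2 = 2 * founder_count, 2 * founder_count + 1
            founder_count += 1
            for ci in range(n_chrom):
                per_chrom.append(
                    (
                        (np.zeros(1, np.int64), np.array([h1], np.int64)),
                        (np.zeros(1, np.int64), np.array([h2], np.int64)),
                    )
                )
        else:
            s, d = int(pedigree.sire[i]), int(pedigree.dam[i])
            for ci, length in enumerate(genome.lengths):
                g_pat = _meiosis(*mosaics[s][ci], length, recomb_rate_cM_per_Mb, rng)
                g_mat = _meiosis(*mosaics[d][ci], length, recomb_rate_cM_per_Mb, rng)
                per_chrom.append((g_pat, g_mat))
        mosaics.append(per_chrom)

    # genotypes + IBD tracts
    gt = np.empty((n_sites, pedigree.n), dtype=np.int8)
    tracts: dict[str, dict[str, np.ndarray]] = {}
    ibd_bp = np.zeros(pedigree.n)
    starts_of_chrom = np.searchsorted(chrom_idx, np.arange(n_chrom), side="left")
    ends_of_chrom = np.searchsorted(chrom_idx, np.arange(n_chrom), side="right")
    for i, ind in enumerate(pedigree.ids):
        tracts[ind] = {}
        for ci, (name, length) in enumerate(zip(genome.names, genome.lengths)):
            lo, hi = starts_of_chrom[ci], ends_of_chrom[ci]
            p = pos[lo:hi]
            h1, h2 = mosaics[i][ci]
            id1 = h1[1][np.searchsorted(h1[0], p, side="right") - 1]
            id2 = h2[1][np.searchsorted(h2[0], p, side="right") - 1]
            site_idx = np.arange(lo, hi)
            gt[lo:hi, i] = alleles[id1, site_idx] + alleles[id2, site_idx]
            iv = _ibd_intervals(h1, h2, length)
            tracts[ind][name] = iv
            if genome.is_autosome[ci] and iv.size:
                ibd_bp[i] += (iv[:, 1] - iv[:, 0]).sum()

    f_true = pd.Series(ibd_bp / genome.autosomal_length, index=pedigree.ids)
    ref = np.full(n_sites, "A", dtype="U1")
    alt = np.full(n_sites, "G", dtype="U1")
    matrix = GenotypeMatrix(
        genome=genome,
        chrom_idx=chrom_idx,
        pos=pos,
        ref=ref,
        alt=alt,
        samples=list(pedigree.ids),
        gt=gt,
    )
    return matrix, IBDTrack(tracts=tracts, f_true=f_true)


# --- panel degradation ------------------------------------------------------


def emulate_rrs(
    matrix: GenotypeMatrix,
    target_density_per_Mb: float,
    clustering: float = 0.0,
    extra_missing_rate: float = 0.0,
    seed: int = 0,
) -> GenotypeMatrix:
    """Thin a dense panel to a sparse reduced-representation-like panel.

    With ``clustering`` (kb) > 0, retained SNPs are drawn around random
    "restriction site" anchors so they clump locally, as restriction-enzyme
    libraries do; with 0 the thinning is uniform Bernoulli. Additional
    genotypes are set missing at ``extra_missing_rate`` to mimic the lower
    per-site call rate of sparse libraries.
    """
    if target_density_per_Mb <= 0:
        raise ValueError("target density must be positive")
    total_mb = sum(matrix.genome.lengths) / 1e6
    source_density = matrix.n_sites / total_mb
    if target_density_per_Mb > source_density * (1 + 1e-9):
        raise ValueError("target density exceeds source density")
    rng = np.random.default_rng(seed)
    if (
        abs(target_density_per_Mb - source_density) < 1e-9
        and clustering == 0
        and extra_missing_rate == 0
    ):
        return matrix.copy()

    if clustering <= 0:
        p = target_density_per_Mb / source_density
        keep = rng.random(matrix.n_sites) < p
    else:
        radius_bp = clustering * 1000.0
        keep = np.zeros(matrix.n_sites, dtype=bool)
        for ci, length in enumerate(matrix.genome.lengths):
            rows = np.flatnonzero(matrix.chrom_idx == ci)
            if rows.size == 0:
                continue
            target_n = target_density_per_Mb * length / 1e6
            local_density = rows.size / length  # SNPs per bp
            per_anchor = max(local_density * 2 * radius_bp, 1e-9)
            n_anchors = max(1, int(round(target_n / per_anchor)))
            anchors = rng.integers(0, length, size=n_anchors)
            p = matrix.pos[rows]
            near = np.zeros(rows.size, dtype=bool)
            for a in anchors:
                near |= np.abs(p - a) <= radius_bp
            keep[rows] = near
    thinned = matrix.take_sites(keep)
    if extra_missing_rate > 0:
        blank = rng.random(thinned.gt.shape) < extra_missing_rate
        gt = thinned.gt.copy()
        gt[blank] = MISSING
        thinned.gt = gt
    return thinned


def add_genotype_errors(
    matrix: GenotypeMatrix,
    het_to_hom_rate: float = 0.0,
    hom_to_het_rate: float = 0.0,
    seed: int = 0,
) -> GenotypeMatrix:
    """Plant genotyping errors: hets collapse to a random homozygote at
    ``het_to_hom_rate``; homozygotes gain a spurious het call at
    ``hom_to_het_rate``. Missing calls are untouched."""
    for r in (het_to_hom_rate, hom_to_het_rate):
        if not (0.0 <= r <= 1.0):
            raise ValueError("error rates must be in [0, 1]")
    rng = np.random.default_rng(seed)
    out = matrix.copy()
    gt = out.gt
    if het_to_hom_rate > 0:
        hit = (gt == 1) & (rng.random(gt.shape) < het_to_hom_rate)
        gt[hit] = rng.choice(np.array([0, 2], dtype=np.int8), size=int(hit.sum()))
    if hom_to_het_rate > 0:
        hit = ((gt == 0) | (gt == 2)) & (rng.random(gt.shape) < hom_to_het_rate)
        gt[hit] = 1
    return out


# --- phenotypes -------------------------------------------------------------


@dataclass
class PhenotypeEffects:
    """Planted effects on the standardized-predictor scale.

    Count-trait betas act on the log link; volume betas are in mL. Defaults
    reproduce the observed trait means (clutch 2.74, hatched 1.06, volume
    38.57 mL) and the reported standardized inbreeding effect on hatching
    success (-0.44), with weak effects elsewhere.
    """

    clutch_intercept: float = float(np.log(2.74))
    hatch_intercept: float = float(np.log(1.06))
    volume_intercept: float = 38.57
    beta_froh_clutch: float = -0.02
    beta_froh_hatch: float = -0.44
    beta_froh_volume: float = -1.0
    beta_age_clutch: float = -0.17
    beta_age_hatch: float = -0.03
    beta_gen_volume: float = -3.7
    sd_volume_resid: float = 2.0
    sd_volume_id: float = 2.5
    sd_volume_clutch: float = 1.0
    egg_k: float = 0.51e-3
    egg_aspect_mean: float = 1.31
    egg_aspect_sd: float = 0.03


def simulate_phenotypes(
    f_true: pd.Series,
    effects: PhenotypeEffects | None = None,
    random_sd_id: float = 0.3,
    random_sd_year: float = 0.2,
    n_years: int = 3,
    clutch_model: str = "poisson",
    seed: int = 0,
    ages: pd.Series | None = None,
    generations: pd.Series | None = None,
) -> pd.DataFrame:
    """Simulate repeated reproductive measures for the females in ``f_true``.

    Count traits use a log link: log-rate = intercept + beta_F * std(F) +
    age/generation terms + N(0, sd_id) + N(0, sd_year), with F standardized
    as (F - mean) / (2 SD). Eggs hatched is capped at clutch size by
    rejection redraws under the default ``clutch_model="poisson"``, or drawn
    Binomial(clutch, logistic rate) under ``"binomial"``. Egg volume is
    Gaussian per egg with female and clutch random intercepts; egg length
    and width are back-generated so the geometric volume formula reproduces
    the simulated volume exactly.
    """
    if effects is None:
        effects = PhenotypeEffects()
    if random_sd_id < 0 or random_sd_year < 0:
        raise ValueError("random-effect SDs must be non-negative")
    if clutch_model not in ("poisson", "binomial"):
        raise ValueError(f"unknown clutch model {clutch_model!r}")
    rng = np.random.default_rng(seed)
    females = list(f_true.index)
    f = np.asarray(f_true, dtype=float)
    sd = f.std(ddof=0)
    z_f = (f - f.mean()) / (2 * sd) if sd > 0 else np.zeros_like(f)

    if ages is None:
        ages = pd.Series(rng.integers(8, 53, size=len(females)), index=females)
    if generations is None:
        generations = pd.Series(rng.integers(1, 4, size=len(females)), index=females)
    z_age = _std2(np.asarray(ages, dtype=float))
    z_gen = _std2(np.asarray(generations, dtype=float))

    years = [2000 + y for y in range(n_years)]
    b_year = {
        t: {y: rng.normal(0, random_sd_year) for y in years}
        for t in ("clutch", "hatch")
    }
    rows = []
    for i, female in enumerate(females):
        b_id_c = rng.normal(0, random_sd_id)
        b_id_h = rng.normal(0, random_sd_id)
        b_id_v = rng.normal(0, effects.sd_volume_id)
        for year in years:
            clutch_id = f"{female}_{year}_c1"
            eta_c = (
                effects.clutch_intercept
                + effects.beta_froh_clutch * z_f[i]
                + effects.beta_age_clutch * z_age[i]
                + b_id_c
                + b_year["clutch"][year]
            )
            clutch = 0
            while clutch < 1:  # observed clutches have at least one egg
                clutch = int(rng.poisson(np.exp(eta_c)))
            eta_h = (
                effects.hatch_intercept
                + effects.beta_froh_hatch * z_f[i]
                + effects.beta_age_hatch * z_age[i]
                + b_id_h
                + b_year["hatch"][year]
            )
            if clutch_model == "poisson":
                hatched = _truncated_poisson(np.exp(eta_h), clutch, rng)
            else:
                p = 1.0 / (1.0 + np.exp(-eta_h))
                hatched = int(rng.binomial(clutch, p))
            b_cl = rng.normal(0, effects.sd_volume_clutch)
            for e in range(clutch):
                vol = -1.0
                while vol <= 0:
                    vol = (
                        effects.volume_intercept
                        + effects.beta_froh_volume * z_f[i]
                        + effects.beta_gen_volume * z_gen[i]
                        + b_id_v
                        + b_cl
                        + rng.normal(0, effects.sd_volume_resid)
                    )
                aspect = rng.normal(effects.egg_aspect_mean, effects.egg_aspect_sd)
                length, width = invert_egg_volume(vol, aspect, k=effects.egg_k)
                rows.append(
                    {
                        "female_id": female,
                        "year": year,
                        "clutch_id": clutch_id,
                        "egg_id": e,
                        "clutch_size": clutch,
                        "eggs_hatched": hatched,
                        "egg_length_mm": length,
                        "egg_width_mm": width,
                        "egg_volume_ml": vol,
                        "age": int(ages[female]),
                        "generation": int(generations[female]),
                    }
                )
    return pd.DataFrame(rows)


def _truncated_poisson(lam: float, upper: int, rng: np.random.Generator) -> int:
    """Poisson(lam) conditioned on being <= upper (exact inverse-CDF draw;
    distributionally identical to rejection redraws but never stalls when
    lam >> upper)."""
    k = np.arange(upper + 1)
    logp = k * np.log(lam) - lam - gammaln(k + 1.0)
    p = np.exp(logp - logp.max())
    p /= p.sum()
    return int(rng.choice(k, p=p))


def _std2(x: np.ndarray) -> np.ndarray:
    sd = x.std(ddof=0)
    return (x - x.mean()) / (2 * sd) if sd > 0 else np.zeros_like(x)
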