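"""Simulation of a pepper F2 cross segregating for a major flowering-time locus.

The generator emulates the mapping design used for the *CaFFN* locus: an
intraspecific cross between an early-flowering parent (mean first-flower-node
count, FFN, of 2.3) and a late-flowering parent (mean FFN 14), an F1 with mean
FFN 8.5, and an F2 of 297 plants segregating ~3 late : 1 early for a single
fully recessive early allele near the distal end of chromosome 2.  Meioses are
simulated under a Haldane (no-interference) crossover process so that
recombination fractions have a closed-form oracle, and pooled sequencing of
extreme-phenotype bulks is emulated with Poisson read depth and binomial
allele sampling.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GeneticMap",
    "QtlModel",
    "F2Individual",
    "PoolSpec",
    "SeqNoiseModel",
    "build_genome_map",
    "default_map",
    "simulate_cross",
    "select_extreme_pools",
    "simulate_pool_counts",
    "genotype_matrix",
    "ffn_vector",
]

#: Genotype codes: 0 = homozygous early parent, 1 = het, 2 = homozygous late parent.
EARLY_HOM, HET, LATE_HOM = 0, 1, 2


@dataclasses.dataclass(frozen=True)
class GeneticMap:
    """Coordinate frame for simulation and windowing.

    ``chromosomes`` is an ordered tuple of ``(name, physical_length_bp)``;
    SNPs are stored grouped by chromosome in that order, with 1-based
    positions strictly increasing within a chromosome.  ``cm_per_mb`` is the
    genome-wide recombination rate (centimorgan per megabase).
    """

    chromosomes: tuple[tuple[str, int], ...]
    snp_chrom: np.ndarray
    snp_pos: np.ndarray
    cm_per_mb: float = 2.0

    def __post_init__(self) -> None:
        names = [c for c, _ in self.chromosomes]
        if len(set(names)) != len(names):
            raise ValueError("chromosome names must be unique")
        if self.cm_per_mb <= 0:
            raise ValueError("cm_per_mb must be > 0")
        lengths = dict(self.chromosomes)
        if len(self.snp_chrom) != len(self.snp_pos):
            raise ValueError("snp_chrom and snp_pos length mismatch")
        for name in np.unique(self.snp_chrom):
            if name not in lengths:
                raise ValueError(f"SNP on unknown chromosome {name!r}")
            pos = self.snp_pos[self.snp_chrom == name]
            if np.any(np.diff(pos) <= 0):
                raise ValueError(f"positions not strictly increasing on {name}")
            if pos[0] < 1 or pos[-1] > lengths[name]:
                raise ValueError(f"positions outside [1, length] on {name}")

    @property
    def n_snps(self) -> int:
        return len(self.snp_pos)

    @property
    def lengths(self) -> dict[str, int]:
        return dict(self.chromosomes)

    def chrom_indices(self, name: str) -> np.ndarray:
        idx = np.flatnonzero(self.snp_chrom == name)
        if idx.size == 0:
            raise ValueError(f"no SNPs on chromosome {name!r}")
        return idx

    def nearest_snp(self, chrom: str, position_bp: int) -> int:
        """Index (into the global SNP arrays) of the SNP nearest a coordinate."""
        if chrom not in self.lengths:
            raise ValueError(f"chromosome {chrom!r} not on the map")
        idx = self.chrom_indices(chrom)
        d = np.abs(self.snp_pos[idx].astype(np.int64) - int(position_bp))
        return int(idx[np.argmin(d)])  # ties -> smaller position


@dataclasses.dataclass(frozen=True)
class QtlModel:
    """A single major locus with per-genotype phenotype means and noise.

    Means default to the parental/F1 FFN averages (early parent 2.3, F1 8.5,
    late parent 14); the standard deviations are a calibration chosen so that
    simulated parental ranges match the observed 1-4 and 13-15 leaf counts.
    The early allele is fully recessive: only genotype 0 flowers early.
    """

    chromosome: str = "chr02"
    position_bp: int = 224_250_000  # last 5% of a 230 Mb chromosome
    genotype_means: tuple[float, float, float] = (2.3, 8.5, 14.0)
    genotype_sd: tuple[float, float, float] = (0.7, 1.0, 0.6)
    early_allele: str = "B9431"

    def __post_init__(self) -> None:
        mu_aa, mu_ab, mu_bb = self.genotype_means
        if not (mu_aa < mu_ab <= mu_bb):
            raise ValueError("genotype means must satisfy mu_aa < mu_Aa <= mu_AA")
        if any(s < 0 for s in self.genotype_sd):
            raise ValueError("genotype sd must be >= 0")

    @classmethod
    def default_for(cls, gmap: GeneticMap, chromosome: str = "chr02") -> "QtlModel":
        """Place the default locus at 97.5% of a chromosome's length."""
        length = gmap.lengths[chromosome]
        return cls(chromosome=chromosome, position_bp=int(round(0.975 * length)))


@dataclasses.dataclass(frozen=True)
class F2Individual:
    """Per-SNP genotype codes {0,1,2} plus an integer FFN phenotype (>= 1)."""

    genotypes: np.ndarray
    ffn: int

    def __post_init__(self) -> None:
        if self.ffn < 1:
            raise ValueError("ffn must be >= 1")


@dataclasses.dataclass(frozen=True)
class PoolSpec:
    """An extreme-phenotype bulk: member indices into the population."""

    members: tuple[int, ...]
    label: str

    def __post_init__(self) -> None:
        if self.label not in ("early", "late"):
            raise ValueError("pool label must be 'early' or 'late'")
        if len(set(self.members)) != len(self.members):
            raise ValueError("pool members must be unique")

    @property
    def size(self) -> int:
        return len(self.members)


@dataclasses.dataclass(frozen=True)
class SeqNoiseModel:
    """Pooled-sequencing noise: mean depth per SNP, per-read allele-flip rate."""

    depth: float = 100.0
    error_rate: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if self.depth < 1:
            raise ValueError("depth must be >= 1")
        if not (0 <= self.error_rate < 0.5):
            raise ValueError("error_rate must be in [0, 0.5)")


def build_genome_map(
    n_chromosomes: int = 12,
    length_bp: int | Sequence[int] = 230_000_000,
    snp_spacing_bp: int = 500_000,
    cm_per_mb: float = 2.0,
    seed: int = 0,
) -> GeneticMap:
    """Place parent-informative SNPs on a jittered grid across chromosomes.

    SNPs sit at grid centers spaced ``snp_spacing_bp`` apart with uniform
    jitter of up to 45% of the spacing, so the mean spacing is the requested
    one while positions are irregular.  Deterministic for a fixed seed.
    """
    if n_chromosomes < 1:
        raise ValueError("n_chromosomes must be >= 1")
    if snp_spacing_bp < 1:
        raise ValueError("snp_spacing_bp must be >= 1")
    lengths = (
        [int(length_bp)] * n_chromosomes
        if np.isscalar(length_bp)
        else [int(x) for x in length_bp]
    )
    if len(lengths) != n_chromosomes or any(x < 1 for x in lengths):
        raise ValueError("invalid chromosome lengths")
    rng = np.random.default_rng(seed)
    chroms, all_names, all_pos = [], [], []
    for i, L in enumerate(lengths):
        name = f"chr{i + 1:02d}"
        chroms.append((name, L))
        n = max(1, L // snp_spacing_bp)
        centers = snp_spacing_bp / 2.0 + snp_spacing_bp * np.arange(n)
        jitter = rng.uniform(-0.45, 0.45, n) * snp_spacing_bp
        pos = np.unique(np.clip(np.rint(centers + jitter), 1, L).astype(np.int64))
        all_names.append(np.full(len(pos), name, dtype=object))
        all_pos.append(pos)
    return GeneticMap(
        chromosomes=tuple(chroms),
        snp_chrom=np.concatenate(all_names),
        snp_pos=np.concatenate(all_pos),
        cm_per_mb=cm_per_mb,
    )


def default_map(seed: int = 0) -> GeneticMap:
    """The default study frame: 12 chromosomes of 230 Mb, 500 kb SNP spacing."""
    return build_genome_map(seed=seed)


def _simulate_gametes(gmap: GeneticMap, n_gametes: int, rng: np.random.Generator) -> np.ndarray:
    """Simulate F1 gametes under a Haldane crossover process.

    Crossover counts per chromosome are Poisson with mean equal to the map
    length in Morgans, positions uniform on the chromosome (constant cM/Mb),
    and the starting parental strand is a fair coin.  Returns an
    ``(n_gametes, n_snps)`` array of 0/1 parental-origin alleles
    (1 = late-parent strand).
    """
    out = np.empty((n_gametes, gmap.n_snps), dtype=np.int8)
    start_idx = 0
    for name, L in gmap.chromosomes:
        idx = np.flatnonzero(gmap.snp_chrom == name)
        if idx.size == 0:
            continue
        pos = gmap.snp_pos[idx].astype(np.float64)
        morgans = (L / 1e6) * gmap.cm_per_mb / 100.0
        k = rng.poisson(morgans, n_gametes)
        starts = rng.integers(0, 2, n_gametes)
        xo_flat = rng.uniform(0.0, float(L), int(k.sum()))
        offsets = np.concatenate(([0], np.cumsum(k)))
        for g in range(n_gametes):
            xo = np.sort(xo_flat[offsets[g] : offsets[g + 1]])
            out[g, idx] = (starts[g] + np.searchsorted(xo, pos)) % 2
        start_idx += idx.size
    return out


def simulate_cross(
    gmap: GeneticMap,
    qtl: QtlModel,
    cross_type: str,
    n: int,
    seed: int | np.random.Generator = 0,
) -> list[F2Individual]:
    """Simulate a generation of the cross and draw FFN phenotypes.

    ``cross_type`` is one of ``P_early`` (all genotype 0), ``P_late`` (all 2),
    ``F1`` (all 1) or ``F2`` (two simulated meioses per individual).  The
    phenotype is ``round(Normal(mu_g, sd_g))`` clipped to >= 1, where ``g`` is
    the genotype at the SNP nearest the locus.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if qtl.chromosome not in gmap.lengths:
        raise ValueError(f"QTL chromosome {qtl.chromosome!r} absent from map")
    rng = np.random.default_rng(seed)
    m = gmap.n_snps
    if cross_type == "P_early":
        geno = np.full((n, m), EARLY_HOM, dtype=np.int8)
    elif cross_type == "P_late":
        geno = np.full((n, m), LATE_HOM, dtype=np.int8)
    elif cross_type == "F1":
        geno = np.full((n, m), HET, dtype=np.int8)
    elif cross_type == "F2":
        gametes = _simulate_gametes(gmap, 2 * n, rng)
        geno = (gametes[0::2] + gametes[1::2]).astype(np.int8)
    else:
        raise ValueError(f"unknown cross_type {cross_type!r}")
    q_idx = gmap.nearest_snp(qtl.chromosome, qtl.position_bp)
    g_at_qtl = geno[:, q_idx]
    mu = np.asarray(qtl.genotype_means)[g_at_qtl]
    sd = np.asarray(qtl.genotype_sd)[g_at_qtl]
    ffn = np.maximum(1, np.rint(rng.normal(mu, sd))).astype(int)
    return [F2Individual(genotypes=geno[i], ffn=int(ffn[i])) for i in range(n)]


def select_extreme_pools(
    population: Sequence[F2Individual], k: int = 30
) -> tuple[PoolSpec, PoolSpec]:
    """Pick the k lowest-FFN and k highest-FFN individuals as the two bulks.

    Ties in FFN are broken by individual index (ascending) so that pool
    membership is deterministic.
    """
    n = len(population)
    if 2 * k > n:
        raise ValueError(f"2k = {2 * k} exceeds population size {n}")
    ffn = np.array([ind.ffn for ind in population])
    order = np.argsort(ffn, kind="stable")
    early = tuple(sorted(int(i) for i in order[:k]))
    late = tuple(sorted(int(i) for i in order[n - k :]))
    return PoolSpec(early, "early"), PoolSpec(late, "late")


def simulate_pool_counts(
    gmap: GeneticMap,
    population: Sequence[F2Individual],
    pool: PoolSpec,
    noise: SeqNoiseModel,
) -> pd.DataFrame:
    """Emulate pooled RNA-seq allele depths for one bulk.

    The true late-parent-allele frequency at each SNP is the mean genotype of
    the pool members divided by 2; observed alt counts are
    ``Binomial(D, f(1-e) + (1-f)e)`` with per-SNP depth ``D ~ Poisson(depth)``
    (zero depths resampled so D >= 1).  Returns a long-format count table with
    columns ``chrom, pos, pool, ref_count, alt_count`` where ref is the
    early-parent allele.
    """
    if pool.size == 0:
        raise ValueError("empty pool")
    geno = np.stack([population[i].genotypes for i in pool.members])
    f = geno.mean(axis=0) / 2.0
    rng = np.random.default_rng(noise.seed)
    depth = rng.poisson(noise.depth, gmap.n_snps)
    while np.any(depth == 0):
        z = depth == 0
        depth[z] = rng.poisson(noise.depth, int(z.sum()))
    e = noise.error_rate
    p_obs = f * (1 - e) + (1 - f) * e
    alt = rng.binomial(depth, p_obs)
    return pd.DataFrame(
        {
            "chrom": gmap.snp_chrom,
            "pos": gmap.snp_pos,
            "pool": pool.label,
            "ref_count": depth - alt,
            "alt_count": alt,
        }
    )


def genotype_matrix(population: Sequence[F2Individual]) -> np.ndarray:
    """Stack a population into an (n_individuals, n_snps) genotype array."""
    return np.stack([ind.genotypes for ind in population])


def ffn_vector(population: Sequence[F2Individual]) -> np.ndarray:
    return np.array([ind.ffn for ind in population])
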