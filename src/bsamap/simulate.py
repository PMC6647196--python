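"""Synthetic F2/BC1 populations, phenotype-selected pools and pooled read depths.

The simulator reproduces the statistical structure a bulked-segregant scan
of a single dominant locus relies on:

* Each individual is assembled from parental gametes. A gamete inherits a
  crossover count from a Poisson distribution (Haldane model, no
  interference) with uniformly placed breakpoints, so the expected number
  of crossovers is ``chrom_length * cm_per_mb / 100`` per gamete. An F2
  individual is the union of two F1 gametes; a BC1 individual is one F1
  gamete plus one wild-parent (all-wild) gamete.
* The phenotype follows from the mutant-allele dosage at the causal
  position: under dominance the mutant phenotype (fuzzless) appears with
  dosage >= 1.
* Pooled sequencing draws a Poisson total depth per site and pool, and
  binomial alt reads around the pool's mutant-allele frequency, perturbed
  by a symmetric per-read error rate.

For a dominant trait the phenotype-selected F2 pools bound the expected
ΔSNP-index at the causal site at 2/3 (fuzzless pool frequency 2/3, fuzzy
pool 0), not 1: the fuzzless class mixes heterozygotes and mutant
homozygotes 2:1.

The simulated chromosome is a scaled-down stand-in for a whole-genome
scan, which is why the default map density (``cm_per_mb = 150``) is far
above a physical cotton rate: 10 Mb at 150 cM/Mb spans 1,500 cM, the order
of a genome-wide linkage map, so that most simulated sites are effectively
unlinked to the causal locus. See docs/methods.md for the derivation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .variants import POOLS, VariantSite

__all__ = [
    "SimulationConfig",
    "PopulationSample",
    "simulate_population",
    "make_pools",
    "simulate_pool_depths",
    "simulate_expression",
    "ExpressionSim",
]

_BASES = np.array(list("ACGT"))

# Expected minority phenotype-class fraction per (cross, dominance of the
# mutant phenotype allele). F2 dominant: fuzzy (aa) = 1/4. BC1 to the wild
# parent: 1:1. F2 recessive: fuzzless (aa) = 1/4.
_MINORITY_FRACTION = {"F2": 0.25, "BC1": 0.5}


@dataclass(frozen=True)
class SimulationConfig:
    """Study design for one simulated mapping experiment."""

    n_individuals: int = 4010
    cross_type: str = "F2"  # "F2" | "BC1"
    chrom_length: int = 10_000_000
    n_sites: int = 5000
    causal_pos: int = 2_500_000
    dominance: str = "dominant"  # of the mutant (fuzzless) allele
    pool_size: int = 30
    mean_depth: float = 50.0
    seq_error: float = 0.001
    cm_per_mb: float = 150.0
    indel_fraction: float = 0.13  # ~51k InDels vs ~354k SNPs
    chrom: str = "chr1"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.cross_type not in ("F2", "BC1"):
            raise ValueError(f"cross_type must be F2 or BC1, got {self.cross_type!r}")
        if self.dominance not in ("dominant", "recessive"):
            raise ValueError("dominance must be 'dominant' or 'recessive'")
        if not 0 < self.causal_pos <= self.chrom_length:
            raise ValueError("causal_pos must lie in (0, chrom_length]")
        if self.mean_depth <= 0:
            raise ValueError("mean_depth must be positive")
        if not 0 <= self.seq_error < 0.5:
            raise ValueError("seq_error must be in [0, 0.5)")
        if self.n_individuals < 1 or self.n_sites < 1 or self.pool_size < 0:
            raise ValueError("counts must be positive (pool_size may be 0)")
        if self.cm_per_mb < 0 or self.indel_fraction < 0 or self.indel_fraction > 1:
            raise ValueError("invalid cm_per_mb or indel_fraction")
        expected_minority = _MINORITY_FRACTION[self.cross_type] * self.n_individuals
        if self.pool_size > expected_minority:
            raise ValueError(
                f"pool_size {self.pool_size} exceeds the expected minority phenotype "
                f"class ({expected_minority:.0f} individuals): pools are not fillable"
            )


class PopulationSample:
    """A simulated segregating population, stored as gamete breakpoint maps.

    Gametes are encoded by a starting parental phase (1 = mutant parent)
    and sorted crossover breakpoints; the allele carried at position p is
    ``(start_phase + #breakpoints <= p) mod 2``. Marker dosages at
    arbitrary positions are therefore piecewise constant along the
    chromosome, changing only at breakpoints, and can be queried lazily
    for any subset of individuals.
    """

    def __init__(self, config, start_phase, breakpoints, offsets):
        self.config = config
        self._start = np.asarray(start_phase, dtype=np.int8)  # (n, 2)
        self._bp = np.asarray(breakpoints, dtype=np.float64)  # flat, sorted per gamete
        self._off = np.asarray(offsets, dtype=np.int64)  # (2n + 1,)
        self.causal_dosage = self.dosages([config.causal_pos])[:, 0]
        if config.dominance == "dominant":
            self.is_fuzzless = self.causal_dosage >= 1
        else:
            self.is_fuzzless = self.causal_dosage == 2

    @property
    def n_individuals(self) -> int:
        return self._start.shape[0]

    @property
    def phenotypes(self) -> np.ndarray:
        return np.where(self.is_fuzzless, "fuzzless", "fuzzy")

    def dosages(self, positions: Sequence[float], individuals=None) -> np.ndarray:
        """Mutant-allele dosage (0/1/2) at each position, per individual."""
        positions = np.asarray(positions, dtype=np.float64)
        if individuals is None:
            individuals = np.arange(self.n_individuals)
        individuals = np.asarray(individuals, dtype=np.int64)
        out = np.zeros((individuals.size, positions.size), dtype=np.int8)
        for row, ind in enumerate(individuals):
            for g in (2 * ind, 2 * ind + 1):
                bp = self._bp[self._off[g] : self._off[g + 1]]
                crossings = np.searchsorted(bp, positions, side="right")
                out[row] += (self._start[ind, g % 2] + crossings) % 2
        return out


def simulate_population(config: SimulationConfig) -> PopulationSample:
    """Draw a population of F2 or BC1 individuals under the crossover model."""
    rng = np.random.default_rng([config.seed, 0])
    n = config.n_individuals
    n_gametes = 2 * n
    rate = config.chrom_length * config.cm_per_mb / 100 / 1e6  # Morgans per gamete
    k = rng.poisson(rate, size=n_gametes)
    start = rng.integers(0, 2, size=n_gametes, dtype=np.int8)
    if config.cross_type == "BC1":
        # gamete 0 of each individual comes from the recurrent wild parent
        k[0::2] = 0
        start[0::2] = 0
    flat = rng.uniform(0.0, config.chrom_length, size=int(k.sum()))
    gamete_id = np.repeat(np.arange(n_gametes), k)
    order = np.lexsort((flat, gamete_id))
    flat = flat[order]
    offsets = np.concatenate([[0], np.cumsum(k)])
    return PopulationSample(config, start.reshape(n, 2), flat, offsets)


def make_pools(pop: PopulationSample, pool_size: int, seed: int = 0):
    """Sample disjoint phenotype pools: (fuzzy_indices, fuzzless_indices).

    For a binary trait "extreme" individuals are simply random members of
    each phenotype class.
    """
    rng = np.random.default_rng([seed, 1])
    fuzzless = np.flatnonzero(pop.is_fuzzless)
    fuzzy = np.flatnonzero(~pop.is_fuzzless)
    for name, cls in (("fuzzy", fuzzy), ("fuzzless", fuzzless)):
        if cls.size < pool_size:
            raise ValueError(
                f"phenotype class {name!r} has {cls.size} individuals, "
                f"fewer than pool_size {pool_size}"
            )
    fuzzy_pool = np.sort(rng.choice(fuzzy, size=pool_size, replace=False))
    fuzzless_pool = np.sort(rng.choice(fuzzless, size=pool_size, replace=False))
    return fuzzy_pool, fuzzless_pool


def _site_positions(config: SimulationConfig) -> np.ndarray:
    # Regular grid over the chromosome with the causal position swapped in
    # for the nearest grid point, so the causal site is always observed.
    grid = np.linspace(1, config.chrom_length, config.n_sites)
    grid = np.unique(np.round(grid).astype(np.int64))
    nearest = int(np.argmin(np.abs(grid - config.causal_pos)))
    grid[nearest] = config.causal_pos
    return np.unique(grid)


def simulate_pool_depths(
    pop: PopulationSample,
    pools,
    config: SimulationConfig,
) -> list[VariantSite]:
    """Simulate pooled sequencing read depths at a grid of informative sites.

    The parents are opposite homozygotes at every emitted site (the
    informative-site model): before sequencing error the wild parent's
    mutant-allele frequency is 0 and the mutant parent's is 1. Phenotype
    pools use the pooled mutant-allele frequency, i.e. the mean dosage of
    the pooled individuals divided by two. Per pool and site,
    ``total depth ~ Poisson(mean_depth)`` and
    ``alt reads ~ Binomial(depth, f(1 - e) + (1 - f) e)``.
    """
    rng = np.random.default_rng([config.seed, 2])
    fuzzy_pool, fuzzless_pool = pools
    positions = _site_positions(config)
    m = positions.size
    e = config.seq_error

    freq = {
        "parent_wt": np.zeros(m),
        "parent_mut": np.ones(m),
        "fuzzy": pop.dosages(positions, fuzzy_pool).mean(axis=0) / 2.0
        if len(fuzzy_pool)
        else np.zeros(m),
        "fuzzless": pop.dosages(positions, fuzzless_pool).mean(axis=0) / 2.0
        if len(fuzzless_pool)
        else np.zeros(m),
    }

    is_indel = rng.random(m) < config.indel_fraction
    ref_idx = rng.integers(0, 4, size=m)
    alt_shift = rng.integers(1, 4, size=m)
    refs = _BASES[ref_idx]
    alts = _BASES[(ref_idx + alt_shift) % 4]
    ins = _BASES[rng.integers(0, 4, size=m)]

    depth = {p: rng.poisson(config.mean_depth, size=m) for p in POOLS}
    alt_reads = {}
    for p in POOLS:
        f_obs = freq[p] * (1 - e) + (1 - freq[p]) * e
        alt_reads[p] = rng.binomial(depth[p], f_obs)

    sites = []
    for i in range(m):
        if is_indel[i]:
            ref, alt, vc = refs[i], refs[i] + ins[i], "InDel"
        else:
            ref, alt, vc = refs[i], alts[i], "SNP"
        sites.append(
            VariantSite(
                chrom=config.chrom,
                pos=int(positions[i]),
                ref=str(ref),
                alt=str(alt),
                var_class=vc,
                depths={
                    p: (int(depth[p][i] - alt_reads[p][i]), int(alt_reads[p][i]))
                    for p in POOLS
                },
            )
        )
    return sites


@dataclass
class ExpressionSim:
    """Simulated fragment-count matrix with gene lengths and DEG truth labels."""

    counts: pd.DataFrame  # genes x libraries
    lengths: pd.Series  # bp per gene
    truth: dict  # stage -> set of truly differential gene_ids
    direction: pd.Series = None  # +1 up in mutant, -1 down, 0 null
    library_totals: pd.Series = None  # total mapped fragments per library


def simulate_expression(
    n_genes: int = 2000,
    n_true_deg: int = 50,
    lfc: float = 2.0,
    stages: Sequence[int] = (1, 3, 5),
    reps: int = 2,
    dispersion: float = 0.05,
    deg_stages: Sequence[int] = (1,),
    frac_up: float = 0.5,
    mean_expression: float = 150.0,
    sigma_log: float = 1.2,
    library_size: int | None = None,
    seed: int = 0,
) -> ExpressionSim:
    """Negative-binomial fragment counts for a 2-genotype x stages x reps design.

    True DEGs carry a genotype effect of ``|lfc|`` log2 units in the mutant
    (a fraction ``frac_up`` of them up-regulated, the rest down-regulated,
    keeping library composition roughly balanced) at the stages in
    ``deg_stages`` and no effect elsewhere, mirroring a design where nearly
    all expression differences appear at the earliest ovule stage. Counts
    are Gamma-Poisson draws with a common dispersion; ``dispersion -> 0``
    degenerates to Poisson.

    The ``n_genes`` genes are a panel drawn from a much larger
    transcriptome; ``library_size``, when given, is the total mapped
    fragments of each whole library (the FPKM denominator), so that
    fold changes within the panel do not distort the totals. When it is
    None the panel's own column sums serve as the totals.
    """
    if n_true_deg > n_genes:
        raise ValueError("n_true_deg cannot exceed n_genes")
    if not 0 <= frac_up <= 1:
        raise ValueError("frac_up must lie in [0, 1]")
    rng = np.random.default_rng([seed, 3])
    genes = [f"G{i:05d}" for i in range(n_genes)]
    lengths = pd.Series(rng.integers(400, 5000, size=n_genes), index=genes, name="length_bp")
    base = rng.lognormal(mean=np.log(mean_expression), sigma=sigma_log, size=n_genes)
    deg_genes = rng.choice(n_genes, size=n_true_deg, replace=False)
    is_deg = np.zeros(n_genes, dtype=bool)
    is_deg[deg_genes] = True
    sign = np.zeros(n_genes)
    n_up = int(round(frac_up * n_true_deg))
    sign[deg_genes[:n_up]] = 1.0
    sign[deg_genes[n_up:]] = -1.0

    cols, data = [], []
    for genotype in ("wild", "mutant"):
        for stage in stages:
            effect = np.where(
                is_deg & (genotype == "mutant") & (stage in deg_stages),
                sign * abs(lfc),
                0.0,
            )
            mu = base * 2.0**effect
            for rep in range(1, reps + 1):
                cols.append(f"{genotype}_{stage}DPA_rep{rep}")
                if dispersion > 0:
                    lam = rng.gamma(shape=1.0 / dispersion, scale=mu * dispersion)
                else:
                    lam = mu
                data.append(rng.poisson(lam))
    counts = pd.DataFrame(np.column_stack(data), index=genes, columns=cols)
    truth = {
        stage: (set(np.array(genes)[is_deg]) if stage in deg_stages else set())
        for stage in stages
    }
    direction = pd.Series(sign.astype(int), index=genes, name="direction")
    if library_size is not None:
        totals = pd.Series(int(library_size), index=counts.columns, name="library_total")
    else:
        totals = counts.sum(axis=0).rename("library_total")
    return ExpressionSim(
        counts=counts, lengths=lengths, truth=truth, direction=direction,
        library_totals=totals,
    )


def with_seed(config: SimulationConfig, seed: int) -> SimulationConfig:
    """Copy of a config with a different seed (convenience for replicate runs)."""
    return replace(config, seed=seed)
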