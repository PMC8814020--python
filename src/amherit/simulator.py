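"""Forward-time diploid simulator with block recombination and phenotypic assortment.

The simulator tracks genomes as mosaics of founder-haplotype *blocks*: the
genome is tiled by contiguous, non-overlapping intervals (default 50 kb) and
recombination is restricted to interval boundaries, so an individual's
haplotype is a short vector of founder-haplotype labels rather than p alleles.
Founder haplotypes carry realistic linkage disequilibrium generated by
thresholding a latent stationary Gaussian process whose autocorrelation decays
exponentially with base-pair distance.

A run consists of a growth phase (founders expanded to the target population
size by random non-monogamous mating), a random-mating burn-in, and a series
of assortative-mating generations in which disjoint monogamous pairs are
matched on phenotype via a sorted-Gaussian-copula scheme so that the realized
mate correlation approximates the configured ``r``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "FounderPanel",
    "BlockGenome",
    "TraitArchitecture",
    "Population",
    "SimConfig",
    "EvolveResult",
    "generate_founders",
    "assign_architecture",
    "compute_phenotypes",
    "genetic_values",
    "match_mates",
    "reproduce",
    "evolve",
    "expand_genotypes",
    "drop_variants",
    "filter_relatives",
    "unrelated_indices",
]


@dataclass(frozen=True)
class FounderPanel:
    """Founder haplotypes plus the SNP map shared by all generations.

    ``haplotypes`` has one row per founder haplotype (2 per founder).
    ``block_cm`` holds the cumulative centiMorgan position of each block's
    left boundary within its chromosome; ``boundary_recomb`` the per-boundary
    recombination fraction (0.5 at chromosome starts, i.e. free assortment).
    """

    n_founders: int
    p: int
    haplotypes: np.ndarray  # (2*n_founders, p) uint8
    allele_freq: np.ndarray  # (p,) realized founder frequencies
    chrom: np.ndarray  # (p,) int
    positions_bp: np.ndarray  # (p,) int
    snp_cm: np.ndarray  # (p,) float
    block_of_snp: np.ndarray  # (p,) int
    n_blocks: int
    block_chrom: np.ndarray  # (k,) int
    block_cm: np.ndarray  # (k,) float
    boundary_recomb: np.ndarray  # (k,) float


@dataclass(frozen=True)
class BlockGenome:
    """A single individual's two haplotypes as founder-haplotype block labels."""

    labels: np.ndarray  # (2, k) int


@dataclass(frozen=True)
class TraitArchitecture:
    """Causal loci, standardized substitution effects, and variance targets."""

    causal_indices: np.ndarray
    u: np.ndarray
    V_e: float
    V_g0: float


@dataclass
class Population:
    """A generation of block-label genomes with optional phenotypes.

    ``family`` gives, for each individual, the index of the mating pair it
    descends from (or -1 in the founder/growth generations); individuals
    sharing a family index are full siblings.
    """

    generation: int
    labels: np.ndarray  # (N, 2, k) int
    mating_regime: str = "random"
    phenotypes: np.ndarray = None
    family: np.ndarray = None
    summaries: dict = field(default_factory=dict)

    @property
    def size(self) -> int:
        return self.labels.shape[0]

    def genome(self, i: int) -> BlockGenome:
        return BlockGenome(self.labels[i])


@dataclass(frozen=True)
class SimConfig:
    """Configuration of a full forward simulation run.

    Defaults mirror the study conditions the package targets: a panmictic
    heritability of 0.5, five random-mating burn-in generations, fifteen
    assortative-mating generations, and constant population size with
    monogamous pairs producing two offspring each.  The desk-scale genome is
    20 chromosomes x 50 blocks of 50 kb with 1 cM between adjacent block
    boundaries, so randomly chosen causal pairs are mostly unlinked, as in a
    genome-wide architecture.
    """

    seed: int
    N: int = 4000
    p: int = 2000
    m: int = 1000
    h0_sq: float = 0.5
    r: float = 0.5
    n_founders: int = 1000
    chromosomes: int = 20
    blocks_per_chromosome: int = 50
    block_size_bp: int = 50_000
    cm_per_block: float = 1.0
    maf_min: float = 0.05
    maf_max: float = 0.5
    ld_decay_scale: float = 25_000.0
    burn_in_generations: int = 5
    am_generations: int = 15
    offspring_per_pair: int = 2
    grm_cutoff: float = 0.05

    def __post_init__(self):
        if self.grm_cutoff <= 0:
            raise ValueError("grm_cutoff must be positive")
        if not 0.0 <= self.r < 1.0:
            raise ValueError(f"r must lie in [0, 1), got {self.r}")
        if not 0.0 <= self.h0_sq <= 1.0:
            raise ValueError(f"h0_sq must lie in [0, 1], got {self.h0_sq}")
        if self.m > self.p:
            raise ValueError("m (causal loci) cannot exceed p (SNPs)")
        if self.N % 2:
            raise ValueError("N must be even")


@dataclass
class EvolveResult:
    population: Population
    panel: FounderPanel
    architecture: TraitArchitecture
    summaries: pd.DataFrame
    config: SimConfig


def _haldane(d_cm: np.ndarray) -> np.ndarray:
    """Recombination fraction from map distance in cM (Haldane's function)."""
    return 0.5 * (1.0 - np.exp(-2.0 * np.asarray(d_cm, dtype=float) / 100.0))


def generate_founders(
    p: int,
    n_founders: int,
    chromosomes: int = 20,
    maf_range: tuple = (0.05, 0.5),
    ld_decay_scale: float = 25_000.0,
    seed: int = 0,
    blocks_per_chromosome: int = 50,
    block_size_bp: int = 50_000,
    cm_per_block: float = 1.0,
) -> FounderPanel:
    """Generate a synthetic founder haplotype panel with distance-decaying LD.

    For each chromosome a latent AR(1) Gaussian process with autocorrelation
    ``exp(-d_bp / ld_decay_scale)`` is sampled per haplotype and thresholded
    at each SNP's empirical frequency quantile, so realized allele
    frequencies land exactly on the configured uniform MAF draw (rounded to
    haplotype counts) and pairwise LD decays with physical distance.
    """
    lo, hi = maf_range
    if not (0.0 < lo <= hi <= 0.5):
        raise ValueError(f"infeasible MAF bounds {maf_range}; need 0 < lo <= hi <= 0.5")
    if p < 1 or n_founders < 2:
        raise ValueError("need p >= 1 SNPs and at least 2 founders")
    rng = np.random.default_rng(seed)
    k = chromosomes * blocks_per_chromosome

    # place SNPs: as even as possible across blocks, random offsets within
    snp_block = np.sort(rng.integers(0, k, size=p)) if p < k else np.sort(
        np.concatenate([np.arange(k)] * (p // k) + [rng.choice(k, p % k, replace=False)])
    )
    block_chrom = np.repeat(np.arange(chromosomes), blocks_per_chromosome)
    block_within = np.tile(np.arange(blocks_per_chromosome), chromosomes)
    chrom = block_chrom[snp_block]
    offsets = rng.integers(0, block_size_bp, size=p)
    positions = block_within[snp_block] * block_size_bp + offsets
    # enforce strictly increasing positions within chromosome
    for c in range(chromosomes):
        sel = np.flatnonzero(chrom == c)
        if sel.size:
            pos = np.sort(positions[sel])
            pos += np.arange(sel.size)  # break ties
            positions[sel] = pos
    snp_cm = block_within[snp_block] * cm_per_block + (
        positions % block_size_bp
    ) / block_size_bp * cm_per_block

    block_cm = block_within * float(cm_per_block)
    boundary = np.full(k, _haldane(cm_per_block))
    boundary[block_within == 0] = 0.5  # independent assortment across chromosomes

    n_hap = 2 * n_founders
    target = rng.uniform(lo, hi, size=p)
    hap = np.zeros((n_hap, p), dtype=np.uint8)
    latent = np.empty(n_hap)
    for c in range(chromosomes):
        sel = np.flatnonzero(chrom == c)
        if not sel.size:
            continue
        gaps = np.diff(positions[sel], prepend=positions[sel][0])
        rho = np.exp(-gaps / float(ld_decay_scale))
        rho[0] = 0.0
        for j, snp in enumerate(sel):
            innov = rng.standard_normal(n_hap)
            if j == 0:
                latent = innov
            else:
                latent = rho[j] * latent + np.sqrt(1.0 - rho[j] ** 2) * innov
            count = int(np.clip(round(n_hap * target[snp]), 1, n_hap - 1))
            thresh_idx = np.argpartition(latent, -count)[-count:]
            hap[thresh_idx, snp] = 1

    freq = hap.mean(axis=0)
    return FounderPanel(
        n_founders=n_founders,
        p=p,
        haplotypes=hap,
        allele_freq=freq,
        chrom=chrom,
        positions_bp=positions.astype(np.int64),
        snp_cm=snp_cm,
        block_of_snp=snp_block.astype(np.int32),
        n_blocks=k,
        block_chrom=block_chrom,
        block_cm=block_cm,
        boundary_recomb=boundary,
    )


def assign_architecture(
    panel: FounderPanel, m: int, h0_sq: float, seed: int = 0
) -> TraitArchitecture:
    """Sample m causal loci and Gaussian effects u ~ N(0, V_g0 / m).

    The panmictic phenotypic variance is normalized to 1, so V_g0 = h0_sq and
    V_e = 1 - h0_sq.
    """
    if m > panel.p:
        raise ValueError(f"m={m} exceeds panel SNP count p={panel.p}")
    rng = np.random.default_rng(seed)
    causal = np.sort(rng.choice(panel.p, size=m, replace=False))
    V_g0 = float(h0_sq)
    u = rng.normal(0.0, np.sqrt(V_g0 / m) if m else 0.0, size=m)
    return TraitArchitecture(causal, u, V_e=float(1.0 - h0_sq), V_g0=V_g0)


def _standardized_causal(
    population: Population, architecture: TraitArchitecture, panel: FounderPanel
) -> np.ndarray:
    G = expand_genotypes(population, panel, architecture.causal_indices)
    f = panel.allele_freq[architecture.causal_indices]
    return (G - 2.0 * f) / np.sqrt(2.0 * f * (1.0 - f))


def genetic_values(
    population: Population, architecture: TraitArchitecture, panel: FounderPanel
) -> np.ndarray:
    """Additive genetic values Zu, standardized by founder (panmictic) frequencies."""
    return _standardized_causal(population, architecture, panel) @ architecture.u


def compute_phenotypes(
    population: Population,
    architecture: TraitArchitecture,
    panel: FounderPanel,
    seed: int = 0,
) -> np.ndarray:
    """Phenotypes y = Zu + e with e iid N(0, V_e).

    Standardization of Z uses the founder-panel allele frequencies, fixed
    across generations, so the effect vector keeps its meaning as AM
    reshapes the genotype distribution.
    """
    rng = np.random.default_rng(seed)
    g = genetic_values(population, architecture, panel)
    e = rng.normal(0.0, np.sqrt(architecture.V_e), size=g.size)
    return g + e


def match_mates(phenotypes: np.ndarray, r: float, seed: int = 0) -> np.ndarray:
    """Pair individuals so the mate phenotype correlation approximates r.

    Draws N/2 bivariate-normal pairs with correlation r, pools all N draws,
    and matches phenotype ranks to copula-draw ranks; the two individuals
    landing in the same copula pair become mates.  Returns an (N/2, 2) array
    of disjoint index pairs covering every individual exactly once.
    """
    y = np.asarray(phenotypes, dtype=float)
    N = y.size
    if N % 2:
        raise ValueError("population size must be even to form disjoint pairs")
    if not 0.0 <= r < 1.0:
        raise ValueError(f"r must lie in [0, 1), got {r}")
    rng = np.random.default_rng(seed)
    half = N // 2
    a = rng.standard_normal(half)
    b = r * a + np.sqrt(1.0 - r * r) * rng.standard_normal(half)
    flat = np.empty(N)
    flat[0::2] = a
    flat[1::2] = b
    slot_person = np.empty(N, dtype=np.int64)
    slot_person[np.argsort(flat, kind="stable")] = np.argsort(y, kind="stable")
    return slot_person.reshape(half, 2)


def _gametes(labels: np.ndarray, panel: FounderPanel, rng) -> np.ndarray:
    """One recombinant gamete per input individual (vectorized)."""
    n, _, k = labels.shape
    switch = rng.random((n, k)) < panel.boundary_recomb
    parity = np.cumsum(switch, axis=1, dtype=np.int64) & 1
    return np.take_along_axis(labels, parity[:, None, :], axis=1)[:, 0, :]


def reproduce(
    population: Population,
    pairs: np.ndarray,
    panel: FounderPanel,
    offspring_per_pair: int = 2,
    seed: int = 0,
) -> Population:
    """Next generation from disjoint mating pairs.

    Each offspring receives one recombinant gamete from each parent;
    crossovers occur only at block boundaries with Haldane-map
    probabilities, and chromosomes assort independently.
    """
    pairs = np.asarray(pairs)
    flat = pairs.ravel()
    if np.unique(flat).size != flat.size:
        raise ValueError("mating pairs must be disjoint")
    rng = np.random.default_rng(seed)
    mothers = np.repeat(pairs[:, 0], offspring_per_pair)
    fathers = np.repeat(pairs[:, 1], offspring_per_pair)
    g_m = _gametes(population.labels[mothers], panel, rng)
    g_f = _gametes(population.labels[fathers], panel, rng)
    labels = np.stack([g_m, g_f], axis=1)
    family = np.repeat(np.arange(pairs.shape[0]), offspring_per_pair)
    return Population(
        generation=population.generation + 1,
        labels=labels,
        mating_regime=population.mating_regime,
        family=family,
    )


def _random_offspring(
    population: Population, n_offspring: int, panel: FounderPanel, rng
) -> Population:
    """Non-monogamous random mating: parent pairs sampled with replacement."""
    n = population.size
    mothers = rng.integers(0, n, size=n_offspring)
    fathers = (mothers + 1 + rng.integers(0, n - 1, size=n_offspring)) % n
    g_m = _gametes(population.labels[mothers], panel, rng)
    g_f = _gametes(population.labels[fathers], panel, rng)
    return Population(
        generation=population.generation + 1,
        labels=np.stack([g_m, g_f], axis=1),
        mating_regime="random",
        family=np.full(n_offspring, -1, dtype=np.int64),
    )


def evolve(config: SimConfig) -> EvolveResult:
    """Run growth, burn-in, and assortative-mating phases of a simulation.

    Records realized genetic variance, heritability, and mate correlation
    for every assortative-mating generation.  Deterministic given
    ``config.seed``: every stage draws from its own spawned substream.
    """
    ss = np.random.SeedSequence(config.seed)
    (s_panel, s_arch, s_growth, s_pheno, s_match, s_repr) = ss.spawn(6)
    rng_growth = np.random.default_rng(s_growth)
    pheno_seeds = s_pheno.spawn(config.am_generations + 1)
    match_seeds = s_match.spawn(config.am_generations)
    repr_seeds = s_repr.spawn(config.am_generations)

    panel = generate_founders(
        p=config.p,
        n_founders=config.n_founders,
        chromosomes=config.chromosomes,
        maf_range=(config.maf_min, config.maf_max),
        ld_decay_scale=config.ld_decay_scale,
        seed=s_panel,
        blocks_per_chromosome=config.blocks_per_chromosome,
        block_size_bp=config.block_size_bp,
        cm_per_block=config.cm_per_block,
    )
    arch = assign_architecture(panel, config.m, config.h0_sq, seed=s_arch)

    # founders as a population of diploid individuals
    k = panel.n_blocks
    hap_ids = np.arange(2 * config.n_founders, dtype=np.int32)
    founder_labels = np.repeat(
        hap_ids.reshape(config.n_founders, 2)[:, :, None], k, axis=2
    )
    pop = Population(generation=0, labels=founder_labels, mating_regime="random")

    # growth to target size, then random-mating burn-in
    pop = _random_offspring(pop, config.N, panel, rng_growth)
    for _ in range(config.burn_in_generations):
        pop = _random_offspring(pop, config.N, panel, rng_growth)

    rows = []
    pop.mating_regime = "assortative" if config.r > 0 else "random"
    for t in range(config.am_generations + 1):
        y = compute_phenotypes(pop, arch, panel, seed=pheno_seeds[t])
        pop.phenotypes = y
        g = genetic_values(pop, arch, panel)
        V_g = float(np.var(g))
        h_sq = V_g / (V_g + arch.V_e) if (V_g + arch.V_e) > 0 else 1.0
        mate_corr = np.nan
        if t < config.am_generations:
            pairs = match_mates(y, config.r, seed=match_seeds[t])
            mate_corr = float(np.corrcoef(y[pairs[:, 0]], y[pairs[:, 1]])[0, 1])
        rows.append(
            {"generation": t, "V_g": V_g, "h_sq": h_sq, "mate_corr": mate_corr}
        )
        if t < config.am_generations:
            pop = reproduce(
                pop, pairs, panel, config.offspring_per_pair, seed=repr_seeds[t]
            )
            pop.mating_regime = "assortative" if config.r > 0 else "random"

    summaries = pd.DataFrame(rows)
    pop.summaries = {"per_generation": summaries}
    return EvolveResult(pop, panel, arch, summaries, config)


def expand_genotypes(
    population: Population, panel: FounderPanel, loci: np.ndarray = None
) -> np.ndarray:
    """Materialize 0/1/2 allele counts at the requested loci from block labels."""
    loci = np.arange(panel.p) if loci is None else np.asarray(loci)
    if loci.size and (loci.min() < 0 or loci.max() >= panel.p):
        raise ValueError("requested loci fall outside the founder panel")
    N = population.size
    G = np.empty((N, loci.size), dtype=np.uint8)
    blocks = panel.block_of_snp[loci]
    l0 = population.labels[:, 0, :]
    l1 = population.labels[:, 1, :]
    for b in np.unique(blocks):
        sel = np.flatnonzero(blocks == b)
        H = panel.haplotypes[:, loci[sel]]
        G[:, sel] = H[l0[:, b]] + H[l1[:, b]]
    return G


def drop_variants(
    genotypes: np.ndarray, fraction: float, seed: int = 0
) -> tuple:
    """Randomly drop a fraction of variant columns irrespective of causal status."""
    if not 0.0 <= fraction < 1.0:
        raise ValueError(f"fraction must lie in [0, 1), got {fraction}")
    p = genotypes.shape[1]
    rng = np.random.default_rng(seed)
    n_keep = p - int(np.floor(fraction * p))
    keep = np.sort(rng.choice(p, size=n_keep, replace=False))
    return genotypes[:, keep], keep


def filter_relatives(grm, threshold: float = 0.05) -> np.ndarray:
    """Greedy pruning of individuals until no pairwise relatedness >= threshold.

    Repeatedly deletes the individual participating in the most flagged
    pairs (ties broken by lowest index) and returns the retained indices.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    A = np.asarray(getattr(grm, "values", grm), dtype=float)
    n = A.shape[0]
    adj = A >= threshold
    np.fill_diagonal(adj, False)
    adj = adj | adj.T
    removed = np.zeros(n, dtype=bool)
    deg = adj.sum(axis=1)
    while deg.max(initial=0) > 0:
        i = int(np.argmax(deg))
        removed[i] = True
        deg -= adj[i].astype(deg.dtype)
        adj[i, :] = False
        adj[:, i] = False
        deg[i] = 0
    return np.flatnonzero(~removed)


def unrelated_indices(population: Population) -> np.ndarray:
    """One individual per sibship: an unrelated subsample under monogamous mating."""
    if population.family is None or np.all(population.family < 0):
        return np.arange(population.size)
    _, first = np.unique(population.family, return_index=True)
    return np.sort(first)
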