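"""Forward simulation of the genome and populations.

A genome of one or more 1-Morgan chromosomes carries biallelic loci: candidate
QTL placed uniformly at random and candidate SNPs on a near-even grid.  A base
population drifts for many discrete generations of random mating to build up
linkage disequilibrium; two breeds are then split off and drift apart; finally
a marker/QTL panel is chosen among loci segregating at minor allele frequency
above a threshold in the founders.

Haplotypes are stored as an ``(2N, L)`` int8 array with individual ``i`` on
rows ``2i`` (paternal) and ``2i + 1`` (maternal).  For crossbreds the paternal
row is by construction the sire-breed (A) gamete and the maternal row the
dam-breed (B) gamete, so breed origin of every allele is known exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

from ._kernels import make_gametes

QTL = 0
SNP = 1
ROLE_NAMES = {QTL: "QTL", SNP: "SNP"}

DEFAULT_MUTATION_RATE = 2.5e-5


class InvalidConfigError(ValueError):
    pass


class PanelSelectionError(RuntimeError):
    """Not enough loci above the MAF threshold; re-simulate the history."""


def _kernel_seed(rng: np.random.Generator) -> int:
    return int(rng.integers(1, 2**31 - 1))


@dataclass
class GenomeMap:
    """Locus layout: chromosome assignment, Morgan positions and roles."""

    n_chromosomes: int
    chrom_length: float
    chrom: np.ndarray          # (L,) int32
    positions: np.ndarray      # (L,) float64, Morgans within chromosome
    role: np.ndarray           # (L,) int8, QTL or SNP
    mutation_rate: float = DEFAULT_MUTATION_RATE
    interference: int = 4      # binomial map parameter N; 0 = Haldane
    grid_index: Optional[np.ndarray] = None  # candidate-SNP grid slot, -1 else

    def __post_init__(self):
        for c in range(self.n_chromosomes):
            pos = self.positions[self.chrom == c]
            if pos.size and not np.all(np.diff(pos) > 0):
                raise InvalidConfigError(
                    f"positions not strictly increasing on chromosome {c}")
        if np.any(self.positions < 0) or np.any(
                self.positions > self.chrom_length):
            raise InvalidConfigError("locus positions outside [0, length]")

    @property
    def n_loci(self) -> int:
        return self.positions.shape[0]

    @property
    def qtl_indices(self) -> np.ndarray:
        return np.flatnonzero(self.role == QTL)

    @property
    def snp_indices(self) -> np.ndarray:
        return np.flatnonzero(self.role == SNP)

    def chrom_bounds(self) -> tuple[np.ndarray, np.ndarray]:
        """(start, end) locus index per chromosome (loci are chrom-sorted)."""
        start = np.searchsorted(self.chrom, np.arange(self.n_chromosomes))
        end = np.searchsorted(self.chrom, np.arange(self.n_chromosomes),
                              side="right")
        return start.astype(np.int64), end.astype(np.int64)

    def subset(self, idx: np.ndarray) -> "GenomeMap":
        idx = np.asarray(idx)
        return replace(
            self,
            chrom=self.chrom[idx],
            positions=self.positions[idx],
            role=self.role[idx],
            grid_index=None if self.grid_index is None
            else self.grid_index[idx],
        )


@dataclass
class Population:
    """A set of diploid individuals sharing one GenomeMap."""

    haplotypes: np.ndarray     # (2N, L) int8
    breed: str = "founder"     # founder | A | B | AB
    generation: int = 0
    phenotypes: Optional[np.ndarray] = None
    sire: Optional[np.ndarray] = None
    dam: Optional[np.ndarray] = None

    @property
    def n(self) -> int:
        return self.haplotypes.shape[0] // 2

    @property
    def n_loci(self) -> int:
        return self.haplotypes.shape[1]

    def genotypes(self, loci: Optional[np.ndarray] = None) -> np.ndarray:
        """Allele counts 0/1/2, individuals x loci."""
        h = self.haplotypes if loci is None else self.haplotypes[:, loci]
        return (h[0::2] + h[1::2]).astype(np.int8)

    def het_indicator(self, loci: Optional[np.ndarray] = None) -> np.ndarray:
        h = self.haplotypes if loci is None else self.haplotypes[:, loci]
        return (h[0::2] != h[1::2]).astype(np.int8)

    def paternal_alleles(self, loci: Optional[np.ndarray] = None) -> np.ndarray:
        """Sire-origin allele per individual; breed-A origin for crossbreds."""
        h = self.haplotypes[0::2]
        return h if loci is None else h[:, loci]

    def maternal_alleles(self, loci: Optional[np.ndarray] = None) -> np.ndarray:
        """Dam-origin allele per individual; breed-B origin for crossbreds."""
        h = self.haplotypes[1::2]
        return h if loci is None else h[:, loci]

    def subset_loci(self, idx: np.ndarray) -> "Population":
        return replace(self, haplotypes=np.ascontiguousarray(
            self.haplotypes[:, idx]))


# ---------------------------------------------------------------------------
# Genome construction

def build_genome(n_chrom: int,
                 rng: np.random.Generator,
                 n_qtl_candidates: int = 500,
                 n_snp_candidates: int = 5000,
                 chrom_length: float = 1.0,
                 mutation_rate: float = DEFAULT_MUTATION_RATE,
                 interference: int = 4,
                 snp_jitter: float = 0.1) -> GenomeMap:
    """Lay out candidate loci: uniform QTL and near-even-grid SNPs.

    Five times as many candidates as the final panel (500 QTL + 5000 SNPs per
    chromosome by default) are simulated so that enough loci pass the MAF
    filter at panel selection.  Candidate SNPs sit on an even grid with
    uniform jitter of +-``snp_jitter`` grid spacings.
    """
    if n_chrom < 1:
        raise InvalidConfigError("n_chrom must be positive")
    chroms, poss, roles, grids = [], [], [], []
    spacing = chrom_length / n_snp_candidates
    for c in range(n_chrom):
        qtl_pos = rng.uniform(0.0, chrom_length, n_qtl_candidates)
        grid = (np.arange(n_snp_candidates) + 0.5) * spacing
        snp_pos = grid + rng.uniform(-snp_jitter, snp_jitter,
                                     n_snp_candidates) * spacing
        snp_pos = np.clip(snp_pos, 0.0, chrom_length)
        pos = np.concatenate([qtl_pos, snp_pos])
        role = np.concatenate([np.full(n_qtl_candidates, QTL, np.int8),
                               np.full(n_snp_candidates, SNP, np.int8)])
        gidx = np.concatenate([np.full(n_qtl_candidates, -1, np.int64),
                               np.arange(n_snp_candidates)])
        order = np.argsort(pos, kind="stable")
        pos, role, gidx = pos[order], role[order], gidx[order]
        # break the (measure-zero) ties so positions are strictly increasing
        dup = np.flatnonzero(np.diff(pos) <= 0)
        while dup.size:
            pos[dup + 1] = np.nextafter(pos[dup], np.inf)
            dup = np.flatnonzero(np.diff(pos) <= 0)
        chroms.append(np.full(pos.size, c, np.int32))
        poss.append(pos)
        roles.append(role)
        grids.append(gidx)
    return GenomeMap(
        n_chromosomes=n_chrom,
        chrom_length=chrom_length,
        chrom=np.concatenate(chroms),
        positions=np.concatenate(poss),
        role=np.concatenate(roles),
        mutation_rate=mutation_rate,
        interference=interference,
        grid_index=np.concatenate(grids),
    )


def founder_population(gmap: GenomeMap, n: int,
                       rng: np.random.Generator) -> Population:
    """Unrelated base individuals with every allele at frequency 0.5."""
    hap = (rng.random((2 * n, gmap.n_loci)) < 0.5).astype(np.int8)
    return Population(haplotypes=hap, breed="founder", generation=0)


# ---------------------------------------------------------------------------
# Meiosis and random mating

def sample_gametes(pop: Population, parents: np.ndarray, gmap: GenomeMap,
                   rng: np.random.Generator,
                   mutation_rate: Optional[float] = None) -> np.ndarray:
    """One recombinant (and possibly mutated) gamete per parent index."""
    start, end = gmap.chrom_bounds()
    mu = gmap.mutation_rate if mutation_rate is None else mutation_rate
    return make_gametes(pop.haplotypes, np.asarray(parents, np.int64),
                        start, end, gmap.positions, gmap.chrom_length,
                        gmap.interference, mu, _kernel_seed(rng))


def mate(pop_sires: Population, sires: np.ndarray,
         pop_dams: Population, dams: np.ndarray,
         gmap: GenomeMap, rng: np.random.Generator,
         breed: str, generation: int,
         mutation_rate: Optional[float] = None) -> Population:
    """Offspring from explicit sire/dam index lists (one offspring each)."""
    g_s = sample_gametes(pop_sires, sires, gmap, rng, mutation_rate)
    g_d = sample_gametes(pop_dams, dams, gmap, rng, mutation_rate)
    hap = np.empty((2 * len(sires), gmap.n_loci), np.int8)
    hap[0::2] = g_s
    hap[1::2] = g_d
    return Population(haplotypes=hap, breed=breed, generation=generation,
                      sire=np.asarray(sires), dam=np.asarray(dams))


def evolve_random_mating(pop: Population, generations: int, pop_size: int,
                         gmap: GenomeMap,
                         rng: np.random.Generator) -> Population:
    """Discrete non-overlapping Wright-Fisher generations.

    Parents are drawn uniformly with replacement (monoecious; selfing
    allowed), the standard idealized-population convention for historical
    drift phases.
    """
    if pop_size < 1:
        raise InvalidConfigError("pop_size must be >= 1")
    for _ in range(generations):
        sires = rng.integers(0, pop.n, pop_size)
        dams = rng.integers(0, pop.n, pop_size)
        pop = mate(pop, sires, pop, dams, gmap, rng,
                   breed=pop.breed, generation=pop.generation + 1)
    return pop


def form_breeds(founders: Population, gmap: GenomeMap,
                rng: np.random.Generator,
                n_breed: int = 100,
                generations: int = 54) -> tuple[Population, Population]:
    """Split two breeds off the founders and let them drift apart.

    Each breed starts from an independent random sample of ``n_breed``
    founders and random-mates at constant size for ``generations``
    generations (mutation continuing at the genome-wide rate).
    """
    if founders.n < n_breed:
        raise InvalidConfigError(
            f"need at least {n_breed} founders, got {founders.n}")
    pops = []
    for name in ("A", "B"):
        pick = rng.choice(founders.n, n_breed, replace=False)
        rows = np.empty(2 * n_breed, np.int64)
        rows[0::2] = 2 * pick
        rows[1::2] = 2 * pick + 1
        seed_pop = Population(haplotypes=founders.haplotypes[rows].copy(),
                              breed=name, generation=0)
        pops.append(evolve_random_mating(seed_pop, generations, n_breed,
                                         gmap, rng))
    return pops[0], pops[1]


# ---------------------------------------------------------------------------
# Panel selection and summaries

def allele_frequencies(pop: Population,
                       loci: Optional[np.ndarray] = None) -> np.ndarray:
    """Per-locus frequency of the counted (1) allele."""
    h = pop.haplotypes if loci is None else pop.haplotypes[:, loci]
    return h.mean(axis=0)


def heterozygosity(pop: Population,
                   loci: Optional[np.ndarray] = None) -> float:
    """Mean observed heterozygote fraction over the selected loci."""
    return float(pop.het_indicator(loci).mean())


def select_panel(founders: Population, cmap: GenomeMap,
                 rng: np.random.Generator,
                 n_qtl: int = 100, n_snp: int = 1000,
                 maf_threshold: float = 0.1
                 ) -> tuple[GenomeMap, np.ndarray]:
    """Choose the trait QTL and the marker panel among segregating candidates.

    Per chromosome, ``n_qtl`` QTL are drawn at random from candidate QTL with
    founder minor allele frequency above ``maf_threshold``; ``n_snp`` SNPs are
    chosen by assigning each of ``n_snp`` even grid targets the nearest
    qualifying candidate, which preserves the near-even marker spacing while
    honouring the MAF filter.

    Returns the restricted map and the locus indices into ``cmap``.
    """
    freqs = allele_frequencies(founders)
    maf = np.minimum(freqs, 1.0 - freqs)
    ok = maf > maf_threshold
    chosen: list[np.ndarray] = []
    for c in range(cmap.n_chromosomes):
        on_c = cmap.chrom == c
        cand_qtl = np.flatnonzero(on_c & (cmap.role == QTL) & ok)
        cand_snp = np.flatnonzero(on_c & (cmap.role == SNP) & ok)
        if cand_qtl.size < n_qtl or cand_snp.size < n_snp:
            raise PanelSelectionError(
                f"chromosome {c}: only {cand_qtl.size} QTL / "
                f"{cand_snp.size} SNP candidates above MAF "
                f"{maf_threshold}")
        qtl_pick = rng.choice(cand_qtl, n_qtl, replace=False)
        snp_pick = _pick_grid_snps(cmap.positions[cand_snp], cand_snp,
                                   n_snp, cmap.chrom_length)
        chosen.append(np.sort(np.concatenate([qtl_pick, snp_pick])))
    idx = np.concatenate(chosen)
    return cmap.subset(idx), idx


def _pick_grid_snps(pos: np.ndarray, cand_idx: np.ndarray,
                    n_target: int, chrom_length: float) -> np.ndarray:
    """Nearest unused qualifying candidate for each even grid target."""
    targets = (np.arange(n_target) + 0.5) * (chrom_length / n_target)
    used = np.zeros(pos.size, bool)
    picks = np.empty(n_target, np.int64)
    for t, tgt in enumerate(targets):
        j = np.searchsorted(pos, tgt)
        lo, hi = j - 1, j
        best = -1
        best_d = np.inf
        # scan outwards from the insertion point until the nearest free
        # candidate cannot be beaten
        while lo >= 0 or hi < pos.size:
            if lo >= 0:
                d = abs(pos[lo] - tgt)
                if d < best_d and not used[lo]:
                    best, best_d = lo, d
                if d >= best_d:
                    lo = -1
                else:
                    lo -= 1
            if hi < pos.size:
                d = abs(pos[hi] - tgt)
                if d < best_d and not used[hi]:
                    best, best_d = hi, d
                if d >= best_d:
                    hi = pos.size
                else:
                    hi += 1
        used[best] = True
        picks[t] = cand_idx[best]
    return picks


# ---------------------------------------------------------------------------
# Full purebred history

def simulate_purebred_history(
        n_chrom: int,
        rng: np.random.Generator,
        n_base: int = 500,
        n_base_generations: int = 1000,
        n_breed: int = 100,
        n_breed_generations: int = 54,
        n_qtl: int = 100,
        n_snp: int = 1000,
        max_retries: int = 5,
        **genome_kwargs,
) -> tuple[GenomeMap, Population, Population, Population]:
    """Base population -> LD -> panel selection -> breed formation.

    Returns ``(panel_map, founders_on_panel, breed_A, breed_B)`` where the
    breeds are the 100-individual generation -1 populations and all
    haplotypes are restricted to the selected panel.  Histories whose
    founders fail the MAF filter are re-simulated (fresh draws from the same
    stream), up to ``max_retries`` times.
    """
    genome_kwargs.setdefault("n_qtl_candidates", 5 * n_qtl)
    genome_kwargs.setdefault("n_snp_candidates", 5 * n_snp)
    for _ in range(max_retries):
        cmap = build_genome(n_chrom, rng, **genome_kwargs)
        base = founder_population(cmap, n_base, rng)
        founders = evolve_random_mating(base, n_base_generations, n_base,
                                        cmap, rng)
        try:
            pmap, idx = select_panel(founders, cmap, rng,
                                     n_qtl=n_qtl, n_snp=n_snp)
        except PanelSelectionError:
            continue
        founders_p = founders.subset_loci(idx)
        breed_a, breed_b = form_breeds(founders_p, pmap, rng,
                                       n_breed=n_breed,
                                       generations=n_breed_generations)
        return pmap, founders_p, breed_a, breed_b
    raise PanelSelectionError(
        f"no qualifying panel after {max_retries} histories")
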