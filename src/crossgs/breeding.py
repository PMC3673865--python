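"""Two-way crossbreeding program with genomic truncation selection.

Each cycle selects the top 600 of 1000 candidates per parental breed on GEBV
(ranks 1-100 serve as males, 101-600 as females), random-mates the selected
animals within breed to produce 1000 purebred replacements, and mates the 100
breed-A males to the 500 breed-B females to produce 1000 crossbreds whose
phenotypic mean measures response.  Selection runs for 20 generations from a
fixed generation-0 state, with marker effects trained once on the
generation-0 crossbreds:

* additive model: one substitution effect per SNP, reused unchanged;
* BSAM: breed-of-origin effects alpha^A / alpha^B, reused unchanged;
* dominance model: breed-specific substitution effects recomputed every
  generation as alpha_j = a_j + (1 - 2 p'_j) d_j from the current allele
  frequencies p' among the candidates of the opposite breed.

Cumulative response is R_i = (mu_i - mu_0) / sigma_0 with mu_i the crossbred
phenotypic mean and sigma_0 the phenotypic standard deviation of the shared
generation-0 crossbreds.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from . import mcmc
from .genome import (GenomeMap, InvalidConfigError, Population,
                     allele_frequencies, mate)
from .trait import TraitArchitecture, simulate_phenotypes


@dataclass
class BreedingConfig:
    n_candidates: int = 1000
    n_selected: int = 600
    n_males: int = 100
    n_females: int = 500
    n_generations: int = 20
    n_crossbreds: int = 1000
    mutation_in_program: bool = True
    # use frequencies among post-selection mates instead of all candidates
    # when recomputing dominance-model substitution effects
    opposite_freq_post_selection: bool = False
    # hook: recompute substitution effects each generation (dominance only)
    recompute_substitution_effects: bool = True

    def __post_init__(self):
        if self.n_males + self.n_females != self.n_selected:
            raise InvalidConfigError(
                "n_males + n_females must equal n_selected")
        if self.n_selected > self.n_candidates:
            raise InvalidConfigError("cannot select more than the candidates")


@dataclass
class GenerationSummary:
    generation: int
    crossbred_mean: float
    mean_a: float                  # breed-A candidate phenotypic mean
    mean_b: float
    heterosis: float               # crossbred mean - midparent mean
    cumulative_response: float     # R_i in sigma_0 units
    od_heterozygosity: Optional[float] = None
    freq_a: Optional[np.ndarray] = None   # QTL allele frequencies, breed A
    freq_b: Optional[np.ndarray] = None


@dataclass
class Generation0:
    """The shared starting state of every repetition: candidate purebreds,

    the trained-on crossbreds, and the baseline location/scale."""

    pop_a: Population
    pop_b: Population
    crossbreds: Population
    mu0: float
    sigma0: float
    mean_a0: float
    mean_b0: float


def substitution_effects(a_hat: np.ndarray, d_hat: np.ndarray,
                         freq_opposite: np.ndarray) -> np.ndarray:
    """Breed-specific alpha_j = a_j + (1 - 2 p'_j) d_j (mate-breed p')."""
    a_hat = np.asarray(a_hat, float)
    d_hat = np.asarray(d_hat, float)
    p = np.asarray(freq_opposite, float)
    if not (a_hat.shape == d_hat.shape == p.shape):
        raise mcmc.InvalidInputError("effect/frequency length mismatch")
    return a_hat + (1.0 - 2.0 * p) * d_hat


def gebv(genotypes: np.ndarray, alpha: np.ndarray) -> np.ndarray:
    """GEBV_i = sum_j Z_ij alpha_j (centering shifts all GEBV equally)."""
    return np.asarray(genotypes, float) @ np.asarray(alpha, float)


def tbv(qtl_genotypes: np.ndarray, arch: TraitArchitecture,
        freq_opposite_qtl: np.ndarray) -> np.ndarray:
    """True breeding values from the true QTL effects (diagnostics only)."""
    alpha = substitution_effects(arch.a, arch.d, freq_opposite_qtl)
    return gebv(qtl_genotypes, alpha)


def model_gebv(fit: mcmc.ModelFit, pop: Population, snp_idx: np.ndarray,
               breed: str,
               freq_opposite: Optional[np.ndarray] = None) -> np.ndarray:
    """GEBV of purebred candidates under a trained model.

    ``breed`` is the candidates' own breed ("A" or "B").  The dominance model
    needs ``freq_opposite``, the current SNP allele frequencies in the other
    breed, to rebuild its breed-specific substitution effects.
    """
    Z = pop.genotypes(snp_idx)
    if fit.model_kind == mcmc.ADDITIVE:
        return gebv(Z, fit.effects["alpha"])
    if fit.model_kind == mcmc.BSAM:
        key = "alpha_A" if breed == "A" else "alpha_B"
        return gebv(Z, fit.effects[key])
    if fit.model_kind == mcmc.DOMINANCE:
        if freq_opposite is None:
            raise mcmc.InvalidInputError(
                "dominance-model GEBV needs opposite-breed frequencies")
        alpha = substitution_effects(fit.effects["a"], fit.effects["d"],
                                     freq_opposite)
        return gebv(Z, alpha)
    raise mcmc.InvalidInputError(f"unknown model kind {fit.model_kind!r}")


def rank_candidates(gebv_values: np.ndarray,
                    rng: np.random.Generator) -> np.ndarray:
    """Indices sorted by decreasing GEBV; ties broken uniformly at random."""
    n = gebv_values.shape[0]
    perm = rng.permutation(n)
    order = np.argsort(-gebv_values[perm], kind="stable")
    return perm[order]


def select_and_mate(candidates: Population, gebv_values: np.ndarray,
                    cfg: BreedingConfig, gmap: GenomeMap,
                    rng: np.random.Generator
                    ) -> tuple[np.ndarray, np.ndarray, Population]:
    """Truncation-select, then random-mate within breed for replacements.

    Returns (selected male indices, selected female indices, replacement
    population of ``cfg.n_candidates`` offspring); each replacement draws its
    sire uniformly from the males and its dam uniformly from the females.
    """
    if candidates.n < cfg.n_selected:
        raise InvalidConfigError("fewer candidates than n_selected")
    order = rank_candidates(gebv_values, rng)
    males = order[:cfg.n_males]
    females = order[cfg.n_males:cfg.n_selected]
    sires = males[rng.integers(0, cfg.n_males, cfg.n_candidates)]
    dams = females[rng.integers(0, cfg.n_females, cfg.n_candidates)]
    mu = None if cfg.mutation_in_program else 0.0
    replacements = mate(candidates, sires, candidates, dams, gmap, rng,
                        breed=candidates.breed,
                        generation=candidates.generation + 1,
                        mutation_rate=mu)
    return males, females, replacements


def produce_crossbreds(pop_a: Population, sires_a: np.ndarray,
                       pop_b: Population, dams_b: np.ndarray,
                       n: int, gmap: GenomeMap, rng: np.random.Generator,
                       mutation: bool = True) -> Population:
    """AB crossbreds; paternal haplotype = breed-A gamete by construction."""
    sires = np.asarray(sires_a)[rng.integers(0, len(sires_a), n)]
    dams = np.asarray(dams_b)[rng.integers(0, len(dams_b), n)]
    off = mate(pop_a, sires, pop_b, dams, gmap, rng, breed="AB",
               generation=max(pop_a.generation, pop_b.generation) + 1,
               mutation_rate=None if mutation else 0.0)
    return off


def track_overdominant_heterozygosity(crossbreds: Population,
                                      arch: TraitArchitecture,
                                      qtl_idx: np.ndarray
                                      ) -> Optional[float]:
    """Mean heterozygote fraction at QTL with |d| > |a|; None if there are

    no overdominant QTL (scenarios without overdominance)."""
    od = arch.overdominant
    if not od.any():
        return None
    return float(crossbreds.het_indicator(np.asarray(qtl_idx)[od]).mean())


def make_generation0(pop_a: Population, pop_b: Population,
                     gmap: GenomeMap, arch: TraitArchitecture,
                     rng: np.random.Generator,
                     n_candidates: int = 1000,
                     n_crossbreds: int = 1000,
                     n_sires: int = 100,
                     n_dams: int = 500) -> Generation0:
    """Expand the generation -1 breeds to the generation-0 state.

    Each breed is expanded to ``n_candidates`` selection candidates by one
    round of random mating.  The AB_0 training crossbreds are produced under
    the same mating design as every later generation -- ``n_sires`` breed-A
    males and ``n_dams`` breed-B females -- except that the parents are a
    random draw rather than selected.  Phenotypes for all three groups are
    simulated here, so the baseline is fixed once and shared by every
    repetition of the selection program.
    """
    from .genome import evolve_random_mating
    qtl = gmap.qtl_indices
    a0 = evolve_random_mating(pop_a, 1, n_candidates, gmap, rng)
    b0 = evolve_random_mating(pop_b, 1, n_candidates, gmap, rng)
    a0.phenotypes = simulate_phenotypes(a0.genotypes(qtl), arch, rng)
    b0.phenotypes = simulate_phenotypes(b0.genotypes(qtl), arch, rng)
    sires0 = rng.choice(a0.n, n_sires, replace=False)
    dams0 = rng.choice(b0.n, n_dams, replace=False)
    ab0 = produce_crossbreds(a0, sires0, b0, dams0,
                             n_crossbreds, gmap, rng)
    ab0.phenotypes = simulate_phenotypes(ab0.genotypes(qtl), arch, rng)
    return Generation0(
        pop_a=a0, pop_b=b0, crossbreds=ab0,
        mu0=float(ab0.phenotypes.mean()),
        sigma0=float(ab0.phenotypes.std(ddof=1)),
        mean_a0=float(a0.phenotypes.mean()),
        mean_b0=float(b0.phenotypes.mean()),
    )


def run_program(fit: Optional[mcmc.ModelFit], gen0: Generation0,
                gmap: GenomeMap,
                arch: TraitArchitecture, cfg: BreedingConfig,
                rng: np.random.Generator,
                record_frequencies: bool = False
                ) -> list[GenerationSummary]:
    """Run the selection program for one model and one repetition.

    Starts from the shared generation-0 candidates; only selection/mating
    randomness differs between repetitions.  ``fit=None`` selects on the
    true breeding values (true QTL effects with current opposite-breed
    frequencies) -- the upper bound on marker-based selection.
    """
    qtl = gmap.qtl_indices
    snp = gmap.snp_indices
    pop_a, pop_b = gen0.pop_a, gen0.pop_b
    mid0 = 0.5 * (gen0.mean_a0 + gen0.mean_b0)

    summaries = [GenerationSummary(
        generation=0,
        crossbred_mean=gen0.mu0,
        mean_a=gen0.mean_a0,
        mean_b=gen0.mean_b0,
        heterosis=gen0.mu0 - mid0,
        cumulative_response=0.0,
        od_heterozygosity=track_overdominant_heterozygosity(
            gen0.crossbreds, arch, qtl),
        freq_a=(allele_frequencies(pop_a, qtl) if record_frequencies
                else None),
        freq_b=(allele_frequencies(pop_b, qtl) if record_frequencies
                else None),
    )]

    for gen in range(1, cfg.n_generations + 1):
        if fit is None:
            gebv_a = tbv(pop_a.genotypes(qtl), arch,
                         allele_frequencies(pop_b, qtl))
            gebv_b = tbv(pop_b.genotypes(qtl), arch,
                         allele_frequencies(pop_a, qtl))
        else:
            if fit.model_kind == mcmc.DOMINANCE \
                    and cfg.recompute_substitution_effects:
                freq_opp_for_a = allele_frequencies(pop_b, snp)
                freq_opp_for_b = allele_frequencies(pop_a, snp)
            else:
                freq_opp_for_a = freq_opp_for_b = None
            gebv_a = model_gebv(fit, pop_a, snp, "A", freq_opp_for_a)
            gebv_b = model_gebv(fit, pop_b, snp, "B", freq_opp_for_b)

        males_a, _, next_a = select_and_mate(pop_a, gebv_a, cfg, gmap, rng)
        _, females_b, next_b = select_and_mate(pop_b, gebv_b, cfg, gmap, rng)
        crossbreds = produce_crossbreds(
            pop_a, males_a, pop_b, females_b, cfg.n_crossbreds, gmap, rng,
            mutation=cfg.mutation_in_program)

        crossbreds.phenotypes = simulate_phenotypes(
            crossbreds.genotypes(qtl), arch, rng)
        next_a.phenotypes = simulate_phenotypes(
            next_a.genotypes(qtl), arch, rng)
        next_b.phenotypes = simulate_phenotypes(
            next_b.genotypes(qtl), arch, rng)

        pop_a, pop_b = next_a, next_b
        mu_i = float(crossbreds.phenotypes.mean())
        mean_a = float(pop_a.phenotypes.mean())
        mean_b = float(pop_b.phenotypes.mean())
        summaries.append(GenerationSummary(
            generation=gen,
            crossbred_mean=mu_i,
            mean_a=mean_a,
            mean_b=mean_b,
            heterosis=mu_i - 0.5 * (mean_a + mean_b),
            cumulative_response=(mu_i - gen0.mu0) / gen0.sigma0,
            od_heterozygosity=track_overdominant_heterozygosity(
                crossbreds, arch, qtl),
            freq_a=(allele_frequencies(pop_a, qtl) if record_frequencies
                    else None),
            freq_b=(allele_frequencies(pop_b, qtl) if record_frequencies
                    else None),
        ))
    return summaries
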