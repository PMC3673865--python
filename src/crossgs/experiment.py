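"""Experiment orchestration: configuration, seeding, and the full loop.

One experiment = for each random simulation: simulate the purebred history,
draw and scale a trait architecture per scenario, build the generation-0
state and the crossbred training data, train each requested model once, then
repeat the 20-generation selection program ``n_repetitions`` times per model
from the identical generation-0 candidates and trained effects.

Reproducibility: every unit of work draws its random stream from a child of
one master seed via ``numpy.random.SeedSequence`` spawn keys, so results are
identical regardless of the order in which models or repetitions are run.
"""

from __future__ import annotations

import hashlib
import logging
import time
from dataclasses import asdict, dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import breeding, mcmc
from .analysis import summaries_to_frame
from .breeding import BreedingConfig, Generation0, make_generation0
from .genome import (GenomeMap, InvalidConfigError, Population,
                     allele_frequencies, simulate_purebred_history)
from .mcmc import MCMCConfig, ModelFit
from .trait import (ScenarioSpec, TraitArchitecture, expected_heterosis,
                    make_trait_architecture, variance_components)

logger = logging.getLogger(__name__)

# spawn-key name space for deterministic child streams
_PHASE_HISTORY = 0
_PHASE_TRAIT = 1
_PHASE_GEN0 = 2
_PHASE_TRAIN = 3
_PHASE_PROGRAM = 4
_MODEL_ID = {mcmc.ADDITIVE: 0, mcmc.DOMINANCE: 1, mcmc.BSAM: 2}


def child_rng(master_seed: int, *key: int) -> np.random.Generator:
    """Deterministic child stream for a (simulation, phase, ...) unit."""
    ss = np.random.SeedSequence(entropy=master_seed, spawn_key=tuple(key))
    return np.random.default_rng(ss)


@dataclass
class ExperimentConfig:
    scenario: int = 2
    n_chromosomes: int = 1
    n_simulations: int = 1
    n_repetitions: int = 1
    seed: int = 0
    models: tuple[str, ...] = (mcmc.ADDITIVE, mcmc.DOMINANCE, mcmc.BSAM)
    # population history
    n_base: int = 500
    n_base_generations: int = 1000
    n_breed: int = 100
    n_breed_generations: int = 54
    n_qtl_per_chrom: int = 100
    n_snp_per_chrom: int = 1000
    mutation_rate: float = 2.5e-5
    interference: int = 4
    negative_d_fraction: Optional[float] = None  # override for big genomes
    mcmc: MCMCConfig = field(default_factory=MCMCConfig)
    breeding: BreedingConfig = field(default_factory=BreedingConfig)
    out_dir: Optional[str] = None
    record_frequencies: bool = False

    def config_hash(self) -> str:
        """Hash of the scientific configuration (output location excluded)."""
        plain = _to_plain(asdict(self))
        plain.pop("out_dir", None)
        blob = yaml.safe_dump(plain, sort_keys=True)
        return hashlib.sha1(blob.encode()).hexdigest()[:10]


def _to_plain(obj):
    if isinstance(obj, dict):
        return {k: _to_plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_plain(v) for v in obj]
    if isinstance(obj, np.generic):
        return obj.item()
    return obj


def validate_config(raw: Optional[dict] = None) -> ExperimentConfig:
    """Build a normalized config from a (possibly empty) mapping.

    Unknown keys and inconsistent values are reported together in one
    InvalidConfigError; an empty input yields the full default
    configuration.
    """
    raw = dict(raw or {})
    errors: list[str] = []
    mcmc_raw = raw.pop("mcmc", {}) or {}
    breed_raw = raw.pop("breeding", {}) or {}
    known = {f.name for f in ExperimentConfig.__dataclass_fields__.values()}
    for key in raw:
        if key not in known:
            errors.append(f"unknown field: {key}")
    try:
        mc = MCMCConfig(**mcmc_raw)
    except (TypeError, mcmc.InvalidInputError) as e:
        errors.append(f"mcmc: {e}")
        mc = MCMCConfig()
    try:
        bc = BreedingConfig(**breed_raw)
    except (TypeError, InvalidConfigError) as e:
        errors.append(f"breeding: {e}")
        bc = BreedingConfig()
    cfg = None
    try:
        cfg = ExperimentConfig(**{k: v for k, v in raw.items()
                                  if k in known})
        cfg.mcmc = mc
        cfg.breeding = bc
    except TypeError as e:
        errors.append(str(e))
    if cfg is not None:
        if "models" in raw:
            cfg.models = tuple(raw["models"])
        for m in cfg.models:
            if m not in mcmc.MODEL_KINDS:
                errors.append(f"models: unknown model kind {m!r}")
        if cfg.scenario not in (1, 2, 3, 4):
            errors.append("scenario: must be in {1, 2, 3, 4}")
        for name in ("n_chromosomes", "n_simulations", "n_repetitions",
                     "n_base", "n_breed", "n_qtl_per_chrom",
                     "n_snp_per_chrom"):
            if getattr(cfg, name) < 1:
                errors.append(f"{name}: must be positive")
        if cfg.mutation_rate < 0:
            errors.append("mutation_rate: must be non-negative")
    if errors:
        raise InvalidConfigError("; ".join(errors))
    return cfg


def load_config(path: str) -> ExperimentConfig:
    with open(path) as fh:
        return validate_config(yaml.safe_load(fh) or {})


@dataclass
class TrainingData:
    """Crossbred training records plus everything hyperparameters need."""

    X: np.ndarray            # SNP dosages 0/1/2 of the AB_0 crossbreds
    W: np.ndarray            # heterozygosity indicators
    XA: np.ndarray           # breed-A-origin allele dosages (0/1)
    XB: np.ndarray
    y: np.ndarray
    snp_freqs: np.ndarray    # training-crossbred SNP allele frequencies
    delta: np.ndarray        # generation-0 breed SNP frequency differences
    origin_freqs: tuple[np.ndarray, np.ndarray]
    v_a: float
    v_d: float
    v_e: float
    h: float


def build_training_data(gen0: Generation0, gmap: GenomeMap,
                        arch: TraitArchitecture) -> TrainingData:
    snp = gmap.snp_indices
    qtl = gmap.qtl_indices
    ab0 = gen0.crossbreds
    X = ab0.genotypes(snp)
    W = ab0.het_indicator(snp)
    XA = ab0.paternal_alleles(snp)
    XB = ab0.maternal_alleles(snp)
    freq_a_snp = allele_frequencies(gen0.pop_a, snp)
    freq_b_snp = allele_frequencies(gen0.pop_b, snp)
    qtl_freq_ab = allele_frequencies(ab0, qtl)
    vc = variance_components(qtl_freq_ab, arch)
    h = expected_heterosis(arch, allele_frequencies(gen0.pop_a, qtl),
                           allele_frequencies(gen0.pop_b, qtl))
    return TrainingData(
        X=X, W=W, XA=XA, XB=XB, y=ab0.phenotypes,
        snp_freqs=allele_frequencies(ab0, snp),
        delta=freq_a_snp - freq_b_snp,
        origin_freqs=(XA.mean(axis=0), XB.mean(axis=0)),
        v_a=vc.va, v_d=vc.vd, v_e=arch.residual_variance, h=h,
    )


def train_model(model_kind: str, data: TrainingData, cfg: MCMCConfig,
                rng: np.random.Generator) -> ModelFit:
    hp = mcmc.derive_hyperparameters(
        data.v_a, data.v_d, data.v_e, data.h, data.snp_freqs, data.delta,
        cfg, model_kind, origin_freqs=data.origin_freqs)
    if model_kind == mcmc.ADDITIVE:
        return mcmc.fit_additive(data.X, data.y, hp, cfg, seed=rng)
    if model_kind == mcmc.DOMINANCE:
        return mcmc.fit_dominance(data.X, data.W, data.y, hp, cfg, seed=rng)
    if model_kind == mcmc.BSAM:
        return mcmc.fit_bsam(data.XA, data.XB, data.y, hp, cfg, seed=rng)
    raise mcmc.InvalidInputError(f"unknown model kind {model_kind!r}")


@dataclass
class SimulationState:
    """Everything shared by the repetitions of one random simulation."""

    gmap: GenomeMap
    breed_a: Population          # generation -1
    breed_b: Population
    arch: TraitArchitecture
    gen0: Generation0
    training: TrainingData
    fits: dict[str, ModelFit]


def prepare_simulation(cfg: ExperimentConfig, sim: int,
                       scenario: Optional[ScenarioSpec] = None,
                       models: Optional[tuple[str, ...]] = None,
                       history: Optional[tuple] = None) -> SimulationState:
    """History, trait, generation 0 and one training per model for one
    simulation seed.  ``history`` may carry a pre-computed
    (gmap, founders, breed_a, breed_b) so that several scenarios share one
    genome, as locus positions, LD and allele frequencies are held constant
    across scenarios."""
    if scenario is None:
        scenario = ScenarioSpec.from_id(cfg.scenario,
                                        cfg.negative_d_fraction)
    models = cfg.models if models is None else models
    if history is None:
        history = simulate_history(cfg, sim)
    gmap, founders, breed_a, breed_b = history

    arch = simulation_architecture(cfg, sim, scenario,
                                   (gmap, breed_a, breed_b))

    rng_gen0 = child_rng(cfg.seed, sim, _PHASE_GEN0, scenario.id)
    gen0 = make_generation0(breed_a, breed_b, gmap, arch, rng_gen0,
                            n_candidates=cfg.breeding.n_candidates,
                            n_crossbreds=cfg.breeding.n_crossbreds,
                            n_sires=cfg.breeding.n_males,
                            n_dams=cfg.breeding.n_females)
    data = build_training_data(gen0, gmap, arch)

    fits = {}
    for m in models:
        t0 = time.perf_counter()
        rng_train = child_rng(cfg.seed, sim, _PHASE_TRAIN, scenario.id,
                              _MODEL_ID[m])
        fits[m] = train_model(m, data, cfg.mcmc, rng_train)
        logger.info("sim %d scenario %d: trained %s in %.1fs",
                    sim, scenario.id, m, time.perf_counter() - t0)
    return SimulationState(gmap=gmap, breed_a=breed_a, breed_b=breed_b,
                           arch=arch, gen0=gen0, training=data, fits=fits)


def simulation_architecture(cfg: ExperimentConfig, sim: int,
                            scenario: ScenarioSpec,
                            history: tuple) -> TraitArchitecture:
    """Draw and scale the trait architecture for one simulation seed.

    The scaling reference is the two generation -1 breeds jointly, so that
    the per-breed variance components average to the scenario targets.
    """
    gmap, breed_a, breed_b = history[0], history[-2], history[-1]
    rng_trait = child_rng(cfg.seed, sim, _PHASE_TRAIT, scenario.id)
    qtl = gmap.qtl_indices
    ref_freqs = np.vstack([allele_frequencies(breed_a, qtl),
                           allele_frequencies(breed_b, qtl)])
    return make_trait_architecture(scenario, ref_freqs, rng_trait)


def simulate_history(cfg: ExperimentConfig, sim: int):
    """Base population, panel and breeds for one simulation seed."""
    rng = child_rng(cfg.seed, sim, _PHASE_HISTORY)
    t0 = time.perf_counter()
    gmap, founders, breed_a, breed_b = simulate_purebred_history(
        cfg.n_chromosomes, rng,
        n_base=cfg.n_base, n_base_generations=cfg.n_base_generations,
        n_breed=cfg.n_breed, n_breed_generations=cfg.n_breed_generations,
        n_qtl=cfg.n_qtl_per_chrom, n_snp=cfg.n_snp_per_chrom,
        mutation_rate=cfg.mutation_rate, interference=cfg.interference)
    logger.info("sim %d: history simulated in %.1fs", sim,
                time.perf_counter() - t0)
    return gmap, founders, breed_a, breed_b


def run_repetitions(state: SimulationState, cfg: ExperimentConfig, sim: int,
                    scenario_id: int) -> pd.DataFrame:
    """All repetitions x models of the selection program for one
    simulation."""
    frames = []
    g0 = state.gen0
    for m, fit in state.fits.items():
        for rep in range(cfg.n_repetitions):
            rng = child_rng(cfg.seed, sim, _PHASE_PROGRAM, scenario_id,
                            _MODEL_ID[m], rep)
            summaries = breeding.run_program(
                fit, g0, state.gmap, state.arch, cfg.breeding, rng,
                record_frequencies=cfg.record_frequencies)
            frames.append(summaries_to_frame(
                summaries, sim, rep, m, g0.mu0, g0.sigma0,
                g0.mean_a0, g0.mean_b0))
    return pd.concat(frames, ignore_index=True)


@dataclass
class ExperimentResult:
    summaries: pd.DataFrame          # long per-generation table
    nonzero_counts: pd.DataFrame     # per (simulation, model, class)
    config: ExperimentConfig


def run_experiment(cfg: ExperimentConfig) -> ExperimentResult:
    frames = []
    counts = []
    for sim in range(cfg.n_simulations):
        state = prepare_simulation(cfg, sim)
        frames.append(run_repetitions(state, cfg, sim, cfg.scenario))
        for m, fit in state.fits.items():
            for cls, cnt in fit.nonzero_counts().items():
                counts.append({"simulation": sim, "model": m,
                               "effect_class": cls, "nonzero_count": cnt})
    result = ExperimentResult(
        summaries=pd.concat(frames, ignore_index=True),
        nonzero_counts=pd.DataFrame(counts),
        config=cfg,
    )
    if cfg.out_dir is not None:
        write_experiment(result)
    return result


def write_experiment(result: ExperimentResult) -> None:
    from .io import write_table
    import os
    cfg = result.config
    os.makedirs(cfg.out_dir, exist_ok=True)
    header = {"seed": cfg.seed, "config_sha": cfg.config_hash()}
    write_table(os.path.join(cfg.out_dir, "summaries.tsv"),
                result.summaries, header)
    write_table(os.path.join(cfg.out_dir, "nonzero_counts.tsv"),
                result.nonzero_counts, header)
    with open(os.path.join(cfg.out_dir, "config.yaml"), "w") as fh:
        yaml.safe_dump(_to_plain(asdict(cfg)), fh, sort_keys=True)
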