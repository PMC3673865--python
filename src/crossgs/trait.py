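"""Trait architecture: QTL effect sampling, variance scaling, phenotypes.

The additive effect ``a`` of a QTL is half the genotypic-value difference
between alternate homozygotes and the dominance effect ``d`` the deviation of
the heterozygote from the homozygote mean, so genotypic values at one locus
are 0, a + d and 2a for genotypes 00, 01/10 and 11.

Raw effects are drawn per scenario and then rescaled so that, at reference
allele frequencies, the additive and dominance variances hit their targets:
with residual variance fixed at V_E = 1 and broad-sense heritability 0.5 the
total genetic variance target is 1, split V_A : V_D = 2:1, 4:1 or 1:0
depending on the scenario.  Scenarios with overdominance scale d by
s = sqrt(V_D*/V_D) and a by the positive root t of the quadratic obtained by
expanding V_A* = sum_j 2 p q (t a_j + (q - p) s d_j)^2; the scenario without
overdominance scales both effects by the common factor c = sqrt(V_A*/V_A),
which preserves every dominance coefficient |d/a| <= 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

DEFAULT_ADDITIVE_RATE = 5.81


class ScalingError(RuntimeError):
    """The additive-scalar quadratic has no positive real root."""


class InvalidScenarioError(ValueError):
    pass


@dataclass(frozen=True)
class ScenarioSpec:
    """One of the four dominance scenarios.

    ====  =====================  ================  =========
    id    dominance mode         P(d < 0)          V_A : V_D
    ====  =====================  ================  =========
    1     independent Exp(5.81)  0.30              2 : 1
    2     independent Exp(5.81)  0.30              4 : 1
    3     Uniform(0, |a|)        0.20              4 : 1 (*)
    4     none (d = 0)           --                1 : 0
    ====  =====================  ================  =========

    (*) scenario 3 controls V_A only; common scaling leaves V_D free but
    guarantees no overdominance.
    """

    id: int
    additive_rate: float = DEFAULT_ADDITIVE_RATE
    dominance_mode: str = "independent-exponential"
    negative_d_fraction: Optional[float] = 0.30
    va_vd_ratio: tuple[float, float] = (2.0, 1.0)
    broad_sense_h2: float = 0.5
    residual_variance: float = 1.0

    @classmethod
    def from_id(cls, scenario_id: int,
                negative_d_fraction: Optional[float] = None) -> "ScenarioSpec":
        presets = {
            1: dict(dominance_mode="independent-exponential",
                    negative_d_fraction=0.30, va_vd_ratio=(2.0, 1.0)),
            2: dict(dominance_mode="independent-exponential",
                    negative_d_fraction=0.30, va_vd_ratio=(4.0, 1.0)),
            3: dict(dominance_mode="bounded-uniform",
                    negative_d_fraction=0.20, va_vd_ratio=(4.0, 1.0)),
            4: dict(dominance_mode="none",
                    negative_d_fraction=None, va_vd_ratio=(1.0, 0.0)),
        }
        if scenario_id not in presets:
            raise InvalidScenarioError(f"unknown scenario {scenario_id}")
        kw = presets[scenario_id]
        if negative_d_fraction is not None and kw["dominance_mode"] != "none":
            kw = dict(kw, negative_d_fraction=negative_d_fraction)
        return cls(id=scenario_id, **kw)

    @property
    def overdominance_allowed(self) -> bool:
        return self.dominance_mode == "independent-exponential"

    @property
    def genetic_variance_target(self) -> float:
        h2 = self.broad_sense_h2
        return self.residual_variance * h2 / (1.0 - h2)

    @property
    def va_target(self) -> float:
        ra, rd = self.va_vd_ratio
        return self.genetic_variance_target * ra / (ra + rd)

    @property
    def vd_target(self) -> float:
        ra, rd = self.va_vd_ratio
        return self.genetic_variance_target * rd / (ra + rd)


@dataclass
class TraitArchitecture:
    a: np.ndarray              # per-QTL additive effect
    d: np.ndarray              # per-QTL dominance effect
    residual_variance: float = 1.0
    scaling: dict = field(default_factory=dict)

    @property
    def n_qtl(self) -> int:
        return self.a.shape[0]

    @property
    def overdominant(self) -> np.ndarray:
        return np.abs(self.d) > np.abs(self.a)


@dataclass
class VarianceComponents:
    va: float
    vd: float

    @property
    def vg(self) -> float:
        return self.va + self.vd


def sample_qtl_effects(spec: ScenarioSpec, n_qtl: int,
                       rng: np.random.Generator) -> TraitArchitecture:
    """Unscaled per-QTL effects under the scenario's generating process."""
    if n_qtl < 1:
        raise InvalidScenarioError("n_qtl must be positive")
    scale = 1.0 / spec.additive_rate
    a = rng.exponential(scale, n_qtl)
    a *= rng.choice([-1.0, 1.0], n_qtl)
    if spec.dominance_mode == "none":
        d = np.zeros(n_qtl)
    elif spec.dominance_mode == "independent-exponential":
        d = rng.exponential(scale, n_qtl)
        d[rng.random(n_qtl) < spec.negative_d_fraction] *= -1.0
    elif spec.dominance_mode == "bounded-uniform":
        d = rng.uniform(0.0, np.abs(a))
        d[rng.random(n_qtl) < spec.negative_d_fraction] *= -1.0
    else:
        raise InvalidScenarioError(
            f"unknown dominance mode {spec.dominance_mode!r}")
    return TraitArchitecture(a=a, d=d,
                             residual_variance=spec.residual_variance)


def variance_components(freqs: np.ndarray,
                        arch: TraitArchitecture) -> VarianceComponents:
    """V_A = sum 2pq alpha^2 and V_D = sum (2pq d)^2 at the given frequencies,

    with the within-population substitution effect alpha = a + (q - p) d.
    Fixed loci (p = 0 or 1) contribute nothing.  A 2-D ``freqs`` array (one
    row per population) yields the components averaged over populations --
    the reference used when scaling effects against the two breeds jointly.
    """
    p = np.atleast_2d(np.asarray(freqs, float))
    q = 1.0 - p
    alpha = arch.a[None, :] + (q - p) * arch.d[None, :]
    va = float(np.mean(np.sum(2.0 * p * q * alpha ** 2, axis=1)))
    vd = float(np.mean(np.sum((2.0 * p * q * arch.d[None, :]) ** 2, axis=1)))
    return VarianceComponents(va=va, vd=vd)


def scale_effects(arch: TraitArchitecture, freqs: np.ndarray,
                  spec: ScenarioSpec) -> TraitArchitecture:
    """Rescale effects to the scenario's variance targets at ``freqs``.

    ``freqs`` may be a 2-D array (one row per reference population), in
    which case the targets apply to the variance components averaged over
    the populations.
    """
    p = np.atleast_2d(np.asarray(freqs, float))
    q = 1.0 - p
    vc = variance_components(p, arch)
    if spec.overdominance_allowed and spec.vd_target > 0:
        if vc.vd <= 0:
            raise InvalidScenarioError(
                "V_D = 0 in the sampled effects but V_D* > 0")
        s = np.sqrt(spec.vd_target / vc.vd)
        d_new = s * arch.d
        w = 2.0 * p * q / p.shape[0]
        a_row = arch.a[None, :]
        d_row = d_new[None, :]
        qa = float(np.sum(w * a_row ** 2))
        qb = float(np.sum(2.0 * w * a_row * (q - p) * d_row))
        qc = float(np.sum(w * ((q - p) * d_row) ** 2)) - spec.va_target
        disc = qb * qb - 4.0 * qa * qc
        if disc < 0 or qa <= 0:
            raise ScalingError("no real root for the additive scalar")
        roots = ((-qb + np.sqrt(disc)) / (2.0 * qa),
                 (-qb - np.sqrt(disc)) / (2.0 * qa))
        t = max(r for r in roots if r > 0) if any(
            r > 0 for r in roots) else None
        if t is None:
            raise ScalingError("no positive root for the additive scalar")
        a_new = t * arch.a
        scaling = {"s": float(s), "t": float(t)}
    else:
        if vc.va <= 0:
            raise ScalingError("V_A = 0 in the sampled effects")
        c = np.sqrt(spec.va_target / vc.va)
        a_new, d_new = c * arch.a, c * arch.d
        scaling = {"c": float(c)}
    out = TraitArchitecture(a=a_new, d=d_new,
                            residual_variance=spec.residual_variance,
                            scaling=scaling)
    vc_new = variance_components(p, out)
    if not np.isclose(vc_new.va, spec.va_target, rtol=1e-8):
        raise ScalingError("additive variance target missed after scaling")
    if (spec.overdominance_allowed and spec.vd_target > 0
            and not np.isclose(vc_new.vd, spec.vd_target, rtol=1e-8)):
        raise ScalingError("dominance variance target missed after scaling")
    return out


def make_trait_architecture(spec: ScenarioSpec, freqs: np.ndarray,
                            rng: np.random.Generator,
                            max_tries: int = 50) -> TraitArchitecture:
    """Sample and scale effects, re-sampling if the quadratic has no root."""
    n_qtl = np.asarray(freqs).shape[-1]
    for _ in range(max_tries):
        try:
            return scale_effects(sample_qtl_effects(spec, n_qtl, rng),
                                 freqs, spec)
        except ScalingError:
            continue
    raise ScalingError(f"scaling failed in {max_tries} attempts")


def genotypic_value(genotypes: np.ndarray,
                    arch: TraitArchitecture) -> np.ndarray:
    """Sum over QTL of {0, a + d, 2a} for codes {0, 1, 2}."""
    g = np.asarray(genotypes)
    return g @ arch.a + (g == 1) @ arch.d


def simulate_phenotypes(genotypes: np.ndarray, arch: TraitArchitecture,
                        rng: np.random.Generator) -> np.ndarray:
    """y = G + e with e ~ N(0, V_E)."""
    gv = genotypic_value(genotypes, arch)
    return gv + rng.normal(0.0, np.sqrt(arch.residual_variance), gv.shape)


def expected_heterosis(arch: TraitArchitecture, freq_a: np.ndarray,
                       freq_b: np.ndarray) -> float:
    """H = sum_j d_j Delta_j^2 with Delta the parental frequency difference.

    Equals the crossbred mean minus the midparent mean under Hardy-Weinberg
    equilibrium within each parental population.
    """
    delta = np.asarray(freq_a, float) - np.asarray(freq_b, float)
    return float(np.sum(arch.d * delta ** 2))
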