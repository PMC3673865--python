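"""Bayesian whole-genome regression of crossbred phenotypes on SNPs.

Three models share one Gibbs engine:

* additive -- BayesCpi: y = mu + X alpha + e with a spike-and-slab prior on
  each substitution effect, a common slab variance sigma_alpha^2 and an
  estimated null proportion Pi (uniform prior).
* dominance -- y = mu + X a + W d + e, where W indicates heterozygotes.
  Additive effects have a zero-mean slab; dominance effects have a slab with
  an *unknown nonzero mean* mu_d ~ N(eta, sigma_d^2 / phi), which lets the
  model absorb directional dominance (the source of heterosis).  Inclusion is
  decided separately per SNP for a and d.
* bsam -- breed-specific allele model: y = mu + X^A alpha^A + X^B alpha^B + e
  with the 0/1 breed-of-origin allele dosages of the crossbreds as
  covariates, and breed-specific slab variances and null proportions.

Per SNP and class, the inclusion indicator and the effect are sampled jointly
(indicator from its marginal with the effect integrated out, then the effect
from its normal full conditional); the scan is systematic with an
incrementally updated residual.  Slab variances have scaled-inverse-chi-square
priors whose scales derive from trait variance components via
S^2 = E(sigma^2) (nu - 2) / nu.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from ._kernels import sweep_class

logger = logging.getLogger(__name__)

ADDITIVE = "additive"
DOMINANCE = "dominance"
BSAM = "bsam"
MODEL_KINDS = (ADDITIVE, DOMINANCE, BSAM)


class InvalidInputError(ValueError):
    pass


@dataclass
class MCMCConfig:
    """Chain and prior settings (defaults: 11000 samples, 1000 burn-in,

    nu = 4 for every variance, phi = 10 for the mu_d prior, and null
    proportion 0.9 used only to derive prior scales)."""

    chain_length: int = 11000
    burn_in: int = 1000
    nu_alpha: float = 4.0
    nu_a: float = 4.0
    nu_d: float = 4.0
    nu_e: float = 4.0
    phi: float = 10.0
    pi0_alpha: float = 0.9
    pi0_a: float = 0.9
    pi0_d: float = 0.9
    seed: Optional[int] = None
    # diagnostics / oracle hooks
    estimate_pi: bool = True
    pi_fixed: Optional[float] = None
    update_variances: bool = True   # False freezes every variance
                                    # (slabs and residual) at its prior mean
    mu_d_fixed: Optional[float] = None
    # if True, the mu_d and sigma_d^2 full conditionals sum over all k
    # effects (zeros included) as literally printed; default sums over the
    # effects currently in the model.
    mu_d_sum_all: bool = False
    init_var_scale: float = 1.0   # diagnostic: scale the slab-variance start
    refresh_every: int = 500
    log_every: int = 1000

    def __post_init__(self):
        if not 0 <= self.burn_in < self.chain_length:
            raise InvalidInputError("burn_in must be < chain_length")
        if self.phi <= 0:
            raise InvalidInputError("phi must be positive")
        for name in ("pi0_alpha", "pi0_a", "pi0_d"):
            if not 0 <= getattr(self, name) < 1:
                raise InvalidInputError(f"{name} must be in [0, 1)")


@dataclass
class Hyperparams:
    """Prior scales derived from trait variance components."""

    S2_e: float
    S2_alpha: Optional[float] = None      # additive model
    S2_a: Optional[float] = None          # dominance model
    S2_d: Optional[float] = None
    eta: float = 0.0                      # prior mean of mu_d
    S2_alpha_A: Optional[float] = None    # bsam
    S2_alpha_B: Optional[float] = None


def _scale_from_expectation(e_sigma2: float, nu: float) -> float:
    """Invert E(sigma^2) = S^2 nu / (nu - 2)."""
    return e_sigma2 * (nu - 2.0) / nu


def derive_hyperparameters(v_a: float, v_d: float, v_e: float, h: float,
                           snp_freqs: np.ndarray,
                           delta: Optional[np.ndarray],
                           cfg: MCMCConfig,
                           model_kind: str,
                           origin_freqs: Optional[tuple[np.ndarray,
                                                        np.ndarray]] = None,
                           ) -> Hyperparams:
    """Prior scales from (true) V_A, V_D, V_E and heterosis H.

    ``snp_freqs`` are training-population SNP allele frequencies; ``delta``
    the generation-0 parental-breed frequency differences (dominance model);
    ``origin_freqs`` the per-breed-of-origin allele frequencies in the
    training crossbreds (BSAM).
    """
    p = np.asarray(snp_freqs, float)
    q = 1.0 - p
    k = p.shape[0]
    e_2pq = float(np.mean(2 * p * q))
    s2_e = _scale_from_expectation(v_e, cfg.nu_e)
    hp = Hyperparams(S2_e=s2_e)
    if model_kind == ADDITIVE:
        e_sig = v_a / (k * (1.0 - cfg.pi0_alpha) * e_2pq)
        hp.S2_alpha = _scale_from_expectation(e_sig, cfg.nu_alpha)
    elif model_kind == DOMINANCE:
        if delta is None:
            raise InvalidInputError(
                "dominance hyperparameters need the breed "
                "frequency-difference vector")
        e_2pq2 = float(np.mean((2 * p * q) ** 2))
        e_1m2p2 = float(np.mean((1.0 - 2.0 * p) ** 2))
        e_d2 = float(np.mean(np.asarray(delta, float) ** 2))
        k_d = k * (1.0 - cfg.pi0_d)
        eta = h / (k_d * e_d2) if e_d2 > 0 else 0.0
        sig_d2 = (v_d / (k_d * e_2pq2) - eta ** 2) / (1.0 + 1.0 / cfg.phi)
        if sig_d2 <= 0:
            # a (near-)zero slab variance makes inclusion undecidable (the
            # slab collapses onto the spike and the Bayes factor tends to
            # one); fall back to the additive per-effect scale so the data
            # keep discriminating and null dominance yields few inclusions
            floor = v_a / (k * (1.0 - cfg.pi0_a) * e_2pq)
            if v_d > 0:
                warnings.warn(
                    "derived sigma_d^2 is non-positive (eta^2 exceeds the "
                    "per-effect dominance variance); falling back to the "
                    "additive per-effect scale",
                    RuntimeWarning)
            sig_d2 = floor
        sig_a2 = (v_a / (k * (1.0 - cfg.pi0_a) * e_2pq)
                  - e_1m2p2 * (sig_d2 + eta ** 2))
        if sig_a2 <= 0:
            warnings.warn("derived sigma_a^2 is non-positive; clamping",
                          RuntimeWarning)
            sig_a2 = 1e-6 * v_a / (k * (1.0 - cfg.pi0_a) * e_2pq)
        hp.eta = float(eta)
        hp.S2_d = _scale_from_expectation(sig_d2, cfg.nu_d)
        hp.S2_a = _scale_from_expectation(sig_a2, cfg.nu_a)
    elif model_kind == BSAM:
        if origin_freqs is None:
            raise InvalidInputError(
                "BSAM hyperparameters need per-origin allele frequencies")
        pa, pb = (np.asarray(f, float) for f in origin_freqs)
        e_pq = float(np.mean(pa * (1 - pa)) + np.mean(pb * (1 - pb)))
        e_sig = v_a / (k * (1.0 - cfg.pi0_alpha) * max(e_pq, 1e-12))
        hp.S2_alpha_A = _scale_from_expectation(e_sig, cfg.nu_alpha)
        hp.S2_alpha_B = hp.S2_alpha_A
    else:
        raise InvalidInputError(f"unknown model kind {model_kind!r}")
    return hp


@dataclass
class ModelFit:
    """Posterior summaries of one trained model."""

    model_kind: str
    effects: dict[str, np.ndarray]          # posterior-mean effects per class
    inclusion: dict[str, np.ndarray]        # posterior inclusion frequency
    pi: dict[str, float]                    # posterior mean null proportion
    nonzero_trace: dict[str, np.ndarray]    # per-iteration nonzero counts
    var_effect: dict[str, float]            # posterior mean slab variances
    mu: float
    sigma_e2: float
    mu_d: Optional[float] = None
    mu_d_trace: Optional[np.ndarray] = None
    col_means: dict[str, np.ndarray] = field(default_factory=dict)
    burn_in: int = 0

    def nonzero_counts(self) -> dict[str, float]:
        """Posterior mean number of nonzero effects per class."""
        return {name: float(tr[self.burn_in:].mean())
                for name, tr in self.nonzero_trace.items()}


def count_nonzero_effects(fit: ModelFit) -> dict[str, float]:
    return fit.nonzero_counts()


@dataclass
class _EffectClass:
    name: str
    X: np.ndarray            # float32, F-order, column-centered
    xtx: np.ndarray          # float64 column sums of squares
    S2: float
    nu: float
    pi: float
    dominance_mean: bool = False   # slab mean is mu_d rather than 0


def _center(X: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    X = np.asarray(X, np.float64)
    if X.ndim != 2:
        raise InvalidInputError("genotype matrix must be 2-D")
    means = X.mean(axis=0)
    Xc = np.asfortranarray((X - means), dtype=np.float32)
    xtx = np.einsum("ij,ij->j", Xc, Xc, dtype=np.float64)
    return Xc, xtx, means


def _gibbs(y: np.ndarray, classes: list[_EffectClass], hp: Hyperparams,
           cfg: MCMCConfig, rng: np.random.Generator,
           model_kind: str) -> ModelFit:
    y = np.asarray(y, np.float64)
    if not np.all(np.isfinite(y)):
        raise InvalidInputError("phenotypes must be finite")
    n = y.shape[0]
    T, B = cfg.chain_length, cfg.burn_in
    n_post = T - B

    mu = float(y.mean())
    var_e = hp.S2_e * cfg.nu_e / max(cfg.nu_e - 2.0, 1e-12)
    var = {c.name: c.S2 * c.nu / max(c.nu - 2.0, 1e-12)
           * cfg.init_var_scale for c in classes}
    for name in var:
        var[name] = max(var[name], 1e-12)
    eff = {c.name: np.zeros(c.X.shape[1]) for c in classes}
    incl = {c.name: np.zeros(c.X.shape[1], np.uint8) for c in classes}
    pi = {c.name: (cfg.pi_fixed if cfg.pi_fixed is not None else c.pi)
          for c in classes}
    has_dom = any(c.dominance_mean for c in classes)
    mu_d = (cfg.mu_d_fixed if cfg.mu_d_fixed is not None
            else (hp.eta if has_dom else 0.0))

    resid = (y - mu).astype(np.float32)

    sum_eff = {c.name: np.zeros(c.X.shape[1]) for c in classes}
    sum_incl = {c.name: np.zeros(c.X.shape[1]) for c in classes}
    sum_pi = {c.name: 0.0 for c in classes}
    sum_var = {c.name: 0.0 for c in classes}
    trace = {c.name: np.zeros(T) for c in classes}
    mu_d_trace = np.zeros(T) if has_dom else None
    sum_mu = 0.0
    sum_ve = 0.0

    for it in range(T):
        # overall mean (columns are centered, so mu is near-orthogonal)
        r_sum = float(resid.sum(dtype=np.float64))
        mu_new = rng.normal(mu + r_sum / n, np.sqrt(var_e / n))
        resid -= np.float32(mu_new - mu)
        mu = mu_new

        for c in classes:
            k = c.X.shape[1]
            pm = mu_d if c.dominance_mean else 0.0
            n_in = sweep_class(c.X, c.xtx, resid, eff[c.name], incl[c.name],
                               rng.random(k), rng.standard_normal(k),
                               pm, var[c.name], var_e, pi[c.name])
            trace[c.name][it] = n_in

            if c.dominance_mean and cfg.mu_d_fixed is None:
                k_eff = k if cfg.mu_d_sum_all else n_in
                denom = k_eff + cfg.phi
                mean_d = (eff[c.name].sum() + cfg.phi * hp.eta) / denom
                mu_d = rng.normal(mean_d, np.sqrt(var[c.name] / denom))

            if cfg.update_variances:
                pm = mu_d if c.dominance_mean else 0.0
                if c.dominance_mean and cfg.mu_d_sum_all:
                    ssq = float(np.sum((eff[c.name] - pm) ** 2))
                    df = k + c.nu
                else:
                    mask = incl[c.name].astype(bool)
                    ssq = float(np.sum((eff[c.name][mask] - pm) ** 2))
                    df = n_in + c.nu
                var[c.name] = max((ssq + c.nu * c.S2) / rng.chisquare(df),
                                  1e-14)

            if cfg.estimate_pi and cfg.pi_fixed is None:
                pi[c.name] = rng.beta(k - n_in + 1, n_in + 1)

        if cfg.update_variances:
            rss = float(resid @ resid)
            var_e = (rss + cfg.nu_e * hp.S2_e) \
                / rng.chisquare(cfg.nu_e + n)

        if cfg.refresh_every and (it + 1) % cfg.refresh_every == 0:
            # re-derive the residual in float64 to cancel drift
            r = y - mu
            for c in classes:
                r -= c.X.astype(np.float64) @ eff[c.name]
            resid = r.astype(np.float32)

        if it >= B:
            sum_mu += mu
            sum_ve += var_e
            if has_dom:
                mu_d_trace[it] = mu_d
            for c in classes:
                sum_eff[c.name] += eff[c.name]
                sum_incl[c.name] += incl[c.name]
                sum_pi[c.name] += pi[c.name]
                sum_var[c.name] += var[c.name]
        elif has_dom:
            mu_d_trace[it] = mu_d

        if cfg.log_every and (it + 1) % cfg.log_every == 0:
            logger.debug("%s chain iteration %d/%d", model_kind, it + 1, T)

    return ModelFit(
        model_kind=model_kind,
        effects={k2: v / n_post for k2, v in sum_eff.items()},
        inclusion={k2: v / n_post for k2, v in sum_incl.items()},
        pi={k2: v / n_post for k2, v in sum_pi.items()},
        nonzero_trace=trace,
        var_effect={k2: v / n_post for k2, v in sum_var.items()},
        mu=sum_mu / n_post,
        sigma_e2=sum_ve / n_post,
        mu_d=(float(mu_d_trace[B:].mean()) if has_dom else None),
        mu_d_trace=mu_d_trace,
        burn_in=B,
    )


def _make_rng(cfg: MCMCConfig, seed) -> np.random.Generator:
    if seed is None:
        seed = cfg.seed
    return seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)


def fit_additive(X: np.ndarray, y: np.ndarray, hp: Hyperparams,
                 cfg: MCMCConfig, seed=None) -> ModelFit:
    """BayesCpi on allele dosages X (codes 0/1/2)."""
    rng = _make_rng(cfg, seed)
    Xc, xtx, mx = _center(X)
    classes = [_EffectClass("alpha", Xc, xtx, hp.S2_alpha, cfg.nu_alpha,
                            cfg.pi0_alpha)]
    fit = _gibbs(y, classes, hp, cfg, rng, ADDITIVE)
    fit.col_means = {"alpha": mx}
    return fit


def fit_dominance(X: np.ndarray, W: np.ndarray, y: np.ndarray,
                  hp: Hyperparams, cfg: MCMCConfig, seed=None) -> ModelFit:
    """Joint additive + dominance fit; W is the heterozygosity indicator."""
    rng = _make_rng(cfg, seed)
    Xc, xtx, mx = _center(X)
    Wc, wtw, mw = _center(W)
    classes = [
        _EffectClass("a", Xc, xtx, hp.S2_a, cfg.nu_a, cfg.pi0_a),
        _EffectClass("d", Wc, wtw, hp.S2_d, cfg.nu_d, cfg.pi0_d,
                     dominance_mean=True),
    ]
    fit = _gibbs(y, classes, hp, cfg, rng, DOMINANCE)
    fit.col_means = {"a": mx, "d": mw}
    return fit


def fit_bsam(XA: np.ndarray, XB: np.ndarray, y: np.ndarray,
             hp: Hyperparams, cfg: MCMCConfig, seed=None) -> ModelFit:
    """Breed-specific allele model on 0/1 breed-of-origin dosages."""
    XA = np.asarray(XA)
    XB = np.asarray(XB)
    if XA.max(initial=0) > 1 or XB.max(initial=0) > 1:
        raise InvalidInputError(
            "BSAM needs phased 0/1 breed-of-origin allele dosages")
    rng = _make_rng(cfg, seed)
    Ac, atx, ma = _center(XA)
    Bc, btx, mb = _center(XB)
    classes = [
        _EffectClass("alpha_A", Ac, atx, hp.S2_alpha_A, cfg.nu_alpha,
                     cfg.pi0_alpha),
        _EffectClass("alpha_B", Bc, btx, hp.S2_alpha_B, cfg.nu_alpha,
                     cfg.pi0_alpha),
    ]
    fit = _gibbs(y, classes, hp, cfg, rng, BSAM)
    fit.col_means = {"alpha_A": ma, "alpha_B": mb}
    return fit
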