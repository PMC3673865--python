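"""Compiled inner loops: meiosis (recombination + mutation) and the Gibbs sweep.

Both kernels take all their randomness either from an explicit integer seed
(meiosis; numba keeps its own Mersenne-Twister state) or from pre-drawn
uniform/normal arrays (Gibbs sweep), so that every stochastic decision is
ultimately controlled by one numpy Generator on the Python side.
"""

import numpy as np
from numba import njit


@njit(cache=True)
def make_gametes(hap, parents, chrom_start, chrom_end, positions,
                 chrom_length, interference, mut_rate, seed):
    """Sample one gamete per entry of ``parents`` from diploid haplotypes.

    hap is (2*N, L) int8 with individual i on rows 2i, 2i+1. Crossover counts
    per chromosome follow Binomial(interference, L/interference) (a binomial
    map with interference); interference == 0 selects the Haldane limit
    (Poisson(L)). Mutation is a symmetric allele flip at rate ``mut_rate`` per
    allele copy per meiosis.
    """
    np.random.seed(seed)
    n_out = parents.shape[0]
    n_loci = hap.shape[1]
    n_chrom = chrom_start.shape[0]
    out = np.empty((n_out, n_loci), dtype=np.int8)
    for g in range(n_out):
        h0 = 2 * parents[g]
        for c in range(n_chrom):
            s = chrom_start[c]
            e = chrom_end[c]
            if interference > 0:
                k = np.random.binomial(interference,
                                       chrom_length / interference)
            else:
                k = np.random.poisson(chrom_length)
            strand = np.random.randint(0, 2)
            if k == 0:
                for j in range(s, e):
                    out[g, j] = hap[h0 + strand, j]
            else:
                xo = np.sort(np.random.uniform(0.0, chrom_length, k))
                xi = 0
                for j in range(s, e):
                    while xi < k and positions[j] > xo[xi]:
                        strand = 1 - strand
                        xi += 1
                    out[g, j] = hap[h0 + strand, j]
    if mut_rate > 0.0:
        n_mut = np.random.binomial(n_out * n_loci, mut_rate)
        for _ in range(n_mut):
            r = np.random.randint(0, n_out)
            j = np.random.randint(0, n_loci)
            out[r, j] = 1 - out[r, j]
    return out


@njit(cache=True, fastmath=True)
def sweep_class(X, xtx, resid, eff, incl, u, z,
                prior_mean, var_eff, var_e, pi_null):
    """One systematic-scan Gibbs sweep over the columns of one effect class.

    For each column j the inclusion indicator and the effect are sampled
    jointly: the indicator from its marginal (the effect integrated out of
    the likelihood), then the effect from its normal full conditional
    N(b_hat + lambda*prior_mean/C, var_e/C) with C = x'x + lambda and
    lambda = var_e/var_eff. The running residual vector is updated in place.
    Columns with zero variance (monomorphic after centering) are pinned to 0.

    X : (n, k) float32, Fortran order, column-centered.
    u, z : k pre-drawn Uniform(0,1) / N(0,1) variates.
    Returns the number of columns currently in the model.
    """
    n, k = X.shape
    lam = var_e / var_eff
    pm = prior_mean
    n_in = 0
    log_odds_prior = 0.0
    if 0.0 < pi_null < 1.0:
        log_odds_prior = np.log(1.0 - pi_null) - np.log(pi_null)
    for j in range(k):
        cj = xtx[j]
        ej = eff[j]
        if cj <= 1e-10:
            eff[j] = 0.0
            incl[j] = 0
            continue
        rhs = 0.0
        for i in range(n):
            rhs += X[i, j] * resid[i]
        rhs += ej * cj          # as if column j were removed from the model
        C = cj + lam
        m = (rhs + lam * pm) / C
        # log Bayes factor for inclusion, computed on the log scale
        logbf = (-0.5 * np.log(var_eff * C / var_e)
                 + (C * m * m - lam * pm * pm) / (2.0 * var_e))
        if pi_null <= 0.0:
            include = True
        elif pi_null >= 1.0:
            include = False
        else:
            t = log_odds_prior + logbf
            if t > 35.0:
                p1 = 1.0
            elif t < -35.0:
                p1 = 0.0
            else:
                p1 = 1.0 / (1.0 + np.exp(-t))
            include = u[j] < p1
        if include:
            b = m + z[j] * np.sqrt(var_e / C)
            incl[j] = 1
            n_in += 1
        else:
            b = 0.0
            incl[j] = 0
        eff[j] = b
        diff = ej - b
        if diff != 0.0:
            d32 = np.float32(diff)
            for i in range(n):
                resid[i] += X[i, j] * d32
    return n_in
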