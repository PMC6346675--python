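"""Numba Gibbs/Metropolis kernel for the admixture model.

The model is the structure-style correlated allele-frequency admixture model
with genotype uncertainty: each gene copy of individual i at locus l carries
a latent cluster z drawn from the individual's ancestry vector q_i, an allele
drawn from the cluster frequency p_{z,l}, and the read data enter through the
genotype-likelihood triple.  Cluster frequencies are tied to a shared
ancestral frequency pi_l through per-cluster drift F_k:

    p_{k,l} ~ Beta(pi_l (1-F_k)/F_k, (1-pi_l)(1-F_k)/F_k)

Updates: latent genotypes and gene-copy ancestries by direct sampling from
their discrete conditionals, q rows from a Dirichlet conditional, and p
entries from a conjugate beta.  The hyperparameters pi and F are updated by
random-walk Metropolis against the *collapsed* model in which p is
integrated out analytically (a beta-binomial marginal of the current
cluster allele counts).  This partially collapsed scheme is exact and,
unlike density evaluation at the sampled p, is bounded: the Balding–Nichols
beta density diverges at the frequency boundaries when (1-F)/F pseudo-counts
drop below one, and a naive Metropolis step on pi/F can ratchet F upward by
chasing those spikes at near-fixed loci.  The deviance is -2 times the log
of the genotype-likelihood-weighted mixture probability, recorded at every
retained (post-burn-in, thinned) step.
"""

import math

import numpy as np
from numba import njit

_P_EPS = 1e-9
_PI_LO, _PI_HI = 1e-3, 1.0 - 1e-3
_F_LO, _F_HI = 1e-3, 0.999


@njit(cache=True)
def _lbeta(a, b):
    return math.lgamma(a) + math.lgamma(b) - math.lgamma(a + b)


@njit(cache=True)
def _bb_logmarg(c1, c0, pi_l, scale):
    """Log beta-binomial marginal of cluster allele counts at one locus,
    with the cluster frequency integrated out under its Balding–Nichols
    prior (combinatorial factor dropped — constant in pi and F)."""
    a = pi_l * scale
    b = (1.0 - pi_l) * scale
    return _lbeta(a + c1, b + c0) - _lbeta(a, b)


@njit(cache=True, fastmath=True)
def run_gibbs(gl, q0, p0, pi0, F0, alpha, n_iter, burn, thin, seed,
              pi_step, f_step, f_prior_shape, f_prior_rate, hyper_every,
              pi_prior_a, pi_prior_b):
    """Run one MCMC chain.

    Parameters
    ----------
    gl : (N, L, 3) normalized genotype-likelihood triples
    q0 : (N, K) starting ancestry coefficients (simplex rows)
    p0 : (K, L) starting cluster allele frequencies
    pi0 : (L,) starting ancestral frequencies
    F0 : (K,) starting drift parameters
    alpha : Dirichlet concentration for q
    pi_step, f_step : random-walk half-widths for the Metropolis updates
    f_prior_shape, f_prior_rate : gamma prior on each F_k (shape/rate);
        a rate of 0 selects the flat prior on (0, 1)
    hyper_every : update pi and F on every hyper_every-th sweep (a fixed
        cycling schedule; their conditionals are tight, and the collapsed
        Metropolis evaluations dominate the sweep cost)
    pi_prior_a, pi_prior_b : beta prior on each ancestral frequency pi_l
        (1, 1 is the uniform prior)

    Returns
    -------
    q_mean, p_mean, pi_mean, F_mean, dosage_mean, dev_trace
    """
    np.random.seed(seed)
    N, L, _ = gl.shape
    K = q0.shape[1]

    q = q0.copy()
    p = p0.copy()
    pi = pi0.copy()
    F = F0.copy()

    n_keep = (n_iter - burn + thin - 1) // thin
    dev_trace = np.empty(n_keep)
    q_mean = np.zeros((N, K))
    p_mean = np.zeros((K, L))
    pi_mean = np.zeros(L)
    F_mean = np.zeros(K)
    dosage_mean = np.zeros((N, L))

    nz = np.zeros((N, K))
    c1 = np.zeros((K, L))
    c0 = np.zeros((K, L))
    w = np.zeros(K)

    kept = 0
    for it in range(n_iter):
        keep = it >= burn and (it - burn) % thin == 0
        nz[:, :] = 0.0
        c1[:, :] = 0.0
        c0[:, :] = 0.0
        dev = 0.0

        for i in range(N):
            for l in range(L):
                theta = 0.0
                for k in range(K):
                    theta += q[i, k] * p[k, l]
                om = 1.0 - theta
                pg0 = om * om * gl[i, l, 0]
                pg1 = 2.0 * theta * om * gl[i, l, 1]
                pg2 = theta * theta * gl[i, l, 2]
                s = pg0 + pg1 + pg2
                if keep:
                    dev += math.log(s)
                    dosage_mean[i, l] += (pg1 + 2.0 * pg2) / s

                u = np.random.random() * s
                if u < pg0:
                    g = 0
                elif u < pg0 + pg1:
                    g = 1
                else:
                    g = 2

                # gene-copy ancestries given the alleles implied by g
                for copy in range(2):
                    a = 0
                    if g == 2 or (g == 1 and copy == 0):
                        a = 1
                    tot = 0.0
                    for k in range(K):
                        wk = q[i, k] * (p[k, l] if a == 1 else 1.0 - p[k, l])
                        w[k] = wk
                        tot += wk
                    u2 = np.random.random() * tot
                    acc = 0.0
                    kz = K - 1
                    for k in range(K):
                        acc += w[k]
                        if u2 < acc:
                            kz = k
                            break
                    nz[i, kz] += 1.0
                    if a == 1:
                        c1[kz, l] += 1.0
                    else:
                        c0[kz, l] += 1.0

        # q | z  ~ Dirichlet(alpha + counts), via normalized gammas
        for i in range(N):
            tot = 0.0
            for k in range(K):
                g_ = np.random.gamma(alpha + nz[i, k], 1.0)
                q[i, k] = g_
                tot += g_
            for k in range(K):
                q[i, k] /= tot

        # pi | z-alleles, F (p marginalized) — random-walk Metropolis.
        # Updating against the collapsed beta-binomial marginal and then
        # redrawing p keeps the chain exact (partially collapsed Gibbs).
        update_hypers = it % hyper_every == 0
        if update_hypers:
            for l in range(L):
                prop = pi[l] + (np.random.random() * 2.0 - 1.0) * pi_step
                if _PI_LO < prop < _PI_HI:
                    logr = ((pi_prior_a - 1.0) * (math.log(prop) - math.log(pi[l]))
                            + (pi_prior_b - 1.0) * (math.log(1.0 - prop) - math.log(1.0 - pi[l])))
                    for k in range(K):
                        scale = (1.0 - F[k]) / F[k]
                        logr += _bb_logmarg(c1[k, l], c0[k, l], prop, scale)
                        logr -= _bb_logmarg(c1[k, l], c0[k, l], pi[l], scale)
                    if logr >= 0.0 or np.random.random() < math.exp(logr):
                        pi[l] = prop

            # F | z-alleles, pi (p marginalized) — random-walk Metropolis
            # with a gamma (or flat) prior on (0, 1)
            for k in range(K):
                prop = F[k] + (np.random.random() * 2.0 - 1.0) * f_step
                if _F_LO < prop < _F_HI:
                    scale_new = (1.0 - prop) / prop
                    scale_old = (1.0 - F[k]) / F[k]
                    logr = 0.0
                    if f_prior_rate > 0.0:
                        logr += (f_prior_shape - 1.0) * (math.log(prop) - math.log(F[k]))
                        logr -= f_prior_rate * (prop - F[k])
                    for l in range(L):
                        logr += _bb_logmarg(c1[k, l], c0[k, l], pi[l], scale_new)
                        logr -= _bb_logmarg(c1[k, l], c0[k, l], pi[l], scale_old)
                    if logr >= 0.0 or np.random.random() < math.exp(logr):
                        F[k] = prop

        # p | alleles, pi, F — conjugate beta under the Balding–Nichols
        # prior (redrawn after the collapsed pi/F moves)
        for k in range(K):
            scale = (1.0 - F[k]) / F[k]
            for l in range(L):
                a_ = pi[l] * scale + c1[k, l]
                b_ = (1.0 - pi[l]) * scale + c0[k, l]
                x = np.random.beta(a_, b_)
                if x < _P_EPS:
                    x = _P_EPS
                elif x > 1.0 - _P_EPS:
                    x = 1.0 - _P_EPS
                p[k, l] = x

        if keep:
            dev_trace[kept] = -2.0 * dev
            q_mean += q
            p_mean += p
            pi_mean += pi
            F_mean += F
            kept += 1

    q_mean /= kept
    p_mean /= kept
    pi_mean /= kept
    F_mean /= kept
    dosage_mean /= kept
    return q_mean, p_mean, pi_mean, F_mean, dosage_mean, dev_trace
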