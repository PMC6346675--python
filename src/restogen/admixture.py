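"""Hierarchical Bayesian admixture inference from genotype likelihoods.

Implements the structure-style correlated allele-frequency admixture model
with genotype uncertainty: individuals carry simplex ancestry vectors q over
k clusters, cluster allele frequencies p are tied to shared ancestral
frequencies pi through per-cluster drift parameters F, and low-coverage read
data enter through genotype-likelihood triples rather than called genotypes.
Posterior mean genotypes ("genotype probabilities" on the 0–2 dosage scale)
fall out of the same sampler.

Chains are initialized from PCA of the genotype-likelihood point summaries,
k-means on the principal components, and a linear discriminant fit giving
starting membership probabilities.  Model choice across k uses the deviance
information criterion (DIC), with the effective-parameter penalty taken as
half the variance of the deviance trace.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
from scipy.optimize import linear_sum_assignment
from sklearn.base import BaseEstimator
from sklearn.cluster import KMeans
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

from . import _mcmc
from .formats import CohortGL, DosageMatrix

__all__ = [
    "AdmixtureModel",
    "AdmixtureFit",
    "MCMC_PRESETS",
    "init_chains",
    "run_mcmc",
    "dic",
    "fit_admixture",
    "align_columns",
]

#: MCMC schedules.  ``production`` is the full-scale schedule used for real
#: cohorts; ``desk`` is the reduced schedule for tests and demonstrations.
MCMC_PRESETS = {
    "production": {"n_iter": 100_000, "burn_in": 30_000, "thin": 10},
    "desk": {"n_iter": 20_000, "burn_in": 5_000, "thin": 10},
}


@dataclasses.dataclass
class AdmixtureFit:
    """Posterior summaries of one admixture fit (chains combined)."""

    k: int
    q: np.ndarray              # (N, k) posterior mean ancestry coefficients
    p: np.ndarray              # (k, L) posterior mean cluster allele freqs
    pi: np.ndarray             # (L,) posterior mean ancestral freqs
    F: np.ndarray              # (k,) posterior mean drift parameters
    deviance_trace: np.ndarray # concatenated retained deviances, all chains
    dic: float
    dosage: DosageMatrix | None = None
    dosage_array: np.ndarray | None = None
    chain_dics: list = dataclasses.field(default_factory=list)
    rhat_deviance: float = float("nan")


def _as_cohort_arrays(X):
    """Accept a CohortGL or a raw (N, L, 3) likelihood array."""
    if isinstance(X, CohortGL):
        return X.normalized_gl(), X
    arr = np.asarray(X, dtype=float)
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise ValueError("expected a CohortGL or an (N, L, 3) likelihood array")
    tot = arr.sum(axis=2, keepdims=True)
    return np.where(tot > 0, arr / np.where(tot > 0, tot, 1.0), 1.0 / 3.0), None


def _pc_scores(gl_norm: np.ndarray) -> np.ndarray:
    """PC scores of individuals from the centered point-dosage covariance."""
    dos = gl_norm[:, :, 1] + 2.0 * gl_norm[:, :, 2]
    x = dos - dos.mean(axis=0, keepdims=True)
    cov = x @ x.T / max(x.shape[1] - 1, 1)
    vals, vecs = np.linalg.eigh(cov)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    pos = vals > max(vals.max(), 0) * 1e-10
    return vecs[:, pos] * np.sqrt(np.clip(vals[pos], 0, None))


def init_chains(X, k: int, n_chains: int = 1, seed: int = 0) -> list:
    """Starting membership probabilities for each chain.

    PCA is run on the covariance of likelihood-weighted mean genotypes,
    k-means clusters individuals on the PCs (a distinct seed per chain), and
    a linear discriminant fit on all PCs converts the hard clustering into
    membership probabilities.  Degenerate discriminant fits fall back to
    softened k-means labels.
    """
    gl_norm, _ = _as_cohort_arrays(X)
    n = gl_norm.shape[0]
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > n:
        raise ValueError(f"k={k} exceeds the number of individuals ({n})")
    if k == 1:
        return [np.ones((n, 1)) for _ in range(n_chains)]

    scores = _pc_scores(gl_norm)
    inits = []
    for c in range(n_chains):
        km = KMeans(n_clusters=k, random_state=seed + c, n_init=10)
        labels = km.fit_predict(scores)
        # re-seed degenerate clusterings (fewer than k distinct labels)
        tries = 0
        while len(np.unique(labels)) < k and tries < 10:
            tries += 1
            km = KMeans(n_clusters=k, random_state=seed + c + 1000 * tries, n_init=10)
            labels = km.fit_predict(scores)
        try:
            lda = LinearDiscriminantAnalysis(solver="lsqr", shrinkage="auto")
            proba = lda.fit(scores, labels).predict_proba(scores)
        except Exception:
            proba = np.full((n, k), 0.0)
            proba[np.arange(n), labels] = 1.0
        # keep memberships strictly inside the simplex
        proba = 0.95 * proba + 0.05 / k
        inits.append(proba / proba.sum(axis=1, keepdims=True))
    return inits


def _resolve_pi_prior(pi_prior, pi0: np.ndarray):
    """Beta prior shapes for the ancestral frequencies.

    "empirical" matches beta moments to the pooled point-dosage frequency
    spectrum (shapes capped at 1 so the prior never overrides the boundary
    behaviour of genuinely rare alleles, and floored away from 0).
    """
    if pi_prior is None or pi_prior == "uniform":
        return 1.0, 1.0
    if pi_prior == "empirical":
        mean = float(np.mean(pi0))
        var = float(np.var(pi0))
        var = min(max(var, 1e-4), mean * (1.0 - mean) * 0.999)
        nu = mean * (1.0 - mean) / var - 1.0
        a = np.clip(mean * nu, 0.05, 1.0)
        b = np.clip((1.0 - mean) * nu, 0.05, 1.0)
        return float(a), float(b)
    a, b = pi_prior
    if a <= 0 or b <= 0:
        raise ValueError("pi_prior shapes must be positive")
    return float(a), float(b)


def dic(deviance_trace: np.ndarray) -> float:
    """DIC = mean deviance + effective parameters (= half its variance)."""
    d = np.asarray(deviance_trace, dtype=float)
    if d.size < 10:
        raise ValueError("need at least 10 retained samples to compute DIC")
    return float(d.mean() + 0.5 * d.var(ddof=1))


def _split_rhat(trace: np.ndarray) -> float:
    """Split-chain potential scale reduction factor of a scalar trace."""
    n = trace.size // 2
    if n < 2:
        return float("nan")
    halves = np.stack([trace[:n], trace[trace.size - n:]])
    w = halves.var(axis=1, ddof=1).mean()
    b = n * halves.mean(axis=1).var(ddof=1)
    if w <= 0:
        return 1.0
    return float(np.sqrt((n - 1) / n + b / (w * n)))


def run_mcmc(X, spec: "AdmixtureModel", init: np.ndarray, seed: int | None = None) -> AdmixtureFit:
    """Run a single chain from one initialization and summarize it."""
    gl_norm, cohort = _as_cohort_arrays(X)
    n, L = gl_norm.shape[:2]
    k = init.shape[1]
    dos = gl_norm[:, :, 1] + 2.0 * gl_norm[:, :, 2]
    # moment-based starting values for p, pi, F
    wsum = init.sum(axis=0)
    p0 = np.clip((init.T @ dos) / (2.0 * wsum[:, None]), 0.02, 0.98)
    pi0 = np.clip(dos.mean(axis=0) / 2.0, 0.02, 0.98)
    F0 = np.full(k, 0.1)
    pi_a, pi_b = _resolve_pi_prior(spec.pi_prior, pi0)
    if seed is None:
        seed = spec.seed if spec.seed is not None else 0
    q_m, p_m, pi_m, F_m, dos_m, dev = _mcmc.run_gibbs(
        np.ascontiguousarray(gl_norm),
        np.ascontiguousarray(init, dtype=float),
        np.ascontiguousarray(p0),
        np.ascontiguousarray(pi0),
        F0,
        float(spec.alpha),
        int(spec.n_iter),
        int(spec.burn_in),
        int(spec.thin),
        int(seed) % (2**31 - 1),
        float(spec.pi_step),
        float(spec.f_step),
        float(spec.f_prior[0]) if spec.f_prior else 0.0,
        float(spec.f_prior[1]) if spec.f_prior else 0.0,
        int(spec.hyper_every),
        pi_a,
        pi_b,
    )
    if not np.all(np.isfinite(dev)):
        raise RuntimeError(
            f"non-finite deviance in chain (k={k}, seed={seed}); "
            f"first bad index {int(np.flatnonzero(~np.isfinite(dev))[0])}"
        )
    dosage = None
    if cohort is not None:
        dosage = DosageMatrix(cohort.individual_ids, cohort.locus_ids,
                              cohort.unit_of, dos_m)
    fit = AdmixtureFit(k=k, q=q_m, p=p_m, pi=pi_m, F=F_m,
                       deviance_trace=dev, dic=dic(dev), dosage=dosage,
                       dosage_array=dos_m)
    fit.rhat_deviance = _split_rhat(dev)
    if fit.rhat_deviance > 1.1:
        warnings.warn(
            f"deviance split-Rhat {fit.rhat_deviance:.3f} > 1.1 for k={k}; "
            "chain may not have converged", RuntimeWarning,
        )
    return fit


def align_columns(q_ref: np.ndarray, q: np.ndarray) -> np.ndarray:
    """Permutation of q's columns best matching q_ref (min L1 distance)."""
    k = q_ref.shape[1]
    cost = np.empty((k, k))
    for a in range(k):
        for b in range(k):
            cost[a, b] = np.abs(q_ref[:, a] - q[:, b]).sum()
    _, perm = linear_sum_assignment(cost)
    return perm


class AdmixtureModel(BaseEstimator):
    """Genotype-likelihood admixture estimator (scikit-learn style).

    Parameters
    ----------
    k : int
        Number of ancestral clusters.
    n_iter, burn_in, thin : int
        MCMC schedule.  Defaults follow the production preset
        (100,000 / 30,000 / 10); tests use ``MCMC_PRESETS['desk']``.
    alpha : float
        Dirichlet concentration of the ancestry prior (default 1, uniform
        on the simplex).
    n_chains : int
        Replicate chains; posterior summaries are combined after cluster
        labels are aligned across chains.
    seed : int or None
        Governs initialization and all chains.
    pi_step, f_step : float
        Random-walk half-widths of the Metropolis updates for the ancestral
        frequencies and the drift parameters.
    f_prior : (shape, rate) or None
        Gamma prior on each drift parameter F_k, truncated to (0, 1).  The
        default (0.04, 4.0) has mean 0.01 and sd 0.05 — the weakly
        informative small-drift prior conventional for the correlated
        allele-frequency model, which anchors the scale of cluster
        divergence and keeps ancestry coefficients identifiable when
        differentiation is weak.  ``None`` selects a flat prior on (0, 1).
    hyper_every : int
        The ancestral frequencies and drift parameters are refreshed on
        every ``hyper_every``-th sweep (their collapsed Metropolis
        evaluations dominate sweep cost; the conditionals are tight).
    pi_prior : "empirical", "uniform", or (a, b)
        Beta prior on the ancestral frequencies pi_l.  "empirical" fits the
        beta by moments to the cohort's point-dosage frequency spectrum, an
        empirical-Bayes shrinkage that stabilizes the per-locus pi estimates
        (a uniform prior systematically pulls near-fixed loci inward, and
        the unabsorbed dispersion inflates the drift estimates).

    Attributes
    ----------
    q_ : ndarray (N, k)
        Posterior mean ancestry coefficients (rows on the simplex).
    p_ : ndarray (k, L)
        Posterior mean cluster allele frequencies.
    pi_ : ndarray (L,)
        Posterior mean ancestral allele frequencies.
    F_ : ndarray (k,)
        Posterior mean drift parameters.
    dic_ : float
        Deviance information criterion (chains averaged).
    dosage_ : ndarray (N, L)
        Posterior mean genotypes on the 0–2 scale.
    """

    def __init__(self, k=2, n_iter=100_000, burn_in=30_000, thin=10,
                 alpha=1.0, n_chains=1, seed=None, pi_step=0.1, f_step=0.05,
                 f_prior=(0.04, 4.0), hyper_every=5, pi_prior="empirical"):
        self.k = k
        self.n_iter = n_iter
        self.burn_in = burn_in
        self.thin = thin
        self.alpha = alpha
        self.n_chains = n_chains
        self.seed = seed
        self.pi_step = pi_step
        self.f_step = f_step
        self.f_prior = f_prior
        self.hyper_every = hyper_every
        self.pi_prior = pi_prior

    def fit(self, X, y=None):
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if self.burn_in >= self.n_iter:
            raise ValueError("burn_in must be smaller than n_iter")
        seed = 0 if self.seed is None else int(self.seed)
        inits = init_chains(X, self.k, self.n_chains, seed)
        fits = [
            run_mcmc(X, self, init, seed=seed + 7919 * (c + 1))
            for c, init in enumerate(inits)
        ]
        ref = fits[0]
        q_all, p_all, F_all = [ref.q], [ref.p], [ref.F]
        for f in fits[1:]:
            perm = align_columns(ref.q, f.q)
            q_all.append(f.q[:, perm])
            p_all.append(f.p[perm])
            F_all.append(f.F[perm])
        self.q_ = np.mean(q_all, axis=0)
        self.p_ = np.mean(p_all, axis=0)
        self.F_ = np.mean(F_all, axis=0)
        self.pi_ = np.mean([f.pi for f in fits], axis=0)
        self.dosage_ = np.mean([f.dosage_array for f in fits], axis=0)
        self.chain_dics_ = [f.dic for f in fits]
        self.dic_ = float(np.mean(self.chain_dics_))
        self.deviance_trace_ = np.concatenate([f.deviance_trace for f in fits])
        self.rhat_deviance_ = max(f.rhat_deviance for f in fits)
        self.fits_ = fits
        return self

    def fit_dosage(self, X) -> DosageMatrix:
        """Fit and return the posterior dosage matrix (requires a CohortGL)."""
        self.fit(X)
        if not isinstance(X, CohortGL):
            raise ValueError("fit_dosage requires a CohortGL input")
        return DosageMatrix(X.individual_ids, X.locus_ids, X.unit_of, self.dosage_)


def fit_admixture(X, k_range, spec: AdmixtureModel | None = None):
    """Fit the admixture model over a range of k and select by DIC.

    Returns
    -------
    table : list of dict
        Per-k rows with the fitted model and its DIC.
    selected : AdmixtureModel
        The fitted model with the smallest mean DIC.
    """
    k_range = list(k_range)
    if not k_range:
        raise ValueError("k_range must be non-empty")
    base = spec if spec is not None else AdmixtureModel()
    rows = []
    for k in k_range:
        model = AdmixtureModel(**{**base.get_params(), "k": k})
        model.fit(X)
        rows.append({"k": k, "dic": model.dic_, "model": model})
    best = min(rows, key=lambda r: r["dic"])
    return rows, best["model"]
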