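"""Region-wise Bayesian whole-genome regression Gibbs sampler (BayesN0).

The model for genotyped, phenotyped animals is

    y_t = 1 mu_t + M alpha_t + e_t,   t = L, H

with e ~ N(0, R_0 (x) I) across traits and alpha_sj | B_s ~ N(0, B_s):
all SNPs j inside genome region s share the (co)variance B_s. Conjugate
priors B_s ~ IW(v_B, V_B) and R_0 ~ IW(v_R, V_R) give closed-form full
conditionals, sampled by a systematic Gibbs scan:

    mu -> alpha (SNP order) -> B_s -> R_0

per cycle, with the residual vector updated incrementally. Region size
one SNP recovers BayesA behavior; a single whole-genome region is the
SNPBLUP/GBLUP-equivalent special case. With ``fixed_variances`` the
(co)variance updates are skipped (plug-in mode) and the posterior mean of
(mu, alpha) solves the corresponding ridge mixed-model equations.

The same scan, extended with imputation residuals, powers the single-step
sampler in :mod:`ssbayesn.singlestep`; the shared engine lives in
``_gibbs_engine``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from ._kernels import alpha_scan, eps_scan
from ._linalg import inv_small, sample_invwishart, sample_invwishart_batch
from .regions import PriorSpec, RegionMap

__all__ = [
    "GenomicModelData",
    "ChainOptions",
    "PosteriorChain",
    "FixedVariances",
    "gibbs_bayesn0",
    "predict_gebv_direct",
    "genetic_cov_from_chain",
    "fullcond_mu",
    "fullcond_alpha",
    "fullcond_Bs",
    "fullcond_R0",
]


@dataclass
class GenomicModelData:
    """Inputs for a genotyped-only analysis.

    ``y`` is (n, T) with both traits observed for every record; ``M`` is
    the centered marker matrix aligned with ``y`` rows.
    """

    y: np.ndarray
    M: np.ndarray
    regions: RegionMap
    priors: PriorSpec

    def __post_init__(self):
        self.y = np.asarray(self.y, dtype=float)
        if self.y.ndim == 1:
            self.y = self.y[:, None]
        self.M = np.ascontiguousarray(self.M, dtype=float)
        if self.y.shape[0] != self.M.shape[0]:
            raise ValueError("y and M row counts differ")
        if self.M.shape[1] != self.regions.n_snp:
            raise ValueError("region map does not cover the marker matrix")
        if self.y.shape[1] != self.priors.n_traits:
            raise ValueError("prior trait dimension does not match y")


@dataclass
class ChainOptions:
    """MCMC chain settings.

    Defaults are desk-scale (5,000 cycles, 2,000 burn-in, thin 10); the
    full-scale settings used for serious analyses (50,000 / 30,000 / 10)
    are reached through configuration.
    """

    n_iter: int = 5000
    burn_in: int = 2000
    thin: int = 10
    seed: int = 0

    def __post_init__(self):
        if not (0 <= self.burn_in < self.n_iter):
            raise ValueError("burn_in must be in [0, n_iter)")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")

    @property
    def n_stored(self) -> int:
        return (self.n_iter - self.burn_in) // self.thin


@dataclass
class FixedVariances:
    """Plug-in (co)variances: when supplied, the sampler keeps them fixed."""

    B: np.ndarray  # (S, T, T) per-region SNP covariance
    R0: np.ndarray  # (T, T)
    G0: Optional[np.ndarray] = None  # (T, T), single-step only


@dataclass
class PosteriorChain:
    """Thinned post-burn-in samples.

    Arrays are indexed by stored sample first: ``mu`` (m, n_fixed, T),
    ``alpha`` (m, k, T), ``B`` (m, S, T, T), ``R0`` (m, T, T); single-step
    chains additionally carry ``eps`` (m, N_n, T) and ``G0`` (m, T, T).
    Point estimates are posterior means.
    """

    mu: np.ndarray
    alpha: np.ndarray
    B: np.ndarray
    R0: np.ndarray
    eps: Optional[np.ndarray] = None
    G0: Optional[np.ndarray] = None
    options: Optional[ChainOptions] = None
    region_sizes: Optional[np.ndarray] = None

    @property
    def n_samples(self) -> int:
        return self.mu.shape[0]

    def mean_alpha(self) -> np.ndarray:
        return self.alpha.mean(axis=0)

    def mean_B(self) -> np.ndarray:
        return self.B.mean(axis=0)

    def mean_R0(self) -> np.ndarray:
        return self.R0.mean(axis=0)

    def mean_G0(self) -> np.ndarray:
        if self.G0 is None:
            raise ValueError("chain has no sampled G0 component")
        return self.G0.mean(axis=0)


# ---------------------------------------------------------------------------
# full conditionals (closed forms, used by tests and by the engine)

def fullcond_mu(y_star: np.ndarray, R0: np.ndarray):
    """Full conditional of the general means given residual-corrected
    phenotypes: N[(X'R^-1 X)^-1 X'R^-1 y*, (X'R^-1 X)^-1]. With one
    intercept per trait and all traits recorded on every animal this is the
    per-trait mean with covariance R_0 / n."""
    y_star = np.atleast_2d(np.asarray(y_star, dtype=float))
    n = y_star.shape[0]
    if n == 0:
        raise ValueError("no records")
    R0 = np.atleast_2d(R0)
    if np.linalg.det(R0) <= 0:
        raise ValueError("singular residual covariance")
    return y_star.mean(axis=0), R0 / n


def fullcond_alpha(m_j: np.ndarray, y_star: np.ndarray, B_s: np.ndarray,
                   R0: np.ndarray, mjmj: Optional[float] = None):
    """Full conditional N[(M*'R^-1 M* + B_s^-1)^-1 M*'R^-1 y*, (.)^-1] of
    one SNP's bivariate effect, reduced to a T x T system."""
    m_j = np.asarray(m_j, dtype=float)
    y_star = np.atleast_2d(np.asarray(y_star, dtype=float))
    B_s = np.atleast_2d(B_s)
    R0 = np.atleast_2d(R0)
    if np.linalg.eigvalsh(B_s).min() <= 0:
        raise ValueError("B_s must be positive definite")
    if mjmj is None:
        mjmj = float(m_j @ m_j)
    R0inv = inv_small(R0)
    P = mjmj * R0inv + inv_small(B_s)
    C = inv_small(P)
    mean = C @ (R0inv @ (y_star.T @ m_j))
    return mean, C


def fullcond_Bs(alphas: np.ndarray, priors: PriorSpec):
    """IW[v_B + k_s, S_Bs + V_B] with S_Bs the sum of outer products of
    the region's sampled SNP effects."""
    alphas = np.atleast_2d(np.asarray(alphas, dtype=float))
    if alphas.shape[0] == 0:
        raise ValueError("empty region")
    S_B = alphas.T @ alphas
    return priors.nu_B + alphas.shape[0], S_B + priors.V_B


def fullcond_R0(residuals: np.ndarray, priors: PriorSpec):
    """IW[v_R + n, S_R + V_R] with S_R the residual outer-product sum."""
    residuals = np.atleast_2d(np.asarray(residuals, dtype=float))
    S_R = residuals.T @ residuals
    return priors.nu_R + residuals.shape[0], S_R + priors.V_R


# ---------------------------------------------------------------------------
# the Gibbs engine (shared by BayesN0 and ssBayesN0)

_REFRESH_EVERY = 200  # recompute residuals exactly to cap float drift

# joint epsilon draws use a dense Cholesky up to this many non-genotyped
# animals; beyond it a single-site scan (same stationary distribution)
_EPS_DENSE_MAX = 150


class _EpsBlock:
    """Imputation-residual block of the single-step sampler."""

    def __init__(self, Ainv_nn, phen_row: np.ndarray):
        self.Ainn = Ainv_nn.tocsr()
        self.phen_row = np.asarray(phen_row, dtype=np.int64)
        self.N_n = self.phen_row.size
        self.diag = self.Ainn.diagonal()
        self.dense = self.N_n <= _EPS_DENSE_MAX
        if self.dense:
            self._Ainn_d = self.Ainn.toarray()

    def joint_draw(self, e, eps, R0inv, G0inv, rng):
        """Exact multivariate draw via dense Cholesky of the precision."""
        Nn, T = eps.shape
        D = np.zeros(Nn)
        D[self.phen_row >= 0] = 1.0
        P = np.kron(G0inv, self._Ainn_d) + np.kron(R0inv, np.diag(D))
        b = np.zeros(T * Nn)
        rows = self.phen_row
        obs = rows >= 0
        ytilde = np.zeros((Nn, T))
        ytilde[obs] = e[rows[obs]] + eps[obs]
        for t in range(T):
            b[t * Nn:(t + 1) * Nn] = (R0inv[t] @ ytilde.T) * obs
        L = np.linalg.cholesky(P)
        mean = np.linalg.solve(L.T, np.linalg.solve(L, b))
        z = rng.standard_normal(T * Nn)
        draw = mean + np.linalg.solve(L.T, z)
        new = draw.reshape(T, Nn).T
        e[rows[obs]] -= new[obs] - eps[obs]
        eps[:] = new


def _sample_mu(XtX, X, e, mu, R0inv, rng):
    """Joint draw of all fixed effects; updates residuals in place.

    Handles a rank-deficient fixed-effect design (e.g. an unidentified
    genotyped-mean contrast) by sampling in the row space only.
    """
    n_fixed, T = mu.shape
    ystar_tX = X.T @ e + XtX @ mu  # (n_fixed, T) = X'y* per trait
    P = np.kron(R0inv, XtX)
    b = (R0inv @ ystar_tX.T).reshape(-1)  # trait-major
    try:
        L = np.linalg.cholesky(P)
        mean = np.linalg.solve(L.T, np.linalg.solve(L, b))
        draw = mean + np.linalg.solve(L.T, rng.standard_normal(b.size))
    except np.linalg.LinAlgError:
        # pinv mean; sample only along directions with information
        w, V = np.linalg.eigh(P)
        keep = w > w.max() * 1e-10
        mean = V[:, keep] @ ((V[:, keep].T @ b) / w[keep])
        draw = mean + V[:, keep] @ (rng.standard_normal(keep.sum()) / np.sqrt(w[keep]))
    new = draw.reshape(T, n_fixed).T
    e -= X @ (new - mu)
    mu[:] = new


def _gibbs_engine(
    y: np.ndarray,
    X: np.ndarray,
    W: np.ndarray,
    regions: RegionMap,
    priors: PriorSpec,
    opts: ChainOptions,
    eps_block: Optional[_EpsBlock] = None,
    fixed: Optional[FixedVariances] = None,
) -> PosteriorChain:
    """Systematic-scan Gibbs sampler shared by BayesN0 and ssBayesN0."""
    n, T = y.shape
    k = W.shape[1]
    S = regions.n_regions
    rng = np.random.default_rng(opts.seed)

    region_of = regions.region_of_snp
    starts = regions.starts
    sizes = regions.sizes.astype(float)

    mu = np.zeros((X.shape[1], T))
    alpha = np.zeros((k, T))
    if fixed is not None:
        B = np.array(fixed.B, dtype=float).reshape(S, T, T)
        R0 = np.array(fixed.R0, dtype=float).reshape(T, T)
    else:
        B = np.broadcast_to(priors.V_B / (priors.nu_B - T - 1), (S, T, T)).copy()
        R0 = priors.V_R / (priors.nu_R - T - 1)
    R0inv = inv_small(R0)
    Binv = inv_small(B)

    eps = None
    G0 = G0inv = None
    if eps_block is not None:
        eps = np.zeros((eps_block.N_n, T))
        if fixed is not None:
            if fixed.G0 is None:
                raise ValueError("fixed variances for a single-step chain "
                                 "require G0")
            G0 = np.array(fixed.G0, dtype=float).reshape(T, T)
        else:
            G0 = priors.V_G / (priors.nu_G - T - 1)
        G0inv = inv_small(G0)

    XtX = X.T @ X
    wjwj = np.einsum("ij,ij->j", W, W)
    e = y - X @ mu - W @ alpha

    n_stored = opts.n_stored
    out_mu = np.empty((n_stored, X.shape[1], T))
    out_alpha = np.empty((n_stored, k, T))
    out_B = np.empty((n_stored, S, T, T))
    out_R0 = np.empty((n_stored, T, T))
    out_eps = np.empty((n_stored, eps_block.N_n, T)) if eps_block is not None else None
    out_G0 = np.empty((n_stored, T, T)) if eps_block is not None else None

    stored = 0
    for cycle in range(1, opts.n_iter + 1):
        _sample_mu(XtX, X, e, mu, R0inv, rng)

        z = rng.standard_normal((k, T))
        alpha_scan(W, e, alpha, wjwj, R0inv, Binv[region_of], z)

        if eps_block is not None:
            if eps_block.dense:
                eps_block.joint_draw(e, eps, R0inv, G0inv, rng)
            else:
                z_eps = rng.standard_normal((eps_block.N_n, T))
                eps_scan(eps_block.Ainn.indptr, eps_block.Ainn.indices,
                         eps_block.Ainn.data, eps_block.diag,
                         eps_block.phen_row, e, eps, R0inv, G0inv, z_eps)

        if fixed is None:
            # B_s | . ~ IW(v_B + k_s, S_Bs + V_B), all regions at once
            outer = alpha[:, :, None] * alpha[:, None, :]
            S_B = np.add.reduceat(outer, starts, axis=0)
            B = sample_invwishart_batch(rng, priors.nu_B + sizes, S_B + priors.V_B)
            Binv = inv_small(B)
            if eps_block is not None:
                S_G = np.asarray(eps.T @ (eps_block.Ainn @ eps))
                G0 = sample_invwishart(rng, priors.nu_G + eps_block.N_n,
                                       S_G + priors.V_G)
                G0inv = inv_small(G0)
            S_R = e.T @ e
            R0 = sample_invwishart(rng, priors.nu_R + n, S_R + priors.V_R)
            R0inv = inv_small(R0)

        if not np.all(np.isfinite(e)):
            raise FloatingPointError(f"sampler diverged at cycle {cycle}")
        if cycle % _REFRESH_EVERY == 0:
            e = y - X @ mu - W @ alpha
            if eps_block is not None:
                obs = eps_block.phen_row >= 0
                e[eps_block.phen_row[obs]] -= eps[obs]

        if cycle > opts.burn_in and (cycle - opts.burn_in) % opts.thin == 0:
            out_mu[stored] = mu
            out_alpha[stored] = alpha
            out_B[stored] = B
            out_R0[stored] = R0
            if eps_block is not None:
                out_eps[stored] = eps
                out_G0[stored] = G0
            stored += 1

    return PosteriorChain(mu=out_mu[:stored], alpha=out_alpha[:stored],
                          B=out_B[:stored], R0=out_R0[:stored],
                          eps=None if out_eps is None else out_eps[:stored],
                          G0=None if out_G0 is None else out_G0[:stored],
                          options=opts, region_sizes=regions.sizes.copy())


def gibbs_bayesn0(
    data: GenomicModelData,
    opts: ChainOptions,
    fixed_variances: Optional[FixedVariances] = None,
) -> PosteriorChain:
    """Run the BayesN0 Gibbs sampler on genotyped data.

    Monomorphic marker columns are tolerated (they simply draw from their
    prior); callers normally remove them when centering genotypes.
    """
    n, T = data.y.shape
    X = np.ones((n, 1))
    return _gibbs_engine(data.y, X, data.M, data.regions, data.priors, opts,
                         fixed=fixed_variances)


def predict_gebv_direct(M: np.ndarray, chain: PosteriorChain,
                        per_cycle: bool = False) -> np.ndarray:
    """Genomic breeding values g_t = M alpha_t from a genotyped-only chain.

    Returns (n, T) posterior-mean GEBVs, or (m, n, T) per stored cycle when
    ``per_cycle`` (used for prediction-error variance).
    """
    M = np.asarray(M, dtype=float)
    if M.shape[1] != chain.alpha.shape[1]:
        raise ValueError("marker matrix column count does not match chain")
    if per_cycle:
        return np.einsum("nk,mkt->mnt", M, chain.alpha)
    return M @ chain.mean_alpha()


def genetic_cov_from_chain(chain: PosteriorChain, M: np.ndarray) -> np.ndarray:
    """Genetic (co)variance as the across-cycle mean of the per-cycle
    empirical (co)variance of breeding values M alpha."""
    M = np.asarray(M, dtype=float)
    if M.shape[0] < 2:
        raise ValueError("need at least two individuals")
    g = np.einsum("nk,mkt->mnt", M, chain.alpha)  # (m, n, T)
    gc = g - g.mean(axis=1, keepdims=True)
    covs = np.einsum("mnt,mnu->mtu", gc, gc) / (M.shape[0] - 1)
    return covs.mean(axis=0)
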