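"""Single-step machinery: joint evaluation of genotyped and non-genotyped
animals at the SNP level.

Phenotypes of all recorded animals are modeled as

    y = X* mu* + W alpha + U eps + e

where for each trait the fixed design carries an intercept and a
genotyped-mean contrast (-A_ng A_gg^{-1} 1 on non-genotyped records, -1 on
genotyped records), W applies observed genotypes M_g and pedigree-imputed
genotypes M_hat_n = A_ng A_gg^{-1} M_g to the records, and eps are
imputation residuals for every non-genotyped animal in the pedigree with
prior N(0, G_0 (x) A). Two inference routes are provided:

* ``gibbs_ssbayesn0`` — the fully Bayesian sampler (region-wise SNP
  (co)variances B_s, residual R_0 and genetic G_0 all sampled);
* ``run_sssnpblup`` — the practical plug-in route: (co)variances fixed at
  posterior means from a BayesN0 or ssBayesN0 chain and the mixed-model
  equations solved by diagonally preconditioned conjugate gradients.

Breeding values for all animals come from the single-step predictor
 g_t = [-A_ng A_gg^{-1} 1; -1] mu_g,t + [M_hat_n; M_g] alpha_t + [eps_t; 0]
(non-genotyped block first, then genotyped).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import sparse
from scipy.linalg import cho_factor, cho_solve

from ._linalg import inv_small
from .mcmc import (ChainOptions, FixedVariances, PosteriorChain, _EpsBlock,
                   _gibbs_engine)
from .regions import PriorSpec, RegionMap
from .relationship import RelationshipBlocks, impute_genotypes

logger = logging.getLogger(__name__)

__all__ = [
    "SingleStepSystem",
    "MmeSystem",
    "build_ss_system",
    "gibbs_ssbayesn0",
    "fullcond_epsilon",
    "fullcond_G0",
    "assemble_mme",
    "solve_pcg",
    "run_sssnpblup",
    "predict_gebv_singlestep",
    "PcgError",
]


@dataclass
class SingleStepSystem:
    """Assembled single-step design.

    Animal ordering is non-genotyped block first (``nongenotyped_idx``)
    then genotyped (``genotyped_idx``), both in pedigree order. Records are
    phenotyped animals in that same ordering, shared by both traits.

    ``X`` is the per-trait fixed design (intercept, genotyped-mean
    contrast); ``W`` the per-trait marker design on records; ``phen_row``
    maps each non-genotyped animal to its record row (-1 if unrecorded).
    """

    y: np.ndarray  # (n_rec, T)
    X: np.ndarray  # (n_rec, n_fixed)
    W: np.ndarray  # (n_rec, k)
    phen_row: np.ndarray  # (N_n,)
    Ainv_nn: sparse.csr_matrix
    M_g: np.ndarray  # centered, (n_g, k)
    M_hat_n: np.ndarray  # centered, (N_n, k)
    xg_contrast: np.ndarray  # (N_n + n_g,) the -A_ng A_gg^{-1} 1 / -1 column
    genotyped_idx: np.ndarray
    nongenotyped_idx: np.ndarray
    record_animals: np.ndarray  # pedigree index of each record row
    regions: RegionMap
    priors: PriorSpec
    allele_freq: np.ndarray
    has_mug: bool = True

    @property
    def n_traits(self) -> int:
        return self.y.shape[1]

    @property
    def n_records(self) -> int:
        return self.y.shape[0]

    @property
    def N_n(self) -> int:
        return self.phen_row.size

    @property
    def n_markers(self) -> int:
        return self.W.shape[1]


def build_ss_system(
    y_obs: np.ndarray,
    genotyped: np.ndarray,
    phenotyped: np.ndarray,
    M_raw: np.ndarray,
    blocks: RelationshipBlocks,
    regions: RegionMap,
    priors: PriorSpec,
) -> SingleStepSystem:
    """Assemble the single-step design matrices.

    ``y_obs`` is (n_animals, T) in pedigree order with NaN for missing;
    ``M_raw`` holds raw allele counts for the genotyped animals only (rows
    ordered as ``blocks.genotyped_idx``). Genotypes are imputed on the raw
    scale and both blocks are then centered with the same allele
    frequencies 2 p_j computed from the genotyped animals.

    When every pedigree animal is genotyped the genotyped-mean contrast is
    unidentifiable (it is collinear with the intercept) and is dropped with
    a log note.
    """
    y_obs = np.atleast_2d(np.asarray(y_obs, dtype=float))
    if y_obs.ndim == 1:
        y_obs = y_obs[:, None]
    n_anim, T = y_obs.shape
    g_idx = blocks.genotyped_idx
    n_idx = blocks.nongenotyped_idx
    if M_raw.shape[0] != g_idx.size:
        raise ValueError("M_raw rows must match the genotyped block")
    phen = np.asarray(phenotyped, dtype=bool)
    geno = np.asarray(genotyped, dtype=bool)
    if phen.size != n_anim:
        raise ValueError("phenotype flags do not match the pedigree length")
    # every phenotyped animal must have a complete record
    obs = ~np.isnan(y_obs)
    if np.any(obs.any(axis=1) != obs.all(axis=1)):
        raise ValueError("records must be observed for all traits or none")
    if np.any(phen & ~obs.all(axis=1)):
        raise ValueError("a flagged phenotyped animal has missing records")

    M_raw = np.asarray(M_raw, dtype=float)
    p = M_raw.mean(axis=0) / 2.0
    M_hat_n_raw = impute_genotypes(blocks, M_raw)
    M_g = M_raw - 2.0 * p
    M_hat_n = M_hat_n_raw - 2.0 * p

    # genotyped-mean contrast column, per animal
    n_g = g_idx.size
    N_n = n_idx.size
    if N_n > 0:
        c = cho_factor(blocks.A_gg, lower=True)
        xg_n = -(blocks.A_ng @ cho_solve(c, np.ones(n_g)))
    else:
        xg_n = np.zeros(0)
    xg = np.concatenate([xg_n, -np.ones(n_g)])

    # records: phenotyped non-genotyped animals first, then genotyped
    phen_n = phen[n_idx]
    phen_g = phen[g_idx]
    rec_animals = np.concatenate([n_idx[phen_n], g_idx[phen_g]])
    if rec_animals.size == 0:
        raise ValueError("no phenotyped animals")
    y = y_obs[rec_animals]

    has_mug = N_n > 0
    if not has_mug:
        logger.info("all pedigree animals genotyped: dropping the "
                    "unidentifiable genotyped-mean contrast")
    anim_rows = np.concatenate([np.arange(N_n)[phen_n],
                                N_n + np.arange(n_g)[phen_g]])
    M_all = np.vstack([M_hat_n, M_g]) if N_n else M_g
    W = np.ascontiguousarray(M_all[anim_rows])
    xg_rec = xg[anim_rows]
    X = np.column_stack([np.ones(rec_animals.size), xg_rec]) if has_mug \
        else np.ones((rec_animals.size, 1))

    phen_row = np.full(N_n, -1, dtype=np.int64)
    phen_row[phen_n] = np.arange(int(phen_n.sum()))

    return SingleStepSystem(
        y=y, X=X, W=W, phen_row=phen_row, Ainv_nn=blocks.Ainv_nn,
        M_g=M_g, M_hat_n=M_hat_n, xg_contrast=xg,
        genotyped_idx=g_idx, nongenotyped_idx=n_idx,
        record_animals=rec_animals, regions=regions, priors=priors,
        allele_freq=p, has_mug=has_mug,
    )


def gibbs_ssbayesn0(
    system: SingleStepSystem,
    opts: ChainOptions,
    fixed_variances: Optional[FixedVariances] = None,
) -> PosteriorChain:
    """Single-step BayesN0 sampler: the BayesN0 scan extended with
    imputation residuals eps (prior N(0, G_0 (x) A)) and the genetic
    covariance G_0 ~ IW(v_G, V_G). With no non-genotyped animals the eps
    block is empty and the chain reduces to BayesN0."""
    eps_block = None
    if system.N_n > 0:
        eps_block = _EpsBlock(system.Ainv_nn, system.phen_row)
    return _gibbs_engine(system.y, system.X, system.W, system.regions,
                         system.priors, opts, eps_block=eps_block,
                         fixed=fixed_variances)


def fullcond_epsilon(system: SingleStepSystem, y_star_rec: np.ndarray,
                     G0: np.ndarray, R0: np.ndarray):
    """Exact full conditional of all imputation residuals,
    N[(U'R^-1 U + G_0^-1 (x) A^{-nn})^-1 U'R^-1 y*, (.)^-1], returned as a
    dense (mean, covariance) pair (trait-major stacking [eps_L; eps_H]).

    ``y_star_rec`` is (n_rec, T): records corrected for all effects except
    the eps contribution. Intended for desk-scale verification.
    """
    T = system.n_traits
    Nn = system.N_n
    R0inv = inv_small(np.atleast_2d(R0))
    G0inv = inv_small(np.atleast_2d(G0))
    D = np.zeros(Nn)
    obs = system.phen_row >= 0
    D[obs] = 1.0
    P = np.kron(G0inv, system.Ainv_nn.toarray()) + np.kron(R0inv, np.diag(D))
    if np.linalg.eigvalsh(P).min() <= 0:
        raise ValueError("singular epsilon precision")
    b = np.zeros(T * Nn)
    yt = np.zeros((Nn, T))
    yt[obs] = np.atleast_2d(y_star_rec)[system.phen_row[obs]]
    for t in range(T):
        b[t * Nn:(t + 1) * Nn] = (R0inv[t] @ yt.T) * D
    C = np.linalg.inv(P)
    return C @ b, C


def fullcond_G0(eps: np.ndarray, Ainv_nn, priors: PriorSpec):
    """IW[v_G + N_n, S_G + V_G] with S_G the matrix of quadratic forms
    eps_t' A^{-nn} eps_u."""
    eps = np.atleast_2d(np.asarray(eps, dtype=float))
    if eps.shape[0] != Ainv_nn.shape[0]:
        raise ValueError("eps length does not match A^{-nn}")
    S_G = np.asarray(eps.T @ (Ainv_nn @ eps))
    return priors.nu_G + eps.shape[0], S_G + priors.V_G


# ---------------------------------------------------------------------------
# plug-in mixed model equations

class PcgError(RuntimeError):
    def __init__(self, msg, best_residual, iterations):
        super().__init__(msg)
        self.best_residual = best_residual
        self.iterations = iterations


@dataclass
class MmeSystem:
    """Matrix-free single-step SNPBLUP normal equations.

    Unknown ordering: mu* (n_fixed per trait, trait-major), alpha
    (trait-major: all trait-L effects then trait-H), eps (trait-major).
    ``matvec`` applies the symmetric coefficient operator, ``diag`` is its
    exact diagonal (Jacobi preconditioner), ``rhs`` the right-hand side.
    """

    matvec: callable
    diag: np.ndarray
    rhs: np.ndarray
    n_fixed: int
    n_markers: int
    N_n: int
    n_traits: int

    @property
    def dim(self) -> int:
        return self.rhs.size

    def split(self, x: np.ndarray):
        """Split a solution vector into (mu*, alpha, eps) arrays shaped
        (n_fixed, T), (k, T), (N_n, T)."""
        T, f, k, Nn = self.n_traits, self.n_fixed, self.n_markers, self.N_n
        mu = x[:T * f].reshape(T, f).T
        al = x[T * f:T * f + T * k].reshape(T, k).T
        ep = x[T * f + T * k:].reshape(T, Nn).T
        return mu, al, ep

    def dense(self) -> np.ndarray:
        """Materialize the coefficient matrix (small systems only)."""
        d = self.dim
        C = np.empty((d, d))
        eye = np.eye(d)
        for i in range(d):
            C[:, i] = self.matvec(eye[:, i])
        return C


def assemble_mme(
    system: SingleStepSystem,
    B: np.ndarray,
    G0: np.ndarray,
    R0: np.ndarray,
) -> MmeSystem:
    """Assemble the single-step SNPBLUP equations with plug-in variances.

    ``B`` is (S, T, T) per-region SNP covariance; the prior block B^{-1} is
    block-diagonal with each SNP's 2x2 (or 1x1) inverse of its region's
    B_s. Products are matrix-free (W and U applied directly); the diagonal
    is computed analytically for Jacobi preconditioning.
    """
    T = system.n_traits
    X, W = system.X, system.W
    f = X.shape[1]
    k = system.n_markers
    Nn = system.N_n
    B = np.asarray(B, dtype=float).reshape(system.regions.n_regions, T, T)
    for name, m in (("B_s", B), ("R0", np.atleast_2d(R0))):
        ev = np.linalg.eigvalsh(m)
        if np.min(ev) <= 0:
            raise ValueError(f"{name} must be positive definite")
    R0inv = inv_small(np.atleast_2d(R0))
    Binv_snp = inv_small(B)[system.regions.region_of_snp]  # (k, T, T)
    if Nn:
        G0 = np.atleast_2d(G0)
        if np.linalg.eigvalsh(G0).min() <= 0:
            raise ValueError("G0 must be positive definite")
        G0inv = inv_small(G0)
        Ainn = system.Ainv_nn
        obs = system.phen_row >= 0
        rows = system.phen_row[obs]
        D = obs.astype(float)
    else:
        G0inv = None

    def record_pred(mu, al, ep):
        """(n_rec, T) predicted records from split components."""
        r = X @ mu + W @ al
        if Nn:
            r[rows] += ep[obs]
        return r

    def matvec(x):
        mu = x[:T * f].reshape(T, f).T
        al = x[T * f:T * f + T * k].reshape(T, k).T
        ep = x[T * f + T * k:].reshape(T, Nn).T
        r = record_pred(mu, al, ep)
        s = r @ R0inv.T  # residual-precision mixing across traits
        out_mu = (X.T @ s).T.reshape(-1)
        out_al = (W.T @ s) + np.einsum("ktu,ku->kt", Binv_snp, al)
        out_al = out_al.T.reshape(-1)
        if Nn:
            out_ep = np.zeros((Nn, T))
            out_ep[obs] = s[rows]
            out_ep += (Ainn @ ep) @ G0inv.T
            out_ep = out_ep.T.reshape(-1)
        else:
            out_ep = np.zeros(0)
        return np.concatenate([out_mu, out_al, out_ep])

    # right-hand side
    sy = system.y @ R0inv.T
    rhs_mu = (X.T @ sy).T.reshape(-1)
    rhs_al = (W.T @ sy).T.reshape(-1)
    if Nn:
        rhs_ep = np.zeros((Nn, T))
        rhs_ep[obs] = sy[rows]
        rhs_ep = rhs_ep.T.reshape(-1)
    else:
        rhs_ep = np.zeros(0)
    rhs = np.concatenate([rhs_mu, rhs_al, rhs_ep])

    # analytic diagonal
    x2 = np.einsum("ij,ij->j", X, X)
    w2 = np.einsum("ij,ij->j", W, W)
    dmu = np.concatenate([R0inv[t, t] * x2 for t in range(T)])
    dal = np.concatenate([R0inv[t, t] * w2 + Binv_snp[:, t, t]
                          for t in range(T)])
    if Nn:
        adiag = system.Ainv_nn.diagonal()
        dep = np.concatenate([R0inv[t, t] * D + G0inv[t, t] * adiag
                              for t in range(T)])
    else:
        dep = np.zeros(0)
    diag = np.concatenate([dmu, dal, dep])

    return MmeSystem(matvec=matvec, diag=diag, rhs=rhs, n_fixed=f,
                     n_markers=k, N_n=Nn, n_traits=T)


def solve_pcg(mme: MmeSystem, tol: float = 1e-12, max_iter: int = 10_000):
    """Diagonally preconditioned conjugate gradients.

    Converges when the relative residual ||b - C x|| / ||b|| drops below
    ``tol``. Returns ``(x, iterations)``; raises :class:`PcgError` carrying
    the best residual if ``max_iter`` is exceeded.
    """
    b = mme.rhs
    bnorm = np.linalg.norm(b)
    if bnorm == 0:
        return np.zeros_like(b), 0
    d = np.where(mme.diag > 0, mme.diag, 1.0)
    x = np.zeros_like(b)
    r = b.copy()
    z = r / d
    pvec = z.copy()
    rz = r @ z
    best = np.linalg.norm(r) / bnorm
    for it in range(1, max_iter + 1):
        Ap = mme.matvec(pvec)
        alpha = rz / (pvec @ Ap)
        x += alpha * pvec
        r -= alpha * Ap
        rel = np.linalg.norm(r) / bnorm
        best = min(best, rel)
        if rel <= tol:
            return x, it
        z = r / d
        rz_new = r @ z
        pvec = z + (rz_new / rz) * pvec
        rz = rz_new
    raise PcgError(f"PCG did not reach tol={tol} in {max_iter} iterations",
                   best_residual=best, iterations=max_iter)


def run_sssnpblup(
    system: SingleStepSystem,
    chain: PosteriorChain,
    varsource: str = "ssbayesn0",
    M_for_G0: Optional[np.ndarray] = None,
    tol: float = 1e-12,
    max_iter: int = 20_000,
):
    """Single-step SNPBLUP with plug-in (co)variances from a chain.

    ``varsource='ssbayesn0'`` takes G_0 as the posterior mean of the
    sampled genetic covariance (the ssSNPB2 route); ``'bayesn0'`` computes
    it as the across-cycle mean of the (co)variance of breeding values
    M alpha from the source chain (the ssSNPB1 route; supply ``M_for_G0``,
    typically the centered genotypes the chain was fitted on). B_s and R_0
    are posterior means in both cases.

    Returns a dict with mu*, alpha, eps, the plug-in variances and the PCG
    iteration count.
    """
    B = chain.mean_B()
    R0 = chain.mean_R0()
    if varsource == "ssbayesn0":
        if chain.G0 is None:
            raise ValueError("varsource 'ssbayesn0' needs a chain with "
                             "sampled G0 (run gibbs_ssbayesn0)")
        G0 = chain.mean_G0()
    elif varsource == "bayesn0":
        if M_for_G0 is None:
            raise ValueError("varsource 'bayesn0' needs M_for_G0 to compute "
                             "the breeding-value covariance")
        from .mcmc import genetic_cov_from_chain

        G0 = genetic_cov_from_chain(chain, M_for_G0)
    else:
        raise ValueError(f"unknown varsource {varsource!r}")
    if B.shape[0] != system.regions.n_regions:
        raise ValueError("chain region count does not match the system")
    mme = assemble_mme(system, B, G0, R0)
    x, iters = solve_pcg(mme, tol=tol, max_iter=max_iter)
    mu, al, ep = mme.split(x)
    return {"mu_star": mu, "alpha": al, "eps": ep, "B": B, "R0": R0,
            "G0": G0, "iterations": iters}


def predict_gebv_singlestep(
    system: SingleStepSystem,
    mu_g: np.ndarray,
    alpha: np.ndarray,
    eps: np.ndarray,
) -> np.ndarray:
    """Breeding values for all pedigree animals (non-genotyped block first,
    then genotyped), per trait:

        g_t = xg * mu_g,t + [M_hat_n; M_g] alpha_t + [eps_t; 0].
    """
    alpha = np.atleast_2d(np.asarray(alpha, dtype=float))
    if alpha.shape[0] != system.n_markers:
        raise ValueError("alpha length does not match the marker set")
    T = alpha.shape[1]
    mu_g = np.broadcast_to(np.asarray(mu_g, dtype=float), (T,))
    Nn = system.N_n
    if Nn:
        eps = np.atleast_2d(np.asarray(eps, dtype=float))
        if eps.shape[0] != Nn:
            raise ValueError("eps must cover every non-genotyped animal")
        M_all = np.vstack([system.M_hat_n, system.M_g])
    else:
        M_all = system.M_g
    g = system.xg_contrast[:, None] * mu_g[None, :] + M_all @ alpha
    if Nn:
        g[:Nn] += eps
    return g


def predict_gebv_singlestep_chain(system: SingleStepSystem,
                                  chain: PosteriorChain,
                                  per_cycle: bool = False) -> np.ndarray:
    """Posterior-mean (or per-cycle) single-step breeding values from a
    ssBayesN0 chain."""
    mug_col = 1 if system.has_mug else None
    if per_cycle:
        m = chain.n_samples
        n_anim = system.N_n + system.genotyped_idx.size
        T = chain.alpha.shape[2]
        out = np.empty((m, n_anim, T))
        for i in range(m):
            mug = chain.mu[i, mug_col] if mug_col is not None else np.zeros(T)
            ep = chain.eps[i] if chain.eps is not None else np.zeros((0, T))
            out[i] = predict_gebv_singlestep(system, mug, chain.alpha[i], ep)
        return out
    mug = chain.mu.mean(axis=0)[mug_col] if mug_col is not None else \
        np.zeros(chain.alpha.shape[2])
    ep = chain.eps.mean(axis=0) if chain.eps is not None else \
        np.zeros((0, chain.alpha.shape[2]))
    return predict_gebv_singlestep(system, mug, chain.mean_alpha(), ep)
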