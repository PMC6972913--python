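"""Genome-region partitioning and prior hyperparameter construction.

Markers are grouped into regions that share one SNP-effect (co)variance
matrix B_s. Supported modes: one region per SNP (BayesA-like), fixed
blocks of N consecutive SNPs, one region per chromosome, or a single
whole-genome region (SNPBLUP/GBLUP-like).

Priors follow the conjugate parameterization: for the multi-trait case
B_s ~ IW(v_B, V_B) with V_B = (v_B - 2 - 1) * Btilde where
Btilde = Gtilde_0 / sum_j 2 p_j (1 - p_j), so the prior mean equals the
base estimate; similarly for R_0 and G_0. Single-trait variances use a
scaled inverse-chi-square with the matching mean.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from ._linalg import is_spd

__all__ = [
    "RegionMap",
    "PriorSpec",
    "partition_regions",
    "sum_2pq",
    "derive_priors_multitrait",
    "derive_priors_singletrait",
    "estimate_base_variances",
]

MODES = ("one_snp", "fixed_n", "chromosome", "whole_genome")


@dataclass
class RegionMap:
    """Assignment of each analysis SNP to a region.

    ``region_of_snp[j]`` is the region index of SNP j; regions are
    contiguous runs in map order. ``sizes[s]`` = k_s.
    """

    region_of_snp: np.ndarray
    sizes: np.ndarray
    mode: str

    @property
    def n_regions(self) -> int:
        return self.sizes.size

    @property
    def n_snp(self) -> int:
        return self.region_of_snp.size

    @property
    def starts(self) -> np.ndarray:
        """Start offsets of each region (for reduceat-style grouping)."""
        return np.concatenate([[0], np.cumsum(self.sizes)[:-1]])


def partition_regions(
    chrom: np.ndarray,
    mode: str = "fixed_n",
    region_size: int = 100,
    cross_chromosomes: bool = False,
) -> RegionMap:
    """Partition markers (sorted by chromosome, then position) into regions.

    ``fixed_n`` makes consecutive blocks of ``region_size`` SNPs; by
    default blocks never span a chromosome boundary, leaving one smaller
    trailing region per chromosome (set ``cross_chromosomes`` to block the
    genome as one sequence instead).
    """
    chrom = np.asarray(chrom)
    k = chrom.size
    if k == 0:
        raise ValueError("empty marker map")
    if mode not in MODES:
        raise ValueError(f"unknown region mode {mode!r}; choose from {MODES}")
    if mode == "one_snp":
        region = np.arange(k)
    elif mode == "whole_genome":
        region = np.zeros(k, dtype=np.int64)
    elif mode == "chromosome":
        _, region = np.unique(chrom, return_inverse=True)
    else:
        if region_size < 1:
            raise ValueError(f"region_size must be >= 1, got {region_size}")
        region = np.empty(k, dtype=np.int64)
        if cross_chromosomes:
            region[:] = np.arange(k) // region_size
        else:
            nxt = 0
            for c in np.unique(chrom):
                cols = np.flatnonzero(chrom == c)
                local = np.arange(cols.size) // region_size
                region[cols] = nxt + local
                nxt += local[-1] + 1
    sizes = np.bincount(region)
    return RegionMap(region_of_snp=region.astype(np.int64),
                     sizes=sizes.astype(np.int64), mode=mode)


def sum_2pq(p: np.ndarray) -> float:
    """sum_j 2 p_j (1 - p_j): expected genotype variance under HWE, used to
    move between SNP-level and genetic-level variances."""
    p = np.asarray(p, dtype=float)
    return float(np.sum(2.0 * p * (1.0 - p)))


@dataclass
class PriorSpec:
    """Conjugate prior hyperparameters for one analysis (T = 1 or 2 traits).

    V_* are T x T scale matrices; nu_* degrees of freedom. For T = 1 the
    inverse-Wishart degenerates to the scaled inverse-chi-square
    InvChi2(nu, V / nu). ``base_G0``/``base_R0`` record the base estimates
    the scales were derived from; ``s2pq`` the genotype-variance sum.
    """

    n_traits: int
    nu_B: float
    V_B: np.ndarray
    nu_R: float
    V_R: np.ndarray
    nu_G: float
    V_G: np.ndarray
    base_G0: np.ndarray
    base_R0: np.ndarray
    s2pq: float

    def snp_scale(self) -> np.ndarray:
        """Prior mean of B_s (the base SNP-level covariance Btilde)."""
        return self.V_B / (self.nu_B - self.n_traits - 1)


def _as_cov(x, name) -> np.ndarray:
    m = np.atleast_2d(np.asarray(x, dtype=float))
    if m.shape[0] != m.shape[1]:
        raise ValueError(f"{name} must be square")
    if not is_spd(m):
        raise ValueError(f"{name} must be symmetric positive definite")
    return m


def derive_priors_multitrait(G0_base, R0_base, p, v: float = 5.0) -> PriorSpec:
    """Multi-trait priors from base (co)variance estimates.

    V_B = (v - 3) * Gtilde_0 / sum 2p(1-p), V_R = (v - 3) * Rtilde_0,
    V_G = (v - 3) * Gtilde_0 for two traits, so each IW prior mean equals
    its base estimate. The implied marginal for each diagonal of B_s with
    v = 5 is InvChi2(4, btilde / 2).
    """
    G0_base = _as_cov(G0_base, "G0_base")
    R0_base = _as_cov(R0_base, "R0_base")
    T = G0_base.shape[0]
    if v <= T + 1:
        raise ValueError(f"v must exceed n_traits + 1 = {T + 1}, got {v}")
    s = sum_2pq(p)
    if s <= 0:
        raise ValueError("sum 2p(1-p) is zero: no segregating markers")
    c = v - T - 1
    return PriorSpec(
        n_traits=T,
        nu_B=float(v), V_B=c * G0_base / s,
        nu_R=float(v), V_R=c * R0_base,
        nu_G=float(v), V_G=c * G0_base,
        base_G0=G0_base, base_R0=R0_base, s2pq=s,
    )


def derive_priors_singletrait(sigma2_g: float, sigma2_e: float, p,
                              df: float = 4.0) -> PriorSpec:
    """Single-trait priors: scaled inverse-chi-square with scale
    S2 = sigma2 * (df - 2) / df so the prior mean equals the base variance
    (for the SNP variance, sigma2_alpha = sigma2_g / sum 2p(1-p)).

    Stored as the equivalent 1x1 inverse-Wishart with nu = df and
    V = df * S2 = (df - 2) * sigma2.
    """
    if sigma2_g <= 0 or sigma2_e <= 0:
        raise ValueError("base variances must be > 0")
    if df <= 2:
        raise ValueError(f"df must be > 2, got {df}")
    s = sum_2pq(p)
    if s <= 0:
        raise ValueError("sum 2p(1-p) is zero: no segregating markers")
    c = df - 2.0
    one = lambda x: np.array([[x]])
    return PriorSpec(
        n_traits=1,
        nu_B=float(df), V_B=one(c * sigma2_g / s),
        nu_R=float(df), V_R=one(c * sigma2_e),
        nu_G=float(df), V_G=one(c * sigma2_g),
        base_G0=one(sigma2_g), base_R0=one(sigma2_e), s2pq=s,
    )


def estimate_base_variances(
    y: np.ndarray,
    M: np.ndarray,
    p: np.ndarray,
    mode: str = "multi",
    n_iter: int = 10_000,
    burn_in: int = 5_000,
    thin: int = 10,
    seed: int = 0,
):
    """Base genetic/residual (co)variances by SNP-level ridge regression.

    Runs the package's own Gibbs sampler with a single whole-genome region
    (all markers share one covariance) under weakly informative priors
    anchored at a half/half split of the phenotypic (co)variance. Returns
    ``(G0_tilde, R0_tilde)`` for ``mode='multi'`` (2x2 arrays) or
    ``(sigma2_g, sigma2_e)`` per supplied trait column for
    ``mode='single'``. SNP-level variance is scaled to the genetic level
    with sum 2p(1-p).
    """
    from .mcmc import ChainOptions, GenomicModelData, gibbs_bayesn0

    y = np.asarray(y, dtype=float)
    if y.ndim == 1:
        y = y[:, None]
    if y.shape[0] == 0:
        raise ValueError("no phenotyped genotyped animals available")
    vy = y.var(axis=0, ddof=1)
    if np.any(vy <= 0):
        raise ValueError("a phenotype column has zero variance")
    s = sum_2pq(p)
    rmap = partition_regions(np.zeros(M.shape[1]), mode="whole_genome")
    opts = ChainOptions(n_iter=n_iter, burn_in=burn_in, thin=thin, seed=seed)
    if mode == "multi":
        if y.shape[1] != 2:
            raise ValueError("multi mode expects two phenotype columns")
        # half-phenotypic diagonal anchor; weakly informative via v=5
        priors = derive_priors_multitrait(0.5 * np.diag(vy), 0.5 * np.diag(vy), p)
        data = GenomicModelData(y=y, M=M, regions=rmap, priors=priors)
        chain = gibbs_bayesn0(data, opts)
        B_mean = chain.B.mean(axis=0)[0]
        G0 = B_mean * s
        R0 = chain.R0.mean(axis=0)
        return G0, R0
    elif mode == "single":
        if y.shape[1] != 1:
            raise ValueError("single mode expects one phenotype column")
        priors = derive_priors_singletrait(0.5 * vy[0], 0.5 * vy[0], p)
        data = GenomicModelData(y=y, M=M, regions=rmap, priors=priors)
        chain = gibbs_bayesn0(data, opts)
        sigma2_g = float(chain.B.mean(axis=0)[0, 0, 0] * s)
        sigma2_e = float(chain.R0.mean(axis=0)[0, 0])
        return sigma2_g, sigma2_e
    raise ValueError(f"unknown mode {mode!r}")
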