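"""Pedigree numerator relationship algebra.

Builds the additive relationship matrix A (tabular method), its sparse
inverse (Henderson's rules with inbreeding from the Meuwissen-Luo
recursion), the genotyped/non-genotyped partition used by single-step
models, and pedigree-based genotype imputation
``M_hat_n = A_ng A_gg^{-1} M_g``.

A is dense and intended for desk-scale pedigrees; a size guard warns
before very large allocations. A^{-1} is always sparse.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import sparse
from scipy.linalg import cho_factor, cho_solve

from ._kernels import inbreeding_meuwissen_luo

__all__ = [
    "PedigreeGraph",
    "RelationshipBlocks",
    "build_A",
    "build_A_inverse",
    "inbreeding",
    "partition_blocks",
    "impute_genotypes",
    "export_coo",
]

_DENSE_A_WARN = 8000


@dataclass
class PedigreeGraph:
    """Topologically ordered pedigree (parents precede offspring).

    ``sire``/``dam`` hold parent indices into the same ordering, -1 for
    unknown. Validation of the ordering happens at construction.
    """

    sire: np.ndarray
    dam: np.ndarray

    def __post_init__(self):
        self.sire = np.asarray(self.sire, dtype=np.int64)
        self.dam = np.asarray(self.dam, dtype=np.int64)
        if self.sire.shape != self.dam.shape:
            raise ValueError("sire and dam arrays must have equal length")
        n = self.sire.size
        ids = np.arange(n)
        for name, par in (("sire", self.sire), ("dam", self.dam)):
            bad = (par >= ids) & (par >= 0)
            if np.any(bad):
                raise ValueError(
                    f"{name} of animal {int(np.flatnonzero(bad)[0])} does not "
                    "precede it; pedigree must be topologically ordered"
                )
            if np.any(par < -1):
                raise ValueError(f"invalid {name} code below -1")

    @property
    def n(self) -> int:
        return self.sire.size

    @classmethod
    def from_population(cls, pop) -> "PedigreeGraph":
        return cls(pop.sire, pop.dam)


@dataclass
class RelationshipBlocks:
    """A partitioned for a genotyped set: A_gg, A_ng and the (n,n) block of
    the sparse A^{-1}. Index arrays map block rows back to pedigree order."""

    A_gg: np.ndarray
    A_ng: np.ndarray
    Ainv_nn: sparse.csr_matrix
    genotyped_idx: np.ndarray
    nongenotyped_idx: np.ndarray


def inbreeding(ped: PedigreeGraph) -> np.ndarray:
    """Inbreeding coefficients F (Meuwissen-Luo ancestor recursion)."""
    return inbreeding_meuwissen_luo(ped.sire, ped.dam)


def build_A(ped: PedigreeGraph) -> np.ndarray:
    """Dense numerator relationship matrix by the tabular method.

    A_ii = 1 + 0.5 A_sd; A_ij = 0.5 (A_js + A_jd), unknown parents
    contribute zero.
    """
    n = ped.n
    if n > _DENSE_A_WARN:
        warnings.warn(
            f"building a dense {n}x{n} relationship matrix "
            f"({n * n * 8 / 1e9:.1f} GB)", RuntimeWarning, stacklevel=2)
    A = np.zeros((n, n))
    for i in range(n):
        s, d = ped.sire[i], ped.dam[i]
        row = np.zeros(i)
        if s >= 0:
            row += 0.5 * A[s, :i]
        if d >= 0:
            row += 0.5 * A[d, :i]
        A[i, :i] = row
        A[:i, i] = row
        aii = 1.0
        if s >= 0 and d >= 0:
            aii += 0.5 * A[s, d]
        A[i, i] = aii
    return A


def build_A_inverse(ped: PedigreeGraph) -> sparse.csr_matrix:
    """Sparse A^{-1} via Henderson's rules with inbreeding.

    The Mendelian-sampling variance d_i uses the parents' inbreeding
    coefficients: d = 0.5 - 0.25 (F_s + F_d) with both parents known,
    0.75 - 0.25 F_p with one, 1 with none.
    """
    n = ped.n
    F = inbreeding(ped)
    rows, cols, vals = [], [], []
    for i in range(n):
        s, d = ped.sire[i], ped.dam[i]
        if s >= 0 and d >= 0:
            di = 0.5 - 0.25 * (F[s] + F[d])
        elif s >= 0:
            di = 0.75 - 0.25 * F[s]
        elif d >= 0:
            di = 0.75 - 0.25 * F[d]
        else:
            di = 1.0
        if di <= 0:
            raise ValueError(f"non-positive Mendelian variance at animal {i}")
        a = 1.0 / di
        rows.append(i); cols.append(i); vals.append(a)
        for p in (s, d):
            if p >= 0:
                rows += [i, p]; cols += [p, i]; vals += [-0.5 * a, -0.5 * a]
        for p in (s, d):
            if p < 0:
                continue
            for q in (s, d):
                if q >= 0:
                    rows.append(p); cols.append(q); vals.append(0.25 * a)
    Ainv = sparse.coo_matrix((vals, (rows, cols)), shape=(n, n)).tocsr()
    return Ainv


def partition_blocks(ped: PedigreeGraph, genotyped: np.ndarray) -> RelationshipBlocks:
    """Split A by genotyping status.

    ``genotyped`` is a boolean mask or an index array over pedigree order.
    A^{-nn} is read off directly as the (n,n) block of the sparse A^{-1}
    (the standard partitioned-inverse identity; no re-inversion).
    """
    n = ped.n
    mask = np.zeros(n, dtype=bool)
    g = np.asarray(genotyped)
    if g.dtype == bool:
        if g.size != n:
            raise ValueError("boolean genotyped mask has wrong length")
        mask[:] = g
    else:
        mask[g] = True
    g_idx = np.flatnonzero(mask)
    n_idx = np.flatnonzero(~mask)
    if g_idx.size == 0:
        raise ValueError("at least one genotyped animal is required")
    A = build_A(ped)
    Ainv = build_A_inverse(ped)
    Ainn = Ainv[n_idx][:, n_idx].tocsr()
    return RelationshipBlocks(
        A_gg=A[np.ix_(g_idx, g_idx)],
        A_ng=A[np.ix_(n_idx, g_idx)],
        Ainv_nn=Ainn,
        genotyped_idx=g_idx,
        nongenotyped_idx=n_idx,
    )


def export_coo(path, mat, tol: float = 0.0) -> None:
    """Write a (sparse or dense) matrix as coordinate-format text
    (row, col, value; 0-based) for debugging A / A^{-1} blocks."""
    coo = sparse.coo_matrix(mat)
    with open(path, "w") as fh:
        fh.write("row\tcol\tvalue\n")
        for i, j, v in zip(coo.row, coo.col, coo.data):
            if abs(v) > tol:
                fh.write(f"{i}\t{j}\t{v:.12g}\n")


def impute_genotypes(blocks: RelationshipBlocks, M_g: np.ndarray) -> np.ndarray:
    """Pedigree-based expectation of non-genotyped animals' genotypes,
    M_hat_n = A_ng A_gg^{-1} M_g, via a symmetric (Cholesky) solve."""
    M_g = np.asarray(M_g, dtype=float)
    if M_g.ndim == 1:
        M_g = M_g[:, None]
    if M_g.shape[0] != blocks.A_gg.shape[0]:
        raise ValueError(
            f"M_g has {M_g.shape[0]} rows but {blocks.A_gg.shape[0]} genotyped "
            "animals are in the blocks")
    if blocks.A_ng.shape[0] == 0:
        return np.zeros((0, M_g.shape[1]))
    c = cho_factor(blocks.A_gg, lower=True)
    return blocks.A_ng @ cho_solve(c, M_g)
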