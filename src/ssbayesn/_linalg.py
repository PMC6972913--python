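"""Small covariance-matrix utilities: batched inverse-Wishart sampling and
SPD checks for 1x1 / 2x2 matrices (the trait dimensions used here).

Convention: Sigma ~ IW(nu, Psi) means Sigma^{-1} ~ Wishart(nu, Psi^{-1})
and E[Sigma] = Psi / (nu - p - 1). The 1-D special case coincides with the
scaled inverse-chi-square: IW_1(nu, Psi) == InvChi2(nu, Psi / nu).
"""

from __future__ import annotations

import numpy as np

__all__ = ["sample_invwishart", "sample_invwishart_batch", "is_spd", "inv_small"]


def inv_small(mats: np.ndarray) -> np.ndarray:
    """Inverse of stacked 1x1 or 2x2 symmetric matrices (closed form)."""
    mats = np.asarray(mats, dtype=float)
    squeeze = mats.ndim == 2
    if squeeze:
        mats = mats[None]
    p = mats.shape[-1]
    out = np.empty_like(mats)
    if p == 1:
        out[..., 0, 0] = 1.0 / mats[..., 0, 0]
    elif p == 2:
        det = mats[..., 0, 0] * mats[..., 1, 1] - mats[..., 0, 1] * mats[..., 1, 0]
        out[..., 0, 0] = mats[..., 1, 1] / det
        out[..., 1, 1] = mats[..., 0, 0] / det
        out[..., 0, 1] = -mats[..., 0, 1] / det
        out[..., 1, 0] = -mats[..., 1, 0] / det
    else:
        out = np.linalg.inv(mats)
    return out[0] if squeeze else out


def _chol2_batch(mats: np.ndarray) -> np.ndarray:
    """Lower Cholesky factors of stacked 2x2 SPD matrices."""
    L = np.zeros_like(mats)
    l11 = np.sqrt(mats[..., 0, 0])
    L[..., 0, 0] = l11
    L[..., 1, 0] = mats[..., 1, 0] / l11
    L[..., 1, 1] = np.sqrt(mats[..., 1, 1] - L[..., 1, 0] ** 2)
    return L


def sample_invwishart_batch(rng: np.random.Generator, df, scales: np.ndarray) -> np.ndarray:
    """Draw from IW(df_s, scale_s) for a stack of 1x1 or 2x2 scale matrices.

    Uses the Bartlett decomposition of the corresponding Wishart, fully
    vectorized over the stack.
    """
    scales = np.asarray(scales, dtype=float)
    S, p, _ = scales.shape
    df = np.broadcast_to(np.asarray(df, dtype=float), (S,))
    if np.any(df <= p - 1):
        raise ValueError("inverse-Wishart degrees of freedom too small")
    if p == 1:
        chi = rng.chisquare(df)
        return (scales[:, 0, 0] / chi)[:, None, None]
    if p != 2:
        from scipy.stats import invwishart

        return np.stack([
            invwishart.rvs(df=float(d), scale=s, random_state=rng)
            for d, s in zip(df, scales)
        ])
    # Wishart(df, V) with V = scale^{-1}: W = (L A)(L A)', V = L L'
    V = inv_small(scales)
    L = _chol2_batch(V)
    A = np.zeros((S, 2, 2))
    A[:, 0, 0] = np.sqrt(rng.chisquare(df))
    A[:, 1, 1] = np.sqrt(rng.chisquare(df - 1.0))
    A[:, 1, 0] = rng.standard_normal(S)
    LA = L @ A
    W = LA @ np.swapaxes(LA, -1, -2)
    return inv_small(W)


def sample_invwishart(rng: np.random.Generator, df: float, scale: np.ndarray) -> np.ndarray:
    """Single inverse-Wishart draw (thin wrapper over the batch sampler)."""
    scale = np.atleast_2d(np.asarray(scale, dtype=float))
    return sample_invwishart_batch(rng, df, scale[None])[0]


def is_spd(mat: np.ndarray, tol: float = 0.0) -> bool:
    """Symmetric positive definite check via eigenvalues."""
    mat = np.atleast_2d(mat)
    if not np.allclose(mat, mat.T, rtol=1e-10, atol=1e-12):
        return False
    return bool(np.linalg.eigvalsh(mat).min() > tol)
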