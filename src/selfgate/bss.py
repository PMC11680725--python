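"""Source separation on the self-gating matrix: PCA, SOBI and FastICA.

PCA is always applied first: it reduces the channel dimension (10 components
capture the physiology), whitens the retained subspace and serves itself as
the reference extraction method.  The two blind source separation methods
then rotate the whitened component set: SOBI (second-order blind
identification) jointly diagonalises symmetrised time-lagged covariance
matrices -- it assumes temporally correlated sources with distinct spectra,
which respiration (0.1-0.7 Hz) and the heart (0.5-2 Hz) satisfy -- while
FastICA maximises non-Gaussianity via the log-cosh negentropy approximation.
All methods return unit-variance sources with sign fixed so that skewness is
non-negative, removing the inherent sign ambiguity.

The SOBI joint diagonaliser is written here in full (Jacobi-style Givens
rotation sweeps minimising the summed squared off-diagonal entries); PCA and
FastICA are backed by scikit-learn.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import skew
from sklearn.decomposition import PCA, FastICA
from sklearn.exceptions import ConvergenceWarning

from .si_preproc import SGMatrix

__all__ = [
    "SourceSet",
    "pca_reduce",
    "sobi",
    "fastica",
    "joint_diagonalize",
    "offdiag_criterion",
    "amari_index",
]


@dataclass
class SourceSet:
    """Estimated source time series with their mixing/unmixing maps.

    ``sources`` (time x k) are unit-variance; they satisfy
    ``sources = ((X - pre_mean) / pre_scale) @ unmixing.T`` where X is the
    self-gating matrix the set was estimated from.  ``mixing`` is the
    pseudo-inverse of ``unmixing``.  ``explained_variance`` holds the PCA
    explained-variance fractions (None for SOBI/ICA).
    """

    sources: np.ndarray
    unmixing: np.ndarray
    mixing: np.ndarray
    method: str
    fs: float
    pre_mean: np.ndarray
    pre_scale: np.ndarray
    explained_variance: np.ndarray | None = None
    converged: bool = True
    extras: dict = field(default_factory=dict)

    @property
    def n_sources(self) -> int:
        return self.sources.shape[1]


def _fix_sign_and_scale(sources: np.ndarray, unmixing: np.ndarray):
    """Scale each source to unit variance and make its skewness >= 0."""
    sd = sources.std(axis=0)
    sd[sd == 0] = 1.0
    sources = sources / sd
    unmixing = unmixing / sd[:, None]
    flip = np.where(skew(sources, axis=0) < 0, -1.0, 1.0)
    return sources * flip, unmixing * flip[:, None]


def pca_reduce(m: SGMatrix, n_components: int = 10, standardize: bool = False) -> SourceSet:
    """Project the self-gating matrix onto its top principal components.

    Columns are centred and projected on the leading eigenvectors of the
    covariance.  Optional z-scoring of the columns is exposed but off by
    default: the magnitude self-gating matrix weights channels by their
    physiological signal amplitude, and z-scoring would inflate pure-noise
    channels to the same scale as signal-carrying ones.  The returned
    component time series are mutually uncorrelated and whitened to unit
    variance, ready for the downstream blind source separation rotations.
    """
    X = m.values
    if n_components > X.shape[1]:
        raise ValueError("n_components exceeds the number of channels")
    if X.shape[0] <= n_components:
        raise ValueError("need more time points than components")
    mu = X.mean(axis=0)
    if standardize:
        scale = X.std(axis=0)
        scale[scale == 0] = 1.0
    else:
        scale = np.ones(X.shape[1])
    Z = (X - mu) / scale

    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(Z)
    unmixing = pca.components_.copy()
    total_mean = mu + scale * pca.mean_

    sources, unmixing = _fix_sign_and_scale(scores, unmixing)
    return SourceSet(
        sources=sources,
        unmixing=unmixing,
        mixing=np.linalg.pinv(unmixing),
        method="PCA",
        fs=m.fs,
        pre_mean=total_mean,
        pre_scale=scale,
        explained_variance=pca.explained_variance_ratio_.copy(),
    )


def offdiag_criterion(mats: np.ndarray) -> float:
    """Sum of squared off-diagonal entries over a stack of square matrices."""
    mats = np.asarray(mats)
    k = mats.shape[-1]
    mask = ~np.eye(k, dtype=bool)
    return float((mats[..., mask] ** 2).sum())


def joint_diagonalize(
    mats: np.ndarray, max_sweeps: int = 200, tol: float = 1e-8
) -> tuple[np.ndarray, bool, list[float]]:
    """Orthogonal joint diagonalisation by Jacobi-style Givens rotations.

    Finds one orthogonal V minimising the summed squared off-diagonal
    entries of V^T A_i V over the given stack of symmetric matrices, by
    sweeping over index pairs and applying, for each pair, the closed-form
    optimal plane rotation.  Returns (V, converged, criterion history); the
    criterion is non-increasing across sweeps.  Non-convergence returns the
    best iterate with the flag set False rather than raising.
    """
    A = np.array(mats, dtype=float, copy=True)
    k = A.shape[-1]
    V = np.eye(k)
    history = [offdiag_criterion(A)]
    converged = False
    for _ in range(max_sweeps):
        max_sin = 0.0
        for p in range(k - 1):
            for q in range(p + 1, k):
                h = np.stack([A[:, p, p] - A[:, q, q], A[:, p, q] + A[:, q, p]], axis=1)
                G = h.T @ h
                evals, evecs = np.linalg.eigh(G)
                x, y = evecs[:, np.argmax(evals)]
                if x < 0:
                    x, y = -x, -y
                r = np.hypot(x, y)
                if r == 0:
                    continue
                c = np.sqrt((x + r) / (2.0 * r))
                s = y / np.sqrt(2.0 * r * (x + r))
                if abs(s) < tol:
                    continue
                max_sin = max(max_sin, abs(s))
                # rotate rows/columns p,q of every matrix and accumulate V
                Ap, Aq = A[:, :, p].copy(), A[:, :, q].copy()
                A[:, :, p] = c * Ap + s * Aq
                A[:, :, q] = -s * Ap + c * Aq
                Ap, Aq = A[:, p, :].copy(), A[:, q, :].copy()
                A[:, p, :] = c * Ap + s * Aq
                A[:, q, :] = -s * Ap + c * Aq
                Vp, Vq = V[:, p].copy(), V[:, q].copy()
                V[:, p] = c * Vp + s * Vq
                V[:, q] = -s * Vp + c * Vq
        history.append(offdiag_criterion(A))
        if max_sin < tol:
            converged = True
            break
    return V, converged, history


def lagged_covariances(S: np.ndarray, lags) -> np.ndarray:
    """Symmetrised time-lagged covariance matrices of the source columns."""
    S = S - S.mean(axis=0)
    out = []
    for tau in lags:
        if tau <= 0 or tau >= S.shape[0]:
            raise ValueError("lags must be positive and shorter than the series")
        C = S[:-tau].T @ S[tau:] / (S.shape[0] - tau)
        out.append(0.5 * (C + C.T))
    return np.stack(out)


def sobi(
    components: SourceSet,
    lags=None,
    max_sweeps: int = 200,
    tol: float = 1e-8,
) -> SourceSet:
    """Second-order blind identification of the whitened component set.

    Computes symmetrised lagged covariances of the (whitened) components for
    the given lags (default 1..20 samples, covering at least one cardiac
    period at the ~16 Hz self-gating rate) and jointly diagonalises them
    with one orthogonal rotation.  Sources with distinct spectra -- hence
    distinct lagged autocovariance signatures -- are thereby separated even
    when PCA left them mixed.
    """
    if components.n_sources < 2:
        raise ValueError("SOBI needs at least 2 components")
    if lags is None:
        lags = range(1, 21)
    S = components.sources
    mats = lagged_covariances(S, lags)
    V, converged, history = joint_diagonalize(mats, max_sweeps=max_sweeps, tol=tol)
    if not converged:
        warnings.warn("SOBI joint diagonalization did not converge; best iterate returned")
    sources = S @ V
    unmixing = V.T @ components.unmixing
    sources, unmixing = _fix_sign_and_scale(sources, unmixing)
    return SourceSet(
        sources=sources,
        unmixing=unmixing,
        mixing=np.linalg.pinv(unmixing),
        method="SOBI",
        fs=components.fs,
        pre_mean=components.pre_mean,
        pre_scale=components.pre_scale,
        converged=converged,
        extras=dict(offdiag_history=history, lags=list(lags)),
    )


def fastica(
    components: SourceSet,
    nonlinearity: str = "logcosh",
    seed: int = 0,
    max_iter: int = 500,
    tol: float = 1e-6,
) -> SourceSet:
    """FastICA rotation of the whitened component set (negentropy contrast).

    Symmetric fixed-point iteration with the chosen contrast function
    (default log-cosh).  The seed is a required part of the configuration:
    the fixed-point iteration starts from a random rotation and its result
    is only reproducible for a fixed seed.  Non-convergence returns the best
    iterate with ``converged=False``.
    """
    if components.n_sources < 2:
        raise ValueError("FastICA needs at least 2 components")
    S = components.sources
    rng = np.random.default_rng(seed)
    w_init = rng.standard_normal((components.n_sources, components.n_sources))
    ica = FastICA(
        n_components=components.n_sources,
        algorithm="parallel",
        whiten=False,
        fun=nonlinearity,
        max_iter=max_iter,
        tol=tol,
        w_init=w_init,
    )
    converged = True
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always", ConvergenceWarning)
        sources = ica.fit_transform(S)
        if any(issubclass(w.category, ConvergenceWarning) for w in caught):
            converged = False
    unmixing = ica.components_ @ components.unmixing
    sources, unmixing = _fix_sign_and_scale(sources, unmixing)
    return SourceSet(
        sources=sources,
        unmixing=unmixing,
        mixing=np.linalg.pinv(unmixing),
        method="ICA",
        fs=components.fs,
        pre_mean=components.pre_mean,
        pre_scale=components.pre_scale,
        converged=converged,
        extras=dict(n_iter=int(ica.n_iter_), seed=seed),
    )


def amari_index(P: np.ndarray) -> float:
    """Amari separation performance index of a square gain matrix P = W A.

    0 for a perfect separation (P a scaled permutation); larger values mean
    more residual mixing.  Normalised to [0, 1] by the matrix size.
    """
    P = np.abs(np.asarray(P, dtype=float))
    k = P.shape[0]
    rows = (P / P.max(axis=1, keepdims=True)).sum(axis=1) - 1.0
    cols = (P / P.max(axis=0, keepdims=True)).sum(axis=0) - 1.0
    return float((rows.sum() + cols.sum()) / (2.0 * k * (k - 1)))
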