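"""PCA + ICA decomposition into channel-space spatial filters and patterns.

The unsupervised pipeline is: centre the channels x samples training matrix,
project it to a 15-dimensional principal subspace, and unmix the principal
scores with extended-infomax ICA.  Composing the two linear maps gives a
15 x channels matrix of spatial filters (rows) whose pseudo-inverse columns
are the corresponding scalp patterns — the channel-space generalization of
the unmixing/mixing pair when the inverse only exists in the PC subspace.

ICA's sign ambiguity is resolved by a fixed convention: each pattern is
flipped so that its largest-|weight| electrode is positive.  All pattern
comparisons in this package happen after this normalization.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np

logger = logging.getLogger(__name__)

N_COMPONENTS = 15


@dataclass
class Decomposition:
    """Spatial filters and patterns from one training state.

    ``filters`` (k x channels) act on channel data; ``patterns``
    (channels x k) are the scalp projections.  ``filters @ patterns`` is the
    identity on the retained subspace.  ``mean`` stores the training channel
    means so filters can be applied to new data with the same centering.
    """

    pca_basis: np.ndarray
    ica_unmix: np.ndarray
    filters: np.ndarray
    patterns: np.ndarray
    mean: np.ndarray
    state_tag: str = ""

    def __post_init__(self) -> None:
        k = self.filters.shape[0]
        if self.patterns.shape[1] != k:
            raise ValueError("pattern count must equal filter count")
        dev = np.abs(self.filters @ self.patterns - np.eye(k)).max()
        if dev > 1e-6:
            raise ValueError(f"filters @ patterns deviates from identity by {dev:.2e}")

    @property
    def n_components(self) -> int:
        return self.filters.shape[0]


@dataclass
class ComponentTimecourse:
    """Component x sample activations at sampling rate ``fs``."""

    data: np.ndarray
    fs: float

    def __post_init__(self) -> None:
        self.data = np.atleast_2d(np.asarray(self.data, dtype=float))


def pca_reduce(
    X: np.ndarray, n_components: int = N_COMPONENTS
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Project channel data onto its leading principal directions.

    Returns ``(basis, scores, mean)``: ``basis`` rows are unit-norm principal
    directions of the channel covariance in descending variance order,
    ``scores = basis @ (X - mean)``, and ``mean`` the per-channel means.
    If the data rank is below ``n_components`` the basis is truncated to the
    effective rank with a warning.
    """
    X = np.asarray(X, dtype=float)
    n_ch, n_samp = X.shape
    if n_samp <= n_ch:
        raise ValueError("need more samples than channels")
    if n_components > n_ch:
        raise ValueError("n_components exceeds channel count")
    mean = X.mean(axis=1)
    Xc = X - mean[:, None]
    U, s, _ = np.linalg.svd(Xc, full_matrices=False)
    tol = s[0] * max(n_ch, n_samp) * np.finfo(float).eps
    rank = int(np.sum(s > tol))
    if rank < n_components:
        warnings.warn(
            f"input rank {rank} < requested {n_components} components; reducing",
            stacklevel=2,
        )
        logger.warning("PCA rank deficiency: keeping %d of %d components", rank, n_components)
        n_components = rank
    basis = U[:, :n_components].T
    return basis, basis @ Xc, mean


def run_ica(
    scores: np.ndarray,
    seed: int = 0,
    engine: str = "fastica",
    max_iter: int | None = None,
) -> np.ndarray:
    """Unmix (PCA-score or any full-rank) channel data into maximally
    independent components.

    The input is symmetrically whitened, unmixed, and the whitening is
    folded back so the returned k x k matrix applies to the raw input.
    Deterministic given ``seed``.

    Two engines satisfy the separation contract (on linear mixtures of
    independent non-Gaussian sources, ``unmixing @ mixing`` is a permutation
    of a diagonal matrix): ``"fastica"`` (default — deflation-free parallel
    FastICA, roughly two orders of magnitude faster on session-length EEG)
    and ``"extended-infomax"`` (the classical EEG choice, via mne).  Both
    are tested against the same contract; the choice does not change the
    package's guarantees.
    """
    scores = np.asarray(scores, dtype=float)
    k, n = scores.shape
    if n < 50 * k:
        raise ValueError(f"need >= {50 * k} samples to estimate {k} components")
    # symmetric whitening; for PCA scores the covariance is already diagonal
    # and this reduces to per-row scaling
    Xc = scores - scores.mean(axis=1, keepdims=True)
    cov = Xc @ Xc.T / n
    lam, U = np.linalg.eigh(cov)
    if lam[0] <= 0 or lam[0] / lam[-1] < 1e-12:
        raise ValueError("rank-deficient input: a score dimension has no variance")
    white = U @ np.diag(lam**-0.5) @ U.T
    Y = (white @ Xc).T
    if engine == "fastica":
        import warnings as _warnings

        from sklearn.decomposition import FastICA
        from sklearn.exceptions import ConvergenceWarning

        max_iter = 1000 if max_iter is None else max_iter
        fica = FastICA(whiten=False, max_iter=max_iter, tol=1e-6,
                       random_state=int(seed))
        with _warnings.catch_warnings():
            _warnings.simplefilter("ignore", ConvergenceWarning)
            fica.fit(Y)
        if fica.n_iter_ >= max_iter:
            logger.info("FastICA hit the iteration cap (%d); residual rotation "
                        "of near-Gaussian components may remain", max_iter)
        W = fica.components_
    elif engine == "extended-infomax":
        from mne.preprocessing import infomax

        max_iter = 200 if max_iter is None else max_iter
        W = infomax(Y, extended=True, max_iter=max_iter,
                    random_state=int(seed), verbose="error")
    else:
        raise ValueError(f"unknown ICA engine {engine!r}")
    if not np.all(np.isfinite(W)):
        raise RuntimeError(f"ICA ({engine}) did not converge within {max_iter} iterations")
    return W @ white


def compose(
    basis: np.ndarray,
    unmixing: np.ndarray,
    mean: np.ndarray | None = None,
    state_tag: str = "",
) -> Decomposition:
    """Compose PCA basis and ICA unmixing into channel-space filters/patterns.

    ``filters = unmixing @ basis``; ``patterns`` is the Moore-Penrose
    pseudo-inverse of ``filters`` (the mixing columns generalized through the
    PC subspace).  ICA's sign/scale ambiguity is resolved by convention:
    each pattern column is scaled to unit norm with its largest-|value|
    electrode weight positive, the reciprocal scale going into the filter
    row.  A component's time course therefore carries the physical
    (microvolt-at-scalp) amplitude of its source, so hemispheric power
    asymmetries survive the decomposition instead of being normalized away.
    """
    basis = np.asarray(basis, dtype=float)
    unmixing = np.asarray(unmixing, dtype=float)
    if unmixing.shape[1] != basis.shape[0]:
        raise ValueError("unmixing/basis shapes do not conform")
    filters = unmixing @ basis
    patterns = np.linalg.pinv(filters)
    flip = np.sign(patterns[np.abs(patterns).argmax(axis=0), np.arange(patterns.shape[1])])
    flip[flip == 0] = 1.0
    scale = flip / np.linalg.norm(patterns, axis=0)
    patterns = patterns * scale[None, :]
    filters = filters / scale[:, None]
    if mean is None:
        mean = np.zeros(basis.shape[1])
    return Decomposition(basis, unmixing, filters, patterns, np.asarray(mean, float), state_tag)


def decompose_state(
    X: np.ndarray,
    n_components: int = N_COMPONENTS,
    seed: int = 0,
    state_tag: str = "",
    engine: str = "fastica",
) -> Decomposition:
    """Full PCA -> ICA -> compose pipeline on one training matrix."""
    basis, scores, mean = pca_reduce(X, n_components)
    unmix = run_ica(scores, seed=seed, engine=engine)
    return compose(basis, unmix, mean, state_tag)


def apply_filters(
    dec: Decomposition,
    X: np.ndarray,
    which: np.ndarray | list[int] | None = None,
    recenter: bool = True,
) -> ComponentTimecourse:
    """Apply selected spatial filters to channel data.

    ``X`` must use the decomposition's channel order.  With ``recenter``
    (default) the training channel means are subtracted first; the linear
    filters otherwise absorb all scaling.
    """
    X = np.asarray(X, dtype=float)
    if X.shape[0] != dec.filters.shape[1]:
        raise ValueError(
            f"data has {X.shape[0]} channels, decomposition expects {dec.filters.shape[1]}"
        )
    if recenter:
        X = X - dec.mean[:, None]
    idx = (np.arange(dec.n_components) if which is None
           else np.atleast_1d(np.asarray(which, dtype=int)))
    return ComponentTimecourse(dec.filters[idx] @ X, fs=np.nan)


def sign_normalize(v: np.ndarray) -> np.ndarray:
    """Flip a channel vector so its largest-|value| entry is positive."""
    v = np.asarray(v, dtype=float)
    s = np.sign(v[np.abs(v).argmax()])
    return v * (s if s != 0 else 1.0)


def pattern_correlation(p: np.ndarray, q: np.ndarray) -> float:
    """Pearson correlation of two sign-normalized channel vectors."""
    p = sign_normalize(p)
    q = sign_normalize(q)
    if p.shape != q.shape or p.size < 3:
        raise ValueError("vectors must have equal length >= 3")
    if p.std() == 0 or q.std() == 0:
        raise ValueError("zero-variance vector")
    return float(np.corrcoef(p, q)[0, 1])


def best_match_correlations(patterns: np.ndarray, targets: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """For each target column, the best-matching pattern column by absolute
    Pearson correlation.  Returns (indices, |r| values); resolves ICA's
    permutation/scale ambiguity in recovery tests."""
    k = targets.shape[1]
    idx = np.zeros(k, dtype=int)
    r = np.zeros(k)
    for j in range(k):
        cors = [abs(np.corrcoef(targets[:, j], patterns[:, i])[0, 1])
                for i in range(patterns.shape[1])]
        idx[j] = int(np.argmax(cors))
        r[j] = cors[idx[j]]
    return idx, r
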