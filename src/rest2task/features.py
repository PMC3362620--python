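"""Band-power features for the three compared methods.

All three methods reduce an imagery-window EEG segment to a two-dimensional
feature vector of accumulated 8-30 Hz power — one value per hemisphere —
differing only in the spatial projection applied first:

* monopolar: the raw C3 and C4 channels;
* ICA: the two selected motor-component spatial filters (which may come
  from the resting state, the imagery state, or another session — the
  caller's choice of filter source is what implements the translation);
* CSP: the two supervised common-spatial-pattern projections corresponding
  to the extreme eigenvalues.

Band power is computed by plain FFT with a rectangular window and a
Parseval normalization: summing the one-sided per-bin power over all bins
gives the segment's mean squared amplitude, so a unit sinusoid at a
bin-aligned frequency contributes exactly 0.5.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.linalg

from .decomposition import Decomposition, apply_filters

DEFAULT_BAND = (8.0, 30.0)


def band_power(
    x: np.ndarray, fs: float, band: tuple[float, float] = DEFAULT_BAND
) -> float | np.ndarray:
    """Accumulated one-sided FFT power in ``band`` (inclusive bin centres).

    Works on a single segment (last axis = time) or any stack of segments.
    Requires at least 0.5 s of data and a band inside Nyquist.
    """
    x = np.asarray(x, dtype=float)
    n = x.shape[-1]
    if n < 0.5 * fs:
        raise ValueError("segment shorter than 0.5 s")
    if not 0 <= band[0] < band[1] <= fs / 2:
        raise ValueError(f"band {band} outside [0, {fs / 2}] Hz")
    X = np.fft.rfft(x, axis=-1)
    p = np.abs(X) ** 2 / n**2
    # one-sided: double everything except DC and (for even n) Nyquist
    p[..., 1:] *= 2.0
    if n % 2 == 0:
        p[..., -1] /= 2.0
    f = np.fft.rfftfreq(n, d=1.0 / fs)
    sel = (f >= band[0]) & (f <= band[1])
    return p[..., sel].sum(axis=-1)


@dataclass
class FeatureVector:
    """Left/right accumulated band powers plus the method that produced them."""

    left: float
    right: float
    method: str

    def as_array(self) -> np.ndarray:
        return np.array([self.left, self.right])


def monopolar_features(
    segment: np.ndarray, channel_labels: list[str], fs: float,
    band: tuple[float, float] = DEFAULT_BAND,
    log_power: bool = False,
) -> FeatureVector:
    """(band power at C3, band power at C4) of one imagery segment."""
    lower = [c.lower() for c in channel_labels]
    try:
        i3, i4 = lower.index("c3"), lower.index("c4")
    except ValueError as exc:
        raise KeyError("electrodes C3 and C4 are required") from exc
    p3 = band_power(segment[i3], fs, band)
    p4 = band_power(segment[i4], fs, band)
    if log_power:
        p3, p4 = np.log(p3), np.log(p4)
    return FeatureVector(float(p3), float(p4), "monopolar")


def ica_features(
    segment: np.ndarray, dec: Decomposition, left_ic: int, right_ic: int, fs: float,
    band: tuple[float, float] = DEFAULT_BAND,
    log_power: bool = False,
) -> FeatureVector:
    """Band powers of the two motor-component time courses of one segment."""
    tc = apply_filters(dec, segment, [left_ic, right_ic])
    p = band_power(tc.data, fs, band)
    if log_power:
        p = np.log(p)
    return FeatureVector(float(p[0]), float(p[1]), "ica")


@dataclass
class CSPModel:
    """Two-filter common-spatial-patterns model.

    ``w_max``/``w_min`` are the channel-space projections with the highest
    and lowest generalized eigenvalue: maximal variance for class 1 relative
    to class 2 and vice versa.  ``eigenvalues`` is the full spectrum of the
    whitened class-1 covariance (values in (0, 1), classes sum to 1).
    """

    w_max: np.ndarray
    w_min: np.ndarray
    eigenvalues: np.ndarray


def _mean_normalized_cov(trials: np.ndarray) -> np.ndarray:
    covs = []
    for tr in trials:
        x = tr - tr.mean(axis=1, keepdims=True)
        c = x @ x.T
        covs.append(c / np.trace(c))
    return np.mean(covs, axis=0)


def csp_train(
    trials_class1: np.ndarray, trials_class2: np.ndarray, eps: float = 1e-10
) -> CSPModel:
    """Train two CSP filters on band-filtered imagery trials.

    Per-trial channel covariances are trace-normalized and averaged per
    class; the composite covariance is whitened; the whitened class-1
    covariance is eigendecomposed; and the eigenvectors of the largest and
    smallest eigenvalues are projected back to channel space.  Exactly two
    filters are produced to match the two-component ICA feature set.
    """
    if len(trials_class1) < 2 or len(trials_class2) < 2:
        raise ValueError("need at least 2 trials per class")
    c1 = _mean_normalized_cov(np.asarray(trials_class1, float))
    c2 = _mean_normalized_cov(np.asarray(trials_class2, float))
    comp = c1 + c2
    lam, U = np.linalg.eigh(comp)
    if lam[-1] <= 0 or lam[0] / lam[-1] < eps:
        raise np.linalg.LinAlgError(
            "singular composite covariance: add trials or regularize"
        )
    P = np.diag(lam**-0.5) @ U.T             # whitening: P comp P^T = I
    S1 = P @ c1 @ P.T
    mu, V = np.linalg.eigh(S1)               # ascending; class-2 spectrum is 1 - mu
    if mu[-1] - mu[0] < 1e-12:
        import logging

        logging.getLogger(__name__).warning(
            "degenerate CSP: class covariances are identical (all eigenvalues 0.5)"
        )
    W = V.T @ P                              # rows are channel-space filters
    return CSPModel(w_max=W[-1], w_min=W[0], eigenvalues=mu[::-1])


def csp_features(
    segment: np.ndarray, model: CSPModel, fs: float,
    band: tuple[float, float] = DEFAULT_BAND,
    log_power: bool = False,
) -> FeatureVector:
    """Band powers of the two CSP-projected time courses of one segment."""
    segment = np.asarray(segment, dtype=float)
    if segment.shape[0] != model.w_max.shape[0]:
        raise ValueError("segment channel count does not match CSP model")
    p_max = band_power(model.w_max @ segment, fs, band)
    p_min = band_power(model.w_min @ segment, fs, band)
    if log_power:
        p_max, p_min = np.log(p_max), np.log(p_min)
    return FeatureVector(float(p_max), float(p_min), "csp")


def csp_oracle(c1: np.ndarray, c2: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Independent reference solve of the CSP objective via the generalized
    eigenproblem c1 w = lambda (c1 + c2) w (dense solver).  Used to
    cross-check :func:`csp_train`, never as the implementation."""
    lam, V = scipy.linalg.eigh(c1, c1 + c2)
    return V[:, -1], V[:, 0]
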