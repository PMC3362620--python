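"""Fisher-discriminant classification, repeated cross-validation, the
zero-training baseline-weighted rule, and PSD/ERSP descriptive analyses.

The classifier is two-dimensional Fisher discriminant analysis: the weight
vector is ``S_w^-1 (m1 - m2)`` with the bias at the midpoint of the
projected class means.  Accuracy is estimated by repeated stratified k-fold
cross-validation (default 10 repetitions of 10 folds, reshuffled per
repetition from a seed).

The zero-training rule needs no labels at all: a trial is called left-hand
if its left motor-component power, divided by that component's mean resting
power, is at least the correspondingly weighted right-component power.
Dividing by the resting baseline cancels the hemispheric power asymmetry
that defeats the unweighted sign rule.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.signal import stft, welch
from sklearn.model_selection import StratifiedKFold

logger = logging.getLogger(__name__)


@dataclass
class FDAModel:
    """Linear discriminant: predicts ``classes[0]`` when w.x + b > 0."""

    w: np.ndarray
    bias: float
    classes: tuple

    def decision(self, X: np.ndarray) -> np.ndarray:
        return np.asarray(X, float) @ self.w + self.bias

    def predict(self, X: np.ndarray) -> np.ndarray:
        d = self.decision(X)
        return np.where(d > 0, self.classes[0], self.classes[1])


@dataclass
class CVResult:
    """Accuracies (%) from repeated k-fold cross-validation."""

    fold_accuracies: np.ndarray  # (repetitions, folds)

    @property
    def mean(self) -> float:
        return float(self.fold_accuracies.mean())

    @property
    def std(self) -> float:
        return float(self.fold_accuracies.mean(axis=1).std(ddof=1)) \
            if self.fold_accuracies.shape[0] > 1 else 0.0


@dataclass
class RestBaseline:
    """Mean resting band power of the left and right motor components."""

    mu_left: float
    mu_right: float

    def __post_init__(self) -> None:
        if self.mu_left <= 0 or self.mu_right <= 0:
            raise ValueError("baseline powers must be positive")


def fda_train(features: np.ndarray, labels: np.ndarray, ridge: float = 1e-8) -> FDAModel:
    """Fisher discriminant on n x d features with two classes.

    If the pooled within-class scatter is ill-conditioned a ridge of
    ``ridge * trace`` is added (logged).
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels)
    classes = tuple(np.unique(y))
    if len(classes) != 2:
        raise ValueError(f"exactly two classes required, got {len(classes)}")
    m1 = X[y == classes[0]].mean(axis=0)
    m2 = X[y == classes[1]].mean(axis=0)
    Sw = np.zeros((X.shape[1], X.shape[1]))
    for c, m in ((classes[0], m1), (classes[1], m2)):
        d = X[y == c] - m
        Sw += d.T @ d
    try:
        w = np.linalg.solve(Sw, m1 - m2)
    except np.linalg.LinAlgError:
        logger.info("singular within-class scatter: adding ridge")
        Sw = Sw + ridge * np.trace(Sw) * np.eye(Sw.shape[0])
        w = np.linalg.solve(Sw, m1 - m2)
    bias = -0.5 * float(w @ (m1 + m2))
    return FDAModel(w, bias, classes)


def cross_validate(
    features: np.ndarray,
    labels: np.ndarray,
    k: int = 10,
    repetitions: int = 10,
    seed: int = 0,
) -> CVResult:
    """Repeated stratified k-fold accuracy of the FDA classifier (%)."""
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels)
    _, counts = np.unique(y, return_counts=True)
    if counts.min() < k:
        raise ValueError(f"every class needs at least k={k} members")
    rng = np.random.default_rng(seed)
    acc = np.zeros((repetitions, k))
    for r in range(repetitions):
        skf = StratifiedKFold(n_splits=k, shuffle=True,
                              random_state=int(rng.integers(2**31)))
        for fold, (tr, te) in enumerate(skf.split(X, y)):
            model = fda_train(X[tr], y[tr])
            acc[r, fold] = 100.0 * np.mean(model.predict(X[te]) == y[te])
    return CVResult(acc)


def cross_validate_extractor(
    trials: np.ndarray,
    labels: np.ndarray,
    extractor_factory,
    k: int = 10,
    repetitions: int = 10,
    seed: int = 0,
) -> CVResult:
    """Repeated stratified k-fold where feature extraction itself is trained
    per fold (used for CSP, whose filters are supervised).

    ``extractor_factory(train_trials, train_labels)`` must return a callable
    mapping a single trial segment to a feature array.
    """
    trials = np.asarray(trials, dtype=float)
    y = np.asarray(labels)
    _, counts = np.unique(y, return_counts=True)
    if counts.min() < k:
        raise ValueError(f"every class needs at least k={k} members")
    rng = np.random.default_rng(seed)
    acc = np.zeros((repetitions, k))
    for r in range(repetitions):
        skf = StratifiedKFold(n_splits=k, shuffle=True,
                              random_state=int(rng.integers(2**31)))
        for fold, (tr, te) in enumerate(skf.split(trials[:, :, 0], y)):
            extract = extractor_factory(trials[tr], y[tr])
            Xtr = np.stack([extract(t) for t in trials[tr]])
            Xte = np.stack([extract(t) for t in trials[te]])
            model = fda_train(Xtr, y[tr])
            acc[r, fold] = 100.0 * np.mean(model.predict(Xte) == y[te])
    return CVResult(acc)


def zero_train_classify(
    p_left: np.ndarray | float, p_right: np.ndarray | float, baseline: RestBaseline
) -> np.ndarray | int:
    """Baseline-weighted sign rule: +1 (left hand) iff
    ``p_left / mu_left >= p_right / mu_right`` else -1 (right hand).

    Left-hand imagery desynchronizes the contralateral (right) motor
    component, leaving the weighted left power larger.  Ties return +1
    (probability-zero on real data; logged).
    """
    wl = np.asarray(p_left, dtype=float) / baseline.mu_left
    wr = np.asarray(p_right, dtype=float) / baseline.mu_right
    if np.any(wl == wr):
        logger.info("tie in zero-training rule resolved as +1")
    out = np.where(wl >= wr, 1, -1)
    return int(out) if out.ndim == 0 else out


def psd(x: np.ndarray, fs: float) -> tuple[np.ndarray, np.ndarray]:
    """Welch power spectral density: 1-s windows, 50% overlap."""
    x = np.asarray(x, dtype=float)
    nper = min(int(fs), x.shape[-1])
    return welch(x, fs=fs, nperseg=nper, noverlap=nper // 2, axis=-1)


def ersp(
    trials: np.ndarray,
    fs: float,
    baseline_window: tuple[float, float],
    window_sec: float = 0.25,
    overlap: float = 0.875,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Event-related spectral perturbation of single-component trials.

    Short-time spectra (250-ms windows, 87.5% overlap) are averaged over
    trials and expressed per frequency as ``10 log10(power / mean baseline
    power)``, where the baseline is the mean trial-averaged power over the
    time bins falling inside ``baseline_window`` (seconds, half-open).

    Returns ``(times, freqs, map)`` with ``map`` of shape (freq, time) in dB.
    """
    trials = np.atleast_2d(np.asarray(trials, dtype=float))
    nper = int(round(window_sec * fs))
    f, t, Z = stft(trials, fs=fs, nperseg=nper,
                   noverlap=int(round(overlap * nper)), axis=-1)
    power = (np.abs(Z) ** 2).mean(axis=0)            # (freq, time)
    lo, hi = baseline_window
    base_bins = (t >= lo) & (t < hi)
    if not base_bins.any():
        raise ValueError("baseline window contains no time bins")
    base = power[:, base_bins].mean(axis=1, keepdims=True)
    if np.any(base == 0):
        raise ValueError("zero baseline power")
    with np.errstate(divide="ignore"):  # silent bins legitimately read -inf dB
        return t, f, 10.0 * np.log10(power / base)
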