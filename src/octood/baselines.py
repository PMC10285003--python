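"""Comparison OoD detectors: SNR, Raw-MahaAD, Supervised, No-rejection.

All detectors follow the same estimator contract as
:class:`~octood.mahaad.MahaADDetector`: ``fit(X)`` on clean training
M-scans and ``ood_scores(X)`` returning one score per M-scan with
higher meaning more out-of-distribution.  The heatmap-entropy
"Uncertainty" baseline lives with the retina model
(:meth:`octood.retina.IlmHeatmapRegressor.uncertainty_scores`) and can
be wrapped with :class:`UncertaintyDetector`.
"""

from __future__ import annotations

import logging

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.neural_network import MLPClassifier

from .corruptions import SUPERVISED_TRAINING_TYPES, apply_corruption
from .features import preprocess
from .gaussian import ShrunkGaussian

logger = logging.getLogger(__name__)

__all__ = [
    "SNRDetector",
    "RawMahalanobisDetector",
    "SupervisedCorruptionDetector",
    "NoRejectionDetector",
    "UncertaintyDetector",
    "snr_score",
]


def snr_score(m: np.ndarray) -> float:
    """OoD score -mu/sigma of one M-scan (higher ⇒ more OoD).

    The signal-to-noise ratio mu/sigma over all pixels is a scan
    quality measure; the sign is flipped so that the canonical
    noisy-scan-is-degraded case ranks as more OoD.  A constant M-scan
    (sigma = 0) gets the -inf sentinel, i.e. maximally in-distribution.
    """
    m = np.asarray(m, dtype=np.float64)
    sd = m.std()
    if sd == 0:
        logger.warning("constant M-scan encountered in SNR scoring; "
                       "returning -inf sentinel")
        return -np.inf
    return float(-(m.mean() / sd))


class SNRDetector(BaseEstimator):
    """Stateless scan-quality baseline scoring -mean/std per M-scan."""

    def fit(self, X=None, y=None) -> "SNRDetector":
        self.is_fitted_ = True
        return self

    def ood_scores(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=np.float64)
        if X.ndim == 2:
            X = X[None]
        return np.array([snr_score(m) for m in X])

    def score_samples(self, X):
        return -self.ood_scores(X)


class RawMahalanobisDetector(BaseEstimator):
    """Raw-MahaAD: a single (K=1) Gaussian fitted on the raw signal.

    Each M-scan is flattened to a T*P vector (optionally the resized
    64x224 preprocessed image instead, ``use_resized=True``).  With a
    few hundred training scans and 6740 dimensions the sample
    covariance is far from full rank, so shrinkage is mandatory.
    """

    def __init__(self, shrinkage: str = "ledoit-wolf", eps: float = 1e-3,
                 use_resized: bool = False):
        self.shrinkage = shrinkage
        self.eps = eps
        self.use_resized = use_resized

    def _flatten(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=np.float64)
        if X.ndim == 2:
            X = X[None]
        if self.use_resized:
            return np.stack([preprocess(m)[0].ravel() for m in X])
        return X.reshape(X.shape[0], -1)

    def fit(self, X: np.ndarray, y=None) -> "RawMahalanobisDetector":
        V = self._flatten(X)
        self.gaussian_ = ShrunkGaussian(self.shrinkage, self.eps).fit(V)
        return self

    @property
    def K(self) -> int:
        return 1

    def ood_scores(self, X: np.ndarray) -> np.ndarray:
        return self.gaussian_.mahalanobis(self._flatten(X))

    def score_samples(self, X):
        return -self.ood_scores(X)


def _pooled_stats(img: np.ndarray, block: int = 4) -> np.ndarray:
    """Blockwise mean and std of one preprocessed channel (texture + brightness)."""
    h, w = img.shape[0] // block, img.shape[1] // block
    v = img[: h * block, : w * block].reshape(h, block, w, block)
    return np.concatenate([v.mean(axis=(1, 3)).ravel(), v.std(axis=(1, 3)).ravel()])


class SupervisedCorruptionDetector(BaseEstimator):
    """Supervised binary OoD classifier trained on synthetic corruptions.

    Half of the clean training M-scans are perturbed with the four
    training corruption types (noise, smoothing, shift, intensity); a
    small trainable classifier (multilayer perceptron on blockwise
    mean/std statistics of the preprocessed image) is fitted to
    separate clean from corrupted, and its predicted corruption
    probability is the OoD score.  By construction it has never seen
    stripes, rectangle, zoom or contrast corruptions.
    """

    def __init__(self, hidden: int = 64, max_iter: int = 500, seed: int = 0):
        self.hidden = hidden
        self.max_iter = max_iter
        self.seed = seed

    @property
    def training_ctypes(self) -> tuple[str, ...]:
        return SUPERVISED_TRAINING_TYPES

    def make_training_set(self, X: np.ndarray, rng: np.random.Generator):
        """Perturb 50% of the clean scans; returns (mscans, labels, specs)."""
        X = np.asarray(X, dtype=np.float64)
        n = X.shape[0]
        if n < 4:
            raise ValueError("need at least 4 training M-scans")
        k = n // 2
        idx = rng.choice(n, size=k, replace=False)
        out = X.copy()
        labels = np.zeros(n, dtype=np.int64)
        specs = [None] * n
        for i in idx:
            ctype = self.training_ctypes[rng.integers(len(self.training_ctypes))]
            out[i], specs[i] = apply_corruption(X[i], ctype, rng)
            labels[i] = 1
        return out, labels, specs

    def _vectors(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=np.float64)
        if X.ndim == 2:
            X = X[None]
        return np.stack([_pooled_stats(preprocess(m)[0]) for m in X])

    def fit(self, X: np.ndarray, y=None) -> "SupervisedCorruptionDetector":
        rng = np.random.default_rng(self.seed)
        scans, labels, self.training_specs_ = self.make_training_set(X, rng)
        if labels.min() == labels.max():
            raise ValueError("degenerate class balance in supervised training set")
        self.classifier_ = MLPClassifier(
            hidden_layer_sizes=(self.hidden,),
            max_iter=self.max_iter,
            random_state=self.seed,
        )
        self.classifier_.fit(self._vectors(scans), labels)
        self.training_labels_ = labels
        return self

    def ood_scores(self, X: np.ndarray) -> np.ndarray:
        return self.classifier_.predict_proba(self._vectors(X))[:, 1]

    def score_samples(self, X):
        return -self.ood_scores(X)


class NoRejectionDetector(BaseEstimator):
    """Reference baseline: every sample is an inlier (constant score 0).

    Under top-p rejection the all-equal scores are resolved by the
    documented stable order, so the first round(p*n) dataset entries
    are rejected.
    """

    def fit(self, X=None, y=None) -> "NoRejectionDetector":
        self.is_fitted_ = True
        return self

    def ood_scores(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X)
        n = 1 if X.ndim == 2 else X.shape[0]
        return np.zeros(n)

    def score_samples(self, X):
        return -self.ood_scores(X)


class UncertaintyDetector(BaseEstimator):
    """Heatmap-entropy baseline wrapping a trained retina model."""

    def __init__(self, model):
        self.model = model

    def fit(self, X=None, y=None) -> "UncertaintyDetector":
        self.is_fitted_ = True
        return self

    def ood_scores(self, X: np.ndarray) -> np.ndarray:
        return self.model.uncertainty_scores(X)

    def score_samples(self, X):
        return -self.ood_scores(X)
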