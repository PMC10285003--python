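"""MahaAD: Mahalanobis-distance out-of-distribution detection on deep features.

The detector describes each training M-scan by K spatially-averaged
feature vectors (one per stage of a feature pyramid) and fits one
multivariate Gaussian per stage: mean

    mu_k = (1/N) sum_i f_{i,k}

and biased covariance

    Sigma_k = (1/N) sum_i (f_{i,k} - mu_k)(f_{i,k} - mu_k)^T,

regularized for invertibility (see :mod:`octood.gaussian`).  A test
M-scan x is scored by the sum of per-stage Mahalanobis distances

    s(x) = sum_k d_k(x),   d_k = sqrt((f_k - mu_k)^T Sigma_k^{-1} (f_k - mu_k)),

and declared out-of-distribution when s(x) strictly exceeds the single
hyperparameter tau, in which case all T A-scans of the M-scan are
treated as unreliable for the downstream distance-estimation model.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator

from .features import FeatureExtractor, make_test_extractor, preprocess
from .gaussian import ShrunkGaussian

__all__ = [
    "GaussianBank",
    "OodScore",
    "MahaADDetector",
    "fit_gaussian_bank",
    "threshold_from_quantile",
]


@dataclass
class OodScore:
    """Per-stage distances, their sum, and the thresholded decision."""

    stage_distances: np.ndarray  # (K,)
    score: float
    is_ood: bool | None = None


class GaussianBank:
    """Per-stage Gaussians (mu_k, regularized Sigma_k) for k = 1..K."""

    def __init__(self, stages: list[ShrunkGaussian]):
        if not stages:
            raise ValueError("bank needs at least one stage")
        self.stages = stages

    @property
    def K(self) -> int:
        return len(self.stages)

    @property
    def dims(self) -> tuple[int, ...]:
        return tuple(g.dim_ for g in self.stages)

    def stage_distance(self, features: list[np.ndarray], k: int) -> np.ndarray:
        """Mahalanobis distance d_k for stage ``k`` (batched)."""
        return self.stages[k].mahalanobis(features[k])

    def score(self, features: list[np.ndarray]) -> np.ndarray:
        """Summed distance s = sum_k d_k for each sample (batched)."""
        if len(features) != self.K:
            raise ValueError(f"expected {self.K} stages, got {len(features)}")
        return sum(self.stage_distance(features, k) for k in range(self.K))

    def stage_distances(self, features: list[np.ndarray]) -> np.ndarray:
        """All per-stage distances; shape ``(n, K)``."""
        return np.stack(
            [self.stage_distance(features, k) for k in range(self.K)], axis=1
        )

    # -- serialization -------------------------------------------------
    def save(self, path: str | os.PathLike) -> None:
        arrays = {}
        meta = []
        for k, g in enumerate(self.stages):
            arrays[f"mean_{k}"] = g.mean_
            arrays[f"eigvecs_{k}"] = g.eigvecs_
            arrays[f"eigvals_{k}"] = g.eigvals_
            meta.append(
                {
                    "shrinkage": g.shrinkage,
                    "eps": g.eps,
                    "scale": g.scale_,
                    "alpha": g.alpha_,
                    "n_samples": g.n_samples_,
                    "dim": g.dim_,
                }
            )
        np.savez(path, **arrays)
        with open(str(path).removesuffix(".npz") + ".json", "w") as fh:
            json.dump({"K": self.K, "stages": meta}, fh, indent=1)

    @classmethod
    def load(cls, path: str | os.PathLike) -> "GaussianBank":
        base = str(path).removesuffix(".npz")
        with open(base + ".json") as fh:
            meta = json.load(fh)
        stages = []
        with np.load(base + ".npz") as z:
            for k, sm in enumerate(meta["stages"]):
                g = ShrunkGaussian(shrinkage=sm["shrinkage"], eps=sm["eps"])
                g.mean_ = z[f"mean_{k}"]
                g.eigvecs_ = z[f"eigvecs_{k}"]
                g.eigvals_ = z[f"eigvals_{k}"]
                g.scale_ = sm["scale"]
                g.alpha_ = sm["alpha"]
                g.n_samples_ = sm["n_samples"]
                g.dim_ = sm["dim"]
                ev = g.scale_ * g.eigvals_
                g._beta = ev / (ev + g.alpha_) if g.alpha_ > 0 else None
                stages.append(g)
        return cls(stages)


def fit_gaussian_bank(
    train_features: list[np.ndarray],
    shrinkage: str = "ledoit-wolf",
    eps: float = 1e-3,
) -> GaussianBank:
    """Fit one regularized Gaussian per feature stage.

    ``train_features[k]`` holds the ``(N, dims[k])`` matrix of stage-k
    vectors over the N training samples; N must be at least 2.
    """
    stages = []
    n_ref = None
    for k, X in enumerate(train_features):
        X = np.asarray(X, dtype=np.float64)
        if n_ref is None:
            n_ref = X.shape[0]
        elif X.shape[0] != n_ref:
            raise ValueError(f"stage {k} has {X.shape[0]} samples, expected {n_ref}")
        stages.append(ShrunkGaussian(shrinkage=shrinkage, eps=eps).fit(X))
    return GaussianBank(stages)


def threshold_from_quantile(train_scores: np.ndarray, q: float) -> float:
    """tau helper: the q-quantile of the training-set OoD scores."""
    return float(np.quantile(np.asarray(train_scores, dtype=np.float64), q))


class MahaADDetector(BaseEstimator):
    """Unsupervised M-scan OoD detector (scikit-learn style estimator).

    Parameters
    ----------
    extractor : FeatureExtractor or None
        Feature pyramid; ``None`` builds the seeded random 9-stage
        pyramid.  Extractors with ``expects_preprocessed=False`` (e.g.
        the flattening extractor of the raw-signal baseline) receive
        raw M-scans.
    shrinkage : {"ledoit-wolf", "diag", "none"}
        Covariance regularization per stage.
    eps : float
        Diagonal loading strength when ``shrinkage="diag"``.
    tau : float or None
        Decision threshold; a sample is OoD iff score > tau (strict).
        ``None`` leaves only rank-based use (scores, top-p rejection).

    Attributes
    ----------
    bank_ : GaussianBank
        The fitted per-stage Gaussians.
    extractor_ : FeatureExtractor
        The extractor actually used.
    train_scores_ : ndarray
        OoD scores of the training set under the fitted bank, for
        quantile-based threshold calibration.
    """

    def __init__(
        self,
        extractor: FeatureExtractor | None = None,
        shrinkage: str = "ledoit-wolf",
        eps: float = 1e-3,
        tau: float | None = None,
    ):
        self.extractor = extractor
        self.shrinkage = shrinkage
        self.eps = eps
        self.tau = tau

    # ------------------------------------------------------------------
    def _features(self, X: np.ndarray) -> list[np.ndarray]:
        X = np.asarray(X, dtype=np.float64)
        if X.ndim == 2:
            X = X[None]
        ex = self.extractor_
        inputs = (preprocess(m) for m in X) if ex.expects_preprocessed else iter(X)
        return ex.extract_batch(inputs)

    def fit(self, X: np.ndarray, y=None) -> "MahaADDetector":
        """Fit the Gaussian bank on clean training M-scans ``(n, T, P)``."""
        self.extractor_ = self.extractor or make_test_extractor(0)
        feats = self._features(X)
        self.bank_ = fit_gaussian_bank(feats, self.shrinkage, self.eps)
        self.train_scores_ = self.bank_.score(feats)
        self.threshold_ = self.tau
        return self

    def ood_scores(self, X: np.ndarray) -> np.ndarray:
        """s(x) per M-scan; higher means more out-of-distribution."""
        return self.bank_.score(self._features(X))

    def stage_distances(self, X: np.ndarray) -> np.ndarray:
        """Per-stage distances d_k; shape ``(n, K)``."""
        return self.bank_.stage_distances(self._features(X))

    def score_samples(self, X: np.ndarray) -> np.ndarray:
        """scikit-learn orientation: higher = more normal (negated s)."""
        return -self.ood_scores(X)

    def set_threshold_from_quantile(self, q: float = 0.99) -> float:
        """Set tau to the q-quantile of the training scores; returns tau."""
        self.threshold_ = threshold_from_quantile(self.train_scores_, q)
        return self.threshold_

    def is_ood(self, X: np.ndarray) -> np.ndarray:
        """Boolean per-M-scan decision, s > tau strictly."""
        if self.threshold_ is None:
            raise ValueError("no threshold set; pass tau or call "
                             "set_threshold_from_quantile()")
        return self.ood_scores(X) > self.threshold_

    def predict(self, X: np.ndarray) -> np.ndarray:
        """scikit-learn outlier convention: +1 inlier, -1 outlier."""
        return np.where(self.is_ood(X), -1, 1)

    def classify_mscan(self, score: float, tau: float | None = None, T: int = 10) -> np.ndarray:
        """Propagate one M-scan decision to its T A-scans (all-or-none)."""
        tau = self.threshold_ if tau is None else tau
        if tau is None:
            raise ValueError("tau must be set")
        return np.full(T, bool(score > tau))
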