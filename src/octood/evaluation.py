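"""The two evaluation protocols: rejection/MAE curves and AUROC/AP.

Rejection protocol: a clean annotated test set is corrupted at ratio p,
every M-scan is scored by a detector, the top-p highest-scoring M-scans
are rejected, and the downstream ILM model's mean absolute error (MAE)
is computed on the retained A-scans against the *pre-corruption*
annotations (the corruption is a fault, not a new ground truth).  A
perfect detector rejects exactly the corrupted scans, keeping the MAE
flat as p grows.

Detection protocol: scores plus binary corruption labels are reduced to
AUROC and average precision; a per-corruption-type report isolates each
corruption at p = 0.5.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import average_precision_score, roc_auc_score

from .corruptions import (
    CORRUPTION_TYPES,
    SUPERVISED_UNSEEN_TYPES,
    corrupt_dataset,
    round_half_up,
)
from .retina import MICRONS_PER_PIXEL

__all__ = [
    "EvalCurve",
    "DetectionResult",
    "topp_reject",
    "detection_metrics",
    "rejection_experiment",
    "per_corruption_report",
    "oracle_scorer",
    "random_scorer",
]


@dataclass
class EvalCurve:
    """Per-p MAE of one detector in the rejection protocol."""

    method: str
    p_grid: np.ndarray
    mae_px: np.ndarray
    n_retained: np.ndarray

    @property
    def mae_um(self) -> np.ndarray:
        return MICRONS_PER_PIXEL * self.mae_px

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "method": self.method,
                "p": self.p_grid,
                "mae_px": self.mae_px,
                "mae_um": self.mae_um,
                "n_retained": self.n_retained,
            }
        )


@dataclass
class DetectionResult:
    """Scores, binary labels (1 = OoD) and threshold-free metrics."""

    scores: np.ndarray
    labels: np.ndarray
    auroc: float = field(init=False)
    average_precision: float = field(init=False)

    def __post_init__(self) -> None:
        scores = np.asarray(self.scores, dtype=np.float64)
        labels = np.asarray(self.labels)
        if not set(np.unique(labels)) <= {0, 1}:
            raise ValueError("labels must be binary 0/1")
        if labels.min() == labels.max():
            raise ValueError("AUROC/AP undefined with a single class present")
        self.scores, self.labels = scores, labels.astype(np.int64)
        self.auroc = float(roc_auc_score(self.labels, scores))
        self.average_precision = float(average_precision_score(self.labels, scores))


def detection_metrics(scores: np.ndarray, labels: np.ndarray) -> DetectionResult:
    """AUROC (midrank tie handling) and AP for OoD scores vs labels."""
    return DetectionResult(scores=scores, labels=labels)


def topp_reject(scores: np.ndarray, p: float) -> np.ndarray:
    """Indices of the round(p*n) highest-scoring samples.

    Ties are broken by stable dataset order (earlier index rejected
    first).  Returned indices are in rank order.
    """
    if not 0.0 <= p <= 1.0:
        raise ValueError("p must be in [0, 1]")
    scores = np.asarray(scores, dtype=np.float64)
    k = round_half_up(p * scores.shape[0])
    if k == 0:
        return np.array([], dtype=np.int64)
    order = np.argsort(-scores, kind="stable")
    return order[:k]


def oracle_scorer(X, labels):
    """Perfect detector: scores equal the corruption labels."""
    return np.asarray(labels, dtype=np.float64)


def random_scorer(seed: int = 0):
    """Detector assigning i.i.d. uniform scores (worst-case ranking)."""
    rng = np.random.default_rng(seed)

    def scorer(X, labels):
        return rng.random(np.asarray(labels).shape[0])

    return scorer


def _resolve_scorer(detector):
    if hasattr(detector, "ood_scores"):
        return lambda X, labels: detector.ood_scores(X)
    if callable(detector):
        return detector
    raise TypeError("detector must expose ood_scores(X) or be callable(X, labels)")


DEFAULT_P_GRID = np.round(np.arange(0.0, 0.91, 0.1), 10)


def rejection_experiment(
    mscans: np.ndarray,
    ilm: np.ndarray,
    detector,
    retina_model,
    p_grid=None,
    seed: int = 0,
    method: str | None = None,
) -> EvalCurve:
    """Rejection/MAE curve of one detector over the corruption-ratio grid.

    Parameters
    ----------
    mscans : (n, T, P) clean test M-scans.
    ilm : (n, T) pre-corruption ILM annotations (the MAE ground truth).
    detector : fitted detector with ``ood_scores`` or callable
        ``scorer(X_corrupted, labels) -> scores`` (oracle/random use the
        labels).
    retina_model : trained :class:`~octood.retina.IlmHeatmapRegressor`.
    p_grid : iterable of corruption ratios; default {0, 0.1, ..., 0.9}.
    seed : corruption randomness (independent stream per p).
    """
    mscans = np.asarray(mscans, dtype=np.float64)
    ilm = np.asarray(ilm)
    p_grid = DEFAULT_P_GRID if p_grid is None else np.asarray(list(p_grid), float)
    scorer = _resolve_scorer(detector)
    n = mscans.shape[0]
    streams = np.random.SeedSequence(seed).spawn(len(p_grid))

    mae = np.empty(len(p_grid))
    n_ret = np.empty(len(p_grid), dtype=np.int64)
    for j, p in enumerate(p_grid):
        rng = np.random.default_rng(streams[j])
        corrupted, labels, _ = corrupt_dataset(mscans, float(p), rng)
        scores = np.asarray(scorer(corrupted, labels), dtype=np.float64)
        rejected = topp_reject(scores, float(p))
        retained = np.setdiff1d(np.arange(n), rejected)
        n_ret[j] = retained.size
        pred = retina_model.predict(corrupted[retained])
        mae[j] = float(np.mean(np.abs(pred - ilm[retained])))
    name = method or getattr(detector, "__class__", type(detector)).__name__
    return EvalCurve(method=name, p_grid=p_grid, mae_px=mae, n_retained=n_ret)


def per_corruption_report(
    mscans: np.ndarray,
    detectors: dict[str, object],
    p: float = 0.5,
    seed: int = 0,
    ctypes=CORRUPTION_TYPES,
) -> pd.DataFrame:
    """Isolated per-corruption-type AUROC at ratio ``p`` for each detector.

    Each type is applied on its own to round(p*n) of the clean test
    M-scans; every (fitted) detector then scores the mixed set.  The
    returned long-format frame has columns ``method``, ``ctype``,
    ``auroc`` and ``unseen_by_supervised`` (the four types the
    Supervised baseline never trains on).
    """
    mscans = np.asarray(mscans, dtype=np.float64)
    streams = np.random.SeedSequence(seed).spawn(len(ctypes))
    rows = []
    for ct, ss in zip(ctypes, streams):
        rng = np.random.default_rng(ss)
        corrupted, labels, _ = corrupt_dataset(mscans, p, rng, ctypes=(ct,))
        for name, det in detectors.items():
            scorer = _resolve_scorer(det)
            res = detection_metrics(scorer(corrupted, labels), labels)
            rows.append((name, ct, res.auroc, ct in SUPERVISED_UNSEEN_TYPES))
    return pd.DataFrame(rows, columns=["method", "ctype", "auroc",
                                       "unseen_by_supervised"])
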