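"""Downstream instrument-to-retina distance estimation.

A 1-D U-Net-like network maps each A-scan (length P) to a heatmap over
depth giving the probability that the internal limiting membrane (ILM)
lies at each pixel; the argmax is the predicted ILM index and the
physical distance is ``index * 3.7`` micrometers (the probe's depth
sampling).  Training minimises the L2 loss against unit-peak Gaussian
target heatmaps centered on the annotated ILM, with Adam (lr 1e-4) and
early stopping on a validation split.

The heatmap also yields the "Uncertainty" OoD baseline: the Shannon
entropy of the normalised heatmap, averaged over an M-scan's A-scans
(degraded inputs tend to produce flatter, higher-entropy heatmaps).
"""

from __future__ import annotations

import json
import os

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin

from .nn import Adam, UNet1D, mse_loss

__all__ = [
    "MICRONS_PER_PIXEL",
    "make_target",
    "heatmap_entropy",
    "IlmHeatmapRegressor",
]

MICRONS_PER_PIXEL = 3.7


def make_target(ilm_index: np.ndarray | int, P: int, sigma: float = 3.0) -> np.ndarray:
    """Unit-peak Gaussian target heatmap(s) centered at the ILM index.

    ``sigma`` is the target width in pixels; the limit sigma -> 0 gives
    a one-hot vector.  Accepts a scalar index or an array of indices and
    returns ``(P,)`` or ``(n, P)``.
    """
    idx = np.asarray(ilm_index)
    scalar = idx.ndim == 0
    idx = np.atleast_1d(idx).astype(np.float64)
    if np.any((idx < 0) | (idx >= P)):
        raise ValueError(f"ILM index out of range [0, {P})")
    d = np.arange(P, dtype=np.float64)[None, :] - idx[:, None]
    if sigma <= 0:
        target = (d == 0).astype(np.float64)
    else:
        target = np.exp(-0.5 * (d / sigma) ** 2)
    return target[0] if scalar else target


def heatmap_entropy(heatmap: np.ndarray) -> np.ndarray:
    """Shannon entropy (nats) of heatmap(s) normalised over depth.

    An all-zero heatmap is treated as uniform (maximal entropy).
    """
    h = np.atleast_2d(np.asarray(heatmap, dtype=np.float64))
    P = h.shape[-1]
    total = h.sum(axis=-1, keepdims=True)
    uniform = total[:, 0] <= 0
    with np.errstate(invalid="ignore", divide="ignore"):
        q = np.where(total > 0, h / np.where(total > 0, total, 1.0), 1.0 / P)
        ent = -np.sum(np.where(q > 0, q * np.log(q), 0.0), axis=-1)
    ent[uniform] = np.log(P)
    return ent if heatmap_ndim(heatmap) > 1 else ent[0]


def heatmap_ndim(x) -> int:
    return np.asarray(x).ndim


def _pad_length(P: int) -> int:
    return ((P + 15) // 16) * 16


class IlmHeatmapRegressor(BaseEstimator, RegressorMixin):
    """Per-A-scan ILM localisation by heatmap regression (1-D U-Net).

    Parameters
    ----------
    base_channels : int
        Encoder width at the first level (doubles per level).
    sigma_gt : float
        Width (px) of the Gaussian target heatmaps.
    lr : float
        Adam learning rate (study default 1e-4).
    batch_size : int
    max_epochs : int
    patience : int
        Early-stopping patience in epochs on the validation loss.
    val_fraction : float
        Fraction of the training M-scans held out for validation when
        no explicit validation split is passed to :meth:`fit`.
    seed : int

    Attributes
    ----------
    net_ : UNet1D
        Trained network (best validation weights restored).
    history_ : dict
        Per-epoch train/validation losses and the early-stop epoch.
    """

    def __init__(self, base_channels: int = 16, sigma_gt: float = 3.0,
                 lr: float = 1e-4, batch_size: int = 64, max_epochs: int = 60,
                 patience: int = 10, val_fraction: float = 0.15, seed: int = 0):
        self.base_channels = base_channels
        self.sigma_gt = sigma_gt
        self.lr = lr
        self.batch_size = batch_size
        self.max_epochs = max_epochs
        self.patience = patience
        self.val_fraction = val_fraction
        self.seed = seed

    # ------------------------------------------------------------------
    def _ascan_arrays(self, X: np.ndarray, y: np.ndarray):
        """Flatten (n, T, P) M-scans / (n, T) ILM indices to A-scan level."""
        X = np.asarray(X, dtype=np.float64)
        y = np.asarray(y)
        if X.ndim == 2:  # already A-scans
            ascans, idx = X, y.reshape(-1)
        else:
            ascans = X.reshape(-1, X.shape[-1])
            idx = y.reshape(-1)
        if ascans.shape[0] != idx.shape[0]:
            raise ValueError("X and y disagree on the number of A-scans")
        return ascans, idx

    def _prepare(self, ascans: np.ndarray) -> np.ndarray:
        P = self.P_
        if ascans.shape[-1] != P:
            raise ValueError(f"expected A-scans of length {P}, got {ascans.shape[-1]}")
        Lp = _pad_length(P)
        left = (Lp - P) // 2
        x = np.pad(ascans / 255.0, ((0, 0), (left, Lp - P - left)), mode="edge")
        return x[:, None, :].astype(np.float32)

    def fit(self, X, y, X_val=None, y_val=None) -> "IlmHeatmapRegressor":
        """Train on M-scans ``X`` (n, T, P) with ILM indices ``y`` (n, T)."""
        X = np.asarray(X, dtype=np.float64)
        if X.size == 0:
            raise ValueError("empty training set")
        self.P_ = int(X.shape[-1])
        rng = np.random.default_rng(self.seed)

        if X_val is None:
            n = X.shape[0] if X.ndim == 3 else X.shape[0]
            n_val = max(1, int(round(self.val_fraction * n)))
            if n - n_val < 1:
                raise ValueError("training split is empty after validation split")
            perm = rng.permutation(n)
            val_ids, train_ids = perm[:n_val], perm[n_val:]
            X, X_val = X[train_ids], X[val_ids]
            y = np.asarray(y)
            y, y_val = y[train_ids], y[val_ids]

        tr_a, tr_i = self._ascan_arrays(X, y)
        va_a, va_i = self._ascan_arrays(X_val, y_val)

        Lp = _pad_length(self.P_)
        left = (Lp - self.P_) // 2
        self._crop = (left, left + self.P_)

        def targets(idx):
            t = np.zeros((idx.shape[0], 1, Lp), dtype=np.float32)
            t[:, 0, left : left + self.P_] = make_target(idx, self.P_, self.sigma_gt)
            return t

        xt, yt = self._prepare(tr_a), targets(tr_i)
        xv, yv = self._prepare(va_a), targets(va_i)

        net = UNet1D(self.base_channels, rng=np.random.default_rng(rng.integers(2**31)))
        opt = Adam(net.params, lr=self.lr)
        n_train = xt.shape[0]
        best_val, best_weights, best_epoch = np.inf, net.get_weights(), -1
        history = {"train_loss": [], "val_loss": []}
        since_best = 0
        for epoch in range(self.max_epochs):
            order = rng.permutation(n_train)
            ep_loss = 0.0
            for start in range(0, n_train, self.batch_size):
                b = order[start : start + self.batch_size]
                pred = net.forward(xt[b], train=True)
                loss, dpred = mse_loss(pred, yt[b])
                opt.step(net.backward(dpred))
                ep_loss += loss * len(b)
            history["train_loss"].append(ep_loss / n_train)
            val_loss = self._eval_loss(net, xv, yv)
            history["val_loss"].append(val_loss)
            if val_loss < best_val - 1e-12:
                best_val, best_epoch, since_best = val_loss, epoch, 0
                best_weights = net.get_weights()
            else:
                since_best += 1
                if since_best >= self.patience:
                    break
        net.set_weights(best_weights)
        self.net_ = net
        self.history_ = {**history, "best_epoch": best_epoch, "best_val_loss": best_val}
        return self

    @staticmethod
    def _eval_loss(net, x, y, chunk: int = 256) -> float:
        total = 0.0
        for s in range(0, x.shape[0], chunk):
            pred = net.forward(x[s : s + chunk])
            total += float(np.sum((pred - y[s : s + chunk]) ** 2))
        return total / y.size

    # ------------------------------------------------------------------
    def predict_heatmaps(self, ascans: np.ndarray, chunk: int = 512) -> np.ndarray:
        """Heatmaps over depth for A-scans ``(n, P)``; values in [0, 1]."""
        ascans = np.atleast_2d(np.asarray(ascans, dtype=np.float64))
        x = self._prepare(ascans)
        lo, hi = self._crop
        out = np.empty((x.shape[0], self.P_), dtype=np.float64)
        for s in range(0, x.shape[0], chunk):
            out[s : s + chunk] = self.net_.forward(x[s : s + chunk])[:, 0, lo:hi]
        # the regression head is linear; clip to the heatmap's [0, 1] range
        return np.clip(out, 0.0, 1.0)

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Predicted ILM index per A-scan (argmax; ties -> smallest index).

        ``X`` may be ``(P,)``, ``(n, P)`` A-scans or ``(n, T, P)``
        M-scans; the output matches the leading shape.
        """
        X = np.asarray(X, dtype=np.float64)
        lead = X.shape[:-1]
        h = self.predict_heatmaps(X.reshape(-1, X.shape[-1]))
        idx = np.argmax(h, axis=-1)  # np.argmax returns the first maximum
        return idx.reshape(lead) if lead else int(idx[0])

    def predict_distance_um(self, X: np.ndarray) -> np.ndarray:
        """Predicted probe-to-ILM distance in micrometers."""
        return np.asarray(self.predict(X), dtype=np.float64) * MICRONS_PER_PIXEL

    def uncertainty_scores(self, X: np.ndarray) -> np.ndarray:
        """"Uncertainty" OoD baseline: mean heatmap entropy per M-scan."""
        X = np.asarray(X, dtype=np.float64)
        if X.ndim == 2:
            X = X[None]
        ent = heatmap_entropy(self.predict_heatmaps(X.reshape(-1, X.shape[-1])))
        return ent.reshape(X.shape[0], X.shape[1]).mean(axis=1)

    # -- serialization -------------------------------------------------
    def save(self, path: str | os.PathLike) -> None:
        base = str(path).removesuffix(".npz")
        np.savez(base + ".npz",
                 **{f"w_{i:03d}": p for i, p in enumerate(self.net_.params)})
        meta = {"params": self.get_params(), "P": self.P_, "history": self.history_}
        with open(base + ".json", "w") as fh:
            json.dump(meta, fh, indent=1)

    @classmethod
    def load(cls, path: str | os.PathLike) -> "IlmHeatmapRegressor":
        base = str(path).removesuffix(".npz")
        with open(base + ".json") as fh:
            meta = json.load(fh)
        model = cls(**meta["params"])
        model.P_ = meta["P"]
        Lp = _pad_length(model.P_)
        left = (Lp - model.P_) // 2
        model._crop = (left, left + model.P_)
        model.history_ = meta["history"]
        net = UNet1D(model.base_channels)
        with np.load(base + ".npz") as z:
            net.set_weights([z[k] for k in sorted(z.files)])
        model.net_ = net
        return model
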