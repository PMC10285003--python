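"""Regularized multivariate Gaussian with fast Mahalanobis distances.

The detector fits one Gaussian per feature stage with the biased (1/N)
sample covariance.  Late-stage feature dimensionalities typically exceed
the training count, so the raw covariance is singular and must be
regularized before inversion.  All regularizations here share the form

    Sigma_reg = c * S + alpha * I

with S the 1/N sample covariance.  Three methods are supported:

* ``"ledoit-wolf"`` (default): shrinkage toward the scaled identity,
  c = 1 - rho, alpha = rho * tr(S)/d, with intensity rho estimated by
  the Ledoit-Wolf formula (scikit-learn's estimator).
* ``"diag"``: diagonal loading, c = 1, alpha = eps * tr(S)/d.
* ``"none"``: no regularization; fitting fails if S is singular.

S is stored through the economy eigendecomposition of the centered data
(rank r <= min(N, d)), so Mahalanobis distances cost O(d*r) per sample
via the Woodbury identity — this keeps the raw-signal baseline (d=6740,
N a few hundred) cheap without ever forming a d x d matrix.
"""

from __future__ import annotations

import numpy as np
from sklearn.covariance import ledoit_wolf_shrinkage

__all__ = ["ShrunkGaussian"]

# alpha floor for the degenerate zero-variance case (all samples identical):
# the regularized covariance then degrades gracefully to eps * I.
_ALPHA_FLOOR = 1e-6


class ShrunkGaussian:
    """Mean + regularized covariance of one feature stage.

    Parameters
    ----------
    shrinkage : {"ledoit-wolf", "diag", "none"}
        Covariance regularization method.
    eps : float
        Relative diagonal loading strength for ``shrinkage="diag"``.
    """

    def __init__(self, shrinkage: str = "ledoit-wolf", eps: float = 1e-3):
        if shrinkage not in ("ledoit-wolf", "diag", "none"):
            raise ValueError(f"unknown shrinkage method {shrinkage!r}")
        self.shrinkage = shrinkage
        self.eps = float(eps)

    def fit(self, X: np.ndarray) -> "ShrunkGaussian":
        """Fit mean and 1/N covariance of ``X`` (shape ``(N, d)``), N >= 2."""
        X = np.asarray(X, dtype=np.float64)
        if X.ndim != 2:
            raise ValueError(f"expected (N, d) features, got shape {X.shape}")
        N, d = X.shape
        if N < 2:
            raise ValueError(f"need at least 2 samples to fit a covariance, got {N}")
        self.n_samples_ = N
        self.dim_ = d
        self.mean_ = X.mean(axis=0)
        Xc = X - self.mean_
        # economy SVD: S = (1/N) Xc^T Xc = V diag(lam) V^T with rank <= min(N, d)
        _, s, Vt = np.linalg.svd(Xc, full_matrices=False)
        lam = s * s / N
        keep = lam > max(lam[0], 1.0) * 1e-15 if lam.size else np.zeros(0, bool)
        self.eigvecs_ = Vt[keep].T          # (d, r)
        self.eigvals_ = lam[keep]           # (r,)
        trace = float(lam.sum())
        mu = trace / d

        if self.shrinkage == "ledoit-wolf":
            rho = float(ledoit_wolf_shrinkage(X)) if trace > 0 else 1.0
            self.scale_ = 1.0 - rho
            self.alpha_ = max(rho * mu, _ALPHA_FLOOR)
        elif self.shrinkage == "diag":
            self.scale_ = 1.0
            self.alpha_ = max(self.eps * mu, _ALPHA_FLOOR)
        else:  # "none"
            if self.eigvals_.size < d:
                raise np.linalg.LinAlgError(
                    f"covariance is singular (rank {self.eigvals_.size} < dim {d}); "
                    "use shrinkage='ledoit-wolf' or 'diag'"
                )
            self.scale_ = 1.0
            self.alpha_ = 0.0
        # Woodbury coefficients: Sigma_reg^-1 = (I - V diag(beta) V^T) / alpha
        ev = self.scale_ * self.eigvals_
        if self.alpha_ > 0:
            self._beta = ev / (ev + self.alpha_)
        else:
            self._beta = None  # exact inverse through the eigenbasis
        return self

    # ------------------------------------------------------------------
    @property
    def covariance_(self) -> np.ndarray:
        """The unregularized biased (1/N) sample covariance, reconstructed."""
        V, lam = self.eigvecs_, self.eigvals_
        return (V * lam) @ V.T

    @property
    def regularized_covariance_(self) -> np.ndarray:
        return self.scale_ * self.covariance_ + self.alpha_ * np.eye(self.dim_)

    def mahalanobis(self, X: np.ndarray) -> np.ndarray:
        """Mahalanobis distance of each row of ``X`` to the fitted mean."""
        X = np.atleast_2d(np.asarray(X, dtype=np.float64))
        if X.shape[1] != self.dim_:
            raise ValueError(f"expected dim {self.dim_}, got {X.shape[1]}")
        delta = X - self.mean_
        proj = delta @ self.eigvecs_                      # (n, r)
        if self._beta is None:
            d2 = np.einsum("nr,r,nr->n", proj, 1.0 / (self.scale_ * self.eigvals_), proj)
        else:
            d2 = (np.einsum("nd,nd->n", delta, delta)
                  - np.einsum("nr,r,nr->n", proj, self._beta, proj)) / self.alpha_
        return np.sqrt(np.maximum(d2, 0.0))
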