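"""Synthetic iiOCT M-scan phantom generator.

An instrument-integrated OCT probe looking at the retina produces A-scans
(1-D depth profiles) with a characteristic structure: a dark vitreous
region near the probe, a sharp rise in reflectivity at the internal
limiting membrane (ILM), a textured retinal band, and a hyperreflective
retinal-pigment-epithelium (RPE) stripe deeper in the tissue.  Coherent
imaging adds multiplicative speckle, and probe/eye motion makes the ILM
depth drift smoothly across consecutive A-scans.

This module emulates exactly those features with known ground truth, so
the whole detection pipeline can be exercised without access to real
recordings.  It makes no attempt at wave-optics realism.
"""

from __future__ import annotations

import dataclasses
import os
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "PhantomParams",
    "IlmAnnotation",
    "generate_mscan",
    "generate_mscans",
    "generate_dataset",
]

#: depth sampling of the probe, used to convert ILM indices to distances
MICRONS_PER_PIXEL = 3.7


@dataclass(frozen=True)
class PhantomParams:
    """Parameters of the synthetic M-scan phantom.

    Intensities are generated directly on the [0, 255] scale that the
    corruption operators assume.  Depth indices are 0-based, index 0 at
    the probe.
    """

    P: int = 674                  # depth pixels per A-scan
    T: int = 10                   # A-scans per M-scan
    vitreous_level: float = 20.0  # mean intensity above the ILM
    retina_level: float = 90.0    # mean intensity of the retinal band
    rpe_level: float = 190.0      # mean intensity of the RPE stripe
    ilm_mean_depth: float = 300.0  # population mean ILM depth [px]
    ilm_jitter: float = 40.0      # per-M-scan std of the starting ILM depth [px]
    drift_sigma: float = 2.0      # per-step std of the ILM random walk [px]
    speckle_strength: float = 0.35  # sigma of the multiplicative log-normal speckle
    rpe_offset: int = 120         # ILM-to-RPE distance [px]
    rpe_width: int = 14           # RPE stripe thickness [px]
    seed: int = 0

    def validate(self) -> None:
        if not (self.vitreous_level < self.retina_level < self.rpe_level):
            raise ValueError(
                "band intensities must satisfy vitreous < retina < rpe, got "
                f"{self.vitreous_level}, {self.retina_level}, {self.rpe_level}"
            )
        if not (0 < self.ilm_mean_depth < self.P):
            raise ValueError(f"ilm_mean_depth must lie in (0, {self.P})")
        if self.P < 1 or self.T < 1:
            raise ValueError("P and T must be positive")
        if self.speckle_strength < 0 or self.drift_sigma < 0 or self.ilm_jitter < 0:
            raise ValueError("noise/drift parameters must be non-negative")


@dataclass
class IlmAnnotation:
    """Ground-truth ILM depth per A-scan of one M-scan (0-based indices)."""

    ilm_index: np.ndarray  # (T,) int
    valid: np.ndarray      # (T,) bool

    def __post_init__(self) -> None:
        self.ilm_index = np.asarray(self.ilm_index, dtype=np.int64)
        self.valid = np.asarray(self.valid, dtype=bool)


def _reflect(x: float, lo: float, hi: float) -> float:
    """Reflect x into [lo, hi] (single bounce is enough for small steps)."""
    if x < lo:
        x = lo + (lo - x)
    if x > hi:
        x = hi - (x - hi)
    return float(np.clip(x, lo, hi))


def generate_mscan(
    params: PhantomParams, rng: np.random.Generator
) -> tuple[np.ndarray, IlmAnnotation]:
    """Generate one synthetic M-scan and its exact ILM annotation.

    Returns a ``(T, P)`` float array with integer values in [0, 255]
    (rows are A-scans, columns depth) and the per-A-scan ILM indices.
    The ILM performs a reflected Gaussian random walk with per-step std
    ``drift_sigma`` starting from a jittered per-M-scan depth.
    """
    params.validate()
    P, T = params.P, params.T

    # keep the ILM away from the extremes so the retinal band exists
    lo, hi = 0.02 * P, 0.9 * P
    depth = _reflect(
        params.ilm_mean_depth + rng.normal(0.0, params.ilm_jitter), lo, hi
    )
    ilm = np.empty(T, dtype=np.int64)
    template = np.empty((T, P), dtype=np.float64)
    d_axis = np.arange(P)
    for t in range(T):
        ilm[t] = int(round(depth))
        row = np.where(d_axis < ilm[t], params.vitreous_level, params.retina_level)
        r0 = min(ilm[t] + params.rpe_offset, P)
        r1 = min(r0 + params.rpe_width, P)
        row[r0:r1] = params.rpe_level
        # attenuated signal below the RPE
        row[r1:] = 0.6 * params.retina_level
        template[t] = row
        depth = _reflect(depth + rng.normal(0.0, params.drift_sigma), lo, hi)

    if params.speckle_strength > 0:
        # multiplicative log-normal speckle with unit mean
        s = params.speckle_strength
        speckle = np.exp(rng.normal(-0.5 * s * s, s, size=(T, P)))
        template = template * speckle
    out = np.clip(np.rint(template), 0.0, 255.0)
    ann = IlmAnnotation(ilm_index=ilm, valid=np.ones(T, dtype=bool))
    return out, ann


def generate_mscans(
    n: int, params: PhantomParams, seed: int | np.random.Generator | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Generate ``n`` M-scans in memory.

    Returns ``(mscans, ilm)`` with shapes ``(n, T, P)`` and ``(n, T)``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(params.seed if seed is None else seed)
    )
    mscans = np.empty((n, params.T, params.P), dtype=np.float64)
    ilm = np.empty((n, params.T), dtype=np.int64)
    for i in range(n):
        mscans[i], ann = generate_mscan(params, rng)
        ilm[i] = ann.ilm_index
    return mscans, ilm


def generate_dataset(
    out_dir: str | os.PathLike,
    n_mscans: int,
    params: PhantomParams | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Write ``n_mscans`` M-scans as TIFFs plus one annotation TSV.

    Output is bit-reproducible for a fixed seed: one 16-bit grayscale
    TIFF per M-scan (``mscan_<i>.tif``, rows = A-scans) and
    ``annotations.tsv`` with columns ``mscan_id``, ``ascan_index``
    (0-based), ``ilm_index`` (0-based), ``valid``.
    """
    from .io import write_annotations, write_mscan

    params = params or PhantomParams()
    mscans, ilm = generate_mscans(n_mscans, params, seed)
    os.makedirs(out_dir, exist_ok=True)
    rows = []
    for i in range(n_mscans):
        mscan_id = f"mscan_{i:06d}"
        write_mscan(os.path.join(out_dir, f"{mscan_id}.tif"), mscans[i])
        for t in range(params.T):
            rows.append((mscan_id, t, int(ilm[i, t]), True))
    ann = pd.DataFrame(rows, columns=["mscan_id", "ascan_index", "ilm_index", "valid"])
    write_annotations(os.path.join(out_dir, "annotations.tsv"), ann)
    return ann
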