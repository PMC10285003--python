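"""The eight synthetic M-scan corruption operators.

Each operator maps an M-scan (``(T, P)`` array, intensities on the
[0, 255] scale) to a corrupted copy plus a :class:`CorruptionSpec`
recording the concrete sampled parameters.  Operators never modify the
input and always clip the result back to [0, 255].

Severity parameters follow the study conditions they simulate:

========== =================================================================
noise       additive Gaussian, mu=0, sigma=50
smoothing   2-D Gaussian filter, sigma=5 px, reflective boundary
contrast    factor from {0.1, 0.2, 0.3, 2, 3, 4} about the M-scan mean
intensity   one scalar shift, sign equiprobable, magnitude U(25, 50)
stripes     1 or 2 A-scans replaced by constants drawn from U(100, 200)
rectangle   width U{6..10} x depth U{15..30} block filled with U(100, 200)
shift       suffix of A-scans circularly rolled in depth by +-U(25, 100) px
zoom        each A-scan magnified by U(1.5, 1.75) and center-cropped to P
========== =================================================================
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Callable

import numpy as np
from scipy import ndimage

__all__ = [
    "CORRUPTION_TYPES",
    "SUPERVISED_TRAINING_TYPES",
    "SUPERVISED_UNSEEN_TYPES",
    "CorruptionSpec",
    "sample_corruption_type",
    "apply_corruption",
    "corrupt_noise",
    "corrupt_smoothing",
    "corrupt_contrast",
    "corrupt_intensity",
    "corrupt_stripes",
    "corrupt_rectangle",
    "corrupt_shift",
    "corrupt_zoom",
    "corrupt_dataset",
]

CORRUPTION_TYPES: tuple[str, ...] = (
    "noise",
    "smoothing",
    "contrast",
    "intensity",
    "stripes",
    "rectangle",
    "shift",
    "zoom",
)

#: corruption types the Supervised baseline is trained on
SUPERVISED_TRAINING_TYPES: tuple[str, ...] = ("noise", "smoothing", "shift", "intensity")
#: the complementary types, unseen by the Supervised baseline
SUPERVISED_UNSEEN_TYPES: tuple[str, ...] = ("stripes", "rectangle", "zoom", "contrast")


@dataclass
class CorruptionSpec:
    """Type tag plus the concrete sampled parameters of one perturbation."""

    ctype: str
    params: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.ctype not in CORRUPTION_TYPES:
            raise ValueError(f"unknown corruption type {self.ctype!r}")


def _as_mscan(m: np.ndarray) -> np.ndarray:
    m = np.asarray(m, dtype=np.float64)
    if m.ndim != 2:
        raise ValueError(f"expected a (T, P) M-scan, got shape {m.shape}")
    return m


def _clip(m: np.ndarray) -> np.ndarray:
    return np.clip(m, 0.0, 255.0)


def sample_corruption_type(rng: np.random.Generator) -> str:
    """Draw one of the eight corruption types uniformly."""
    return CORRUPTION_TYPES[rng.integers(len(CORRUPTION_TYPES))]


def corrupt_noise(
    m: np.ndarray,
    rng: np.random.Generator,
    *,
    sigma: float = 50.0,
    clip: bool = True,
) -> tuple[np.ndarray, CorruptionSpec]:
    """Additive i.i.d. Gaussian noise (``clip=False`` exposes the raw sum)."""
    m = _as_mscan(m)
    out = m + rng.normal(0.0, sigma, size=m.shape) if sigma > 0 else m.copy()
    if clip:
        out = _clip(out)
    return out, CorruptionSpec("noise", {"sigma": sigma})


def corrupt_smoothing(
    m: np.ndarray, rng: np.random.Generator, *, sigma: float = 5.0
) -> tuple[np.ndarray, CorruptionSpec]:
    """2-D Gaussian blur with reflective boundary handling."""
    m = _as_mscan(m)
    out = _clip(ndimage.gaussian_filter(m, sigma=sigma, mode="reflect"))
    return out, CorruptionSpec("smoothing", {"sigma": sigma})


CONTRAST_FACTORS: tuple[float, ...] = (0.1, 0.2, 0.3, 2.0, 3.0, 4.0)


def corrupt_contrast(
    m: np.ndarray, rng: np.random.Generator, *, factor: float | None = None
) -> tuple[np.ndarray, CorruptionSpec]:
    """Rescale contrast about the M-scan mean by a factor from the fixed set."""
    m = _as_mscan(m)
    if factor is None:
        factor = CONTRAST_FACTORS[rng.integers(len(CONTRAST_FACTORS))]
    pivot = float(m.mean())
    out = _clip(pivot + factor * (m - pivot))
    return out, CorruptionSpec("contrast", {"factor": float(factor), "pivot": pivot})


def corrupt_intensity(
    m: np.ndarray, rng: np.random.Generator, *, shift: float | None = None
) -> tuple[np.ndarray, CorruptionSpec]:
    """Add one scalar from U([-50,-25] ∪ [25,50]) to every pixel."""
    m = _as_mscan(m)
    if shift is None:
        magnitude = rng.uniform(25.0, 50.0)
        sign = 1.0 if rng.random() < 0.5 else -1.0
        shift = sign * magnitude
    out = _clip(m + shift)
    return out, CorruptionSpec("intensity", {"shift": float(shift)})


def corrupt_stripes(
    m: np.ndarray, rng: np.random.Generator
) -> tuple[np.ndarray, CorruptionSpec]:
    """Replace one or two A-scans with per-stripe constants from U(100, 200)."""
    m = _as_mscan(m)
    T = m.shape[0]
    count = int(rng.integers(1, 3))
    count = min(count, T)
    rows = rng.choice(T, size=count, replace=False)
    out = m.copy()
    values = []
    for r in rows:
        v = rng.uniform(100.0, 200.0)
        out[r, :] = v
        values.append(float(v))
    return out, CorruptionSpec(
        "stripes", {"rows": [int(r) for r in rows], "values": values}
    )


def corrupt_rectangle(
    m: np.ndarray, rng: np.random.Generator
) -> tuple[np.ndarray, CorruptionSpec]:
    """Fill a random interior rectangle with one constant from U(100, 200).

    The rectangle spans ``width`` A-scans (uniform in 6..10) by ``depth``
    pixels (uniform in 15..30) and must fit inside the T×P grid.
    """
    m = _as_mscan(m)
    T, P = m.shape
    width = int(rng.integers(6, 11))
    depth = int(rng.integers(15, 31))
    if width > T or depth > P:
        raise ValueError(
            f"rectangle {width}x{depth} cannot fit in a {T}x{P} M-scan"
        )
    r0 = int(rng.integers(0, T - width + 1))
    c0 = int(rng.integers(0, P - depth + 1))
    value = float(rng.uniform(100.0, 200.0))
    out = m.copy()
    out[r0 : r0 + width, c0 : c0 + depth] = value
    return out, CorruptionSpec(
        "rectangle",
        {"row": r0, "col": c0, "width": width, "depth": depth, "value": value},
    )


def corrupt_shift(
    m: np.ndarray, rng: np.random.Generator
) -> tuple[np.ndarray, CorruptionSpec]:
    """Circularly roll a random suffix of A-scans in depth by ±U(25, 100) px."""
    m = _as_mscan(m)
    T = m.shape[0]
    split = int(rng.integers(1, T)) if T > 1 else 0
    magnitude = int(round(rng.uniform(25.0, 100.0)))
    sign = 1 if rng.random() < 0.5 else -1
    s = sign * magnitude
    out = m.copy()
    out[split:] = np.roll(m[split:], s, axis=1)
    return out, CorruptionSpec("shift", {"split": split, "shift": s})


def corrupt_zoom(
    m: np.ndarray, rng: np.random.Generator, *, factor: float | None = None
) -> tuple[np.ndarray, CorruptionSpec]:
    """Magnify every A-scan in depth by one shared factor from U(1.5, 1.75).

    Each A-scan is linearly resampled to length ``round(z*P)`` and
    center-cropped back to P, so the output shape is unchanged.  A depth
    index ``d`` maps to ``round(z*d) - (round(z*P) - P)//2``.
    """
    m = _as_mscan(m)
    T, P = m.shape
    z = float(rng.uniform(1.5, 1.75)) if factor is None else float(factor)
    L = int(round(z * P))
    offset = (L - P) // 2
    # zoomed[j] = m[j / z], sampled by linear interpolation
    coords = np.arange(L, dtype=np.float64) / z
    src = np.arange(P, dtype=np.float64)
    out = np.empty_like(m)
    for t in range(T):
        zoomed = np.interp(coords, src, m[t])
        out[t] = zoomed[offset : offset + P]
    return _clip(out), CorruptionSpec("zoom", {"factor": z, "offset": offset})


_OPERATORS: dict[str, Callable] = {
    "noise": corrupt_noise,
    "smoothing": corrupt_smoothing,
    "contrast": corrupt_contrast,
    "intensity": corrupt_intensity,
    "stripes": corrupt_stripes,
    "rectangle": corrupt_rectangle,
    "shift": corrupt_shift,
    "zoom": corrupt_zoom,
}


def apply_corruption(
    m: np.ndarray, ctype: str, rng: np.random.Generator, **overrides
) -> tuple[np.ndarray, CorruptionSpec]:
    """Apply the named corruption; ``overrides`` forward to the operator."""
    try:
        op = _OPERATORS[ctype]
    except KeyError:
        raise ValueError(f"unknown corruption type {ctype!r}") from None
    return op(m, rng, **overrides)


def round_half_up(x: float) -> int:
    """round(x) with ties going up, as used for the corrupted-count p·n."""
    return int(np.floor(x + 0.5))


def corrupt_dataset(
    mscans: np.ndarray,
    p: float,
    rng: np.random.Generator,
    *,
    ctypes: tuple[str, ...] = CORRUPTION_TYPES,
    op_kwargs: dict[str, dict] | None = None,
) -> tuple[np.ndarray, np.ndarray, list[CorruptionSpec | None]]:
    """Corrupt exactly ``round_half_up(p * n)`` M-scans of a dataset.

    Each corrupted M-scan receives one corruption drawn uniformly from
    ``ctypes``.  Returns ``(corrupted, labels, specs)`` where ``labels``
    is a 0/1 array marking corrupted M-scans and ``specs[i]`` is the
    applied :class:`CorruptionSpec` or ``None``.
    """
    if not 0.0 <= p <= 1.0:
        raise ValueError("p must be in [0, 1]")
    mscans = np.asarray(mscans, dtype=np.float64)
    n = mscans.shape[0]
    k = round_half_up(p * n)
    idx = rng.choice(n, size=k, replace=False) if k else np.array([], dtype=int)
    out = mscans.copy()
    labels = np.zeros(n, dtype=np.int64)
    specs: list[CorruptionSpec | None] = [None] * n
    op_kwargs = op_kwargs or {}
    for i in idx:
        ctype = ctypes[rng.integers(len(ctypes))]
        out[i], specs[i] = apply_corruption(
            mscans[i], ctype, rng, **op_kwargs.get(ctype, {})
        )
        labels[i] = 1
    return out, labels, specs
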