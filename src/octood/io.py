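"""File formats: 16-bit grayscale TIFF M-scans and TSV tables.

One M-scan per TIFF, rows = A-scans (T), columns = depth (P), intensity
values on the integer [0, 255] scale stored as uint16.  Annotations and
corruption-spec logs are tab-separated tables with 0-based indices.
"""

from __future__ import annotations

import json
import os

import numpy as np
import pandas as pd
import tifffile

from .corruptions import CorruptionSpec

__all__ = [
    "FormatError",
    "read_mscan",
    "write_mscan",
    "read_dataset",
    "read_annotations",
    "write_annotations",
    "write_spec_log",
    "read_spec_log",
]

ANNOTATION_COLUMNS = ["mscan_id", "ascan_index", "ilm_index", "valid"]


class FormatError(ValueError):
    """A file does not match the expected on-disk dialect."""


def write_mscan(path: str | os.PathLike, m: np.ndarray) -> None:
    """Write one M-scan as 16-bit grayscale TIFF (values rounded to ints)."""
    m = np.asarray(m, dtype=np.float64)
    if m.ndim != 2:
        raise FormatError(f"M-scan must be 2-D (T, P), got shape {m.shape}")
    if m.min() < 0 or m.max() > 255:
        raise FormatError("intensities must lie in [0, 255]")
    tifffile.imwrite(path, np.rint(m).astype(np.uint16))


def read_mscan(
    path: str | os.PathLike, expected_shape: tuple[int, int] | None = (10, 674)
) -> np.ndarray:
    """Read one M-scan TIFF back as a float array on [0, 255].

    ``expected_shape`` (default the study geometry, 10 A-scans x 674
    depth pixels) is enforced; pass ``None`` to accept any 2-D shape.
    """
    try:
        arr = tifffile.imread(path)
    except Exception as exc:  # malformed/unreadable file
        raise FormatError(f"cannot read TIFF M-scan from {path}: {exc}") from exc
    if arr.ndim != 2:
        raise FormatError(f"{path}: expected a 2-D grayscale image, got {arr.shape}")
    if expected_shape is not None and tuple(arr.shape) != tuple(expected_shape):
        raise FormatError(
            f"{path}: expected a {expected_shape[0]}x{expected_shape[1]} M-scan "
            f"(A-scans x depth), got {arr.shape[0]}x{arr.shape[1]}"
        )
    return arr.astype(np.float64)


def write_annotations(path: str | os.PathLike, ann: pd.DataFrame) -> None:
    missing = set(ANNOTATION_COLUMNS) - set(ann.columns)
    if missing:
        raise FormatError(f"annotation table missing columns {sorted(missing)}")
    ann.loc[:, ANNOTATION_COLUMNS].to_csv(path, sep="\t", index=False)


def read_annotations(path: str | os.PathLike) -> pd.DataFrame:
    ann = pd.read_csv(path, sep="\t")
    missing = set(ANNOTATION_COLUMNS) - set(ann.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    return ann


def read_dataset(
    directory: str | os.PathLike, expected_shape: tuple[int, int] | None = (10, 674)
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Load a generated dataset directory.

    Returns ``(mscans, ilm, ids)`` with shapes ``(n, T, P)`` and
    ``(n, T)``; M-scans are ordered by their id (stable dataset order).
    """
    ann = read_annotations(os.path.join(directory, "annotations.tsv"))
    ids = sorted(ann["mscan_id"].unique())
    mscans, ilm = [], []
    for mid in ids:
        mscans.append(read_mscan(os.path.join(directory, f"{mid}.tif"), expected_shape))
        sub = ann[ann["mscan_id"] == mid].sort_values("ascan_index")
        ilm.append(sub["ilm_index"].to_numpy())
    return np.stack(mscans), np.stack(ilm), ids


def write_spec_log(
    path: str | os.PathLike, ids: list[str], specs: list[CorruptionSpec | None]
) -> None:
    """Log applied corruptions as TSV: mscan_id, ctype, JSON params."""
    rows = [
        (mid, s.ctype if s else "none", json.dumps(s.params if s else {}))
        for mid, s in zip(ids, specs)
    ]
    pd.DataFrame(rows, columns=["mscan_id", "ctype", "params"]).to_csv(
        path, sep="\t", index=False
    )


def read_spec_log(path: str | os.PathLike) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    df["params"] = df["params"].apply(json.loads)
    return df
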