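"""Core data model and I/O for intensity images, label images and feature tables.

Conventions used throughout the package
---------------------------------------
* Axes are ``(z,) y, x``; indices are 0-based; pixel *centers* sit on the
  integer lattice, so a pixel at index ``(r, c)`` occupies the closed square
  ``[r - 0.5, r + 0.5] x [c - 0.5, c + 0.5]``.
* Bounding boxes are half-open ``[min, max)`` in index units.
* Intensity data are floats scaled to ``[0, 1]``; the number of grey levels of
  the *source* (256 for 8-bit, 65,536 for 16-bit) travels with the image
  because threshold searches use it as their candidate grid.
* Label images are non-negative integer grids; 0 is background and every
  positive id names one object. Objects within one label image cannot overlap.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import tifffile

logger = logging.getLogger("microquant")

OBJECT_ID_COLUMN = "object_id"


class FormatError(ValueError):
    """Raised for unsupported image files (dtype, shape, colour layout)."""


class DimensionError(ValueError):
    """Raised when two grids that must share a shape do not."""


class DegenerateImageError(ValueError):
    """Raised when an operation needs intensity variation the image lacks."""


@dataclass(frozen=True)
class IntensityImage:
    """A single-channel intensity image scaled to [0, 1].

    Parameters
    ----------
    values
        Float array, 2D or 3D, all values finite and in ``[0, 1]``.
    grey_levels
        Number of representable intensity levels of the source data
        (256 for 8-bit, 65,536 for 16-bit). Must be >= 2.
    """

    values: np.ndarray
    grey_levels: int = 256

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=np.float64)
        if v.ndim not in (2, 3):
            raise FormatError(f"intensity image must be 2D or 3D, got ndim={v.ndim}")
        if not np.all(np.isfinite(v)):
            raise ValueError("intensity values must be finite")
        if v.size and (v.min() < 0.0 or v.max() > 1.0):
            raise ValueError("intensity values must lie in [0, 1]")
        if int(self.grey_levels) < 2:
            raise ValueError("grey_levels must be >= 2")
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "grey_levels", int(self.grey_levels))

    @property
    def ndim(self) -> int:
        return self.values.ndim

    @property
    def shape(self) -> tuple[int, ...]:
        return self.values.shape


@dataclass(frozen=True)
class LabelImage:
    """An integer label grid; 0 is background, positive ids are objects."""

    labels: np.ndarray

    def __post_init__(self) -> None:
        lab = np.asarray(self.labels)
        if lab.ndim not in (2, 3):
            raise FormatError(f"label image must be 2D or 3D, got ndim={lab.ndim}")
        if not np.issubdtype(lab.dtype, np.integer):
            raise FormatError("label image must have an integer dtype")
        if lab.size and lab.min() < 0:
            raise ValueError("label ids must be non-negative")
        object.__setattr__(self, "labels", lab.astype(np.int32, copy=False))

    @property
    def ndim(self) -> int:
        return self.labels.ndim

    @property
    def shape(self) -> tuple[int, ...]:
        return self.labels.shape

    @property
    def ids(self) -> np.ndarray:
        """Sorted array of object ids present (background excluded)."""
        u = np.unique(self.labels)
        return u[u > 0]

    @property
    def n_objects(self) -> int:
        return int(self.ids.size)


@dataclass
class FeatureTable:
    """Per-object measurement rows keyed by object id.

    Thin wrapper around a :class:`pandas.DataFrame` whose index is the object
    id. Row order is ascending id, column order lexicographic; both are
    enforced on construction so serialization is deterministic.
    """

    frame: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        df = self.frame
        if df.index.name != OBJECT_ID_COLUMN:
            df = df.rename_axis(OBJECT_ID_COLUMN)
        self.frame = df.sort_index().reindex(sorted(df.columns), axis=1)

    @classmethod
    def from_records(cls, records: dict[int, dict[str, float]]) -> "FeatureTable":
        """Build a table from ``{object_id: {feature_name: value}}``."""
        df = pd.DataFrame.from_dict(records, orient="index")
        df.index.name = OBJECT_ID_COLUMN
        return cls(df)

    @property
    def ids(self) -> list[int]:
        return [int(i) for i in self.frame.index]

    @property
    def columns(self) -> list[str]:
        return list(self.frame.columns)

    def __len__(self) -> int:
        return len(self.frame)

    def __getitem__(self, key: str) -> pd.Series:
        return self.frame[key]


# ---------------------------------------------------------------------------
# TIFF I/O

_INT_DTYPES = {
    np.dtype(np.uint8): 256,
    np.dtype(np.uint16): 65536,
    np.dtype(np.int16): 65536,
    np.dtype(np.uint32): 2**32,
    np.dtype(np.int32): 2**32,
}


def read_image(path, kind: str = "intensity", grey_levels_hint: int | None = None):
    """Read a single-channel 2D/3D TIFF as an intensity or label image.

    Integer intensity data are rescaled to [0, 1] by the declared dtype
    maximum; float data are assumed pre-scaled to [0, 1] (values outside are
    clipped with a warning). ``grey_levels`` is inferred from the bit depth
    unless ``grey_levels_hint`` is given (floats default to 256).
    """
    arr = tifffile.imread(str(path))
    arr = np.squeeze(arr)
    if arr.ndim == 3 and arr.shape[-1] in (3, 4) and arr.shape[-1] < min(arr.shape[:2]):
        raise FormatError(
            "RGB(A) TIFF not supported; extract one channel per file "
            "(e.g. arr[..., 0]) and load channels separately"
        )
    if arr.ndim not in (2, 3):
        raise FormatError(f"expected a 2D or 3D single-channel TIFF, got shape {arr.shape}")

    if kind == "label":
        if not np.issubdtype(arr.dtype, np.integer):
            raise FormatError(f"label TIFF must be integer-typed, got {arr.dtype}")
        return LabelImage(arr)
    if kind != "intensity":
        raise ValueError(f"unknown image kind {kind!r}")

    if np.issubdtype(arr.dtype, np.integer):
        if arr.dtype not in _INT_DTYPES:
            raise FormatError(f"unsupported integer dtype {arr.dtype}")
        if np.issubdtype(arr.dtype, np.signedinteger):
            if arr.min() < 0:
                raise FormatError("signed intensity data with negative values not supported")
            arr = arr.astype(np.uint32 if arr.dtype.itemsize > 2 else np.uint16)
        levels = _INT_DTYPES[np.dtype(arr.dtype)]
        values = arr.astype(np.float64) / (levels - 1)
        return IntensityImage(values, grey_levels_hint or levels)
    if np.issubdtype(arr.dtype, np.floating):
        values = arr.astype(np.float64)
        if not np.all(np.isfinite(values)):
            raise FormatError("float TIFF contains non-finite values")
        if values.size and (values.min() < 0.0 or values.max() > 1.0):
            logger.warning(
                "float image %s has values outside [0, 1]; clipping (range %.4g..%.4g)",
                path, values.min(), values.max(),
            )
            values = np.clip(values, 0.0, 1.0)
        return IntensityImage(values, grey_levels_hint or 256)
    raise FormatError(f"unsupported dtype {arr.dtype}")


def write_image(image, path) -> None:
    """Write an image/grid to TIFF.

    Label images go out as uint16 (uint32 if ids exceed 65535), boolean masks
    as uint8 {0, 255}, intensity/surface data as float32.
    """
    if isinstance(image, LabelImage):
        lab = image.labels
        dtype = np.uint16 if (lab.size == 0 or lab.max() <= 65535) else np.uint32
        tifffile.imwrite(str(path), lab.astype(dtype))
    elif isinstance(image, IntensityImage):
        tifffile.imwrite(str(path), image.values.astype(np.float32))
    else:
        arr = np.asarray(image)
        if arr.dtype == bool:
            tifffile.imwrite(str(path), (arr * np.uint8(255)))
        elif arr.dtype in (np.dtype(np.uint8), np.dtype(np.uint16), np.dtype(np.uint32)):
            tifffile.imwrite(str(path), arr)
        elif np.issubdtype(arr.dtype, np.integer):
            dtype = np.uint16 if (arr.size == 0 or arr.max() <= 65535) else np.uint32
            tifffile.imwrite(str(path), arr.astype(dtype))
        else:
            tifffile.imwrite(str(path), arr.astype(np.float32))


# ---------------------------------------------------------------------------
# Table I/O

def write_table(table: FeatureTable, path) -> None:
    """Write a feature table to CSV.

    Object id first column, rows in ascending id order, measurement columns in
    lexicographic order. Floats are printed with 17 significant digits so a
    round-trip read reproduces them exactly (well within the 12-digit
    contract); an empty table yields a header-only CSV.
    """
    df = table.frame
    df.to_csv(str(path), float_format="%.17g")


def read_table(path) -> FeatureTable:
    """Read back a CSV written by :func:`write_table`."""
    df = pd.read_csv(str(path), index_col=OBJECT_ID_COLUMN)
    return FeatureTable(df)
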