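"""Global and adaptive thresholding engine.

Any global method (Otsu here) can be run in *adaptive* mode: the image is
tiled into blocks, the method is applied per block, and the block-center
thresholds are interpolated into a smooth per-pixel threshold surface —
useful for images with highly variable background. Sauvola local
thresholding is available as an alternative adaptive strategy, and a
log-transform wrapper can be applied around any global method to help with
dim images.

Foreground is always ``value > threshold`` (strict).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy import ndimage
from scipy.interpolate import RegularGridInterpolator

from .images import DegenerateImageError, DimensionError, IntensityImage

GlobalMethod = Callable[[IntensityImage], float]


@dataclass(frozen=True)
class ThresholdResult:
    """A global scalar threshold or a per-pixel threshold surface."""

    kind: str  # "global" | "surface"
    value: float | None = None
    surface: np.ndarray | None = None
    method: str = ""
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind == "global":
            if self.value is None or not (0.0 <= self.value <= 1.0):
                raise ValueError("global threshold must lie in [0, 1]")
        elif self.kind == "surface":
            if self.surface is None:
                raise ValueError("surface result needs a surface array")
            s = np.asarray(self.surface, dtype=np.float64)
            if s.size and (s.min() < 0.0 or s.max() > 1.0):
                raise ValueError("surface values must lie in [0, 1]")
            object.__setattr__(self, "surface", s)
        else:
            raise ValueError(f"unknown result kind {self.kind!r}")


# ---------------------------------------------------------------------------
# Otsu

def otsu_threshold(image: IntensityImage, nbins: int | None = None) -> float:
    """Two-class Otsu threshold.

    Builds an ``nbins`` histogram over ``[min, max]`` of the image and returns
    the bin-edge value maximizing the between-class variance. ``nbins``
    defaults to ``min(grey_levels, 256)``. The result lies strictly between
    the image min and max.

    Raises
    ------
    DegenerateImageError
        If the image is constant (no two classes to separate).
    """
    v = image.values.ravel()
    vmin, vmax = float(v.min()), float(v.max())
    if vmin == vmax:
        raise DegenerateImageError("constant image has no Otsu threshold")
    if nbins is None:
        nbins = min(image.grey_levels, 256)
    counts, edges = np.histogram(v, bins=int(nbins), range=(vmin, vmax))
    centers = (edges[:-1] + edges[1:]) / 2.0

    w = counts.astype(np.float64)
    total = w.sum()
    cum_w = np.cumsum(w)
    cum_m = np.cumsum(w * centers)
    mean_all = cum_m[-1] / total
    # cut after bin k: class 0 = bins [0..k], class 1 = bins [k+1..]
    w0 = cum_w[:-1] / total
    w1 = 1.0 - w0
    with np.errstate(divide="ignore", invalid="ignore"):
        mu0 = cum_m[:-1] / cum_w[:-1]
        mu1 = (cum_m[-1] - cum_m[:-1]) / (total - cum_w[:-1])
    sigma_b = w0 * w1 * (mu0 - mu1) ** 2
    sigma_b[~np.isfinite(sigma_b)] = -1.0
    k = int(np.argmax(sigma_b))  # first maximum on ties
    return float(edges[k + 1])


# ---------------------------------------------------------------------------
# Log-transform wrapper

def log_wrap(method: GlobalMethod) -> GlobalMethod:
    """Wrap a global method so it operates on log-transformed intensities.

    The forward transform is ``x -> log(x + eps)`` rescaled to [0, 1] with
    ``eps = 1/grey_levels``; the wrapped method's threshold is mapped back to
    the original intensity scale through the exact inverse.
    """

    def wrapped(image: IntensityImage) -> float:
        eps = 1.0 / image.grey_levels
        lo = np.log(eps)
        hi = np.log(1.0 + eps)
        t_values = (np.log(image.values + eps) - lo) / (hi - lo)
        t_image = IntensityImage(np.clip(t_values, 0.0, 1.0), image.grey_levels)
        t_thr = method(t_image)
        thr = float(np.exp(t_thr * (hi - lo) + lo) - eps)
        return min(max(thr, 0.0), 1.0)

    wrapped.__name__ = f"log_{getattr(method, '__name__', 'method')}"
    return wrapped


# ---------------------------------------------------------------------------
# Sauvola

def sauvola_surface(
    image: IntensityImage,
    window: int = 25,
    k: float = 0.2,
    R: float = 0.5,
) -> ThresholdResult:
    """Sauvola local threshold surface ``T = m * (1 + k * (s/R - 1))``.

    ``m`` and ``s`` are the local mean and standard deviation over a
    ``window``-sized neighbourhood (reflective padding at borders). ``R`` is
    the dynamic range of the standard deviation; the default 0.5 is half the
    0-1 intensity range.
    """
    if window < 3 or window % 2 == 0:
        raise ValueError("window must be an odd integer >= 3")
    if R <= 0:
        raise ValueError("R must be positive")
    v = image.values
    m = ndimage.uniform_filter(v, size=window, mode="reflect")
    m2 = ndimage.uniform_filter(v * v, size=window, mode="reflect")
    s = np.sqrt(np.maximum(m2 - m * m, 0.0))
    surf = m * (1.0 + k * (s / R - 1.0))
    return ThresholdResult(
        kind="surface",
        surface=np.clip(surf, 0.0, 1.0),
        method="sauvola",
        params={"window": window, "k": k, "R": R},
    )


# ---------------------------------------------------------------------------
# Adaptive (blockwise) framework

def adaptive_surface(
    image: IntensityImage,
    method: GlobalMethod = otsu_threshold,
    window: int = 64,
    bounds: tuple[float, float] = (0.7, 1.5),
) -> ThresholdResult:
    """Run a global threshold method blockwise and interpolate a surface.

    The image is tiled into blocks of roughly ``window`` pixels per axis; the
    method is applied per block (blocks where it degenerates inherit the
    whole-image global threshold); block-center thresholds are multilinearly
    interpolated to a per-pixel surface with edge clamping, then clamped to
    ``[global * bounds[0], global * bounds[1]]`` where ``global`` is the
    method applied to the whole image.
    """
    if window < 8:
        raise ValueError("window must be >= 8 pixels")
    shape = image.shape
    if any(s <= window for s in shape):
        raise ValueError(
            f"image shape {shape} not larger than window {window} in every "
            "axis; use the global method instead"
        )
    global_thr = method(image)

    # block index ranges per axis: ceil(size/window) near-equal tiles
    axes_edges = []
    for size in shape:
        n_blocks = int(np.ceil(size / window))
        axes_edges.append(np.linspace(0, size, n_blocks + 1).astype(int))
    centers = [
        (edges[:-1] + edges[1:] - 1) / 2.0 for edges in axes_edges
    ]
    grid_shape = tuple(len(c) for c in centers)
    block_thr = np.empty(grid_shape, dtype=np.float64)
    for idx in np.ndindex(grid_shape):
        sl = tuple(
            slice(axes_edges[d][i], axes_edges[d][i + 1]) for d, i in enumerate(idx)
        )
        block = image.values[sl]
        try:
            block_thr[idx] = method(IntensityImage(block, image.grey_levels))
        except DegenerateImageError:
            block_thr[idx] = global_thr

    # multilinear interpolation between block centers, edge-clamped
    coords = np.meshgrid(
        *[np.arange(s, dtype=np.float64) for s in shape], indexing="ij"
    )
    pts = np.stack(
        [
            np.clip(c.ravel(), centers[d][0], centers[d][-1])
            for d, c in enumerate(coords)
        ],
        axis=1,
    )
    # axes with a single block carry no variation; drop them for RGI
    keep = [d for d in range(len(shape)) if grid_shape[d] > 1]
    if keep:
        interp = RegularGridInterpolator(
            tuple(centers[d] for d in keep),
            block_thr.squeeze(
                axis=tuple(d for d in range(len(shape)) if d not in keep)
            ),
            method="linear",
        )
        surf = interp(pts[:, keep]).reshape(shape)
    else:
        surf = np.full(shape, float(block_thr.ravel()[0]))

    lo = global_thr * bounds[0]
    hi = global_thr * bounds[1]
    surf = np.clip(surf, lo, hi)
    surf = np.clip(surf, 0.0, 1.0)
    return ThresholdResult(
        kind="surface",
        surface=surf,
        method=f"adaptive_{getattr(method, '__name__', 'method')}",
        params={"window": window, "bounds": bounds, "global": global_thr},
    )


def apply_threshold(image: IntensityImage, result: ThresholdResult) -> np.ndarray:
    """Binary foreground mask: ``value > threshold`` (strict)."""
    if result.kind == "global":
        return image.values > result.value
    if result.surface.shape != image.shape:
        raise DimensionError(
            f"surface shape {result.surface.shape} != image shape {image.shape}"
        )
    return image.values > result.surface
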