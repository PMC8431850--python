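"""Deterministic synthetic fixtures for every input class the toolkit measures.

Three generators cover the full test surface with no external data:

* :func:`make_blob_labels` — random discs/spheres as a label image.
* :func:`make_object_pair` — two label images whose objects overlap by a
  controlled intersection-over-union, exercising the combination strategies.
* :func:`make_correlated_pair` — two smoothed Gaussian-field channels with an
  exact target Pearson correlation (before quantization), exercising the
  Costes threshold search at 8- and 16-bit depth.

All randomness flows from ``spec.seed`` through one ``numpy`` Generator, so
every fixture is bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .images import IntensityImage, LabelImage


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of one synthetic fixture."""

    shape: tuple[int, ...] = (64, 64)
    n_objects: int = 6
    radius_range: tuple[int, int] = (4, 9)
    overlap: float = 0.3
    rho: float = 0.5
    bit_depth: int = 8
    seed: int = 0
    smooth_sigma: float = 1.5

    def __post_init__(self) -> None:
        if any(s < 16 for s in self.shape):
            raise ValueError("fixture extents must be >= 16 per axis")
        if not -1.0 <= self.rho <= 1.0:
            raise ValueError("rho must lie in [-1, 1]")
        if not 0.0 <= self.overlap <= 1.0:
            raise ValueError("overlap must lie in [0, 1]")
        if self.bit_depth not in (8, 16):
            raise ValueError("bit_depth must be 8 or 16")

    @property
    def grey_levels(self) -> int:
        return 2 ** self.bit_depth


def _ball_mask(shape, center, radius) -> np.ndarray:
    grids = np.ogrid[tuple(slice(0, s) for s in shape)]
    d2 = sum((g - c) ** 2 for g, c in zip(grids, center))
    return d2 <= radius**2


def _place_blobs(spec: FixtureSpec, rng, min_gap: float):
    """Sample non-colliding centers/radii; ValueError if packing infeasible."""
    rmin, rmax = spec.radius_range
    ndim = len(spec.shape)
    unit = np.pi if ndim == 2 else 4.0 * np.pi / 3.0
    if spec.n_objects * unit * rmax**ndim >= np.prod(spec.shape):
        raise ValueError("infeasible packing: objects do not fit the image")
    placed: list[tuple[np.ndarray, int]] = []
    for _ in range(spec.n_objects):
        for _attempt in range(500):
            r = int(rng.integers(rmin, rmax + 1))
            c = np.array(
                [rng.uniform(r, s - 1 - r) for s in spec.shape]
            )
            if all(
                np.linalg.norm(c - c2) >= r + r2 + min_gap for c2, r2 in placed
            ):
                placed.append((c, r))
                break
        else:
            raise ValueError("infeasible packing: could not place all objects")
    return placed


def make_blob_labels(spec: FixtureSpec, touching: bool = False) -> LabelImage:
    """Random discs (2D) or spheres (3D) painted as a label image.

    With ``touching=False`` (default) objects are separated by at least 3
    pixels so each forms its own connected component under full connectivity;
    with ``touching=True`` the generated blobs are dilated by one pixel so
    neighbouring objects may touch (later ids win contested pixels).
    """
    rng = np.random.default_rng(spec.seed)
    lab = np.zeros(spec.shape, dtype=np.int32)
    if spec.n_objects == 0:
        return LabelImage(lab)
    placed = _place_blobs(spec, rng, min_gap=1.0 if touching else 3.0)
    for k, (c, r) in enumerate(placed):
        mask = _ball_mask(spec.shape, c, r)
        if touching:
            mask = ndimage.binary_dilation(
                mask, ndimage.generate_binary_structure(lab.ndim, 1)
            )
        lab[mask] = k + 1
    return LabelImage(lab)


def _disc_iou(d: float, r: float, ndim: int) -> float:
    """IoU of two equal discs/spheres of radius r at center distance d."""
    if d >= 2 * r:
        return 0.0
    if ndim == 2:
        inter = 2 * r * r * np.arccos(d / (2 * r)) - 0.5 * d * np.sqrt(
            4 * r * r - d * d
        )
        area = np.pi * r * r
    else:
        inter = np.pi * (2 * r - d) ** 2 * (d * d + 4 * d * r) / (12 * d) if d > 0 else (
            4.0 / 3.0
        ) * np.pi * r**3
        area = (4.0 / 3.0) * np.pi * r**3
    return float(inter / (2 * area - inter))


def _shift_for_iou(target: float, r: float, ndim: int) -> float:
    lo, hi = 0.0, 2.0 * r
    for _ in range(60):
        mid = (lo + hi) / 2.0
        if _disc_iou(mid, r, ndim) > target:
            lo = mid
        else:
            hi = mid
    return (lo + hi) / 2.0


def make_object_pair(spec: FixtureSpec) -> tuple[LabelImage, LabelImage]:
    """Two label images whose paired objects hit the IoU target ``overlap``.

    The initial set is a non-touching blob image; each addition object is a
    copy of one initial disc displaced by the distance that yields the target
    intersection-over-union (continuous-geometry inversion, accurate to well
    within the 0.1 contract at the default radii). ``overlap=0`` places the
    addition objects in free space; ``overlap=1`` duplicates the initial set.
    """
    rng = np.random.default_rng(spec.seed)
    initial = make_blob_labels(spec)
    lab1 = initial.labels
    if spec.overlap >= 1.0:
        return initial, LabelImage(lab1.copy())
    ndim = lab1.ndim
    placed = _place_blobs(spec, np.random.default_rng(spec.seed), min_gap=3.0)
    lab2 = np.zeros(spec.shape, dtype=np.int32)
    next_id = 1
    for c, r in placed:
        if spec.overlap <= 0.0:
            # free-space placement away from everything painted so far
            for _attempt in range(500):
                c2 = np.array([rng.uniform(r, s - 1 - r) for s in spec.shape])
                mask = _ball_mask(spec.shape, c2, r)
                if not (mask & ((lab1 > 0) | (lab2 > 0))).any():
                    lab2[mask] = next_id
                    next_id += 1
                    break
            else:
                raise ValueError("no free space for a disjoint addition object")
            continue
        d = _shift_for_iou(spec.overlap, r, ndim)
        direction = rng.normal(size=ndim)
        direction /= np.linalg.norm(direction)
        c2 = np.clip(c + direction * d, 0, np.array(spec.shape) - 1)
        mask = _ball_mask(spec.shape, c2, r)
        if mask.any():
            lab2[mask] = next_id
            next_id += 1
    return initial, LabelImage(lab2)


def make_correlated_pair(spec: FixtureSpec) -> tuple[IntensityImage, IntensityImage]:
    """Two channels with Pearson correlation exactly ``rho`` pre-quantization.

    Three independent smoothed white-noise fields are exponentiated to a
    log-normal marginal — the background-dominated, right-skewed intensity
    histogram of a fluorescence micrograph, where most pixels are dim and a
    bright structured minority carries the signal — then exactly
    orthonormalized (Gram-Schmidt over the pixel sample) so the mixtures
    ``a = sqrt(|rho|) S + sqrt(1-|rho|) N1`` and
    ``b = sign(rho) sqrt(|rho|) S + sqrt(1-|rho|) N2`` have sample
    correlation exactly ``rho``. Each channel is mapped linearly onto [0, 1]
    (no clipping, so the correlation survives) and quantized to the requested
    bit depth.

    The skewed marginal matters for the Costes threshold search: the dim
    background majority is never jointly above threshold, so the
    below-threshold population stays large at every candidate and its
    correlation profile is smooth. A symmetric marginal would shrink that
    population to a handful of pixels near the zero crossing, which is not
    how micrographs behave.
    """
    rng = np.random.default_rng(spec.seed)
    fields = []
    for _ in range(3):
        f = rng.normal(size=spec.shape)
        if spec.smooth_sigma > 0:
            f = ndimage.gaussian_filter(f, spec.smooth_sigma)
        f = np.exp(2.0 * f / f.std())  # log-normal texture, dim-dominated
        fields.append(f.ravel())
    # exact orthonormalization over the pixel sample
    basis = []
    for f in fields:
        f = f - f.mean()
        for b in basis:
            f = f - (f @ b) * b
        f /= np.linalg.norm(f)
        basis.append(f)
    s, n1, n2 = basis
    rho = spec.rho
    w_s = np.sqrt(abs(rho))
    w_n = np.sqrt(1.0 - abs(rho))
    sign = 1.0 if rho >= 0 else -1.0
    a = (w_s * s + w_n * n1).reshape(spec.shape)
    b = (sign * w_s * s + w_n * n2).reshape(spec.shape)

    levels = spec.grey_levels

    def to_unit(v: np.ndarray) -> np.ndarray:
        v = (v - v.min()) / (v.max() - v.min())
        return np.round(v * (levels - 1)) / (levels - 1)

    return (
        IntensityImage(to_unit(a), levels),
        IntensityImage(to_unit(b), levels),
    )
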