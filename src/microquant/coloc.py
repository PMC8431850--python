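"""Colocalization statistics between two channels.

Implements Pearson correlation, Manders coefficients, and the Costes
automatic threshold: starting from the brightest candidate, the channel-A
threshold is serially reduced (channel B coupled through an orthogonal
regression line) until the Pearson correlation of the below-threshold
pixel population — every pixel not above threshold in both channels —
drops to zero; that population is then considered background and the Costes
colocalization coefficients are the Manders coefficients computed at those
thresholds. See :func:`below_threshold_corr` for why this population makes
the zero-crossing search well-posed.

Four search strategies are provided:

``canonical``
    Fixed-step downward scan (default step 1/255, the historical behaviour
    appropriate for 8-bit data only).
``accurate``
    Scan every representable grey level of channel A, but recompute the
    correlation only when the below-threshold pixel count changed — an
    identical-result optimization, since an unchanged pixel set has an
    unchanged correlation.
``fast``
    Downward scan whose step grows with the last observed correlation;
    when the sign first flips the skipped interval is re-scanned at unit
    steps, so the result matches ``accurate`` on monotone profiles.
``faster``
    Weighted bisection: a window of candidate grey levels is narrowed by at
    least 1/6 per cycle based on the correlation sign at a probe candidate,
    followed by a unit-step refinement, again matching ``accurate`` on
    monotone profiles.

All strategies share one evaluation engine so sign decisions at equal
thresholds are bit-identical across modes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .images import DegenerateImageError, DimensionError, IntensityImage
from .threshold import otsu_threshold

logger = logging.getLogger("microquant")

# slack added to threshold comparisons so float candidate grids built by
# different arithmetic routes (max - j*step vs g/(L-1)) select identical
# pixel sets; far below one 16-bit grey level (1/65535 ~ 1.5e-5)
_GRID_TOL = 1e-9

COSTES_MODES = ("canonical", "accurate", "fast", "faster")


class UndefinedCorrelationError(ValueError):
    """Pearson correlation is undefined (fewer than 2 pixels or a constant
    channel); distinct from any numeric correlation value."""


@dataclass(frozen=True)
class CostesResult:
    """Outcome of a Costes automatic-threshold search."""

    tA: float
    tB: float
    slope: float
    intercept: float
    mode: str
    evaluations: int
    converged: bool
    cycles: int | None = None


@dataclass(frozen=True)
class ColocStats:
    """Per-image colocalization summary."""

    pearson: float
    manders_m1: float
    manders_m2: float
    costes_c1: float
    costes_c2: float
    costes: CostesResult | None = None


# ---------------------------------------------------------------------------
# Basic statistics

def _flat(a: IntensityImage, b: IntensityImage, mask=None):
    if a.shape != b.shape:
        raise DimensionError(f"channel shapes differ: {a.shape} vs {b.shape}")
    if mask is not None:
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != a.shape:
            raise DimensionError("mask shape does not match channels")
        return a.values[mask], b.values[mask]
    return a.values.ravel(), b.values.ravel()


def _pearson_from_sums(n, sa, sb, saa, sbb, sab):
    """Pearson r from raw sums; None when undefined."""
    if n < 2:
        return None
    va = saa - sa * sa / n
    vb = sbb - sb * sb / n
    # guard against catastrophic cancellation on constant channels
    if va <= 1e-18 * n or vb <= 1e-18 * n:
        return None
    cov = sab - sa * sb / n
    return float(cov / np.sqrt(va * vb))


def pearson_r(a: IntensityImage, b: IntensityImage, mask=None) -> float:
    """Pearson product-moment correlation of two channels over ``mask``.

    Raises :class:`UndefinedCorrelationError` when fewer than 2 pixels are
    selected or either channel is constant within the mask.
    """
    x, y = _flat(a, b, mask)
    r = _pearson_from_sums(
        x.size,
        float(x.sum()), float(y.sum()),
        float((x * x).sum()), float((y * y).sum()), float((x * y).sum()),
    )
    if r is None:
        raise UndefinedCorrelationError(
            "correlation undefined: <2 pixels or constant channel in mask"
        )
    return r


def costes_regression(
    a: IntensityImage, b: IntensityImage, mask=None, method: str = "orthogonal"
) -> tuple[float, float]:
    """Regression line coupling the two channel thresholds.

    Orthogonal (total least squares) regression of b on a, per the original
    Costes formulation: the slope is the principal axis of the 2x2
    covariance matrix. ``method='ols'`` gives ordinary least squares instead.
    """
    x, y = _flat(a, b, mask)
    if x.size < 2:
        raise DegenerateImageError("need at least 2 pixels for a regression")
    sxx = float(np.var(x))
    syy = float(np.var(y))
    sxy = float(np.mean(x * y) - np.mean(x) * np.mean(y))
    if sxx <= 0:
        raise DegenerateImageError("channel A is constant; regression undefined")
    if method == "ols":
        slope = sxy / sxx
    elif method == "orthogonal":
        if sxy == 0.0:
            slope = 0.0
        else:
            slope = (syy - sxx + np.sqrt((syy - sxx) ** 2 + 4.0 * sxy * sxy)) / (
                2.0 * sxy
            )
    else:
        raise ValueError(f"unknown regression method {method!r}")
    intercept = float(np.mean(y) - slope * np.mean(x))
    return float(slope), intercept


def below_threshold_corr(
    a: IntensityImage,
    b: IntensityImage,
    tA: float,
    slope: float,
    intercept: float,
    mask=None,
) -> float | None:
    """Correlation over the below-threshold pixel population.

    A pixel is below threshold unless it exceeds the threshold in *both*
    channels: the set is the complement of ``{a > tA and b > tB}`` with
    ``tB = slope*tA + intercept``. This is what makes the serial reduction
    well-posed: the retained population keeps the pixels bright in exactly
    one channel, whose anti-correlated contribution drives the correlation
    firmly negative once the threshold falls below the colocalized signal,
    giving a single zero crossing. (Restricting to pixels below threshold in
    *both* channels instead truncates a positively correlated cloud, whose
    correlation never goes systematically negative — the stopping rule would
    then fire on sampling noise.)

    Returns ``None`` (undefined) when the set holds fewer than 2 pixels or a
    constant channel.
    """
    x, y = _flat(a, b, mask)
    sel = ~((x > tA + _GRID_TOL) & (y > slope * tA + intercept + _GRID_TOL))
    xs, ys = x[sel], y[sel]
    return _pearson_from_sums(
        xs.size,
        float(xs.sum()), float(ys.sum()),
        float((xs * xs).sum()), float((ys * ys).sum()), float((xs * ys).sum()),
    )


# ---------------------------------------------------------------------------
# Shared scan engine

class _CostesScanEngine:
    """Evaluates below-threshold pixel counts and correlations at arbitrary
    candidate thresholds, with an O(n log n) nested fast path when the
    regression slope is non-negative (the below-threshold sets are then
    nested in tA and fully determined by their size)."""

    def __init__(self, x: np.ndarray, y: np.ndarray, slope: float, intercept: float):
        self.x, self.y = x, y
        self.slope, self.intercept = slope, intercept
        self.nested = slope >= 0.0
        self._corr_by_count: dict[int, float | None] = {}
        if self.nested:
            # a pixel leaves the below-threshold population once tA drops
            # under min(a, (b - intercept)/slope): both channels above
            if slope > 0:
                entry = np.minimum(x, (y - intercept) / slope)
            else:
                entry = np.where(y > intercept + _GRID_TOL, x, -np.inf)
            order = np.argsort(entry, kind="stable")
            self._entry_sorted = entry[order]
            xs, ys = x[order], y[order]
            z = np.zeros(1)
            self._cs_x = np.concatenate([z, np.cumsum(xs)])
            self._cs_y = np.concatenate([z, np.cumsum(ys)])
            self._cs_xx = np.concatenate([z, np.cumsum(xs * xs)])
            self._cs_yy = np.concatenate([z, np.cumsum(ys * ys)])
            self._cs_xy = np.concatenate([z, np.cumsum(xs * ys)])

    def counts_at(self, tAs: np.ndarray) -> np.ndarray:
        """Vectorized pixel counts for an array of candidates (nested path)."""
        assert self.nested
        return np.searchsorted(self._entry_sorted, tAs + _GRID_TOL, side="right")

    def corrs_for_counts(self, counts: np.ndarray) -> np.ndarray:
        """Vectorized correlations for pixel counts; NaN where undefined.

        Uses the identical arithmetic as the scalar path so sign decisions
        agree bit-for-bit across strategies.
        """
        assert self.nested
        n = counts.astype(np.float64)
        with np.errstate(divide="ignore", invalid="ignore"):
            va = self._cs_xx[counts] - self._cs_x[counts] * self._cs_x[counts] / n
            vb = self._cs_yy[counts] - self._cs_y[counts] * self._cs_y[counts] / n
            cov = self._cs_xy[counts] - self._cs_x[counts] * self._cs_y[counts] / n
            r = cov / np.sqrt(va * vb)
        bad = (counts < 2) | (va <= 1e-18 * n) | (vb <= 1e-18 * n)
        r[bad] = np.nan
        return r

    def count(self, tA: float) -> int:
        if self.nested:
            return int(
                np.searchsorted(self._entry_sorted, tA + _GRID_TOL, side="right")
            )
        sel = ~((self.x > tA + _GRID_TOL) & (
            self.y > self.slope * tA + self.intercept + _GRID_TOL
        ))
        return int(sel.sum())

    def corr(self, tA: float) -> float | None:
        """Correlation of the below-threshold set at ``tA`` (None = undefined).

        On the nested path results are cached by pixel count, since the set
        is determined by its size there.
        """
        if self.nested:
            n = self.count(tA)
            if n in self._corr_by_count:
                return self._corr_by_count[n]
            r = _pearson_from_sums(
                n,
                self._cs_x[n], self._cs_y[n],
                self._cs_xx[n], self._cs_yy[n], self._cs_xy[n],
            )
            self._corr_by_count[n] = r
            return r
        sel = ~((self.x > tA + _GRID_TOL) & (
            self.y > self.slope * tA + self.intercept + _GRID_TOL
        ))
        xs, ys = self.x[sel], self.y[sel]
        return _pearson_from_sums(
            xs.size,
            float(xs.sum()), float(ys.sum()),
            float((xs * xs).sum()), float((ys * ys).sum()), float((xs * ys).sum()),
        )


def _prepare(a, b, mask):
    x, y = _flat(a, b, mask)
    slope, intercept = costes_regression(a, b, mask)
    return x, y, slope, intercept, _CostesScanEngine(x, y, slope, intercept)


def _result(tA, slope, intercept, mode, evals, converged, cycles=None):
    return CostesResult(
        tA=float(tA),
        tB=float(slope * tA + intercept),
        slope=slope,
        intercept=intercept,
        mode=mode,
        evaluations=int(evals),
        converged=bool(converged),
        cycles=cycles,
    )


# ---------------------------------------------------------------------------
# Canonical fixed-step scan

def costes_threshold_canonical(
    a: IntensityImage, b: IntensityImage, step: float = 1.0 / 255.0, mask=None
) -> CostesResult:
    """Fixed-step downward scan from max(a); the reference strategy.

    Every candidate visited with a defined correlation counts as one
    evaluation; undefined correlations are skipped and the scan continues.
    If no candidate reaches correlation <= 0 the minimum candidate is
    returned with ``converged=False``.
    """
    x, y, slope, intercept, eng = _prepare(a, b, mask)
    top = float(x.max())
    n_cand = int(np.floor(top / step + _GRID_TOL)) + 1
    tAs = top - step * np.arange(n_cand)
    if eng.nested:
        counts = eng.counts_at(tAs)
        rs = eng.corrs_for_counts(counts)
        defined = ~np.isnan(rs)
        cross = defined & (rs <= 0.0)
        if cross.any():
            idx = int(np.argmax(cross))
            evals = int(defined[: idx + 1].sum())
            return _result(tAs[idx], slope, intercept, "canonical", evals, True)
        return _result(tAs[-1], slope, intercept, "canonical", int(defined.sum()), False)
    evals = 0
    tA = top
    for j in range(n_cand):
        tA = tAs[j]
        r = eng.corr(tA)
        if r is None:
            continue
        evals += 1
        if r <= 0.0:
            return _result(tA, slope, intercept, "canonical", evals, True)
    return _result(tA, slope, intercept, "canonical", evals, False)


# ---------------------------------------------------------------------------
# Grid helpers for the accelerated strategies

def _grid(a: IntensityImage, x: np.ndarray):
    L = a.grey_levels
    denom = L - 1
    g_top = int(np.floor(float(x.max()) * denom + _GRID_TOL))
    g_lo = int(np.floor(float(x.min()) * denom + _GRID_TOL))
    return denom, g_top, g_lo


def costes_threshold_accurate(
    a: IntensityImage, b: IntensityImage, mask=None
) -> CostesResult:
    """Exhaustive grey-level scan with the pixel-count skip.

    Candidates are every representable grey level of channel A from the image
    maximum downward; the correlation is recomputed only when the
    below-threshold pixel count changed, which cannot alter the returned
    threshold because an unchanged set has an unchanged correlation.
    """
    x, y, slope, intercept, eng = _prepare(a, b, mask)
    denom, g_top, _ = _grid(a, x)
    if eng.nested:
        gs = np.arange(g_top, -1, -1)
        tAs = gs / denom
        counts = eng.counts_at(tAs)
        changed = np.ones(counts.size, dtype=bool)
        changed[1:] = counts[1:] != counts[:-1]
        rs = np.full(counts.size, np.nan)
        rs[changed] = eng.corrs_for_counts(counts[changed])
        defined = changed & ~np.isnan(rs)
        cross = defined & (rs <= 0.0)
        if cross.any():
            idx = int(np.argmax(cross))
            evals = int(defined[: idx + 1].sum())
            return _result(tAs[idx], slope, intercept, "accurate", evals, True)
        return _result(0.0, slope, intercept, "accurate", int(defined.sum()), False)
    evals = 0
    last_count = None
    for g in range(g_top, -1, -1):
        tA = g / denom
        c = eng.count(tA)
        if c == last_count:
            continue
        last_count = c
        r = eng.corr(tA)
        if r is None:
            continue
        evals += 1
        if r <= 0.0:
            return _result(tA, slope, intercept, "accurate", evals, True)
    return _result(0.0, slope, intercept, "accurate", evals, False)


def costes_threshold_fast(
    a: IntensityImage,
    b: IntensityImage,
    mask=None,
    step_r: float = 0.35,
) -> CostesResult:
    """Adaptive-step downward scan.

    The step multiplier is ``max(1, floor(r/step_r) + 1)`` grey levels, i.e.
    unit steps while the last correlation is below ``step_r``. On the first
    sign flip the skipped interval is re-scanned at unit steps (with the
    pixel-count skip), so on monotone profiles the returned threshold equals
    accurate mode while never costing more evaluations.
    """
    x, y, slope, intercept, eng = _prepare(a, b, mask)
    denom, g_top, _ = _grid(a, x)
    evals = 0
    last_count = None
    last_eval_g = None
    g = g_top
    step = 1
    while g >= 0:
        tA = g / denom
        c = eng.count(tA)
        if c == last_count:
            g -= step
            continue
        r = eng.corr(tA)
        if r is None:
            last_count = c
            g -= 1
            continue
        evals += 1
        if r <= 0.0:
            if last_eval_g is not None and last_eval_g - g > 1:
                # backtrack: unit-step rescan of the skipped interval
                prev_count = eng.count(last_eval_g / denom)
                for j in range(last_eval_g - 1, g, -1):
                    tj = j / denom
                    cj = eng.count(tj)
                    if cj == prev_count:
                        continue
                    prev_count = cj
                    rj = eng.corr(tj)
                    if rj is None:
                        continue
                    evals += 1
                    if rj <= 0.0:
                        return _result(tj, slope, intercept, "fast", evals, True)
            return _result(tA, slope, intercept, "fast", evals, True)
        last_count = c
        last_eval_g = g
        step = max(1, int(r / step_r) + 1)
        g -= step
    return _result(0.0, slope, intercept, "fast", evals, False)


def costes_threshold_faster(
    a: IntensityImage, b: IntensityImage, mask=None
) -> CostesResult:
    """Weighted bisection over the candidate grey-level window.

    The window ``[lo, hi]`` starts at ``[min(a), max(a)]`` (in grey levels).
    Each cycle probes the 5/6 position of the window (descending): a positive
    correlation discards the top 1/6 (the target is lower), a non-positive or
    undefined one discards the bottom 5/6 (the target is at or above the
    probe). Every cycle therefore discards at least 1/6 of the window. When
    the window narrows below one grey level a unit-step downward scan
    finishes the search, matching accurate mode on monotone profiles.

    Evaluations count distinct below-threshold pixel sets whose correlation
    was computed; ``cycles`` counts bisection iterations.
    """
    x, y, slope, intercept, eng = _prepare(a, b, mask)
    denom, g_top, g_lo = _grid(a, x)
    seen_counts: set[int] = set()
    evals = 0

    def probe(tA: float):
        nonlocal evals
        c = eng.count(tA)
        r = eng.corr(tA)
        if r is not None and c not in seen_counts:
            seen_counts.add(c)
            evals += 1
        return r

    r_top = probe(g_top / denom)
    if r_top is not None and r_top <= 0.0:
        return _result(g_top / denom, slope, intercept, "faster", evals, True, cycles=0)

    lo, hi = float(g_lo), float(g_top)
    cycles = 0
    while hi - lo >= 1.0:
        c = hi - (hi - lo) / 6.0
        r = probe(c / denom)
        cycles += 1
        if r is not None and r > 0.0:
            hi = c
        else:  # <= 0, or undefined (too few pixels: target is higher)
            lo = c
    # unit-step refinement from the top of the terminal window; scanning
    # continues below the window as a safety net on non-monotone profiles
    for g in range(min(g_top, int(np.ceil(hi))), -1, -1):
        r = probe(g / denom)
        if r is not None and r <= 0.0:
            return _result(g / denom, slope, intercept, "faster", evals, True, cycles=cycles)
    return _result(0.0, slope, intercept, "faster", evals, False, cycles=cycles)


def costes_threshold(
    a: IntensityImage, b: IntensityImage, mode: str = "faster", mask=None, **kw
) -> CostesResult:
    """Dispatch to one of the four Costes search strategies."""
    if mode == "canonical":
        return costes_threshold_canonical(a, b, mask=mask, **kw)
    if mode == "accurate":
        return costes_threshold_accurate(a, b, mask=mask, **kw)
    if mode == "fast":
        return costes_threshold_fast(a, b, mask=mask, **kw)
    if mode == "faster":
        return costes_threshold_faster(a, b, mask=mask, **kw)
    raise ValueError(f"unknown Costes mode {mode!r}; choose from {COSTES_MODES}")


# ---------------------------------------------------------------------------
# Summary statistics

def manders_coefficients(
    a: IntensityImage, b: IntensityImage, tA: float, tB: float, mask=None
) -> tuple[float, float]:
    """Manders M1/M2: fraction of each channel's intensity in pixels where
    the *other* channel exceeds its threshold (strict ``>``)."""
    x, y = _flat(a, b, mask)
    sum_a = float(x.sum())
    sum_b = float(y.sum())
    m1 = float(x[y > tB].sum()) / sum_a if sum_a > 0 else 0.0
    m2 = float(y[x > tA].sum()) / sum_b if sum_b > 0 else 0.0
    return m1, m2


def coloc_stats(
    a: IntensityImage,
    b: IntensityImage,
    costes_mode: str | None = "faster",
    manders_thresholds: tuple[float, float] | None = None,
    mask=None,
) -> ColocStats:
    """Full colocalization summary for a channel pair.

    Manders thresholds default to per-channel Otsu when not supplied. Costes
    coefficients are the Manders coefficients evaluated at the Costes
    automatic thresholds; pass ``costes_mode=None`` to skip the Costes search
    (the Costes coefficients are then reported as 0).
    """
    r = pearson_r(a, b, mask)
    if manders_thresholds is None:
        manders_thresholds = (otsu_threshold(a), otsu_threshold(b))
    m1, m2 = manders_coefficients(a, b, *manders_thresholds, mask=mask)
    if costes_mode is None:
        return ColocStats(r, m1, m2, 0.0, 0.0, None)
    cres = costes_threshold(a, b, mode=costes_mode, mask=mask)
    tB = min(max(cres.tB, 0.0), 1.0)
    c1, c2 = manders_coefficients(a, b, cres.tA, tB, mask=mask)
    return ColocStats(r, m1, m2, c1, c2, cres)
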