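# Methods

This note records the models, conventions and numerical choices behind each
measurement engine, what the synthetic fixtures do and do not emulate, and
the known limitations.

## Data model and conventions

Axes are `(z,)y,x`, indices 0-based; pixel centers sit on the integer
lattice, so pixel `(r, c)` occupies the closed square `[r−½, r+½] × [c−½,
c+½]`. Bounding boxes are half-open `[min, max)`. Intensities are float64 in
[0, 1]; integer TIFFs are scaled by their dtype maximum, float TIFFs are
assumed pre-scaled (values outside [0, 1] are clipped with a warning, since
no native range is recorded in the file). The number of representable grey
levels of the *source* (256 for 8-bit, 65,536 for 16-bit, 256 by default for
floats) travels with the image: it sets the candidate grid of threshold
searches. Foreground is always `value > threshold`, strictly — fixed so that
masks are bit-reproducible.

## Combining object sets

The disputed region is the intersection of the two foregrounds. All four
strategies are defined so that the output foreground is exactly the set
predicted by the strategy's formula (union of both foregrounds for
merge/preserve/segment; initial ∪ non-overlapping addition objects for
discard) — asserted exactly in the tests, not approximately.

"Nearest" is the exact Euclidean distance to an object's *undisputed* pixel
set, computed by one distance transform per candidate object. Distances are
rounded to 9 decimals before the argmin so genuine ties break
deterministically by source set (initial before addition) then ascending
original id. Output ids are renumbered sequentially in (source set, original
id) order.

In `merge`, disputed pixels are assigned first and touching objects fused
second, on the final adjacency graph; fusion edges are kept only between
objects from *different* source sets, so two abutting initial objects stay
separate unless an addition object bridges them (then they fuse
transitively). The alternative order — fuse before assigning — can differ on
pathological inputs; assigning first keeps every disputed pixel's owner
independent of later fusion.

In `segment`, an object whose pixels are all disputed has no seed and is
dropped; its territory goes to the nearest seeded object. If *no* object has
a seed (e.g. both foregrounds identical), seed growth is undefined and the
initial labeling is kept as-is — the only reading that preserves the
foreground-conservation contract at this degenerate point.

"Touching" defaults to full connectivity (8-neighbour in 2D, 26 in 3D),
selectable down to face connectivity.

## Thresholding

Otsu maximizes between-class variance over an `nbins` histogram spanning
[min, max] and returns the *bin edge* after the best cut (first maximum on
ties), which always lies strictly between min and max. `nbins` defaults to
`min(grey_levels, 256)`: exact for 8-bit data, tractable for 16-bit. Only
the two-class method is implemented.

The log wrapper transforms `x → log(x + ε)` with `ε = 1/grey_levels`,
rescales to [0, 1], applies the wrapped method, and inverts exactly. It is
an explicit, composable setting — the threshold it returns is on the
original intensity scale.

Adaptive mode tiles the image into near-equal blocks of roughly `window`
pixels per axis (`ceil(size/window)` blocks per axis), applies the global
method per block, inherits the whole-image threshold in blocks where the
method degenerates (constant block), and interpolates block-center values
multilinearly with edge clamping — the minimal smooth interpolant with no
extrapolation overshoot. The surface is then clamped to
`[global·low, global·high]` (defaults 0.7, 1.5) to stop runaway local
thresholds in empty regions; bounds `(1, 1)` reproduce the global method
exactly, which the tests assert to 1e-12.

Sauvola: `T = m·(1 + k·(s/R − 1))` with local mean/sd over a reflective
window; defaults `window=25, k=0.2, R=0.5` (half the 0–1 dynamic range),
following the method's standard parameterization.

## Costes colocalization

The regression coupling channel B to channel A is orthogonal (total least
squares): the slope is the principal axis of the 2×2 covariance matrix,
`slope = (s_yy − s_xx + √((s_yy−s_xx)² + 4s_xy²)) / (2s_xy)`; ordinary least
squares is available as an option.

**The below-threshold population.** A pixel belongs to the below-threshold
population unless it is above threshold in *both* channels; the population
is the complement of `{a > t_a and b > t_b}`. This choice is load-bearing.
The retained population keeps pixels bright in exactly one channel, whose
anti-correlated contribution drives the correlation firmly negative once
`t_a` falls below the colocalized signal — the profile declines monotonically
through a single zero crossing, which is what makes "reduce until the
correlation drops below zero" a well-posed stopping rule and lets a
bisection bracket the crossing. Under the alternative reading (pixels below
threshold in *both* channels), one truncates a positively correlated cloud
from above; the truncated correlation never becomes systematically negative,
the "crossing" is a sampling-noise event, and the four search strategies
measurably disagree. Both facts were verified empirically on the synthetic
fixtures.

Numerics: threshold comparisons carry a 1e-9 slack so candidate grids built
by different float arithmetic (`max − j·step` vs `g/(L−1)`) select identical
pixel sets; correlations are computed from prefix sums on the nested path
(non-negative slope, where the below-set is determined by its size) with the
identical arithmetic in scalar and vectorized form, so sign decisions agree
bit-for-bit across strategies. A correlation over fewer than 2 pixels or
with a constant channel is *undefined*: scans skip it and keep going, and
the bisection treats it as "the crossing is higher" (undefined sets occur
only below the defined region on the nested path). An unconverged scan
returns threshold 0 with `converged=False` in every mode.

Strategy details. `canonical` counts one evaluation per visited candidate
with a defined correlation. `accurate` walks every representable grey level
of channel A downward but recomputes only when the below-population pixel
count changed — an unchanged set has an unchanged correlation, so the
returned threshold is provably that of the exhaustive scan. `fast` uses step
multiplier `max(1, floor(r/0.35) + 1)` grey levels (unit steps below
r = 0.35; the constant is configurable) and, on the first sign flip after a
multi-level jump, rescans the skipped interval at unit steps with the same
pixel-count gate — each candidate is evaluated at most once, so it never
costs more than `accurate`. `faster` maintains a window `[lo, hi]` over grey
levels, initialized to `[min(a), max(a)]` after a full-set check at the top;
each cycle probes `hi − (hi−lo)/6` (the 5/6 position, descending): a
positive correlation discards the top sixth, otherwise the bottom five
sixths — at least 1/6 of the window per cycle, hence at most
`⌈log(L)/log(6/5)⌉` cycles. When the window narrows below one grey level a
unit-step downward scan (continuing past the window as a safety net on
non-monotone profiles) finishes the search. Its evaluation count tallies
distinct below-populations whose correlation was actually computed; repeated
probes of an unchanged population hit a cache.

Manders coefficients use strict `>` and default to per-channel Otsu
thresholds when none are supplied, so the module runs standalone; the Costes
coefficients C1/C2 are the Manders coefficients at the automatic thresholds.

## Per-object texture

Quantization is per object, into `levels` bins (default 8) over the
object's own min/max with a closed top bin; constant objects map to bin 0.
The GLCM counts ordered pairs whose *both* pixels lie in the object mask at
the given displacement, symmetrized by transpose-addition, then normalized.
Directions default to `(0,1),(1,0),(1,1),(1,−1)` at distance `scale` in 2D,
plus the axial `(1,0,0)` in 3D; features are averaged over directions.

Thirteen Haralick statistics are reported (the unstable fourteenth, maximal
correlation coefficient, is omitted — a standard omission). Entropies use
log₂ with `0·log 0 = 0`; a degenerate one-hot GLCM reports correlation 0;
sum variance is taken about the sum average. An object with no valid pair at
any offset reports all features 0 with a logged flag.

Crop equivalence holds *by construction*: the bounding box is expanded by
the offset distance before cropping, so every within-mask pair is
representable in the crop, and both quantization and pair counting see only
object pixels either way. The suite asserts bit-identity (not tolerance) on
50 fixtures including border-touching, adjacent and 3D objects.

## Shape

Moments are computed from pixel-center coordinates; the inertia tensor is
the central second-moment matrix (unnormalized; eigenvalues sorted
descending), eccentricity `√(1 − λ₂/λ₁)` in 2D, normalized moments
`μ_pq / n^{1+(p+q)/d}`. Perimeter uses weighted boundary-segment counting
(scikit-image's standard weights); form factor is `4πA/P²`.

The Euler number is obtained by counting cells of the cubical complex, not
lookup tables. Under full connectivity the object is the union of *closed*
unit pixels/voxels: χ = V − E + F (2D) or V − E + F − C (3D) over the
distinct vertices, edges, faces and cubes of that union. Under face
connectivity the dual open-cell count is used (a shared cell counts only
when every incident pixel is foreground). Both agree with independent
reference implementations on random masks in the tests.

Solidity divides the object size by the number of pixel centers inside the
convex hull of the object's pixel *squares* (corner points at centers
± 0.5), with closed inclusion at 1e-9 facet tolerance; one- and two-pixel
objects are 1 by convention. Axis-aligned filled rectangles and boxes score
exactly 1. A digitized disc scores slightly below 1: the hull bridges the
staircase boundary, adding a perimeter-band of centers — a property of any
hull-of-squares convention, noted so users do not read sub-unity solidity of
smooth convex objects as concavity.

## Synthetic fixtures

`make_blob_labels` packs random discs/spheres with rejection sampling (≥3 px
separation unless touching is requested); `make_object_pair` displaces
copies of the initial discs by the distance whose continuous-geometry
intersection-over-union equals the overlap target (bisection on the lens
formula; measured IoU within 0.07 of target at the default radii, inside the
0.1 contract).

`make_correlated_pair` builds three smoothed white-noise fields, maps them
through `exp` to a log-normal marginal, orthonormalizes them exactly over
the pixel sample (Gram–Schmidt), and mixes `a = √ρ·S + √(1−ρ)·N₁`,
`b = sign(ρ)√|ρ|·S + √(1−|ρ|)·N₂`, so the sample correlation equals ρ
*exactly* before quantization; each channel is then mapped linearly onto
[0, 1] (no clipping) and snapped to the 8- or 16-bit grid. The log-normal
marginal emulates the background-dominated histogram of a fluorescence
micrograph: most pixels are dim, a bright structured minority carries the
signal. This matters for the Costes search — the dim majority is never
jointly above threshold, so the below-threshold population stays large at
every candidate and its correlation profile is smooth. A symmetric marginal
instead shrinks that population to a handful of pixels near the crossing,
where the profile is sampling noise; no micrograph behaves that way.

What the fixtures do *not* emulate: cell-like morphology, per-pixel shot
noise, uneven illumination, channel bleed-through, or spatially varying
correlation. Passing tests therefore demonstrate the algorithmic contracts
(equivalences, conservation laws, oracle agreement) under controlled
statistics, not measurement validity on real specimens.

A degenerate condition worth naming: at target correlation ρ = 0 the
channels are orthogonal by construction, so the full-image correlation after
quantization is ±10⁻³ with a seed-dependent sign. When it is slightly
positive, the zero crossing sits within a few grey levels of the top of the
scan; the serial strategies find it in ~2 evaluations, which no bisection
can match, and on a near-zero correlation plateau the crossing location
itself is not well defined. Strategy identity and the evaluation-count
ordering are guaranteed only for ρ > 0 — the regime colocalization analysis
is actually about.

## Problem sizes

The property suites run at the sizes stated throughout: 104 channel pairs at
64×64 for the Costes study (13 seeds × {0, 0.3, 0.6, 0.9} × {8, 16}-bit), 50
texture fixtures (46 at 48², 4 at 20×24²), 50 object-set pairs at 48² with
overlaps spanning 0–1 plus 8 oracle pairs at 32², and brute-force shape
oracles at 32² and 16³. These sizes keep every brute-force oracle exact and
the whole suite fast while exercising each code path (borders, touching
objects, both bit depths, 2D and 3D).
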