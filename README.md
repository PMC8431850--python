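# microquant

A measurement toolkit for segmented microscopy images. Given plain TIFF
intensity images (2D or 3D, 8/16-bit or float scaled 0–1) and integer label
images (0 = background, positive ids = objects), it provides five measurement
engines behind one library API and one `microquant` command line:

* **combine** — merge two independently segmented object sets into one label
  image, with four strategies for resolving the *disputed region* (pixels
  claimed by objects from both sets): `merge` joins touching objects and hands
  each disputed pixel to the nearest initial-set object, `preserve` keeps
  initial objects intact and adds only the non-overlapping parts of new
  objects, `discard` adds only objects with zero overlap, and `segment`
  re-segments disputed pixels by seeded nearest-seed growth.
* **threshold** — a global/adaptive thresholding engine: two-class Otsu,
  any global method run blockwise in *adaptive* mode (block-center thresholds
  multilinearly interpolated into a per-pixel surface, clamped around the
  global value), Sauvola local thresholding
  `T = m · (1 + k·(s/R − 1))`, and a log-transform wrapper usable with any
  method.
* **coloc** — colocalization statistics for a channel pair: Pearson *r*,
  Manders coefficients `M1 = Σ aᵢ[bᵢ > t_b] / Σ aᵢ` (and symmetrically `M2`),
  and the **Costes automatic threshold**: starting from the brightest
  candidate, the channel-A threshold `t_a` is serially reduced — channel B
  coupled through an orthogonal regression `t_b = α·t_a + β` — until the
  Pearson correlation of the below-threshold pixel population reaches zero;
  the Costes coefficients C1/C2 are the Manders coefficients at those
  thresholds. Four search strategies are provided: the `canonical` fixed-step
  scan (step 1/255), `accurate` (every representable grey level, recomputing
  the correlation only when the below-threshold pixel count changes), `fast`
  (correlation-dependent step size with a unit-step backtrack), and `faster`
  (weighted bisection discarding at least 1/6 of the candidate window per
  cycle). All return identical thresholds on well-posed inputs, at very
  different cost.
* **texture** — the 13 classical Haralick statistics of the grey-level
  co-occurrence matrix, measured per object with per-object quantization. The
  `cropped` mode computes inside each object's bounding box (expanded by the
  offset distance); it is *bit-for-bit identical* to the full-size masked
  computation while being much faster on sparse objects.
* **shape** — per-object 2D/3D morphology: size, bounding boxes, centroids,
  central and normalized moments to order 3, the inertia tensor and its
  eigenvalues, extent, eccentricity / perimeter / form factor (2D), plus
  Euler number and solidity defined in both 2D **and 3D** (Euler by direct
  cell counting on the cubical complex; solidity by convex-hull inclusion of
  pixel centers against the hull of the object's pixel squares).

A deterministic fixture generator (`microquant.synth`) produces every input
class the toolkit measures — blob label images with controlled overlap and
channel pairs with an exact target Pearson correlation at 8- or 16-bit depth
— so the entire test surface runs without external data.

## Worked example

Generate a correlated 16-bit channel pair, run the colocalization module,
then build an object set and measure its shapes:

```bash
$ microquant synth coloc --seed 7 --rho 0.6 --bit-depth 16 --out fix/
wrote ch1.tif, ch2.tif to fix
$ microquant coloc --a fix/ch1.tif --b fix/ch2.tif --costes faster --out stats.csv
pearson=0.6000 M1=0.2917 M2=0.1392
```

`stats.csv` holds the full per-image row. The channels were generated with
target correlation 0.6 and measure `pearson = 0.59999973…` — the generator
mixes exactly orthonormalized texture fields, so the sample correlation
equals the target up to quantization. The Costes search converged to
`t_a = 0.0356`, `t_b = 0.1015` (the regression-coupled channel-B threshold)
after only 20 Pearson evaluations of the 65,536-level candidate grid, and
the Costes coefficients are `C1 = 0.492`, `C2 = 0.286`: about half of
channel A's intensity lies in pixels where channel B is above its automatic
threshold.

```bash
$ microquant synth pair --seed 7 --overlap 0.5 --out fix/
$ microquant combine --initial fix/initial.tif --addition fix/addition.tif \
      --strategy segment --out combined.tif --report report.csv
combined 6 + 6 objects (0 dropped, 487 disputed px)
$ microquant shape --labels combined.tif --out shape.csv
measured 32 shape features for 12 objects
```

The two object sets overlapped on 487 pixels; `segment` re-divided those
pixels between their claimants by nearest-seed growth, keeping all 12
objects. The first rows of `shape.csv`:

```
object_id  size  solidity  euler_number  eccentricity
1           174     0.935             1         0.763
2           103     0.851             1         0.753
3            53     0.869             1         0.788
```

Each object is simply connected (`euler_number = 1`); solidity below one
reflects the lens bitten out of each disc by its partner in the re-division.

Every command writes a `<output>.params.json` echo of its parameters, and
reruns with identical inputs, parameters and seed produce byte-identical
outputs.

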