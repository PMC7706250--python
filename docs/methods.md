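# Methods

## Model and procedure

`psared` estimates, from `n` PSA iterations `(x_k, y_k)` (incremental
effects, incremental costs), a relative-density surface and a family of
highest-density-region (HDR) contours on the cost-effectiveness plane.

**Kernel density estimate.** On an `n_bins × n_bins` grid of evenly spaced
nodes (endpoints included) the density is the Gaussian product-kernel
estimate

    f(x, y) = (1/n) Σ_k φ((x − x_k)/s_x)/s_x · φ((y − y_k)/s_y)/s_y

with per-axis kernel scales `s = h/4` and the normal-reference bandwidth

    h = 4 · 1.06 · min(sd, IQR/1.34) · n^(−1/5).

The rule assumes the data are roughly unimodal at the scale of interest; it
oversmooths sharply multimodal clouds slightly, which is the standard,
deliberate trade-off of automatic reference rules. Quartiles for the IQR use
linear interpolation between order statistics (type 7, numpy's default), so
the rule is exactly reproducible: for the values 1…10 it gives
h = 4·1.06·sqrt(82.5/9)·10^(−1/5) = 8.0997….

If exactly one of `sd` and `IQR/1.34` is zero (heavily tied data), the other
is used; if both are zero the axis is degenerate and bandwidth selection
raises an error advising jitter or a manual `Bandwidths` override. The KDE is
evaluated as a separable two-factor product (`O(n · n_bins)` kernel
evaluations plus one matrix product), so 10,000 iterations on a 1000-bin grid
take seconds, and is deterministic bit-for-bit.

**Grid extents.** Default extents are exactly the sample minima/maxima per
axis (an explicit window overrides them). Kernel tail mass falling outside
the window is truncated; the cumulative transform below renormalizes over
the in-plot mass, so contour levels are *conditional on the plotted window*.
With default extents at n = 10,000 the truncated mass is a fraction of a
percent and the coverage tests confirm calibration survives it.

**Relative density.** For display, densities are divided by their maximum
(equivalently multiplied by the reciprocal of the maximum), giving a 0–1
scale with 1 at the densest cell. This changes nothing downstream — the
cumulative map is scale-invariant.

**Cumulative-probability map.** Cell masses (density × cell area, cells
being node-centred with area Δx·Δy) are sorted descending and accumulated;
each cell receives the running total, divided by the total in-plot mass, at
the end of its tie block. Tie blocks make the map independent of sort order
and send a uniform grid to 1 everywhere. The final running total is pinned
to exactly 1 (cumsum round-off is ~1e−13 at 10⁶ cells). The level-p HDR is
`{cells : cumprob ≤ p}`; HDRs are nested by construction.

**Contours.** Iso-lines of the cumulative surface are extracted by marching
squares with linear edge interpolation (scikit-image's `find_contours`;
saddle cells resolved by that implementation's documented rule). A level may
own zero (level below the densest cell's own mass share — warned), one, or
several polylines; lines meeting the grid boundary are clipped there and
flagged open. Contours are taken on the cumulative surface rather than raw
density iso-lines so a level *is* a cumulative probability; because the map
is a monotone transform of density, the line geometry coincides with the
corresponding density iso-line.

**Point-in-region queries.** Empirical coverage interpolates the cumulative
surface bilinearly at the sample points and counts values ≤ p. This avoids
polygon-containment ambiguity for boundary-clipped lines; the two approaches
agree away from boundaries.

## Tunable parameters

| parameter | default | units | rationale |
|---|---|---|---|
| `n_bins` | 1000 | nodes/axis | image is visually smooth and contour placement stable; fewer bins give rough contours, more only cost memory/time |
| `contour_levels` | 0.1, 0.5, 0.95 | cumulative probability | conventional inner-core / median-mass / near-total trio |
| bandwidths | automatic per axis | axis units | normal-reference rule above; manual override via `Bandwidths` |
| `wtp_thresholds` | none | currency per effect | drawn as `cost = λ·effect` through the origin (standard CE-plane convention) |
| `zoom_window` | none | axis units | re-filters the sample and recomputes all stages on the subsample (a new plot of that area, not a crop) |
| colormap | blue → green → yellow → red | — | fixed 4-anchor gradient, monotone in normalized density; user-overridable anchors |

"Bins" count grid *nodes* per axis; nothing at 1000 bins depends on the
node-vs-cell distinction.

## Synthetic data

The three generators (all seeded `numpy.random.Generator(PCG64)`) emulate
the regimes the method must handle, not any particular model's numbers:

* `simulate_bivariate_normal` — independent N(mean, sd²) axes; the analytic
  validation case (HDR radii `sqrt(χ²₂(p))`).
* `simulate_skewed_psa` — effects ~ Gamma(shape α, rate β), costs linear in
  effects plus Gaussian noise. Defaults α = 0.5, β = 5 put the effect density
  mode at 0 and the mean at α/β = 0.1, reproducing the geometry seen in real
  models with α < 1 gamma/beta inputs where base case and PSA mean fall
  outside the densest contour region. Default cost parameters (base 4000,
  slope 10000, noise sd 500) give a currency-scaled, strongly correlated
  cloud typical of published PSAs.
* `simulate_bimodal` — a two-component normal mixture; defaults (modes at
  (0,0) and (10,10), sd 0.5) separate the modes far enough that mid-level
  contours are provably disjoint.

What these fixtures do **not** emulate: parameter correlation structures of
real decision models, beta-distributed utility axes, heavy cost tails, or
iteration counts beyond 10⁴. Passing tests therefore demonstrate correctness
of the density→cumulative→contour machinery and its calibration on smooth
clouds, not fidelity to any specific published model output.

## Numerical choices and degenerate inputs

* CSV cells are parsed with exact `float()` so write→read round-trips are
  bit-identical; decimal commas are rejected with the offending row number.
* A PSA sample may have zero spread on an axis (legal data); the failure is
  raised at bandwidth selection, where it is actionable.
* Negative round-off in the KDE matrix product is clipped at 0.
* Coverage/HDR self-consistency is exact up to one cell's mass (discreteness
  of the grid), and empirical coverage at level p converges to p at rate
  governed by KDE error, verified at n = 10,000, 1000 bins to within 0.01
  (level 0.95) and 0.02 (levels 0.1, 0.5).
* At n = 10,000 the 0.95 contour of a normal cloud has ~3 % vertex-radius
  noise (relative KDE error at that level is ~20 %), so its max/min radius
  ratio typically falls in 1.14–1.20 even though the *mean* radius matches
  the analytic 2.45 within 0.02–0.05. Cross-checked against an independent
  R implementation of the same estimator, which agrees to four decimals.

## Problem sizes

The test suite runs the full study conditions — 10,000 iterations, 1000-bin
grids — once per session for the calibration and geometry checks, and uses
40–400-bin grids for unit and property tests where the contract is
resolution-independent. The acceptance script uses 10,000 iterations and
1000 bins.

## Limitations

* Fixed (non-adaptive) Gaussian bandwidths; very sharp modes (e.g. gamma
  shape ≪ 1) are smoothed, so small-level coverages on such data run a few
  points high. The normal-case calibration is unaffected.
* Contour levels are conditional on the plotted window (in-plot mass
  renormalization); zooming changes them by design.
* No polygon-area integration, polyline smoothing, CEAC computation, or
  RData import.
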