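# Methods

## The model

`turingrowth` simulates a two-morphogen reaction–diffusion (Turing) system
on a fixed rectangular grid with periodic boundaries, coupled to tissue
growth. The fields are a substrate `a` and an autocatalytic activator `b`
(dimensionless concentrations). One synchronous explicit-Euler step reads

```
a' = clamp( a/(1+g·dt) + (16 − a·b/(1+g·dt)² + d·r·s·∇²a) · dt ,  0,   4.4 )
b' = clamp( b/(1+g·dt) + (a·b/(1+g·dt)² − b/(1+g·dt) − 12 + d·s·∇²b) · dt ,  3.5, 100 )
```

with `dt = 0.002`. `∇²` is the nine-point (Moore-neighbourhood) Laplacian
`[[1,4,1],[4,−20,4],[1,4,1]]/6` with periodic wrap on both axes; it is
evaluated in difference form (neighbour − centre), which makes the
homogeneous state exactly stationary in floating point. The kinetics have a
homogeneous fixed point at `(a, b) = (4, 4)`; `s` (scale) and `r` (ratio)
set the two diffusivities `D_a = d·r·s` and `D_b = d·s`. Since `r > 1`, the
substrate diffuses faster than the activator and the system forms spots
(high `b`, depleted `a`) or stripes depending on `(s, r)`.

### Growth

Growth is represented *indirectly* on the fixed grid, through two effects
applied at every step of the growth phase:

* **dilution** — both concentrations are divided by `(1 + g·dt)`, following
  the update rule verbatim;
* **diffusion decay** — the multiplier `d` (initialised to 1) is divided by
  `(1 + g·dt)²`, so the pattern wavelength measured in grid units shrinks
  exactly as if the domain had stretched by `(1 + g·dt)` per axis.

The tissue surface is therefore tracked as `S(t) = 1/d(t)`: one growth step
multiplies it by `(1 + g·dt)²`. Growth is off until iteration `t_start`
(a classic Turing pattern organises first), runs at rate `g` until
`S ≥ max_surface`, and is off again while the system relaxes. An
equivalent reading of the growth bookkeeping — per-step surface factor
`(1 + g·dt)` with diffusion decaying by one factor of `(1 + g·dt)` — was
implemented and probed during development; it yields the same
final-equilibrium motif-count deficits, and the `(1 + g·dt)²` form was kept
because it follows the published update rule term-for-term and fits the
published iteration budgets. Keeping `S = 1/d` in either case is what makes
the no-growth baseline (below) and the growth runs comparable on one
effective-size axis. With `couple_diffusion=False` only dilution acts
(an option because the published description can be read either way).

Anisotropic growth (e.g. stronger lateral growth in a floral organ) is
available as per-axis rates `(g_y, g_x)` with per-axis diffusion decay
through an axis-split Laplacian; the surface advances by
`(1+g_y·dt)(1+g_x·dt)` per step and dilution uses the geometric mean of the
axis factors. This path is a small pure-numpy implementation intended for
qualitative scenarios only.

### Presets and defaults

The five named presets pin `(s, r, g, initial condition, t_start)`:
leopard (6, 30, 0.05, noise, 10000), emu (10, 6, 0.05, middle stripe,
10000), pomacanthus (10, 6, 0.05, middle stripe, 20000), ictidomys
(6, 30, 0.01, periodic stripes, 1000), tetraodon (10, 8, 0.075, noise,
10000). Values not pinned by the presets are package defaults, chosen once:

* `max_surface = 4.0` (the middle of the calibration size grid) — the
  final sizes of the published scenario figures are not stated;
* grid 200×200 for production runs, 128×128 in tests and calibration;
* noise initial condition: uniform ±0.5 around (4, 4), clipped to the clamp
  ranges (any small perturbation seeds the instability; the original noise
  law is unstated);
* stripe initial conditions: stripes of elevated `a` (at its ceiling) of
  width `max(3 px, 5% of the cross axis)`, on the fixed-point background,
  plus a ±0.05 seeded perturbation so the along-stripe symmetry can break
  (needed for stripe→dot fragmentation);
* snapshots every 250 iterations, plus exact extra snapshots at the start
  and end of the growth phase.

The inner loop is a numba-compiled stencil kernel; a pure-numpy stepper
with identical semantics backs it and the two are cross-checked in the test
suite. Histories are bit-reproducible from the config seed.

## Colour rendering

`render_instant` paints one snapshot, either thresholded (two pole colours)
or as a continuous palette interpolation in `a` (out-of-equilibrium
intermediate states give intermediate colours). `render_memory` averages the
thresholded readout over the stored snapshots: a pixel's final colour is the
fraction of the patterning period it spent in each state, which is how
rosette interiors and intermediate bands acquire a third colour. Averaging
weights are uniform per snapshot, so the snapshot cadence (recorded in the
output manifest) is part of the render definition; a flag restricts the
average to the growth phase onward. The default binary threshold is
`a = 3.0`: at pattern equilibrium `a` is depleted inside spots (≈2.5) and
elevated in the background (≈3.4), and the whole field sits below the
homogeneous fixed point (4), which is therefore *not* a usable threshold.

## Pattern metrics

* **Binarization** — `pixel = 1 iff value > threshold`. The default
  threshold maps the fixed point `a = 4` into the image's units (integer
  dtype range, [0,1] floats, or raw field units).
* **Motif counting** — binary images: 8-connected components. Greyscale:
  prominence-based maxima (`h_maxima` with the tolerance as the height),
  maxima merged when connected at the tolerance level — the same idea as the
  "find maxima" detector in common image software. Default tolerance: 10% of
  the image's value range (the tolerance used in the original counts is not
  published). The binary path is validated against a brute-force flood-fill
  oracle.
* **Spectra** — centred 2D DFT magnitude; post-processing applies log10
  (zero bins mapped to the smallest positive magnitude first, then shifted
  non-negative), normalization by a maximum, and a hard threshold keeping
  bins ≥ 1/20 or 1/100 of the maximum. The reference maximum is taken over
  the off-centre bins — the DC bin is the image mean, not a periodicity —
  and either per image (`own_max`) or shared across a picture series
  (`series_max`), which is what makes thresholded spectra of different
  developmental stages comparable. `radial_band_set` divides the off-DC
  plane into equal-width annuli and reports which contain surviving power,
  plus a richness score; multi-periodicity claims ("the intermediate stage
  carries both the early and the late periodicity") are tested as band-set
  inclusion with a one-band tolerance.

## Growth maps

Per-segment growth factors are length ratios between two developmental
stages. The per-pixel map is the inverse-squared-distance weighted mean of
the segment factors, with Euclidean point-to-segment distances floored at
0.5 px (the printed weighting is singular on the segment itself; the floor
makes on-segment pixels take their segment's factor smoothly). The map is
exact on segments, bounded by the factor range, linear in the factors and
invariant to segment relabelling. `region_growth_contrast` scores a map
against an occurrence mask (mean in/out, ratio, point-biserial correlation);
the published comparison was visual, so the metric is this package's own.

## The reverse method

Premise: at the end of pattern production all motifs are equally spaced, so
motif-count ratios equal length ratios at that moment. For each body
distance, the estimated formation stage is where its relative length
(linear interpolation between measured stages; the stage axis is treated as
ordinal with user-supplied absolute lengths) crosses its corrected
motif-count ratio; dispersion across distances is the interquartile range,
the per-distance wavelength is the absolute length at the estimated stage
divided by the corrected count, and the consensus wavelength is the median.
Ratios outside the observed trajectory range are flagged as extrapolated
rather than clipped. Corrected counts stay real-valued inside the
estimator. A prose example in the source material implies the reciprocal
rule (relative size `1/(x·y)`); that is not consistent with the
equal-wavelength premise stated alongside it, so the self-consistent rule
(formation relative size = count ratio) is implemented.

**Rosette correction.** Counts made in the presence of rosettes are raised
by +15% (uncertainty band ±5 points, i.e. ×1.10–×1.20) before use: growth
after formation leaves the count below the proportional expectation.

**Delta calibration** re-derives that correction by simulation. The
expected count comes from no-growth runs at effective sizes `S ∈ {1} ∪`
final sizes (diffusion multiplier fixed at `d = 1/S`, 30 000 iterations),
fitted through the origin (`N = c·S`; residuals < 10%). Each (growth rate,
final size) scenario on the grid rates {0.01, 0.02, 0.05, 0.1, 0.2} ×
sizes {2.5, 4, 5.4} is run at 128×128 with growth from `t = 10000` and a
25 000-iteration relaxation tail (at least 45 000 iterations in total),
over 3 seeded replicates. `delta = 100·(c·S − N)/(c·S)` is reported at the
end of growth and at the final state; scenarios whose motif count did not
increase during growth (growth too fast to produce growth patterns, judged
by the median over replicates) are flagged and excluded from the
recommended correction. Motifs are counted on the `b` field (the activator,
whose maxima are the pigment spots).

At this scale the final-equilibrium deficit averages ≈13–15% with
per-scenario means inside the 10–20% band, reproducing the +15% correction.
The deficit measured at the instant growth stops is substantially larger
(≈30–55% for the rates that form growth patterns) because the growth phase
(1 700–42 000 steps) is comparable to the system's pattern-response time
(a few thousand steps), so the count lags the moving target and only
catches up during relaxation; the published growth-end band (16–20%) is not
reproduced at this reduced scale.

## Survey records

Records carry two four-level labels (`Y`/`M`/`N?`/`N`) for classic and
growth-generated patterns, the growth-pattern categories (rosettes,
intermediate bands, mixed colours, line-and-dots), and the two qualifying
criteria flags (≥3 motifs; not based on a pre-existing periodicity). A
growth-pattern `Y` must satisfy both flags and cite at least one category;
violations are returned as data, not exceptions. Tallies report counts and
percentages per label combination at survey precision (integer percent,
one decimal below 5%). Tree-leaf colour export uses the precedence
growth-`Y` > classic-`Y` > none, with lighter shades for the `M` classes
(the published legend does not state a precedence; this one matches its
reading "growth pattern found in at least one species"). Storage is CSV,
one record per row, categories semicolon-joined — the original database
schema is not published, so this schema is reconstructed from the survey's
description.

## Synthetic data

All test inputs are generated, seeded and bit-reproducible:

* **blob images** — Gaussian blobs at rejection-sampled centres with a
  minimum separation (ground truth for motif counting);
* **trajectory sets** — linear growth trajectories passing through an exact
  integer number of wavelengths at the prescribed formation stage (so the
  noiseless reverse-method recovery is exact by construction), with the
  reference distance growing slowest so relative trajectories are strictly
  monotone; optional multiplicative noise on the counts only;
* **segment tables** — random landmark segments with uniform growth
  factors in [1, 4];
* **record sets** — survey records with a prescribed label composition.

What these emulate is the *structure* of the real inputs (morphometric
tables, motif counts, survey databases), not their content: real landmark
coordinates, embryo measurements and species records exist only as figures
in the source material. Passing tests therefore demonstrate the estimators'
correctness and calibration on data with known ground truth, not claims
about any particular species.

## Numerical notes and limitations

* Explicit Euler with `D_a·dt = 0.36` is just inside the nine-point-stencil
  stability bound (0.375); the hard clamps additionally bound any transient.
  Divergence (non-finite fields) raises an error naming the iteration.
* Snapshots are stored as float32 to keep long histories small; all
  arithmetic is float64.
* Motif counts at a given tolerance are discrete; proportionality residuals
  and deltas inherit that discretisation (a few percent at 128×128).
* The simulator reproduces qualitative pattern classes and the quantitative
  delta calibration; published scenario figures themselves are not pixel
  targets.
* Off-lattice or remeshed growing domains, tissue mechanics and 3D are out
  of scope, as are automatic landmarking and the processing of photographs.
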