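# Model and methods

## The problem

Percentages of heat-altered lithic artefacts (reddening, lustre,
potlids) are widely used as a proxy for past fire use in Palaeolithic
layers where hearth features themselves did not survive. The proxy is
indirect: most heated lithics were not dropped into a fire but were
*already buried* under a later hearth. The fraction of a layer's
assemblage that ends up heat-altered therefore depends not only on how
often fire was used, but on site size, where hearths and knapping
scatters were placed relative to each other, how many times the site
was occupied, and how much sediment accumulated between occupations.
`pyrolith` simulates this interplay so that an observed fire-proxy
percentage can be confronted with explicit occupation scenarios.

## Thermal buffering (deterministic sub-model)

A hearth's heat signature in the substrate is modelled as a spherical
cap: chord diameter `d` at the surface and height `H`, the maximum
depth of the 250–300 °C isotherm (the visible-discoloration threshold
for iron-bearing siliceous stone). With `a = d/2` the cap sits on a
sphere of radius `R = (a² + H²) / (2H)`, and the heated cross-section
at depth `z` has area

    A(z) = π (H − z) (2R − (H − z)),   0 ≤ z ≤ H,   A(z ≥ H) = 0.

The *heatable fraction* at depth `z` is `A(z)/A(0)`. Tabulating its
decrease per 1-cm step and averaging over the `H` steps gives a mean
per-centimetre loss (e.g. 100/6 ≈ 16.7 %/cm for a 50-cm hearth with
6-cm penetration). The layer's **TB value** multiplies this mean by the
sediment thickness deposited per occupation and rounds half-up to a
whole percent, capped at 100. The 1-cm averaging step is fixed
regardless of the sediment interval; this is what makes the calculator
self-consistent across intervals (17 % at 1 cm ⇒ 33 % at 2 cm for the
same basin). For caps deeper than hemispherical (`H > a`) the
cross-section is not monotone in depth; hearth basins in practice are
much shallower than that, and the monotonicity properties documented in
the tests assume `H ≤ a`.

## Occupation engine (stochastic sub-model)

A layer is `m` ordered occupations of a grid of 50-cm cells (interior /
wall / exterior). Per occupation, in this order (ordering matters: a
scatter is never heated by its own occupation's fires):

1. **Fires.** If the occupation is fire-bearing (skip pattern: 1-based
   occupation `i` bears fire iff `(i−1) mod (skip+1) = 0`), each of the
   `fires_per_occupation` hearths is placed — a single cell (50-cm
   hearth) or a 2×2 block (1-m hearth). `FR` draws anchors uniformly
   over valid positions; `FNP` draws uniformly over valid anchors
   within Chebyshev distance `NEAR_RADIUS` of a uniformly chosen hearth
   anchor of the most recent fire-bearing occupation (first fire, or
   empty neighbourhood: fall back to `FR`). Hearths may overlap.
2. **Heating.** Each hearth immediately heats the cohorts buried under
   its footprint: a cohort deposited `k` occupations earlier lies under
   `k` sediment increments, and each of its still-unheated lithics is
   heated with probability `p(k) = max(0, 1 − k·TB/100)` (one binomial
   draw per cohort per fire event). Heating is absorbing: a heated
   lithic never reverts. The rule implies a hard heating window — gaps
   `k ≥ ceil(100/TB)` can no longer heat — which produces the plateau
   of heated percentage against occupation count (onset ≈ 20
   occupations at TB 5).
3. **Scatters.** Each of the `scatters_per_occupation` knapping
   scatters deposits `lithics_per_scatter` lithics (default 100). In
   fire-bearing occupations, `round(introduced_pct)` % of each scatter
   (default 1 %) enters a burning hearth: these lithics are deposited
   already heated into the covered cells of one uniformly chosen
   current hearth. The rest is deposited unheated according to the
   placement mode: discrete scatters (`LSR` random centroid, `LSNF`
   centroid within Chebyshev `NEAR_RADIUS` of a current hearth cell)
   spread over a 3×3 kernel — 60 % centre, 8 % per orthogonal, 2 % per
   diagonal neighbour, wall/exterior kernel cells zeroed and the
   remainder renormalised, integer counts by largest-remainder
   apportionment with a fixed row-major tie-break (so a 100-lithic
   scatter in the open reproduces 60/8/8/8/8/2/2/2/2 exactly); `LR`
   places each lithic in an independent uniform interior cell; `LU`
   splits lithics evenly over all interior cells.

The output statistic is the percentage of all deposited lithics that
are heated at the end of the layer. A *session* repeats the experiment
(default 30 replicates, as in the reference runs this package
reproduces) and reports mean ± sample SD (n−1 denominator).

### Choice of stochastic (binomial) heating

A deterministic-fraction rule would have the same expectation; the
binomial rule was chosen because replicate scatter in reference runs is
reported as a standard deviation across experiments, implying
per-lithic stochasticity.

### Closed-form check for random placement

For `FR` size-1 fires with any spatially unbiased lithic mode, a lithic
deposited at occupation `s` on an `N`-cell surface survives all later
fire-bearing occupations `t` unheated with probability
`Π_t (1 − p(t−s)/N)^fires`, because fire anchors are i.i.d. uniform and
independent of lithic positions. `expected_heated_pct_random` evaluates
this expectation exactly (including the introduced share and skip
patterns); the test suite requires simulated session means to agree
with it within three standard errors. The oracle is analytic and never
used by the simulator itself.

### Calibration of the "near" neighbourhoods

The near-placement strategies are qualitative ("near previous fires",
"knapping near the fire") and need a neighbourhood scale on a 50-cm
grid. A Chebyshev radius of 1 (3×3) makes hearths re-stack almost
perfectly and roughly doubles the heated percentages of every
near-placement case-study scenario relative to their documented
outcomes. The radius was therefore calibrated once against the
documented Layer-1 base scenario (FNP/LSNF, one 50-cm fire, TB 4 →
≈19 %): **radius 2 (5×5, i.e. within ~1 m)** for both FNP anchoring and
LSNF centroids reproduces it, keeps the two-fire variant within its
documented spread, and preserves the documented ordering of both
case-study chains. Known limitation: with this single radius the
1-m-fire near-placement scenarios still come out higher (≈47 % and
≈41 % vs documented ≈33 % and ≈28 %) — the amplification of clustering
by fire size is flatter in the reference outcomes than any fixed
neighbourhood radius reproduces. Orderings are unaffected; treat
absolute near-placement values for 1-m fires as upper-bound-ish.

## Random streams and reproducibility

One master seed per configuration. Experiment `i` of session `j` uses
`numpy` `SeedSequence([seed, j, i])`, so experiments are independent,
order-independent, and reproducible across machines; re-running a
session with the same seed yields byte-identical CSV logs (floats are
written at full `repr` precision). Seeds must be non-negative.

## Case-study layers

The two shipped cave layouts have exactly 80 and 160 interior cells
(20 m² and 40 m² of floor). The original outlines are not reproducible
from the published figures; the shipped shapes are fixed convex-ish
blobs bounded by wall cells, generated once and frozen as area files.
Random-placement results depend only on the interior-cell count;
near-placement results are mildly shape-sensitive, which is part of the
calibration uncertainty discussed above. The layers' TB values derive
from the calculator: 0.25 cm sediment per occupation with 6-cm
penetration → TB 4 (warm scenario); 1.5 cm with 3-cm penetration →
TB 50 (cold scenario).

## Problem sizes and numerical choices

Reference sessions use 30 experiments (their historical size); the
oracle-agreement tests use 200 so the Monte-Carlo standard error is
well below the effects being checked. Grids up to 25×25, 30–100
occupations and ≤4 fires per occupation run in milliseconds per
experiment. Rounding of TB values is half-up (ties-away-from-zero on
the positive axis); apportionment ties are broken by fixed kernel
order. Degenerate inputs are rejected with explicit errors: empty
grids, a 2×2 hearth on a grid with no 2×2 interior block, non-positive
basin dimensions or sediment thickness, empty layers when computing a
percentage.

## Out of scope

No post-depositional disturbance (bioturbation, deflation), no
inflation of fragment counts by thermal fracture, no decay of hearth
visibility with time, no heat-transfer PDE (the isotherm depth is an
input), no import of real site plans, no 3-D stratigraphy.
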