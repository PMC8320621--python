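# Methods

## Drop-shape model (adsa)

The meridian contour of an axisymmetric drop is integrated from the apex as
the Bashforth–Adams system in arc length s,

    dφ/ds = 2/R₀ + c·z − sin φ / r,   dr/ds = cos φ,   dz/ds = sin φ,

with c = Δρ·g/γ (converted to 1/mm² for lengths in mm and γ in mN/m) and z
measured from the apex toward the pedestal, so c > 0 for a sessile drop and
the Bond number is β = c·R₀². The sin φ / r singularity at the apex is
removed by starting the integration at s₀ = 10⁻⁴·R₀ from the series
expansion φ = s/R₀ + c·s³/(8R₀), r = s − s³/(6R₀²), z = s²/(2R₀). The
integrator is adaptive Runge–Kutta (scipy RK45, rtol 10⁻¹⁰) with terminal
events at (i) the first radial crossing of the pedestal radius, (ii) drop
closure (r returning to the axis) and (iii) turning angle π, beyond which a
knife-edge-pinned profile would self-intersect; (ii) and (iii) raise a
geometry error. The returned contour is sampled on a uniform arc-length grid
plus the exact termination point.

Surface area (2π∫r ds) and volume (π∫r² dz) use trapezoidal quadrature on
the stored grid; with the default output step the quadrature error is well
below 10⁻⁵ relative, confirmed against the spherical-cap closed forms at
zero Bond number.

**Hydrostatic distortion direction.** With the apex radius and pedestal
fixed, increasing Δρ makes the integrated profile strictly *taller*
(curvature grows with depth, bending the contour toward the axis), so the
max-radius/height ratio decreases monotonically in β. The shape family is
scale-invariant: multiplying γ and Δρ·g·R₀² by the same factor leaves the
dimensionless contour unchanged, which is why only β is identifiable from
shape alone and the fit requires a known density difference.

### Inverse problem

`fit_surface_tension` minimizes the sum of squared point-to-curve distances
between the observed contour and a densely sampled forward profile over
(log γ, log R₀), with the apex fixed at the origin (apex detection and
registration are upstream image-processing steps, not modeled here).
Numerical choices that matter:

* Distances are projections onto the polyline **segments** adjacent to the
  nearest sampled vertex; nearest-vertex distances alone carry a
  half-spacing discretization noise that flattens the cost gradient.
* Candidate profiles are integrated to a fixed arc length (1.15× the
  observed contour's), never to a radial stop: a radial stopping condition
  jumps discontinuously when a candidate's equatorial bulge grazes the
  target radius, which breaks the optimizer exactly in the near-tangential
  geometries where it is most needed.
* Levenberg–Marquardt with an explicit finite-difference step (10⁻³ in log
  parameters), large enough that differenced shape changes clear the forward
  integrator's tolerance; multi-start over γ initializations because the
  shape response saturates at both Bond-number extremes; a final
  derivative-free (Nelder–Mead) polish because the (γ, R₀) valley is nearly
  degenerate at low β and LM can stall a fraction of a percent from the
  floor. R₀ is initialized from the apex-local paraboloid z ≈ r²/(2R₀).
* Δρ = 0 raises an identifiability error: a zero-Bond drop is spherical at
  every γ.

**Accuracy and its limits.** On noiseless contours the fit recovers γ to
better than 0.01% across β ∈ [0.05, 2]. With Gaussian coordinate noise the
error is set by the statistical identifiability of the shape, not by the
optimizer: the profiled likelihood in γ flattens as 1/β, so at β = 0.05 a
1 µm noise level on a 2 mm drop leaves ~5% scatter while at β ≥ 0.5 it
leaves well under 1%. The validation grid therefore uses a 2 mm apex radius
(10 µL-scale drop), contours sampled at 1.25 µm arc spacing (1400–1800
points, high-resolution sub-pixel edge extraction scale), and a pedestal at
~90% of each shape's equatorial bulge radius so every contour is a deep,
well-conditioned cap; the reported noisy figure is the mean absolute error
pooled over the grid (100 replicates), about 1.4%.

## Film simulator (simulate)

The generator emulates what the instrument records, not film mechanics:

* Area cycling is exactly sinusoidal, A(t) = A₀(1 − a/2 + (a/2)cos 2πft),
  f = 20/60 Hz, sampled at 10 Hz; defaults A₀ = 50 mm², a = 0.25 (below the
  30% QC bound; a = 0.35 builds a QC-failing trace).
* Surface tension interpolates between a dose-dependent floor and γ_max at
  full expansion: γ(t) = γ_floor(D) + (γ_max − γ_floor(D))(1 − c(t))ᵖ + ε,
  where c(t) ∈ [0, 1] is the normalized compression and
  γ_floor(D) = γ_f0 + (γ_f∞ − γ_f0)·D/(D + D₅₀) saturates in the cumulative
  dose D = J·t. Defaults: γ_max = 40 mN/m (clean-interface scale),
  γ_f0 = 2 mN/m (functional film, below the 5 mN/m QC bound),
  γ_f∞ = 25 mN/m (inhibited plateau, above the 10 mN/m dysfunction
  threshold), p = 1, ε i.i.d. N(0, 0.3² mN²/m²) on γ only — the area is
  pump-controlled. The analytic time at which the floor crosses a threshold
  T, t* = (D₅₀/J)·(T − γ_f0)/(γ_f∞ − T) (in minutes), is the ground truth
  for dose-estimation checks; for the defaults, the 10 mN/m crossing is at
  cumulative dose (8/15)·D₅₀.
* A saturating (Hill-type, exponent 1) dose–response was chosen over a
  mechanistic adsorption/squeeze-out model: the assay's published rules
  concern threshold crossings of per-cycle minima, which this reproduces
  with two interpretable parameters (D₅₀, J).
* Exposure starts at t = 0 and dose accrues continuously. A consequence
  worth knowing: a chemical whose floor crosses 5 mN/m inside the baseline
  window correctly fails baseline QC, so simulated "inhibitory" chemicals
  must cross 10 mN/m after the baseline (t* ≳ 55 s for the default 5-cycle
  baseline with d₅₀-proportional flux); the end-to-end validation draws
  crossing times in 60–100 s on 240 s traces.

Outcome panels are generated margin-exactly: given per-scenario (TP, FN,
FP, TN) margins that agree on the in vitro positive count, labels are
assigned by seeded permutation; clinical positivity is realized as actual
raw-sign observations (synonyms of the six lexicon terms in windows H0–H2)
and negativity as non-respiratory or late observations, so the concordance
stage exercises the real standardization path. What the generator does
*not* emulate: instrument drift, evaporation, correlated (non-white) noise,
partial inhibition with recovery, and volatile-compound dosimetry failure —
passing tests say nothing about those.

## Trace analysis (traces)

Cycles are delimited by successive prominence-filtered local maxima of the
area signal (prominence ≥ 10% of the area range, so sub-sample jitter does
not split cycles); the trace is padded by one virtual sample so maxima at
the boundaries count, and partial cycles beyond the last maximum are
discarded. Per cycle the **minimum γ sample** is extracted — the rule speaks
of the minimum reached at minimal area, but with noise the two can differ by
a sample, so the minimum over the cycle is the conservative reading and the
area at the minimum is recorded so the alternative remains computable.

QC uses the first 5 complete cycles (configurable; the assay does not define
the span): lowest minimum strictly < 5 mN/m and mean compression ratio
strictly < 30% — values exactly at a threshold fail. Inhibition is a run of
≥ 3 consecutive minima ≥ 10 mN/m (inclusive); the onset is the first cycle
of the earliest run and the onset time is that cycle's minimum-γ sample
time. Replicates failing QC are discarded (not re-interpreted); a chemical
is called inhibitory when ≥ 50% of QC-passing replicates are positive
(majority rule; the aggregation rule is not published, so it is a config
value and discordant sets are flagged). All thresholds live in
`AssayCriteria` / the YAML `criteria:` block.

Inhibitory dose: dose/area = flux × onset time (min), total mass =
dose/area × mean cycling drop area (mm² → cm²); volatile chemicals return
"not estimable" because deposited-mass measurement is unreliable for them.

## Concordance

GHS reference label: positive iff category ∈ {3, 4}; category 5 and
unclassifiable chemicals are negative (the binary rule names only 3 and 4).
Clinical reference label: positive iff ≥ 1 standardized respiratory sign in
windows H0–H2; later windows are ignored. The synonym table mapping raw
observation strings to the six lexicon terms ships as editable YAML; terms
matching no entry are reported as "unmapped", never dropped silently.
Metrics are exact `Fraction`s; display rounding is half-up to 2 decimals
(so 3/8 → 0.38, 17/21 → 0.81); zero-denominator metrics are undefined, not
coerced. Wilson 95% score intervals (statsmodels) attach on request, off by
default.

## Problem sizes used in validation

Bond grid of 5 β values with 20 noisy replicates each (100 fits); 10,000
random minima series for the detector/oracle check; 50 simulated chemicals ×
4 replicates × 240 s traces for end-to-end recovery; the 26-chemical
reference panel for the predictivity table. These sizes give stable
statistics at desk-scale runtimes (a few minutes on one CPU).

## Known limitations

* The ADSA fit assumes apex-registered contours; apex detection and image
  segmentation are out of scope.
* Only the first radial crossing of the pedestal is modeled; drops bulging
  wider than the pedestal and re-entrant pinned shapes are rejected rather
  than fitted.
* The inhibition model is phenomenological; D₅₀ and J are not mapped to any
  specific chemical's physical properties.
* In vivo observations (GHS categories, rat clinical signs) are inputs;
  nothing here derives categories from LC50 or models rat physiology, and
  per-chemical identities in the reference panel are not claimed — any
  assignment with the published margins yields identical metrics.
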