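# Methods

This note documents the models, numerical choices and limitations of
`inkwindow`, in the spirit of the methods documentation of statsmodels or
scanpy: what each stage assumes, which knobs matter, and what a green test
does and does not establish.

## Rheology

**Cross fit.** Flow curves η(γ̇) are fitted to
η = η∞ + (η₀ − η∞)/(1 + (kγ̇)^m) by least squares on **log viscosity**.
Viscosities span decades over a 0.1–300 s⁻¹ sweep; a raw-space fit would be
dominated by the low-rate plateau and essentially ignore the thinning
region. Bounds keep all parameters non-negative and m ∈ [0, 1]. The fit is
multi-started (m ∈ {0.3, 0.6, 0.9} by default; η₀ from the maximum
viscosity, k from the rate at which viscosity has dropped half a decade)
because the (k, m) coupling admits shallow local minima. For polysaccharide
solutions η∞ is far below the observable window, so pipelines pin it to zero
(`fix_eta_inf_zero=True`); the free-η∞ fit is available when a sweep reaches
the high-rate plateau. A curve whose log-viscosity spread is below 1% is
reported as Newtonian: η₀ is the (geometric) mean, k = m = 0, and the
`unidentifiable_m` flag is set — k and m have no information in the data.

**Edge-fracture truncation.** Rheometer plate sweeps lose sample from the
gap at high rates; the symptom is an implausibly steep viscosity drop. A
Cross fluid's log–log slope is bounded below by −m ≥ −1, so the auto rule
cuts the curve at the first point whose local (backward-difference) slope
falls below −1.1 (slope margin δ = 0.1, configurable). The instrument
literature gives no numeric criterion; this slope rule is this package's
construction and is therefore exposed as configuration, with an explicit
cutoff rate as the manual override. Truncation is idempotent.

**LVE plateau.** The linear-viscoelastic plateau is the longest initial run
of the stress sweep in which both moduli stay within 5% (configurable) of
their low-stress medians. The run is robust to one isolated mild outlier: it
ends only at a point beyond 1.5× the tolerance or at two consecutive
out-of-band points; a 2–3% multiplicative measurement noise otherwise kills
plateau detection with a few percent probability. Plateau moduli are plain
means over the run; the run indices are reported for audit.

**Yield onset.** τ_y is the stress at the intersection of two straight lines
fitted to log G′ vs log stress: one over the detected plateau run, one over
the post-yield decay (skipping a transition buffer of 10% of the sweep,
shrunk so that at least two decay points always remain). This mimics the
tangent-intersection "onset point" construction of rheometer software. The
construction is scale-equivariant: rescaling stress by c rescales τ_y by
exactly c. Parallel tangents or an intersection outside the sweep raise an
error rather than returning an extrapolated onset.

Replicate sweeps are fitted per replicate; report mean ± sd downstream
rather than pooling raw curves, since replicates can differ in gap loading.

## Image analysis

**Segmentation.** Construct images (dark dyed ink on a light dish) are
binarized with block-wise Otsu thresholds (default block 65 px); blocks with
less than 5% of the global intensity range fall back to the global Otsu
threshold, since Otsu is meaningless on a unimodal tile. Polarity is
ink = darker, invertible by flag. For grids, hole filling is **bounded**:
only enclosed background pockets of at most `max_hole_px` pixels (default =
`min_object_px`) are filled. Filling all enclosed pockets would erase the
grid pores that the printability index must measure; the bound removes
specular-reflection speckles inside strands while preserving pores.
Components smaller than `min_object_px` (default 50 px) are removed. Block
size and the size cutoffs are not dictated by any instrument standard; the
defaults were chosen on the synthetic fixtures and both are configuration.

**Filament measures.** Length is the extent along the principal axis of the
foreground pixels (+1 px to convert center spacing to extent); mean width
t_av is area / length, which is rotation-robust, unlike per-row averaging.
Perimeters are traced by marching squares at the 0.5 level of a lightly
Gaussian-smoothed (σ = 1.5 px) copy of the mask: on raw binary masks the
contour staircase overestimates curved boundaries by ~5%, while the
smoothed contour keeps both a 100 px disk and an axis-aligned rectangle
within ~0.3%. The smoothing rounds sharp corners by ~σ, a ≤0.1% effect at
the scales used.

**Angle fidelity.** The medial path is the longest geodesic through the
skeleton (robust to short spurs); local widths are twice the Euclidean
distance transform along it. The vertex is the path point farthest from the
chord joining the path endpoints — for a straight filament the choice is
arbitrary and AF degenerates to 1, as intended. t_line is the median width
away from the vertex (> 3 arm-widths) and away from the end caps; t_tip is
the largest inscribed-disk diameter within 2.5 arm-widths of the vertex,
searched over the mask rather than only along the skeleton, because on
strongly bulged sharp angles the discrete skeleton cuts the corner by up to
one arm-width. AF = t_tip / t_line, so sharp-angle material accumulation
gives AF > 1; the inverse convention is available by flag.

**Grid pores.** Enclosed pores are background components not touching the
image border. The "central" pores are the 16 whose centroids are nearest the
construct centroid, ties broken in row-major centroid order — the selection
rule is this package's construction; fewer than 16 detectable pores raises a
merged/incomplete-grid error. Pr = L²/(16A) per pore; the isoperimetric
floor π/4 (disk) is asserted in tests with a 0.02 discretization allowance.

**Calibration.** All metrics that leave pixel space require the µm/px
calibration; SR additionally requires the nozzle inner diameter. Neither has
a default: a 25G conical nozzle does not determine an inner diameter, so the
value must be stated (example configurations use 250 µm).

## Response surfaces

Yields are modeled as polynomials of A (alginate mg/mL), B (hyaluronic acid
mg/mL), C (pressure kPa) and, for AF only, D (angle °). The candidate set is
the full quadratic with two-way interactions — the contour curvature of the
fitted surfaces requires at least order 2, and the order is configurable.
Quadratic terms are excluded for factors with fewer than 3 levels (they are
exactly collinear with the linear term), and a rank guard drops residual
collinear terms highest-order-first.

**Centering.** The model is estimated on mid-range-centered factors
(standard DoE coding). On raw factor values A and A² correlate at ≈ 0.98
and stepwise selection becomes path-dependent: in pure-noise simulations the
per-term false-retention rate of backward elimination roughly doubles
(≈ 0.18 at α = 0.1) on the raw basis but stays near α (≈ 0.13) when
centered. Reported `coefficients` are converted back to the raw monomial
basis (exact for order ≤ 2); standard errors, p-values and the covariance
refer to the centered basis actually fitted.

**Selection.** Backward elimination refits after removing the least
significant removable term until every removable term has p ≤ α = 0.1.
Hierarchy is enforced: a parent linear term is never dropped while its
square or an interaction containing it is retained, so hierarchy-forced
parents may stay with p > α — they are retained for model validity, not
claimed significant. The model as a whole is flagged significant at
p ≤ 0.05 (overall F-test); significance stars follow the usual
legend (· ≤ 0.1, * ≤ 0.05, ** ≤ 0.01, *** ≤ 0.001). Replicates enter as
independent rows and feed the residual variance.

**Transforms.** A Box–Cox exponent is selected over {−1, −½, 0, ½, 1} by
profile likelihood under the full quadratic model, using the
Jacobian-normalized transform so likelihoods are comparable; identity is
kept whenever λ = 1 lies inside the 95% profile interval (Δlog-lik < 1.92).
Shapiro–Wilk statistics of the residuals before/after are recorded. The
chosen transform is applied un-normalized for fitting, and predictions are
back-transformed (with the domain edge λz + 1 ≤ 0 clamped, which can occur
only for band endpoints, not fitted values).

**Bands.** `predict_with_band` returns t-distribution bands on the
transformed scale, back-transformed. The default is the single-observation
prediction band — the appropriate band for validating a model with one
fresh printing trial — with the mean-confidence band selectable. Points
outside the design's factor ranges are served with an `extrapolated` flag.

## Printability window and desirability

The window is evaluated exactly on every grid cell: printable ⇔ predicted
mean Qm > 0 **and** predicted mean SR < 6 (threshold configurable). The
inequalities are strict; a cell with predicted Qm exactly 0 is unprintable.
Only predicted means are used — the window is not probabilistic. An empty
window is a flagged result, not an exception.

Projecting the window onto the rheology surfaces (functions of composition
A, B only) yields, per property, the [min, max] envelope over printable
cells — the band of η₀, k, m, G′_LVE, G″_LVE, τ_y an ink must fall in to be
printable at the window's settings.

Desirability uses the standard Derringer–Suich ramps with weight 1 (weights
exposed): minimize-mode for SR, target-mode with T = 1 for Pr. L and U
default to the min/max of the predictions over the printable cells; a
(near-)constant yield is padded by 10⁻⁹ relative so that float noise is not
amplified into an O(1) desirability spread. D is the geometric mean; any
zero desirability zeroes D. The optimum is the grid argmax — ties at the
10⁻⁶ level broken toward lower pressure, then lower total polymer (printing
at the lowest workable pressure maximizes accuracy) — refined by bounded
Nelder–Mead on the continuous D (zero outside the Qm/SR constraints), and
refinement never returns a worse point than the grid seed.

## Synthetic fixtures

The generators state a world and keep it fixed:

* Flow curves: 30 log-spaced rates over 0.1–300 s⁻¹; default Cross
  parameters η₀ = 200 Pa·s, k = 0.5 s, m = 0.7, η∞ = 0 (a mid-range
  shear-thinning blend); multiplicative lognormal noise; optional
  edge-fracture artifact as an extra power-law decay beyond 100 s⁻¹ (slope
  −3, safely past the −1.1 detection threshold).
* Stress sweeps: 0.1–1000 Pa; plateaus G′ = 250 Pa, G″ = 357 Pa with yield
  at τ_y = 500 Pa followed by power-law decay (G′ slope −2) — values of the
  same order as measured for mid-concentration alginate/HA blends.
* Constructs: anti-aliased rasters (4× supersampling so sub-pixel contour
  tests are meaningful at modest resolution) of lines (default 500 µm wide,
  5 mm long), angles (60/90/120°, tip bulge factor ≥ 1) and 20 × 20 mm
  grids at 15% infill. Grid pitch follows from the infill fraction f via
  2q − q² = f, q = strand width / pitch; pores are rounded squares whose
  corner radius emulates pressure-driven rounding. The angle renderer trims
  the arms' overlap wedge to constant width at the junction: a plain capsule
  union overfills the inner corner (bisector width 1.5× at 60° even with no
  bulge), which would make the generator's stated AF ground truth false.
  Canvas sides are even so construct edges land on pixel boundaries rather
  than centers.
* Designs: full factorials mirroring the studied layout (alginate
  {10, 20, 40, 60} mg/mL × HA {20, 40, 60, 80} mg/mL, five pressures,
  triplicates; angles {60, 90, 120}° where AF is a response), responses =
  stated polynomial + Gaussian noise.

What the fixtures do **not** emulate: uneven illumination, dish glare,
motion blur, partially translucent ink edges, non-stationary rheometer
drift, or physics of filament spreading — the renderer is geometric. A
green loop-closure test therefore establishes that segmentation + metrics
recover known geometry, not that segmentation parameters transfer to any
particular camera setup.

## Known limitations

* The angle-fidelity vertex search assumes a single open filament path;
  self-intersecting or closed paths raise a geometry error.
* Backward elimination after a data-driven Box–Cox choice does not account
  for selection in the reported p-values (standard practice, but worth
  remembering); the type-I rate of the stepwise procedure is near, not
  exactly at, α.
* The window uses predicted means only; parameter and residual uncertainty
  are available (bands) but not propagated into the window boundary.
* Rheology surfaces are treated as pressure-independent (composition only)
  when projecting the window onto rheology bands.
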