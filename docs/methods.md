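# Methods

This note documents the models, conventions, numerical choices and known
limitations of the package, in the spirit of a model-documentation page.

## Mechanical testing model

Forces are sensed through an end-loaded Euler-Bernoulli cantilever microbeam:
F = 3 E_b I δ/L³ with I = πΦ⁴/64, beam modulus E_b = 411 GPa, lengths 57–59 mm
and diameters 0.0762–0.1524 mm (indentation) or 0.3048–0.5588 mm
(compression). Commercial instruments calibrate the beam empirically, so
`CantileverSpec` accepts a user-supplied stiffness (N/m) that bypasses the
formula. Deflection-to-force conversion is linear; the homogeneity properties
(∝ Φ⁴, ∝ L⁻³) are asserted by tests.

Stepped protocols are described by (`n_steps`, `step_magnitude`,
`hold_duration`, optional `ramp_rate`). The packaged defaults are the printed
protocols: 5 × 1% steps with 1-min holds for local indentation and 8 × 2.5%
steps (20% total) with 2-min holds for unconfined compression. Boundary
convention: a sample at exactly a step boundary carries the *next* step's
load; all tail-window extractions use half-open windows accordingly. Ramps,
when rendered, are excluded from every fit — the relaxation equations are
written for post-step holds, and holds dominate the record (minutes vs
seconds).

All quantities are SI internally. CSV columns must declare units via name
suffixes (`time_s`, `force_mN`, `deflection_um`, ...) or an explicit units
config; undeclared units are rejected rather than guessed, since silent unit
errors dominate this domain.

## Indentation (Sneddon)

F = E·2Rδ/(1 − ν²) has no offset term, so the fit is a through-origin
least-squares line of steady hold force against cumulative indentation
(default punch radius 38.1 µm, ν = 0.5). The steady force is the mean over
the final `window_fraction` (default 0.2) of each hold: how the original
steady states were extracted from 1-min holds is not published, so the window
is configurable; tail averaging suppresses residual relaxation. Indentation
protocols beyond 5% of specimen height trigger a warning (outside the
small-deformation regime). A negative fitted slope is clamped to E = 0 with a
flag.

## Unconfined compression (neo-Hookean)

Strains use the engineering definitions on measured geometry; compressive
stress and strain are kept signed (negative), moduli are reported positive.
The Poisson ratio is −slope of the through-origin regression of ε_rr on ε_zz,
clamped to (0, 0.5] with a flag. For the equilibrium stress model the
derivation of σ_zz from W = (c/2)(I_C − 3) under traction-free lateral faces
gives σ_zz = c(λ_z² − λ_r²) when the lateral stretch is measured; when it is
not, incompressible kinematics λ_r = λ_z^(−1/2) give the classical
σ = c(λ² − 1/λ). Both reduce identically in the incompressible limit (a
tested identity), and which path was used is logged, since the original
estimation details are not published. The model is linear in c, so the fit is
the closed-form projection — no iteration, no convergence failure modes; c is
clamped at 0 with a flag if the projection is negative. E = 2c(1 + ν) enables
comparison with indentation (E = 3c at ν = 0.5); for small strains (|ε| ≤ 1%)
the fitted E agrees with the linear-elastic slope within 5% (tested), the
cross-scale consistency the two experiments are designed to exhibit.

## Nonlinear viscoelasticity (Maxwell-Wiechert)

The relaxation model is a nonlinear equilibrium spring
σᵢ⁰ = c_a·exp(c_b εᵢ)·εᵢ in parallel with two Maxwell elements of shared
stiffness c_m and viscosities η₁ < η₂ (ordering enforced by relabeling; the
elements are exchangeable). The printed spring-strain closed form
ε_s(t) = η ε̂/(η + ε̂ c_m(t − tᵢ)) is implemented exactly as printed; it is the
solution of the quadratic-decay dashpot law dε_s/dt = −(c_m/η)ε_s², verified
against independent ODE integration to < 1e-8 relative error. Two
consequences of that law shape the implementation:

- Relaxation is hyperbolic (1/t), not exponential: a non-negligible Maxwell
  stress remains at the end of any finite hold.
- The closed form only decays for positive spring strain; for negative ε̂ the
  denominator vanishes at t* = tᵢ + η/(−ε̂ c_m) (a domain error reporting t*).
  Signed compressive strains (ε_zz < 0) hit this divergence within the 8-step
  protocol for any realistic parameters, so the simulation and fitting
  pipeline operates on compression strain *magnitudes*; the sign convention
  (compressive Cauchy stress negative) lives at the stress-computation
  interface.

Fitting follows the two-step procedure: (1) (c_a, c_b) by nonlinear least
squares on the end-of-hold stresses (mean of the final 10% of each hold);
(2) (c_m, η₁, η₂) by least squares on the full hold-phase trace with
(c_a, c_b) frozen, multi-started from a log-spaced grid of viscosity
initializations (8 starts; scale set by ε·c_m·T_hold) with log-parametrized
bounds c_a, c_m ∈ [1, 10⁶] Pa, c_b ∈ [−50, 50], η ∈ [1, 10⁸] Pa·s. Because
of the unrelaxed 1/t tail, the staged (c_a, c_b) estimate is biased, so a
joint refinement of all five parameters on the full hold trace runs from the
staged start; noiseless traces are then recovered to optimizer tolerance.
Residuals are weighted by 1/|stress| (floored at 0.1% of the trace maximum):
the trace spans an order of magnitude across the steps and instrument noise
is closer to constant relative error, making relative weighting the
maximum-likelihood choice. A fit flags the slow element as poorly constrained
when η₂/c_m exceeds 10× the hold duration.

## Histology colorimetrics

Conversion is standard bi-cone HSL from normalized 8-bit channels in floating
point, no gamma correction; it matches the stdlib scalar implementation
(tested) and is vectorized here because the installed imaging stacks provide
only HSV. Background is lightness-thresholded: L ≥ 0.95 (white, trichrome) or
L ≤ 0.05 (black, picrosirius); the cutoffs are configurable since the original
script's values are unpublished. Hue bands are half-open [lo, hi+1°) on the
printed integer boundaries, so adjacent bands (…–12°, 13°–…) partition
without double-counting; the red band wraps through 0°. Band overlap is a
configuration error. Fractions are band pixels over tissue pixels; they are
exactly invariant to rotation, mirroring and nearest-neighbor upsampling
(tested), and unclassified tissue is allowed (trichrome has one printed band,
blue = collagen).

## Fiber metrics

Orientations are axial data, analyzed by doubling: OI = R̄(2θ). Without
doubling, uniformly random axial angles on [0°, 180°) give OI ≈ 0.64,
contradicting the 0-for-random endpoint the index is defined to have; with
doubling the endpoints hold exactly (uniform grid → 0, aligned → 1). A
non-axial mode is retained for a literal raw-angle reading, and whether
doubling was used is logged. The OI is unweighted by default (each fiber
counts once); a length-weighted variant exists but is off, as no weighting
convention is published.

## Synthetic data: what it emulates, and what it does not

Generators are pure functions of (parameters, seed) — byte-identical output
for identical arguments — and write the same formats the readers consume,
with a YAML ground-truth sidecar sufficient for regeneration.

- Mechanics: hold forces/stresses from the constitutive models above with
  additive Gaussian noise (absolute, or proportional "relative" noise for
  stress); geometry frames satisfy ε_rr = −ν·ε_zz exactly. Default truth
  parameters sit at the sub-3-kPa stiffness scale these tissues show
  (c_a = 1500 Pa, c_b = 2, c_m = 500 Pa, η₁ = 400, η₂ = 4000 Pa·s), chosen so
  the fast element decays to ~20% and the slow to ~70% within one 2-min hold
  — identifiable but not trivially so. Not emulated: drift, preconditioning
  history, adhesion, poroelastic fluid flow.
- Stain rasters: contiguous irregular class regions (quantile bins of a
  smoothed Gaussian field) with exact pixel counts; per-pixel H/S/L jitter
  inside the central part of each band (8-bit-quantization safe). Class
  fractions are requested over the whole raster, the remainder renders as
  background (white for trichrome, black for picrosirius), and the truth
  records the implied over-tissue fractions. Not emulated: stain variability,
  illumination gradients, out-of-band tissue hues.
- Fibers: von Mises on doubled angles (κ = 0 uniform; an even-grid option
  gives the exact-uniform case); truncated-normal lengths/widths/intensities.
- Cells: four phenotype archetypes (epithelial-large/-small, stroma, immune)
  with log-normal areas (positive, right-skewed), mixed within the four
  onset × tissue groups; the default group effects encode the qualitative
  shifts of interest (smaller cells and lower PanCK / higher Vimentin in
  early-onset tissue, larger cells in cancer). Not emulated: segmentation
  errors, spatial structure, marker bleed-through.

Passing tests on these inputs demonstrates estimator correctness under the
stated noise models — not robustness to the instrument and imaging artifacts
listed above.

## Group statistics

Midranks throughout. The Scheirer-Ray-Hare statistic divides each rank
sum-of-squares by MS_total = SS_total/(N − 1); using the realized rank
variance is exactly the tie-corrected form, and `tie_correction=False`
substitutes N(N+1)/12 (which published variant was used originally is
unstated, so both are available). Balanced layouts use the closed-form
decomposition; unbalanced layouts (the realistic case — specimen counts per
group differ) use Type-II sums of squares on ranks via OLS. With a
single-level factor the main effect reduces exactly to tie-corrected
Kruskal-Wallis (tested). Dunn's z uses the tie-corrected pooled variance and
Bonferroni multiplies raw p by the number of pairs, capped at 1. Fully
degenerate data (all values identical) returns H = 0, p = 1 rather than 0/0.

Type-I calibration is verified by simulation at α = 0.05: balanced 2×2 with
n = 10/cell for the two-way test (1000 replicates, all three effects) and
k = 3 groups of n = 30 for Kruskal-Wallis (n chosen at the realistic
specimen-count scale, large enough for the chi-square reference to be
accurate).

## Cell phenotyping

z-scores use population SD by default (sample SD per config; logged); they
are invariant to affine rescaling of raw features, which makes the whole
pipeline invariant to linear intensity recalibration (tested). The kNN graph
(k = 15 default; k unpublished) is symmetrized by union and clustered with
seeded Louvain at resolution 0.1. The high/low rule for phenotype naming uses
the across-cluster median with rank-based tie resolution (upper half of the
stable ordering is "high", marker axis decided first); clusters whose PanCK
and Vimentin calls agree (both high or both low) are labeled by PanCK and
flagged ambiguous.

## Problem sizes used in the packaged studies

Parameter-recovery studies use 200 replicates (indentation, 2% force noise)
and 100 replicates (relaxation, 1% proportional stress noise) at 1 Hz
sampling; statistical calibration uses 1000 replicates per test; histology
recovery uses 512² rasters. These sizes give Monte-Carlo error comfortably
below the asserted tolerances.

## Known limitations

- Uniaxial, isotropic constitutive models only; no multiaxial or anisotropic
  behavior, no poroelasticity, no adhesion or substrate corrections.
- Two Maxwell elements with shared stiffness; no continuous relaxation
  spectra. The slow viscosity is weakly identified when its time scale
  greatly exceeds the hold (flagged, not constrained).
- Region selection for histology/fiber analysis is user input (masks/crops),
  not automated; whole-slide stitching and stain deconvolution are out of
  scope.
- Cell segmentation itself is upstream; the package consumes feature tables.
- Spatial transcriptomics analysis is out of scope; only the gene-filter
  bookkeeping utility is provided.
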