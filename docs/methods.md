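# Methods

## The adsorption free-energy model

The core object is the free energy per unit length of an n-filament
septin bundle adsorbed on a membrane substrate of signed curvature `c`
(all energies in k_BT, lengths in nm internally, µm at the interfaces):

    Δg_n(c) = Δg_n⁰ (1 − a_n c / 2) + L_pn c² / 2 ,   Δg_n⁰ < 0.

Assumptions: filaments are already polymerized (no polymerization
kinetics); the filament cross-section is incompressible, so the
membrane-contact width — and hence the magnitude of the binding term —
grows linearly with concave curvature; bending is harmonic with a
persistence-length prefactor; the adsorbed filament is uniform, so a
per-unit-length treatment suffices.  The sign convention is measured on
the binding face: a convex hill or sphere exterior is positive, a
concave valley or neck circumference negative.

Because the energy is strictly convex in `c` (L_pn > 0), the closed
forms used throughout — optimum `c_n* = Δg_n⁰ a_n / (2 L_pn)`,
curved-over-flat threshold `c_n = 2c_n*`, and the maximum curvature
`c_n^max = sqrt(−2Δg_n⁰/L_pn)` obtained by dropping the (sub-percent)
contact-area term — are exact minimizers/roots, and the test suite
checks each against brute-force grid minimization over random parameter
sets.  Bundle scalings `a_n = a₁√n`, `L_pn = L_p1 n²`, `Δg_n⁰ = Δg₁⁰√n`
(circular bundle cross-section) are treated as exact definitions, and
`n` is restricted to integers.

### Default parameters

| parameter | default | units | why |
| --- | --- | --- | --- |
| `a1_nm` | 4 | nm | septin monomer size |
| `Lp1_nm` | 2000 | nm | L_p2 ≈ 8 µm measured for paired filaments; L_p scales as n², so L_p1 = L_p2/4 |
| `dg1_flat` | −0.7305 | k_BT/nm | calibrated so the model's minimum adsorption radius is 37 nm and its threshold radius ≈ −0.7 µm with the defaults above |
| `Kd_nM` | 88 | nM | measured per-octamer dissociation constant on flat bilayers (informational) |
| `ref_conc_M` | 1 | M | standard-state concentration for the K_d-to-energy logarithm |

Two routes to Δg₁⁰ exist and disagree: the standard-state estimate
`ln(K_d/c_ref)/(8a₁) ≈ −0.51 k_BT/nm` (exposed as
`model.dg_flat_from_kd`; it omits unmeasured entropic contributions)
and the value −0.7305 back-computed from the observed
threshold/minimum-radius chain.  The package defaults to the internally
consistent −0.7305; both are available, and
`SeptinModelParams.from_threshold_radius` calibrates Δg₁⁰ directly from
an observed threshold radius.

### Wavy-substrate orientation

On a uniaxially wavy substrate the principal curvatures at the
adsorption site are `(c, 0)` with 0 along the wave axis, so a filament
tilted by φ samples the normal curvature `c sin²φ` (Euler's formula).
The classifier follows: `c ≥ 0` or `c ≤ c_n` → straight along the axis;
`c_n* ≤ c < 0` → fully bent across the groove; in between → tilted with
`sin²φ = c_n*/c`, the angle at which the sampled curvature equals the
optimum.  The tilt-band interpolation via Euler's formula is a design
choice — the underlying theory only orders the regimes — and ties at
band edges resolve to the lower-tilt regime.  A property test verifies
the tilt angle against grid minimization of `Δg(c sin²φ)` and the
continuity of the angle (→90°) at the band edge.

### Bud-neck theory

The neck is described pointwise at the waist by independently signed
radii `(R_∥, R_⊥)`; no meridian profile is computed.  For spherical
shapes `sin θ = R_⊥/R_∥` cancels the contact-area terms and the smaller
curvature magnitude (radial) always wins; geometries with
`|R_⊥| > |R_∥|` are rejected rather than clamped.  For oblong shapes
(`sin θ = 1`) the energy gap factorizes into
`(L_pn/2)(c_∥ − c_⊥)(c_∥ + c_⊥ − c_n)`, which is used directly; the
closed-form product is cross-checked against the explicit two-energy
comparison on 10⁴ random geometries.  Exact degeneracy reports both
orientations rather than an arbitrary winner.

`stage_sequence` labels a constriction path.  Note the total curvature
`c_∥ + c_⊥` *increases* along constriction — the sharpening saddle's
positive meridian curvature outgrows the deepening negative
circumferential one — and the path validator enforces exactly that
monotonicity, which reproduces the stage order: radial on the sphere,
mixed band (`c₁ < c_∥+c_⊥ < c₂`: singles circumferential, pairs still
axial), all-circumferential past `c₂`, and ring splitting once
`|c_⊥|` exceeds `c_n^max` of the assumed bundle.  Bundling requires
additional molecular players the model does not contain, so the bundle
size for the splitting criterion is a caller-supplied parameter
(default 50, giving a ~0.7 µm minimum ring radius; 30–50 spans
0.47–0.70 µm).

## Estimators

**Persistence length.**  Tangents by central differences on the
(optionally 3-point smoothed) polyline; `⟨cos θ⟩` pooled over all
ordered point pairs across tracks and frames, equal-weighted per pair;
pairs binned by arclength separation with the *mean* separation per bin
as abscissa (an unbiased regressor, unlike the bin center).  The L = 0
bin holds only self pairs and is exactly 1.  The fit is a
count-weighted linear regression of `ln⟨cos θ⟩` on L with
`L_p = −1/(2·slope)` (2D), using bins with `⟨cos θ⟩ > 0.2` and ≥ 50
pairs by default (no fit range is prescribed by the procedure itself).
A decaying correlation requires the exponent to be negative; a
non-negative slope is reported as an estimation failure, never clipped.

**Hill isotherm.**  Nonlinear least squares of
`S_sat/((K_d/bulk)^n + 1)` with positivity bounds; initial values
S_sat = max density, K_d = concentration nearest half-max, n = 1.  The
Hill coefficient can be frozen (`fix_hill_n`); with only ~8
concentrations that do not reach saturation the three-parameter fit is
weakly identified and its K_d sampling distribution is heavy-tailed
(median unbiased, mean inflated ~15%), so the recovery studies fit with
n fixed at the generating value 1.

**Aspiration moduli.**  Bending: regression of `ln(σ/σ₀)` on `ΔA/A₀`
over points with σ ≤ 0.5 mN/m; `κ = slope/8π` in k_BT; invariant to
σ₀.  Stretching: regression of `ΔA/A₀` on σ over points with
σ ≥ 1 mN/m (cutoff configurable — the exact experimental window is not
prescribed); `K_a = 1/slope`, reported in mN/m.  Both fail explicitly
on wrong-sign slopes or too few points (4 and 3 respectively).

**Spike geometry.**  The closed contour is unwrapped to `r(φ)` around
its centroid (valid for star-shaped vesicle outlines), circularly
smoothed (5-point default), and spikes detected as maxima with
prominence ≥ 5% of the median radius — both defaults configurable since
no detection criterion is prescribed by the measurement itself.
Amplitude is peak radius minus the mean of the flanking minima radii;
spacing is the mean Euclidean distance between consecutive spike tips
(the distance one would measure on an image); the concave radius is a
least-squares (Kasa) circle fit over the valley bottom — points within
10% of the local depth above the minimum, which isolates the concave
arc from the straight spike flanks — on *coordinate-smoothed* points,
because a circle fit through raw jittered points of a shallow arc is
biased toward small radii.  Noiseless construction is recovered
exactly; at 0.02 µm jitter the residual biases are ~1% each.

## Synthetic generators

All generators are pure functions of (parameters, seed); a fixed
spawn-key registry derives independent child streams per generator and
replicate, so adding a generator never perturbs existing streams.

* **Worm-like chains** — tangent-angle random walk, i.i.d. Gaussian
  increments of variance step/L_p (step defaults to L_p/100; a warning
  marks steps above L_p/10 where discretization bias appears), giving
  `⟨cos θ(L)⟩ = e^{−L/2L_p}` in 2D.  Default study condition: 300
  chains of 10 µm contour at L_p = 8 µm, emulating ~300 frames of
  tracked filaments; an optional time-correlated mode mixes successive
  frames' angle increments while preserving the marginal statistics
  (frames are treated as independent by default).
* **Binding curves** — Hill isotherm × (1 + ε), ε ~ N(0, cv²),
  truncated at 0; defaults S_sat = 4000 µm⁻² (the order of observed
  surface densities; the saturation density itself is not reported),
  K_d = 88 nM, one-site (n = 1), cv = 5%.
* **Aspiration series** — `ΔA/A₀ = ln(σ/σ₀)/(8πκ) + σ/K_a + ε` with
  constant volume; either branch can be disabled.  With the measured
  moduli (κ ≈ 10 k_BT, K_a ≈ 40–65 mN/m) the two branches are of
  comparable size across any single tension window, so a single-branch
  fit of a combined series is biased by construction (≈30% for κ over
  the low-tension decade); the recovery studies therefore generate each
  regime with the other branch disabled, mirroring the regime each fit
  models.  The combined generator remains the default surface and its
  branch limits are tested.
* **Spiky contours** — alternating spike tips (at the base radius) and
  concave circular-arc valleys (of exactly the requested osculating
  radius, at base − amplitude) joined by tangent lines;
  arcs-plus-tangents rather than a Fourier star so the concave radius
  is an exact construction parameter.  Defaults: base 10 µm, amplitude
  0.9 µm, spacing 3.9 µm, concave curvature 1.1 µm⁻¹, 0.02 µm radial
  jitter, random rotation — the observed spiky-GUV geometry.
* **Wavy substrates** — `h(x) = A₀ sin(2πx/λ₀)` with the exact signed
  curvature field (hills positive), spanning the fabricated template
  range (A₀ 0.6–1.1 µm, λ₀ 1.8–5.8 µm).

### What the generators do and do not emulate

They reproduce the statistical structure the estimators assume —
exponential tangent decorrelation, multiplicative binding noise,
two-regime tension-area response, jittered piecewise-analytic contours.
They do not model camera/photophysics noise, tracking errors,
out-of-plane fluctuations, vesicle-to-vesicle parameter spread, or
deviations of real spike shapes from the arc-and-tangent idealization.
Passing round trips therefore demonstrate estimator correctness under
the assumed model, not robustness to the full noise structure of real
microscopy data.

## Numerical choices and problem sizes

Internal units nm / nm⁻¹ / k_BT with exact 10³ conversion at the µm
interfaces, avoiding silent unit errors.  Brute-force oracles use
10⁵–10⁶-point grids, giving curvature resolution far below every
tolerance asserted.  Recovery studies use 300 chains / 100 binding
curves / 100 aspiration series / 35 contours — the scale of the
underlying experiments — and finish in seconds.  Degenerate inputs
(zero radii, non-positive moduli, infeasible spike geometry, unordered
constriction paths) raise typed errors rather than returning clamped
values.

## Known limitations

* The per-unit-length model ignores filament ends, filament–filament
  interactions and membrane deformation feedback; it predicts
  preference bands, not densities (the observed ~2.2× top/bottom
  density ratio on wavy substrates needs a bundling/mass-action layer
  the model does not contain).
* The bud-neck stages are evaluated pointwise at the waist; no membrane
  shape evolution or constriction dynamics.
* The two printed single-filament optimal-curvature statements in the
  source measurements are mutually inconsistent (−1.4 µm⁻¹ vs the
  −0.7 µm threshold-radius chain); the package follows the consistent
  radius chain and the consistency check asserts band membership
  (0.7–1.4 µm⁻¹) rather than a point value.
* `R₂^min` evaluates to 62.2 nm where 63 nm is conventionally quoted
  (rounding in the source chain).
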