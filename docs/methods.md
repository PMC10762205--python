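# Methods

## The model

A phagophore is an open double-membrane cisterna whose inner and outer
membranes are closely juxtaposed (fixation that preserves the native state
keeps them attached), so the whole organelle is treated as a **single
axisymmetric surface of revolution with a free circular rim**. The meridian
is parametrized by arc length `s` from the pole (`s = 0`, on the symmetry
axis) to the rim (`s = s₁`); `θ(s)` is the tilt of the tangent against the
radial plane, and `x(s)`, `z(s)` follow from `ẋ = cos θ`, `ż = sin θ`.
The principal curvatures are the meridional `J_m = θ̇` and the parallel
`J_p = sin θ / x`; `J = J_m + J_p`, `K = J_m J_p`.

The free energy at fixed membrane area `A` and rim length `L` is

    F = 2π ∫₀^{s₁} [ κ_b x (J − J₀)² + 2 κ_G θ̇ sin θ
                     + 2 γ_A x + γ_L ẋ ] ds ,

the **doubled-membrane convention**: both membranes are counted, so
`A = 4π ∫ x ds` and a closed double sphere has elastic energy
`16π κ_b + 8π κ_G` (Gauss–Bonnet). `κ_b` is the bending modulus (default
20 k_BT), `κ_G` the Gaussian/saddle-splay modulus (default −0.2 κ_b; lipid
bilayers fall in −κ_b < κ_G < 0), `J₀` the spontaneous curvature (default
0: the membranes carry few proteins), and `γ_A`, `γ_L` the Lagrange
multipliers conjugate to `A` and `L` (γ_L is the rim line tension).

Since `F` is scale invariant up to the line term, shapes are reported in
units of `√(A/2π)` and parametrized by the dimensionless rim radius
`l = x_r / √(A/2π) ∈ (0, 1)`: `l = 1` is a flat cisterna, `l → 0` a closed
sphere (stomatocyte).

### Shape equations and the regular formulation

Varying `θ` with the constraint `ẋ = cos θ` (multiplier `γ_x`) gives the
Euler–Lagrange system. The textbook reduction eliminates `γ_x` through the
conserved Hamiltonian `H = 2x θ̇ u + γ_x cos θ − x u² − 2 γ_A x`
(`u = θ̇ + sin θ/x − J₀`), which vanishes identically because `x(0) = 0`
forces `H = γ_x(0) = 0`; the result is the familiar second-order equation

    θ̈ = −(tan θ/2) θ̇² − θ̇ cos θ / x + sin 2θ / (2x²)
         + γ_A tan θ + (tan θ/2)(sin θ/x − J₀)² ,

exposed as `shape_rhs` and verified in the tests against a numerically
differentiated Lagrangian. It is singular at `θ = ±π/2`, which late cups
cross. The **solver therefore integrates the pre-reduction system instead**,
keeping `γ_x` as a dynamical variable:

    θ̇ = ψ
    ψ̇ = [γ_x sin θ/2 − ψ cos θ + sin θ cos θ/x] / x
    γ̇_x = u² − 2 (sin θ/x) u + 2 γ_A ,     γ_x(0) = 0 .

This is regular everywhere except the pole, which is entered through the
series `θ = θ̇₀ s + a₃ s³`, `16 a₃ = θ̇₀ (2γ_A − J₀(2θ̇₀ − J₀))`, starting at
`s = 10⁻⁴ s₁` (results are insensitive to the offset down to 3·10⁻⁶).

### Boundary conditions

At the free rim two conditions hold. The **moment balance**

    θ̇ − J₀ + (1 + κ_G/κ_b) sin θ / x = 0      at s = s₁

is the shooting target; it is algebraically the statement
`M_m = κ_b J + κ_G J_p = 0` (no external torque on the open edge), i.e.
`κ_G/κ_b = −J/J_p` at the rim. The **force balance** determines the line
tension. In its usual printed form it divides by `cos θ(s₁)` and degenerates
where the rim tangent is vertical; on-shell it is exactly

    γ_L = −γ_x(s₁) ,

which is finite and smooth along the whole branch and is what the package
reports (the printed form is kept as a test cross-check away from
`θ(s₁) = π/2`).

### Solving and continuation

With `s₁ = 1` fixed by scale invariance, equilibria are found by
two-parameter shooting on `(θ̇₀, γ_A)` against (moment-balance residual,
`l − l_target`), warm-started by marching `l` downward from the near-flat
limit. Cup solutions bifurcate from the flat disk at
`γ_A* = −μ²` where `μ J₀(μ) + κ_G J₁(μ) = 0` (Bessel functions; μ ≈ 2.317
for κ_G = −0.2), which seeds the march. Spontaneous curvature and other
Gaussian moduli are reached by continuation in `J₀` or `κ_G` from the
solved branch. Integration uses adaptive RK45 at rtol 10⁻⁹ (10⁻¹⁰ for the
final refinement), root-finding at xtol 10⁻¹²; a converged solution has
moment-balance residual and `l` error below 10⁻⁷ (in practice ~10⁻¹⁵).

**Branch structure.** The branch continued from the flat disk runs without
any fold in `l` all the way to closure; along it `γ_A < 0` everywhere and
the elastic energy rises monotonically to the Gauss–Bonnet value
(F(l=0.02) = 45.07 vs 16π κ_b + 8π κ_G = 45.24 κ_b). Mapping the full
solution set of the shooting problem reveals two further stationary
families: a wavy-saucer family bifurcating from the flat disk at the second
Bessel mode (μ ≈ 5.48), and a curled-lip family in which the rim rolls
through more than 270°; both have strictly higher energy wherever they
coexist with the principal branch (e.g. +16 κ_b at l = 0.13) and the
curled-lip family has γ_A > 0. Ties between multiple shooting roots are
broken by minimum energy, which always selects the principal branch.

**Flat-limit energetics.** The bending energy vanishes linearly in `1 − l`
with slope ≈ 73 κ_b, so even at `l = 0.99` it is still 0.73 κ_b under the
doubled-membrane convention (0.36 κ_b per membrane). A "bending energy
below 0.5 κ_b at l = 0.99" check therefore fails by construction under the
canonical convention; the trend itself (F_bend → 0 as l → 1) holds.

## Normalization and the σ_e ↔ l mapping

Experimental clouds are z-score normalized: centroid to zero, RMS spread
`σ_X` to one. The normalized rim size `σ_e` (RMS deviation of the edge
points from their own mean) is the staging statistic. For a theoretical
shape, `σ_e = x_r / σ` where `σ` is the RMS spread of the surface — which
depends on the **measure** used to turn the surface into a point cloud:

- `meridian` (default): equal weight per arc-length element, i.e. the cloud
  is an evenly spaced profile polyline revolved with the same number of
  points per ring. A flat disk gives σ_e = √3.
- `area`: weight ∝ ring circumference (uniform sampling over the surface,
  the convention of real segmentations and of the synthetic generator).
  A flat disk gives σ_e = √2, and **no** equilibrium shape exceeds √2.

The published mapping pairs (σ_e, l) = (1.45, 0.8), (0.75, 0.39),
(0.48, 0.24), (0.28, 0.13). Since 1.45 > √2, those reference values can
only arise from a meridian-uniform cloud, so that is the default measure.
On the principal branch it gives

    σ_e(0.8)  = 1.456     σ_e(0.39) = 0.752
    σ_e(0.24) = 0.467     σ_e(0.13) = 0.255 .

Three of the four reference pairs are reproduced to better than 0.015. The
**late-cup pair is not**: σ_e(0.13) computes to 0.255 (area measure: 0.259),
not 0.28, and inverting instead gives l = 0.143 for σ_e = 0.28. The value is
fully converged (invariant under tolerance, pole-offset and quadrature
refinement) and measure-robust. Intriguingly, the metastable curled-lip
family does pass through (l = 0.13, σ_e = 0.274), but selecting it would
contradict both energy minimization and the γ_A < 0 property of the
reference branch, so the package reports the principal-branch value and
flags the discrepancy rather than switching branches to match.

`l_of_sigma_e` inverts the mapping by bracketed root search; σ_e(l) is
monotone for l ≲ 0.85 and folds near the flat limit (σ_e rises from √3 to a
maximum ≈ 1.46 before the disk limit), where a multi-root report is raised
instead of a silent pick.

## Gaussian-modulus estimation

`κ_G/κ_b = −J/J_p` is exact **at the rim**. Along an equilibrium meridian
the ratio moves fast inside a rim boundary layer: −0.20 at the rim, −0.25
one percent of arc inward, −0.30 at two percent. Consequently:

- A **whole-shape cubic fit** cannot resolve the layer; applied to dense
  samples of solved shapes it returns −0.71 / −0.79 / −1.53 at
  l = 0.6 / 0.4 / 0.2 — biased far beyond the target. The bias is
  quantified in the tests as a diagnostic.
- The package's estimator (`gaussian_modulus_from_points`) fits the same
  cubic family **to the rim neighbourhood only** (default window: top 5% of
  the axial extent) and evaluates at `z_rim` itself. On dense noiseless
  samples of solved shapes it recovers −0.199 / −0.203 / −0.205 at
  l = 0.2 / 0.4 / 0.6.
- On **noisy pooled clouds** the narrow window is variance-dominated; there
  the whole-shape fit (or a wide window) is the right tool. On the
  spherical-cap stand-ins of the synthetic study the whole-shape fit
  correctly returns −2 — a cap's rim is isotropic (J = 2 J_p), and caps are
  not equilibria of the bending model, so the out-of-range flag is the
  expected outcome there.

Estimates outside (−1, 0) are flagged, never clipped.

## Synthetic serial-section generator

The generator emulates array-tomography acquisition of a segmented
organelle: a known surface (a solved equilibrium shape, or a spherical cap
— whose squared radius is exactly quadratic in z, giving closed-form fit
targets) is sampled **uniformly by surface area** (inverse CDF of the
cumulative area along the meridian, uniform azimuth), scaled to physical
units (default 500 nm), rotated to an arbitrary orientation, optionally
compressed along the stack axis, quantized to 25 nm sections, and
perturbed by 2 nm in-plane Gaussian tracing noise (segmentation error lives
in-section; the stack coordinate error is the quantization itself).
Structures of 300–600 points emulate the tracing density of real
segmentations; structures spanning fewer than 3 sections are rejected.

**Edge annotation.** Real segmentations mark the two endpoints of each open
section contour — two dots per section, lying on the rim circle. The
default `paired` mode reproduces this geometry by intersecting the rim
circle with the section planes. The pairing matters: each pair's mean lies
on a fixed diameter of the rim circle, so the mean edge vector converges to
the ring centre. Randomly flagged rim-band points (the alternative `band`
mode) instead leave an azimuthal sampling error of order `ρ/√(2M)` in the
ring mean — several degrees of orientation error at any realistic edge
count — so the band mode is kept only as an explicit option.

**What the generator does not emulate.** Contours are not traced as
connected in-section curves (body points are independent area-uniform
draws); membranes have no thickness; no cargo deformation, no attachment to
other organelles, no anisotropic shrinkage other than the single stack-axis
factor. Passing recovery tests on this data therefore validates the
geometry pipeline, not robustness to biological confounders.

## Estimator error floors (measured)

- **Orientation.** The mean-edge-vector estimator carries an intrinsic
  statistical floor: the cloud centroid (which normalization subtracts)
  fluctuates transversely by ≈ √(E[x²]/N), giving an axis error of
  ≈ 2–3° RMS at N ≈ 450 points — independent of section spacing (verified
  by a spacing sweep) and worst for shallow saucers, whose mean edge vector
  is short. A 2° bound sits just below this floor; the measured study mean
  is 2.7° (max ≈ 10° for the shallowest stage).
- **Rim size.** σ_e is recovered within 1–2% for middle/late cups; the
  shallowest (σ_e ≈ 1.3) caps reach ≈ 5–6% because their edge ring carries
  most of the signal and their axial extent spans only 3–4 sections.
- **Profile coefficients.** OLS standard errors absorb the
  section-quantization scatter, so 3-SE coverage of the closed-form cap
  coefficients is ≈ 96% (the truth must be mapped through the *estimated*
  axis; mapping through the true axis misattributes orientation error to
  the linear coefficient).
- **Stack-axis scale.** The axisymmetry cost (azimuth-sector variance of
  the radius in equal-count axial bins, after removing the quadratic axial
  trend per bin) recovers a known compression to ~0.5–1% at n = 2000
  points; the binning gives it a finite resolution floor, so recovery is
  not exact even for noiseless data.

## Other numerical choices

- Stage thresholds are applied literally as printed; σ_e values in the gaps
  (0.4–0.5, 0.7–0.8, 1.0–1.1) are labeled `unclassified` rather than
  silently assigned.
- k-means clustering (features: σ_e plus a 10-bin normalized radial
  profile) is exploratory parity only; the σ_e thresholds are the operative
  classifier.
- `fit_profile` fits squared radius (linear least squares, uniform
  weights); the positivity domain of the fitted cubic is bounded by its
  real roots, truncated to the data range when positivity is unbounded
  (a fitted cylinder would otherwise acquire spurious far-away roots).
- The azimuth of an already-aligned cloud is defined as φ_e = 0 (atan2
  tie-break); rotation about z is a symmetry of everything downstream.
- The rim-torus line tension `γ_L = (κ_b/2) π r (1/r − J̄_r)²` uses the
  thin-rim limit `l ≫ r`; a flag is raised when `l < 10 r`, and the exact
  half-torus quadrature is available as `torus_rim_energy`.
- Degenerate inputs fail loudly: coincident points, missing edge flags,
  structures under 3 sections, negative σ_e, rank-deficient fits, rim
  radius targets outside (0, 1).

## Known limitations

- The rim is a line: no finite intermembrane gap or rim swelling, no
  membrane thickness.
- Equilibrium only: no dynamics of growth, no stability analysis beyond
  energy comparison and perturbation stationarity of the returned branch.
- The σ_e ↔ l mapping reproduces three of the four reference pairs; the
  late-cup pair disagrees by 0.025 in σ_e on the minimal-energy branch (see
  above), which is documented rather than absorbed.
- Pooled-cloud modulus estimates inherit the bias/variance trade-off of the
  fit window; on real (non-cap) data the whole-shape fit mixes rim and body
  curvature and should be read as a lower bound on κ_G/κ_b.
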