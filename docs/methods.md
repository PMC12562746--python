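# Methods

## Model

The simulator treats the sensor as a one-dimensional stratified medium:
semi-infinite glass ambient (n = 1.5) on both sides, a finite stack of
homogeneous, isotropic layers in between, and plane-wave illumination at
angle θ (measured in the incident medium) with TE or TM polarization.
Conventions, fixed everywhere:

* time dependence e^(−iωt); forward waves e^(+ik_z z); passive media have
  κ ≥ 0 and Im ε ≥ 0; evanescent/absorbed branches take Im k_z ≥ 0;
* k_z = (2π/λ)·√(ε − n_inc² sin²θ); the polarization admittance is
  q = k_z (TE) or k_z/ε (TM);
* the stack matrix M is the ordered product of interface-plus-propagation
  factors ½[[(1+h)e^(−iφ), (1−h)e^(+iφ)], [(1−h)e^(−iφ), (1+h)e^(+iφ)]]
  with h = q_next/q_prev and φ = k_z,next·γ_next, whence r = M₂₁/M₁₁,
  t = 1/M₁₁, R = |r|², T = Re(q_exit)/Re(q_inc)·|t|² (a power ratio also
  for unequal ambient media) and A = 1 − R − T identically.

Internal fields are obtained by peeling the amplitude pair (a, b) layer by
layer from the incidence side; the reported field is E_y for TE and H_y for
TM, normalized to unit incident amplitude.

The engine is pinned by closed-form oracles evaluated independently of the
matrix code: Fresnel coefficients (single interface, both polarizations,
oblique incidence, total internal reflection), the Airy single-film
summation, the quarter-wave Bragg-mirror admittance formula, and energy /
reciprocity / TE–TM-degeneracy invariants, all enforced at 1e-8..1e-12.

## Materials

* TiO₂ and SiO₂ follow Cauchy laws n(λ) = A + B/λ² + C/λ⁴ (λ in µm) valid
  on 0.30–1.25 µm, with coefficients (2.39513, 0.03471, 0.00835) and
  (1.46705, 0.00364, −3.049·10⁻⁶).  Both are normally dispersive over the
  whole validity window.  Evaluation outside the window is an error, never
  an extrapolation.
* Ag, Au, Cu use the Johnson & Christy (1972) n/κ tables, vendored as
  3-column text files covering 0.413–1.937 µm, interpolated separately in
  n(λ) and κ(λ) with a monotone piecewise cubic (PCHIP).  The scheme is
  recorded in every output header because resonance positions, and
  especially linewidths, are sensitive to it: a few percent change in κ
  near 900 nm moves the Tamm wavelengths by several nm and the cavity
  FWHM by ~10%.  Published wavelengths are therefore reproduced only to
  interpolation accuracy (sub-nm for the three baseline resonances here).
* The analyte is a non-dispersive real index n_a ≥ 1 — one number per
  glucose concentration, as in the underlying sensing model.

## Geometries

`build_baseline(n_a, metal)`: glass | (SiO₂ 130 / TiO₂ 75)×5 | SiO₂ 130 |
TiO₂ 65 | M 30 | analyte 1000 | M 30 | (TiO₂ 100 / SiO₂ 150)×6 | glass,
27 finite layers, light incident on the PC1 side.  The thinned 65 nm TiO₂
layer abuts the metal (it tightens the TPP1 confinement); the high-index
layer also abuts the metal on the PC2 side — the standard Tamm-supporting
ordering.  Where the published description leaves the intra-mirror ordering
and the ambient open, this variant was fixed once because it reproduces the
three printed resonance wavelengths, and is kept frozen; both choices are
overridable through the stack-config format.

`build_enhanced(n_a)`: (SiO₂ 60 / TiO₂ 47)×6 + TiO₂ 47 mirror, 60 nm Ag
films, PC2 with TiO₂ 120 / SiO₂ 200 — 28 layers.  The thicker metal
decouples the references from the cavity and narrows the cavity line; no
Tamm mode remains inside the 750–1100 nm scan window, which is why its
sensitivity is evaluated with the stationary-reference convention (below).

## Resonance measurement

Dips are detected on a 0.1 nm coarse grid (prominence ≥ 0.05), refined by
bounded minimization of R(λ) to ~1e-4 nm, and measured at the midpoint
between the refined minimum R₀ and the local baseline.  The baseline is the
maximum reflectance within ±50 linewidth-estimates of the dip: for dips
sitting on a bandgap plateau this is the plateau itself (neighboring
features are also dips), and unlike a windowed median it is not biased by
the resonance's own Lorentzian tails — the bias budget of the median
variant breaks the 1e-3 nm synthetic-linewidth recovery this package holds
itself to.  Q = λ₀/FWHM and G = (1−R₀)/FWHM(µm) follow directly.  Dips
whose half-depth crossing leaves the grid are flagged `edge`, not dropped.

Modes are classified by field localization at the dip wavelength:
f_A > 0.5 → cavity; 0.3 ≤ f_A ≤ 0.5 → hybrid (the angular anticrossing
regime); otherwise Tamm, with the side given by the location of the
intensity maximum.  The 0.3/0.5 thresholds are implementation choices
exposed as function arguments.

The cavity eigenfrequency is also computed without any spectrum by solving
k = [2πm − arg r₁(k) − arg r₂(k)]/(4π n_a d_A) as a damped fixed point
(damping 0.5, tolerance 1e-8 µm⁻¹), with r₁, r₂ the half-stack reflection
coefficients seen from inside the cavity; the order m is scanned over 1–6
and solutions inside the bandgap kept.  Agreement of this route with the
reflectance-dip route to within half a linewidth is part of the acceptance
suite.  The analogous Tamm diagnostic evaluates
arg r_DBR + arg r_metal + 2k_z n d for the terminal dielectric adjacent to
the metal and reports the distance to the nearest 2π multiple; the
round-trip propagation term references both phases to a common plane, and
the residual vanishes (< 0.5 rad) at the detected Tamm dips.

Angular maps R(θ, λ) are scanned at 0.5° × 0.2 nm; branches are traced by
nearest-dip continuation with a 10 nm/° jump limit, and the anticrossing
angle is the point of minimal branch separation (flagged when a branch is
lost or the separation is flat to 2%, i.e. non-interacting branches).

## Sensitivity conventions

S = (Δλ_cavity − Δλ_TPP)/(n_a − 1.335) subtracts the measured drift of the
chosen Tamm reference (`reference="TPP1"`/`"TPP2"`).  With 30 nm silver
films the Tamm tail penetrates into the analyte (f_A ≈ 0.13 for TPP1), so
the references co-move by ~0.04 nm per 0.001 RIU and the corrected S
(≈ 608 nm·RIU⁻¹) sits ~6% below the conventional Δλ_cavity/Δn
(≈ 644 nm·RIU⁻¹).  The published table values correspond to the
idealization of a perfectly stationary reference — Δλ_TPP ≡ 0 — which is
available as `reference=None` and is the convention used when reproducing
those tables.  The FWHM entering FoM = S/FWHM is the cavity-dip width at
the same n_a as the S measurement.

Broad-range sweeps (n_a = 1.00–1.75, step 0.05) follow a single
longitudinal order with the phase solver rather than by dip picking, since
over so wide a span different orders enter the spectral window and
dip-based tracking would mode-hop.  The branch is linear to R² > 0.99999
with slope ≈ 693 nm·RIU⁻¹ for the enhanced design.

## Known limitations

* Reproduction fidelity is bounded by unstated conventions of the source
  numbers: with canonical Johnson–Christy data and PCHIP interpolation the
  three baseline resonances land within 0.6 nm of the printed values and
  the baseline sensing metrics within ~1%, but the enhanced design's
  linewidth computes ~13% wider than the value back-solved from its printed
  FoM — the FoM gain of the enhanced design is correspondingly ~60% here
  rather than the published >80%.
* Exactly stationary Tamm references are an idealization; the computed
  drift is small (≲ 0.04 nm per 0.001 RIU) but resolvable at the 0.001 nm
  precision of the published tables.
* Substrates are semi-infinite (no incoherent back-face reflections), media
  are linear, isotropic and planar (no roughness or thickness disorder),
  and no noise model is attached to the metrics — S and FoM quantify the
  idealized optical response, not a limit of detection.
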