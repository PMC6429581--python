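# Methods

## Physical model

A sessile drop of volume `V` on a papilla-patterned surface is treated as a
spherical cap. The total interfacial energy
`G = γ_LV S_LV + γ_SV S_SV + γ_LS S_LS` is evaluated under four standard
approximations: (a) gravity is negligible — for a 5 µL water drop the radius
(~1.06 mm) is below the capillary length `√(γ_LV/ρg) ≈ 2.7 mm`, so the cap
stays spherical; (b) the drop is much larger than the roughness, so the
liquid–vapor meniscus suspended between protrusions is planar and the liquid
volume inside the asperities is negligible; (c) the cap base equals the
projected contact area; (d) line tension is neglected. The solid–liquid and
solid–vapor tensions never appear separately: they enter only through
`cos θ_Y = (γ_SV − γ_LS)/γ_LV`, and the constant term `γ_SV·S_SV-total`
(the `reference_offset`) cancels from every energy difference, so all
energies are reported as excesses.

With those assumptions,

    G(θ; Ff) = K · F(θ)^(−2/3) · [2 − 2cosθ − sin²θ·Ff],
    K = γ_LV (3V)^(2/3) π^(1/3),   F(c) = 2 − 3c + c³,

where `Ff = r_f f cosθ_Y + f − 1` in the composite state and `r cosθ_Y` in
the wetted state. The stationary condition is `cosθ = Ff`; substituting it
gives the equilibrium energy `K·F(θ)^(1/3)`. Both forms are implemented and
tested against each other to 1e−12 relative, and the θ-minimisation is
verified against a brute-force grid search.

## Geometry

Protrusions are hemispheres (base radius `r₀`) optionally raised on
cylinders (height `h₀`), one per primitive cell of a hexagonal
(`A = (√3/2)(2r₀+2d₀)²`) or square (`A = (2r₀+2d₀)²`) lattice, where `2d₀`
is the edge-to-edge spacing. All outputs depend on lengths only through
`δ = d₀/r₀` and `η = h₀/r₀` (scale invariance, property-tested). Penetration
depth is non-dimensionalised as `x = h/r₀` from the apex; the cap-section
formulas hold on `[0, 1]` and the cylinder-section ones on `(1, 1+η]`, with
continuity at `x = 1` enforced by test. The roughness formulas are kept
general in `δ` even where the reference treatment approximates `d₀ ≈ r₀`;
at `δ = 1` the general forms reduce to the familiar `8√3` hexagonal cell
denominators. Touching hemispheres (`d₀ = 0`) are admitted; the projected
solid fraction then peaks at `π/(2√3) ≈ 0.907 < 1`, so the `f ≤ 1` invariant
cannot be violated on either lattice.

A closed form of `F` as an explicit rational function of `x` for the
hemisphere model exists but is error-prone to transcribe; the implementation
always composes `F(cassie_cos(composite_roughness(x)))` from the primitive
relations instead, which is exact and keeps one code path for both models.

## Transition analysis

* **Composite minimum.** The Cassie cosine along the cap section is
  `c(x) = C(2x cosθ_Y + x(2−x)) − 1` with `C = πr₀²/A`; its stationary point
  is `x* = 1 + cosθ_Y`, independent of `δ` — 0.758 at θ_Y = 104°. The closed
  form is used whenever it falls inside (0, 1) (any hydrophobic chemistry)
  and is cross-checked against bounded scalar minimisation over
  θ_Y ∈ {100°, 104°, 110°, 120°} and δ ∈ {0…4}.
* **Energy barrier ΔG₁** = `K[F(x_eval)^{1/3} − F(x*)^{1/3}]` along the
  composite branch. For hemisphere arrays the barrier is evaluated at
  `x_eval = 0.95` by default — the last tabulated composite state before
  bottom contact; the evaluation point is an explicit parameter
  (`eval_x` / `barrier_eval_x`) because the published convention is
  ambiguous (a stated `x = 0.99` whose tabulated values are matched at
  0.95; both values are recoverable by passing the point explicitly). For
  capped cylinders the barrier is taken at bottom contact or Cassie
  saturation, whichever comes first: `x_end = min(1+η, −1/(2cosθ_Y))`.
  Structures taller than the saturation depth all share the same maximum
  barrier `K(4^{1/3} − F_min^{1/3})` (property-tested).
* **Energy potential ΔG₂** = `K[F_min^{1/3} − F(r cosθ_Y)^{1/3}]` with the
  full-structure Wenzel roughness. When `r > −1/cosθ_Y` the Wenzel equation
  has no solution and a `NoWettedEquilibriumError` is raised rather than a
  value fabricated; uncertainty propagation counts such samples separately.
* **Landmarks.** Saturation of the composite branch at
  `x_sat = −1/(2cosθ_Y)` (2.067 at 104°) and of the wetted branch at
  `r(x) = −1/cosθ_Y` (x = 7.41 for δ = 1) are closed-form; the
  composite/wetted crossing (4.607 for δ = 1) is found by Brent root
  finding bracketed between them (xtol 1e−9) and cross-checked against a
  1e−4 grid sign-change oracle.
* **Formal continuation.** Past saturation no equilibrium contact angle
  exists; the branch cosine is nevertheless continued formally (`c < −1`,
  flagged per point) because the deep-penetration landscape — the branch
  maximum at saturation, the crossing, the Wenzel limit — only appears in
  that reading. A clamp policy (`continuation="clamp"`, energy pinned at the
  non-wetting-sphere plateau `K·4^{1/3}`) is provided for users who prefer
  the strict-equilibrium interpretation. Likewise the capped-cylinder
  composite branch can be extended past the physical structure bottom
  (`allow_extension=True`) to map the same landscape.

## Defaults and units

| parameter | default | unit | rationale |
|---|---|---|---|
| θ_Y | 104 | deg | water on leaf wax |
| γ_LV | 72.8 | mN/m | water at 20 °C; with V = 5 µL gives K = 648.5 nJ |
| V | 5 | µL | standard goniometry drop |
| ρ | 998 | kg/m³ | capillary-length guard only |
| barrier eval (hemisphere) | 0.95 | — | tabulation convention, see above |
| packing | hexagonal | — | quasi-hexagonal papilla arrangement on real leaves |

Interfaces accept degrees, micrometres, mN/m and µL; everything is SI
internally. Energies are reported in nJ with a 2-decimal display column
beside the full-precision one.

The hexagonal-vs-square packing difference in equilibrium contact angle is
computed and *reported* per species (1–3° at these geometries) but not
asserted against any bound: the two lattices differ in `f` by exactly
`2/√3`, and how small a difference counts as "negligible" is a judgement
left to the user.

## Synthetic measurements

The generator emulates the SEM measurement protocol behind the reference
geometries: for each species, ten feature measurements per image drawn from
independent normals at the catalog mean ± sd (lotus 5±0.5 / 5±0.5 / 10±1.2 µm
for r₀ / h₀ / 2d₀; *E. woodwardii* 8±0.8 / 0 / 14±2.8; *E. pachyphylla*
9±0.6 / 0 / 9±2.8; *E. dolorosa* 10±1.0 / 0 / 16±5.4). The ± values are
treated as standard deviations. Draws are clipped at a 0.1 µm floor so every
sample is a valid geometry; at the catalog sds the clip probability is
negligible, and sd recovery within 10% at n = 10⁴ is tested. Heights with
zero mean stay exactly zero (hemisphere species). Generators are seeded and
reproducible.

What passing these tests shows — and does not. The generator reproduces the
first two moments of independent per-feature measurements; it does not model
spatial correlation between neighbouring papillae, within-leaf versus
between-leaf variance, measurement bias, or the nanoscale wax texture that
real leaves add on top of the micro-papillae. Uncertainty bands derived from
it quantify sensitivity of the model outputs to geometric scatter, not the
full biological variability.

## Numerical choices and degenerate inputs

Root finding and minimisation tolerances are 1e−9 in `x`; branch-continuity
and identity tests run at 1e−12 relative. `F(θ) → 0` as `θ → 0` makes the
drop radius diverge; this raises an explicit error at `F ≤ 0` rather than
returning inf. `x = 1` is evaluated identically by both sub-branch formulas
(tie-break by `x ≤ 1` choosing the cap branch; tested equal to 1e−12).
Degenerate `d₀ = 0` and `h₀ = 0` are ordinary inputs. Percentile summaries
use the empirical 2.5/97.5 points; samples whose wetted state is saturated
are excluded from ΔG₂ statistics and reported in an `n_saturated` column.

## Known limitations

The model is quasi-static and thermodynamic: no contact-angle hysteresis,
roll-off dynamics, vibration-driven barrier crossing, line tension, gravity
correction, or meniscus curvature; a single roughness tier (no nanoscale wax
layer superimposed on the papillae). One reference value resists exact
reproduction: the spacing sweep's `d₀ = 0` energy potential computes to
3.98 nJ where 4.05 nJ is the published figure (−1.6%); every other tabulated
potential agrees to ≤0.35%. The discrepancy is consistent with a slightly
displaced composite minimum in the original tabulation for small spacings,
and the exact model value is reported unchanged.
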