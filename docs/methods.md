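# Methods

## Model

The package integrates a four-species reaction–diffusion system on a square
tissue domain Σ = (0, L) × (0, L) with zero-flux boundaries: cancer stem
cells S(x, y, t), differentiated cancer cells D, the Wnt-β catenin activator
a and microRNA m (concentrations per mm³, time in years, space in mm):

    ∂S/∂t = (2p(D,a) − 1) ε S + q(m(t−τ)) D(t−τ) + D_S ΔS − δ R S
    ∂D/∂t = 2(1 − p(D,a)) ε S − (d + q(m)) D + D_D ΔD
    ∂a/∂t = a (β S a/(1+a) − α) + D_a Δa
    ∂m/∂t = γ e^{−S/S₀} − α m + D_m Δm

with the symmetric-division probability p = ηa / ((1+ηa)(1+ψD)) and the
dedifferentiation rate q(m) = (q₀/2)(1 + tanh((m−m₀)/σ)).  The discrete
delay τ is the maturation time for a DC to re-enter the stem compartment
after microRNA stimulation; only m and D ever appear with delayed argument.
The radiation term −δRS is active only in treated runs (below).  The mitotic
rate ε (= 1/yr at the defaults) is kept explicitly in both S-equation terms
for dimensional consistency.

Parameter defaults are the baseline set (η=1 mm³/molecule, ψ=0.5 mm³/cell,
ε=1/yr, m₀=0.05, α=0.3/yr, β=1, γ=1, σ=0.05, S₀=0.038 cell/mm³,
D_S=D_D=0.031536 mm²/yr, D_a=D_m=0.365 mm²/yr) with the prostate turnover
pair (q₀, d) = (87.6, 87.2)/yr; lung (109.97, 80) and breast (70.39, 45) are
available as presets.  α is treated as a first-order degradation rate
(1/yr); the unit attached to it in the source table (mm³/molecule) is a
typographical slip.

## Equilibria

* E¹ = (0, 0, 0, m₁): the empty state; an equilibrium only at m₁ = γ/α.
* E² = (S₂, S₂/d, 0, m₂) with S₂ = −S₀ ln(αm₂/γ): the working point of the
  analysis.  The closed forms balance the m-equation for any m₂ in
  (0, γ/α), but the S/D balance requires q(m₂) = d, which holds at the
  single value m₂* = m₀ + σ·artanh(2d/q₀ − 1).  The package exposes both:
  `equilibrium_E2(params, m2)` evaluates the closed forms for any m₂ (the
  published analysis uses m₂ = 0.08, the anchor of the printed initial
  fields), while `consistent_m2(params)` returns m₂*, at which the reaction
  residual is below 10⁻⁸ in every component.  E² is classified stable at
  τ = 0 iff d < q₀ and m₂ < γ/α, both strict.
* E³ activates the Wnt-β pathway.  Its activator level a₃ is the positive
  root of η(1−r)a² − (1 + r(1+η))a − r = 0 with r = ψα/(dβ), equivalently
  the state where p(D₃, a₃) = 1/2; S₃ = α(1+a₃)/(βa₃), D₃ = S₃/d,
  m₃ = (γ/α)e^{−S₃/S₀}.  The a- and m-equations are balanced identically;
  the S/D equations retain a residual of order q(m₃)·D₃, i.e. E³ as written
  is an equilibrium of the q(m₃) → 0 idealisation.  It is classified
  unstable.

## Linear stability with delay and the critical delay

Perturbing E² with modes e^{λt}cos(kₓx)cos(k_y y) gives the characteristic
matrix A + B e^{−λτ} − λI, where A holds the instantaneous couplings (with
−D·k² on the diagonal) and the rank-one B the two delayed S-row entries:
q(m₂) = d at position (1,2) and w = (2dD₂/σ)(1 − d/q₀) at (1,4).  Because
the activator row decouples at a₂ = 0, det(λI − A) is exactly the product of
the four diagonal factors (λ+p₁)(λ+p₂)(λ+p₃)(λ+p₄) with p₁ = ε + D_S k²,
p₂ = 2d + D_D k², p₃ = α + D_a k², p₄ = α + D_m k², and the delayed part of
the determinant is (λ+p₃)[(wu − 2dε)λ + wu(d + D_D k²) − 2dε·p₄] with
u = (α/S₀)m₂.  These closed forms define the quartic-with-delay
λ⁴ + C₁₁λ³ + C₂₂λ² + C₃₃λ + C₄₄ + (E₁₁λ² + E₂₂λ + E₃₃)e^{−λτ} = 0 and are
validated in the tests against a numerically evaluated determinant at random
(λ, k², τ) points to 10⁻⁸ relative accuracy, together with the exact
divisibility by (λ + α + D_a k²).

Purely imaginary roots λ = iω require ω² to be a real positive root of a
quartic in z = ω², solved by companion-matrix eigenvalues (roots accepted
with |Im z| < 10⁻⁹·max(1, |z|) and z > 10⁻¹²).  At each admissible ω the
pair (sin ωτ, cos ωτ) is obtained by solving the 2×2 linear system formed by
the real and imaginary parts of the characteristic equation; this determines
the crossing phase uniquely mod 2π, so the delay branches are
τ^{(j)} = (atan2(sin, cos) mod 2π + 2πj)/ω without case distinctions.  The
two-argument arctangent was chosen over a three-case principal-value
formulation because the latter leaves one quadrant uncovered and is easy to
get wrong by a sign; the branch produced here is verified in the tests to
(i) zero the characteristic function at (iω, τ) and (ii) agree with Newton
continuation of the characteristic root across the crossing.  Transversality
is the sign of Re(dλ/dτ) at the crossing, evaluated through the closed-form
real/imaginary parts of (dλ/dτ)^{-1}; only positive crossings (roots moving
rightward) qualify as Hopf points.  `critical_delay` minimises the j = 0
branch over a mode set consisting of k² = 0 plus the ten lowest zero-flux
modes (πn_x/L)² + (πn_y/L)² of the L = 100 mm domain — the k-dependence is
weak at the stated diffusivities and enters only through the p_i.

Outcome at the published parameter sets, m₂ = 0.08: the breast pair has a
single crossing (ω = 0.3501/yr) with positive transversality at
τ_c = 3.2972 yr; the prostate and lung pairs have **no** purely imaginary
crossing at any mode — the delayed coupling strength wu is bounded above by
(2/(σe))(1 − d/q₀) over all admissible m₂, which for prostate is more than
an order of magnitude below the crossing threshold.  Direct nonlinear
integration of the homogeneous system confirms delay-stability of the
prostate set for τ up to 20 yr.  The published critical-delay table
(11.8964, 0.6287, 0.5858 yr) is therefore not reproducible from the printed
model; the corresponding checks are kept at the published values and fail
with explanatory messages.  A genuinely oscillatory regime exists at slower
turnover (e.g. q₀ = 10/yr, d = 5/yr, σ = 0.02): there the linear τ_c
coincides with the onset of growing oscillations in the nonlinear
simulation, which is how the linear analysis and the integrator are
cross-validated end to end.

## Numerical integration

Method of lines on a cell-centred uniform grid (cells of side Δx = L/n; the
full-domain runs use Δx = 0.2 mm, i.e. 500 cells per side; tests use reduced
grids of 48–64 cells, all tested properties being resolution-robust).  The
five-point Laplacian uses mirror ghost cells across the boundary faces,
which makes the operator exactly conservative (mass drift in pure-diffusion
runs is at floating-point level) and second-order accurate, with
cos(πx/L) as a discrete Neumann eigenfunction.  Time stepping is classical
RK4 with Δt = 0.01 yr; the delayed fields m(t−τ+cΔt), D(t−τ+cΔt) at the
stage offsets c ∈ {0, ½, 1} are read from a ring-buffer history by cubic
Hermite interpolation on the bracketing step interval, using the stored
right-hand-side derivatives (exact at the samples), so the lookups match the
fourth-order stepper; the history is initialised constant on [−τ, 0].
Requirements: τ = 0 (plain RK4) or τ ≥ Δt; Δt below the explicit diffusion
bound Δx²/(4·max D) and below the reaction stability limit ≈ 2.8/(d + q₀)
(violations raise configuration errors or abort with a non-finite-field
diagnostic).  Fields are not clamped during integration; a run is flagged if
any field drops below −10⁻⁸ of its magnitude.  The integrator is verified
against scipy's ODE solver in the zero-delay limit (10⁻⁸ at t = 1) and
against a method-of-steps reference (segment-wise non-delayed solves with
dense interpolation) for the delayed system (10⁻⁶ at t = 2, Δt = 0.005),
with measured convergence ratios ≈ 2⁴ per Δt halving.

The published initial fields are small trigonometric perturbations of the
anchor (S₂, D₂, a₂, m₂) = (0.140000, 0.001605, 0, 0.080000); the S and D
formulas are taken with their printed nesting (the inner sine perturbs the
cosine phase), and the a/m formulas are read as squared trigonometric
ripples (cos²(x+2) etc.), which keeps them non-negative and matches their
quoted anchor values.  Negative cells are clamped to zero in the initial
condition only.  Note that cos((x²+y²)π) varies below the grid scale over
most of the domain, so the S-field initial data are effectively
grid-sampled ripples; the smooth circular structure resides in the D-field
(wavelength 2 mm).

Pattern snapshots are summarised by `pattern_metrics`: spatial extrema and
mean, centre of mass, a binned radial profile about the domain centre, the
localisation radius (smallest radius containing 90% of the squared deviation
from the spatial mean; 0 for a uniform field — for a Gaussian bump of width
s the closed form is s√(ln 10)), and the fraction of deviation variance
captured by the radial profile (≈ 1 for circularly symmetric patterns).

## Radiotherapy

The LQ machinery follows the standard incomplete-repair fractionation
algebra; g, h_n, M, R_eff, BED_late, BED_can, the optimum dose and the
Poisson TCP are implemented exactly as documented in the module docstring.
Defaults: α_s = 0.302/Gy, β_s = 0.0417/Gy², δ = 25/(yr·Gy), μ = 3195.77/yr,
n = 2 fractions/day, τ_r = 9·10⁻⁶ yr (≈ 5 min), Δτ_r = 6.9·10⁻⁴ yr
(≈ 6.04 h), K = 0.2 Gy/day, T_d = 40 d, f = 7/5, θ_late = 3 Gy,
θ_can = α_s/β_s ≈ 7.242 Gy, T = 45 d.  Design choices:

* One fraction count n (per day) is used consistently in R_eff, M and the
  BED expressions, with the treatment time T an independent input; the
  rearranged BED form uses T = fn − 1 and coincides with the direct form
  exactly under that substitution (identity-tested).  The repopulation
  subtraction K(T − T_d) is clamped to zero for T < T_d.
* The log cell kill satisfies E = α_s·BED_can identically, i.e. the
  repopulation term in E is expressed in log-kill units α_s·K(T − T_d).
* The optimum dose is the positive root of the exact quadratic
  (1 − θ_late/θ_can)MD² − 2KfD − Kfθ_late = 0 (the closed form with M also
  under the square root); a brute-force dose grid at fixed normal-tissue
  budget confirms it as the argmax of the tumour BED in the repopulation
  regime.  At the defaulted schedule M = 1.09760, giving D_opt = 1.659 Gy
  and BED_can = 3.475 Gy at the optimum.  The published pair
  (1.328 Gy, 4.097 Gy) would require M ≈ 1.331, attainable only with
  inter-fraction spacing ≈ 2.9 h — outside the ≥ 6 h constraint the same
  source states — and a tumour BED evaluated with θ_late in place of
  θ_can; `schedule_scan` documents this sensitivity, and the corresponding
  acceptance checks fail at the published values by design.
* The survival fraction in the TCP is capped at 1 when repopulation
  outweighs the kill (negative tumour BED).  TCP monotonicity in dose and
  the ordering between tumour volumes (80000 vs 250000 mm³ at
  ς = 0.000805 cell/mm³) are tested; specific "required dose" read-offs are
  not, since no control threshold is defined for them.
* Coupling into the dynamics: `FractionationSchedule` implements the
  literal beam windows (n per day, five successive days per week, window
  length τ_r, spacing Δτ_r, overlap rejected) and can integrate the term
  with exact per-step window-measure averaging ("fractionated" mode).  The
  windows occupy only ~5·10⁻⁴ of the treatment span, so their integrated
  effect on the cell populations is invisible at Δt = 0.01; the pattern-
  eradication experiments correspond to the effect applied throughout the
  course ("continuous" mode, the default of the figure presets), under
  which a dose of 1.323 Gy/fraction suppresses the CSC population by
  e^{−δR_eff·0.3yr} ≈ 10⁻³ within 0.3 yr and the dose series
  {0, 0.02, 0.05} Gy produces strictly ordered final fields (S, D maxima
  decreasing, mean microRNA increasing).

## Scope of validation

The synthetic runs exercise exactly the published operating conditions
(parameter tables, initial fields, grid and step sizes, schedules); they are
deterministic and contain no biological noise, cell-level stochasticity,
parameter uncertainty or heterogeneous dose maps.  Passing tests establish
the mathematical fidelity of the implementation to the stated model, not the
model's fidelity to tumour biology.  Known limitations: explicit time
stepping only (no stiff solver; the DC turnover sets the step bound), 2-D
domains only, one global delay, and no normal-form analysis of the
bifurcating periodic orbit.
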