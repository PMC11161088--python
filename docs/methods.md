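# Methods

## Model and assumptions

`rosdyn` implements a three-compartment ordinary-differential-equation
model of rod outer segment (ROS) disc turnover. Discs are counted by the
length they occupy (μm) in a growth compartment `L_g` (nascent discs at
the base), a mature compartment `L_m` (the main stack) and a shed
compartment `L_s` (discs inside the retinal pigmented epithelium, RPE).
The modelling assumptions are:

1. Only G and M discs contribute to the outer-segment length,
   `L_t = L_g + L_m`; shed discs sit in the RPE.
2. Disc addition slows as the ROS approaches its anatomical maximum:
   the addition rate is `μ0 · L_max / L_t`, fast for a short (developing)
   ROS and ≈ μ0 near full length. The term is singular at `L_t = 0`; the
   state domain therefore requires `L_t ≥ 10⁻¹²` μm whenever addition is
   active, and configurations starting at zero total length with δ > 0
   are rejected.
3. Retinal detachment at t = 0 multiplies addition by a severity
   δ0 ∈ [0, 1] and removal by γ0 ≥ 0 (the removal mechanism during
   detachment is unknown and may be weaker or stronger than normal
   shedding). Both revert instantaneously to 1 at the reattachment time
   `T_a`; post-reattachment transients back to normal physiology are not
   modelled. The step functions are taken right-continuous at `T_a` — the
   model leaves the convention open, and right-continuity means the
   reattached regime applies from the instant of surgery.
4. Disposal of shed discs (rate μ_s) is a pure sink: `L_s` never feeds
   back on the outer segment. This has a consequence for calibration
   discussed below.

Units are days and micrometres throughout the dimensional API. The
nondimensional API (lengths over `L_max`, time times α_g) is separate and
explicit, with parameters μ̄0 = μ0/(α_g·L_max), ᾱs = α_s/α_g,
μ̄s = μ_s/α_g.

A transcription note: in the source formulation of this model the origin
equilibrium's third eigenvalue and the frozen-regime shed-compartment
exponent are printed as μ̄0, but the Jacobian's third diagonal entry is
−μ̄s and with γ = 0 the shed compartment obeys `dL_s/dτ = −μ̄s·L_s`; both
are implemented as μ̄s.

## Parameters

| symbol | meaning | default | unit |
|--------|---------------------------------------|----------|--------|
| μ0 | disc-addition scale | 2.2 | μm/day |
| α_g | maturation/translocation rate | 0.85 | 1/day |
| α_s | shedding (removal) rate | 0.155 | 1/day |
| μ_s | disposal rate in the RPE | 0.3 | 1/day |
| L_max | maximum ROS length | 30 | μm |
| Δ_T | disc thickness (mouse) | 1.638e-2 | μm |
| Δ_s | disc–disc spacing (mouse) | 1.556e-2 | μm |

Disc counts and lengths interconvert by `L = Δ_T·N + Δ_s·(N−1)` and
`N = (L+Δ_s)/(Δ_s+Δ_T)`; the inverse is fractional for generic lengths and
a nearest-integer view is provided (30 μm ↔ ≈ 940 discs). The critical
length `L_c` — the total length below which the rod is assumed to die —
has never been measured; it is a required user input everywhere it
appears. Where the package itself needs a concrete value (CLI examples,
sensitivity and region checks in the test suite) it uses `L_c = 10 μm`,
roughly 45% of the normal equilibrium length, chosen once as a mid-range
representative value.

## Numerical choices

- Integration: explicit adaptive Runge–Kutta (RK45) with dense output,
  default `rtol = 1e-9`, `atol = 1e-12`. The system is non-stiff at the
  default parameter scales.
- The time axis is split at `T_a` and each piece integrated with constant
  (γ, δ), so the solver never steps across the discontinuity.
- Critical times are located by a terminal, direction-sensitive root-find
  event on `L_t − L_c` over the dense output; located crossings satisfy
  `|L_t(T_c) − L_c| ≤ 1e-6` μm and are stable to < 1e-3 day under a 10×
  tolerance refinement.
- A finite horizon cannot prove "never crosses". The verdict combines the
  horizon with the regime's asymptotic equilibrium length: "never"
  requires no crossing *and* an asymptote at or above `L_c`; otherwise the
  result is an explicit "undecided" rather than a silent negative. The
  default horizon is 500 days, far beyond every kinetic time scale
  (1/α_g ≈ 1.2 d, 1/α_s ≈ 6.5 d, 1/μ_s ≈ 3.3 d); the default output grid
  is 0.1 day.
- Equilibria come from the closed-form steady-state algebra, re-derived
  rather than transcribed; eigenvalues are computed both numerically from
  the Jacobian and from the factored characteristic polynomial
  −(λ+μ̄s)[λ² + (a+γᾱs+1)λ + (a+γᾱs(a+1))], and the test suite asserts
  agreement to 1e-8.
- "Time to equilibrium" is not a standard quantity; it is defined here as
  the first time of *permanent* entry of `L_t` into a ±2% relative band
  around the analytic equilibrium total length (band configurable). With
  default parameters and a single-disc initial condition this gives
  9.89 days; a one-variable reduction (`u = L_t²`, valid for
  `L_g ≪ L_m`) gives 10.4 days, confirming the order. Note that the
  ~two-week settling time often quoted for rodent outer-segment renewal
  corresponds to a tighter (≈ ±0.5%) band under this model.
- Death/regeneration classification: the authoritative classifier
  compares the closed-form asymptotic total length
  `L_t∞ = sqrt(L_max·ν·(α_g+ε)/(α_g·ε))` with `L_c`; the equivalent
  inequality form (ν < κ and ε > α_g·ν/(κ−ν), with κ = α_g·L_c²/L_max) is
  implemented separately as a cross-check. κ was re-derived from the
  condition "asymptotic length = L_c", which reproduces the inequality
  form exactly and fixes its otherwise ambiguous printed rendering.
  Points whose asymptote lies within a relative band of 1e-9 around `L_c`
  are labelled "boundary". The classifier is asymptotic by construction;
  transient dips below `L_c` with a recovery afterwards belong to
  `critical_time`, not to the region logic.
- Degenerate regimes are first-class: δ = γ = 0 conserves `L_t` (the
  frozen case, solved in closed form), δ > 0 with γ = 0 grows without
  bound and has no finite equilibrium, ν = ε = 0 region queries return a
  distinct "frozen" verdict.

## Synthetic data and calibration

The calibration observable is the mature-compartment length `L_m`, the
quantity that length measurements of renewing outer segments most closely
track. The generator integrates the model under known parameters and adds
i.i.d. Gaussian noise (default SD 0.5 μm, of the order of the ±2.4 μm
spread reported for RCS-rat outer-segment lengths; configurable and
recorded in the dataset). It emulates a clean fixed-cadence measurement
series: no attrition, no heteroscedasticity, no animal-to-animal variance
component, so parameter-recovery results bound what is attainable under
idealised sampling rather than what a real histology series would give.

Calibration is a plain grid sweep: for each candidate (α_s, μ_s) pair the
model is integrated and scored by the unweighted sum of squared residuals
against the observed `L_m` at the observation times; the full objective
surface and per-axis profiles are returned with the argmin. Grids default
to 21 log-uniform points spanning ±50% of the supplied centre values.

**Structural identifiability.** Because the shed compartment never feeds
back, `L_m` carries *no* information about μ_s under any detachment
schedule: the objective is exactly constant along the μ_s axis (up to
solver round-off), and only α_s is identified by mature-length data. The
sweep keeps μ_s on the grid deliberately so this flat profile is surfaced
in the result rather than hidden; users should treat any μ_s "estimate"
from mature-length data as arbitrary. Recovering μ_s requires observing
the shed compartment (or RPE phagosome counts) directly. Noiseless
synthetic data reproduces the generating pair exactly (the zero-residual
grid point); under noise, α_s is recovered well within one grid step while
the μ_s argmin wanders the flat profile.

## Problem sizes used in the shipped checks

The test suite and acceptance script use: 60-day horizons for normal
renewal settling, 200-day horizons for the qualitative detachment regimes,
1000-day integrations as the oracle for 200 random death-region points,
16-point γ grids on (0, 2] for the sensitivity shape, and 10 noisy
replicates of 100 observations over 30 days for parameter recovery.

## Known limitations

- γ and δ are two-level step functions; gradual post-reattachment
  recovery, light/dark shedding rhythms and neurochemical modulation are
  out of scope.
- Disc dynamics are deterministic and continuous; single-disc
  stochasticity is not modelled (disc counts are fractional views).
- The death-region logic is asymptotic and says nothing about transient
  survival margins.
- Cone photoreceptors, with their continuous membrane architecture, are
  outside the model's assumptions.
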