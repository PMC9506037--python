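# Methods

## Model

The package implements the simplified CPA equation of state: an SRK
physical term plus a Wertheim first-order association term with the
radial distribution function g(η) = 1/(1 − 1.9η), η = bρ/4. All internal
units are K, bar, L, mol (R = 0.083145 bar·L/mol/K), matching the units
in which the bundled parameters are tabulated; no other unit system is
accepted internally.

Pure fluids carry five parameters (a₀, b, c₁ for the cubic; ε, β for
self-association) plus the critical temperature entering the Soave alpha
function. The alpha function is used unchanged above T_c (supercritical
CO2 has no special treatment). Association schemes are encoded as site
*classes* with multiplicities — 2B = (+1, −1), 4C = (+2, −2),
3×2B = (+3, −3), 1A = one bipolar site of multiplicity 1 — and the
mass-action equations are solved over classes, with multiplicities folded
into the sums. A bipolar site pairs with itself (acid dimerization) and,
when a binary declares a cross rule, with both polarities of the
partner's sites.

Cross-association parameters follow CR-1 (arithmetic-mean energy,
geometric-mean volume; both partners self-associating), mCR-1
(arithmetic-mean energy with a non-self-associating partner contributing
zero; adjustable volume), or explicit stored values. A non-self-
associating component (CO2, in practice) acquires one positive solvation
site exactly when one of its binaries declares mCR-1 or explicit
parameters; toward every other partner it stays inert. This reproduces
the two standard treatments of CO2: fully inert toward PEGs and
glycerides, solvating toward glycerol and the low alcohols.

## Residual Helmholtz energy and fugacity coefficients

The pressure equation alone does not fix fugacity coefficients, so the
package works from the reduced residual Helmholtz energy

a_res = −ln(1 − bρ) − a/(bRT) ln(1 + bρ) + Σᵢ xᵢ Σ_A m_A (ln X_A − X_A/2 + ½).

Its analytic volume derivative reproduces the pressure equation exactly
(the association pressure term −½(RT/Vm)(1 + ρ∂ln g/∂ρ)·h follows from the
density dependence of g alone), and ln φᵢ = ∂(n·a_res)/∂nᵢ − ln Z uses the
stationarity of the site-fraction equations: X is held fixed in the
explicit derivative, plus the packing-fraction term −(h/2)·(1.9/(1−1.9η))
·bᵢ/(4Vm). Both identities are enforced in the test suite by numerical
differentiation (5-point volume stencil, central composition differences);
the achievable agreement is ~1e−9 relative for pressure and better than
1e−6 for ln φ, limited by floating-point cancellation in the liquid-branch
pressure sum (terms of order 10³ bar cancelling to order 1 bar leave an
absolute noise floor of ~1e−13 bar, which is also why the pure-saturation
fugacity-equality contract of 1e−10 is only meaningful at saturation
pressures well above ~1e−3 bar).

## Numerical methods

- **Site fractions**: clamped Newton iteration on the mass-action defect
  (site systems here have at most six classes), converged to a fixed-point
  residual of 1e−12, with damped successive substitution (ω = 0.5) as
  fallback and as the vectorized path used on volume grids. Starting
  values come from the previous state wherever a caller iterates.
- **Volume roots**: vectorized pressure evaluation on a two-region
  log-spaced grid (dense within 8b of the co-volume, where the narrow dip
  near the liquid spinodal lives; coarse out to beyond the ideal-gas
  volume), sign-change bracketing of mechanically stable crossings
  (P decreasing), Brent refinement, and a final Newton polish that pushes
  |P(V) − P| to 1e−13 relative. Hint "liquid"/"vapor" selects the
  smallest/largest stable root; with no hint the root of lowest Gibbs
  energy wins, ties (< 1e−12) resolving to the vapor-like root. Warm
  starts try a ±35% bracket around the previous root first.
- **Pure saturation**: the spinodal window is located on a dense volume
  grid (the vapor-spinodal maximum is polished by bounded minimization),
  then the equal-fugacity condition is solved by Brent on ln P, with the
  bracket endpoints walked inward when coincident roots make the
  objective vanish.
- **Bubble/dew points**: successive substitution on K with a pressure
  update from the summation condition (secant on ln S(ln P) once |ln S| <
  0.3, damped direct substitution otherwise), Raoult-type initialization
  from EoS pure saturation pressures; supercritical components use a
  Clausius–Clapeyron extrapolation anchored at 0.80 and 0.90 T_c. Slow
  linear tails (CO2-rich, near-critical feeds) are collapsed by
  dominant-eigenvalue extrapolation of the K-vector, gated to the locally
  converging regime (step norm < 1e−2, eigenvalue estimate in (0.2,
  0.995)) so it cannot jump between the two bubble-pressure solutions
  that exist for feeds on the retrograde side of the envelope — the
  physically continuous lower branch is the one reported. A collapse to
  x = y within 1e−5 is flagged as a near-critical failure rather than
  returned as converged; divergence beyond 5·10⁴ bar aborts with an
  "outside the two-phase region" diagnosis.
- **Flash**: Rachford–Rice with a negative-flash window inside φ-φ
  successive substitution; single-phase outcomes are reported with vapor
  fraction 0 or 1.
- **Binary state at fixed (T, P)**: solved as the root of
  bubble-P(x₁) = P (unique for a binary two-phase state), by secant from
  a warm guess with a bracketing fallback that treats "no bubble point"
  as "above the maximum solubility".

## Regression

The binary fit minimizes mean squared relative deviations of the quantity
matched to the data pattern: bubble pressure at (T, x) where liquid
compositions exist, the computed x₁ and/or y₂ at (T, P) otherwise. The
choice is exposed as a flag because the original workflow (pressure
deviations for CO2–PEG; liquid- and/or vapor-composition deviations for
CO2–glycerol and CO2–glycerides) implies different objectives per system.
One-parameter fits use bounded Brent over k_ij ∈ [−0.3, 0.5]; the
two-parameter (k_ij, β_cross) fit uses multi-start trust-region least
squares over the per-record residual vector with β_cross ∈ (10⁻⁴, 0.5],
stopping early when a start reaches an essentially exact fit. Records are
weighted uniformly. The pure-fluid fit adjusts (a₀, b, c₁) to saturation
pressures and liquid molar volumes (equal weights, relative residuals)
with the association parameters held fixed — the family-constant
convention under which the glycol parameters were originally estimated —
and reports %AAD = 100·mean(|exp − calc|/exp) for both properties.

## PEG parameter correlations

The co-volume of the four oligoethylene glycols (MEG, DEG, TEG, TeEG;
62.07, 106.12, 150.17, 194.23 g/mol) is linear in molecular weight; a₀ is
provided as both a linear and a quadratic law. Association parameters are
family constants (ε = 143.37 bar·L/mol, β = 0.0188, 4C). The correlations
are refitted from the glycol registry rows at import time — the tabulated
PEG rows (150–600 g/mol) are therefore a genuine reproduction check, and
the linear-a₀ values are the defaults used in VLE work since they
extrapolate more reliably to higher molecular weights. c₁ and T_c have no
recoverable functional form (c₁ plateaus with size), so the tabulated
values are authoritative and intermediate molecular weights are
piecewise-linearly interpolated on [62, 650] g/mol with edge clamping.

## Synthetic data

The generator replaces literature VLE measurements that are not
redistributable: isothermal binary bubble sweeps (303–393 K, up to ~350
bar) with per-record measurement patterns (full T-P-x-y, liquid-only, or
vapor-only, mirroring how triglyceride data were actually reported),
fixed-composition ternary bubble curves at the bundled feed compositions,
and a CO2 + five-ester biodiesel surrogate whose default ester profile is
a synthetic soy-type distribution (a real fuel analysis is a required
user input when comparing to a specific sample). Noise is multiplicative
log-normal — 1% on pressure and 10% on heavy-compound vapor fractions by
default, engineering choices rather than literature facts — with a
heavy-tailed mode (σ of ln y up to ln 10) emulating vapor-phase
glyceride solubilities that disagree between sources by orders of
magnitude. Generation is bit-reproducible for a fixed seed.

Because the data come from the model itself, zero-noise datasets are
exactly model-consistent, which is what makes the recovery audits sharp:
every bundled k_ij (and the glycerol (k_ij, β_cross) pair) is recovered
from its own synthetic data to ~1e−3 or better. Passing these audits
demonstrates identifiability and correctness of the fitting machinery —
not accuracy against real measurements, which the synthetic data cannot
speak to (in particular, real systems carry model error the generator
does not emulate, so real-data AADs are necessarily worse).

Problem sizes used in the bundled audits (two temperatures per system,
three to four liquid compositions per isotherm, 20 noisy replicates at 2%
pressure noise) were chosen as the smallest designs that leave the
parameters clearly identifiable; larger designs change the recovered
values only in digits beyond the reported precision.

## The glycerol vapor-composition minimum

With the one-site CO2 treatment (k_ij = 0.3084, β_cross = 0.0979 under
mCR-1), the glycerol mole fraction in the CO2-rich vapor first falls like
~1/P (dilution of the nearly fixed glycerol fugacity) and then rises as
solvation in the dense fluid phase takes over — an interior minimum
analogous to the well-known CO2–water behaviour. With these parameters
the minimum at 323 K sits near 30 bar (moving to ~40 bar at 353 K and
~50 bar at 373 K): the large cross-association volume makes the
enhancement overtake dilution early. The locator scans the isotherm and
refines interior candidates by bounded minimization, returning the
boundary (flagged) when the window contains no interior minimizer.

## Limitations

- Only two-phase VLE is implemented: no three-phase flash, LLE/VLLE
  construction, critical-locus tracing, or volume translation.
- k_ij is temperature-independent throughout, by design.
- Near mixture critical points the bubble/dew iterations slow down and
  may be flagged rather than converged; the trivial-solution guard errs
  on the side of reporting failure.
- The registry ships exactly the parameter sets needed for the bundled
  systems; users can register additional components and pairs, but no
  group-contribution or critical-constant estimation is provided.
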