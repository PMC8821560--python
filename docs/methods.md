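# Methods

## Physical model and assumptions

A tree trunk is idealised as a solid circular cylinder of radius `r`,
elastic modulus `E`, clamped at the ground and free at the top, loaded
only by its own distributed weight. The density varies along the axis;
the coordinate u = x/l_c runs from the free end (u = 0) to the fixed end
(u = 1). The stability analysis is linear: the deflection angle θ is
assumed small (sin θ ≈ θ), so the package finds the onset of buckling
(the critical height), not post-buckling shapes. Taper, hollow sections,
crown point loads and wind loading are out of scope.

Balancing the shear produced by the weight of the column above a section
against the bending moment gives

    θ''(u) + λ W(u) θ(u) = 0,   θ'(0) = 0,   θ(1) = 0,

with W(u) the cumulative weight above u normalised by a uniform column of
the reference density, and λ = (ω l_c)³ the single dimensionless
eigenvalue, ω = (ρ₀ g A / (E I))^(1/3) = (4 ρ₀ g / (E r²))^(1/3).

A note on this formulation: writing the equation on the unit domain with
λ as the only eigenvalue is an exact rescaling of the dimensional
problem, in which ω·l_c would otherwise appear inside the coefficient
functions and make the series coefficients self-referential. The rescaled
form makes the characteristic function an ordinary polynomial in λ and
makes explicit that ξ_c = λ_c^(1/3) depends only on the density-shape
parameters, never on the material constants.

## Density models

| id | normalised density s(u)        | n range    | uniform state |
|----|--------------------------------|------------|---------------|
| A  | (n−1)u + 1                     | 0 ≤ n ≤ 3  | n = 1         |
| B  | (1−n)u + n                     | 0 ≤ n ≤ 3  | n = 1         |
| C  | 2nu + (1−n)                    | −1 ≤ n ≤ 1 | n = 0         |
| D  | 1 − n·cos(πu)                  | −1 ≤ n ≤ 1 | n = 0         |
| E  | W_R·s_C(u) + 1                 | −1 ≤ n ≤ 1 | W_R = 0       |
| F  | W_R·s_D(u) + 1                 | −1 ≤ n ≤ 1 | W_R = 0       |

A and B pin the density at the free/fixed end respectively and share the
same total weight at equal n; C and D redistribute mass at exactly
constant total weight (W(1) = 1 for every n); E and F superpose a
branch-and-leaf distribution of relative weight W_R = ρ_B/ρ_T on a
uniform trunk, whose density is the reference ρ₀. The n ranges reflect
field observations that branch weight rarely exceeds trunk weight; the
realistic-tree region used for the safety-factor analysis is 0 ≤ n ≤ 1
with 0.1 ≤ W_R ≤ 0.6, from published branch-weight surveys.

Each density is stored as the exact polynomial coefficients of its
cumulative weight W(u); the sine term of D/F is pre-expanded in its
Maclaurin series, by default to power 25 of u. The first dropped term
bounds that truncation error at ~π²⁶/27! ≈ 1e−15 (order 15 would already
give ~2.5e−7, order 21 about 1e−12), so the expansion never limits the
overall accuracy. Keeping W polynomial means the eigenproblem stays a
polynomial recurrence with no numerical quadrature anywhere.

## Series solution and root finding

With θ = Σₖ aₖ uᵏ, a₀ = 1 (amplitude normalisation) and a₁ = 0 (free-end
condition), the recurrence

    a_{k+2} = −λ/((k+2)(k+1)) · Σ_j w_j a_{k−j}

generates each aₖ as a polynomial in λ; the fixed-end condition gives the
characteristic polynomial F(λ) = Σ_{k≤N} aₖ(λ). F(0) = 1 always: an
unloaded column does not buckle. The truncation order N counts the
highest power of u retained; the package default is N = 25.

The smallest positive root is bracketed by scanning λ upward in steps of
0.1 from zero (the smallest root lies below λ ≈ 35 for every in-range
parameter, and root spacing is far coarser than the step, so the first
sign change is the first root) and then polished by secant iteration.
Following the convention of reporting heights on the ξ scale, the secant
update and its relative convergence test (default 1e−5) run on
ξ = λ^(1/3).

**Truncation-order selection.** The convergence-judgement function
f₍N,N+ΔN₎ = |ξ₍N₎ − ξ₍N+ΔN₎|/ξ₍N+ΔN₎ is swept from N₀ = 5 in steps of 5
until it drops below 1e−4 (a sub-centimetre height change for a
60 m tree). Very low truncations can lose the root altogether — model D
at N = 10 yields a rootless quadratic — and are treated as unconverged
rather than as errors. Models A, B, C and E, F pass at N = 20
(f₍₂₀,₂₅₎ ≈ 2e−6); the cosine model D is the slow one: f₍₂₀,₂₅₎ reaches
9.2e−4 at n = ±1, and even f₍₂₅,₃₀₎ reaches 5.8e−4 there, so the judged
order for D is 30 near the range ends. The package keeps N = 25 as the
global default — at that order the worst-case ξ error (model D, n = ±1)
is 5e−4 relative, which moves no reported 2–3-digit quantity — and every
function takes N as an argument so either choice can be reproduced.

**Independent verification.** A shooting solver integrates the same ODE
with classical fixed-step RK4 (default 2000 steps; bracketing scans run
batched over λ), bisecting λ to relative width 1e−8. Series and shooting
agree to better than 1e−4 relative for A, B, C, E, F at N = 25 across
their full ranges (worst 2e−6) and for D at N = 30; the uniform column
reproduces ξ_c³/4 = 1.95934, Greenhill's constant, by both routes, and
the model C, n = 1 case agrees to 4e−8 with the closed-form eigenvalue
λ = 4j², j the first zero of J₋₁/₄.

## Heights, ratios, and the tree application

Physical heights follow from l_c = ξ_c/ω. Ratio curves use
f = ξ_c/(4C)^(1/3) with C fixed at the printed Greenhill value 1.959 (the
solver's own uniform-column constant, 1.95934, is used only as a
cross-check; the 0.002% difference is invisible at reported precision).
For E/F the same normalisation compares against the branchless tree,
since W_R = 0 reduces both models to the uniform column.

Extremes of f over a parameter region are taken on tensor grids (default
21 × 21; f is monotone in W_R and in n for each model, so extremes sit on
the region boundary and modest grids are exact to grid resolution). The
safety-factor range multiplies the reference value S₀ = 4.0 (Niklas's
ratio of Greenhill height to observed tree heights) by the f extremes and
rounds to one decimal, giving 3.4–3.9 for the realistic region.
The allowable-weight interpretation is f³: since l_c ∝ γ^(−1/3), a column
that stands f times taller at equal unit weight can carry f³ times the
unit weight at equal height (1.25³ ≈ 1.95, 1.38³ ≈ 2.63).

One measured disagreement with commonly quoted figures deserves note: the
model C ratio maximum is f(1) = 1.2713 (confirmed by the series solver,
the shooting oracle and the Bessel closed form), slightly above the 1.25
often cited for the linear constant-weight redistribution; the package
reports the computed value.

## Buckling modes

The deflection y follows from θ by term-wise integration of the series at
λ_c: y(u) ∝ B(u) − B(1) with B(u) = Σ aₖ u^{k+1}/(k+1), anchored by
y(1) = 0 and normalised by y(0). That the free end is the deflection
maximum is verified numerically on a dense grid at every call (a
diagnostic is raised if violated, never a silent renormalisation). Modes
are monotone nonincreasing from tip to ground for every model and nearly
indistinguishable across density shapes — the practical content of the
first-mode similarity observed for heavy columns.

## Regression into scaling laws

f(n) curves are sampled on uniform grids — by default step 0.1 for A/B
(31 points) and step 0.05 for C/D (41 points) — and fitted by
unweighted non-linear least squares (scipy's `curve_fit`) to the four
forms above. Standard errors come from the asymptotic covariance,
p-values from two-sided t-tests with m − p degrees of freedom, and AIC
uses the full Gaussian log-likelihood, m(ln(2π·RSS/m)+1) + 2(p+1) — the
convention of R's `AIC()` for `nls` fits. These defaults are chosen so
that the fitted parameters and AICs land on the published regression
table for this problem to the printed precision; absolute AIC values
scale with the sample count, so conclusions should rest on the ranking,
which is grid-insensitive (step 0.05 vs 0.02 changes no ranking). The
power-law form is undefined at n ≤ 0 and silently uses the positive-n
subset of the common grid, the only sample-set difference `compare_fits`
accepts. The quadratic wins on AIC for A/C/D; the power law wins for B,
whose curve diverges like n^(−1/5) toward n = 0.

Coefficient simplification rounds a fitted value to the nearest multiple
of 1/q and reduces (q = 40 for exponents, 10 for prefactors), e.g.
−0.073 → −3/40, 0.190 → 1/5, 1.081 → 11/10. This deliberately prefers
*simple* fractions over best rational approximations (the continued-
fraction best q ≤ 40 approximation of −0.073 would be the unmemorable
−2/27). The resulting closed formulas track the full solver to 2.1% (A),
9.4% (B, at n = 3), 5.7% (C) and 8.0% (D, at n = −1), the larger errors
reflecting the exponential's missing curvature at the range ends.

## Numerical choices and degenerate inputs

- Bracket scan step 0.1 in λ, ceiling 500; first sign change wins
  (smallest root). A characteristic function with no sign change raises
  a "no buckling root" error rather than returning a sentinel.
- Secant limited to 100 iterations; convergence on the ξ scale.
- Validation is eager: non-positive section constants, out-of-range n,
  W_R on models A–D, or a negative density shape raise `ValueError`
  naming the offending field.
- The pipeline contains no randomness; identical inputs give
  byte-identical CSV/JSON outputs.

## Known limitations

Small-angle onset analysis only; solid non-tapered circular sections
only; the six built-in density families (arbitrary W(u) polynomials can
be fed to the eigensolver directly via `CumulativeWeightShape`, but the
convenience layers cover A–F); regression p-values assume independent
Gaussian residuals, which sampled deterministic curves do not satisfy —
they are reported for comparability, not as genuine error rates.
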