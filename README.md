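# selfbuckle

Self-weight buckling of heavy cylindrical cantilevers whose density varies
along the axis — the classical mechanical model of a tree.

A uniform heavy column of elastic modulus *E*, unit weight *γ = ρg* and
radius *r* buckles under its own weight at Greenhill's critical height

```
l_c = (C · E · r² / γ)^(1/3),    C ≈ 1.959,
```

the origin of the 2/3-power trunk allometry used throughout forest science.
Real trees, however, are not uniform: trunks taper in mass, branches and
leaves pile weight high or low. `selfbuckle` answers how that distribution
changes the critical height. It is written for plant biomechanists,
forest ecologists working with allometric scaling laws, and structural
engineers interested in self-weight buckling of towers.

## The model

The trunk is a clamped-free cylinder with axial density ρ(x), x measured
from the free end. Small-deflection equilibrium of the deflection angle θ
gives, on the unit domain u = x/l_c,

```
θ''(u) + λ W(u) θ(u) = 0,     θ'(0) = 0,  θ(1) = 0,
```

where W(u) is the dimensionless cumulative weight above u and
λ = (ω l_c)³ is the only eigenvalue, with ω = (4ρ₀g/(E r²))^(1/3).
Substituting a truncated power series θ = Σ aₖuᵏ turns the fixed-end
condition into a polynomial characteristic equation F(λ) = 0; its smallest
positive root λ_c gives ξ_c = λ_c^(1/3) and the critical height
l_c = ξ_c/ω. Six density shapes are built in (A/B: linear with free/fixed
end pinned; C/D: linear/cosine redistribution at constant total weight;
E/F: uniform trunk plus C/D-shaped branches with branch-to-trunk weight
ratio W_R). An independent Runge–Kutta shooting solver cross-checks every
eigenvalue.

On top of the solver the package computes critical-height ratio curves
f(n) = ξ_c(n)/(4C)^(1/3), their extremes over realistic parameter regions,
buckling-mode shapes, safety factors against observed tree heights, and
non-linear regressions of f(n) (exponential, linear, quadratic, power law,
ranked by AIC) whose coefficients snap to simple fractions, yielding
Greenhill-style closed formulas such as l_c = e^(n/5)(C E r²/γ)^(1/3).

## Worked example

```python
from selfbuckle import build_section, critical_height, make_density_model

section = build_section(E=1.1e10, rho0=526.0, g=9.81, r=0.23)  # hardwood trunk
uniform = critical_height(section, make_density_model("C", 0.0))
bottom_heavy = critical_height(section, make_density_model("C", 1.0))
print(f"{uniform.l_c:.3f} m", f"{bottom_heavy.l_c:.3f} m",
      f"x{bottom_heavy.f_ratio:.3f}")
```

prints

```
60.455 m 76.853 m x1.271
```

— the uniform 0.23 m-radius hardwood trunk buckles at 60.455 m, and moving
the same total mass linearly toward the ground raises the limit 1.27-fold.
The `examples/` directory holds one short script per capability (critical
heights, ratio curves, real-tree safety factors, buckling modes, scaling
laws); each prints its numbers with a line of interpretation. A thin CLI
wraps the same calls:

```
selfbuckle solve --model C --n 0
selfbuckle trees --model E -o trees_E.csv
selfbuckle report -o out/
```

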