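# sugausspb

Polar solvation free energies of molecules from a **regularized
Poisson–Boltzmann (PB) equation with a super-Gaussian smooth dielectric**,
solved by finite differences on a uniform grid.

## The problem and who this is for

Implicit-solvent electrostatics treats water as a dielectric continuum and
computes the polar part of the solvation free energy, ΔG_polar — the
electrostatic work of moving a solute (an ion, a small molecule, a protein
structure in PQR format) from vacuum (ε = 1) into water (ε = 80).
Classical two-dielectric PB solvers draw a sharp molecular surface between
solute and solvent; this package instead uses a smooth, atom-packing-
dependent dielectric, which removes the sharp boundary, reflects density
variations inside the solute, and improves grid-scale convergence.  It is
aimed at computational structural biologists and method developers who
want a transparent, fully scriptable PB pipeline with analytic internals.

## The model

Each atom *j* carries a super-Gaussian density
`g_j(r) = exp(−[(|r−r_j|²)/(σ²R_j²)]^m)` (m = 1 Gaussian, m ≥ 2
flat-topped, m → ∞ hard sphere).  Densities combine as
`g = 1 − Π_j (1 − g_j)`, and the dielectric blends a packing-dependent
interior value into the solvent through a sigmoidal surface function:

    ε_g(r) = ε_ref + (ε_gap − ε_ref) Π_j (1 − g_j(r))
    S(g)   = 1 / (1 + (1/g − 1)^η)
    ε(r)   = S ε_g + (1 − S) ε_out

The linearized PB equation `−∇·(ε∇φ) + (1−S)κ²φ = ρ` is **regularized**:
the singular Coulomb part `G(r) = (e²/kBT) Σ_j q_j/(ε_ref|r−r_j|)` is
removed analytically, and the bounded reaction field φ_RF solves

    −∇·(ε∇φ_RF) + (1−S)κ²φ_RF = ∇ε·∇G − (1−S)κ²G,
    φ_RF = φ_b − G  on the box faces,

with `∇ε` evaluated from closed-form gradients (no differencing).  Solving
in water (ε_out = 80) and vacuum (ε_out = 1) on one grid gives

    ΔG_polar = (kB T / 2) Σ_j q_j [φ_RF(r_j; water) − φ_RF(r_j; vacuum)].

The direct (non-regularized) route, with point charges spread to the grid,
is also provided for cross-validation.  The linear system is solved by
successive over-relaxation (SOR) on a 7-point flux stencil with the
dielectric evaluated analytically at cell midpoints.

Recommended parameters (the shipped defaults): σ = 1.0, m = 2, ε_ref = 1,
ε_gap = 22, ε_out = 80, η = 4/m = 2, no salt, scale 2.5 grids/Å, 15 Å box
padding.

## Worked example

```python
from sugausspb import make_born_ion, default_params, polar_solvation

ion = make_born_ion(q=1.0, R=2.0)            # unit charge, 2 A radius
params = default_params().replace(padding_A=10.0)
result = polar_solvation(ion, params, method="rpb")
print(f"dG_polar = {result.dG_polar:.2f} kcal/mol")
```

prints

```
dG_polar = -80.65 kcal/mol
```

the solvation energy of a Born-like ion under the smooth dielectric
(the classical sharp-sphere Born value for q = 1 e, R = 2 Å is
−(332.06/2)(1 − 1/80)/2 ≈ −82 kcal/mol; the smooth model differs slightly
because its effective dielectric boundary is not a hard sphere at R).
Doubling the charge quadruples the energy (linear response), and tightening
the grid from scale 1.5 to 4.0 moves ΔG monotonically toward its fine-grid
value.

The same computation from the shell:

```sh
sugausspb ion.pqr --padding 10
sugausspb ion.pqr --scan-scales 1.5:4.0:0.5     # grid-convergence table
```

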