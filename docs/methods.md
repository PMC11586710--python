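# Methods

## Model

The solute is a set of N atoms with centers r_j (Å), partial charges q_j
(e) and radii R_j (Å).  Atom j contributes a super-Gaussian density

    g_j(r) = exp(−[(|r−r_j|²)/(σ² R_j²)]^m),

equal to 1 at the center, e⁻¹ at |r−r_j| = σR_j, and decaying faster the
larger the exponent m (m = 1 is a Gaussian; m → ∞ a hard sphere of radius
σR_j).  Densities combine by the complement product g = 1 − Π_j(1 − g_j),
which saturates at 1 where atoms overlap.  Two dielectric ingredients are
built from g:

* the packing-dependent interior dielectric
  ε_g = ε_ref + (ε_gap − ε_ref) Π_j(1 − g_j), running from ε_ref at atom
  centers to ε_gap in loosely packed pockets and cavities;
* the surface sigmoid S(g) = 1/(1 + (1/g − 1)^η), with S(½) = ½ for every
  η, blending ε_g into the solvent: ε = S ε_g + (1 − S) ε_out.

The water phase uses ε_out = 80, the vacuum phase ε_out = 1; the density
and surface fields are phase-independent.  In the vacuum phase with
ε_gap > 1 the profile is non-monotonic (1 at the center, a hump up to
ε_gap-ish inside, back to 1 outside): the interior polarizability of the
solute is retained even without solvent.

## Regularized formulation

The linearized PB equation −∇·(ε∇φ) + (1−S)κ²φ = ρ has a singular
point-charge source.  We split φ = G + φ_RF with
G = (e²/k_BT) Σ_j q_j/(ε_ref |r−r_j|), the Green's function of the
homogeneous ε_ref Poisson problem, and solve for the bounded reaction
field:

    −∇·(ε∇φ_RF) + (1−S)κ²φ_RF = ∇ε·∇G − (1−S)κ²G   in the box,
    φ_RF = φ_b − G                                   on the faces.

The right side is finite everywhere: ∇ε vanishes at atom centers faster
than ∇G diverges (for m ≥ 2), and (1−S) is zero inside the solute where G
is large.  Nodes that coincide exactly with an atom center get source 0
(the limit value).  All gradients entering the source are closed-form:

    ∇g_j  = −(2m/(σ^{2m}R_j^{2m})) g_j (|r−r_j|²)^{m−1} (r−r_j)
    ∇g    = Σ_j ∇g_j Π_{k≠j}(1−g_k)
    ∇ε_g  = −(ε_gap−ε_ref) ∇g
    ∇S    = η (1/g−1)^{η−1} S²/g² ∇g
    ∇ε    = S ∇ε_g + ∇S (ε_g − ε_out)

Every analytic gradient is validated against central finite differences in
the test suite; that numeric oracle is the sign and factor authority.

The energy is the charge-site difference of the two phases,
ΔG_polar = (k_BT/2) Σ_j q_j [φ_RF(r_j; w) − φ_RF(r_j; v)], with φ_RF
interpolated trilinearly at the atom positions.  Both phases are solved on
the same grid (identical origin, spacing, dimensions) so interpolation
bias cancels in the difference.  A direct route (`method="gauss"`) solves
the non-regularized equation with trilinear (cloud-in-cell) charge
assignment and differences the full potentials; its grid self-energy
cancels between phases only approximately and it serves as an internal
cross-check of the regularized route.

## Parameters

| parameter | meaning | default | notes |
|---|---|---|---|
| σ | density variance | 1.0 | widens the atom density; larger σ inflates the solute |
| m | super-Gaussian exponent | 2 | flattens the density top; m → ∞ is a hard sphere |
| ε_ref | dielectric at atom centers | 1 | lower bound of ε inside |
| ε_gap | loose-packing interior dielectric | 22 | the interior limiting value |
| ε_out | solvent dielectric | 80 | vacuum phase uses 1 |
| η | surface steepness | 4/m = 2 | S(½)=½ regardless |
| I | 1:1 ionic strength (mol/L) | 0 | κ² = 8π l_B N_A I·10⁻²⁷ Å⁻², Debye length √(ε_out/κ²) |
| T | temperature (K) | 300 | enters k_BT and the Coulomb prefactor |
| scale | grid nodes per Å | 2.5 | h = 1/scale |
| padding | box margin (Å) | 15 | distance from every atom center to every face |
| bc | boundary condition | coulombic | screened per-charge sum; `dipolar` uses the two net-charge centers |
| ω, tol | SOR controls | 1.9, 10⁻⁶ | see below |

## Numerics

**Grid.** Cuboidal, node-centered, h = 1/scale, bounding box of atom
centers plus the padding on each side, snapped outward to whole cells.
Padding is measured from atom centers (not surfaces).

**Discretization.** 7-point flux stencil; the dielectric is evaluated
analytically at the six cell midpoints (not averaged from nodes), giving a
symmetric operator for any dielectric field.  The screening coefficient
(1−S)κ² sits on the diagonal; the boundary nodes are Dirichlet.

**SOR.** Lexicographic Gauss–Seidel sweeps with fixed ω = 1.9 (a
vectorized red/black ordering is provided as an alternative; both must and
do agree with a sparse direct factorization to 10⁻⁸ on small systems).
Convergence is declared on the *diagonally scaled* residual
max_i |r_i|/a_ii ≤ tol, which has units of potential (kT/e) and is
insensitive to the very different source magnitudes of the regularized
(smooth, O(10²)) and direct (grid-delta, O(10⁵)) routes; the raw residual
max-norm would make the tolerance route-dependent.  Divergence (50
consecutive residual increases) is reported through diagnostics rather
than an exception.  Sweeps are fixed-order, so repeated solves are
bitwise identical.

**Floors and cutoffs.**  g is floored at 10⁻¹⁴ before the surface sigmoid
(S is exactly 0/1 outside that band, and ∇S exactly 0 there); 1−g_j is
computed with expm1 so products near atom centers keep full precision;
per-atom densities are truncated beyond the radius where the exponent
argument reaches 36 (g_j < 10⁻¹⁵, below solver tolerance) — the cutoff can
be disabled, which the gradient-oracle tests do.

**Units.**  Lengths Å, charges e, potentials kT/e internally; energies
converted to kcal/mol on reporting.  All constants (Coulomb prefactor
e²/4πε₀k_BT·Å ≈ 557 at 300 K, k_BT ≈ 0.59616 kcal/mol, the Coulomb
constant 332.06 kcal·Å/mol·e²) are derived from CODATA values at run time.
The Green's function denominator uses ε_ref — the dielectric of the
homogeneous problem that defines the Coulomb component — so the
decomposition remains self-consistent for ε_ref ≠ 1.

## Fixtures and what passing tests show

The test fixtures are a Born-type ion (unit charge, 2 Å radius), a
two-atom dipole (radii 1.5/1.7 Å at (−1.5,0,0)/(1.7,0,0), charges ±0.5 e),
and a deterministic 12-atom random-walk "peptide-like" solute with mixed
charges (net +1) and radii 1.2–1.9 Å.  These exercise overlap saturation,
interface asymmetry, buried and surface charges, and net-charged boundary
conditions, but they do not reproduce protein-scale features: thousands of
atoms, irregular cavities, or conformational averaging.  Agreement on the
fixtures validates the machinery (model evaluation, sources, solver,
energies), not protein-level accuracy of the parameterization.

**Born anchor.**  The only closed-form check: with ε_gap = ε_ref = 1 the
interior is homogeneous and the model approaches a sharp sphere as m
grows, with the 50%-density radius R_eff = σR(ln 2)^{1/2m}.  The computed
ΔG approaches −(332.06/2)q²(1/ε_in − 1/ε_out)/R_eff: relative deviation
0.62 → 0.25 → 0.07 for m = 2 → 4 → 8 at scale 4.  η is held at 2 in this
configuration: the anchor tests the sharp-m limit, and scaling η as 4/m
would flatten the surface sigmoid exactly as m sharpens the density,
defeating the limit.  The residual 7% at m = 8 reflects the still-smooth
interface, not solver error.

**Known limitations.**
* The nonlinear sinh term is never iterated; only the linearized operator
  is solved (weak-potential regime).
* The regularized and direct routes agree to 1.2% at scale 4 for the Born
  fixture but only ~5% for the two-atom fixture, whose 1.5/1.7 Å radii
  put interface features at the grid spacing; the gap shrinks to 2.2% at
  scale 6 and extrapolates to ~1% in the continuum, so it is
  discretization error, not a formulation difference.  Expect a few
  percent cross-route disagreement at scale 4 whenever atomic radii are
  small compared to the transition width.
* A single uniform grid: no focusing, multigrid, or adaptive refinement;
  practical solves top out around 150³ nodes on one core.
* m = 1 (pure Gaussian) is supported by the formulas but not tuned.

**Problem sizes.**  Verification runs use boxes with 8–10 Å padding for
the scale-4 checks and the full 15 Å padding at the default scale 2.5;
the grid-scale scan covers 1.5–4.0 in steps of 0.5.  The convergence scan
normalizes to the scale-4.0 energy (exactly 100% there) and, for the
regularized route, approaches 100% monotonically (deviation sequence for
the Born fixture at 15 Å padding: 16.5, 7.3, 1.2, 1.0, 0.4, 0 %).
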