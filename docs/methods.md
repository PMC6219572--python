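# Methods

## The elastic model

A membrane-bound amphipathic helix ("wedge") inserted into the upper
leaflet of a lipid bilayer is described by two fields on the membrane
plane: the upper-leaflet height `h⁺` and its thickness deformation `u⁺`
(the lower-leaflet thickness deformation is frozen, `u⁻ = 0`, because the
wedge contacts only one leaflet; the lower-leaflet height follows from
bilayer continuity and is eliminated).  The elastic energy is

    G = ½ ∫ dA { K_b [ (∇²h⁺)² − (∇²h⁺)(∇²u⁺) + ½(∇²u⁺)² ]
                 + (K_t/2)(u⁺/a)² + τ (u⁺/a)
                 + τ [ (∇h⁺)² − ∇h⁺·∇u⁺ + ½(∇u⁺)² ] }.

Parameters, with units and defaults:

| symbol | meaning                                | default | unit     |
|--------|----------------------------------------|---------|----------|
| K_b    | bilayer bending rigidity               | 20      | k_BT     |
| K_t    | thickness deformation modulus          | 60      | k_BT/nm² |
| a      | monolayer hydrophobic thickness        | 2.0     | nm       |
| τ      | membrane tension                       | 0       | k_BT/nm² |
| U      | wedge immersion depth (≤0 compresses)  | 0 / −0.9| nm       |
| L      | helix length                           | 3       | nm       |
| r0     | wedge cross-section radius             | 0.6     | nm       |
| slope_h| contact slope of h⁺ (outward normal)   | −tan 9° | —        |
| slope_u| contact slope of u⁺ (outward normal)   | 0       | —        |

The defaults are standard phospholipid values and endophilin H0 geometry;
`U ≈ 0` and `U ≈ −0.9 nm` are the shallow (vesicle) and deep (tube) H0
immersion states measured by EPR.  The model excludes lipid tilt degrees of
freedom and uses a flat reference membrane.

## 1D analytic solution (`elastic1d`)

For face-on parallel helices the problem is one-dimensional in the
coordinate `r` perpendicular to the helix axes.  The substitution
`ū = u⁺ + τa/K_t`, `p = h⁺ − ū/2` decouples the functional exactly:

    g = ½{ K_b[ū''²/4 + p''²] + (K_t/2a²) ū² + τ[ū'²/4 + p'²] } − τ²/4K_t.

`ū` obeys a fourth-order equation with inverse-square decay constants
`ν± = ½[λ_t⁻² ± (λ_t⁻⁴ − λ_s⁻⁴)^½]`, `λ_t = (K_b/τ)^½`,
`λ_s = (K_b a²/8K_t)^¼ = 0.639 nm` at the defaults.  At τ = 0 the roots are
purely imaginary conjugates and `ū` is a damped oscillation with rate
`Re√ν ≈ 0.5/λ_s`; complex arithmetic with enforced conjugate pairing keeps
the evaluated fields real (a guard trips if the imaginary residue exceeds
1e−6 absolute + 1e−8 relative).  `p` obeys `K_b p'''' = τ p''`; at τ = 0
its general solution is a cubic, and a dedicated polynomial branch avoids
the catastrophic cancellation of the degenerate `e^{±r/λ_t}` basis.

Boundary conditions (three per contact): `u⁺ = U`, `du⁺/dn = slope_u`,
`dh⁺/dn = slope_h` along the outward normal, mirror-symmetric across each
wedge.  Wedge heights are free; minimising over the height difference
("zero vertical force") removes the odd cubic branch of `p` at τ = 0 and
the linear branch at τ > 0.  For a wedge pair at axis-to-axis separation
`d` the interior region spans the facing edges at `±(d/2 − r0)`; the
exponential basis is anchored at the edges for conditioning, and spans
narrower than 1e−3 nm are rejected as degenerate.

Region energies are evaluated in closed form from the on-shell
total-derivative (boundary-term) representation of the density, and
independently by adaptive quadrature of the raw two-field density; the two
agree to <1e−6 k_BT over random parameter draws (this dual route is a
standing test).  Interaction potentials subtract the exact
large-separation reference, the summed semi-infinite exterior energies of
the two isolated wedges, so no numerical `d → ∞` extrapolation enters:
`G_int(d) = E_interior(d) − E_ext,a − E_ext,b`, scaled by `L`.  Negative
values are favourable.

Two structural consequences of the mirrored `−tan 9°` height slope are
worth flagging:

* At τ = 0 the height field mediates an algebraically decaying repulsion
  `G_p = 2 K_b slope_h² L/(d − 2r0)` (the standard result for mismatched
  contact angles on a tensionless film with free heights).  The full
  `G_int` therefore approaches this tail — 0.078 k_BT at d = 40 nm — rather
  than zero; only the thickness-mediated part decays exponentially.  This
  repulsion is what makes shallow wedges repel and sets the critical
  immersion depth `U_c ≈ −0.40 nm`.
* Under tension the isolated-wedge reference acquires a height-field term
  `L slope_h² (K_b τ)^½` per wedge, so the dimerization energy first rises
  by ≲0.03 k_BT (up to τ ≈ 0.05 k_BT/nm²) before the tension shift of the
  effective immersion `ū(edge) = U + τa/K_t` takes over and weakens it
  (−0.76 k_BT at τ = 1 k_BT/nm²).  The τ = 0 branch is the
  τ → 0⁺ limit with an O(√τ) difference from exactly this term.

The headline outputs at the defaults: dimerization gain 12.8 k_BT at
`d* = 1.78 nm` for `U = −0.9 nm`; favourable window 1.34–3.88 nm;
`U_c = −0.404 nm`; shallow-state cost 3.8 k_BT at d = 2 nm, exceeding
10 k_BT for d ≤ 1.5 nm.  Near the upper window endpoint `|G_int|` stays
below ~0.3 k_BT over d ∈ [3.8, 5.5], so that endpoint is intrinsically
soft: sub-k_BT changes in conventions move it by nanometres.

## 2D pinned-height solver (`thickness2d`)

For arbitrary wedge orientations the tips matter, and the model is solved
with `h⁺ = 0` for the thickness field alone over a 2D patch.  A wedge is a
stadium footprint (rectangle of length `L − 2r0` capped by semicircles of
radius `r0`); the imposed immersion equals `U` on the straight sides and
tapers linearly in arc length to 0 at the cap centres, switching the
deformation source off smoothly at the helix tips (the taper's linear form
is a recorded choice; only "gradual" is physically required).

Discretisation: regular-grid finite differences; the squared 5-point
Laplacian gives the 13-point biharmonic stencil.  All nodes covered by a
footprint carry Dirichlet values extended from the nearest outline point;
the energy is integrated over membrane nodes only; the patch edge (≥10 λ_s
from any footprint) is clamped to the uniform tension equilibrium
`u_eq = −τa/K_t`, and the tension background energy is subtracted.  The
resulting contact condition is hinged (prescribed value, zero bending
moment): enforcing a zero normal slope on an embedded staircase boundary
has a non-convergent interface energy on regular grids, whereas the hinged
discretisation converges cleanly, so the hinged contact is the package's
2D convention and the matching 1D closed form
`u = U e^{−βr} cos βr`, `β = (K_t/K_b a²)^¼/√2`, is the transect oracle
(agreement <0.1% at 0.1 nm resolution; energy per unit length within 10%).
Grid nodes live on an absolute lattice with an irrational phase so that
footprint outlines never pass exactly through nodes and references cancel
between patches.  Energies converge O(dx) (staircase boundary): the
isolated-footprint energy moves ~4% from dx = 0.15 to 0.1 nm, and pair
interactions carry ±0.1–0.2 k_BT pose-aliasing noise — small against the
~−6 k_BT face-on well.

Pair-potential tables sample the relative pose of two footprints
(quadrant `Δx, Δy ≥ 0` by the stadium's mirror symmetries; orientation
periodic over [0, π)) at 0.5 nm / 30° spacing to 6 nm range in the test
configuration.  Overlapping poses are flagged hardcore (lookup returns
+∞ geometrically, never interpolated) and their cells are filled from the
nearest solved neighbour so interpolation near contact stays finite.
Tabulated energies blend smoothly (cosine) to zero over the outer quarter
of the range — the usual truncation convention; the raw interaction tail
(~e^{−βr}, 0.07 k_BT at 9 nm) is physical for the pinned-height model.
Three-wedge fields confirm approximate pairwise additivity (collinear
triples within 2%, a worst case of ~20% retained as the test bound; dense
face-on stacks genuinely violate additivity and are not used in lookups).

## Rigid-body annealing (`assembly_mc`)

An N-BAR protein is a rigid 2D body: a crescent backbone (three capsules,
span 8.6 nm, sagitta 1.1 nm, radius 0.9 nm) with the two H0 helices as
capsules protruding axially past the tips (centres ±5.7 nm, 0.14 nm
towards the concave "outer" side), helix directions outward per the
dimer's C2 symmetry.  Only an inset drawing constrains this geometry, so
all dimensions are parameters; the near-axial H0 placement is load-bearing:
it makes lateral face-to-face double dimers sterically impossible (the
backbones would have to approach closer than one backbone diameter), which
restricts H0 dimerisation to the tip-to-tail antiparallel motif seen
experimentally.  Sterics are exact capsule–capsule (segment distance)
tests.  H0–H0 energies come from the pair table, looked up by relative
footprint pose and symmetrised over both helices' frames so that the pair
energy is identical whichever protein moves (without this, interpolation
asymmetry breaks detailed balance and T = 0 energies can climb).  The
optional BAR–BAR term is the modified Lennard-Jones potential
`ε[(r_m/r)¹² − 2(r_m/r)⁶(1 − |2θ₁−π|/2π − |2θ₂−π|/2π)]` with ε = 10 k_BT,
`r_m = 10 nm`, evaluated between the backbone centroids (0, 0.8 nm in the
body frame); using the centroid rather than the pose centre lifts the
outer/inner degeneracy of chain links by ~2 k_BT in favour of outer links.

Monte Carlo: per step, each protein (freshly shuffled order) attempts one
translation (uniform, ±0.1 nm) and one rotation (±1°), accepted by the
Metropolis rule with energies in k_B·T_room and the dimensionless
temperature in units of room temperature.  Annealing runs a hot phase at
T = 2 followed by a linear ramp to 0.  The full-scale protocol is 10⁷ hot
+ 5×10⁶ cooling steps; the package's study conditions for tests and
examples are a scaled-down 10⁵ + 5×10⁴ steps with 16 proteins in a 60 nm
periodic box (≈16% area coverage), chosen so that an ensemble of ten seeds
runs in minutes while still assembling dimers in every seed and 3–4-protein
chains in about half of them.  Chain statistics gate H0 dimers at 2.5 nm
centre separation (2.2 nm plus a 30° antiparallel gate for architecture
counts); annealed ensembles give a pooled alignment median at 180° and an
outer-link fraction of ~0.55 without and ~0.65 with the BAR term.
Annealing locates low-energy configurations only; it is not thermodynamic
sampling, and scaled-down runs under-grow chains relative to full-scale
ones.

## Conformational switch (`confswitch`)

A pair of proteins, each shallow (s = 0) or deep (s = 1), has energy
`G_pair = (s₁+s₂) ε_d + G_int(s₁,s₂,r)` with `G_int` from the 1D solver
(face-on, isotropic in the axis separation r; the mixed state uses the
asymmetric-pair solution with the same contact slopes on both wedges).
Sampling r over a disc up to `r_c = 40 nm` gives
`z(s₁,s₂) = e^{−(s₁+s₂)ε_d}[1 + cπ∫_{2r0}^{r_c} (e^{−G_int}−1) r dr]` and
`P_d = z(1,1)/[z(0,0)+2z(0,1)+z(1,1)]`, with `c` in proteins/nm².  The
Mayer integrals are computed once per state pair on a monotone-cubic
interpolant (dense near contact; the sub-0.01 nm band where the repulsion
exceeds ~300 k_BT is handled in closed form with f = −1), then weights and
whole phase diagrams are closed-form in `(c, ε_d)`.  Checks: the dilute
limit `P_d → 1/(1+e^{ε_d})²`; `P_d` monotone in c; a `P_d = ½` contour at
ε_d > 0 — the concerted switch.  Because every state pair carries the
algebraic height-mediated tail, `P_d` retains a mild cutoff dependence
(ΔP_d ≈ 0.009 for r_c 40 → 80 nm at c = 10⁻⁴) and the dilute-pair bracket
`1 + cπI` turns negative above c ≈ 1.3×10⁻³ nm⁻² (a `RangeError`); default
grids stay below 10⁻³ nm⁻².

## Known limitations

* The model omits lipid tilt, curved reference states, and the general
  two-leaflet (`u⁻ ≠ 0`) problem.
* The upper endpoint of the favourable window and the shallow-state
  contact cost depend on sub-k_BT features of the height-mediated tail and
  on where "contact" is evaluated; both are soft numbers.
* 2D energies converge only O(dx) on the embedded staircase boundary, and
  the hinged 2D contact differs from the clamped 1D contact by
  construction.
* The N-BAR body and the scaled-down annealing protocol are reconstructed
  study conditions; conclusions from them are qualitative (which motifs
  form), not quantitative (how fast or how large).
* Synthetic rigid-body configurations emulate crowding and steric shape
  only; real membranes add curvature feedback, protein flexibility and
  lipid demixing that the model does not represent, so passing tests
  demonstrate internal consistency of the elastic mechanism, not a
  quantitative match to any specific experiment.
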