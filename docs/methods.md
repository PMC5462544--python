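# Methods

## Geometry of the shape family

A cisterna is a pair of parallel circular membranes (lumenal half
thickness `h`) joined by an open toroidal rim of cross-sectional radius
`r_rim`; the rim meets the sheet at the angle `α = arcsin(h/r_rim)`.
The single shape coordinate is `r_gap`, the radius of the rim's
centre-line circle: `r_gap = r_flat` for the flat disc, small values for
tightly curled shapes. The rim area follows from the toroidal area
element integrated between the junction angles,
`A_rim = 4π r_rim [r_gap(π−α) − r_rim sin α sin φ₀]` with
`φ₀ = arcsin(1 − 2r_gap²/r_flat²)`; the curled sheet consists of two
spherical caps of radius `R` and cap angle θ with `r_gap = R sin θ`.

Total membrane area is conserved along the family. Rather than root
finding, the conservation identity is solved exactly in the cap-angle
coordinate: with `A_mid = A_total − A_rim(r_gap)` fixed,
`cos θ = 4π r_gap²/A_mid − 1`, which selects the unique branch
continuous with the flat limit (θ → 0 at `r_gap = r_flat`, crossing the
hemisphere θ = π/2 as curling proceeds). The flat state is represented
explicitly with `R = ∞` and zero sheet curvature, avoiding large-`R`
overflow. Conservation therefore holds to machine precision at every
grid point (tested against 1e−9 relative).

Units: lengths nm, areas nm², curvatures nm⁻¹, energies k_BT
(temperature is absorbed into the energy unit).

## Free energy

Three additive terms:

1. **Sheet bending.** The two caps carry total curvature ±2/R; averaging
   the Helfrich density over both leaflet signs cancels the odd cross
   terms, giving `F_bend^mid = (κ_mid/2)(4/R² + J_s,mid²)A_mid +
   α_κ̄ κ_mid A_mid/R²`.
2. **Rim bending.** On the torus `J = (r_gap + 2r_rim cos φ)/(r_rim(r_gap
   + r_rim cos φ))` and `K = cos φ/(r_rim(r_gap + r_rim cos φ))`.
   Expanding `(J − J_s)²` reduces the surface integral to three
   geometric moments `∮J dA`, `∮J² dA`, `∮K dA`; the first and third are
   analytic, the second is evaluated by adaptive Gauss–Kronrod
   quadrature (relative tolerance 1e−10) and verified against a
   10⁵-point midpoint Riemann sum to 1e−6 relative. The moments depend
   only on geometry, so they are computed once per shape and reused
   across all elastic parameter scans — this is the main performance
   lever of the package.
3. **Partitioning entropy.** Mean-field mixing of rigid nanodomains
   (area `πR_d²` each) with region-wise constant fractions `Φ_rim`,
   `Φ_mid` tied by conservation
   `Φ_mid = Φ + (Φ − Φ_rim)A_rim/A_mid`. The `x ln x` limits at 0 and 1
   are handled exactly.

The local bending modulus is the harmonic mean
`1/κ(ϕ) = ϕ/κ_lo + (1−ϕ)/κ_ld` and the Gaussian modulus is `α_κ̄ κ(ϕ)`.
Because composition differs between rim and sheet, the Gaussian term is
not topologically invariant; numerically, the total `∮K dA` varies by a
factor ~3 along the shape family, so dropping it would bias every
landscape.

## Equilibria and classification

For each `r_gap` on a 200-point geometrically spaced grid (dense near
`r_rim`, where the rim energy diverges, and ending exactly at
`r_flat`), `Φ_rim` is minimized by bounded Brent search (tolerance 1e−6)
over the interval where both region fractions stay in [0, 1]. Energies
are reported relative to the flat configuration. Interior minima and
the barrier maximum are detected by 3-point stencils and refined by
bounded scalar search to 1e−3 nm; the flat endpoint counts as a local
minimum iff the energy decreases towards it (one-sided slope test with
a 0.5 nm step). Because each grid point is optimized independently, the
profile is exactly grid-size independent at shared abscissae; refined
extrema agree to ≲1e−4 k_BT under grid doubling. Degenerate double
minima (within 1e−3 k_BT) are flagged rather than silently resolved.

Boundary curves of the shape diagram are located per Φ by bisection in
`J_s` (tolerance 1e−4 nm⁻¹) on the existence of each minimum (spinodals)
and on the sign of `F_curl` (equal-energy locus), which is sharper than
contouring cell classifications. The default scan grid is 21 Φ × 34
`J_s` values; all scans are deterministic.

Near the curled spinodal the interior minimum flattens into a fold and
its `r_gap` grows rapidly (≈113 nm within 2×10⁻⁴ nm⁻¹ of the spinodal).
Band-wide statements about the curled minimum therefore sample the five
interior septiles of the band — the natural "5 points spanning the
band" with both minima guaranteed to exist — giving `r_gap` between
~60 and ~90 nm at Φ = 0.2.

## Kinetics and hysteresis

Transition times follow `τ = t₀ e^{ΔF}` with `t₀ = 1 ms` from the
mechanical relaxation estimate `ηR³/κ` (water-like cytosol viscosity
10⁻³ Pa·s, R ~ 500 nm, κ ~ 20 k_BT); barriers above 700 k_BT return an
infinite-time sentinel. Hysteresis sweeps are quasi-static and
deterministic: the system keeps its branch while the branch exists and
the exit barrier towards a lower minimum exceeds a feasibility
threshold (default 25 k_BT, from inverting Arrhenius at observation
times of hours: ln(h/ms) ≈ 17–25). The thresholds' two limits recover
pure spinodal-following (threshold → 0) and pure equilibrium-following
(threshold → ∞); the stochastic triggering of real transitions is
represented by this feasible-jump interval, not by random sampling.

## DAG sub-model

Six DAG fractions (cytosolic/luminal leaflet × top cap/bottom cap/rim)
shift each region's effective spontaneous curvature by
`½(ϕ_cyt − ϕ_lum)ζ_DAG` (with `ζ_DAG = −1 nm⁻¹`, `a_DAG = 0.6 nm²`) and
pay ideal mixing entropy per leaflet with prefactor `1/a_DAG`. Fast
flip-flop keeps the two leaflets' total DAG equal, which eliminates the
rim fractions; the remaining four are minimized by L-BFGS-B seeded at
homogeneity with an **analytic gradient** — the entropy offset is
~5×10⁵ k_BT, so a finite-difference gradient loses the k_BT-scale
curvature signal to cancellation noise (this failure mode was observed
and is the reason for the analytic gradient). Cap curvature signs are
`J_top = −2/R`, `J_bottom = +2/R`, under which the cytosolic leaflet of
the top cap enriches upon curling. The membrane is uniform
liquid-disordered (`κ_ld`); no Gaussian term appears (with a uniform
modulus it is topologically constant). At `ζ_DAG = 0` or `ϕ_DAG = 0`
the exactly homogeneous analytic optimum is returned directly. The
joint optimum over fractions and shape classifies the global state per
`(ϕ_DAG, J_s)` cell; the flat/curled boundary moves by less than a
`J_s` grid step over the full `ϕ_DAG ∈ [0, 0.05]` range — DAG
redistribution is not a shape driver.

## Default parameters

| parameter | default | meaning |
|---|---|---|
| `r_flat` | 500 nm (variant 1000) | flat sheet radius |
| `r_rim` | 30 nm | rim cross-sectional radius |
| `h` | 15 nm | lumenal half-thickness |
| `R_d` | 5 nm (variants 2, 20) | nanodomain radius |
| `Φ` | 0–0.4 | nanodomain area fraction |
| `κ_ld`, `κ_lo` | 20, 80 k_BT | bending moduli of the two phases |
| `α_κ̄` | −0.83 | Gaussian/bending modulus ratio |
| `J_s` | 0–0.033 nm⁻¹ | rim spontaneous curvature |
| `t₀` | 1 ms | Arrhenius attempt time |
| `ϕ_DAG` | 0–0.05 | total DAG fraction |

## Scope and limitations

The rim cross-section is circular (spontaneous-curvature-driven
deviations are neglected); fenestrations, multi-cisterna stacks, and
non-axisymmetric shapes are out of scope. Nanodomain fractions are
region-wise constants, not continuous fields, and nanodomains are
uncorrelated with curvature generators. Sweeps are quasi-static; no
Langevin or kinetic Monte Carlo dynamics. The model has no data-fitting
step: all quantitative outputs are deterministic functions of the
parameter set, and the test suite checks internal consistency
(conservation laws, quadrature oracles, limit identities) plus the
qualitative physics (bistability, hysteresis, monotonicities) rather
than agreement with any measured dataset; the one experimental contact
point is the area-conservation prediction `R ≈ 290 nm` for a curled
cisterna of flat radius 510 nm, compatible with the measured
270 ± 26 nm.
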