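# Methods

## Model overview

The stented ureter is modelled as a lumped linear hydraulic network. Two
fixed-pressure reservoirs — the kidney pelvis (97.8 Pa) and the bladder
(0 Pa) — drive steady, incompressible, laminar flow of urine
(ρ = 997.044 kg m⁻³, μ = 10⁻³ Pa s) through two parallel axial chains:

- the **intraluminal** chain: the cylindrical channel inside the stent
  (inner diameter 1.5 mm);
- the **extraluminal** chain: the annulus between the stent outer wall
  (2.5 mm) and the ureter lumen.

The chains are coupled radially by the stent's side holes (0.8 mm), by
Darcy seepage through the porous stent wall (permeability α), and at both
ends where the stent openings and the anchoring-coil holes sit inside the
reservoirs.

Every element is a linear conductance G (kg s⁻¹ Pa⁻¹), mass flow
ṁ = G Δp. Kirchhoff's law at each node gives a sparse symmetric
positive-definite system G·p = b for the unknown nodal pressures, solved
directly (sparse LU); a fully independent dense assembly + LAPACK solve
serves as an oracle in the tests. The accepted Kirchhoff residual is
10⁻¹² relative to the total flow.

## Closures

| element | conductance |
|---|---|
| stent lumen | Hagen–Poiseuille, G = ρπd⁴/(128μL) |
| extraluminal annulus | concentric annulus, G = ρπ/(8μL)·[R₀⁴−Rᵢ⁴−(R₀²−Rᵢ²)²/ln(R₀/Rᵢ)] |
| side hole | series of Sampson orifice (R = 3μ/r³) and short tube, G = ρ/R |
| porous wall (radial) | cylindrical Darcy shell, G = 2πραΔz/(μ ln(r₀/rᵢ)) |

The ureter tapers, so annulus conductances over an interval are composed
harmonically from 8 sub-segments evaluated at their midpoint diameters
(verified to converge under refinement). Inertial and entrance losses are
neglected: every edge Reynolds number in every shipped case stays below
75, far under the laminar threshold of 2300, which the solution itself
verifies a posteriori.

Two caveats about the closures' limits, reflected in the test suite:

- The annulus tends to the open pipe as Rᵢ → 0 only **logarithmically**
  (relative deficit ≈ 1/ln(R₀/Rᵢ)): even a hair-thin axial wire pins the
  centreline velocity to zero. At Rᵢ/R₀ = 10⁻³ the deficit is ≈ 14.5%.
- The geometric bracket of the annulus formula is a small difference of
  large terms; it must be evaluated without intermediate rounding. At
  R₀ = 1.5 mm, Rᵢ = 1.25 mm, L = 100 mm the exact value is
  G = 1.1222×10⁻⁷ kg s⁻¹ Pa⁻¹ (bracket 2.8662×10⁻¹⁴ m⁴, confirmed at
  40-digit precision).

## Geometry

The ureter lumen (ex vivo) is piecewise linear over L = 240 mm: 6.0 mm at
the pelvi-ureteric junction tapering to 3.0 mm over the proximal third,
2.5 mm in the middle third, 2.4 mm distally, flaring to 2.9 mm at the
vesicoureteric junction (5 mm transitions, 8 mm flare).

**Stented lumen.** The middle/distal ex vivo lumen (2.4–2.5 mm) is no
wider than the stent itself (2.5 mm), so an indwelling stent dilates those
segments. The post-insertion lumen is modelled as

    d_eff = max(d, d_min + s·(d − d_ref)),   d_min = OD + 2δ

with clearance δ = 0.35 mm, slope s = 0.5 and d_ref = 2.4 mm (the
narrowest ex vivo diameter). Wide proximal segments are untouched; narrow
segments keep their relative ordering at compressed amplitude, leaving a
patent annulus everywhere. δ and s were fixed once, by requiring the
mid-ureter flow split (a thin but non-negligible extraluminal share, and
distal re-entry of annular flow at the flare) to sit in the physically
expected regime; they were not tuned against any test after that.

**Side holes.** 42 holes: 4 on each anchoring coil (lumped into the end
attachments, since the coils sit inside the reservoirs) and 34 on the
shaft at x = jL/35, j = 1…34. The axial discretisation always uses the
34-station layout — also for the hole-less stent — so reporting surfaces
(one per segment between adjacent stations) are comparable across cases.

**Occlusion.** A complete 6 mm extraluminal blockage centred between
holes 21 and 22 (mid-ureter). Annulus and wall edges overlapping the
blocked interval are removed; flow must re-enter the lumen upstream
(making hole 21 the busiest) and exit downstream.

**Wall transport.** The porous wall is modelled as purely radial exchange
between the chains, lumped at each segment midpoint. The axial in-wall
flow `m_wall` is therefore identically zero in the reported decomposition
ṁ_total = ṁ_intra + ṁ_extra + ṁ_wall; the radial seepage per segment is
reported separately as `wall_exchange`. Axial conduction inside a 0.5 mm
wall of permeability ≤ 10⁻¹⁰ m² is smaller than either channel by many
orders of magnitude.

## Randomized-scenario generator

`random_scenario(seed)` draws geometry within ±20% of the defaults
(length, lumen diameters, stent inner diameter, hole diameter — jointly
scaled where physical), permeability log-uniform over [10⁻¹⁸, 10⁻¹⁰] m²
(unporous with probability 0.2), removes all side holes with probability
0.2 and adds the reference occlusion with probability 0.25. It is used
for property tests only (monotonicity of flow in permeability, solver vs
oracle agreement, validation); its parameters were chosen a priori to
stay inside the model's validity envelope and were not adjusted
afterwards.

## Numerical choices

- Sparse direct solve (scipy `spsolve`) on the reservoir-eliminated SPD
  system; no iterative tolerances enter the results.
- Nodes not connected to either reservoir (e.g. when an occlusion strands
  part of a chain) are excluded from the solve and reported with NaN
  pressure; a network whose reservoirs are disconnected from each other is
  an error naming the pelvis-side component.
- A zero-conductance edge (α = 0 wall) never enters the matrix, making the
  unporous case bit-identical to a network without wall edges.
- All outputs are deterministic and byte-stable: the embedded provenance
  record carries package version, config hash, solver description and
  seed, but deliberately no wall-clock timestamp.

## Limitations

- Fully developed laminar closures; entrance effects, hole jet momentum
  and local losses at the taper transitions are neglected. This is
  consistent at Re ≲ 75 but underestimates losses near holes carrying
  their largest fluxes.
- The ureter wall is rigid; peristalsis, wall compliance and micturition
  pressure swings are out of scope, as are gravity/orientation effects,
  heat transfer, and encrustation/biofilm kinetics.
- The concentric-annulus closure ignores stent eccentricity, which in
  reality increases annular conductance at fixed cross-section.
- The stented-lumen dilation transform is a modelling assumption, not an
  imaging-derived geometry; absolute flow magnitudes inherit its
  uncertainty, while orderings and trends (permeability monotonicity,
  occlusion rerouting, hole-activity patterns) are robust to it.
- Total flow responds only weakly to wall permeability
  (d ln Q/d ln α ≈ 0.01–0.05 over α ∈ [10⁻¹², 10⁻¹⁰] m²); consequently,
  recovering α from a measured total flow is ill-conditioned under even
  1% observation noise (median error ≈ 20–25%), although the noise-free
  inverse problem is solved to machine-level flow tolerance.
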