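# Methods

## The system being modelled

Cumulus–oocyte complexes (COCs) from prepubertal sheep are matured in vitro
for 24 h either statically (a multiwell plate: 400 µL of medium, 2.1 mm deep,
under a 2.1 mm mineral-oil overlay) or under millifluidic perfusion in a
2 mL cylindrical PDMS bioreactor chamber fed at 50 or 100 µL/min. Inside the
chamber the COCs are cultured naked on the floor ("native"), confined by
3D-printed resin supports (a ring; a concave dish with the ring on top; the
fully closed "box" of dish + ring + plain lid), or embedded in 150 µL of
alginate gel held by the dish + ring. The package computes the two physical
exposure metrics that differentiate these configurations:

* the maximum viscous shear stress on the COC surfaces, from a steady
  incompressible flow solution, and
* the volume-averaged oxygen concentration in the culture region, from an
  oxygen convection–reaction–diffusion (CRD) solution with COC consumption.

It also reproduces the statistical treatment of the oocyte-outcome tables
(chi-square grading of categorical outcomes; ANOVA + Dunnett on per-oocyte
fluorescence intensities) and provides synthetic generators so the whole
pipeline is testable without the unpublished raw data.

## Transport model

Flow: steady incompressible Navier–Stokes in the medium, with the COC
spheres, resin inserts, gel and oil as rigid no-slip regions. Medium
viscosity 0.6913 mPa·s (water, 37 °C), density 993 kg/m³. The inlet and
outlet ports impose a parabolic profile carrying exactly the pump rate, so
inflow equals outflow identically. The port Reynolds number is O(1), so the
convective term is a small correction: it is treated as a lagged explicit
source around exact Stokes solves (Picard), converging in 3–4 sweeps and
giving the slightly sub-linear 100:50 shear ratio (≈1.96). With inertia
disabled the solution is exactly linear in the flow rate, which the tests
exploit.

Oxygen: ∂c/∂t + u·∇c = ∇·(D∇c) − q(c), with D = 3×10⁻⁹ m²/s in medium,
2.5×10⁻⁹ in alginate, 2×10⁻⁹ in oil. Each COC consumes OCR = 4 pmol/min
(interpreted per COC, 21 COCs; a `per_coc=False` switch implements the
total-OCR reading), distributed over its sphere; below c_crit = 0.005 mol/m³
the sink decays linearly to zero so concentrations can never go negative.
Boundaries: saturated inlet (0.21 mol/m³ by default — the perfusion loop is
oxygenated through a sterile filter and is reduced to this inlet condition),
advective outflow, Robin flux through the PDMS side walls
(permeability 3.78×10⁻¹¹ mol·m·m⁻²·s⁻¹·mmHg⁻¹ over a 3 mm wall; Henry
solubility α fixed by the stated pair 0.21 mol/m³ ↔ 159 mmHg), fixed
saturation at the oil surface of the static well, zero flux elsewhere.
No oil/water partition coefficient is applied (concentration continuous
across the oil interface), matching a model specified purely by
diffusivities.

## Discretisation

Both solvers share a graded tensor-product rectilinear (voxel) grid per
scenario. Cell size is 0.15 mm vertically across the COC layer (half the COC
radius), 0.3 mm laterally, 2× coarser around the port band and insert tops
and 5× coarser in the upper chamber; material interfaces (oil surface, dish
rim, ring top, the box assembly clearance, the gel surface) always land on
mesh faces. A full bioreactor scenario is ≈70–90 k cells. The anisotropic
default is a desk-scale choice: it resolves the vertical shear gradient at
the floor (which sets the traction on the COCs) and the thin diffusive
features, at about a tenth of the cost of an isotropic 0.15 mm mesh; pass
`lateral_factor=1` for isotropic refinement.

Flow uses a staggered (MAC) finite-volume scheme. The discrete Stokes
saddle-point system is solved exactly: the SPD viscous block is factorised
once (sparse LU, reused across pump rates) and a preconditioned conjugate
gradient iterates on the pressure Schur complement to 10⁻⁶; mass is
conserved to solver precision. Oxygen uses a conservative finite-volume
scheme: harmonic-mean diffusive conductances across material interfaces,
first-order upwind advection, and a direct sparse solve with Picard
iteration on the (rarely active) sink cutoff; the resulting M-matrix
guarantees the discrete maximum principle 0 ≤ c ≤ 0.21 mol/m³. The
transient solver is implicit Euler from a uniform 0.21 mol/m³ initial state
and matches the steady solver within 1 % after a few diffusive times.

Wall shear on flat surfaces is the one-sided difference µ·u_t/(Δ/2) at the
first cell centre — the estimator consistent with the mirror-ghost no-slip
discretisation (it recovers plane-Poiseuille wall shear to rounding error on
the duct fixture, and to 0.5 % once the inlet profile discretisation is
included). On the COC spheres, whose voxelised surface has staircase corners
that overshoot face-local estimates by up to ~1.7×, the traction is instead
probed on the analytic sphere: the velocity is interpolated one fine cell
outward along 256 uniformly distributed surface normals and the traction is
µ·|u_tangential|/distance. COCs embedded in gel report exactly zero shear.

## Geometry defaults and calibrated parameters

Printed dimensions are used directly: ring inner/outer radius 5.5/7 mm,
dish outer radius 7 mm, bowl depth 1.5 mm, COC radius 0.3 mm (n = 21),
2 mL chamber volume, 2.1 mm media and oil layers (well radius 7.79 mm from
400 µL). The dish sits on the chamber floor with the ring on top and, for
the box, the plain disk as lid. Unprinted dimensions were fixed once, as
follows, and are all overridable:

* chamber radius 7.8 mm / height 10.5 mm (24-well-plate footprint, 2 mL);
* ring height 2 mm, lid thickness 1 mm, dish rim thickness 2 mm, bowl rim
  radius 6 mm (spherical-cap bowl);
* ports: two diametrically opposed lateral circular ports, radius 0.75 mm,
  centred 9 mm above the floor (near the lid, where the commercial
  chamber's fill ports sit). Port placement is the one genuinely sensitive
  free dimension: ports low on the wall aim the inlet jet at the
  floor-resting COCs and raise their peak shear by more than an order of
  magnitude; with high ports the COC shear is set by the gentle
  chamber-scale circulation, the regime the reported values correspond to;
* box assembly clearance 0.55 mm between ring top and lid. The resin is
  treated as impermeable, so this clearance is the box's only oxygen
  supply path; it is an *effective, calibrated* parameter — its
  series conductance (D·2πR·w / path length) was matched to the reported
  interior depletion, the same way an unknown leak conductance is fitted to
  an observed concentration. Interior oxygen moves ≈0.09 mol/m³ per 0.1 mm
  of clearance around the default, so reported box values should be read as
  conditional on this calibration;
* PDMS wall thickness 3 mm (Robin coefficient = permeability/thickness).

The headline `avg_oxygen` of a scenario is the volume average over the
*culture region*: all medium for the static well and the native chamber, the
insert interior for ring/concave/box, and the gel plus interior medium for
the alginate configuration. The reported per-configuration values, and in
particular their ordering (the insert configurations below the static well
despite a saturated perfusion supply), are mutually consistent only with an
average over the region the COCs occupy — a whole-chamber average of any
perfused scenario sits near saturation. The whole-liquid average is always
reported alongside (`avg_oxygen_liquid`). Relatedly, a series-resistance
estimate with the stated parameters puts the static well near 0.200 mol/m³
rather than the reported 0.188; both our steady and 24 h transient solutions
agree with the estimate, so the residual gap (well inside the ±0.02
tolerance used for comparison) is left as a documented discrepancy rather
than absorbed into a parameter.

COC placement is uniform over the admissible floor (bowl for concave
configurations, a slab inside the gel for alginate) with an enforced minimum
centre distance of one diameter, deterministic per seed; the default
configuration pins one seed per scenario. Placement is static: the observed
migration of COCs toward the chamber edges over 24 h is not modelled.

## Statistics

Categorical tables are graded per cell: category-versus-rest 2×2 collapse,
uncorrected Pearson chi-square against the control, thresholds 0.05/0.01/
0.001. The uncorrected test is required for the published alginate
"Abnormal" contrast (16/74 vs 7/72, p = 0.049) to reach significance; a
Yates-corrected variant and a full-table omnibus pooling are available
behind flags. Percentages are rounded half-up, the dominant convention in
the published tables. Fluorescence samples are compared by one-way ANOVA
plus Dunnett's many-to-one test (scipy's implementation). The overlap
coefficient is the Manders form Σab/√(Σa²·Σb²) — the source names but does
not define it, so this standard definition is an interpretation. A handful
of published cells are internally inconsistent with their own counts (three
percentages that appear truncated rather than rounded, and five
superscripts not reproducible under any single test convention); these are
catalogued in `mivmsim.tables.PRINT_ERRATA_*` and asserted explicitly in
the test suite.

## Synthetic data

The outcome generator draws per-group multinomial counts; its defaults are
the observed control/perfused proportions at the published sample sizes, so
recovery tests measure the real design's power (the control-vs-perfused MII
contrast is recovered at p < 0.001 in ≥95 % of replicates). The
fluorescence generator draws truncated-normal ADU values on [0, 255]; its
default group means are a synthetic calibration chosen to reproduce the
reported significance pattern, *not* data from the study. What these
generators do not emulate: overdispersion across experimental runs
(replicates are pooled, as in the published tables), measurement floor/
ceiling artefacts, and any correlation between nuclear outcome and
fluorescence intensity within an oocyte. Passing recovery tests therefore
demonstrate pipeline correctness at the stated effect sizes, not robustness
to those real-data features.

## Numerical choices and limitations

* Problem sizes: default scenario meshes are desk-scale (≈10⁵ cells); the
  full six-configuration comparison runs in about ten minutes on one CPU.
  Refining the mesh by 2× changes the scenario oxygen averages by ≪1 %;
  the peak COC shear is the least converged output (it sits on 2–4 voxel
  spheres) and is treated throughout with factor-two, not percent,
  expectations.
* The pump loop (mixing chamber, reservoir, 450 µL/min filling phase) is
  reduced to the saturated-inlet boundary condition; no pulsatility.
* No CO₂/pH chemistry, nutrient transport, temperature fields, or
  cumulus-cell-resolved consumption; the gel and oil are rigid for flow.
* The chi-square grading assumes the published per-cell superscripts came
  from category-versus-rest collapses; alternative poolings are provided
  without endorsing either.
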