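# Methods

`amyvisc` models how the measurable diffusion coefficient of Aβ42
protofibrils changes while the protofibrils laterally associate.  The core
claim it implements is that the viscosity entering the Stokes–Einstein
relation must be the *effective* viscosity of the whole suspension — solvent
plus every aggregate species — and that the drag must reflect the strongly
non-spherical shape of protofibrils.  This note records the model, the
choices made where the design was genuinely open, and what the synthetic
conditions do and do not establish about real data.

## Reaction model

Protofibrils are 1600-mers (`F_1600`); lateral association produces
`F_3200 … F_8000` by the reversible pairwise reactions

    F_{i·1600} + F_{j·1600}  ⇌  F_{(i+j)·1600},   i ≤ j, i + j ≤ n_max,

with a single shared rate-constant pair, defaults k₊ = 0.9 h⁻¹·mM⁻¹ and
k₋ = 6×10⁻³ h⁻¹ (previously validated lateral-association values).  The
closure `i + j ≤ n_max` encodes the observation that protofibrils do not
grow beyond roughly five-fold within the first 1.5 h.  Mass action gives the
net flux `R(i,j) = k₊[F_i][F_j] − k₋[F_{i+j}]`; homodimerisation consumes
two particles of species `i` per event, the unique stoichiometry under
which the monomer mass `Σᵢ i·[F_{i·1600}]` is exactly conserved.  The ODE
system is integrated with SciPy's BDF method at `rtol 1e-8`, `atol 1e-12`
mM, tight enough that the conservation check (≤10⁻⁶ relative drift) probes
the model, not the integrator.  Concentrations are held in mM — the unit in
which k₊ is quoted — and converted from µM at the interface.

At the default 5 µM initial protofibril concentration the dimensionless
driving rate k₊·C ≈ 4.5×10⁻³ h⁻¹, so only ≈1.3 % of `F_1600` reacts within
the 0–90 min observation window.  All trend statements are therefore tested
with rank statistics, which are insensitive to amplitude.

## Geometry and volume conventions

A protofibril is a prolate spheroid with semi-axes `c = 300 nm` and
`b = 2.25 nm` by default.  The published dimensions ("minor axis 2.25 nm,
major axis 300 nm") are read as the semi-axes that enter the drag formulas
directly; the alternative full-axis reading is one configuration change
(`semi_major_nm=150, semi_minor_nm=1.125`).  The reported average
protofibril length of 64 nm is likewise accepted through the same keys.
Lateral association of `n` protofibrils keeps the major axis and yields an
enveloping spheroid of semi-minor axis `n·b`, so the envelope volume grows
as `n²` while the monomer content grows as `n` — two side-by-side spheroids
do not fill their envelope.

Because of that mismatch no single volume bookkeeping is "the" right one,
and three are provided for converting concentrations to volume fractions
`φᵢ = N_A·Cᵢ·Vᵢ`:

* `envelope` (default): `Vᵢ = (4/3)π c (i·b)²`, the geometric envelope.
  Total solute volume *grows* along an association trajectory.
* `mass`: `Vᵢ = i·V₁`.  Total solute volume is exactly conserved; the
  effective viscosity is then constant to O(φ³) and trend signs are
  numerically meaningless.
* `count`: `Vᵢ = V₁` for every species, so the total solute volume tracks
  the particle count, which falls as protofibrils merge.  This is the only
  convention under which the effective viscosity is an increasing function
  of the 1600-mer concentration and a decreasing function of each larger
  species' concentration — the qualitative behaviour reported for this
  system — and it is the convention the trend tests use.  The envelope and
  count conventions bracket the physical truth; the package treats the
  band-style diffusion outputs (envelope) and the viscosity–concentration
  trends (count) as complementary views rather than forcing one convention
  to do both jobs.

## Effective viscosity

A single suspension follows the Quemada law `η = η₀(1 − φ/φ_m)⁻²`, with the
solvent (water) at `η₀ = 0.89×10⁻³ Pa·s` and maximum packing fraction
`φ_m = 0.6`, the midpoint of the literature range 0.58–0.69 (configurable).

For n species the effective viscosity is a weighted average of component
viscosities.  Component `j` views the suspension with species `j`
outermost: `j` suspended in a background of solvent plus all other species,
the background built recursively in the cyclic order
`j, j+1, …, n, 1, …, j−1`.  Relative viscosities compose multiplicatively
(the smaller constituents are "sensed" as part of the continuous phase), so

    η_j = η₀ · Π_p (1 − φ̂_p/φ_m)⁻²,

where the species at chain position `p` enters at its fraction relative to
the sub-suspension that still contains it, `φ̂ = φ_k / (1 − Σ φ_peeled)`.
The outermost relative fraction is the plain `φ_j`, which keeps the
per-species definitions even under relabelling; for two species the scheme
is exactly label-swap symmetric.  The weighted average is not unique; this
cyclic construction is adopted as printed and no alternative blends are
offered.  Averaging weights are either the absolute fractions (solvent
weighted by φ₀) or, by default in the case studies, the solute-normalised
fractions `ψ_j = φ_j/Σφ` with the solvent dropped — the convention in which
only the solutes' mutual proportions matter and the solvent enters through
the component viscosities alone.  Quemada arguments are always absolute
fractions: normalised arguments would sit at the packing singularity
whenever one species holds all solute volume (e.g. at t = 0).

Any relative fraction reaching `φ_m` raises an explicit singularity error
rather than returning a value on the unphysical branch of the squared pole.

A separate empirical sphere–rod model covers bidisperse suspensions of
small spheres and long rods (rod half-length > 20× sphere radius): sphere
and rod relative viscosities compose multiplicatively on the solvent, the
spheres at their fraction within the solvent+spheres continuum.  The sphere
factor uses the Maron–Pierce/Quemada form; the rod factor uses the same
form with the Kitano–Kataoka fibre packing fraction
`φ_m(p) = 0.53 − 0.013·p`, restricting validity to aspect ratios below
≈40.  The companion rod-diffusion relation switches at `φ_r = 0.125`
between a dilute branch (rods sense only solvent+spheres) and a crowded
branch (full effective viscosity); the boundary itself takes the dilute
branch.  Rod friction uses the Tirado–García de la Torre shape factors,
which depend on `ln(L/d)` with end corrections and whose
perpendicular/parallel ratio tends to 2 for long rods.

## Hydrodynamics and the modified Stokes–Einstein relation

Prolate-spheroid drag uses the published Chwang–Wu closed forms

    f∥ = 16π η c e³ / [(1+e²)Λ − 2e],   f⊥ = 32π η c e³ / [(3e²−1)Λ + 2e],

with `Λ = ln((1+e)/(1−e))`.  These satisfy the two limits that pin the
prefactors: `f → 6πηc` as `e → 0` (Stokes sphere) and
`f∥ → 4πηc/(ln(2c/b) − ½)` as `e → 1` (slender body).  Below `e = 10⁻²`
the denominators are evaluated by series with the `e³` factor cancelled
analytically; this removes a ~10⁻⁶ cancellation error near the sphere
limit and makes `e = 0` exact.  Orientation is *not* averaged: the model
deliberately reports the bracket

    k_upper = k_B T / f∥(shape, η_e),   k_lower = k_B T / f⊥(shape, η_e),

with Perrin-style orientational averaging out of scope.  Temperature
defaults to 298.15 K ("room temperature"); k_B and N_A are CODATA-exact.

The single-species reduction `D = k_BT / (6πη₀a·(φ₀ + φ(1−φ/φ_m)⁻²))`
recovers the classical Stokes–Einstein value exactly at φ = 0, and its
first-order expansion in `ε = φ/φ₀` agrees with the full form to O(ε²)
(verified at ε = 10⁻³ to better than 10⁻⁵ relative).  The sedimentation
coefficient `s = M(1 − v̄ρ)/(N_A·6πηa)` is provided for cross-checking
centrifugation-derived sizes; `s/D = M(1 − v̄ρ)/(N_A k_BT)` when both use
the same drag.

## Case-study pipeline and synthetic DLS traces

`run_case` integrates the 2-, 3- or 5-species network (initial condition:
all material in `F_1600`, defaults 5 µM, 0–90 min on a 91-point grid),
converts each state to volume fractions, and emits one row per time point
with concentrations, η_e, and per-species diffusion bounds.  Runs are
deterministic given the configuration; each run logs a configuration hash,
mass drift, and output ranges.  CSV output is lossless at 12 significant
digits.

`generate_synthetic_dls` emulates instrument exports for testing
comparison code: it perturbs a model diffusion series with mean-preserving
multiplicative lognormal noise of chosen coefficient of variation, seeded.
It reproduces only the marginal noise level of a DLS trace — not baseline
drift, correlated residuals, intensity weighting across a polydisperse
ensemble, or the inversion artefacts of real correlator data — so tests
passing on these traces show the comparison plumbing works, not that the
model fits any particular instrument's output.

## Known limitations

* With the default rate constants and 5 µM load, concentration changes
  within 90 min are ~1 %, so all within-window trends are small-amplitude;
  the model's headline diffusion band is set almost entirely by geometry
  and the dilute effective viscosity (η_e/η₀ ≈ 1.07).  The computed band
  across the three case studies is ≈2.6–5.8×10⁻¹² m²/s; reported model
  values near 1.7–2.4×10⁻¹² m²/s would require η_e/η₀ ≈ 2.5 at these
  loadings, which no volume convention implemented here produces from
  5 µM of 300×2.25 nm spheroids.
* "Mutual viscosity" interaction terms, stress-tensor mixture rheology,
  shear-rate dependence, rotational diffusion, oblate spheroids, monomer
  addition/elongation kinetics, stochastic simulation, parameter fitting,
  and the spatial reaction–diffusion extension are all out of scope.
* The cyclic weighted average is one defensible mixture rule among
  several; results at higher loadings depend on that choice.
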