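# Methods

`nanosolv` models the solvation thermodynamics of a drug–nanotube carrier system:
sulfasalazine (SSZ, keto and enol tautomers) adsorbed on the outer wall of a
hydrogen-capped zigzag (9,0) boron-nitride nanotube (BNNT), in explicit
three-site water at 298 K.  This note records the model, its assumptions, the
defaults, and the deliberate design choices.

## Structures

All structures are generated programmatically; nothing is downloaded.

**BN nanotube.**  A zigzag (n,0) honeycomb lattice is rolled onto a cylinder of
radius √3·a·n/(2π) (a = B–N bond length, default 1.45 Å).  The rolling preserves
every bond length exactly: circumferential bond components become chords, and the
axial row spacing is adjusted to compensate, so the builder's lattice is ideal by
construction.  With n = 9 and 22 atom rows the tube holds 99 B + 99 N over
22.6 Å at radius 3.60 Å.  (DFT-relaxed tubes are reported slightly wider, ~3.67 Å;
the ideal rolled value is the geometric reference here and the difference does not
affect any computed observable's contract.)  Rim atoms are saturated with one
hydrogen each along the severed bond direction (B–H 1.19 Å, N–H 1.01 Å, 18 caps),
the standard capping convention.  Wall charges default to the reported
Mulliken averages, ±0.83 e on B/N; cap hydrogens absorb any residual in equal
shares so every structure is exactly neutral.

**SSZ fixture.**  No optimized coordinates are deposited for this system, so the
drug is an idealized rigid fixture: the correct atom inventory (C₁₈O₅N₄SH₁₄,
42 atoms), standard bond lengths and ring geometries, and the published Mulliken
charges on the thirteen tabulated sites (C1, C2, O1–O3, N1–N4, S, O(S), H2, H3)
for the chosen tautomer.  The residual charge is spread uniformly over the
remaining hydrogens to force exact neutrality (unlisted heavy atoms carry zero).
The Monte Carlo / FEP machinery is insensitive to the exact internal geometry;
observables that would require the true DFT structures and charges (absolute
solvation energies of the real complexes) are out of reach of this fixture and
are therefore handled as bookkeeping over the transcribed tables instead.

**Complex placement** is deterministic: the named interaction atom (carbonyl O,
sulfonyl O, or pyridine N) is posed over a boron atom at the tube's axial
midplane along the outward normal, the body is rotated so the interaction bond
points at the wall, and the pose slides along the normal until the minimum
cross-body distance equals the requested gap.  Only the contact pair and the gap
are contractual; the rest of the pose is a documented construction.

**Solvation.**  Waters are seeded on a cubic lattice with small jitter and random
orientations at the requested mass density (default 0.993 g/cm³, i.e. 0.0332
molecules/Å³ — ~4150 molecules in the 50 Å reference box), then any water whose O
lies within 2.6 Å of a solute atom is removed.  The 2.6 Å carve-out avoids
initial clashes while reproducing the expected depletion (≈3950–4060 waters
around the tube complexes in a 50 Å box).  The construction is a pure function of
the seed.

## Energetics

Rigid bodies only; the potential is purely intermolecular:

    E = E_water–water + E_solute–water,
    E_solute–water = E_elec + E_vdW.

Water is the standard rigid three-site model (O–H 0.9572 Å, H–O–H 104.52°; LJ on
O with ε = 0.1521 kcal/mol, σ = 3.1507 Å; charges −0.834/+0.417 e).  The cited
water potential is named but its parameters are not printed in the reference
tables, so the standard published set is adopted and exposed in the config.
Solute sites use the transcribed LJ table (C, N(NT), B(NT), S, N, H, "H on C")
with Lorentz–Berthelot mixing, ε_ij = √(ε_i ε_j), σ_ij = (σ_i+σ_j)/2.  The
Coulomb constant is 332.06 kcal·Å/(mol·e²).

Two quirks of the transcribed LJ table are kept as printed but configurable:
the bare-H site's σ = 0.094 Å (very likely a typo for 0.94 or 2.5 — it makes the
site essentially LJ-silent) and the absence of an O row for solute oxygens, which
fall back to the water-O parameters.  Both choices are overridable through the
registry.

**Cutoffs and boundaries.**  Cubic periodic box, minimum image.  Water–water
pairs use a molecule-centre (O–O) spherical cutoff, default 9.5 Å, with no
long-range correction; the box must be at least twice the cutoff.  Solute–water
energies are summed over all waters with per-site-pair minimum image: a
molecule-centre cutoff is ill-posed for a solute longer than the cutoff sphere
(the 22 Å tube), and the full sum keeps the energy decomposition exact.  The
small-box test systems (12.4 Å) use a 6 Å cutoff so the cutoff stays below half
the edge.

## Monte Carlo

Canonical-ensemble Metropolis sampling over waters only; the solute is fixed
(rigid, never moved).  One cycle: pick a water uniformly, translate each axis by
U(−d, d) with d = 0.13 Å, rotate by U(−θ, θ) with θ = 10° about a uniformly
random axis through the O atom (O-centred rotation keeps the proposal symmetric),
wrap, and accept with min(1, exp(−ΔE/RT)), R = 1.98720425×10⁻³ kcal/(mol·K).
With these amplitudes dense water accepts ≈52–55% of trials, consistent with the
~50% the protocol was tuned to.  Whether the ±0.13 Å bound is per-axis or a
vector norm is not specified in the source; per-axis is implemented and
configurable.

Energies are maintained by local updates (only the moved molecule's pairs) with
a full refresh every 10⁵ moves to bound floating-point drift; the running energy
stays within 10⁻⁶ kcal/mol of a fresh total over 10⁴ moves.  The random-draw
order per cycle (molecule, translation ×3, axis normals ×3, angle, acceptance —
the acceptance uniform is always drawn) is frozen, so a seed determines the
trajectory bit-for-bit.  Equilibration defaults to a config choice; production
samples energies every `sample_every` cycles and, optionally, thinned coordinate
frames.

**Problem sizes.**  The reference protocol (50 Å box, ~4000 waters, 10⁷
configurations) is reproduced at reduced scale for routine runs: the shipped
hydration-structure pipeline uses a half-length tube (12 rows, 108 B/N + 18 H),
a 30 Å box (~830 waters after carve-out), 6×10⁵ equilibration and 7×10⁵
production configurations.  These sizes resolve the first hydration shell
cleanly; they are the package's default desk-scale protocol, not a claim that
they match the reference run's statistical precision.

## Free-energy perturbation

Increments use the Zwanzig estimator, ΔG(A→B) = −RT ln⟨exp(−(E_B−E_A)/RT)⟩_A,
computed with log-sum-exp (overflow-safe).  Solvation legs are computed by
annihilation: solute–water charges scale linearly in λ and the LJ term through a
soft-core form, 4ελ[(α(1−λ)+(r/σ)⁶)⁻² − (α(1−λ)+(r/σ)⁶)⁻¹] with α = 0.5, which
reduces to plain LJ at λ = 1 and removes the end-point singularity as atoms
vanish.  The default ladder has 11 windows denser near λ = 0
(1, 0.9, …, 0.1, 0.05, 0); windows are warm-started from the previous window's
final configuration; estimates are double-wide (each trajectory re-scored at
both neighbours, the two estimates of every increment averaged), with
block-averaged (10 blocks) standard errors and a warning when a window's
effective sample size falls below 10%.  Because the gap observable decorrelates
slowly in dense water, single-run error bars remain optimistic; where an
honest interval matters (the cross-check below) the estimate is repeated over
independent seeds and a t-interval is used.  No BAR/MBAR: the exponential-average
estimator is the method under study.

For a rigid solute the gas-phase leg is identically zero (no intramolecular or
solvent terms change), recorded explicitly so that
ΔG_solv(A) = ΔG_gas(A→0) − ΔG_sol(A→0) = −ΔG_sol(A→0) stays auditable.  The
association free energy closes the cycle
ΔG_ass = ΔG_sol(drug→0) + ΔG_sol(tube→0) − ΔG_sol(complex→0); the equivalent
solvation-convention entry point is provided and tested for consistency.

The annihilation route is cross-checked against Widom test-particle insertion
for a single neutral LJ site in a small water box.  The Widom estimator
converges poorly for large probes (cavity statistics), so the cross-check uses a
modest probe (ε = 0.15 kcal/mol, σ = 2.9 Å); the two independent routes agree
within combined 95% intervals.

## Hydration structure

The cylindrical RDF g(r) = ρ(r)/ρ_bulk counts water oxygens (H excluded, the
convention for hydration shells) in coaxial shells of height equal to the full
box edge around the tube axis, bin width 0.2 Å, with ρ_bulk = N_water/V.  No
axial truncation at the tube ends is applied, so peak heights are comparable
run-to-run but slightly diluted by bulk water beyond the tube tips; because the
tube excludes volume, g at large r settles marginally above 1 (a few percent).
The highest peak outside the wall radius marks the first hydration shell; the
profile returns to bulk beyond ~9 Å from the axis.

With the shipped parameter set the first shell settles ~3.2–3.3 Å above the wall
atoms (a single-water potential scan over B and N sites puts the energy minimum
there, in line with typical simulated water–BN layer spacings), i.e. at
6.5–6.9 Å from the tube axis for the (9,0) tube.  Literature values placing this
peak as close as 6 Å from the axis (≈2.3 Å clearance) imply a substantially
softer wall repulsion than these LJ parameters produce; with the transcribed
table and Lorentz–Berthelot mixing the tighter clearance is not reachable, and
the package reports the peak its own model produces.

## Bookkeeping layer

Quantum-chemical results enter only as transcribed constants (packaged CSVs):
total energies and binding energies in both phases, free-energy legs, and AIM
bond-critical-point descriptors.  The package recomputes
E_b = E(complex) − [E(drug) + E(tube)] + BSSE (BSSE defaults to 0; the printed
tables are internally consistent at that resolution), GVR = −G/V with the
non-covalent (GVR > 1) / partly covalent (0.5 < GVR < 1) classification, and the
local-virial residual ∇²ρ − 4(2G + V).  The factor 4 is what the tabulated
ρ/G/V data satisfy (it corresponds to the standard local-virial theorem in
atomic units with the ¼∇²ρ form); the consistency suite follows the data.

Two transcription defects are carried, flagged, never silently fixed: the
enol/carbonyl-ver2 gas-phase row prints a binding energy inconsistent with its
own species energies (its duplicate total energy matches the sulfonamide row
instead), and one complex free-energy leg is printed without its minus sign (the
CSV ships both the printed and the sign-corrected value).  One association free
energy is printed with only two decimals and is compared at that precision.

## Known limitations

- No Ewald/PME electrostatics, no long-range LJ correction, no polarizability;
  truncation effects are part of the model, as in the reference protocol.
- The solute never moves: adsorption geometry is an input, not an outcome.
- The drug fixture's idealized geometry and residual-charge scheme make absolute
  solvation free energies of the drug and complexes fixture-dependent; the
  machinery is validated instead by oracles (brute-force energies, enumeration,
  Widom) and by the structural observable of the solvated tube.
- Synthetic water boxes start from a jittered lattice; short runs retain some
  memory of it, so production-quality runs should extend equilibration well
  beyond the defaults used in the test suite.
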