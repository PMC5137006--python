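# Methods

This note documents the models, numerical choices and known limitations
behind `turntilt`, in the spirit of a package reference manual. Nothing
here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Backbone model

Chains are built by sequential internal-coordinate placement (the
torsion-to-Cartesian construction used by standard backbone builders):
residue 1 seeds an arbitrary frame (N at the origin, CA on +x, C in the
xy-plane) and each subsequent atom is placed from the previous three by
bond length, bend angle and dihedral. All outputs are invariant under
rigid motion, so the seed frame is immaterial (asserted by tests).

Geometry defaults (mean values observed in experimentally determined
protein structures): d(N–Cα) = 1.46 Å, d(Cα–C) = 1.52 Å, d(C–N) = 1.33 Å,
d(C–O) = 1.23 Å, d(N–H) = 0.98 Å; angles Cα–C–N = 117°, C–N–Cα = 121°,
N–Cα–C = 111°; ω fixed trans at 180°; 30 residues. The carbonyl oxygen
is placed in the peptide plane with equal bend angles Cα–C–O = N(next)–C–O;
the amide hydrogen in the same plane with equal angles C(prev)–N–H =
Cα–N–H. The terminal carbonyl uses a virtual next-residue nitrogen so
every residue carries an oxygen. Dihedrals follow the IUPAC sign
convention (verified against Bio.PDB's `calc_dihedral`).

## Helix axis and the (ρ, ϑ) descriptors

The axis is the principal direction of the centred Cα cloud
(total-least-squares line), oriented from the N toward the C terminus.
This estimator is exact for long ideal helices, noise-robust for PDB
fragments, and leaves only end effects: for a parametric 3.6-point/turn
helix the fitted ρ converges to the construction value as the chain
grows (error < 0.005 at 73 points; tests assert the trend). Per-step
rotations r_{i,i+1} are signed angles between consecutive Cα radial
projections about the axis, positive by the right-hand rule, so
right-handed α-helices accumulate positive rotation; ρ = 360°·N/R is
undefined (raises) for non-positive cumulative rotation. ϑ averages
asin(−q̂ᵢ·n̂_CO,i) over all residues with a defined carbonyl, terminal
residues included.

## Hydrogen-bond alignment score

Sub-scores per i→i+4 bond: the harmonic distance score
s_HO = max(0, 1 − ((d − 1.9 Å)/1.2 Å)²); collinearity scores
s_OCNH = max(0, û_OC·û_NH) and s_OCHO = max(0, û_OC·û_HO) with
û_OC = (C−O)/‖·‖ of residue i, û_NH = (H−N)/‖·‖ of residue i+4 and
û_HO = (O−H)/‖·‖ — directions chosen so the ideal linear N–H···O=C
geometry scores +1 in both; and the handedness gate s_HAND ∈ {0, 1} from
the sign of the cumulative axis rotation. The per-bond score is the
product of the four factors (each lies in [0, 1]; any hard failure must
annihilate the bond, which is the gate semantics of s_HAND extended to
the continuous factors). S is the arithmetic mean over all bonds; chains
shorter than five residues return an explicit zero-bond flag.

Under this model the S maximum (1° sweep, 0.1° refinement) sits at
(φ, ψ) = (−48.0, −59.0) on the diagonal φ+ψ = −107.0, where the chain
measures ρ = 3.70 Res/Turn and ϑ = 2.0°. The optimum is a very flat
ridge: S varies by < 0.005 within ±2° along the diagonal, so its precise
location is sensitive to sub-degree conventions in the H/O placement.

## Conformational sweeps and the linear transform

Sweeps evaluate a property on every bin of a grid; the batched backbone
builder makes the full 360×360 1° sweep (129,600 chains of 30 residues)
run in seconds. The basin mask is S > 0 (2,662 bins at 1°). ρ and ϑ are
fitted independently on (φ, ψ) by unweighted least squares over the
basin (for an affine model the joint and independent fits coincide).
Residual maxima at 1°: 0.046 Res/Turn and 2.12°, shrinking monotonically
as the mask is restricted to higher S. The transform is stored as an
invertible 2×2 matrix plus offset; the inverse is the exact matrix
inverse.

## Energy model

Van der Waals: OPLS Lennard-Jones 12-6 over backbone N, CA, C, O with
σ = (3.25, 3.50, 3.75, 2.96) Å, ε = (0.17, 0.066, 0.105, 0.21) kCal/mole
and geometric mixing for both parameters; no distance cutoff; hydrogens
carry no LJ site. Hydrogen bonds contribute −e_hb·sᵢ per i→i+4 bond
(default e_hb = 4 kCal/mole, the middle of the 2–6 kCal/mole range
quoted for backbone hydrogen bonds), i.e. −e_hb·n_bonds·S per chain.
The per-bond form matters: the chain vdW sum varies by ~100 kCal/mole
across the basin, so an intensive (mean-S) bond term could never
compete; summing per bond is the physically meaningful bookkeeping.

**Exclusions.** Pairs separated by ≤ 4 covalent bonds are excluded by
default. 1-2 and 1-3 terms are conformational constants under fixed
internal coordinates (asserted by a test); 1-4 terms are conventionally
scaled in force fields; and the 1-5 set contains the Oᵢ–Cᵢ₊₁
carbonyl–carbonyl contact, which real helices hold at ~2.8 Å — well
inside the LJ radius — stabilised by charge interactions (the n→π*
contact) that this electrostatics-free model does not carry. Pure LJ
would misprice every helical conformation by ~+2.5 kCal/mole/residue
through that single pair and push the energy optimum to ϑ ≈ 18–20°.
The policy is a model parameter; `energy.exclusion_sensitivity` tabulates
the optima under alternative policies, and the acceptance script reports
both the default and the tighter ≤ 3-bond policy.

With the default model the basin argmin moves from (ρ, ϑ) =
(4.08, 27.9°) with no hydrogen bonds to (3.63, 7.6°) at
e_hb = 4 kCal/mole; the steric-to-bonded flip occurs below
e_hb = 2 under this exclusion choice, and past the flip the optimum
creeps along the score ridge toward the pure-S optimum (3.70, 2.0°).
Optima are located by a coarse basin sweep plus a local 0.1° grid
refinement spanning ± one coarse bin; a one-bin shift of the coarse
argmin corresponds to ~0.03 Res/Turn and ~0.3° — the resolution quantum
quoted wherever monotonicity of optimum trajectories is asserted.

The harmonic surrogate E = (ϑ−ϑ₀)² + K²(ρ−ρ₀)² uses
K = 10.6/0.63 ≈ 16.8 °·Turn/Res, the ratio of the level-averaged 50%
confinement half-widths of helices in (ϑ, ρ); its unit EU is the energy
of a 1° shift in ϑ. Energy maps for display pass through the double-log
compression log(1+log(1+E)) (monotone, argmin-preserving) after shifting
the map minimum to zero.

## PDB statistics pipeline

Coordinates are read with Bio.PDB (first model only, HETATM and
non-standard residues skipped, disordered atoms resolved to the
highest-occupancy location); HELIX intervals come from a fixed-column
reader, since Bio.PDB's header parser does not expose them. Files
without HELIX records contribute to Level 0 only. Transitions break at
C–N distances > 2.0 Å.

Filtering levels: 0 — −100° < φ < −20° and −80° < ψ < 0°; 1 — both
residues inside an annotated helix; 2 — the single i→i+4 bond of the
5-residue window starting at the transition's donor scores S ≥ 0.01
(the amide hydrogen is estimated from the backbone, handedness from the
five Cα's); 3 — the same with S ≥ 0.5. Levels nest by construction.
Transitions whose donor lies within four residues of the chain end have
no scoreable window and stop at Level 1.

Histograms: 2° bins over the Level-0 window (40×40). Redundancy damping
applies log(1+count) — base e, offset 1 keeps empty bins empty — before
unit-mass normalisation; a symmetric sample distribution keeps the
compressed mean unbiased. Means are histogram-weighted bin centres;
(ρ, ϑ) means are affine images of the (φ, ψ) means. Confinement takes
the smallest harmonic contour (aspect ratio fixed to K, centred on the
pooled mean) containing 50% of samples, reported as half-widths
(Δϑ, Δϑ/K); a K-consistent rectangle ("box", the Chebyshev contour in
scaled coordinates) is available as a configuration switch since the
printed half-width pairs are consistent with either reading. The IPH
table prices each heterogeneous mean against the average of its two
homogeneous means with the measured mean as the energy minimum; the
diagonal is zero by construction and missing means leave NaN cells.

## Synthetic fixtures

The generator emits multi-chain PDB files of 30-residue helices with
HELIX records and per-residue identities. Per-transition targets are
(φ, ψ) pairs; noise is drawn as an isotropic Gaussian in (ρ, ϑ) — the
space in which real helix scatter is symmetric — and mapped back through
the inverse transform before construction. Alternating X-Y-X-Y chains
realise heterogeneous transitions (both directions), homopolymer chains
the homogeneous ones; chains are emitted until every requested
transition has its sample count. Default noise SDs
(σ_ϑ = 10.6/√(2 ln 2) ≈ 9.0°, σ_ρ ≈ 0.54 Res/Turn) make the generated
50% confinement radius match the level-averaged half-widths observed
for real helices; closure tests state tighter SDs explicitly where mean
recovery at 3 standard errors is the point. `iph_exact_targets` places
homogeneous targets on the histogram-bin lattice with even-bin spacing
so heterogeneous midpoints are bin centres and the zero-noise IPH table
is exactly zero. Decoy chains (built outside the helical window, no
HELIX records) exercise the Level-0 rejection path. Output is
byte-identical for a fixed seed.

What the fixtures deliberately do not emulate: experimental noise models
(B-factors, occupancies), crystal packing, chain gaps, side chains
beyond the residue label, or sequence-dependent conformational
preferences. Passing closure tests therefore demonstrates that the
pipeline recovers known ground truth through the full PDB round-trip —
not that real PDB data would show any particular distribution.

## Conceptual simulations

All four perturbations re-optimise the total energy over the basin with
an added term; at zero perturbation they reduce exactly to the
unperturbed optimum (same grid, same refinement path).

1. **Near bulk**: one virtual LJ site per residue (ε = 0.066 kCal/mole,
   ALA-like; σ swept 3.5–9.5 Å) held 1.54 Å from its Cα, radially
   outward from the axis. The site ignores its own residue's backbone
   atoms (bonded exclusion) and interacts with everything else,
   including other virtual sites — inflating σ makes neighbouring
   side-chain shells collide, squeezing both ϑ and ρ down.
2. **Far bulk**: the same site held at σ − 1.96 Å; below a critical
   radius near 6 Å the inflated shells clear the backbone and each
   other, so the optimum is unchanged; above it ρ falls while ϑ stays
   within ~1° of the base optimum.
3. **Electric field**: cylindrical potential linear in axis distance
   acting on carbonyl oxygens (charge −0.5) and amide hydrogens (+0.33,
   OPLS partial charges); the field steers ϑ with ~2% K-scaled
   cross-talk into ρ, antisymmetrically in the field sign. The residual
   ρ response traces to the unequal charge magnitudes.
4. **Radial stretch**: dE = −scale·Σᵢ D_axis(Cαᵢ); positive scale
   (outward force) increases ρ, sign reversal gives the mirror response.
   In this energy model the stretch response rides along the basin's
   soft valley, so ϑ co-moves by roughly twice the K-scaled ρ response
   rather than staying fixed — the valley orientation near the optimum,
   set by the same vdW/HB balance discussed under *Energy model*, is
   the limiting factor, and the cross-talk is reported by the
   acceptance script rather than hidden.

Field and force scales are arbitrary units per Å (no physical units are
defined for them); trajectories are reported against the scale.

## Problem sizes and determinism

Production sweeps use 1° grids (129,600 conformations; seconds when
batched) with 0.1° local refinement; pipeline demonstrations use a
four-letter alphabet (16 transitions × 200 samples, ~3,400 transitions
through the full PDB round-trip) — large enough for 3-standard-error
closure, small enough to run everywhere in minutes. Every stochastic
step takes an explicit seed; sweeps and optima are fully deterministic.

## Known limitations

* The energy model is backbone-only: no side chains (beyond the virtual
  site), no electrostatics, no solvent; its absolute energies are not
  comparable to force-field totals, and conclusions are about optimum
  locations and trends.
* The LJ exclusion policy materially moves the energy optima (reported
  by `exclusion_sensitivity`); the default is a modelling choice, argued
  above, not a fitted quantity.
* The score optimum's flat ridge means sub-degree statements about its
  location carry convention sensitivity of order 1–2°.
* Level-1 filtering trusts the file's HELIX annotation; no secondary-
  structure assignment is recomputed when records are absent.
* mmCIF input is not supported.
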