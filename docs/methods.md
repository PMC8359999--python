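# Methods

This note records the models, conventions and numerical choices behind
`puckermc`, in the order the pipeline uses them.

## Puckering coordinates

The mean plane of an N-ring passes through the geometric centre of the
ring atoms and is oriented so that the first-harmonic sine and cosine
projections of the out-of-plane displacements vanish (the classical
Cremer–Pople construction; the orientation is computed from the cross
product of the two first-harmonic position sums).  The displacements
z_j are projections onto the resulting unit normal; they satisfy
Σz_j = 0 and the two orthogonality sums to machine precision by
construction.  The forward transform projects z onto the m-th ring
harmonics (m = 2 … ⌊(N−1)/2⌋), giving amplitudes q_m ≥ 0 and phases
φ_m ∈ [0°, 360°); for even N the alternating sum supplies the last
coordinate.  That alternating amplitude is signed; we store its
magnitude and fold the sign into the polar angle θ = arccos(q₃ˢ/Q), so
θ = 0° is the chair that displaces atom 1 to positive z.  Degenerate
(planar) states report all phases as 0 with an explicit flag rather
than propagating arbitrary angles.

Angles are degrees and lengths Å at every API boundary; radians appear
only inside functions.

### Phase conventions

Two phase readings are provided.  The default ("standard") is the
two-argument arctangent of (A_m, B_m).  The alternative ("paper")
reconstructs the phase from arccos with a smoothed sign factor,

    φ_m = A_m/(A_m² + ε)^½ · arccos(B_m/(A_m² + B_m²)^½) + 180°,

with ε = 10⁻⁶ (overridable).  This form exists for generalized-
internal-coordinate (GIC) interfaces of quantum-chemistry drivers that
expose `sqrt` and `acos` but not `atan`; the emitted GIC text uses it
verbatim.  For inputs with A_m² ≫ ε the two conventions differ by a
constant 180°; near the A_m = 0 seam the smoothed sign biases the
result by up to (ε/2A_m²) radians of the arccos term, so the half-turn
offset is only exact away from the seam (the property test requires
|A| > 0.05 for a 0.1° tolerance).  Classification always uses the
standard convention.  The square-root in the sign factor is the
dimensionally consistent reading of the smoothed sign; a variant
without it would not be a sign at all.

The inverse transform evaluates
z_j = (2/N)^½ Σ_m q_m cos(φ_m + 2πm(j−1)/N) (plus the alternating term
for even N) and is an exact right-inverse of the forward transform;
round-trip errors are at machine precision, and the test suite bounds
them at 10⁻⁶ over 1000 random states per ring size.

### Emitted GIC text

`emit_gic_definitions` writes one definition per line in an
`Name(Add) = expression` style, using only centre-of-geometry
functions, arithmetic, `SQRT` and `ACOS`, with all numeric projection
coefficients printed to 12 decimals so output is byte-identical across
runs.  The exact keyword spelling of GIC blocks varies between driver
versions; the spelling here is best-effort and the mathematical content
is what is guaranteed.  Unlike phase coordinates driven through such
an interface (which lack periodicity and misbehave near 0°/360°), the
native Python implementation has no seam.

## Conformer catalogs

**N = 5.** Twenty conformers at 18° spacing in φ₂, alternating
envelopes (grid points with mirror symmetry through an atom) and
twists (two-fold points).  Names are constructed from the displacement
pattern at the reference point: the mirror atom becomes the
superscript when displaced positive, the subscript when negative; for
twists the dominant adjacent opposite-sign pair supplies one of each.

**N = 6.** The 38 conformers sit on the polar sphere: chairs at the
poles, boats/skew-boats on the equator at 30° spacing, envelopes/
half-chairs on the tetrahedral bands θ = 54.74°/125.26°, with E and B
on even multiples of 30° in φ and H and S on odd multiples.  The two
chair names are anchored by convention — θ = 0° is ⁴C₁, θ = 180° is
¹C₄ — matching the standard Mercator chart; all other names are
derived constructively as for N = 5 (boats take the dominant same-sign
opposite pair; skew-boats take one up and one down atom separated by
an in-plane atom, choosing the candidate pair containing the lowest
ring position).  The constructive rule reproduces the canonical six
skew-boat names (¹S₃, ¹S₅, ²Sᴼ, ³S₁, ⁵S₁, ᴼS₂).  Note the chair
anchoring and the positive-z superscript rule disagree about which
side of the plane counts as "above" (the ⁴C₁ pole displaces atom 1
positive); both are kept deliberately, since the chart position of
⁴C₁ is fixed by universal usage while the remaining labels only need
to be self-consistent and unique.

**N = 7.** The four-dimensional space is organised on three (φ₂, φ₃)
planes of the normalised alternating amplitude q₃/(q₂²+q₃²)^½: 0.6
(chair/twist-chair), 0.0 (boat/twist-boat) and 0.4
(sofa/twist-sofa/sofa-boat).  On each plane, grid points sit at the
symmetry sites of the two contributing harmonics about each ring atom
j: phase offsets (0°, 0°)/(180°, 180°) are mirror-symmetric through
atom j (chairs, boats, sofas), (90°, 90°)/(270°, 270°) are two-fold
(the twist forms), and the mixed offsets (0°, 180°)/(180°, 0°) are
mirror-symmetric through the bond midpoint opposite atom j, used for
the sofa-boats.  That yields 14 conformers per family (98 in total)
with positional naming rules relative to the symmetry atom; the
twist-chair with its axis through atom 1 is ³,⁴TC₅,₆.  Only the plane
amplitudes are fixed by prior convention; the per-plane grids and
label grammar are this package's documented choice.  On the q₃ = 0
plane the m = 3 harmonic contributes nothing, so the shape depends on
φ₂ alone — the "harp" degeneracy — and both the catalog and the
classifier treat φ₃ as immaterial there.

The ring heteroatom (position N) renders as "O" in names, matching
sugar usage (ᴼS₂, Eᴼ).

### Classification

A state maps to the nearest catalog entry under an angular metric:
circular φ₂ distance (N = 5), great-circle distance on the (θ, φ)
sphere (N = 6), or nearest plane (boundaries at the midpoints 0.2 and
0.5 of the normalised q₃) followed by Euclidean distance in circular
(φ₂, φ₃) for N = 7, with φ₂ alone on the boat plane.  The metric uses
no amplitudes, so assignments are invariant to overall puckering
amplitude; states below `min_amplitude` (default 10⁻³ Å) are planar
and return the planar flag.  Ties break to the earlier catalog entry
in the fixed enumeration order.

## Ring construction

`build_ring_geometry` fixes z from the inverse transform and closes
the ring in-plane: atoms sit on a circle of common radius s at
azimuths accumulated from each bond's in-plane chord
(L_k² − Δz_k²)^½, and s is found by bisection (tolerance 10⁻¹³ on the
radius, 500 step cap) so the azimuth increments sum to 360°.  The
angle sum is monotone in s, so the search cannot stall.  Because the
orientation sums of the prescribed z vanish identically, the mean
plane of the built ring is exactly the xy plane and the forward
transform of the result reproduces the requested state to machine
precision; bond lengths are exact by construction, and ring vertex
angles are whatever closure dictates (for the default templates they
land in the chemically sensible 95–120° range).  Atoms are placed
clockwise so the mean-plane normal points along +z, making "up" in
substituent orientations agree with positive displacement.  Total
amplitudes above 0.9 Å are rejected before the search as geometrically
infeasible for these bond lengths.

Default bond lengths (Å): C–C 1.54, C–O 1.43, C–S 1.82 (also SO₂),
C–N 1.47, C–B 1.57, C–P 1.85; all overridable per template.

## Dihedral libraries

For each canonical conformer of a template the builder records the
N−3 endocyclic dihedrals D_k, defined over ring atoms
(k, k+1, k+2, k+3) for k = 1 … N−3 — the only convention giving
exactly N−3 sequential dihedrals starting at the anomeric carbon.
Reference amplitudes are 0.45 / 0.55 / 0.70 Å for N = 5 / 6 / 7,
chosen near the equilibrium puckering amplitudes of cyclopentane,
cyclohexane and cycloheptane-like rings.  These idealized-geometry
libraries stand in for scan-derived dihedral tables; externally
computed tables in the per-dihedral text layout (`…-D1.txt`,
`…-D2.txt`, matching rows keyed by scan coordinate) load through
`read_library_files` and drive the sampler identically, with the
sampled ring then classified after realisation instead of before.

## Substituents and Z-matrices

Substituent heavy atoms leave the ring along tetrahedral completion
directions of the two ring bonds (half-angle 54.75° about the
bisector, signed by the mean-plane normal; ring boron is planar and
uses the bisector itself).  Group internal geometry (bond lengths,
angles) ships as a plain-text `key = value` table
(`data/groups.var`) with standard covalent values; user files in the
same grammar override entries.  Supported groups: OH, CH₃, OCH₃,
CH₂OH, NH₂, F, H, with 1/1/2/2/1/0/0 rotatable bonds respectively;
remaining valences fill with hydrogens.  SO₂ oxygens are fixed
tetrahedral decorations, not rotamers.

The Z-matrix lists ring atoms 1…N as a chain (atom k ≥ 4 placed by
distance, angle and the endocyclic variable D_{k−3}), then heteroatom
attachments, then substituents by ring position (up face first), then
filler hydrogens.  All values are measured from the assembled
Cartesian model, so realising the Z-matrix reproduces the molecule
exactly (up to the fixed frame: first atom at the origin, second on
+x, third spanning xy).  Named variables are D1…D(N−3)
(endocyclic), R1… (one per rotatable exocyclic bond, in placement
order) and HFLIP (the ±120° N–H/P–H hydrogen dihedral).  Charge 0,
multiplicity 1 always.

## Sampling

The batch generator uses NumPy's seeded PCG64 generator; draw order
per conformer is fixed (library entry, then rotamers, then flip), so
one integer seed reproduces a batch bit-for-bit.  Statistical
equivalence — uniformity over library entries, uniformity of rotamer
angles, balance of the ±120° flip — is the contract, verified by
goodness-of-fit at n = 10⁵; bit-compatibility with any other
generator is a non-goal.  Sampling is uniform over canonical
conformations, not over puckering phase space, and involves no energy
model.  Entropy seeding (seed omitted) records the chosen seed in the
batch manifest so any run can be replayed.

Clash detection flags any non-bonded, non-1-3 atom pair closer than
0.7 Å — coincident or interpenetrating atoms, the known failure mode
of random multi-functionalization — without rejecting strained but
intact conformers.  Policies: `flag` (default; emit everything,
mark), `drop` (redraw, with a 100× attempt cap), `keep` (emit
unmarked).

## File formats and docking preparation

Writers are native and deterministic (fixed decimal places).  Gaussian
inputs carry the variable block; XYZ and PDB carry realised
coordinates, with PDB atom names made unique (element + counter) as
ligand-preparation tools require.  Docking preparation scans a
receptor tree (`receptors/<FAMILY>/<id>/` with a structure file and a
six-key `box.txt`), writes one Vina config per ligand–receptor pair
and a serial manifest with exactly one docking command per pair;
ligand PDBQT conversion commands go to a separate
`prepare_ligands.sh` since that conversion belongs to the external
toolchain.  Nothing external is ever executed.

## Problem sizes used in validation

The test suite and the acceptance script exercise: 1000-state
round-trips per ring size; 1000 random ring geometries against a
scalar-loop oracle of the projection sums; geometry builds of every
canonical conformer for all 21 templates (1092 builds); two
500-conformer application batches (2-hydroxy-tetrahydrofuran and
α-D-glucose) run twice for bytewise determinism; 10⁵-draw
goodness-of-fit; and a 50-ligand × 9-receptor docking preparation
(450 jobs).

## What the synthetic inputs do and do not show

Ring geometries here are idealized: fixed bond lengths, closure-
dictated angles, library dihedrals from idealized conformers rather
than quantum-chemistry scans, and substituent geometry from standard
covalent tables.  Passing tests therefore demonstrate the coordinate
mathematics, the combinatorics, the sampling contracts and the file
formats — not the energetic realism of any individual structure.
Generated conformers are meant as starting points for optimization
and docking, exactly as generated ensembles are used in practice; the
package deliberately contains no mechanism to judge physical
reliability beyond the steric clash flag, and post-analysis remains
the user's responsibility.  Receptor folders in tests are synthetic
placeholders: layout and box arithmetic are verified, binding poses
are out of scope.

## Known limitations

* No energy model: conformer and rotamer draws are uniform, so
  ensemble populations are not Boltzmann-weighted.
* Single rings only: no fused or bridged systems, no glycosidic
  linkage sampling between rings, neutral closed-shell molecules only.
* The seven-ring catalog grid is a documented package convention;
  other septanose label placements exist in the literature.
* The supported substituent set is the minimum for the target
  applications; extending it is a matter of adding group parameter
  entries and a placement recipe.
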