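# puckermc

Random conformer generation for 5-, 6- and 7-membered ring molecules —
monosaccharide-like scaffolds in particular — built on Cremer–Pople
puckering coordinates, with canonical conformer classification,
Z-matrix / XYZ / PDB output and AutoDock-Vina docking-input
preparation.

## The problem

Carbohydrate rings are flexible: a pyranose visits chairs, boats,
skew-boats, envelopes and half-chairs, and the shape a sugar adopts in
an enzyme's active site is often *not* its solution ground state.
Anyone modelling glycosidase substrates, inhibitors or mimics
(thio-sugars, iminosugars, septanosides, …) therefore needs many
conformers of a functionalized ring quickly, covering the whole ring
conformational space rather than whatever a single optimization happens
to land on. `puckermc` generates such ensembles by construction: it
enumerates the canonical ring shapes, realises each as 3-D geometry,
decorates it with substituents, randomises every exocyclic rotatable
bond, and writes structure files ready for quantum-chemistry input or
serial docking.

## The method

For an N-membered ring (N = 5, 6, 7), the out-of-plane displacements
z_j of the ring atoms from a uniquely oriented mean plane are projected
onto ring Fourier harmonics,

    q_m cos φ_m =  (2/N)^½ Σ_j z_j cos(2πm(j−1)/N)
    q_m sin φ_m = −(2/N)^½ Σ_j z_j sin(2πm(j−1)/N)
    q_{N/2}     =  N^−½  Σ_j (−1)^(j−1) z_j          (even N)

giving N−3 puckering coordinates: amplitudes q_m (Å) and phases φ_m
(degrees).  For N = 6 the polar form Q = (q₂² + q₃²)^½,
θ = arccos(q₃/Q) places every conformation on a sphere: ⁴C₁ at the
north pole, boats and skew-boats on the equator.  Ring atoms are
numbered with the anomeric carbon as position 1 and the heteroatom
(CH₂, O, S, SO₂, NH, BH or PH) as position N.

The canonical conformers — 20 for furanose-like rings, 38 for
pyranose-like rings, and three (φ₂, φ₃) planes at relative q₃ = 0.6 /
0.0 / 0.4 for septanose-like rings — are enumerated with reference
coordinates and IUPAC-style names (⁴C₁, ᴼS₂, ³,⁴TC₅,₆ …).  An inverse
transform turns any puckering state back into displacements, a
geometric ring builder closes the polygon under template bond lengths,
and the N−3 endocyclic dihedral angles of every canonical conformer
are tabulated into a dihedral library.

A conformer batch then draws, per structure: one library entry
(uniform over canonical conformations), one uniform angle in
[−180°, 180°] per exocyclic rotamer (hydroxyl H–O–C–C torsions, the
CH₂OH rotation, methoxy, …), and ±120° for the equatorial/axial
hydrogen of N–H / P–H ring heteroatoms.  Everything flows through one
seeded generator, so a batch is exactly reproducible.  Structures with
steric overlap (an acknowledged feature of pure random generation) are
flagged, dropped or kept by policy.

Also included: emission of generalized-internal-coordinate (GIC) text
defining the puckering coordinates with arccos instead of arctangent
(for quantum-chemistry scan drivers that lack `atan`), readers for
external per-dihedral scan tables (`N-x-H-y-X-D#.txt` layout) and
`*.var` parameter files, and a docking-prep step that pairs every
generated ligand with every receptor of a family folder (MANNO,
GLUCO, …) into Vina config files plus a serial job manifest.

## Worked example

500 conformers of 2-hydroxy-tetrahydrofuran:

```python
import numpy as np
from puckermc import (RingTemplate, SubstituentSpec, MoleculeSpec,
                      enumerate_catalog, build_dihedral_library,
                      SamplerConfig, generate_batch, RingAtomSet,
                      forward_pucker, mean_plane_displacements, classify)

template = RingTemplate(5, "O")                      # tetrahydrofuran ring
spec = MoleculeSpec(template=template,
                    substituents=(SubstituentSpec(2, "OH", "up"),))
library = build_dihedral_library(template, enumerate_catalog(5), 0.45)
samples, dropped = generate_batch(spec, library,
                                  SamplerConfig(n_conformers=500, seed=42))
print(f"{len(samples)} structures, {dropped} dropped")
s = samples[0]
print("conformer:", s.library_key, "| D =", np.round(s.D_values, 2),
      "| rotamer H-O-C-C =", np.round(s.rotamer_values, 2))
ring = RingAtomSet(coords=s.coords[:5], validate=False)
state = forward_pucker(mean_plane_displacements(ring))
print(f"q2 = {state.q2:.3f} A, phi2 = {state.phi2:.1f} deg ->",
      classify(state).name)
```

prints

```
500 structures, 0 dropped
conformer: 1T2 | D = [-35.32  13.28] | rotamer H-O-C-C = [-22.]
q2 = 0.450 A, phi2 = 18.0 deg -> 1T2
```

The first sample drew the ¹T₂ twist (its two endocyclic dihedrals
−35.3° and 13.3° come from the library) and put the hydroxyl hydrogen
at −22°; re-measuring the realised Cartesian ring recovers the
requested puckering amplitude (0.45 Å) and phase (18°), and
classification returns the same twist that was drawn.

The same run from the shell, via an `input.dat`:

```
ring_size   = 5
heteroatom  = O
substituent = 2:OH:up
calc        = 500
seed        = 42
format      = xyz
outdir      = out
```

```sh
puckermc generate --input input.dat
puckermc classify out/conf_00001.xyz --ring-size 5 --out report.tsv
puckermc catalog --ring-size 6 --out catalog6.tsv
puckermc dockprep out/*.pdb --receptors receptors/ --family MANNO
```

`generate` writes one structure file per conformer plus a tab-separated
batch manifest (conformer name, dihedral draws, clash flag, seed);
`classify` writes a puckering report (q, φ, Q, θ, assigned conformer);
`dockprep` writes one Vina config per ligand–receptor pair and a serial
`jobs.txt`.

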