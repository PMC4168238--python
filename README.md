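# egostretch

Simulated single-molecule force spectroscopy of pyranose oligomers by
**enforced geometry optimization** (EGO): constant-force pulling on the
terminal anchor oxygens of α-D-galacturonic acid chains, with ring-pucker
classification, stretch–relax force-ladder scans, and force–extension
analysis.

## The problem

AFM pulling experiments on polysaccharides show that chains with
*axially* linked units (such as polygalacturonic acid, the backbone of
pectin) lengthen in discrete steps: under enough tension a pyranose ring
flips from its stable ⁴C₁ chair into longer conformers — twist-boats and
the inverted chair ¹C₄ — because the axial glycosidic/aglycone bonds act
as levers that convert tension into ring torque.  Direct force
spectroscopy on short galacturonic oligomers is hard, so the experiment
can be *simulated*: apply a constant force pair **f** to the two anchor
oxygens and minimize the force-modified energy

```
E_eff(x) = E(x) − f · d(x)
```

where `d` is the anchor–anchor distance and `f` is in atomic units of
force (1 au = Hartree/Bohr ≈ 82.39 nN).  Stretching at each ladder force
from the same relaxed start, then *relaxing* (re-optimizing at f = 0),
distinguishes temporary elastic deformation from **permanent**
conformational transitions: the transition has happened when the relaxed
structure no longer classifies as the starting chair.

Ring conformers are identified by standard puckering coordinates
(Q, θ, φ) of the six ring atoms: θ = 0° is the ⁴C₁ chair, θ = 180° the
inverted chair ¹C₄, and the θ = 90° equator holds the boat/twist-boat
itinerary (⁵S₁, ²S_O, …).  A second, independent route decomposes the six
endocyclic torsions over an ideal conformer basis; a third bins each
unit's flanking O–O distance into the characteristic lengths
c ≈ 4.5 Å, b1 ≈ 4.3 Å, b2 ≈ 5.1 Å, ic ≈ 5.5 Å.

The package is backend-agnostic: any object with
`evaluate(coords_Å) -> (energy_Hartree, gradient_Hartree_per_Bohr)` can
drive the engine.  A built-in toy molecular-mechanics backend provides
desk-scale ring energetics with chair, twist-boat and inverted-chair
basins, so the whole pipeline runs in seconds without quantum chemistry.

## Worked example

Pull the minimal anchored pyranose ring with the toy backend across a
force ladder, locate the permanent chair inversion, and read the
force–extension curve:

```python
from egostretch import (ForceLadder, run_stretch_relax_scan,
                        find_minimal_transition_force,
                        build_force_extension_curve, detect_plateaus,
                        convert_force)
from egostretch.builders import build_pyranose_ring
from egostretch.toyff import toy_ff_build

mol, topo = build_pyranose_ring("4C1")   # minimal anchored pyranose ring
model = toy_ff_build(mol, topo)          # built-in toy backend

ladder = ForceLadder(f_min=0.02, f_max=0.12, step=0.01, refine_resolution=0.0025)
scan = run_stretch_relax_scan(mol, topo, model, ladder)
for f_first, f_last, labels in scan.regions:
    print(f"region {f_first:.3f}-{f_last:.3f} au: relaxed conformers {list(labels)}")

search = find_minimal_transition_force(mol, topo, model, ladder)
print(f"minimal transition force: {search.force:.4f} au "
      f"({convert_force(search.force, 'au', 'nN'):.2f} nN), "
      f"bracket {search.bracket[0]:.4f}-{search.bracket[1]:.4f} au")

curve = build_force_extension_curve(scan)
for p in detect_plateaus(curve).plateaus:
    print(f"plateau onset {p.onset_force:.3f} au, extension jump {p.delta_L:.2f} A")
```

Output:

```
region 0.020-0.080 au: relaxed conformers ['4C1']
region 0.090-0.120 au: relaxed conformers ['1C4']
minimal transition force: 0.0863 au (7.11 nN), bracket 0.0850-0.0875 au
plateau onset 0.080 au, extension jump 0.45 A
```

Reading: below its threshold the ring deforms but relaxes back to the
⁴C₁ chair (one constant-label region); above it the relaxed structure is
the inverted chair ¹C₄, the bisection search pins the tipping force to
the requested 0.0025 au resolution, and the transition shows up on the
force–extension curve as a plateau — an extension jump at nearly constant
force.  The trajectory of the stretched optimization passes through the
twist-boat equator (θ ≈ 90°) on its way from chair to inverted chair, and
the chain reaches most of its final length *before* the ring flips.
Threshold values on the toy backend are model quantities, not predictions
of the quantum-level forces.

The same protocol runs on full oligomers:

```bash
egostretch build -n 6 -o hexamer.xyz       # synthetic hexamer + topology JSON
egostretch pucker hexamer.xyz              # per-ring (Q, θ, φ) + labels
egostretch scan -n 1 --f-min 0.05 --f-max 0.2 --step 0.01 -o out/
```

## Layout

| module | role |
| --- | --- |
| `egostretch.mol`, `egostretch.io`, `egostretch.units` | structure record, XYZ/PDB readers/writers, unit conversions |
| `egostretch.backends`, `egostretch.toyff` | energy-backend contract, finite-difference check, toy force field |
| `egostretch.engine` | enforced optimization, relaxation, rupture detection, vibrational analysis |
| `egostretch.pucker` | puckering coordinates, canonical conformers, torsion decomposition, length bins |
| `egostretch.protocol` | force-ladder stretch–relax scans, minimal-force bisection, transition labels |
| `egostretch.curves` | force–extension curves, plateaux, history landmarks, structural traces |
| `egostretch.builders` | synthetic rings, monomers, (1→4)-linked oligomers, seeded perturbations |
| `egostretch.cli` | `egostretch build / pucker / scan / curve` |

See `docs/methods.md` for the model, its assumptions, parameter choices
and limitations.
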