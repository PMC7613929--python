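# filageom

Quaternary-structure geometry of actin-like protein filaments, built
around the analyses needed for bacterial cytoskeletal assemblies such as
the cell-division protein FtsA: antiparallel double filaments, their
interfaces and local symmetry, mini-ring geometry, domain motions,
cysteine cross-link design, and the equilibrium binding isotherms that
accompany such structural work.

## Who this is for

Structural biologists and modellers who have atomic coordinates of a
polymer-forming protein (crystal or EM models, PDB/mmCIF) and want
reproducible, scriptable answers to questions usually settled with ad hoc
molecular-graphics sessions:

* Which chain pairs form interfaces, and are they longitudinal
  (head-to-tail, within a protofilament) or lateral (between antiparallel
  protofilaments)?  Which carry local two-fold (C2) symmetry?
* What are the helical parameters (twist, rise, helical radius) of the
  subunit-to-subunit operator, and does it close into a ring — e.g. the
  12–13-subunit FtsA "mini-rings" of ~20 nm diameter?
* How bent is a filament (radius of curvature of the subunit-centroid
  path)?
* How far does a mobile subdomain rotate between conformers (e.g. the
  FtsA IC domain, which swings ~14° between the open and the closed,
  peptide-binding conformation)?
* Which residue pairs are good cysteine cross-linking sites — Cβ–Cβ
  distance compatible with a thiol cross-linker span (BMOE ≈ 8 Å), exploiting
  interface C2 symmetry for single-mutation designs, and screened against
  endogenous cysteines?

## The core geometry and models

**Screw decomposition.** Any proper rigid transform `x → Rx + t` equals a
rotation by a twist θ about a unique axis plus a rise d along it.  For
the operator mapping subunit *i* onto subunit *i+1*, θ and d are the
helical twist and rise; `360/|θ|` is the number of subunits per turn, and
a ring of n subunits closes when `|360 − n·θ|` and `|n·d|` are both small.
The helical radius is the perpendicular distance of the subunit centroid
from the screw axis.

**Local C2.** The chain-to-chain superposition of an interface is the
candidate symmetry operation: the interface has local two-fold symmetry
exactly when that transform is an involution — twist ≈ 180°, rise ≈ 0 —
with a small mapping RMSD.

**Domain orientation and hinges.** Domain orientation is the first
principal axis (unit-mass second-moment eigenvector) of the domain's
main-chain N, CA, C atoms.  A hinge angle between conformers is measured
by superposing on a fixed domain set and reading off the rotation angle
of the residual mobile-domain superposition.

**Curvature.** Subunit centroids are projected onto their principal
plane and a circle is fitted by least squares (algebraic fit refined
geometrically); the radius is reported in nm.

**Binding isotherms.** Two standard equilibrium models are implemented
as evaluators and bounded nonlinear least-squares fits:

* single-site response (SPR): `R_eq(C) = C·R_max/(C + K_d) + B`
* two-step saturation (FP):
  `F([P_T]) = F_0 + F_Lo·[P_T]/(K_D,Lo + [P_T]) + F_Hi·[P_T]/(K_D,Hi + [P_T])`

with concentrations in μM and `K_D,Lo ≤ K_D,Hi` by convention.

A synthetic-data module generates pseudo-protomers on helices, rings,
arcs and antiparallel double filaments with exactly known parameters
(plus seeded Gaussian noise), so every analysis can be validated against
construction-time ground truth.

## Worked example

```python
import numpy as np
from filageom import (synthetic, find_interfaces, classify_interfaces,
                      build_filament_graph, detect_c2,
                      scan_crosslink_pairs, transform_between_subunits)
from filageom.helical import helical_parameters, predict_ring_closure
from filageom.domains import DomainDefinition

protomer = synthetic.make_protomer(120, seed=1)
filament, truth = synthetic.build_double_filament(protomer,
                                                  n_per_protofilament=3)
domains = DomainDefinition({"IA": [(1, 8)], "IC": [(9, 16)],
                            "IIA": [(17, 24)], "IIB": [(25, 30)]})

interfaces = find_interfaces(filament)          # 4.5 A heavy-atom contacts
classes = classify_interfaces(filament, interfaces, domains)
graph = build_filament_graph(interfaces, classes)
print("protofilaments:", graph.protofilaments)
print("double filament:", graph.is_double_filament())

lateral = next(i for i in interfaces
               if classes[i.chain_pair].label == "lateral_i_istar")
c2 = detect_c2(filament, lateral)
print(f"lateral interface {lateral.chain_pair}: local C2 = {c2.has_c2} "
      f"(|twist-180| = {c2.angle_dev_deg:.2g} deg, rise = {c2.rise_abs:.2g} A)")

op, _ = transform_between_subunits(filament, "A0", "A1")
params = helical_parameters(op, filament.chain("A0").centroid())
print(f"longitudinal operator: twist {params.twist_deg:.2f} deg, "
      f"rise {params.rise:.1f} A")

ring = predict_ring_closure(360.0 / 13.0, rise=0.0)
print(f"360/13-deg twist closes a ring of {ring.n_subunits} subunits")

best = scan_crosslink_pairs(filament, graph, max_distance=8.0)[0]
print(f"best cross-link candidate: {best.site1.chain}:{best.site1.seq_id}"
      f"-{best.site2.chain}:{best.site2.seq_id} at "
      f"{best.cbeta_distance:.2f} A ({best.interface_label})")
```

prints

```
protofilaments: [['A0', 'A1', 'A2'], ['B0', 'B1', 'B2']]
double filament: True
lateral interface ('A0', 'B2'): local C2 = True (|twist-180| = 0 deg, rise = 0 A)
longitudinal operator: twist 0.00 deg, rise 48.0 A
360/13-deg twist closes a ring of 13 subunits
best cross-link candidate: B1:5-B0:30 at 4.70 A (longitudinal_tight)
```

The generator built two antiparallel protofilaments of three subunits
with a 48 Å repeat; the pipeline recovers exactly those protofilaments,
labels the lateral interfaces, verifies their exact local C2 symmetry
(deviation 0° / 0 Å), reads the longitudinal operator back off the
coordinates, predicts the 13-subunit ring from the mini-ring twist, and
ranks cross-linkable Cβ–Cβ pairs across the interfaces.

A command-line interface wraps the same pipeline
(`filageom analyze-filament`, `hinge`, `crosslink-scan`, `fit-binding`,
`simulate`); every run writes tab-delimited tables plus a JSON summary
embedding the configuration digest.

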