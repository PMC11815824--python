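# Methods

## Scope and pipeline

`sugarcg` turns atomistic reference trajectories of Glc/Glc and Man/Man
disaccharides into Martini 3 molecule blocks. The stages are independent
and compose through files: enumeration → atom-graph construction → bead
mapping → trajectory projection → term measurement → Boltzmann inversion →
topology emission, with distribution-comparison and aggregation-network
analyses alongside. Running MD itself is out of scope; the package emits
the topologies, coordinates and run-parameter files an engine would
consume.

## Chemistry representation

Monosaccharides are shipped as editable text templates (GLYCAM/Amber atom
names, explicit bond list, ring cycle, hydroxyl positions). Glucose and
mannose share one covalent topology; the C2 stereo descriptor is metadata
only, because bead assignment is purely graph-based — stereochemistry
enters through the trajectory coordinates, never through the mapping.
Condensation removes the donor anomeric hydroxyl (O1/HO1) and the acceptor
hydroxyl hydrogen at the linkage position; the glycosidic oxygen is the
acceptor's retained O_x (for 1→1, its O1). Enumeration yields
4 anomer combinations × 5 positions per sugar (20 for Glc, 40 for
Glc+Man), counting the two mixed-anomer 1,1 entries separately, with a
`dedupe_symmetric` option to collapse them.

## Bead mapping

Each residue maps to three real beads (3–5 heavy atoms plus their
hydrogens, contiguous in the molecular graph) and one massless virtual
site at the center of geometry of the residue's three beads. One
donor-side bead carries the glycosidic bond. The heavy-atom composition is
a rules table keyed by linkage class, with two classes:

- **1→1/2/3/4**: glycosidic bead = donor {C1, C2, O2} + the glycosidic
  oxygen; remaining slots follow the ring order {C3,O3,C4,O4} and
  {C5,O5,C6,O6}; the acceptor uses the same base partition minus O_x.
- **1→6**: glycosidic bead = donor {C1, O5} + acceptor {C6, O6} (the
  glycosidic O is the acceptor O6); the acceptor ring then partitions as
  {C1,O1,O5} / {C2,O2,C3,O3} / {C4,O4,C5}. This is the composition family
  that keeps every bead at 3–5 heavy atoms and contiguous once C6/O6
  migrate into the junction bead — the constraint that drove the choice.

Assignment is deterministic (rules application, ring-order slots,
hydrogens riding their heavy atom) and strictly validated: any unassigned
atom, split (non-contiguous) bead, out-of-range heavy count, or ring not
spanned by its residue's three beads raises `MappingError` naming the
atoms, directing the user to the manual mapping-file path. The manual
dialect is one bead per line (`<residue> <name> <type> <atoms…>`, foreign
atoms as `res:name`, `VS` lines for virtual sites, `#` comments) and
round-trips through the writer to canonical form.

Bead types default to SP4r/SP1r/SP4r per residue slot, SN6 for the
glycosidic bead, SN6r for 1→6 mannose junctions; the virtual-site label
defaults to TC4 (a small apolar bead; the site is massless so the label
only selects nonbonded behaviour) and is configurable, as is the whole
table.

## Projection and measurement

Beads sit at the unweighted mean of their atoms' positions (center of
geometry: hydrogens count equally; no mass weighting). Virtual sites are
centroids of their three beads. Before intramolecular measurement the
molecule is made whole by minimum-image unwrapping about its first atom,
exact while the molecular radius is below half the box edge. Distances are
Euclidean norms (nm); angles come from the arccos of normalized dot
products; dihedrals are signed via the atan2 convention, positive
clockwise looking down the central bond, wrapped to (−180°, 180°].
Degenerate geometries (zero-length vectors) are excluded and logged.
Projection is translation/rotation-equivariant to better than 1e-9 nm
(tested numerically).

Connectivity per disaccharide: ring triangles give 3 distance terms per
residue (bond0–2 acceptor, bond4–6 donor); the inter-monomer term (bond3)
joins the glycosidic bead to the unique bead of the other residue sharing
a covalent bond with it; angles are {x1,x2}–a–b and a–b–{y1,y2} where a,b
are the inter-bonded beads and x,y their ring partners; the dihedral is
x1–a–b–y1 with the lowest-index partner on each side.

## Parameter fitting

Equilibrium values are sample means; force constants follow the
equipartition inversion k = k_B·T / Var with k_B = 0.0083145 kJ mol⁻¹ K⁻¹
(k_B·T = 2.4944 kJ mol⁻¹ at the default 300 K). Conventions and defaults:

- **Bonds** (nm): k in kJ mol⁻¹ nm⁻². A Gaussian-overlap check (data
  histogram vs fitted normal, threshold 0.8, configurable/disableable)
  rejects multimodal bond distributions. Zero-variance or ultra-stiff
  fits (k > 50,000 kJ mol⁻¹ nm⁻², a numerical-stability cap) convert to
  constraints, logged.
- **Angles**: inverted in plain angle space (radians); the sin θ Jacobian
  correction is available behind a flag but off by default — for CG
  junction angles far from 0/180° the correction is small and debatable.
  Multimodality is flagged in diagnostics but never blocks emission.
- **Dihedral**: one proper periodic term, multiplicity 1, phase at the
  circular mean, k from the variance of wrapped deviations, so
  distributions straddling ±180° fit without artifacts. Multi-term or
  tabulated dihedral fits are out of scope.
- **Classification**: the six ring terms become constraints at their mean
  lengths; the inter-monomer term always remains a harmonic bond (it is a
  genuinely flexible degree of freedom, sd ≈ 0.02 nm in the reference
  data), and the code refuses to emit it as a constraint.

## Topology and run files

The GROMACS molecule block uses `nrexcl 1`, 54 amu for all real (small)
beads, massless virtual sites via `[virtual_sitesn]` funct 2 (center of
geometry) with explicit exclusions to their three constructing beads.
Angles are harmonic funct 1 by default (funct 2 switchable); the dihedral
is funct 1 with phase φ₀ − 180° so the potential minimum sits at the
fitted equilibrium value. Numeric fields are canonically rounded at
construction (lengths 1e-5 nm, angles/force constants 1e-3), making
write→read round trips exact. Emitted files also parse under MDAnalysis's
independent ITP reader, which is used as an oracle in the tests; masses
and function types are conventions, so compatibility with externally
published models is "parses and runs", not byte equality.

Run-protocol files cover the simple scheme (500 steepest-descent steps;
100 ns NVT at 20 fs; 1 μs NPT at 300 K/1 bar) and the soft scheme
(minimization and 25 ns at 10 fs with flexible ring bonds, then 50 ns at
20 fs flexible, then 50 ns at 20 fs with ring constraints), all with
reaction-field electrostatics (ε_r = 15) and 1.1 nm cutoffs.

## Comparison statistics

Histogram overlap is Σ min over shared bins of probability mass;
100 equal-width bins by default (configurable — the statistic is mildly
bin-dependent). Full overlap bins over the union of supports; reference
overlap bins over the reference's support and normalizes the new data by
its total count, giving the fraction of the reference that was sampled.
The percentage difference of means is 100·(AA − CG)/CG at two decimals;
the CG denominator is the convention consistent with all the printed
worked examples this implementation reproduces (0.49/0.48 → 2.08%,
0.44/0.43 → 2.33%).

## Composition and aggregation

The disaccharide-to-water ratio for a target concentration uses molecular
weights only, approximating solution volume by water mass at 1 g cm⁻³
(defaults: water 18.015, trehalose 342.30 g mol⁻¹). Inverting 50 g/L for
20 disaccharides gives 7600 waters; the printed reference pair
(7609 waters, 20 solutes) evaluates to 49.94 g/L, i.e. 50 at integer
precision — the calculator anchors to that behaviour and the ~9-water
inversion residual is expected. The 4:1 water mapping is an integer floor
(7609 → 1902 beads).

Aggregation networks use the orthorhombic minimum-image convention
(triclinic boxes are rejected explicitly); an edge survives when the
minimum bead-bead distance is ≤ 0.47 nm (inclusive cutoff). Connected
components give per-frame size multisets whose sum always equals the
molecule count; distributions pool frames at a fixed stride over the final
window of one or more replicas.

## Synthetic fixtures

The generator emulates a mapped reference trajectory: ring triangles are
built at target edge lengths (rigid by default), the junction bead is
placed by trilateration from the sampled inter-monomer distance and two
junction angles, the far ring closes via a distance/angle/dihedral chain
step and a second trilateration, and every bead is decorated with its
mapped atoms at fixed zero-mean offsets, so projection inverts decoration
exactly (< 1e-9 nm). A per-frame random rigid move exercises equivariance
and the periodic-boundary path. Default targets: ring edges
0.32/0.36/0.45 and 0.33/0.36/0.47 nm, inter-monomer bond 0.48 ± 0.02 nm,
angles (120, 100, 110, 130)° ± 5°, dihedral 60° ± 15°, in a 6.145 nm box
at 100 ps frame spacing — values representative of the trehalose-scale
geometry this pipeline targets. Rare Gaussian-tail frames (~10⁻⁵ at
n = 10⁵) that overshoot the feasible closure cone are clamped to the
boundary; a violation rate above 1% means the targets themselves are
infeasible and raises.

Because sampled terms are independent Gaussians — exactly the fit model's
assumption — recovery of means (within 1%) and force constants (within
5%) by the full measure→fit chain validates the pipeline's bookkeeping and
the inversion identity, not the physical realism of any force field: the
fixtures contain no water, no energetic coupling between terms, and no
multimodality unless planted. Conclusions about real atomistic data rest
on the same code paths but not on these numbers.

## Problem sizes in the shipped suites

The shared test fixture uses 2×10⁴ frames; the round-trip recovery
property runs at 10⁵ frames; per-disaccharide structural checks across all
40 species use 300–400 frames each; the acceptance script uses 2000 frames
for the topology pipeline and 10⁵ draws for the bond-fit recovery. These
sizes give sampling errors comfortably below the stated tolerances
(e.g. relative variance error √(2/n) ≈ 0.45% at n = 10⁵).

## Known limitations

- Bead compositions for linkages beyond the shipped Glc/Man templates are
  untested; heterodimers are structurally supported but no templates ship.
- The glycosidic-bead ownership for 1→6 linkages (donor side, pulling in
  the acceptor C6/O6 group) is one defensible reading of the mapping
  scheme; the rules table makes it overridable per linkage.
- Single-Gaussian inversion absorbs small secondary conformational
  populations; the diagnostics flag them but the emitted potential is
  unimodal.
- The aggregation module analyses supplied trajectories; it does not
  generate dynamics, so kinetics (cluster lifetimes) are out of scope.
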