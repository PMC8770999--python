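# Methods

`mandifem` is a desk-scale, fully scripted re-creation of a common clinical
biomechanics experiment: compare single-plate (Champy) against biplanar
miniplate fixation of a mandibular angle fracture under physiological
chewing loads, using static linear-elastic finite elements with frictional
contact across the fracture gap. Everything below is computed by the
package itself; no external data are required.

## The model

**Geometry.** Real studies of this question use CT-derived,
subject-specific mandible meshes. Here the mandible is idealized as a
rectangular cross-section (8 x 14 mm, 2 mm cortical shell over a trabecular
core) swept along a U-shaped centerline: two straight corpus legs (60 mm)
joined by a semicircular dental arch (radius 22 mm), with block rami rising
to 45 mm at the posterior ends and tooth elements along the alveolar
margin. Proportions follow the adult macaque jaw, the animal whose muscle
physiology the loading model is scaled to: in particular the ramus is given
a substantial anteroposterior footprint (twice the corpus height, about
30 mm), because the lever arm between the masticatory muscle insertions and
the condylar constraint is what drives load across the angle region — a
too-shallow ramus funnels muscle force straight into the condyle and
starves the fracture of load. The solid is meshed as a structured hex
lattice split six tetrahedra per hex (Freudenthal), which keeps every
region interface conforming (so bone-bone and bone-teeth "ties" are exact
shared nodes) and makes mesh generation fully deterministic. The
decomposition is mirrored on the right half so that the tet mesh — not just
the node lattice — is mirror-symmetric; left-chew and right-chew solutions
on the intact jaw mirror each other to solver precision, a property the
tests exploit.

**Fracture.** A planar cut at the left corpus-ramus junction (the angle) is
realized by duplicating the interface nodes and rigidly offsetting the two
faces by the 0.2 mm gap width along the plane normal. This produces an
exact registry of matched node pairs spanning the gap — the basis of the
interfragmentary displacement statistic — rather than an approximate
surface-to-surface pairing. The default cut is transverse to the sweep
path (obliquity configurable); a transverse cut gives perfectly planar,
congruent faces.

**Hardware.** Locking miniplates (26.1 x 2.5 x 1.0 mm, titanium,
E = 105 GPa, nu = 0.36) are meshed as thin tetrahedral strips on the
lateral surface: the Champy plate near the superior border (a surrogate
for the external oblique ridge) and, for biplanar fixation, a second plate
near the inferior border. Screws carry no geometry: each screw site pairs
the plate nodes within a screw radius (2.1 mm) of the hole with their
nearest cortical surface nodes, and the solver enforces equal displacement
on each pair. This mirrors how locking (threaded) hardware behaves — screw
rigidly bound to both plate and bone — and avoids thread-scale meshing.
Plate-bone surface contact away from the screws is not modeled; load
transfer is through the screw ties and, when the gap closes, the fracture
faces.

**Materials.** Isotropic, homogeneous linear elasticity everywhere:
teeth E = 24.5 GPa, trabecular bone E = 10 GPa, titanium as above (all
nu = 0.3 except titanium 0.36). Cortical bone, which in life is
heterogeneous and orthotropic, is deliberately simplified to a single
configurable isotropic modulus (default E = 17 GPa, nu = 0.3, a standard
mandibular cortical value); mapping CT-calibrated orthotropy is out of
scope.

**Muscle loading.** Each of the ten jaw adductors (anterior/posterior
temporalis, superficial/deep masseter, medial pterygoid, per side) applies
a force of magnitude

    |F| = EMG x PCSA x 30 N/cm^2

split equally across its insertion patch and directed from the insertion
centroid toward a cranium-side origin anchor (there is no cranium mesh;
only the origin centroid matters for direction). Defaults:

| muscle | PCSA (cm^2) | insertion | origin anchor |
|---|---|---|---|
| anterior temporalis | 5.5 | anterior ramus face, top (coronoid) | above coronoid |
| posterior temporalis | 3.5 | superior ramus surface behind coronoid | posterosuperior |
| superficial masseter | 5.0 | lateral ramus surface, lower half | zygomatic arch, anterolateral |
| deep masseter | 2.5 | lateral ramus surface, upper half | zygomatic arch, lateral |
| medial pterygoid | 3.5 | medial ramus surface, lower half | pterygoid plates, near midline |

PCSAs are at the scale reported for adult macaques (total ~20 cm^2 per
side, working-side resultant ~600 N); the lateral pull of the masseters
(zygomatic origins flare laterally) against the medial pull of the
pterygoid reproduces the transverse "wishboning" load that dominates the
balancing-side corpus during chewing. The EMG drive is 1.0 on the working
(chewing) side and 0.6 on the balancing side for all muscles,
configurable per muscle and side.

**Boundary conditions.** Unilateral chewing: the working-side condyle is
fixed in all three directions; the balancing-side condyle is fixed
anteroposteriorly and superoinferiorly but left free mediolaterally (so the
corpus can wishbone); the occlusal nodes of the working-side premolars and
first molar are fixed in all directions, making bite force an output
reaction rather than an input. Forces landing on constrained DOFs are
zeroed with a warning.

**Solver.** Constant-strain tetrahedra, assembled sparse and symmetric.
Screw ties are condensed by union-find elimination (chains and shared
anchors resolve to one representative); Dirichlet conditions are applied by
row/column elimination so reactions are exact. The fracture interface is a
small-sliding node-pair penalty contact: a pair is active when its normal
gap (0.2 mm undeformed) closes to zero; active pairs receive a
compression-only normal spring (default stiffness 100x the mean adjacent
element diagonal — penetration stays far below mesh scale, conditioning
survives) and a tangential spring whose per-pair secant stiffness is
reduced to mu*f_n/|s_t| whenever the stick force would exceed the Coulomb
bound, so converged tangential forces sit exactly on or inside the friction
cone (mu = 0.3 by default). The outer loop iterates active set, stick/slip
state and displacement to a relative tolerance of 1e-8 with a direct sparse
factorization inside; non-convergence is reported, never silently ignored.
A single static load step is solved (no stick-slip history), consistent
with a static chewing snapshot.

## Outcome statistics

* **Principal strain fields.** Per-element constant strains,
  volume-weighted nodal averaging (tensors averaged before
  eigen-decomposition), e1/e3 in microstrain. Von Mises stress through each
  region's elasticity tensor.
* **Trimmed extremes.** Regional "largest" strains discard the top and
  bottom 5% of nodal values (symmetric percentile exclusion) to suppress
  interface artifacts; a two-standard-deviation exclusion rule is available
  via `method="sd"`. The two rules are numerically different; percentile is
  the default.
* **Interfragmentary displacement (IFD).** Per pair, the percentage change
  of the deformed pair distance against the undeformed 0.2 mm (negative =
  compression, positive = opening). The headline value is the mode on a
  1%-wide histogram (ties to the lowest bin); the mean is always reported
  alongside, since "average (mode)" summaries of a continuous distribution
  are estimator-sensitive.
* **Sectional moment profiles.** At stations along the corpus, a free-body
  cut perpendicular to the sweep path: because element internal nodal
  forces are self-equilibrated, the transmitted force/moment equals the sum
  of external + reaction + contact forces over the nodes of one side,
  with moments about the section centroid in local axes (X mediolateral =
  sagittal bending, Y path tangent = AP twist, Z vertical = transverse
  bending), reported in N*m. Tie forces crossing a cut between a plate node
  and its bone anchor are neglected (the pair is coincident to within a
  couple of millimetres, so the unaccounted moment is at discretization
  level).
* **Strain-difference maps.** Each bone node of the healthy control is
  matched to the nearest treatment bone node in undeformed coordinates
  (plates and plate-side screw nodes excluded); the map is geometric, so
  node renumbering cannot change it.

## The study the pipeline runs

Six arms from one bone mesh: {healthy, Champy, biplanar} x {chew left =
ipsilateral to the left-side fracture, chew right = contralateral}, then
four difference maps against the same-chew control, and the comparison
tables. The default mesh is ~23k tets (~17k DOF); the whole study runs in
well under a minute on one core. A friction-sensitivity sweep
(mu = 0.1..0.5) is one subcommand.

## What the synthetic model does and does not show

The generator emulates the *structure* of the real experiment — two
condyles, a dental arch, an angle region, physiological muscle vectors,
the exact hardware dimensions — not an individual's anatomy. Consequences
observed with the defaults:

* The qualitative orderings that make the clinical argument reproduce:
  Champy shows larger |mode IFD| and larger plate and bone-implant-interface
  strains than biplanar on both chew sides; contralateral chewing loads the
  fracture more than ipsilateral within each technique (by |mode IFD| and
  by difference-map departure from the healthy control); the biplanar
  global strain field stays closest to healthy, especially contralaterally;
  sagittal/transverse moments at the angle are larger contralaterally.
* Absolute magnitudes are smaller than in subject-specific models: the
  idealized solid-section jaw is stiffer than a real one, so peak gap
  closure reaches only ~25-50% and the fracture faces never actually touch
  under the default loads. One known consequence: during *ipsilateral*
  chewing under Champy fixation the axial compression that a real,
  fully-closed fracture would carry across the bone faces instead crosses
  the screw ties, so the interface trimmed e1 comes out slightly (~9%)
  higher ipsilaterally than contralaterally — the one headline ordering the
  desk-scale conditions do not reproduce. Because contact stays open, the
  friction coefficient has no effect on the default study (the sweep
  subcommand shows this flatness; the contact unit problems exercise the
  friction model properly).
* The periodontal ligament, orthotropic cortical bone, thread mechanics
  and non-locking (friction-slip) screws are not modeled.

## Numerical choices and degenerate inputs

Meshes with inverted elements, cortical shells too thick for the
discretization, fracture planes that miss the angle region, gaps wider
than the local element size, plates with unanchored screw sites, empty
trim inputs and non-converged solutions are all rejected with diagnostics
naming the offending quantity. Determinism: identical spec and seed give
byte-identical meshes and byte-identical CSV outputs; the seed is recorded
in the config hash stamped on every output (the default generator is fully
deterministic, so the seed exists for provenance and future stochastic
variants rather than for the current geometry).
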