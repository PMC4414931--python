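# Methods

## Model

`prank` treats pocket prioritization as a point-classification problem.
A candidate pocket is represented by its *inner points*: solvent-accessible
surface points within a short belt of the pocket's heavy atoms. Each point
is described only by its local chemical neighborhood, classified by a
random forest into ligandable / non-ligandable, and the pocket score is the
cumulative sum of squared positive-class probabilities. The method assumes
that ligand binding is decided by local surface chemistry and geometry —
no whole-pocket descriptors (volume, depth, global shape) enter the model —
and that an upstream detection tool has already delimited the candidate
pockets; re-ranking is deliberately unable to create, merge or reshape
pockets, so total coverage of the upstream tool is a hard ceiling.

## Surface construction

The accessible surface is approximated by icosphere sampling: for every
heavy atom, the vertices of a subdivided icosahedron (level k gives
10·4ᵏ + 2 vertices; level 2 → 162) are scaled to r_vdw + probe and vertices
strictly inside another atom's expanded sphere are dropped. Probe radius
1.6 Å and tessellation level 2 are the defaults. This yields evenly spaced
points on the union-of-spheres (solvent-accessible) surface; re-entrant
probe-rolling patches of a true molecular surface are not reconstructed,
and only a single surface layer is used. Since the classifier only needs
evenly spaced near-surface points with local features, the simpler surface
is adequate and keeps the construction exactly reproducible.

An atom is *solvent-exposed* iff at least one of its vertices survives
occlusion. The occlusion test uses a 1e-6 Å tolerance so that coincident
spheres behave deterministically. Van der Waals radii come from a bundled
table (C 1.70, N 1.55, O 1.52, S 1.80, P 1.80 Å); unknown elements fall
back to 1.70 Å with a logged warning, never an error.

## Parameters

| parameter | default | meaning |
|---|---|---|
| probe radius | 1.6 Å | sphere expansion for surface sampling |
| tessellation level | 2 | icosphere subdivision depth (162 vertices/atom) |
| inner belt | 4.0 Å (inclusive) | max distance point → nearest pocket atom |
| label threshold | 2.5 Å (inclusive) | max distance point → ligand atom for a positive label |
| neighborhood radius | 8 Å (inclusive) | AFV aggregation range, weight w(d) = 1 − d/8 |
| protrusion radius | 10 Å | sphere for the local-convexity index |
| protrusion cap | 15 | upper bound (empty-sphere guard) |
| min ligand atoms | 5 | heavy-atom threshold for a relevant ligand |
| trees | 100 | forest size (√p features per split, unlimited depth) |

Boundary inclusivity is closed (≤) throughout: the belt, the label
threshold, the 8 Å neighborhood and the D_CA/D_CC detection thresholds.
Ties in the final ordering keep the upstream tool's original order (stable
sort); a pocket with zero inner points keeps score 0 and is never dropped.

## Features

The exact feature list is a replaceable data file, not code. The bundled
default schema is:

* residue level (inherited by every atom of the residue): Kyte–Doolittle
  hydropathy plus indicator columns for aliphatic, aromatic, polar,
  positively and negatively charged classes;
* atomic level: a one-hot pharmacophore type per (residue, atom-name) pair
  (hydrophobic, aromatic, donor, acceptor, donor+acceptor, positive,
  negative, none) and a numeric ligand-binding propensity column;
* point level: counts of donor-typed and acceptor-typed neighborhood atoms,
  mean B-factor of the neighborhood (0 when empty; synthetic structures
  without measured B-factors carry their generator-assigned values), and a
  protrusion index.

The hydropathy column is the published Kyte–Doolittle scale; the atomic
propensity column and the per-residue PLB propensities are **synthetic
stand-in values** with the right structure and plausible ordering, intended
to be replaced by users who have the original published tables. The schema
version is a content hash of the table files, so datasets and models built
from different tables refuse to mix.

The protrusion index is concretized as the CX-style occupancy ratio
(V_sphere − N·v_atom)/(N·v_atom) with v_atom = 20.1 Å³ and R = 10 Å,
capped at 15: convex, exposed locales score high, concave or buried ones
low. Aggregation sums AFVs over heavy *solvent-exposed* protein atoms
within 8 Å (all protein atoms, not only pocket members). Because exposure
couples atoms over roughly two expanded radii and the protrusion sphere is
10 Å, the effective locality radius of an IFV is about 15 Å; perturbations
farther away leave the vector bit-identical.

## Classifier

A scikit-learn random forest (100 trees, √p candidate features per split,
unlimited depth, fixed seed) is trained on the raw point dataset. The class
ratio is heavily imbalanced (roughly 15–20 negatives per positive on both
realistic corpora and the synthetic benchmark) and is deliberately left
untouched: rebalancing (over/under-sampling, cost weighting) degrades
generalization for this task. The 0.5 threshold is used only to report
precision/recall/MCC; the pocket score consumes raw probabilities, so
points "predicted negative" still contribute. Zero-denominator metric cases
return 0 with an explicit `degenerate` flag rather than raising, because
MCC's denominator can vanish on small folds.

Cross-validation is grouped by protein: all points of one protein stay on
one side of every train/test split. Point-level folds would leak spatially
near-duplicate points between train and test and overstate performance.

## Synthetic benchmark

The fixture generator emulates what the method needs from real data, not
real proteins. A toy protein is two concentric jittered shells of one-atom
residues (~2.9 Å spacing, radius 16 and 13 Å) forming a closed pseudo-
globule; one spherical-cap crater (aperture 0.55 rad, depth 4.5 Å) is the
planted binding site, holding a ring ligand 3.2 Å above the crater floor.
The crater lining differs from the background both chemically (residue/atom
pairs drawn from a donor/acceptor/aromatic-rich set; B-factors shifted by
`effect_size` × 5) and geometrically (concavity → low protrusion index).
Decoy pockets are convex surface patches whose member centroid is ≥ 10 Å
from every ligand atom, so by construction the planted pocket passes the
4 Å D_CA criterion and decoys cannot; original ranks are a seeded random
permutation and volumes are drawn iid for all pockets, so neither the
input order nor the volume baseline encodes the answer. B-factor and
coordinate noise distributions are fixed constants of the generator
(N(20, 5²) and N(0, 0.3²) respectively).

What passing tests on these fixtures shows: the pipeline recovers a planted
local-chemistry signal end to end, the bookkeeping (selection, labeling,
scoring, evaluation) is correct, and re-ranking beats size-based baselines
when local chemistry carries information. What it does not show: performance
on real proteins, where feature tables, surface geometry and the
negative-label noise (undiscovered binding sites labeled negative) are far
harsher. The defaults used by the test suite and the acceptance script —
60 proteins, 4 decoys each, effect size 1.5, train/test split 30/30 — were
chosen as a corpus small enough to run in about a minute on one CPU yet
large enough that success rates over 30 test proteins are meaningful.

## Numerical and design choices

* Point containers are array-backed (`SurfacePoints`, `InnerPoints` hold
  coordinate matrices), the idiomatic vectorized equivalent of per-point
  object lists; KD-trees handle all neighbor queries.
* The pocket score uses `math.fsum`, so appending zero-probability points
  changes the score by exactly nothing (the oversized-pocket robustness
  property holds exactly, not to rounding).
* A surface point adjacent to several pockets is duplicated per pocket, so
  pocket scores are independent of each other.
* Alternate locations resolve to the highest-occupancy conformer (ties →
  first in file order); only model 1 of multi-model PDBs is used;
  coordinates are taken verbatim (no re-centering).
* The relevant-ligand filter (HETATM group, not on the water/ion/
  cryoprotectant ignore list, ≥ 5 heavy atoms) is a documented default and
  fully configurable, because the ligand-centric evaluation denominator
  depends on it.
* Per-protein rescoring is embarrassingly parallel; the threaded path is
  contractually bit-identical to the serial one and covered by a test.
* Fpocket parsing is pinned to the version-1-style `pockets/pocketN_atm.pdb`
  layout; any other tool connects through the generic pocket CSV.

## Known limitations

* The accessible-surface approximation has no re-entrant patches; point
  counts differ from probe-rolling implementations at the same nominal
  parameters.
* Bundled atomic-propensity, pharmacophore and PLB tables are stand-ins;
  absolute classifier metrics on real data will depend on substituting
  measured tables.
* The PLB baseline is concretized as the mean propensity over distinct
  lining residues; published variants differ in normalization.
* mmCIF input and ConCavity's native grid output are unsupported (generic
  CSV is the bridge).
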