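# prank — re-ranking predicted ligand-binding pockets

Pocket detection tools (Fpocket, ConCavity, …) find candidate ligand-binding
sites on a protein structure and emit them as an ordered list, but their
ranking functions are simple and the true binding site often sits far down
the list. `prank` is a post-processing re-ranker: it never adds, removes or
reshapes pockets — it only reorders them so that true binding sites come
first. It is aimed at structural bioinformaticians who run pocket detection
upstream of docking or virtual screening and want a better prioritization of
the candidates.

## Method

1. **Surface sampling.** Evenly spaced points are sampled on the
   solvent-accessible surface: for every heavy atom, the vertices of a
   level-2 subdivided icosahedron are placed on the sphere of radius
   r_vdw + 1.6 Å and vertices buried inside any other atom's expanded
   sphere are discarded.
2. **Inner points.** For each candidate pocket, the surface points within
   4 Å of its heavy member atoms are retained — a thin belt where
   protein–ligand contacts actually form. These *inner pocket points* are
   the classification units.
3. **Features.** Each relevant atom gets an atom feature vector (AFV):
   residue-level features (Kyte–Doolittle hydropathy, physico-chemical
   class) plus atomic-level features (pharmacophore type, binding
   propensity). The feature vector of an inner point *P* aggregates the
   AFVs of the heavy solvent-exposed atoms within 8 Å,

       IFV(P) = Σᵢ AFV(Aᵢ) · w(dist(P, Aᵢ)) ‖ FV(P),   w(d) = 1 − d/8,

   where FV(P) holds point-specific features (H-bond donor/acceptor counts,
   mean B-factor, protrusion index). All features are strictly local.
4. **Classification.** A random forest, trained on points labeled positive
   when they lie within 2.5 Å of a ligand atom (no class rebalancing),
   returns a ligandability probability P₁ for every point.
5. **Scoring.** Each pocket gets the cumulative score

       PScore = Σᵢ P₁(Vᵢ)²

   over its inner points, and pockets are reordered by decreasing PScore.

The package also implements the ligand-centric evaluation protocol
(D_CA / D_CC detection criteria with inclusive thresholds, Top-n and
Top-(n+2) cutoffs where n is the protein's number of relevant ligands,
total coverage) and two baseline rankers for comparison: the
amino-acid-composition PLB index and ranking by pocket volume.

Because realistic evaluation corpora require large external structure sets,
the package ships a first-class synthetic fixture generator: toy globular
proteins with one planted concave binding site (chemically and geometrically
distinct, with controllable effect size), a ring ligand, and convex decoy
pockets — everything needed to train, rescore and evaluate end to end with
no downloads.

## Worked example

```bash
prank synth --out bench --seed 4 --n-proteins 6        # synthetic corpus
prank train --corpus bench/manifest.csv --out model.joblib
prank rescore --structure bench/structures/p005.pdb \
              --pockets bench/pocket_lists/p005_pockets.csv \
              --model model.joblib --out ranked.csv
```

`ranked.csv` then contains:

```
pocket_id,original_rank,new_rank,pscore,n_inner_points
true,3,1,58.362899999999996,280
decoy1,2,2,0.0004,243
decoy2,1,3,0.0,242
decoy3,4,4,0.0,230
decoy4,5,5,0.0,233
```

The planted binding site entered at rank 3 of 5 and is promoted to rank 1:
its 280 inner points include a cluster of high-P₁ (ligandable) points whose
squared probabilities sum to a PScore of 58.4, while the decoy pockets —
similar in point count — collect essentially zero. `prank eval` on the same
corpus reports `top_n = 1.0`: every planted site is ranked first.

The same pipeline is available as library calls
(`prank.rescore_pockets`, `prank.build_point_dataset`, `prank.train`,
`prank.success_rates`); Fpocket output directories are parsed with
`prank.parse_fpocket_output`, anything else via the generic pocket CSV
(`pocket_id,rank,score,volume,atom_serials[,cx,cy,cz]`, serials ';'-joined).

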