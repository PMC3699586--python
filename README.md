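# dockassess

Assessment toolkit for ligand docking into ensembles of comparative
(homology) receptor models, built around the kind of benchmark used for
G-protein coupled receptors: given a family of experimentally solved
receptor structures sharing a multiple alignment and a ligand-binding
pocket, how efficiently does a docking protocol sample near-native
ligand binding modes, and how much do knowledge-based filters and
experimental constraints improve that efficiency?

It is written for structural bioinformaticians running docking
benchmarks: everything is exercisable on synthetic receptor/ligand/pose
ensembles with recorded ground truth, so every statistic the package
reports can be validated against an independent oracle.

## What it computes

**Uniform sampling efficiency (USE2.0).**  The probability that placing
a ligand conformer ensemble uniformly at random — conformer chosen
uniformly from the N-member ensemble, orientation Haar-uniform,
centroid uniform in the docking sphere of radius R = 5.0 Å — lands
within 2.0 Å heavy-atom RMSD of the experimental binding mode, with no
occluding protein.  Each conformer *i* is least-squares aligned to the
reference and rotated about its centroid through a z–y–z Euler grid
(φ, θ, ψ) with M = 40 spacings per axis; uniformity over orientations
requires a sin θ solid-angle weight (the circumference of the circle θ
draws on the sphere).  For centroid-aligned coordinates the RMSD after
translating by **t** obeys RMSD² = RMSD₀² + |t|² exactly, so each
rotation contributes the translation-ball volume fraction

    USE2.0 = (1/N) Σᵢ Σ_{φθψ} w(θ) · (d(i,φ,θ,ψ) / R)³,
    d = √(2.0² − RMSD₀²)  when RMSD₀ < 2.0, else 0.

A Monte-Carlo estimator with the same placement model is the built-in
independent check.  The *fold decrease in sampling efficiency* is
USE2.0(bioactive conformation) / USE2.0(conformer ensemble); dividing a
docking run's observed efficiency by USE2.0 gives its fold improvement
over random sampling.

**Knowledge-based pocket filter.**  Pocket positions are alignment
columns whose Cα lies within 4.0 Å of the bound ligand in at least one
family structure; each position's cutoff is the maximum Cα–Cα distance
between any two family structures at that column.  A model passes only
if every pocket Cα is within the cutoff of the equivalent Cα in at
least one family member other than the model's own target structure
(self-exclusion avoids circular bias); the filtered ensemble is capped
to the 100 lowest-energy models.  Pocket *collapse* profiles report,
per position, the change in distance from the residue's Cβ (Cα for
glycine) to the closest ligand atom, positive meaning toward the ligand.

**Pose/model evaluation.**  Complete-linkage agglomerative clustering
on pairwise RMSD (2.0 Å on ligand heavy atoms for poses, 3.0 Å on Cα
for models after reducing to the 10% best-scored), lowest-energy
cluster representatives, top-k ranking by cluster size; ligand–receptor
contacts at 4.0 Å with contact coverage (correct/|reference|) and
accuracy (correct/|model|); region-restricted Cα RMSD.

**Enrichment.**  Resampled curves of mean sampling efficiency versus
the number n of known ligand contacts imposed (10,000 random n-subsets
per n, poses retained when they contain all drawn contacts), efficiency
after energy-cutoff selection of the best-scored fraction, and explicit
geometric (e.g. salt-bridge distance) constraints with their fold
improvement.

## Worked example

```python
from dockassess import (FamilyConfig, gen_receptor_family, gen_model_ensemble,
                        gen_conformers, build_pocket, apply_pocket_filter,
                        compute_use, fold_decrease)
from dockassess.use_metric import UseParams

family = gen_receptor_family(FamilyConfig(seed=0))     # 5 structures, 1.0 Å spread
pocket = build_pocket(family.members, family.alignment)
print("pocket columns:", sorted(pocket.columns))

models, truth = gen_model_ensemble(family, "S0", n_good=100, sigma_good=0.5,
                                   n_bad=400, sigma_bad=4.0, seed=1)
report = apply_pocket_filter(models, family.members, "S0", pocket, family.alignment)
print(f"models passing filter: {int(report['passed'].sum())}/{len(report)}")

native = family.members[0].ligand_coords()
conformers, _ = gen_conformers(native, n=50, scale=0.3, seed=2)
params = UseParams(threshold=2.0, radius=5.0, spacings=40)
ens = compute_use(conformers, conformers.reference, params)
bio = compute_use(native[None], native, params)
print(f"USE2.0 bioactive: {bio.use:.3e}   ensemble: {ens.use:.3e}   "
      f"fold decrease: {fold_decrease(bio, ens):.2f}")
```

prints

```
pocket columns: [1, 7, 12, 18, 23, 29, 34, 40]
models passing filter: 98/500
USE2.0 bioactive: 5.852e-03   ensemble: 5.472e-03   fold decrease: 1.07
```

The filter recovers the designed 8-column pocket exactly and accepts 98
of the 100 mildly distorted models while rejecting all 400 heavily
distorted ones.  The 8-atom rigid ligand's USE2.0 of ~6·10⁻³ means
roughly 1 in 170 uniform random placements lands within 2.0 Å; the
conformer ensemble at this perturbation scale dilutes that only
slightly (fold decrease 1.07 — small, rigid ligands lose little, while
flexible ligands lose much more).

A full assessment (filter → clustering → USE2.0 → pose evaluation →
enrichment) runs from one config:

```sh
dockassess run --config run.yaml       # writes TSVs + manifest.json
dockassess simulate family --seed 3 --out fam/
dockassess use2 --conformers conf.pdb --mc 100000 --seed 1
```

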