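# Methods

## The assessment problem

Docking benchmarks report "sampling efficiency": the fraction of docked
poses within a heavy-atom RMSD threshold (2.0 Å here) of the
experimental binding mode.  That number is incomparable across targets
because ligands differ in size, shape and flexibility.  The toolkit's
normalizer, USE2.0, is the efficiency a *blind* protocol would achieve:
conformer drawn uniformly from the ensemble, orientation Haar-uniform,
centroid uniform in the docking sphere (radius R = 5.0 Å), no receptor.
A docking run's efficiency divided by USE2.0 is its fold improvement
over random; USE2.0 of the bioactive conformation divided by USE2.0 of
the conformer ensemble is the fold decrease paid for ligand
flexibility.

## USE2.0: model and numerics

For each conformer the computation is exact up to the rotation
quadrature:

1. Kabsch-align the conformer to the reference (bioactive) coordinates.
   Least-squares superposition matches centroids, so the aligned
   conformer and the reference share a centroid.
2. Rotate about that centroid through an intrinsic z–y–z Euler grid
   (φ, θ, ψ), φ and ψ on M uniform points over [0, 2π), θ on M uniform
   points over [0, π], M = 40 by default.  Haar measure in these
   coordinates is dφ sinθ dθ dψ / 8π², so each triple carries a sin θ
   weight, normalized to sum to one.  The θ endpoints get half
   (trapezoidal) weight; sin 0 = sin π = 0 makes this numerically
   immaterial but fixes a deterministic rule.  M = 1 degenerates to the
   identity rotation with weight 1.
3. For centroid-aligned blocks, translating by **t** gives
   RMSD² = RMSD₀² + |t|² exactly (the cross term vanishes because the
   paired differences sum to zero).  The placements within threshold τ
   therefore form a ball of radius d = √(τ² − RMSD₀²), and the
   rotation's contribution to the probability is (d/R)³.

The per-conformer values are averaged unweighted (each conformer is
equally likely under random conformer selection), giving
USE2.0 ≤ (τ/R)³ = 0.064 always — attained exactly by a single-atom
ligand, which is the closed-form sanity check.  RMSD is plain paired
heavy-atom RMSD; molecular-symmetry-corrected RMSD is deliberately out
of scope, so symmetric ligands are scored conservatively.

Rotations are *not* re-superposed after rotating: re-superposition
would undo every rotation and collapse the integral to the aligned
pose.  No occluding receptor means USE2.0 is an upper bound on what
uniform sampling could achieve in a real pocket.

The Monte-Carlo estimator draws the same placement model (uniform
conformer, random unit quaternion, radius ∝ U^(1/3) for uniformity in
the ball) but scores each sample by direct RMSD of the placed
coordinates, keeping it independent of the translation-ball shortcut.
Agreement within 3 binomial standard errors at 10⁶ samples is part of
the acceptance suite.

Grid resolution: at M = 40 the only quadrature error comes from the θ
trapezoid (the φ/ψ sums are exact for low trigonometric harmonics);
observed error on smooth test functions is ~10⁻⁴–10⁻³ relative, and
error decreases monotonically from M = 10 to M = 40.

## Knowledge-based pocket filter

Derivation: a column of the family alignment is a pocket position when
any member's mapped Cα is strictly within 4.0 Å of any heavy atom of
that member's own ligand.  A caller-supplied exclusion list can remove
positions judged biased by the structural alignment (in the motivating
receptor family, positions at the tops of two transmembrane helices).
Cutoff per column: the maximum Cα–Cα distance over ordered structure
pairs in a common superposed frame — the flexibility the family itself
exhibits at that position.  Columns occupied in fewer than two
structures cannot be assigned a cutoff and are flagged.

Application: a model passes iff every pocket Cα is within the cutoff
(non-strict, ≤) of the equivalent Cα of at least one family member
*other than* the model's own target structure.  The strict/non-strict
boundary choices (strict < for the 4.0 Å contact test, ≤ for cutoff
satisfaction) are fixed and tested.  Missing pocket residues fail with
the reason recorded.  The passing set is capped to the 100
lowest-energy models, ties broken by model id.

Pocket collapse: for each pocket column,
collapse = d_reference − d_model, where d is the minimum distance from
the residue's Cβ (Cα for glycine) to any reference-ligand heavy atom,
after superposing the model on the reference when they do not already
share a frame.  Positive values mean the model moved the residue
toward the ligand.  Note a non-obvious property exercised by the tests:
under isotropic Gaussian perturbation the *mean* collapse is slightly
negative (an isotropically displaced point moves away from its nearest
neighbour on average), vanishing only as the noise goes to zero; the
spread grows monotonically with the noise.

## Clustering and contacts

Complete linkage was chosen because a cut at the cutoff guarantees
every intra-cluster pairwise distance is at or below it — the natural
reading of a "cluster radius".  Poses are clustered on frame-fixed
heavy-atom RMSD (the docking evaluation metric); models on pairwise-
superposed Cα RMSD, optionally after reduction to the best-scored 10%.
All orderings are deterministic: clusters sort by size, then
representative energy, then representative id; representatives are the
lowest-energy members with id tie-break; the top-ranked item is the
representative of the largest cluster.

Contacts are residue-granular by default (any residue heavy atom within
4.0 Å of any ligand heavy atom), with atom-pair granularity and
alignment-column translation available for cross-structure comparison.
Coverage and accuracy satisfy the integer identity
coverage·|reference| = accuracy·|model| = |intersection| exactly.

## Enrichment

Contact constraints: for each n from 0 to the number of known native
contacts, 10,000 random n-subsets are drawn without replacement; a pose
is retained when its own 4.0 Å contact set contains **all** drawn
contacts (the all-of reading matches the experimental interpretation
that each implicated residue contacts the ligand; any-of is available).
The retained near-native fraction is averaged over iterations.
Iterations retaining no pose are excluded from the mean and reported
separately as an empty fraction — a fraction of an empty set is
undefined, and counting such iterations as zero would bias the curve
downward.  n = 0 reproduces the base rate exactly in every iteration.
An exhaustive-subset curve (all C(K, n) subsets enumerated) is provided
as the independent check; the resampled curve converges to it.

Energy cutoffs keep the ⌈f·N⌉ best-scored poses (ties by pose index);
geometric constraints retain poses with the minimum selected
receptor-atom-to-ligand-atom distance strictly below the bound (named
hydrogens are allowed here, which is why the PDB reader keeps hydrogens
accessible behind a flag while excluding them from all default
analyses).

## Synthetic data: what it emulates, and what it does not

The generators produce every input with recorded ground truth:

* **Receptor family** — an idealized Cα/Cβ scaffold: 8 pocket residues
  placed 3.0 Å from designated atoms of a rigid 8-heavy-atom ligand
  (inside the 4.0 Å contact rule with margin comparable to the 1.0 Å
  default family jitter), 32 non-pocket residues on a 12 Å cylinder far
  outside contact range.  Family members add isotropic Gaussian jitter
  (σ_family, default 1.0 Å — matching the spread observed across real
  experimental families) to every atom, plus a small rigid ligand
  translation.  The alignment is gapless by default; an indel option
  drops one non-pocket residue from the last member to exercise gap
  handling.  Glycines recur in the sequence cycle so the Cβ→Cα fallback
  is always exercised.
* **Model ensembles** — the self structure with pocket-residue jitter
  at σ_good (default 0.5 Å, within family flexibility) or σ_bad
  (default 4.0 Å, far outside it), emulating native-like vs distorted
  pockets; energies are mean pocket displacement plus Gaussian noise
  scaled to a target energy/accuracy correlation (default 0.8).  Under
  the default acceptance conditions (5 structures at σ_family = 1.0,
  models at 0.5/4.0 Å) the filter's designed operating point is a
  good-model pass rate of roughly 0.93–0.99 across generator seeds
  (mean ≈ 0.97) and a bad-model fail rate indistinguishable from 1.
* **Conformers** — the reference plus torsion-like rigid-subunit
  rotations of half the atom list about a pivot plus small jitter;
  scale 0 reproduces the reference, mean RMSD grows monotonically with
  scale.
* **Poses** — each pose is near-native with probability p (small rigid
  perturbation, RMSD < 2.0 Å by construction with a rejection guard) or
  a decoy (Haar rotation, uniform translation in the 5.0 Å sphere);
  scores are RMSD plus Gaussian noise scaled to a target score/RMSD
  correlation.  Contacts are derived purely from the generated
  geometry, which makes them informative: near-native poses share more
  native contacts than decoys, the regime in which enrichment curves
  are non-decreasing.

Not emulated: real energetics (scores are a correlation model, not a
force field), torsion-angle chemistry, side chains beyond Cβ, membrane
geometry, loop-length variation, and ligand symmetry.  Passing tests
therefore validate the *statistics and geometry* of the assessment
machinery — not the ability of any docking protocol to rank real
complexes, and absolute USE2.0 values for the small synthetic ligand
(~10⁻³–10⁻²) are far larger than for drug-sized ligands (10⁻⁵–10⁻⁷),
simply because the synthetic ligand is small and rigid.

## Pipeline and problem sizes

The `dockassess run` pipeline chains filter → model clustering → USE2.0
→ pose evaluation → enrichment → summary, writing one TSV per stage and
a manifest (version, seed, parameters, per-stage outputs).  All
randomness derives from the single config seed (stage offsets +1..+4),
and no output embeds timestamps, so a rerun with the same config is
byte-identical.

Default test and acceptance problem sizes are chosen to make every
oracle comparison exact or statistically sharp while keeping runs
interactive: 5-structure families, 500-model filter ensembles,
10⁶-sample Monte-Carlo checks, 10⁴ enrichment iterations on 20-pose /
5-contact ensembles (small enough for exhaustive enumeration), and a
150-pose pipeline fixture.  The contact-enrichment resampler handles up
to 63 native contacts (contact sets are packed into 64-bit masks).

## Known limitations

* RMSD is not symmetry-corrected; USE2.0 of symmetric ligands is
  underestimated.
* The pocket filter presumes a common superposed frame; the package
  provides Kabsch superposition helpers but does not choose the frame
  for you.
* Sequence identity is computed over co-aligned columns by default
  (full-alignment-length normalization is available); the choice
  matters for gappy alignments.
* The grid USE2.0 inherits the conformer ensemble's discreteness: it
  does not integrate over ligand internal degrees of freedom beyond the
  ensemble members provided.
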