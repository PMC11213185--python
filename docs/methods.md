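# Methods notes

## Model and assumptions

The pipeline treats a tracing dataset as a marked 3D point process: each
point is a labeled projection neuron in reference-brain coordinates (μm),
and its marks are the injection site(s) — hence cortical categories — that
labeled it. The central quantity is local target composition: inside a
closed ball of radius r around every neuron, the per-injection neighbor
counts N_p,j. Density is deliberately a hard-sphere count, not a kernel
estimate; the radius is the single smoothing parameter.

Assumptions worth making explicit:

* All brains are perfectly co-registered; positional error is not modeled.
* A neuron "projects to" a category if any of its labeling injections has
  that category. Double-labeled neurons (two tracers) are members of each
  labeled population — one full count per injection, never fractional.
* Injection volumes are voxel masks on a common lattice; every volume and
  intersection is a voxel count times the voxel volume. Two masks are only
  compared after explicit resampling to a shared grid (half-open voxel
  boxes, so the grid partitions space).

## Normalization

Two injections of the same category that overlap in cortex label overlapping
neuron populations, inflating that category's counts. The per-injection
constant C_j = V(I_j)/Σ_{I_k∈I_R} V(I_j∩I_k) (sum over the injections of
the same category, self term included) down-weights counts in proportion to
that redundancy: a sole injection has C = 1; two coextensive duplicates get
C = 0.5 each, which exactly cancels the double counting after category
aggregation (a tested invariance). Normalization is applied per injection
*before* summing within category because C_j is defined per injection site.
The set I_R is read as "injections assigned to ontology category R"; the
correlation analysis uses the normalized matrix (the raw one is retained
for sensitivity).

## Parameters

| parameter | default | meaning |
|---|---|---|
| radius | 300 μm | neighborhood ball; structure reported stable over 100–500 μm |
| include_center_cell | true | the sampling neuron counts itself for its own injection(s) |
| linkage | complete | MAX linkage on Euclidean row-vector distances |
| n_bootstrap | 1000 | replicates per bootstrap scale |
| scales | 0.5…1.4 step 0.1 | relative resample sizes (must include 1.0) |
| distance_stat | median | cross-population cell-distance statistic |
| voxel_spacing | 50 μm | mask lattice, matching section-series resolution |

Closed-ball membership (distance ≤ r) plus self-inclusion are conventions
chosen so that every TPV row is non-zero; both are explicit options.

## Numerical and procedural choices

* **Row-vector distances** use all 30 coordinates of each correlation row,
  including the diagonal 1s (simplest reading of "row vectors of
  correlation coefficients"); `include_diagonal=False` exposes the
  sensitivity to dropping self-entries.
* **Agglomeration** is implemented directly (O(n³), n = 30) so the
  tie-break is fully specified: among equally close cluster pairs, the pair
  with the lowest creation-order indices merges first. On tie-free inputs it
  agrees with scipy's complete linkage (tested), and scipy's implementation
  is used inside bootstrap replicates where resampling noise makes ties a
  measure-zero event.
* **Cuts into k clusters** stop the agglomeration after n−k merges
  (`cut_tree` semantics) rather than thresholding heights, so every k in
  2…n−1 is attainable even under tied merge heights. Singleton clusters
  contribute silhouette 0 by the usual convention. All-identical objects are
  a degenerate-input error, not a score.
* **Pearson** is the plain two-pass formula; a constant column has no
  defined correlation and is flagged (its row/column set to NaN and reported
  in the run manifest), never silently imputed — except inside bootstrap
  replicates, where a constant resampled column's correlations are set to 0
  to keep the replicate usable.
* **AU p-values.** For each scale τ, B resamples of ⌈τ·n⌉ TPV rows are
  drawn with replacement and pushed through the full
  correlation → distance → linkage chain; BP(τ) is the fraction containing
  the reference branch as a leaf set (branches encoded as 30-bit masks).
  The probit curve z(τ) = v√τ + c/√τ is fit by weighted least squares with
  BP clamped to [1/(B+1), 1 − 1/(B+1)] and asymptotic binomial weights;
  AU = Φ(c − v). Branches present in every resample at every scale saturate
  at AU = 1 (flagged, not fit); all-absent branches saturate at 0. A
  singular fit raises — AU is never defaulted. Fewer than three distinct
  scales is an error, since the two-parameter curve would be unidentified.
* **PCA** is the eigendecomposition of the correlation matrix itself
  (variance fractions λ_i/Σλ); loading signs are fixed so each component's
  largest-magnitude loading is positive.
* **Pair enumeration** for all distance–similarity analyses is every
  unordered distinct category pair, C(30,2) = 435.
* **"Above-average density"** selection is strictly greater than the column
  mean; ties at the mean are excluded, so the selected set is always a
  proper subset (and empty for a constant column).

## Synthetic generator

The generator emulates the statistical structure the analysis assumes,
at the study's scale: 5,674 cells over 30 categories partitioned into three
functional networks (12 somatic sensory-motor, 9 visual, 9 auditory — the
ontology fixture is user-replaceable). Each network is a chain of four
Gaussian clusters (sd 250 μm) spaced 1,000 μm along the antero-posterior
axis, with networks offset 1,500 μm (6 sd) medio-laterally; a category's
cells are drawn from its network's chain with Gaussian weights (width 1.2
cluster indices) centered at its position along the chain, producing a
systematic antero-posterior transition of co-projecting populations.
A mixing fraction (default 0.05) draws a cell from a foreign network's
chain; ~1% of cells carry a second label from another category of their own
network. Each category has two spherical voxel-mask injections (radius
400 μm, 50 μm lattice) whose center spacing is solved numerically (Brent's
method on the lens-volume formula) for a 0.3 pairwise overlap fraction, so
normalization is genuinely exercised.

What the generator does **not** emulate: the anatomical silhouette of the
basal forebrain, per-area cell-count imbalance, registration error,
brain-to-brain variability, and any cortical geometry beyond
sphere-pair injection footprints. Passing the planted-recovery tests
therefore shows the pipeline recovers block-structured co-projection signal
at realistic scale and noise — not that real tissue has that structure.

## Problem sizes in the test suite

Unit and property tests run on hand-built fixtures and a 600-cell preset of
the generator; end-to-end recovery, branch support and null-behavior tests
run at the full 5,674-cell default with B = 1000 bootstrap replicates per
scale. The seed-stability check (planted partition recovered for ≥ 9 of 10
seeds) uses the 600-cell preset across seeds 0–9.

## Known limitations

* AU p-values are asymptotic; at B = 1000 their Monte-Carlo s.e. near
  BP ≈ 0.9 is ~0.01, and values for weakly supported branches vary by seed.
* The bootstrap resamples cells (TPV rows as features of the 30 area
  objects), not brains; hierarchical sampling error between animals is out
  of scope.
* Mask-less injections (precomputed overlap tables) support normalization
  and centroid analyses but not Dice/participation, which need geometry.
* With tied correlation patterns the dendrogram leaf order, though
  deterministic, is one of several equally valid layouts.
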