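# Methods

This note documents the model implemented in `betop`, the choices made where
the design was genuinely open, and the scope of what the synthetic benchmark
demonstrates.

## Model summary and assumptions

The predictor assumes that (i) an antigen's solvent-exposed residues and
their spatial contacts are well represented by a Delaunay-derived residue
graph, (ii) epitope patches differ from the rest of the surface in the
*composition* of residue types and residue-pair contacts, strongly enough to
be learned as per-edge-type propensities, and (iii) an epitope occupies one
or a few contiguous subgraphs of that graph, so classifying clusters —
rather than residues — both stabilizes the signal and separates multiple
epitopes. Nothing in the pipeline uses protrusion or curvature, which is why
flat epitopes are not penalized.

## Pipeline parameters

| parameter | default | units | role |
|---|---|---|---|
| probe radius | 1.4 | Å | solvent probe for accessibility |
| ASA sphere points | 960 | — | Shrake–Rupley sampling resolution |
| surface threshold | 10 | Å² | atom counts as surface if ASA ≥ threshold (inclusive) |
| contact cutoff | 4.0 | Å | antigen residue is epitope if any heavy atom is within this distance of the antibody (inclusive) |
| edge cutoff | 6.0 | Å | atom contacts longer than this are pruned (strict) before residue-level merging |
| α | 0.3 | — | χ² vs log-odds mixing weight |
| θ, γ | 3, 3 | — | contrast sharpening |
| w0 percentile | 60 | — | boundary-type suppression threshold (see below) |
| inflation r | 1.8 | — | MCL granularity |
| θ₀ | 0.3 | — | vote threshold; raising it shrinks the predicted-epitope set monotonically |
| τ₀ | 0.05 | — | dubiety half-band around p = 0.5 |
| target features | 144 | — | cap of the Fisher-score cut sweep |

Accessibility uses a NACCESS-like van der Waals radii table (C 1.87, N 1.65,
O 1.40, S 1.85 Å; others 1.80 Å). Values computed with a different tool or
radii table will differ by a few percent; all thresholds here are applied to
this package's own ASA values. The sample-point lattice is fixed in space,
so per-atom ASA is exactly translation-invariant but rotation-invariant only
to the discretization (≈ 1–2 Å² per atom at 960 points); totals agree to
well under 1%.

## Numerical and procedural choices

* **Edge statistics.** Expected counts in the χ² statistic come from the
  independence model on the 2×210-type contingency table; a type absent from
  both classes contributes 0. Log-odds are natural-log with 0.5 pseudocount
  per cell (so absent types stay finite). Both tables are min–max normalized
  over their 210 values before mixing; a constant table normalizes to all
  0.5 with a warning. The contrast transform clamps its argument to
  [1e-9, 1−1e-9] and is strictly increasing with f(0)=0, f(1)=1.
* **Single-residue statistic.** Built like the pair weights but over node
  frequencies (epitope vs non-epitope residues), normalized and mixed with
  the same α, without the contrast step: the contrast exists to sharpen MCL
  flow, while the singles statistic is only a feature scale.
* **Boundary suppression (w0).** Types are scored `max(W′, W″)` — boundary
  class contrasted against the epitope class and against the non-epitope
  class — and every edge of a type scoring above the `w0` percentile of the
  210 scores is deleted before clustering. The default percentile is 60.
  With a lenient threshold (e.g. the 90th percentile) most epitope/
  non-epitope divider edges survive, and because those edges are typically
  the strongest edges incident to near-patch background residues, Markov
  flow drags the background ring into patch clusters: on the synthetic
  benchmark the achievable residue-level f-score ceiling (clusters labelled
  by an oracle) drops from ≈ 0.95 to ≈ 0.6 with occasional total failures.
  Aggressive suppression conversely fragments the graph; 60 balances the
  two. The percentile is exposed on the estimator and the CLI.
* **MCL.** Self-loops are added with weight equal to the node's maximum
  incident edge weight (1 for isolated nodes) before normalization —
  standard stabilization. Entries below 1e-6 are pruned each iteration;
  convergence is a max-entry change below 1e-8 (checked idempotent in
  tests). Every node joins its largest-flow attractor, ties to the
  lowest-indexed one; all-zero columns become singletons, so the output is
  always a partition.
* **Cluster labels.** Epitope if epitope members outnumber non-epitope
  members (this majority rule takes precedence), else non-epitope if at most
  two epitope members, else noise; noise clusters are excluded from
  training. Singleton clusters are kept and labelled by the same rule.
* **Feature selection.** Two-class Fisher scores rank features; candidate
  cuts (8, 16, …, up to the 144 cap) are compared by 5-fold stratified CV
  f-score of a small balanced RBF-SVM. If nothing discriminates, the
  smallest cut is kept with a warning.
* **Ensemble.** k = max(1, round(#non/#epi)) classifiers, negatives
  partitioned by a seeded shuffle. Per classifier, grid search maximizes
  5-fold CV f-score over C ∈ {2⁻³ … 2¹¹} with a data-scaled kernel width;
  small balanced groups (tens of samples) overfit a dense (C, γ) grid, which
  is why the search is deliberately coarse. Classifier weights are the
  normalized validation f-scores. Probabilities come from sigmoid
  calibration of SVM margins (seeded). In the vote, sgn(0) contributes
  nothing to the consensus sum, and with τ₀ = 0 the rule reduces to a plain
  weighted vote.
* **Prediction.** Predicted epitope subgraphs merge exactly when an edge of
  the original (pre-suppression) surface graph joins them; merging is the
  connected-components closure, so it is transitive and order-independent.
  Per-epitope confidence is the mean vote score of its member subgraphs.
* **Degenerate inputs.** Fewer than 4 surface atoms, or an exactly
  coplanar/collinear atom set, is an error; a numerically marginal
  tessellation failure is retried once with a deterministic 1e-6 Å joggle.
  Epitope labelling with an empty antibody role is an error. Non-planarity
  of a collinear patch returns 0 with a warning (the plane is not unique).
* **Curation.** Complexes are dropped if any modeled chain is shorter than
  30 residues or the resolution is 3 Å or worse (missing resolution passes).
  Antigen chains with > 80% global-alignment identity (match +1, mismatch 0,
  linear gap −1; identity = matches / shorter length) to an already retained
  chain are removed, first seen wins.

## The synthetic benchmark

`betop.synthetic` generates antigens as ~135 pseudo-residues (3–5 dummy
heavy atoms each) on an 18 Å jittered sphere, with one or two contiguous
geodesic caps of 12% of the residues designated epitope. Epitope residue
types are drawn with 30:1 odds in favour of a configurable pattern set
(default: QQ/DD pairs and QQR/QQS/DDY triangles, echoing the polar
doubled-residue triangles that favour real epitopes); the background is
uniform. A dummy antibody chain is placed within 4 Å of every epitope
residue and verifiably beyond 4 Å of all others, so distance labelling
recovers the planted truth exactly, and the caps sit in the planar
(< 2 Å non-planarity) stratum.

The enrichment odds are deliberately strong: the generator is a
parameter-recovery harness, and the planted signal is chosen so that a
failure to recover it indicates an implementation fault rather than sampling
noise. What passing shows: the full chain — labelling, graph construction,
weight learning (the planted enrichment direction is recovered in the
log-odds signs), boundary suppression, clustering, vectorization, selection,
ensemble voting, merging — is wired correctly and recovers planted structure
end to end, including separating two disjoint epitopes. What it does not
show: performance on real antigens, whose compositional bias is far weaker,
whose surfaces are not spheres, and whose epitope boundaries are not sharp;
expected real-data accuracy is substantially lower than the synthetic
numbers.

Experiment sizes in `scripts/acceptance.py` (20 training complexes, 10 + 10
test antigens, ~135 residues each) are the package's benchmark conditions;
they mirror the epitope:non-epitope residue imbalance (≈ 15:120) typical of
real antigen surfaces.

## Known limitations

* Cluster-level prediction cannot resolve sub-cluster boundaries: residues
  ride with their cluster, so precision is bounded by cluster purity.
* Isolated residues (singleton clusters) carry almost no signal; spurious
  single-residue epitopes appear in the output and are best filtered by
  size downstream.
* The recovered epitope may fragment when mid-patch clusters are voted
  down — the merge rule only bridges subgraphs directly adjacent in the
  original graph.
* PDB input only (first model of NMR ensembles; no mmCIF); chain roles must
  be supplied by the user — there is no automatic antibody detection.
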