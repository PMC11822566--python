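# Methods

## Similarity and decoy selection

Compounds are represented as fixed-width binary substructure fingerprints.
From SMILES, hashed circular (Morgan) fingerprints with radius 2 and width
2048 are computed via RDKit; any fixed-width binary feature table can be
supplied instead, since every downstream stage only needs the bit vectors.
Similarity is the Tanimoto index |A ∩ B| / |A ∪ B|. Two all-zero
fingerprints are defined to have similarity 1 (identical objects); this is a
convention, exposed as `empty_value`.

Negative selection ranks every decoy by its summed Tanimoto similarity to
the positive set and keeps the `ratio · m` least similar, i.e. the decoys
furthest from the active chemistry. Ties keep input order (stable sort), so
the procedure is deterministic with no seed. `ratio` defaults to 2 (m
positives → 2m negatives) but is a free parameter: a 3:1 design (337
positives → 1,011 negatives) is equally valid and used in the target-style
worked example. When several positive sets exist (component-derived,
per-target), negatives are selected per source and the per-source training
sets are kept separate until screening.

## Gradient-boosted trees (from scratch)

Binary logistic loss with a sigmoid link. The model after k rounds is
`sigmoid(base + lr · Σ_k h_k(x))` with `base` the log-odds of the positive
rate. Each tree is fit by least squares to the negative gradient `y − p`;
split gain is weighted variance reduction, ties broken toward the lowest
feature index, then the lowest threshold; each leaf takes a single Newton
step `Σ w·g / Σ w·h` (h = p(1−p)), which acts as the per-tree line search —
training loss is recorded after every round and is non-increasing on the
training set.

Candidate thresholds are midpoints between consecutive unique feature
values. The histogram variant caps the candidates at `bins − 1`
equal-frequency quantile edges per feature (default 32), falling back to the
exact midpoints when a feature has fewer distinct values — hence the exact
reduction to plain GBDT whenever bins ≥ cardinality. GOSS keeps the
⌈a·n⌉ largest-|gradient| rows at weight 1 and uniformly samples ⌈b·n⌉ of the
rest at weight (1−a)/b (defaults a = b = 0.2); the weighted gradient sum is
an unbiased estimate of the full one. EFB greedily merges features whose
nonzero rows conflict in at most `conflict_budget` rows, offsetting member
values so bundles are invertible wherever no conflict occurred; it is off by
default and stored in the model when used. Models serialize to JSON
(trees, thresholds, leaf values, learning rate, base score) and round-trip
exactly.

Defaults (M = 60 trees, depth 3, learning rate 0.1) are ordinary
boosted-tree settings for a few hundred samples; they are starting points
for TPE, not tuned values.

## Flexible neural tree

Instruction sets F = {+_2 … +_n} (flexible neurons) and T = {x_1 … x_m}
(inputs). A neuron with child outputs x_j computes o = Σ w_j x_j and emits
exp(−((o − a)/b)²) — a Gaussian bump peaking at o = a with width |b| (b = 0
is rejected). With inputs in [0, 1] every neuron output lies in (0, 1], so
the 0.5 screening threshold is meaningful at the root.

Structure search is genetic programming: tournament selection (size 3),
subtree crossover with depth-budget retries, and grow/prune/point mutation,
with elitism; fitness is the MSE between tree output and the 0/1 labels.
Two additions make the search informative:

* **Memetic structure fitness.** Each candidate topology is scored at its
  best over its current parameters plus a few re-draws. With a single
  uniform-random parameter set, virtually every topology predicts a
  near-constant value and scores ≈ var(y), leaving selection blind to which
  terminals matter.
* **Class-calibrated draws.** Half of the re-draws center each neuron's
  Gaussian on the positive class: random weights, then a = mean and
  b ∝ std of the weighted sum over the positive samples (bottom-up, children
  first). This is a supervised initialization heuristic in the spirit of
  data-aware neural-network weight initialization; without it, even a
  correct topology is rarely rescued by swarm search because the informative
  region of (w, a, b) space is a small basin.

Parameters of the champion structure are then tuned by global-best PSO over
the flattened preorder parameter vector (inertia 0.7, cognitive = social =
1.5, velocity clamp); the incumbent seeds particle 0, so tuning never
worsens fitness, and the global-best trajectory is non-increasing by
construction. `fit_fnt` alternates structure search and PSO for a configured
number of rounds, keeping the best champion.

Initialization ranges: w ~ U(−1, 1), a ~ U(0, 1), b ~ U(0.1, 2); max arity 5
and max depth 3–4 by default, which keeps models sparse and fast at the few
hundred samples the pipeline trains on. Direct sibling terminals of one
neuron carry distinct feature indices (duplicated siblings are redundant —
their weights just sum). Fitness is training MSE; classification uses
score > 0.5. Genomes serialize to nested JSON and round-trip exactly.

## Hyperparameter search

A minimal tree-structured Parzen estimator handles the boosted backends:
trial 1 is always the space's default configuration, a few startup trials
are uniform, and subsequent proposals maximize l(x)/g(x) where l and g are
per-parameter Parzen densities of the good (best γ = 25 %) and bad trials.
The objective is 3-fold stratified cross-validated log loss. The FNT is
excluded from the search — its own optimization loop already consumes its
budget — and uses the documented defaults instead. The pipeline runs with
fixed documented hyperparameters by default (`tpe_trials = 0`); TPE is
opt-in per run.

## Pipeline protocol and definitions

* OB/DL filter: keep compounds with OB ≥ 25 (percent) and DL ≥ 0.15, both
  inclusive; missing annotations are an error, a library with no annotations
  skips the filter (logged).
* Screening: active means score **strictly** above 0.5.
* Herb frequency: number of screened-active compounds annotated to the
  herb; a multi-herb compound increments each of its herbs, so counts sum to
  the total annotation degree of the actives (checked in tests).
* Top-k: counts descending, ties by normalized name ascending; k = 20.
* Per-algorithm combination: union of the actives from the
  component-trained and the target-trained model before herb counting (one
  list per algorithm); a per-algorithm-per-source mode (six lists) is
  available via `merge_sources=False`.
* Integration: herbs present in ≥ 2 of the per-algorithm lists.
* Accuracy: precision |candidates ∩ reference| / |candidates| of the
  integrated list against the reference herb set, after name normalization
  (case-folded, whitespace-collapsed).
* All randomness derives from one pipeline seed via named seed sequences;
  identical config + seed reproduces the result exactly.

## Synthetic benchmark

The generator emulates the pipeline's inputs at the feature-table level:

* **Actives**: 4 scaffolds × 31 compounds (124 positives, split by scaffold
  parity into a "component" source and a "target" source), each compound an
  independent bit-flip perturbation (rate 0.25) of its scaffold fingerprint
  (width 256, density 0.25). This puts intra-scaffold Tanimoto near 0.4–0.5
  against an active–decoy background near 0.15 — far enough apart to learn,
  close enough that the three classifier families disagree on borderline
  compounds, which is the regime in which consensus integration has value.
* **Decoys**: 1,000 uniform-random fingerprints at popcounts matched to the
  actives, so bit density alone cannot separate the classes.
* **Library**: 160 unseen actives + 340 fresh decoys with OB/DL annotations
  drawn so ~80 % pass the filter.
* **Annotation**: 120 herbs × 12 compounds each. Eight planted herbs draw
  from the active-derived library at rate `enrichment` = 0.9; the rest draw
  actives at the independent `background_rate` = 0.03. Annotation
  specificity and planting strength are deliberately separate dials: a large
  herb vocabulary with a low background is what makes the per-algorithm
  top-20 tails diverge (they are filled by each model's own false positives
  rather than by herbs every model sees), so integration can outperform
  every single list. The planted herb names are returned as the reference
  set.

What passing the recovery experiment shows: under these conditions the
ensemble recovers planted herbs and integration filters algorithm-specific
noise. What it does not show: performance on real chemistry (the simulated
bit-flip noise has no activity cliffs, no scaffold hopping, and fingerprints
are not derived from real molecules), on real annotation databases (herb
sizes are uniform here), or at database scale.

## Numerical choices and limitations

* Split-gain regularizer 1e-12; minimum split gain 1e-12; scores clipped to
  (1e-12, 1 − 1e-12) in log-loss computations.
* Sigmoid arguments clipped at ±500 to avoid overflow.
* FNT |b| floored at 1e-6 when PSO proposes values near zero.
* Boosted-tree tie-breaks (lowest feature, lowest threshold) make training
  fully deterministic given the GOSS subsample.
* The GBDT grows depth-limited level trees, not leaf-wise best-first trees;
  no categorical splits, no multiclass, no parallelism.
* Accuracy is a precision, not a full precision/recall analysis; with a
  forced top-20 per list, single-algorithm precision is bounded by
  (number of true herbs)/20 when the reference is small.
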