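# Methods

## Model

The package assumes a disease arises from the aberrant function of a small
set of pathways, and that a compound is a candidate treatment when it
perturbs those pathways. Three independent evidence channels are modelled:

* **Pathway-pair profiles (PIPP).** Compound-affected pathways are those
  over-represented among its target genes; disease pathways are those
  over-represented among its associated genes. Over-representation uses the
  one-sided hypergeometric test with Benjamini–Hochberg control at
  FDR ≤ 0.05 (both configurable); the background defaults to the union of
  all pathway genes. A (compound-pathway, disease-pathway) pair qualifies
  as *common* (identical), *cross-talking* (≥ 1 shared gene) or
  *interacting* (≥ 1 bridging PPI edge), with precedence in that order.
  Cross-talking and interacting pairs must additionally show correlated
  activity — Pearson correlation of per-tissue mean expression, two-sided
  t-test with n − 2 degrees of freedom, keep if p < 0.01 — across the
  expression panel (36 tissues by default); common pairs bypass this gate.
  Per disease, a pair's score is the exact fraction k/n of the n treating
  compounds exhibiting it. A query compound's disease score is the weighted
  per-type noisy-OR Σₘ αₘ(1 − ∏(1 − P)), α = (0.5, 0.3, 0.2). The sum is
  over the pair types m (common, cross-talking, interacting); an empty type
  contributes 0, so the score is bounded in [0, 1] and monotone in every
  matched profile score. The alternative reading 1 − Σₘ αₘ∏(1 − P) — which
  yields 0 only when *all* types are empty of evidence — is available as
  `eq2_variant="complement"` for comparison.

* **Nearest profiles (NP_C, NP_D).** Single-linkage set similarity: the
  score of (C, D) is the maximum similarity between the query entity and
  the set of entities already holding the association (other compounds
  treating D under Tanimoto fingerprint similarity; other diseases treated
  by C under the supplied disease similarity). A held-out entity never sees
  its own association (`exclude_self`). The literal nearest-neighbour
  variant — project the single globally most similar neighbour's whole
  profile scaled by its similarity — is one flag away
  (`aggregation="nearest_neighbor"`); the max-over-holders default
  reproduces the characteristic 0.0 score when no similar entity holds the
  association.

* **Ensemble (PINA).** P(C, D) = Σ wᵢMᵢ with wᵢ the method's ROC AUC,
  normalised to sum to 1 by default so the combined score stays in [0, 1]
  and remains commensurate with the probability semantics of the formula
  model and the 0.6 calling threshold; raw weights via `normalize=False`.

* **Formula scoring.** A multi-compound preparation scores
  1 − ∏(1 − P(Cᵢ, D)) under component independence; components without a
  prediction contribute 0 (missing evidence is not negative evidence).
  Indications are called at a threshold of 0.6 by default — the
  F1-maximising cross-validation threshold is always re-derivable from the
  `cv` output. Synergy or antagonism between components is deliberately not
  modelled.

## Cross-validation protocol

Positives are the known associations; negatives are every compound–disease
pair never labelled positive. K-fold splitting is a seeded uniform shuffle
followed by round-robin assignment. Per fold, the held-out positives are
masked from the association matrix *before* profiles and nearest-profile
lookups are built (enrichment and pathway-pair classification depend only
on targets/genes, never on labels, so they are computed once). Ensemble
weights are each method's AUC measured on the fold's own training
associations. Held-out predictions are pooled across folds for the
headline metrics; per-fold AUCs are reported alongside. Pooling means each
never-positive pair contributes one (fold-specific) prediction per fold;
AUC is computed by the tie-aware Mann–Whitney rank formulation. The
F1-maximising threshold is searched over the grid of distinct observed
scores, ties broken toward the smallest maximiser (favouring recall).
Precision is defined as 0 (with a warning) when nothing is predicted.

## Disease modules

Two diseases are linked when their associated pathway sets intersect.
Module detection is MCODE-style: each vertex is weighted by
k_max × density of the highest k-core of its closed neighbourhood; modules
grow greedily from the highest-weight unvisited seed. A neighbour is
admitted only if (a) its weight is at least (1 − VWP) times the seed's
(VWP = 0.2) and (b) the growing module's edge density stays at least
(1 − VWP) times the seed's core-clustering density. The density guard is
this package's own refinement of the classic expansion rule: a pure
weight threshold lets two dense regions joined by a single bridge edge
collapse into one module, because the bridge endpoints carry the same
weight as their clique neighbours; the density condition rejects exactly
those sparse attachments. Candidates are examined in (module-connectivity
desc, weight desc, global degree asc, id) order — preferring less
promiscuous vertices keeps bridge endpoints from being pulled in before
their own dense neighbourhood — and a rejected candidate is retired for
the current module, making the procedure deterministic. Post-processing
keeps each module's 2-core (haircut) and drops modules below 3 members
(the `fluff` expansion is available but off by default). Modules are
annotated with the mean pairwise member similarity (over all C(n,2)
pairs) and per-class membership fractions; pathway–class specificity
counts the distinct disease classes each pathway touches.

## Synthetic data

The generator plants exactly the structure the predictors assume.
Diseases come in clusters sharing a causal pathway set; disease genes are
sampled from those pathways. Each cluster has a group of treater
compounds, each treating every disease of the cluster, with targets drawn
from a causal pathway — or, at the configured rates, from a gene-sharing
(crosstalk) or PPI-bridged (interacting) partner pathway whose expression
shares the causal pathway's latent tissue factor. Treaters of a cluster
share a fingerprint archetype; non-treating compounds target decoy
pathways and carry random fingerprints. Disease similarity is the overlap
coefficient of the planted causal pathway sets. Every planted fact goes
into a ground-truth ledger; tests assert against the ledger, never
against re-derived outputs.

Noise knobs independently corrupt disease genes, targets, fingerprint
bits, labels (each flipped positive is replaced by a random pair) and
expression; `shuffle_labels` permutes the association rows outright — the
permutation null. What the generator does *not* emulate: the heavy-tailed
set-size and degree distributions of real curated corpora, fingerprint
bit correlations, text-derived disease similarity, or annotation biases —
so passing tests demonstrate correctness of the machinery and
recoverability of idealised structure, not real-world accuracy.

Two presets are shipped. `tiny` (noise-free; 2 clusters × 7 diseases,
7 treaters per disease, 8 pathways × 12 genes, 36 tissues, 128-bit
fingerprints) is sized so that with 5-fold splitting it is overwhelmingly
likely that every held-out positive leaves at least one same-cluster
association in training — the condition for exact AUC = 1.0 recovery.
`default` (5 clusters × 4 diseases, 30 compounds, 36 pathways, gene noise
0.2, target noise 0.1, fingerprint flips 0.1, label flips 0.1, expression
noise SD 0.3, crosstalk/interacting rates 0.25 each) is the moderate-noise
benchmark on which the ensemble's advantage over its base methods is
demonstrated. These sizes keep a full cross-validation under a second
while leaving hundreds of pooled predictions per run.

## Numerical and design choices

* The enrichment statistic is not dictated by the problem; the
  hypergeometric/BH combination was chosen as the field standard and all
  three knobs (test FDR, background, correlation α) are configurable.
* Profile pairs supported by at least one treating compound are kept
  (`profile_min_score = 0`): the least surprising default, and
  cross-validation can tune it.
* The correlation gate accepts significant correlations of either sign by
  default; `positive_r_only` restricts to r > 0. Constant activity vectors
  make r undefined: such pairs are rejected with a degenerate-input flag.
* A compound contributes at most once per pair to a profile count however
  many enrichment routes produce the pair (pair identity is the ordered id
  pair plus type).
* All ID orderings are lexicographic and every iteration order is
  deterministic, so equal seeds give byte-identical outputs.
* Expression loading rejects missing values rather than imputing: the
  correlation test assumes complete tissue vectors.
* PPI edges lacking a score or evidence labels pass the corresponding
  confidence filter — the filters act only on declared metadata.
* Known limitations: negatives are "never labelled positive", so true but
  unrecorded associations depress measured precision; the ensemble is a
  linear blend and cannot exploit method complementarity beyond weighting;
  formula scoring ignores component interactions; MCODE module boundaries
  depend on the documented tie-breaks for symmetric inputs.
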