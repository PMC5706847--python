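# pina

Network-pharmacology prediction of new indications for compounds (drug
repositioning), and for multi-compound preparations such as traditional
Chinese medicine formulas.

Given a corpus of known compound–disease associations, compound target
genes, disease genes, curated pathways, a protein–protein interaction
network, cross-tissue expression, and chemical / disease similarities, the
package scores every compound against every disease three complementary
ways and blends them:

1. **PIPP — pathway-pair profiles.** For each known association, the
   pathways enriched in the compound's targets (hypergeometric test,
   Benjamini–Hochberg FDR) are paired with the pathways enriched in the
   disease's genes. A pair qualifies when the two pathways are identical
   (*common*), share a gene (*cross-talking*), or are bridged by a protein
   interaction (*interacting*) — the latter two only if their mean-expression
   activities correlate across normal tissues (Pearson, p < 0.01). Per
   disease *D*, a qualifying pair *p* is scored by the fraction of treating
   compounds exhibiting it:

   P(p | D) = N(C | p) / N(C′ | D)

   A query compound with pair set *Q* scores

   S(C, D) = Σₘ αₘ · (1 − ∏_{p ∈ Q, type(p)=m} (1 − P(p | D))),

   a per-type noisy-OR weighted over the three pair types with
   α = (0.5, 0.3, 0.2).

2. **NP_C / NP_D — nearest profiles.** Guilt by association via single
   linkage: NP_C scores (C, D) by the maximum Tanimoto fingerprint
   similarity from C to any other compound known to treat D; NP_D by the
   maximum disease similarity from D to any other disease C is known to
   treat.

3. **PINA — AUC-weighted ensemble.** P(C, D) = Σᵢ wᵢ·Mᵢ, with each
   method's weight set to its cross-validated ROC AUC (normalised to sum
   to 1). The decision threshold is chosen to maximise F1 in 5-fold
   cross-validation.

For a formula *F* composed of compounds Cᵢ, the indication score is the
noisy-OR of the component scores, P(F, D) = 1 − ∏ᵢ (1 − P(Cᵢ, D)),
treating components as independent causes.

The package also builds the disease–disease network in which two diseases
are linked when they share an associated pathway, detects dense modules in
it with an MCODE-style algorithm, annotates modules with average member
similarity and disease-class coverage, and reports how class-specific each
pathway is.

A seeded synthetic-data generator produces complete bundles with planted,
recoverable structure, so the whole pipeline is testable without any
external database.

## Worked example

Generate a noise-free synthetic bundle, cross-validate all methods, and
build the disease module map:

```sh
pina --seed 7 --out bundle synth --preset tiny
pina --seed 7 --out cvout cv --bundle bundle
pina --out net disease-network --bundle bundle
```

which prints

```
        AUC  Precision  Recall   F1
method
PIPP    1.0        1.0     1.0  1.0
NP_C    1.0        1.0     1.0  1.0
NP_D    1.0        1.0     1.0  1.0
PINA    1.0        1.0     1.0  1.0

2 module(s); single-class pathway fraction 1.000
```

The `tiny` preset plants two disease clusters, each with its own causal
pathways and treater compounds; with every noise knob at zero all four
predictors recover the held-out associations perfectly (AUC = 1.0), the
disease network resolves into exactly the two planted clusters, and every
pathway is specific to one disease class. `cvout/cv_report.json` holds the
fold assignment, per-fold AUCs, learned ensemble weights and the selected
threshold; `net/modules.tsv` lists each module with its average member
similarity and class coverage.

The same works from Python:

```python
from pina import synth, run_cv
bundle, ledger = synth.generate_bundle(synth.PRESETS["default"](seed=0))
report = run_cv(bundle, k=5, seed=0)
print(report.to_table())
```

On the moderate-noise `default` preset the base methods land around
AUC 0.83–0.93 and the ensemble above them — the motivation for blending.

Formula-level predictions take a `formula_id<TAB>compound_id` table:

```sh
pina --out f formula --bundle bundle --formula my_formula.tsv --threshold 0.6
```

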