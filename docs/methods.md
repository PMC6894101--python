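# Methods

This note documents the models, procedures, parameter choices and known
limitations of `kgfuse`, in the order data flows through the package.

## Corpus model and preprocessing

A corpus is a set of `(id, text, label)` records, one label per
document. Tokenization is pluggable (`tokenizer: str -> list[str]`);
the default lowercases and splits on punctuation/whitespace (underscore
included as a separator), which is adequate for space-delimited
languages. For languages without whitespace word boundaries a proper
segmenter should be injected; nothing downstream depends on the
tokenizer beyond determinism. Stop words are removed after
tokenization. Token multiplicity is preserved (term frequencies are
needed), set semantics are applied only for membership questions such
as d∩K.

**Rarity binning.** Classes are stratified by prevalence
(class size / corpus size) into left-open right-closed bins with
default edges 0.02%, 0.05%, 0.1%, 0.5%, 1%; the three lowest bins are
the *rare* classes. Fractions are computed on the full corpus, not the
training split, because prevalence is a property of the population
being modeled, and bins partition only the *reporting* — classifiers
are always trained on all classes.

**Per-class splitting.** Each class is split independently so that
every class with ≥ 2 documents appears on both sides.
`round(train_fraction · n)` is implemented as round-half-up
(`floor(x + 0.5)`) and clipped to `[1, n−1]`; deterministic given the
seed. Single-document classes go entirely to train and are flagged
*untestable*; they are trained on but excluded from per-bin test
metrics, and a bin whose every class is untestable is reported as
missing. (At the default benchmark size, classes in the ≤ 0.02% bin
necessarily have one document, so that bin has no test metrics; pooled
rare-bin rows aggregate the three rare bins.)

## Knowledge-graph linking

The KG is an offline snapshot: entities with canonical name, aliases,
categories, free-text attributes and related-entity names. Lookup uses
exact alias matching after NFKC width normalization and casefolding —
deliberately no fuzzy matching, which keeps linking auditable.
Disambiguation requires at least one whitelisted medical category;
among surviving candidates the one with the most whitelisted categories
wins. All ties everywhere in the package are broken lexicographically
(by entity id or term) so every result is reproducible and
input-order-invariant.

A class with no matched entity gets a *surrogate*: the entity whose
content words (tokenized attributes + aliases + related names) overlap
most with the class's profile. The profile is the class's `top_n = 20`
distinct training words ranked by idf (ties: in-class count, then
lexicographic); 20 words is enough to characterize a class's specific
vocabulary without diluting the overlap with common words. The default
`specificity_fraction = 0.0001` (0.01% of entities) caps the
entity-document-frequency of a K₂ word at `max(1, floor(f·|E|))`; the
cap is an upper bound — the condition plays the role of inverse
document frequency on the KG side, keeping only words that are
*specific* to few entities — and the `max(1, ·)` floor keeps small
(synthetic or domain-restricted) stores usable. Raising the fraction
can only grow K₂ (monotonicity is tested). K₁ takes attribute values
and related-entity names, not attribute names, which are schema labels
rather than content.

## Feature construction

The TF-IDF variant is fixed so every example is checkable by hand:
tf = raw count, idf(t) = ln(N/df(t)) + 1 fitted on the training split
only (test documents are transformed with training statistics), L2
normalization per segment, no renormalization after concatenation.
The knowledge segment reuses the idf fitted on full documents rather
than refitting on the restricted segment: one weighting scheme, two
views of the document. Consequence (the emphasis mechanism): for any
document containing both a knowledge word and a weighted non-knowledge
word, the knowledge segment's pre-normalization L2 length is strictly
smaller than the bow segment's, so the shared word's normalized value
is strictly larger in the knowledge segment. The fused vector has norm
in (1, √2].

Knowledge-only representations (KG₁, KG₁₂) and the χ²-selected
representation are the same segment transform over a different term
subset; there is no separate code path. χ² scores use the 2×C
(presence × class) contingency table against independence; the χ² arm
selects |V∩K₁| terms so that external-knowledge selection and
statistical selection are compared at equal feature budget. The
pseudo-count arm adds k = 1 extra counts to knowledge words present in
a document before weighting (larger k makes the vector degenerate
toward knowledge-only). Out-of-vocabulary tokens are ignored; an
all-OOV document maps to the zero vector, which every classifier
handles (it scores as the bias-only prediction).

## Classification and alternative integration strategies

One-vs-rest linear SVM: hinge loss with squared-norm penalty, C = 1
(the conventional default for L2-normalized TF-IDF text; the package
warns when C leaves the usual grid {0.001, …, 100}). The liblinear
dual solver is seeded, with tolerance 1e-4 and a 10,000-iteration cap,
so training is deterministic on fixed input. Decision scores are used
raw for ranking — no probability calibration; "most probable" is read
as score order. Exact score ties rank lexicographically.

*Late fusion* combines the label rankings of a BOW model and a
knowledge-only model by Borda count: a label at 1-based rank r in a
list of L earns L − r points; ties go to the label ranked better in
the first (BOW) list, then lexicographic. Pure rank points are used —
no mixing with decision confidences. *Upsampling* resamples every class
with replacement to the majority size (originals retained, duplicates
suffixed). *Pseudo-document (rationale) augmentation* appends, per
training document with at least one knowledge token, a same-labeled
document containing exactly its knowledge tokens; this is one fixed,
documented variant of rationale-based augmentation, and it reproduces
the strategy's characteristic failure: large classes generate
proportionally more pseudo documents, widening the imbalance.
Upsampled or augmented corpora refit the TF-IDF statistics — the
augmented corpus *is* that arm's training set.

## Evaluation harness

Macro-F1 is the unweighted mean of per-class F1 from global confusion
counts (a prediction onto any trained class can create false positives
for a reported class); zero-denominator classes contribute F1 = 0, and
subset classes with no test documents are excluded with a warning.
MRR averages 1/rank of the true label over test documents whose true
class is in the reported bin. Both are reported ×100.

Significance against the baseline uses a paired randomization test:
each round independently swaps each document's paired outcomes with
probability ½ and recomputes the metric difference; two-sided
p = (#{|Δ_perm| ≥ |Δ_obs|} + 1)/(rounds + 1). The swapped unit is the
per-document outcome — the predicted label for macro-F1, the
reciprocal rank for MRR — pooled across runs, giving one p per
(method, bin, metric). The standalone operation defaults to 10,000
rounds; the experiment driver uses 2,000 per cell (the Monte-Carlo
standard error at p ≈ 0.05 is then ~0.005, ample for a 0.05 threshold),
and `rand_rounds=0` skips significance entirely. No multiple-testing
correction is applied across cells, matching the per-cell star
convention of standard comparison tables.

The experiment driver re-splits per run (seed = base_seed + run),
re-assembles knowledge features from each run's training split (K₂
depends on training documents), trains every method on all classes,
and averages per-bin metrics over runs. Reports serialize to TSV and
JSON with fixed float formatting, so a fixed base seed yields
byte-identical files.

## Synthetic benchmark

The generator emulates the statistical shape of a real diagnosis
corpus, not its semantics. Defaults (the package's study conditions):
60 classes, 8,000 documents, Zipf exponent 2.0, 10 class-exclusive
signal words per class, 2,000 shared background words, mean document
length 28 tokens with ±20% uniform jitter (mimicking short clinical
narratives of ~27–30 words), signal rate 0.3, KG coverage 0.9 with
signal recall 0.9 and 5 background distractor words per entity, 20
irrelevant non-medical entities plus one non-medical alias collision.
Class sizes use largest-remainder apportionment of the Zipf weights
(every class ≥ 1 document, counts sum exactly, monotone in rank). The
exponent 2.0 makes the default benchmark populate all five prevalence
bins with at least three classes (a heavier tail than exponent ~1 seen
in practice, needed because desk-scale corpora would otherwise contain
no class below 0.1%). Uncovered classes receive a "related condition"
entity reachable only through the surrogate path, so K₂ is exercised
at sub-unit coverage.

What the generator does **not** model: overlapping symptom vocabulary
across diseases (signal words are class-exclusive to make ground truth
unambiguous), polysemy, word burstiness, document structure, or any
real KG schema. Consequently absolute scores are far higher than on
real clinical text — common classes saturate near 100 — and passing
tests demonstrate the *mechanism* (knowledge emphasis helps exactly
where training data is scarce; noisy knowledge is bounded in its harm;
more coverage helps) rather than clinical-grade accuracy. The
rare-bin rows, where classes have 1–8 documents, are the informative
ones.

## Numerical and degenerate-input choices

* Zero vectors are left as zeros rather than normalized (0/0 guards).
* χ² requires ≥ 2 classes; terms present in every or no document score 0.
* Randomization test of a system against itself returns exactly 1.0
  (every permuted |Δ| = 0 ≥ |Δ_obs| = 0).
* All RNG flows through `numpy.random.default_rng` with explicit seeds;
  derived seeds stay below 2³¹.
* Model archives are versioned `.npz` files with the feature-space
  sidecar and a config snapshot; the loader rejects unknown versions.

## Known limitations

* Entity linking is exact-alias only; classes whose names differ from
  every alias (misspellings, abbreviations) fall to the surrogate path
  even when the right entity exists.
* The surrogate path assumes the KG contains *something* topically
  related; with a wholly unrelated store K₂ is empty and the method
  degrades gracefully to BOW.
* With a pure-noise KG the emphasized random words can cost rare-bin
  macro-F1 a few points relative to BOW (the bow segment bounds the
  damage, but does not eliminate it); see the noise arm of
  `scripts/acceptance.py` for the measured effect.
* Deep/dense representations are out of scope: at these class sizes
  they underperform sparse linear models and need resources this
  package deliberately avoids.
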