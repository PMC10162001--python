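# Methods

## Model and assumptions

`rarephen` treats rare-disease phenotyping as a filtering problem over
candidate mention–UMLS links emitted by an upstream NER+L tool. The
assumptions the method rests on:

1. The candidate generator has (near-)perfect recall over the rare-disease
   concepts it knows: every true mention appears among the candidates, so
   the task is precision recovery. Evaluation is therefore closed-world
   over a labelled candidate set by default; an open-world mode exists for
   gold mentions found outside the candidate set.
2. False candidates are dominated by short ambiguous abbreviations linked
   by a most-frequent-sense prior, and by common disorders reached through
   over-broad ontology cross-references.
3. The true sense of an ambiguous mention is recoverable from its local
   context (nearby words, note section), so a linear classifier over a
   contextual mention representation can separate senses.
4. Rare-disease concepts are individually infrequent in a consecutive
   sample of notes, so corpus-level concept frequency is an informative
   (if noisy) proxy for "is actually a rare disease here".

## Weak labelling

λ₁ holds when `m_end − m_start > l` (default `l = 3`); λ₂ holds when
`Freq(c)/|L| < p` (default `p = 0.005`). Both inequalities are strict,
read literally from their definitions. Frequencies are computed once over
the full rare-restricted candidate list of the corpus, not per document.
Selection is XNOR (keep only links where λ₁ = λ₂), labelling is AND. The
rules-only baseline classifier exposed for comparison predicts positive
under OR — a deliberately different aggregation, implemented and named
separately (`rules_or_predict`).

Grid search over (l, p) scores the rules-only classifier against gold
labels. Ties break toward higher recall, then larger `p`, then smaller
`l`, then grid order — deterministic and recall-biased, since in this
screening application a missed phenotype is costlier than a false alarm.

## Representation

Encoder backends return a layer stack with per-token character offsets.
The feature layer defaults to the second-to-last of the stack: the top
layer of a masked-language model is biased toward its pre-training
objective, the layer beneath carries the more transferable contextual
signal. Mention/token alignment uses *overlap*, not containment, because
subword tokenizers can merge a mention boundary into a neighbouring
token, and containment would then produce an empty range. Pooling is the
arithmetic mean of the selected layer's rows over the inclusive token
range.

Two encoding strategies are available: prepending the note-section name
(`"<section>: <context>"`, the `": "` delimiter isolated in one constant)
and masking the mention with the backend's native mask token. The default
is non-masked with sections included. Inputs longer than a backend's token
limit are truncated symmetrically around the mention.

## Confirmation model

Logistic regression with an explicitly pinned "default" configuration: L2
penalty, inverse regularisation strength C = 1.0, tolerance 1e-4, at most
100 lbfgs iterations, fixed seed. These are recorded in `train_meta` so a
serialised model documents its own fit. Training data are subsampled
uniformly without replacement to n = 9,000 labelled pairs (larger pools
add little). The decision rule is `p ≥ threshold` with threshold 0.5 —
ties go to positive, again recall-biased; the threshold is a parameter
since no canonical value exists. Inference uses the closed-form sigmoid on
the stored weights, so models serialise to plain JSON and do not depend on
the fitting library at prediction time; a test cross-checks the
probabilities against the library fit.

Strong supervision (manually labelled pairs) reuses the same fit; only the
recorded provenance differs.

## Ontology maps

UMLS→ORDO uses only E (exact) and BTNT (broader-to-narrower) cross-
references, so the external target is itself a rare disease; NTBT targets
are broader, usually common, disorders and are excluded. Concepts under
the "group of disorders" phenome class are removed by default (their UMLS
cross-references are typically common-disease umbrellas). The map is
set-valued: when one UMLS concept has several admissible ORDO targets all
are kept, since no principled precedence exists between an E and a BTNT
row. Cross-references whose ORDO id lacks a metadata row are dropped and
counted — fail-safe toward precision. The ICD-9→ORDO baseline map is the
union of two composition paths (ICD-9→ICD-10→ORDO and ICD-9→UMLS→ORDO)
with per-entry provenance.

Identifier normalisation: whitespace trimmed, UMLS ids upper-cased, ORDO
ids kept as `Orphanet_<digits>`, ICD codes verbatim including the dot.
Ingestion is preprocessed TSV; converting OWL/RRF distributions to these
tables is an upstream concern.

## Pipeline conventions

Links flagged upstream as hypothetical/negated/other-experiencer are
carried on every record but never computed here; they are dropped before
training and inference by default (switchable for ablation). One confirmed
mention suffices to assign an admission-level phenotype. Documents without
an admission row form singleton admissions keyed by their own id.
Per-concept supporting links with probabilities are retained in the output
to seed manual review.

## Synthetic corpora

The generator emulates exactly the structure the method assumes — and
nothing more. Documents are sequences of named sections filled with neutral
filler sentences; mentions are inserted with per-concept target
frequencies (allocated by largest remainder, so realised frequencies track
targets up to rounding); each ambiguous-abbreviation occurrence samples a
sense and injects that sense's cue pseudo-words into the surrounding
window with probability `cue_strength` (default 1.0); true-phenotype
mentions sit in shared diagnosis-style frames, non-phenotype mentions in
procedure/medication-style frames; negated occurrences use negation frames
and are flagged (default `negation_rate` 0); admissions group 1–3
documents; ICD-9 lists contain the codes of truly present phenotypes with
each omitted at `icd_undercoding_rate` (default 0.5), plus unmapped
distractor codes. Cue vocabularies are disjoint across senses — sense is a
linear function of the bag of neighbouring tokens, the minimal structure a
mean-pooled contextual vector plus logistic regression can provably learn.
All randomness flows from one seeded generator; equal configs give
byte-identical corpora.

The **standard** fixture (1,000 documents, ~6,000 candidate links) has 150
long rare concepts at ≈0.33% of candidates each (below the 0.5% prevalence
threshold), two high-frequency ambiguous abbreviations (24% and 15% of
candidates, 8% true-disease sense), one long common concept falsely
cross-referenced to a rare target, one "group of disorders" trap concept
and one NTBT-only trap relation, and one low-frequency short abbreviation
so that both "unseen" strata are populated. The **tiny** fixture (20
documents) serves unit tests and exercises negation flags.

What passing on these corpora shows: the XNOR/AND machinery, the span
arithmetic, the map filtering and the learning loop behave exactly as
specified when the assumptions hold perfectly. What it does not show:
robustness to real clinical language — spelling variation, cue words
shared across senses, negation *detection* (out of scope; flags are assumed
given), or an encoder whose geometry differs from the stub's.

The stub encoder is deterministic by construction: per-token unit vectors
derived from a cryptographic hash of the token (dimension 64), a
context-mixing layer H¹ blending each token with half the mean of its
neighbours within five tokens, and a top layer H² that is a fixed
orthogonal rotation of H¹ so that layer selection is observable in tests.

## Numerical and design choices

* Offsets are 0-based, end-exclusive, in Unicode code points.
* Gazetteer word boundary = alphanumeric/non-alphanumeric transition;
  matching is longest-first, left-to-right, non-overlapping.
* Metrics use the 0-denominator convention (P, R, F1 = 0) and round
  half-up to one decimal only at the reporting boundary.
* Fleiss' and Cohen's kappa are both provided for multi-rater agreement,
  since the choice between them is a protocol detail.
* Sense-recovery (parameter-recovery) experiments use balanced senses of
  one ambiguous abbreviation: with a heavily skewed sense prior, held-out
  accuracy measures the prior rather than the cue signal, which is the
  quantity of interest.
* The end-to-end benefit is measured on the standard fixture with the
  default rule thresholds and encoder strategy; problem sizes (1,000
  documents, n = 9,000 training cap, 200-document sense corpora, 1,000
  randomised lists for the labelling oracle) were chosen as the smallest
  scales at which the corpus statistics are stable.

## Known limitations

* The generator's cue structure makes senses linearly separable by design;
  real abbreviation disambiguation is harder, and the reported synthetic
  precision/recall gains are an existence proof of the mechanism, not a
  clinical performance estimate.
* The ontology stage trusts its input tables; no OWL reasoning or
  hierarchy traversal is performed, and ORDO concepts lacking both UMLS
  and ICD-10 links are out of scope.
* Negation/experiencer detection is assumed upstream; only the flag is
  honoured.
* The pretrained-transformer backend is a thin adapter and is not
  exercised by the test suite (the deterministic stub is).
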