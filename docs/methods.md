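# Methods

## The problem and the model

Dictionary-based NER taggers look up typed names (genes or gene products
`ggp`, chemicals `che`, diseases `dis`, species `org`) in text and
normalize them to database identifiers. Their dominant error mode is not
the matching itself but ambiguous dictionary names: English words, symbols
and cross-type homonyms generate false positives at scale. `nerblock`
treats block-list construction as a classification-and-aggregation
problem: learn what the textual *context* of each entity type looks like,
score every tagger match by how badly its context fits its assigned type,
and promote names whose contexts consistently misfit to a block list.

### Matching model

Names are indexed by a normalized key — casefolded, with all space and
hyphen characters removed. The elastic character sets are ASCII space,
no-break space (U+00A0), hyphen-minus, Unicode hyphen (U+2010) and en-dash
(U+2013); published full text contains all of them. Offsets are 0-based,
half-open, in Unicode code points. A candidate span must start and end on
a letter-or-digit and be delimited by non-alphanumeric characters or the
string boundary; adjacent punctuation is tolerated but never captured.
Among overlapping candidates the longest wins, ties broken leftmost, and
no nested matches are emitted — the common dictionary-tagger policy,
chosen here as an explicit tie-break because elastic matching otherwise
leaves the overlap semantics open. When one name maps to entries of
several types, the fixed trust hierarchy dis > org > ggp > che resolves
the clash (so "NO" tags as a gene, not a chemical, unless filtered).

List semantics are deliberately asymmetric to matching: list entries apply
*case-sensitively* to the exact surface form, so blocking "bad" leaves
"BAD" untouched. Decision precedence per (surface, document) is
local-curated > local-auto > global-curated-allow > global-curated-block >
global-auto-allow > global-auto-block > keep. A conflicting allow+block
pair at the same local level is a configuration error; at the global level
allow outranks block of equal provenance, which is what lets a curated
allow protect a name against automatic blocking mistakes. The tagger's
built-in regular-expression pre-filters are represented by one optional
user-supplied pattern file applied as a full-surface match; passing none
reproduces the no-block-list configuration.

### Consensus training set

Positive examples are spans on which three independent annotation sources
agree on exact character boundaries and entity type. Exactness is a
precision device: partial overlaps and type disagreements are discarded,
and any location that even a single source tagged with a positive type is
barred from the negative pool. Negatives come from noun-phrase candidates
in the untagged remainder. Because no installed dependency provides a
parser, the default chunker is a POS-light heuristic behind a pluggable
interface: maximal runs of non-function-word tokens, with the head taken
as the rightmost token before the first post-modifying preposition
("inhibitor of kinases" → "inhibitor"). Heads on a configurable filter
list — pronouns, number words, and generic type-level terms such as
"protein" or "cytokine" — are removed, since such phrases can refer to
true entities whose contexts would poison the negative class. The shipped
filter list is a seed; production use should extend it.

Context windows keep up to 100 whitespace-delimited words on each side of
the mention ("word" = maximal non-whitespace run; windows never cross
document boundaries; sentence boundaries are ignored). Exactly the focal
span is replaced by a single mask token (default `[MASK]`), and the
construction is reversible: substituting the surface back reproduces the
original window text byte-for-byte, which the tests assert. Dataset
assembly draws requested per-class counts without replacement, splits
80/10/10 into train/dev/test by default, and is byte-reproducible from the
seed.

### Classifier

Two backends share the predict-probabilities interface, with the label
order fixed as (ggp, che, dis, org, neg):

* The **reference backend** hashes words into 2^18 features
  (`HashingVectorizer`, non-negative, L2-normalized) and fits multinomial
  logistic regression (lbfgs, C=10, up to 1000 iterations). It is
  deterministic given the seed (which controls example order), trains in
  seconds on desk-scale data, and is what every test and example uses. On
  the separable synthetic benchmark (disjoint per-class vocabularies, 200
  examples per class) it reaches micro-F1 ≥ 0.99; trained on
  label-shuffled data it stays at chance (≈ 0.2), which guards against
  label leakage through the pipeline.
* The **transformer harness** carries the configuration for fine-tuning a
  pretrained biomedical BERT-style masked-language model and raises a
  clear error unless the `transformers`/`torch` stack is installed.
  Full-scale fine-tuning is a GPU-scale job and intentionally not bundled;
  the downstream aggregation only requires *some* probabilistic scorer.

Default hyperparameters are the selected values: learning rate 2e-5,
batch size 32, one epoch, maximum sequence length 256, 200-word context.
`hyperparameter_grid()` enumerates the full selection grid (learning rates
5e-5…5e-6 × batch 32/64 × 2–4 epochs, 30 configurations). Inputs longer
than the maximum sequence length are truncated symmetrically around the
mask token. Micro-averaged F1 over all five labels equals accuracy in this
single-label setting and is reported as the model metric.

### Aggregation and list generation

For a match assigned class C, P(¬C) = 1 − p(C) is the probability mass on
the other four classes including `neg`. Aggregation is a two-stage
unweighted mean: over a name's mentions within each document, then over
documents — documents count equally however many mentions they contain,
reflecting the assumption that repeated mentions within one document are
correlated while documents are independent. Means use compensated
summation so results are exactly invariant to input order. Name identity
is the case-preserved surface form, matching the case-sensitive list
semantics; the same surface under different resolved classes aggregates
separately per (name, class).

Global blocking requires the class threshold (0.5 for ggp/che/org, 0.85
for dis — diseases need stronger evidence because their baseline precision
is already high) *and* presence in at least two distinct documents, so a
single strange document cannot globally block a name. Comparisons are
inclusive (≥); the output is ranked by descending score so thresholds can
be chosen by inspecting the list.

Local decisions combine global and local class odds:

    ratio_allow = [P(C|N)·P(C|L)] / [P(¬C|N)·P(¬C|L)]

with P(C|N) = 1 − global P(¬C) and P(C|L) = 1 − document-level P(¬C). The
block direction swaps C and ¬C (the exact algebraic form of the block
ratio is a design choice here: the reciprocal, so the two directions
multiply to 1). Local blocks are emitted for ggp and che at ratio ≥ 10³
(list quality for dis/org does not support local decisions); local allows
only for ggp names already on the automatic global list, at ratio ≥ 10¹⁵ —
document evidence must overwhelm a confident global block.

Numerics: the ratio is computed in log space. Each probability and its
complement are floored at ε = 10⁻³⁰ before taking logs; ε exists solely to
keep log(0) finite, and it must sit far below 1/10¹⁵, because a globally
blocked name has global odds ≤ 1 and the allow cutoff can then only be
cleared through the local factor — with a larger floor (say 10⁻¹²) the
local odds would cap at 10¹² and the allow list would be structurally
empty. Complements are floored separately rather than computed from
clipped probabilities because 1 − 10⁻³⁰ is not representable in double
precision.

### Evaluation calculus

With A audited matches per class at curated-lists precision
prec_curated, class block rate x (fraction of matches removed by adding
the automatic lists), and blocking precision prec_blocking (fraction of
removed matches that were false positives), the removed mass A·x splits
into TP_w = A·x·(1 − prec_blocking) wrongly removed and FP_w =
A·x·prec_blocking correctly removed; post-blocking precision and the
relative recall change follow by subtraction. The identity TP_w + FP_w =
A·x and the sign/zero conditions of rec_diff (zero iff nothing is removed
or blocking is perfect) are asserted over a parameter grid. A is a
parameter, not a constant, and a block rate implying more removals than
the sample holds raises an inconsistency error. Reported percentages are
rounded half-away-from-zero to one decimal for display; raw fractions are
preserved.

Co-occurrence evaluation ranks unordered identifier pairs co-mentioned in
documents. The default score is the raw co-mentioning document count; the
significance scoring used by production relation-extraction pipelines is a
pluggable hook, not reimplemented here. Pairs absent from the gold
standard are skipped, not counted as false positives, so the cumulative
TP/FP curve is invariant to appending unjudged pairs.

## Synthetic data: what it emulates and what it does not

The fixtures module plants names into documents whose surrounding words
are drawn from disjoint per-class vocabulary pools. A name's ambiguity
rate q is the probability that a given mention's context is drawn from a
*different* class's pool — the synthetic analogue of "NO" (gene vs the
chemical nitric oxide) or "wingless" (protein vs literal usage). Defaults:
200 documents, one mention of each of six planted names per document
(four clean names at q = 0.05, two problem names at q = 0.9), eight
context words per side, with mention blocks separated by periods and a
mention-free negative-class block closing each document so noun-phrase
negatives exist. Pseudo-tool annotation sets reproduce each true span with
an agreement probability a (default 0.8 per source) and otherwise drop it
or shift one boundary by one word, exercising the exact-boundary rule;
with independent sources the expected consensus recovery is a³, which the
tests check within three binomial standard deviations at n ≥ 1000 spans.
The mock scorer gives the contextual class probability f (fidelity) and
spreads the rest uniformly, making aggregate scores analytically
predictable: a q = 0.9 name at f = 0.99 has expected global P(¬C) ≈
0.9·0.9975 + 0.1·0.01 ≈ 0.9, safely past the 0.5 threshold, while a
q = 0.05 name sits near 0.06.

Disjoint vocabularies make the classification task well-posed and the
expected scores computable, but they are far easier than real biomedical
prose: real contexts share vocabulary across classes, negatives are not
cleanly separable, and real NER tools disagree systematically rather than
independently. Passing the synthetic end-to-end test therefore
demonstrates that the machinery — matching, consensus, scoring,
aggregation, thresholding — composes correctly, not that the reference
classifier would reach any particular accuracy on literature text.

## Problem sizes

Tests run the reference classifier on 1000-example synthetic sets,
matcher/oracle equivalence on 500 random instances of ≤ ~200 characters
with ≤ 10-name dictionaries, consensus statistics on ~1000 planted spans,
and the end-to-end recovery on 200 documents; the whole suite completes in
about a minute on one CPU. The acceptance script is closed-form arithmetic
over the published audit inputs and runs in well under a second.

## Known limitations

* The noun-phrase chunker and head heuristic are POS-light stand-ins; on
  real text a parser-based chunker (pluggable) would produce cleaner
  negative candidates, and the shipped head-filter list is a seed, not the
  full curated list.
* The transformer backend is an interface; no pretrained weights ship.
* Byte-level throughput was a non-goal: the matcher is a transparent
  reference implementation, not a speed-optimized engine.
* Threshold auto-tuning is out of scope by design — thresholds were chosen
  upstream by inspecting ranked name lists, and the ranked list is exposed
  for exactly that purpose.
* Whether the ≥ 2-document rule should count documents or mentions is
  ambiguous in prose; this implementation requires two distinct documents
  with at least one mention each.
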