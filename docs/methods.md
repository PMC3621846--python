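# Methods

## Problem and approach

The task is record linkage between two large, frequently updated string
collections: long forms (LFs) of biomedical abbreviations, each with an
occurrence frequency in the literature, and encyclopedia entry titles
with resource IRIs. Accepted pairs are published as `owl:sameAs`
triples. Because both collections run into the millions, matching is
done by key collision — canonicalise each string once, then hash-join on
the keys — rather than by any pairwise similarity measure.

## Keying

The **fingerprint** key applies, in order: trim, lowercase, removal of
all Unicode punctuation (categories `P*`) and control/format characters
(`C*`), ASCII transliteration (NFKD decomposition, combining marks
dropped), whitespace-run splitting, lexicographic token sort, duplicate
removal, and a single-space join. The **n-gram fingerprint** key
removes whitespace as well and uses the sorted, de-duplicated set of
character n-grams of the cleaned string; n = 2 by default. Both keys
are pure functions of their input, so key equality is an equivalence
relation and linking is deterministic.

Numerical/edge choices:

* A cleaned string shorter than n keys to itself, not to the empty
  string; otherwise all very short strings would mutually collide.
* Digits are retained. Roman-numeral-style suffixes ("polymerase II")
  and alphanumeric designations ("P450 1A1") must stay distinctive.
* Transliteration is a convention choice: whether to fold accents
  before keying is genuinely open, and we fold them so that "Café" and
  "Cafe" collide. Anyone comparing against a link set produced with
  unfolded keys should disable nothing — the keys simply differ for the
  small accented minority.
* Token de-duplication means a doubled token collapses: *mitogen-
  activated protein kinase kinase* and the normalised *mitogen-activated
  protein kinases* share a fingerprint key. This is a known,
  documented false-positive mode of the method, and the matcher
  reproduces it on purpose; the evaluator then counts it against
  precision.

## Normalisation

The lexicon is a two-column TSV of (variant, base form) pairs standing
in for the licence-restricted UMLS SPECIALIST Lexicon files. Chains
(a→b, b→c) are resolved to their terminal base at load time; cycles,
self-maps and conflicting duplicates are load errors, so lookup is a
single dictionary access and `normalise_term` is idempotent.

Normalisation is whole-string first, then token-by-token: whole-string
replacement handles multi-word variants exactly; token-level fallback is
what makes the plural-title/doubled-token collision above possible, and
matches how inflection tables are actually keyed (per word). Lookup is
case-insensitive; replacement uses the base form's stored casing, which
is irrelevant downstream because keying lowercases. Both the titles and
the LFs are normalised when a lexicon is supplied (the index normalises
labels at build time, queries at match time); matching without a lexicon
is the switch for normalisation-off.

## Link selection

Each LF receives at most one link. Within a key bucket, and between the
two keyers' winners under the combined method, the tie-break is: shorter
label, then upper-case ratio closest to the LF's, then lexicographically
smallest label. The case ratio is defined as uppercase letters over
alphabetic letters — a proportion rather than an upper:lower quotient,
which is undefined for all-caps strings; on strings where both are
defined they induce the same ordering. The exact-match baseline is
verbatim, case-sensitive string equality (on normalised strings when a
lexicon is active); anything looser would itself be a keying method.

## Binning and regression

Frequency bins: [10,49], [50,99], then [100,199] … [900,999], and
[1000,∞), numbered 1–12. Frequencies below 10 are outside the scheme
(short-tail extractions are noisy, so the pipeline's default threshold
is 10, applied upstream of linking). Because bins 1–2 have different
widths from bins 3–11, they are averaged into a single point and the
bins renumbered x = 0..10 before regression.

The regression is ordinary least squares of −ln(1−y) on x, with y the
per-bin link ratio. Natural log is the canonical transform (the model's
inverse form is the exponential decay 1−y = exp(−(a·x+b))). The fit is
unweighted by default — "simple" linear regression — although bin
populations differ by orders of magnitude; a population-weighted WLS
variant is available behind `--weighted`/the `weights` argument.
Reported alongside slope and intercept are r², the slope's standard
error and its two-sided t-test p-value. Degenerate inputs: any y ≥ 1
is an error (the transform diverges — a saturated bin carries no
information about absence); a perfectly constant response returns slope
0, r² = 0, p = 1 rather than the 0/0 that centred-total-sum-of-squares
formulas produce; fewer than 3 points is an error.

## Synthetic corpora

The generator emulates the joint structure the pipeline is sensitive
to, with known ground truth:

* **Concepts** are multi-token pseudo-terms from a syllable vocabulary,
  constructed so that no two concepts share a fingerprint or bigram
  fingerprint key and no distractor title collides with any LF under
  either keyer. Consequently every false negative and false positive
  against the gold standard is attributable to a variant operator, not
  to vocabulary coincidence.
* **Variant operators** span the classes seen in real LF/title pairs:
  identical copy, case flips, token reorder, hyphenation changes,
  inflection (covered by the generated lexicon), additive head nouns
  ("… syndrome"), abbreviation substitution (initialisms), and synonym
  swaps. The first five are exactly recoverable by the combined
  matcher (the contract the tests assert); the last three are not
  recoverable by string keys at all.
* **Default mix**: 70 % recoverable variants (25 % identical, 15 % each
  case/reorder/punctuation, 10 % inflection) and 20 % hard classes
  (8 % additive, 7 % abbreviation, 5 % synonym). Real evaluations find
  high combined F with residual errors dominated by the hard classes;
  the default mix reproduces that regime while leaving every stratum
  populated at moderate corpus sizes.
* **Frequencies** are discretised Pareto (α = 0.8) on [10, 5000] by
  default, giving the sharply decreasing bin occupancies seen in real
  MEDLINE frequency tables. A `stratified` sampler (equal occupancy
  per bin, uniform within each bin's range) exists for regression
  validation, where the Pareto tail would leave upper bins with a
  handful of LFs and saturated ratios.
* **Presence** of a title for a concept is Bernoulli with probability
  y(x) = 1 − exp(−(a·x + b)) at the LF's merged bin x, defaults
  a = 0.2, b = 0.92, so the full binning → merging → regression path
  can be checked against the generating coefficients.
* All randomness flows from one integer seed through a single PRNG;
  equal seeds give byte-identical corpus files.

What the generator does **not** emulate: real orthography and
morphology (tokens are synthetic syllable words), polysemy (no two
concepts share a surface form), noisy abbreviation extraction, or the
true prevalence of each variant class. Passing tests therefore
demonstrate the correctness of the machinery and its invariances — not
the field performance of the method on real LF/title collections, which
depends on the actual variant distribution.

## Evaluation conventions

Against a gold link set: a linked LF whose accepted title is its gold
title is a true positive; any other accepted link is a false positive;
an unlinked LF that has a gold title is a false negative; unlinked LFs
without gold titles are true negatives and do not enter precision or
recall. An LF linked to the wrong title counts once, as a false
positive. Precision = tp/(tp+fp), recall = tp/(tp+fn), F is their
harmonic mean; zero denominators raise explicit degenerate-count errors
rather than returning conventional zeros.

## Problem sizes

The shipped validation runs use corpora of 150–2,000 concepts for
matching contracts, 6,000 stratified concepts (≈500 LFs per bin) for
pipeline regression recovery, and 200 Monte-Carlo replicates of 11
binomial bin ratios at 500 LFs per bin for slope-CI coverage. These
sizes put binomial sampling error well below the effects being checked
while keeping the whole suite and the acceptance script within seconds.

## Known limitations

* Additive-term, abbreviation/LF and synonym variant pairs are beyond
  key collision by design; resolving them needs external resources
  (an additive-term dictionary, an abbreviation dictionary, redirect or
  disambiguation links), which are out of scope here.
* One link per LF: the pipeline never emits multiple simultaneous
  links, even when several titles share a key; the tie-break picks one.
* The N-Triples reader accepts any predicate whose object is a
  language-tagged literal; files mixing label predicates with other
  literal-valued predicates should be pre-filtered.
* Untagged literals are excluded by default when a language filter is
  active (encyclopedia label dumps tag their literals); pass
  `include_untagged=True` or `language=None` to widen.
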