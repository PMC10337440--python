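# Methods

## The annotation task

The pipeline emulates, with deterministic rules, the decisions a human
annotator makes when labelling pain mentions in mental-health case
notes. A *mention* is a single token matched by a pain lexicon; each
mention receives five nominal attributes:

| attribute  | values | meaning |
|---|---|---|
| correct    | yes / no | genuine medical mention vs lexical false positive |
| relevance  | relevant / negated / not_relevant / n/a | patient's own physical pain; explicit absence; other experiencer, metaphor, hypothetical, uncertain |
| anatomy    | mentioned / n/a (+ normalized location) | a body part is referenced |
| character  | chronic / other / n/a | "chronic" only when the word is explicit |
| management | medication / other / n/a | co-mentioned treatment |

Structural invariants: `correct = no` forces the other four attributes
to n/a; `anatomy = mentioned` iff a location is attached. Attributes
are computed for *all* correct mentions, negated ones included — a
negated mention such as "He is not on painkillers" legitimately
carries management = medication.

## Wildcard matching

Lexicon patterns carry at most one leading and one trailing `%`; a `%`
matches zero or more alphabetic characters *within one token*.
Matching is case-insensitive and anchored at any end without a
wildcard. Tokens are maximal runs of alphabetic characters — digits
and hyphens separate tokens, so `e-pain` and `pain123` each contain the
token `pain`. When several patterns match one token, the pattern with
the longest literal (non-`%`) part wins; ties break alphabetically by
raw pattern. Known false-positive surfaces (*paint*, *painted*,
*Spain*, *attaches* ...) are **flagged, not dropped**, at match time;
the correctness rule rejects them later. This mirrors a workflow in
which over-general patterns are accepted at extraction and cleaned
during review, and it keeps the matcher a pure function of the text.

Offsets are 0-based half-open throughout; every emitted span slices
back to its surface, which is property-tested on random documents.

## Context and rules

Annotators judge a mention from its surrounding sentence. The context
window is the containing sentence — boundaries are `. `, `! ` or `? `
followed by whitespace and a capital, or a newline — capped at 300
characters on each side of the mention. The cap bounds work on
pathological unbroken lines; clinical sentences are far shorter.

Relevance rules apply in a fixed precedence, each deterministic and
gazetteer-driven:

1. **uncertainty** — `?` immediately adjacent to the mention token
   (before or after, whitespace ignored) → not_relevant;
2. **experiencer** — a third-person trigger (mother, wife, carer,
   staff ...) occurring before the mention inside the window →
   not_relevant. This positional approximation replaces syntactic
   attachment; it is deterministic and desk-scale, and it resolves
   every guideline example correctly, at the cost of occasionally
   over-firing when a relative is mentioned earlier in the same
   sentence for other reasons;
3. **hypothetical / metaphor** — triggers (*fear of*, *afraid*, *if*,
   *would be*, *in case*, *risk of*, *sore thumb*, *worried about*)
   anywhere in the window → not_relevant;
4. **negation** — a trigger (*no*, *not*, *denies*, *denied*,
   *without*, *nil*, *does not complain*) within **6 tokens before**
   the mention, or the frames "no X reported" / "X free" → negated.
   Six preceding tokens is the conventional clinical-negation scope;
   it is configurable (`RuleGazetteers.negation_window`);
5. otherwise **relevant**.

The precedence order itself is a design choice — the category
definitions do not prescribe one — fixed so that uncertain mentions
("?migraine") never count as negated even when a negation trigger is
also present.

Anatomy fires when the mention surface itself encodes a location
(headache → head, backache → back, heartburn → chest) or an anatomy
term occurs within 3 tokens of the mention; abdominal and pelvic terms
normalize to "abdomen". The normalized location vocabulary beyond the
five most frequent regions (chest, head, back, abdomen, neck) is an
extrapolation and easily edited in the gazetteer config.

Character is *chronic* only on a literal "chronic" within 3 tokens
before the mention — "ongoing back pain" is deliberately inconclusive
and stays n/a — *other* on any nearby descriptor (severe, constant,
throbbing, burning, neuropathic — with "uropathic" also present as a
variant spelling of uncertain provenance), with "period pain" as a
special case labelled other. Management prefers medication triggers
(painkillers, analgesia, paracetamol ...) over non-drug measures
(physiotherapy, pain clinic, massage).

Emotional-pain mentions ("causing her a lot of pain" in a relationship
context) are approximated only insofar as the hypothetical/experiencer
triggers catch them; a full physical/emotional distinction needs more
context than these rules see, and this is a known limitation.

## Agreement and adjudication

Cohen's κ = (p_o − p_e)/(1 − p_e) with p_e computed from the two
annotators' marginal distributions; unweighted, since all attributes
are nominal. The degenerate case p_e = 1 (both annotators constant on
the same category) is handled explicitly: κ = 1 when agreement is
perfect, otherwise a `KappaUndefinedError` — never a silent
floating-point accident. Because "overall agreement" is ambiguous, the
report emits both variants, labelled: per-mention (full label tuple as
one item) and pooled over all labels.

Adjudication keeps agreed labels and resolves disagreements by
re-applying the codified guideline rules to the mention's own context;
every decision is logged with both inputs and the resolution source.

## The synthetic generator

Shareable stand-in for a non-shareable clinical corpus. Defaults are
the emulated corpus's published shape:

| parameter | default | note |
|---|---|---|
| words per document (mean) | 1026 | long case notes / correspondence |
| mentions per document | truncated geometric, mean 3, max 84 | |
| documents per patient | truncated geometric, mean 2.75 | ≈ 1985 docs / 723 patients |
| relevance mix | 4028 : 859 : 757 (≈ 71/15/13%) | stored as exact count ratios so mixtures sum to 1 |
| anatomy rate (given relevant) | 2540/4028 ≈ 0.63 | |
| character mix | 157 : 487 : 5000 (≈ 3/8/89%) | sampled per correct mention |
| management mix | 422 : 188 : 5034 (≈ 7/3/89%) | sampled per correct mention |
| location weights | chest .30, head .25, back .20, abdomen .15, neck .10 | published as a ranking only; weights chosen to preserve the order with realistic separation |
| incorrect rate | 0.05 | the true false-positive fraction is unpublished; this is an explicit, arbitrary default |

Character and management mixes are sampled for every *correct* mention
(relevant, negated and not-relevant alike), so empirical gold
frequencies over correct mentions converge to the configured values;
published percentages use all annotations as denominator, which
coincides up to the incorrect fraction. Anatomy is sampled only for
relevant mentions. Diagnosis-chapter and demographic metadata are
sampled from the published distributions but are decorative — no rule
consults them.

Documents are assembled from a template bank: neutral filler sentences
(verified lexicon-silent by a test) interleaved with mention-bearing
sentences rendered from the sampled labels — negation frames
("reports no ...", "denies any ...", "There is no ... reported"),
experiencer frames ("His mother has ..."), hypothetical frames
("afraid of ...", "risk of ..."), question-mark frames ("query ...?"),
and slots for descriptor, location and management clauses. Management
phrases in templates avoid words that are themselves lexicon matches,
so gold mentions align one-to-one with extractor output. The generator
and the annotator share no code: end-to-end label recovery (≥ 95%
required, ~100% observed) is a genuine check of both.

What the generator does **not** emulate: real lexical variety,
misspellings, de-identification artifacts, rule-uncovered phrasings of
negation or experiencer, and emotional-pain ambiguity. Passing tests
on synthetic corpora therefore validate the pipeline's mechanics and
its agreement with the codified guidelines — not clinical
performance on real notes, which must be measured against human
annotation.

## Sample size

n = ⌈z²·p(1−p)/(d²·prevalence)⌉: the standard single-proportion form
for the sensitivity of a class detector, with z the two-sided normal
quantile of the stated confidence, p the expected sensitivity, d the
absolute half-width, and prevalence the fraction of items containing
the class (1 reduces it to the plain proportion formula). The ceiling
is guarded against quantile round-off (z for 95.45% confidence is
2 + O(1e-10)) by rounding to 9 decimals first. All inputs are explicit
so any published parameterization can be replayed.

## Numerical and interface choices

- Newlines normalize to `\n` on read; all offsets refer to normalized
  text.
- Standoff annotations are JSON-lines with an explicit
  `schema_version`; round-trips are lossless and tested.
- Lexicon and gazetteer configs share one sectioned plain-text dialect
  (`[section]` headers, one entry per line, tab-separated pairs for
  patterns and anatomy mappings).
- Location ranking breaks ties alphabetically; top-concept counts
  group by lowercased surface form.
- Test and acceptance runs use corpora of roughly 700 documents /
  2000 mentions — large enough for 3-sigma binomial checks on every
  mixture, generated in a few seconds.
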