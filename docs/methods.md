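# Methods

## Problem setting

A topic search filter is a fixed Boolean query over bibliographic citation
records, judged like a diagnostic test against a manually labeled reference
standard: each record is relevant or not, the filter retrieves it or not,
and the 2×2 cross-classification (a, b, c, d) yields sensitivity a/(a+c),
specificity d/(b+d), precision a/(a+b) and accuracy (a+d)/n. filtercraft
implements the full development-and-validation loop for such filters:
corpus handling and journal-level splitting, dialect-faithful query parsing
and evaluation, candidate screening and Boolean combination, and the
accuracy statistics.

## Query semantics

**Tokenization.** Record text is lowercased, hyphens are split, and other
punctuation is stripped, so `anti-glomerular` is the two-token phrase
[anti, glomerular]. This mirrors how the databases treat hyphenated
variants as separate words while closed-up variants (`antiglomerular`)
remain distinct single tokens — which is why published filters enumerate
both forms.

**Fields.** `ti` searches title tokens; `tiab` title+abstract; `tw` (PubMed)
and `.mp` (Ovid) additionally search the indexing-derived text of the
record: descriptor names, subheadings and entry-term strings, each as its
own token sequence (phrases never straddle two sequences). `.ec` is an
exact classification-code match, `jn` an exact journal match. The journal
name satisfies *only* `jn`: a term occurring solely in the journal name
never matches a text field. Chemical-substance name fields are not
modeled.

**Descriptors.** `Name[mh]` / `exp Name/` leaves match a record when some
index term resolves (case-insensitively, via entry terms and
comma-inversion) to a descriptor in the leaf's target set — the descriptor
alone, or its full tree-number subtree when exploded. PubMed `[mh]`
explodes by default while Ovid `Name/` does not; this asymmetry is forced
by the observation that the single-term filters `Kidney Diseases[mh]` and
`exp Kidney Diseases/` behave identically. `[majr]` / `*Name/` require the
major-topic flag; a subheading-qualified leaf requires that subheading on
the matching index term.

**Truncation and wildcards.** Trailing `*` (PubMed) or `$` (Ovid) makes the
final phrase token a prefix match. `?` matches zero or one character at
its position, so `polyang?itis` covers both the British and American
spellings that PubMed-dialect filters list explicitly.

**Proximity.** Bare `adj` (= `adj1`) requires the left operand immediately
before the right; `adjN` (N ≥ 2) allows at most N−1 intervening tokens in
either order. Operands are single terms or parenthesized OR-groups of
terms, and both occurrences must lie in the same token sequence. Ovid
itself does not document a single canonical semantics across versions;
this convention is the common one and is applied uniformly.

**Precedence.** OR < AND < NOT < adj; NOT is strictly binary
(`A NOT B` ≡ A AND ¬B) and a leading unary NOT is rejected — no published
filter uses one. All six published filters are fully parenthesized, so
precedence choices do not affect them.

**Field distribution.** An Ovid suffix after a parenthesized group —
`(nephrit$ OR (chronic adj2 (kidney or renal))).mp.` — applies to every
unfielded text atom inside the group; trailing periods on suffixes
(`term.tw.`), a typesetting habit of printed tables, are tolerated.

## Vocabularies

One tree structure serves MeSH-like and Emtree-like vocabularies:
descriptors carry ≥1 dot-separated tree numbers, explosion is the
prefix-closure over tree numbers, entry terms provide synonymy, and
subheadings form a flat list. Real MeSH and Emtree are large and licensed,
so the package bundles toy vocabularies (~30 headings each) covering every
descriptor used by the six published filters, including the classic
explosion example: exploding the glomerulonephritis heading pulls in
anti-GBM disease, IgA nephropathy, membranoproliferative and membranous
GN, focal segmental glomerulosclerosis and lupus nephritis. Conclusions
about retrieval performance under the real vocabularies are out of scope.

## Corpus handling

The native interchange format is JSONL (one record per line, with an
optional `relevant` boolean); a MEDLINE `.nbib` subset (PMID, TA, DP, TI,
AB, MH) is read through Bio.Medline, with the MH convention that `/`
separates subheadings and a leading `*` anywhere marks the major topic.
Records may belong to several source databases; per-database views filter
on that set while sharing one journal split. Consensus labels from
multiple readers are majority votes; ties are an error, since the original
calibrated-reader design defines no tie-break. Development/validation
splitting is at the *journal* level (ratio applied to journal counts,
development = first floor(n·r1/(r1+r2)) journals of a seeded PCG64
permutation of the sorted journal list), so the split is a deterministic,
platform-portable function of (journal set, ratio, seed) alone.

## Filter development

Candidate terms expand along the axes used in practice: each allowed text
field × {plain, truncated}, plus for descriptor terms {heading,
major-topic} × {exploded, unexploded}. Screening keeps candidates that are
either broadly sensitive (sensitivity ≥ 0.10) or highly specific
(specificity ≥ 0.90) — defaults chosen so that both OR-fodder and
AND/NOT-fodder survive — and ranks by Youden index (sensitivity +
specificity − 1), breaking ties by leaf count then source text.

The combination algorithm is a beam search over the shape every published
multi-term filter actually has: a large OR whose clauses are single
variants or two-way conjunctions. Moves are (i) add an OR clause — never
lowers sensitivity, never raises specificity — and, when enabled, (ii)
replace a clause by its AND- or NOT-refinement — never raises sensitivity,
never lowers specificity; both laws are asserted at every step. The beam
is best-first across clause counts: each round re-ranks the union of the
current beam and all proposals, so states of different sizes compete and,
with a beam at least as wide as the candidate pool, small pools are
explored exhaustively. Search stops when the best objective value improves
by less than epsilon or clauses reach `max_or_clauses`. Objectives:
balanced (Youden), sensitivity subject to a specificity floor, or
specificity subject to a sensitivity floor; when no state satisfies the
floor the best-effort frontier is returned flagged infeasible rather than
raising. NOT is off by default — none of the published filters contains
one. Precision is reported and used as a Pareto tie-breaker but is not an
optimization constraint. Development touches only the development view;
`DevelopmentResults.evaluate` scores the frozen best filter on the
validation view, mirroring the two-phase design.

Exhaustive enumeration of all candidate combinations (the published study
tested ~10⁶ filters) is supported only at toy scale, as the oracle in the
test suite.

## Synthetic reference standard

The real reference standard — tens of thousands of manually reviewed full
texts — is not public, so testing uses a generative stand-in. Records are
assigned to journals round-robin; relevance is Bernoulli(prevalence)
(default 0.05, matching the low topical prevalence regime of filter
studies; 40 journals × 125 records = 5,000 by default). Each term profile
then fires independently given the class: a text occurrence with
probability p_text_rel / p_text_irr (surface form drawn by weight, placed
in the title with probability 0.3, else the abstract), and, for
descriptor-backed profiles, an index entry with probability p_index_rel /
p_index_irr, thinned by an indexing-dropout of 0.10 (indexing noise) and
flagged major with probability p_major_given_indexed. Filler text is drawn
from a vocabulary disjoint from all profile surfaces. The default profile
set plants five glomerular-disease terms with class separations (e.g.
glomerulonephritis 0.55 vs 0.02 in text plus 0.50 vs 0.01 in indexing;
biopsy deliberately weak at 0.35 vs 0.10) chosen so that the optimal
filter is an OR of the four discriminative terms — a realistic shape with
a known answer.

Class-conditional independence across profiles is the deliberate
simplification that makes expected performance closed-form:
P(OR) = 1 − Π(1 − pᵢ), P(AND) = Π pᵢ, P(A NOT B) = p_A(1 − p_B), with
sensitivity = P(match | relevant) and specificity = 1 − P(match |
irrelevant). Text-word leaves also account for matching the
indexing-derived descriptor name, and leaf probabilities fold in surface
weights, title placement (for `ti`), explosion (profiles whose descriptor
lies in the leaf's target set) and indexing dropout. Leaves backed by the
*same* profile are treated as independent even though they are not; the
closed form is exact for queries over distinct profiles, which is what the
tests use. What passing tests show is therefore that the machinery is
correct under a known generative model — not that the toy corpora
reproduce the term-frequency structure, inter-term correlations or
journal effects of the real glomerular-disease literature. A per-journal
prevalence multiplier (off by default) lets journal-level splitting be
stress-tested under journal heterogeneity.

## Statistics

Confidence intervals default to the Wald normal approximation — published
performance tables in this literature print symmetric intervals consistent
with Wald — with Wilson available by flag (and recommended near 0 or 1,
where Wald collapses to the point and is flagged degenerate). Intervals
come from `statsmodels.stats.proportion.proportion_confint`. A metric with
a zero denominator is reported as undefined, never as 0. Percentages are
formatted to one decimal, rounding half away from zero, matching printed
tables. Cohen's κ is the two-rater, two-category chance-corrected
agreement (p_o − p_e)/(1 − p_e); it is undefined (None) when both raters
are constant and identical.

The inversion utilities answer a question printed tables make possible:
given a row's (sensitivity, specificity, precision), the precision pins
down the prevalence p = ppv(1−sp) / (se(1−ppv) + ppv(1−sp)), and accuracy
follows as se·p + sp·(1−p). A perfect test (se = sp = 1) is rejected —
its precision is 1 at every prevalence and carries no information. For
the published high-specificity filters this reconstruction reproduces the
printed validation accuracies exactly at one decimal; the development rows
for PubMed/Medline land 0.1 point low (98.2 vs 98.3), the expected effect
of inverting already-rounded inputs.

## Numerical and design choices

- Seeded randomness everywhere uses NumPy's PCG64 (`default_rng`); splits,
  generated corpora and the beam search are deterministic given seeds, and
  the generator's JSONL output is byte-identical across runs.
- Beam ranking breaks ties by (feasibility, objective, leaf count, clause
  text), making search output independent of candidate-list order.
- Degenerate inputs: empty queries, unbalanced parentheses, unknown field
  tags and `adj0` are parse errors with positions; an unresolvable
  descriptor in a *query* is an error, while unresolvable descriptors in a
  *record's indexing* simply never match (dirty data is not exceptional).
- The test suite's problem sizes (200-record corpora for oracle
  equivalence, 5,000-record corpora for planted-term recovery) keep the
  full suite under a minute of compute while leaving binomial error bars
  narrow enough for 3-standard-error checks.

## Known limitations

- No PubMed automatic term mapping, stopwords, date/language limits, or
  Ovid multi-line search-history syntax (`1 or 2`).
- Subheading-qualified descriptor parsing is limited to the
  `"Name/subheading"` form; the printed filters use none.
- British/American spelling is handled by explicit enumeration or `?`
  wildcards in term lists, not an automatic variant engine.
- κ is two-rater/two-category only; no ROC analysis (filters produce no
  thresholded score).
- The published filters' absolute performance values cannot be reproduced
  here: they require the licensed, manually labeled 22,992-article corpus.
  What is reproduced is everything checkable without it — parseability,
  structure, dialect parity, and internal consistency of the printed rows.
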