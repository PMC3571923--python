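# Methods

## The annotation model

Annotations live at three levels. Key terms are offset-anchored spans in
a sentence, in seven categories: DRUG, METABOLITE, ENZYME, PK_PARAMETER,
NUMBER, MECHANISM, CHANGE. Sentences carry an interaction label — CDDIS
when at least two distinct interaction entities co-occur with an
interaction statement (a mechanism or change term), VDDIS when exactly
one entity plus a statement is present and the partner is resolvable from
the surrounding abstract, NONE otherwise. Pairs carry one of six relation
labels: DDI / ADDI / NDDI for drug–drug interactions (definite,
ambiguous, asserted-absent) and DEI / ADEI / NDEI for in vitro
drug–enzyme interactions. Character offsets are 0-based half-open within
each sentence throughout, including the unified extraction XML; a
cross-sentence (VDDIS) partner is serialized as a `ctx:<sentence>:<term>`
reference so a pair can point at a mention elsewhere in the abstract.

## Tagging

Enzyme names are matched per token. The annotation guideline's printed
pattern allows only a digit–letter–digit core with end anchors, which
misses CYP2C19 (two-digit tail) and CYP3A (no tail digit) although the
corpus scheme itself uses both; the default pattern therefore extends the
tail to `[0-9]*` with an optional multi-digit allele star, and the
verbatim pattern remains available behind `strict=True`. Anchors are
interpreted at token boundaries — the printed `$` anchors make no sense
mid-sentence otherwise. Normal forms are upper-cased with the CYP prefix
restored (`P4503A4` → `CYP3A4`).

Mechanism and change words are matched by the printed stem+suffix
alternations, applied as token-level full matches. One printed
alternation cannot match a word its own guideline lists as an example
("formation" under the *form-* pattern, which enumerates only "tion");
the shipped pattern accepts `a?tion`. "doesn't interact" / "does not
interact" is matched as a phrase before single-token cues.

PK parameters are matched longest-first over symbols and synonyms,
case-insensitively; subscript parentheses collapse (`K(i)` → Ki,
`C(max)` → Cmax) and a parenthesized qualifier after a symbol is absorbed
into the span with the base symbol as normal form (`AUC(0-48)` → AUC).
Single-letter symbols (E, F, V, k, Q) are excluded from free-text
matching — they are practically always false positives — though direct
lookup still resolves them. Drug tagging is dictionary longest-match;
a token is a METABOLITE when stripping one of the ten phase-I/II affixes
(prefix or suffix, optional hyphen) leaves a known drug name of at least
three characters, which blocks accidental hits like "northern".

Overlaps from the six taggers are resolved longest-span-first, then by
category precedence DRUG > ENZYME > PK_PARAMETER > NUMBER > MECHANISM >
CHANGE.

## The relation rules

The four conditions combine as **C1 ∧ C2 ∧ (C3 ∨ C4)**: the conjunction
printed between C3 and C4 cannot be literal, because several of the
published worked examples are labeled from words alone with no numbers
present. When both kinds of evidence exist, the numeric evidence decides —
hedged or emphatic wording does not override a measured fold change.

C3, in vivo: the fold change of the highest-priority reported parameter
(AUC > CL > t1/2 > Cmax; unranked parameters below all ranked ones, ties
broken by larger |log FC|) with its p-value. Thresholds: FC > 1.50 or
FC < 0.67 with p < 0.05 → DDI; one of the two conditions failing → ADDI;
neither holding → NDDI. A percent change x converts to a fold change
1 ± x/100. The 0.67 lower bound is used exactly as printed, not as 1/1.5
(they differ in the third decimal; 1/1.51 still classifies as definite in
both directions). C3, in vitro: Ki (or IC50, or EC50 for induction) in
microM; (0, 10) definite, (10, 100) ambiguous, (100, ∞) none, modulated
by significance: a definite-band value with non-significant p, or a
none-band value with significant p, reads as ambiguous.

Three deliberately documented decisions:

* **Boundary values.** The printed inequalities are strict on both sides,
  so FC = 1.50, Ki = 10 or Ki = 100 belongs to no band. Such a value
  defers to the language cues when any are present (the worked example
  that reports exactly "1.5 fold" alongside "significantly" is labeled
  definite), otherwise it falls into the ambiguous band. Binary-searching
  the label transition therefore recovers exactly the configured
  thresholds from either side.
* **Missing p-values.** A reported change without a p-value is treated as
  satisfying the significance clause, so the magnitude band decides alone:
  the worked examples label a 64% clearance decrease with no p-value as a
  definite interaction. The alternative reading (demote to the ambiguous
  band) is available as `RuleConfig(missing_p="ambiguous")`.
* **Conflicting measurements.** When several measurements of the
  top-priority parameter fall in different bands (e.g. Ki from two assay
  systems straddling 10 microM), the ambiguous band wins.

C4: cue polarities are definite ("significant(ly)", "markedly",
"potent(ly)", …), ambiguous ("modestly", "may", "might", …) and negative
("slightly", "negligible", "minor significance", "doesn't interact").
A negation adjacent to any cue or mechanism word makes the phrase
negative ("not significantly changed", "not induced"). Aggregation:
negative without definite → N-family; ambiguous without definite →
A-family; definite → definite family. "p ≤ 0.05" counts as significant;
a reported "p > x" bound never does. All thresholds and cue lists live in
`RuleConfig` (defaults 1.50 / 0.67 / 0.05 / 10 / 100 microM) and can be
loaded from a key = value file.

The evidence linker used by the CLI and by corpus-derived candidates is a
stated heuristic: a number attaches to the nearest preceding PK-parameter
mention, a p-value to the nearest preceding measurement, direction
(increase/decrease) from the words between parameter and number, and cue
polarity from a 16-character window before each CHANGE/MECHANISM term.
It assumes parameter–number adjacency; curated corpora should attach
evidence explicitly instead.

## Krippendorff's alpha

Nominal metric, coincidence-matrix form: each unit labeled by m ≥ 2
annotators contributes 1/(m−1) to each ordered label pair; alpha =
1 − Do/De with Do the off-diagonal mass over n and De the chance
disagreement n_c·n_k/(n(n−1)). Units with a single annotator are dropped
from the pairable count; a degenerate case with zero expected
disagreement (one label everywhere) returns alpha = 1.0 by default or
raises under `degenerate="error"`. Unit definitions are a documented
choice of this package (the source reports only the resulting
coefficients): token-level units are the shared
whitespace-plus-punctuation tokens labeled with the covering term's
category or "O"; sentence-level units are sentences; pair-level units are
all candidate entity pairs in any sentence some annotator marked
CDDIS/VDDIS, with non-annotating annotators contributing NONE. Annotators
may lack whole documents, but shared documents must have identical
sentence texts, since unit identity is positional.

## The graph kernel and extraction pipeline

Only clear-DDI (CDDIS) sentences contribute candidates. Pairable entities
are the DRUG and ENZYME terms — metabolites are dropped because parent
drugs and their metabolites rarely interact, enzymes are pairable because
drug–enzyme interactions are first-class — and repeated mentions of one
canonical entity collapse to the first, so C(n,2) counts distinct
entities, not surface mentions. Labels collapse to binary with only DDI
and DEI true.

Each candidate's graph has two disjoint components: (i) the dependency
graph, vertices labeled {lemma, POS} with the two candidate tokens
relabeled ENTITY1/ENTITY2 and other entity mentions ENTITY, edges
directed head→dependent, weighted 0.9 on the undirected shortest path
between the candidates and 0.3 elsewhere; (ii) a linear chain over
position-marked part-of-speech labels (`lin:` prefix keeps the two label
spaces from cross-matching), weight 0.9. The path-weight matrix is the
Neumann series A + A² + … = A(I − A)⁻¹, valid when the spectral radius of
A is below 1 — guaranteed for these acyclic components with weights
≤ 0.9; general graphs that violate it raise, with an explicit `rescale`
option. The kernel between two graphs sums products of path weights over
vertex pairs sharing labels at both path ends; implemented as the inner
product of label-pair feature maps (label-incidence matrices applied to
the weight matrix), which makes symmetry and positive semidefiniteness
structural rather than empirical. The normalized variant
k(a,b)/√(k(a,a)k(b,b)) feeds an SVM with a precomputed kernel matrix.

Defaults: C = 10 — with a normalized kernel all entries are in [0, 1] and
C = 1 visibly underfits even separable data — and
`class_weight="balanced"`, since true pairs are a small minority (11–18%
in real DDI corpora) and an unweighted margin collapses to the majority
class at that prevalence. Splits are document-level (all candidates of an
abstract stay together) and seed-controlled. Parses are consumed from
CoNLL-style files; absent those, a deterministic fallback parser builds a
right-branching chain (token i's head is token i−1) with heuristic POS
tags, so the pipeline runs without any external parser. The fallback
chain makes the dependency component position-like rather than syntactic;
results on it measure the pipeline, not parsing quality.

## The synthetic corpus generator

`GenConfig` defaults describe a corpus like the real annotation effort:
class mix 0.10 / 0.11 / 0.40 / 0.39 over clinical PK, clinical
pharmacogenetics, in vivo DDI and in vitro DDI abstracts (the published
corpus has 56/57/218/210); 4 sentences per abstract; `positive_rate` 0.2,
the probability that a DDI-study sentence plants a definite interaction,
between the true-pair rates of the two published extraction corpora
(359/2024 and 783/7122). Sentence templates follow the worked examples'
phrasing: definite in vivo interactions (AUC fold increase with p, or a
percent clearance reduction), negatives ("did not significantly alter…"
with an in-band fold change), hedged statements ("may moderately
affect…"), in vitro Ki sentences in each band, co-mention sentences with
no interaction statement, single-drug mechanism distractors, and an
occasional context-mention + vague-DDI sentence pair exercising
cross-sentence annotation. Numeric values are drawn inside the intended
rule band, so the planted label, the rule classifier's output on the
linked evidence, and the tallied counts agree by construction — the test
suite asserts all three. The generator counts its tally independently as
it plants; `corpus_stats` must reproduce it exactly.

What the generator does not emulate: real abstracts' vocabulary breadth,
parse complexity, co-reference, multi-clause sentences with many entities,
and reporting styles where numbers are far from their parameters. A
perfect extraction score on synthetic text therefore validates the
pipeline's mechanics (graph construction, kernel, learning, evaluation
protocol), not expected performance on PubMed abstracts, where the
published figures are far lower.

## Scale choices and limitations

The test suite and the examples run the extraction benchmark at 50
abstracts / 200 sentences (seed 7) and the agreement null-distribution
check at 10,000 units — sizes at which every check is exact or
well-converged while the whole suite stays interactive. The published
corpus-level results (inter-annotator alphas of 0.953/0.921/0.905 and
extraction F-measures of 0.73 in vivo / 0.52 in vitro) require the
original annotator files and hosted corpus, which are not bundled; the
methods are implemented and validated on generated data instead. The
bundled drug lexicon covers the probe-drug tables plus the worked-example
drugs; realistic use should load a full drug list via `load_lexicon`.
The sentence splitter is a deterministic abbreviation-guarded rule set,
not a trained model; its guard list is extensible but finite.
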