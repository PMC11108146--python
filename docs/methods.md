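# Methods

## Problem and model

Given a collection of publication abstracts for one organism, the
package extracts directed regulatory claims of the form *agent regulates
target* between gene/protein entities and aggregates them into a
weighted directed network. The core statistic is the confidence factor
of a directed pair (e_a, e_t):

    CF(e_a, e_t) = CF1 + K * CF2
    CF1 = sum over the n unique supporting sentences of the averaged
          classifier vote v̄_s  (each v_s in [0, 1])
    CF2 = sum over the M curated databases of P(e_a, e_t), with
          P = 3 if the relation is curated in that database,
          P = 1 if only the agent is a known regulator there,
          P = 0 otherwise.

Assumptions worth making explicit:

* **A sentence is the unit of evidence.** Cross-sentence (anaphoric)
  relations are out of scope. A relation asserted in more unique
  sentences accumulates more CF1; repeats of a *textually identical*
  sentence (e.g. the same abstract retrieved twice, or boilerplate) are
  averaged into a single vote rather than counted again. Identity is
  exact string equality; near-duplicate detection is deliberately not
  attempted.
* **Direction is learned from context, supported by priors.** The
  anonymization schema marks the roles asymmetrically, so a scorer can
  prefer one direction; the CF2 prior then further separates directions
  because P follows the curated direction and the curated regulator set.
* **Priors never penalize.** P ≥ 0, so activating prior knowledge can
  only raise CF. K = 0 recovers the pure-literature score (CF = CF1).

## Pipeline stages and choices

**Query construction.** The query is the organism name form(s) followed
by the default keyword phrase `gene expression regulation
transcriptional`. A binomial yields the abbreviation forms "G. species"
and "G species"; organism matching in abstracts is case-insensitive
substring over title *and* abstract (the abbreviated forms legitimately
end at punctuation, so whole-word matching would lose them).

**Sentence splitting** is rule-based and abbreviation-aware (genus
initials such as "E.", plus cf./e.g./i.e./sp./spp./et al./Fig./vs.).
A deterministic splitter keeps the test surface hermetic; the splitter
sits behind the same sentence-record interface as any pretrained
alternative. Joining the output with single spaces reconstructs the
abstract.

**Sentence eliminator 1** keeps sentences whose relevance score reaches
a cutoff (default 0.5 on a [0, 1] scorer). The bundled rule scorer
returns 1.0 iff one of the interaction trigger stems (regulat-,
repress-, activat-, induc-, bind-, express-, transcrib-) occurs. The
cutoff is an artifact decision: a binary classifier reports labels, not
calibrated scores, and 0.5 is the natural operating point.

**Sentence eliminator 2** keeps sentences with ≥ 2 *distinct* normalized
gene/protein entities. Distinctness matters: two mentions of one gene
cannot form a directed pair. A provider failure removes the sentence
(fail closed) with a logged reason.

**Candidate enumeration and anonymization.** Each ordered pair of
distinct entities yields one instance; all mentions of the agent entity
are tagged `$GENE_AGENT#`, of the target `$GENE_TARGET#`, and all other
gene/protein mentions are masked `BLANK`. Replacements are applied
right-to-left over the standoff spans, so the transformation is exactly
invertible given the spans — the schema alters no non-entity text, and
this losslessness is tested as string equality. Instances are formed
per entity (not per mention-pair): one rendering per pair per sentence.
Within-sentence duplicate votes therefore cannot arise at the instance
level; the vote-averaging rule still applies to cross-abstract repeats
of identical sentences.

**Rule relation scorer.** Deterministic and direction-sensitive: 0.9
when a trigger stem occurs between or adjacent to the tag pair with the
agent tag first, 0.6 when the target tag precedes the agent tag, 0.1
when no trigger is near the pair (adjacency window: 40 characters).
The asymmetry lets end-to-end tests verify that direction survives the
pipeline; all values are configuration. The transformer fine-tuning
adapter (token length 256 default/512, BertAdam-style optimizer, batch
8, 10–20 epochs, lr 2e-5, warmup 0.1, weight decay 0.01) is an optional
capability behind an explicit dependency check — the package never
silently substitutes one scorer for another.

**Classification cutoff.** Positives are instances with v_s ≥ 0.5 by
default. Like the eliminator-1 cutoff this is an operating-point choice,
exposed as a parameter.

**Refinement.** Multi-word entity phrases are reduced to bare names in
order: stoplist removal first (cheapest; the bundled stoplist of
frequent non-entity words — protein, gene, factor, suppressor, … — is
replaceable), then word-level NER over the survivors, then, only if NER
recognizes nothing, the spelling heuristic: a word absent from the
bundled common-English lexicon is taken to be a gene/protein name, and
words containing digits or capitals beyond the first character are names
regardless (gene symbols are short and case/digit-bearing; spell
lexicons contain their lowercase homographs). When several words
survive, the first in original order is kept with a warning. A phrase
with no survivor marks the relation incomplete and the relation is
dropped — dropping is monotone in the stoplist and the whole operation
is idempotent.

**γ selection.** Candidate thresholds are the distinct observed CF
values; γ maximizes Youden's J = TPR − FPR with the keep rule CF ≥ γ,
ties broken toward the larger γ (fewer false positives). The
implementation uses a standard ROC routine; tests compare it against an
exhaustive hand-written sweep. Edges with CF exactly equal to γ are
kept (the drop condition is strictly CF < γ). Both fixed and
ROC-selected γ are supported; K defaults to 1 and is exposed per run.

## Synthetic study conditions

The generator's defaults define the study the tests and the acceptance
script run: 30 genes, 40 planted directed relations, 50 abstracts of
3–5 sentences (seed 42); 25 % irrelevant sentences, decoy third
entities at 20 %, multi-word entity phrases at 20 %, verbatim duplicate
sentences at 10 %; one prior database fully covering the planted
network. Full prior coverage mirrors the evaluation setting the
pipeline targets, where the gold standard *is* a curated database and
the same resource serves as the prior. Relation sentences are allocated
round-robin (per-relation support counts differ by at most one) and each
relation's successive sentences cycle through distinct templates, so the
unique-sentence rule never collapses genuine support; sentence templates
are bundled data, not code.

Three flavours of irrelevant sentence give each eliminator a dedicated
falsifier: no entities and no trigger (dies at eliminator 1), two
entities without a trigger (eliminator 1), one entity with a trigger
(passes eliminator 1, dies at eliminator 2).

What the generator does **not** emulate: natural prose (templates are
rigid), ambiguous or nested entity mentions, anaphora, negated or
speculative claims, contradictory assertions between papers, and NER
errors (the dictionary provider is a gold oracle). Passing the
end-to-end recovery test therefore demonstrates that the pipeline's
plumbing — filtering, anonymization, refinement, vote aggregation,
prior weighting, thresholding — is correct and lossless, not that the
bundled rule scorer would match a fine-tuned model on real literature.

## Numerical and degenerate-input conventions

* Entity-name normalization for grouping: case-fold + strip surrounding
  punctuation.
* NER overlap resolution: longest match first, then leftmost; matches
  are token-delimited.
* k-fold splitting groups by unique sentence (instances from one
  sentence never straddle train/test), shuffles with a seeded RNG, and
  produces sentence-fold sizes differing by ≤ 1.
* ROC selection raises on degenerate gold labellings (all edges gold or
  none); CF computation raises on an edge with no supporting sentence;
  enumeration raises below two distinct entities.
* Duplicate pmids on input: first record wins, with a warning.
* All randomness (generator, k-fold, noise wrapper) flows from explicit
  integer seeds; same seed, same bytes.

## Problem sizes

The default test and acceptance runs use the study conditions above
(≈ 220 sentences, ≈ 570 candidate instances); the labelling-reversibility
check runs over ≥ 1000 sentences from two larger generated corpora
(40 genes, 60 relations, 170 abstracts each). These sizes exercise every
stage and noise knob while keeping runs comfortably reproducible on a
single CPU.

## Known limitations

* The external NER service adapter and the transformer fine-tuning
  adapter are specified and unit-guarded but not exercised offline.
* Refinement keeps the first recognized word of a multi-entity phrase;
  phrases genuinely naming two entities lose one (logged).
* The spelling heuristic is lexicon-relative: a descriptive word missing
  from the bundled English list is mistaken for a gene name. The lists
  are plain-text and replaceable per run.
* Direction recovery relies on the scorer's asymmetry and on curated
  priors; there is no dedicated direction-flipping step.
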