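# Methods

## The model

A *molecular variant* is one concrete assayed alteration, tagged as an
allele (a literal sequence state over an interval), a copy-number
observation (interval plus absolute count and/or a relative change code), or
an adjacency (two breakends). A *categorical variant* is a non-empty
conjunction of constraints; its members are exactly the variants that
satisfy every constraint. An empty conjunction is rejected rather than read
as "the universal set": a category with no properties has no computable
meaning, and silently accepting one would make every variant a member of a
typo.

Coordinates are inter-residue, 0-based, half-open everywhere internally;
the VCF reader converts 1-based anchored records and the BED/TSV readers
convert their dialects at the boundary. Strand is carried on feature
records but ignored for interval containment and overlap.

### Verdict semantics

Constraint evaluation is three-valued. `INAPPLICABLE` is used exactly when
the variant lacks the attribute a constraint tests (an SNV has no copy
count; a CNV is not an adjacency) and is a pure function of the variant's
kind and attribute *presence*, never of attribute values — so the boundary
between `INAPPLICABLE` and `UNSATISFIED` cannot drift with data. At the
category level membership is closed-world: only variants demonstrably
satisfying every constraint are members, so `INAPPLICABLE` counts as
non-match. A copy count is never auto-converted into a change code: that
would require assuming a baseline ploidy. Callers that do know the baseline
can pass one to the VCF reader, which then derives codes for `<CNV>`
records explicitly.

Two conventions deserve note:

* **Zero-width intervals.** A pure insertion has a zero-width location, and
  the half-open intersection of a zero-width interval with anything is
  empty. Overlap therefore treats a zero-width interval as a closed point
  (`s ≤ p ≤ e`). Without this, "insertion inside an exon" could never
  overlap the exon, and containment-based entailment rules would be
  inconsistent with the matcher. One function implements the convention and
  the engine, the entailment rules and the oracle all share it.
* **Adjacencies and single-location constraints.** An adjacency exposes two
  breakends rather than one payload location, so DefiningLocation returns
  `INAPPLICABLE` for adjacencies; FeatureContext, by contrast, tests both
  breakends (a fusion "involves" a gene if either side touches it).

### Normalization and digests

A single edit admits many spellings: anchored VCF rows share context bases
with the reference, and an indel inside a repeat tract can be written at
any offset. `normalize_allele` produces a *fully justified* form: trim the
shared prefix then suffix; if the remaining edit is a pure insertion or
deletion, roll it left and right across the maximal flanking repeat of the
edited unit and respell the state over that whole window. All equivalent
spellings of a simple edit then coincide exactly, which the tests verify
against an independent oracle (apply each spelling to the reference and
compare the mutated strings). The digest identifier is the first 24 bytes
of SHA-512 over a canonical serialization (key-sorted, whitespace-free,
NFC-normalized UTF-8 JSON), rendered as 32 URL-safe base64 characters with
a short type prefix — allele identity reduces to string equality.

Choices and limits: substitutions and multi-edit delins are trimmed but not
shuffled (sufficient for category membership of single contiguous edits);
protein alleles are trimmed only, since residue-level justification
conventions differ across tools; identity alleles (state equal to the
reference subsequence) keep their site and are flagged rather than
collapsed, because "reference allele at this position" is site-specific
information. The matcher normalizes allele locations before positional
tests, so membership in "deletions within exon E" cannot depend on which
spelling a caller ingested; this also keeps the allele→location entailment
rule sound against the engine.

### Entailment

`entails(A, B)` returns `ENTAILS` only when every constraint of B is
subsumed by some constraint of A under a small set of rules (digest
equality, interval containment, copy-range inclusion, change-code
specialization, location-within-feature, plus identity for all kinds).
The rule set is deliberately incomplete: clinical use demands soundness,
so everything undecided is `UNKNOWN`, and a supplied finite probe universe
can upgrade `UNKNOWN` to `NOT_ENTAILED` only by exhibiting a concrete
counterexample variant. When a user-supplied allele-equivalence table is
present, the positional rules for DefiningAllele back off to `UNKNOWN`,
because an equivalent allele may live on a different sequence. Function
and Adjacency constraints participate only in identity subsumption; in
particular no rule connects a functional category (e.g. loss-of-function)
to molecular constraints — that relationship is biological, not syntactic.

## Profiles

The five categorical-variant types (CanonicalAllele,
ProteinSequenceConsequence, CategoricalCNV, FunctionVariant, GeneFusion)
are data in a registry — cardinality rules over constraint kinds, allowed
kinds, and named predicates — not code, so adopters can register local
profiles or load a registry from JSON. GeneFusion accepts two shapes (one
feature-sided Adjacency, or two FeatureContexts plus an Adjacency).
CategoricalCNV permits a location and a feature context simultaneously, as
the shipped copy-loss example does. Maturity labels are carried as
metadata; `in_progress` profiles and the Function/Adjacency constraint
kinds are gated behind `--experimental` in the CLI. Without a sequence
registry, the DNA-vs-protein decision for allele profiles falls back to
the state's symbols (ACGTN-only reads as DNA) — a documented heuristic,
resolved exactly whenever references are supplied.

## The synthetic universe generator

Universes are combinatorial test beds: 1–3 random DNA references (≈3–8 kb
in the shipped configurations), non-overlapping genes with exons,
and an enumerated variant list — SNVs at random positions, indel spelling
groups planted inside repeat tracts (unit length 1–3, 4–7 copies, two
spellings one unit apart), copy-number segments with counts 0–6 and change
codes consistent with their counts (0 → COMPLETE_LOSS, 1 → LOSS or
LOW_LEVEL_LOSS, 2 → no code, 3 → LOW_LEVEL_GAIN, 4 → GAIN, ≥5 →
HIGH_LEVEL_GAIN), and adjacencies over a breakpoint candidate set.
Annotations (overlapping gene symbols; consequence terms from a six-term
vocabulary with a two-parent hierarchy) emulate what a real pipeline's
VEP-style annotator would attach. Tract edges are stamped with breaking
bases so a planted repeat cannot accidentally extend, keeping spelling
groups exact by construction.

What the generator does **not** emulate: allele frequencies, linkage,
mutational signatures, sequencing error, transcript structure or any other
population- or assay-level realism. Passing tests therefore demonstrate
the *logic* of matching and entailment over the full combinatorial space
of the model's variant kinds — not calibration against real cohorts.

The brute-force oracle `extension()` is a naive double loop calling
`evaluate_constraint` directly, kept independent of the report-building
`match`/`match_batch` path; universes are small (≈10³ variants in the
study configuration) precisely so exhaustive evaluation stays sub-second.
The planted exon-deletion scenario stamps five deletions with
non-repetitive context (three inside the target exon, two outside), so the
expected extension size is exact ground truth, not a measured quantity.

## Problem sizes and numerics

The acceptance checks use three seeded universes of exactly 1000 variants
(600 SNVs, 50 indel groups × 2 spellings, 250 CNVs, 50 adjacencies over
two 6 kb references), 12 categories per universe for matcher/oracle
agreement (36 000 pairs), 33 categories per universe for entailment
(3 267 ordered pairs), 100 indel spelling groups for normalization
invariance, and 100 random categories for monotonicity and round-trip
stability — sizes chosen to exercise every constraint kind densely while
keeping the whole run within a few seconds. All randomness flows from one
explicit integer seed; there is no global random state. Evaluation caches
normalized allele forms keyed by the allele's identifying tuple;
normalization is pure, so the cache cannot change any verdict.

## Known limitations

* No HGVS parsing or printing, no transcript projection, no liftover:
  cross-representation equivalence beyond spelling normalization enters
  only through a user-supplied digest-equivalence table.
* No disjunction or negation over constraints (e.g. "any residue at this
  position except valine" is not expressible).
* Entailment is incomplete by design; `UNKNOWN` is a frequent and honest
  verdict, and `NOT_ENTAILED` requires a finite-universe witness.
* VCF ingestion covers SNV/indel rows, `<DEL>`/`<DUP>`/`<CNV>` with END,
  and MATEID-paired BNDs; other symbolic alleles are skipped with reasons.
  Breakend orientation bracket semantics are not modeled beyond pairing.
* Copy-change fidelity through VCF symbolic alleles is lossy
  (`LOW_LEVEL_LOSS` exports as `<DEL>` and re-ingests as `LOSS`).
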