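# catvar — constraint-based categorical variants

Clinical genomics knowledge is mostly attached to *categories* of variation,
not to single alleles: "TP53 copy-number loss", "EGFR exon 19 deletions",
"PTEN loss-of-function variants". Knowledgebases, trial eligibility criteria
and regulatory labels all use such categories, but usually as free text, so
deciding whether a variant observed in a sample belongs to a category — and
whether one category is a subset of another — is manual work for molecular
pathologists and curation teams.

`catvar` makes both decisions computable. A **categorical variant** is
represented intensionally as a conjunction of **constraints**, each a
computable property over the space of molecular alterations:

* *DefiningAllele* — members are representations of one specific allele;
* *DefiningLocation* — members relate positionally to a sequence interval
  (`EXACT` / `CONTAINED` / `OVERLAPS`);
* *CopyCount* — an absolute copy number within an inclusive range;
* *CopyChange* — a relative dosage code from a small specialization
  hierarchy (`COMPLETE_LOSS → LOSS`, `HIGH_LEVEL_GAIN → GAIN`, …);
* *FeatureContext* — involvement of a named gene/exon feature;
* *Function* — an annotated functional-consequence term (experimental);
* *Adjacency* — a breakend join with two side specifications (experimental).

For a category *C* = c₁ ∧ … ∧ cₙ and a finite variant universe *U*, the
**extension** ext(C) = { v ∈ U : v ⊨ cᵢ for all i }. Category *A* **entails**
*B* when ext(A) ⊆ ext(B) in every universe; the package decides this with
sound syntactic subsumption rules (incomplete by design — verdicts are
`ENTAILS` / `NOT_ENTAILED` / `UNKNOWN`, never a guessed yes).

Because one alteration admits many spellings (VCF anchor bases, indels
shuffled through repeat tracts), alleles are first *normalized* to a fully
justified canonical form and identified by a digest, so membership never
depends on how a variant was written down.

## Worked example

The packaged example category "TP53 CNLoss" carries three constraints:
FeatureContext(TP53) ∧ DefiningLocation(chr17 gene region, OVERLAPS) ∧
CopyChange(LOSS).

```
$ catvar validate tp53.json
VALID	catvar-tp53-cnloss	profiles=CategoricalCNV
# 1 valid, 0 invalid
```

The category is structurally valid and classifies as the `CategoricalCNV`
profile (a location or feature context plus exactly one dosage constraint).
Matching a VCF containing a 17p deletion (`<DEL>`, CN=1) and an SNV inside
TP53:

```
$ catvar match tp53.json sample.vcf --features tp53.bed
#category_id	variant_id	overall	constraint_statuses
catvar-tp53-cnloss	del17p	true	SATISFIED,SATISFIED,SATISFIED
catvar-tp53-cnloss	snv1	false	SATISFIED,SATISFIED,INAPPLICABLE
```

The copy loss satisfies all three constraints, so it is a member. The SNV
overlaps the gene and the region but has no copy-change attribute at all, so
the third verdict is `INAPPLICABLE` — and under closed-world conjunctive
semantics it is not a member. Entailment is reflexive and explained
per-constraint:

```
$ catvar entail tp53.json tp53.json --features tp53.bed
ENTAILS
  b.constraints[0] ⊑-covered by a.constraints[0]: identical constraints
  ...
```

In Python the same operations are `catvar.match`, `catvar.entails`,
`catvar.extension`, `catvar.normalize_allele`; `catvar generate` writes a
fully synthetic universe (FASTA + BED + VCF + annotation TSV) for end-to-end
experiments with no external data.

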