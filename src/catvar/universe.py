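"""Finite synthetic variant universes and the brute-force oracle.

A universe is a small, fully enumerated world — reference sequences, a gene/
exon feature table, and a list of molecular variants — over which the
*extension* of any category (the exact member set) can be computed by
exhaustive evaluation.  That exhaustive loop is the oracle against which the
matcher and the entailment rules are verified: any optimized path must agree
with it exactly.

Universes are combinatorial test beds, not simulations of biology: there are
no allele frequencies, no linkage, no mutation model.  Repeat tracts are
planted so that every universe contains indels with at least two equivalent
spellings, exercising normalization.  Everything is deterministic given
(config, seed); randomness flows through one explicit generator.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
from pydantic import BaseModel, Field

from .core import (
    AdjacencySide,
    AdjacencyConstraint,
    AdjacencyVariant,
    Allele,
    CategoricalVariant,
    Constraint,
    ConstraintKind,
    CopyChange,
    CopyChangeConstraint,
    CopyCountConstraint,
    CopyNumberVariant,
    DefiningAlleleConstraint,
    DefiningLocationConstraint,
    FeatureContextConstraint,
    FunctionConstraint,
    MatchMode,
    MolecularVariant,
    SequenceLocation,
    SequenceRegistry,
    VariantAnnotation,
    VariantKind,
)
from .engine import EvaluationContext, VerdictStatus, evaluate_constraint
from .features import FeatureRecord, FeatureTable
from .profiles import ProfileRegistry, UnknownProfileError, default_registry

__all__ = [
    "BadConfigError",
    "UniverseConfig",
    "Universe",
    "FUNCTION_HIERARCHY",
    "FUNCTION_TERMS",
    "generate_universe",
    "extension",
    "oracle_entails",
    "generate_random_category",
    "planted_exon_deletion_universe",
    "write_universe",
]


class BadConfigError(ValueError):
    code = "BAD_CONFIG"


#: leaf consequence terms assigned to synthetic alleles, with their parents.
FUNCTION_HIERARCHY: dict[str, set[str]] = {
    "stop_gained": {"loss_of_function"},
    "frameshift_variant": {"loss_of_function"},
    "start_lost": {"loss_of_function"},
    "activating_mutation": {"gain_of_function"},
    "missense_variant": set(),
    "synonymous_variant": set(),
}
FUNCTION_TERMS = sorted(FUNCTION_HIERARCHY)


class UniverseConfig(BaseModel):
    """Size parameters of a synthetic universe (all counts are exact)."""

    n_references: int = Field(default=2, alias="nReferences")
    reference_length: int = Field(default=3000, alias="referenceLength")
    n_genes: int = Field(default=4, alias="nGenes")
    exons_per_gene: int = Field(default=3, alias="exonsPerGene")
    n_snvs: int = Field(default=80, alias="nSnvs")
    n_indel_groups: int = Field(default=15, alias="nIndelGroups")
    max_indel_unit: int = Field(default=3, alias="maxIndelUnit")
    n_cnvs: int = Field(default=40, alias="nCnvs")
    n_adjacencies: int = Field(default=12, alias="nAdjacencies")

    model_config = {"populate_by_name": True}

    def check(self) -> None:
        if not (1 <= self.n_references <= 3):
            raise BadConfigError("n_references must be in [1, 3]")
        if self.reference_length < 200 or self.reference_length > 10_000:
            raise BadConfigError("reference_length must be in [200, 10000]")
        if self.n_genes < 1:
            raise BadConfigError("need at least one gene")
        if not (1 <= self.exons_per_gene <= 5):
            raise BadConfigError("exons_per_gene must be in [1, 5]")
        if self.max_indel_unit < 1:
            raise BadConfigError("max_indel_unit must be positive")
        if min(self.n_snvs, self.n_indel_groups, self.n_cnvs, self.n_adjacencies) < 0:
            raise BadConfigError("variant counts must be non-negative")


@dataclass
class Universe:
    """A generated finite world over which extensions are computable."""

    config: UniverseConfig
    seed: int
    references: SequenceRegistry
    features: FeatureTable
    variants: list[MolecularVariant]
    planted: dict = field(default_factory=dict)

    def context(self) -> EvaluationContext:
        return EvaluationContext(
            feature_table=self.features,
            sequences=self.references,
            function_hierarchy=dict(FUNCTION_HIERARCHY),
        )

    def variant(self, vid: str) -> MolecularVariant:
        for v in self.variants:
            if v.id == vid:
                return v
        raise KeyError(vid)


_BASES = np.array(list("ACGT"))


def _random_sequence(rng: np.random.Generator, length: int) -> list[str]:
    return list(_BASES[rng.integers(0, 4, size=length)])


def generate_universe(config: UniverseConfig | None = None, seed: int = 0) -> Universe:
    """Build a universe deterministically from (config, seed).

    Repeat tracts are planted in every reference before variants are drawn,
    and each indel group contains ≥2 spellings of the same edit shifted
    within its tract, so representation invariance is always exercised.
    """
    config = config or UniverseConfig()
    config.check()
    rng = np.random.default_rng(seed)

    # --- references with planted repeat tracts -----------------------------
    seqs: dict[str, list[str]] = {}
    tracts: list[tuple[str, int, int, str]] = []  # (ref, tract_start, unit_len, unit)
    n_tracts_per_ref = max(2, config.n_indel_groups // config.n_references + 1)
    for r in range(config.n_references):
        sid = f"ref{r + 1}"
        seq = _random_sequence(rng, config.reference_length)
        step = max(1, (config.reference_length - 80) // max(1, n_tracts_per_ref))
        for t in range(n_tracts_per_ref):
            k = int(rng.integers(1, config.max_indel_unit + 1))
            copies = int(rng.integers(4, 8))
            unit = "".join(_BASES[rng.integers(0, 4, size=k)])
            pos = 40 + t * step + int(rng.integers(0, max(1, step - copies * k - 10)))
            if pos + copies * k + 2 >= config.reference_length:
                continue
            # break any accidental repeat continuation at the tract edges
            left = "C" if unit[-1] != "C" else "T"
            right = "G" if unit[0] != "G" else "A"
            seq[pos - 1] = left
            for i, ch in enumerate(unit * copies):
                seq[pos + i] = ch
            seq[pos + copies * k] = right
            tracts.append((sid, pos, k, unit))
        seqs[sid] = seq
    references = SequenceRegistry.from_dict({sid: "".join(s) for sid, s in seqs.items()})

    # --- gene / exon features ---------------------------------------------
    features = FeatureTable()
    gene_locs: list[FeatureRecord] = []
    ref_ids = references.ids()
    for g in range(config.n_genes):
        sid = ref_ids[g % len(ref_ids)]
        per_ref = (config.n_genes + len(ref_ids) - 1) // len(ref_ids)
        slot = g // len(ref_ids)
        slot_width = config.reference_length // per_ref
        lo = slot * slot_width + 10
        hi = min((slot + 1) * slot_width - 10, config.reference_length)
        width = max(40, (hi - lo) // 2)
        start = lo + int(rng.integers(0, max(1, hi - lo - width)))
        end = min(start + width, hi)
        symbol = f"GENE{g + 1}"
        strand = "+" if rng.integers(0, 2) else "-"
        gene = FeatureRecord(
            id=symbol,
            symbol=symbol,
            location=SequenceLocation(sequenceId=sid, start=start, end=end),
            strand=strand,
            feature_class="gene",
        )
        features.add(gene)
        gene_locs.append(gene)
        exon_w = max(8, (end - start) // (2 * config.exons_per_gene))
        for e in range(config.exons_per_gene):
            ex_start = start + e * ((end - start) // config.exons_per_gene)
            ex_end = min(ex_start + exon_w, end)
            features.add(
                FeatureRecord(
                    id=f"{symbol}_exon{e + 1}",
                    symbol=symbol,
                    location=SequenceLocation(sequenceId=sid, start=ex_start, end=ex_end),
                    strand=strand,
                    feature_class="exon",
                )
            )

    def genes_at(loc: SequenceLocation) -> set[str]:
        from .core import interval_overlaps

        return {g.symbol for g in gene_locs if interval_overlaps(loc, g.location)}

    def annotate(loc: SequenceLocation, with_function: bool) -> Optional[VariantAnnotation]:
        symbols = genes_at(loc)
        terms: set[str] = set()
        if with_function and rng.random() < 0.7:
            terms = {FUNCTION_TERMS[int(rng.integers(0, len(FUNCTION_TERMS)))]}
        if not symbols and not terms:
            return None
        return VariantAnnotation(geneSymbols=symbols, functionTerms=terms)

    variants: list[MolecularVariant] = []

    # --- SNVs ---------------------------------------------------------------
    for i in range(config.n_snvs):
        sid = ref_ids[int(rng.integers(0, len(ref_ids)))]
        pos = int(rng.integers(1, references.length(sid) - 1))
        ref_base = references.fetch(sid, pos, pos + 1)
        alt = str(rng.choice([b for b in "ACGT" if b != ref_base]))
        loc = SequenceLocation(sequenceId=sid, start=pos, end=pos + 1)
        variants.append(
            MolecularVariant.from_allele(f"snv{i + 1}", Allele(location=loc, state=alt), annotate(loc, True))
        )

    # --- indels with equivalent spellings planted in repeat tracts ----------
    spelling_groups: list[list[str]] = []
    usable = [t for t in tracts]
    for g in range(min(config.n_indel_groups, len(usable))):
        sid, pos, k, unit = usable[g % len(usable)]
        is_deletion = bool(rng.integers(0, 2))
        group: list[str] = []
        for s, shift in enumerate((0, k)):  # two spellings, one unit apart
            if is_deletion:
                loc = SequenceLocation(sequenceId=sid, start=pos + shift, end=pos + shift + k)
                allele = Allele(location=loc, state="")
            else:
                loc = SequenceLocation(sequenceId=sid, start=pos + shift, end=pos + shift)
                allele = Allele(location=loc, state=unit)
            vid = f"indel{g + 1}{'ab'[s]}"
            variants.append(MolecularVariant.from_allele(vid, allele, annotate(loc, True)))
            group.append(vid)
        spelling_groups.append(group)

    # --- copy-number segments ----------------------------------------------
    code_for_count = {
        0: [CopyChange.COMPLETE_LOSS],
        1: [CopyChange.LOSS, CopyChange.LOW_LEVEL_LOSS],
        2: [None],
        3: [CopyChange.LOW_LEVEL_GAIN],
        4: [CopyChange.GAIN],
        5: [CopyChange.HIGH_LEVEL_GAIN],
        6: [CopyChange.HIGH_LEVEL_GAIN],
    }
    for i in range(config.n_cnvs):
        if gene_locs and rng.random() < 0.5:
            g = gene_locs[int(rng.integers(0, len(gene_locs)))]
            sid = g.location.sequence_id
            pad = int(rng.integers(0, 30))
            start = max(1, g.location.start - pad)
            end = min(references.length(sid), g.location.end + pad)
        else:
            sid = ref_ids[int(rng.integers(0, len(ref_ids)))]
            start = int(rng.integers(1, references.length(sid) - 60))
            end = start + int(rng.integers(30, min(600, references.length(sid) - start)))
        count = int(rng.integers(0, 7))
        options = code_for_count[count]
        code = options[int(rng.integers(0, len(options)))]
        loc = SequenceLocation(sequenceId=sid, start=start, end=end)
        cnv = CopyNumberVariant(location=loc, count=count, changeCode=code)
        variants.append(MolecularVariant.from_copy_number(f"cnv{i + 1}", cnv, annotate(loc, False)))

    # --- adjacencies ---------------------------------------------------------
    breakpoints: list[SequenceLocation] = []
    for g in gene_locs:
        mid = (g.location.start + g.location.end) // 2
        breakpoints.append(SequenceLocation(sequenceId=g.location.sequence_id, start=mid, end=mid))
    for _ in range(4):
        sid = ref_ids[int(rng.integers(0, len(ref_ids)))]
        p = int(rng.integers(1, references.length(sid)))
        breakpoints.append(SequenceLocation(sequenceId=sid, start=p, end=p))
    for i in range(config.n_adjacencies):
        if len(breakpoints) < 2:
            break
        ia, ib = rng.choice(len(breakpoints), size=2, replace=False)
        a, b = breakpoints[int(ia)], breakpoints[int(ib)]
        symbols = genes_at(a) | genes_at(b)
        ann = VariantAnnotation(geneSymbols=symbols) if symbols else None
        adj = AdjacencyVariant(breakendA=a, breakendB=b)
        variants.append(MolecularVariant.from_adjacency(f"adj{i + 1}", adj, ann))

    return Universe(
        config=config,
        seed=seed,
        references=references,
        features=features,
        variants=variants,
        planted={"spelling_groups": spelling_groups, "tracts": tracts},
    )


# ---------------------------------------------------------------------------
# Brute-force oracle


def extension(
    catvar: CategoricalVariant, universe: Universe, ctx: EvaluationContext | None = None
) -> set[str]:
    """Exact member set of ``catvar`` in ``universe``.

    Deliberately a naive double loop over variants and constraints calling
    ``evaluate_constraint`` directly — this exhaustive evaluation *is* the
    oracle, and stays independent of any batch or indexing path.
    """
    ctx = ctx if ctx is not None else universe.context()
    members: set[str] = set()
    if not catvar.constraints:
        return members
    for variant in universe.variants:
        ok = True
        for i, constraint in enumerate(catvar.constraints):
            verdict = evaluate_constraint(constraint, variant, ctx, index=i)
            if verdict.status != VerdictStatus.SATISFIED:
                ok = False
                break
        if ok:
            members.add(variant.id)
    return members


def oracle_entails(
    a: CategoricalVariant,
    b: CategoricalVariant,
    universe: Universe,
    ctx: EvaluationContext | None = None,
) -> tuple[bool, Optional[str]]:
    """True iff extension(a) ⊆ extension(b); on failure returns one witness
    variant id satisfying ``a`` but not ``b``."""
    ctx = ctx if ctx is not None else universe.context()
    ext_a = extension(a, universe, ctx)
    ext_b = extension(b, universe, ctx)
    missing = sorted(ext_a - ext_b)
    return (True, None) if not missing else (False, missing[0])


# ---------------------------------------------------------------------------
# Random categories


def _random_location(rng: np.random.Generator, universe: Universe) -> SequenceLocation:
    choice = rng.random()
    feats = list(universe.features)
    if feats and choice < 0.6:
        rec = feats[int(rng.integers(0, len(feats)))]
        pad = int(rng.integers(0, 40))
        sid = rec.location.sequence_id
        start = max(0, rec.location.start - pad)
        end = min(universe.references.length(sid), rec.location.end + pad)
        return SequenceLocation(sequenceId=sid, start=start, end=end)
    sid = universe.references.ids()[int(rng.integers(0, len(universe.references.ids())))]
    n = universe.references.length(sid)
    start = int(rng.integers(0, n - 50))
    end = start + int(rng.integers(20, min(800, n - start)))
    return SequenceLocation(sequenceId=sid, start=start, end=end)


def _random_constraint(rng: np.random.Generator, universe: Universe, kind: ConstraintKind) -> Constraint:
    if kind == ConstraintKind.DEFINING_ALLELE:
        alleles = [v for v in universe.variants if v.kind == VariantKind.ALLELE]
        v = alleles[int(rng.integers(0, len(alleles)))]
        return DefiningAlleleConstraint(allele=v.allele)
    if kind == ConstraintKind.DEFINING_LOCATION:
        mode = [MatchMode.CONTAINED, MatchMode.CONTAINED, MatchMode.OVERLAPS, MatchMode.EXACT][
            int(rng.integers(0, 4))
        ]
        return DefiningLocationConstraint(location=_random_location(rng, universe), matchMode=mode)
    if kind == ConstraintKind.COPY_COUNT:
        lo = int(rng.integers(0, 6))
        hi = lo + int(rng.integers(0, 4))
        return CopyCountConstraint(minCopies=lo, maxCopies=hi)
    if kind == ConstraintKind.COPY_CHANGE:
        codes = list(CopyChange)
        return CopyChangeConstraint(change=codes[int(rng.integers(0, len(codes)))])
    if kind == ConstraintKind.FEATURE_CONTEXT:
        ids = universe.features.ids()
        return FeatureContextConstraint(feature=ids[int(rng.integers(0, len(ids)))])
    if kind == ConstraintKind.FUNCTION:
        terms = FUNCTION_TERMS + ["loss_of_function", "gain_of_function"]
        return FunctionConstraint(term=terms[int(rng.integers(0, len(terms)))])
    if kind == ConstraintKind.ADJACENCY:
        def side() -> AdjacencySide:
            if rng.random() < 0.7:
                ids = universe.features.ids()
                return AdjacencySide(feature=ids[int(rng.integers(0, len(ids)))])
            return AdjacencySide(location=_random_location(rng, universe))

        return AdjacencyConstraint(side_a=side(), side_b=side(), ordered=bool(rng.integers(0, 2)))
    raise ValueError(kind)


_GENERAL_KINDS = [
    ConstraintKind.DEFINING_ALLELE,
    ConstraintKind.DEFINING_LOCATION,
    ConstraintKind.COPY_COUNT,
    ConstraintKind.COPY_CHANGE,
    ConstraintKind.FEATURE_CONTEXT,
    ConstraintKind.FUNCTION,
    ConstraintKind.ADJACENCY,
]


def generate_random_category(
    universe: Universe,
    seed: int,
    profile: Optional[str] = None,
    registry: ProfileRegistry | None = None,
) -> CategoricalVariant:
    """A reproducible random category whose constraints reference only
    entities of ``universe``; with ``profile`` given, the result validates
    against that profile."""
    rng = np.random.default_rng(seed)
    if profile is None:
        n = int(rng.integers(1, 4))
        constraints = [
            _random_constraint(rng, universe, _GENERAL_KINDS[int(rng.integers(0, len(_GENERAL_KINDS)))])
            for _ in range(n)
        ]
        return CategoricalVariant(id=f"cat-{seed}", label="random category", constraints=constraints)

    reg = registry or default_registry()
    if profile not in reg:
        raise UnknownProfileError(profile)
    K = ConstraintKind
    if profile == "CanonicalAllele":
        constraints = [_random_constraint(rng, universe, K.DEFINING_ALLELE)]
    elif profile == "ProteinSequenceConsequence":
        raise UnknownProfileError(
            "ProteinSequenceConsequence cannot be drawn from a DNA universe"
        )
    elif profile == "CategoricalCNV":
        locish = [K.DEFINING_LOCATION, K.FEATURE_CONTEXT][int(rng.integers(0, 2))]
        dosage = [K.COPY_COUNT, K.COPY_CHANGE][int(rng.integers(0, 2))]
        constraints = [
            _random_constraint(rng, universe, locish),
            _random_constraint(rng, universe, dosage),
        ]
    elif profile == "FunctionVariant":
        constraints = [
            _random_constraint(rng, universe, K.FEATURE_CONTEXT),
            _random_constraint(rng, universe, K.FUNCTION),
        ]
    elif profile == "GeneFusion":
        ids = universe.features.ids()
        constraints = [
            AdjacencyConstraint(
                side_a=AdjacencySide(feature=ids[int(rng.integers(0, len(ids)))]),
                side_b=AdjacencySide(feature=ids[int(rng.integers(0, len(ids)))]),
                ordered=True,
            )
        ]
    else:  # pragma: no cover - registry may hold local profiles
        raise UnknownProfileError(profile)
    return CategoricalVariant(
        id=f"cat-{profile}-{seed}", label=f"random {profile}", constraints=constraints, declaredProfile=profile
    )


# ---------------------------------------------------------------------------
# Planted scenario: deletions in and around one exon


def planted_exon_deletion_universe(seed: int = 0) -> Universe:
    """A small universe with 5 planted deletions, exactly 3 of which fall
    inside the designated exon feature (recorded in ``planted``).

    Deletion sites are stamped with non-repetitive context so normalization
    cannot shift them across the exon boundary; the planted inside/outside
    counts are therefore exact by construction.
    """
    rng = np.random.default_rng(seed)
    length = 2000
    seq = _random_sequence(rng, length)

    gene = (400, 1400)
    exons = [(420, 560), (700, 900), (1100, 1300)]
    target_exon = "GENE1_exon2"

    inside_sites = [720, 790, 860]
    outside_sites = [300, 1500]
    for p in inside_sites + outside_sites:
        # stamp 'TTACGGAA' so deleting 'CG' at [p+3, p+5) cannot shuffle
        for i, ch in enumerate("TTACGGAA"):
            seq[p + i] = ch

    references = SequenceRegistry.from_dict({"ref1": "".join(seq)})
    features = FeatureTable()
    features.add(
        FeatureRecord(
            id="GENE1",
            symbol="GENE1",
            location=SequenceLocation(sequenceId="ref1", start=gene[0], end=gene[1]),
            strand="+",
            feature_class="gene",
        )
    )
    for i, (s, e) in enumerate(exons):
        features.add(
            FeatureRecord(
                id=f"GENE1_exon{i + 1}",
                symbol="GENE1",
                location=SequenceLocation(sequenceId="ref1", start=s, end=e),
                strand="+",
                feature_class="exon",
            )
        )

    variants: list[MolecularVariant] = []
    for j, p in enumerate(inside_sites + outside_sites):
        loc = SequenceLocation(sequenceId="ref1", start=p + 3, end=p + 5)
        allele = Allele(location=loc, state="")
        ann = VariantAnnotation(geneSymbols={"GENE1"}) if gene[0] <= p < gene[1] else None
        variants.append(MolecularVariant.from_allele(f"del{j + 1}", allele, ann))

    config = UniverseConfig(
        nReferences=1, referenceLength=length, nGenes=1, exonsPerGene=3,
        nSnvs=0, nIndelGroups=0, nCnvs=0, nAdjacencies=0,
    )
    return Universe(
        config=config,
        seed=seed,
        references=references,
        features=features,
        variants=variants,
        planted={
            "target_exon": target_exon,
            "inside_count": len(inside_sites),
            "total_deletions": len(inside_sites) + len(outside_sites),
        },
    )


# ---------------------------------------------------------------------------
# File export (FASTA + BED + VCF + TSV), so the full pipeline is exercisable
# through the public file interfaces.


def _vcf_text(universe: Universe) -> str:
    refs = universe.references
    lines = ["##fileformat=VCFv4.2"]
    for sid in refs.ids():
        lines.append(f"##contig=<ID={sid},length={refs.length(sid)}>")
    lines.append('##INFO=<ID=END,Number=1,Type=Integer,Description="End position">')
    lines.append('##INFO=<ID=SVTYPE,Number=1,Type=String,Description="SV type">')
    lines.append('##INFO=<ID=MATEID,Number=1,Type=String,Description="Mate breakend id">')
    lines.append('##FORMAT=<ID=CN,Number=1,Type=Integer,Description="Copy number">')
    lines.append('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1")
    rows: list[tuple[str, int, str]] = []

    for v in universe.variants:
        if v.kind == VariantKind.ALLELE:
            loc = v.allele.location
            sid = loc.sequence_id
            if loc.width() > 0 and v.allele.state:
                pos, ref, alt = loc.start + 1, refs.fetch(sid, loc.start, loc.end), v.allele.state
            elif loc.width() > 0:  # pure deletion: left-anchor
                pos = loc.start  # 1-based position of the anchor base loc.start-1
                ref = refs.fetch(sid, loc.start - 1, loc.end)
                alt = refs.fetch(sid, loc.start - 1, loc.start)
            else:  # pure insertion: left-anchor
                pos = loc.start
                anchor = refs.fetch(sid, loc.start - 1, loc.start)
                ref, alt = anchor, anchor + v.allele.state
            rows.append((sid, pos, f"{sid}\t{pos}\t{v.id}\t{ref}\t{alt}\t.\tPASS\t.\tGT\t0/1"))
        elif v.kind == VariantKind.COPY_NUMBER:
            cnv = v.copy_number
            loc = cnv.location
            sid = loc.sequence_id
            code = cnv.change_code
            if code is not None and copy_change_branch(code) == "LOSS":
                alt, svtype = "<DEL>", "DEL"
            elif code is not None:
                alt, svtype = "<DUP>", "DUP"
            else:
                alt, svtype = "<CNV>", "CNV"
            pos = loc.start  # anchor base at POS, interval = [POS, END) 0-based
            ref = refs.fetch(sid, loc.start - 1, loc.start)
            info = f"END={loc.end};SVTYPE={svtype}"
            cn = cnv.count if cnv.count is not None else "."
            rows.append((sid, pos, f"{sid}\t{pos}\t{v.id}\t{ref}\t{alt}\t.\tPASS\t{info}\tGT:CN\t0/1:{cn}"))
        else:
            adj = v.adjacency
            a, b = adj.breakend_a, adj.breakend_b
            id_a, id_b = f"{v.id}_a", f"{v.id}_b"
            ref_a = refs.fetch(a.sequence_id, a.start, a.start + 1) if a.start < refs.length(a.sequence_id) else "N"
            ref_b = refs.fetch(b.sequence_id, b.start, b.start + 1) if b.start < refs.length(b.sequence_id) else "N"
            alt_a = f"{ref_a}[{b.sequence_id}:{b.start + 1}["
            alt_b = f"]{a.sequence_id}:{a.start + 1}]{ref_b}"
            rows.append((a.sequence_id, a.start + 1,
                         f"{a.sequence_id}\t{a.start + 1}\t{id_a}\t{ref_a}\t{alt_a}\t.\tPASS\tSVTYPE=BND;MATEID={id_b}\tGT\t0/1"))
            rows.append((b.sequence_id, b.start + 1,
                         f"{b.sequence_id}\t{b.start + 1}\t{id_b}\t{ref_b}\t{alt_b}\t.\tPASS\tSVTYPE=BND;MATEID={id_a}\tGT\t0/1"))

    rows.sort(key=lambda r: (r[0], r[1]))
    lines.extend(r[2] for r in rows)
    return "\n".join(lines) + "\n"


def copy_change_branch(code: CopyChange) -> str:
    from .core import copy_change_specializes

    return "LOSS" if copy_change_specializes(code, CopyChange.LOSS) else "GAIN"


def _bed_text(universe: Universe) -> str:
    lines = []
    for rec in universe.features:
        loc = rec.location
        lines.append(f"{loc.sequence_id}\t{loc.start}\t{loc.end}\t{rec.id}\t0\t{rec.strand}\t{rec.feature_class}")
    return "\n".join(lines) + "\n"


def _annotations_text(universe: Universe) -> str:
    lines = ["#variant_id\tgene_symbols\tfunction_terms"]
    for v in universe.variants:
        if v.annotation is None:
            continue
        genes = ",".join(sorted(v.annotation.gene_symbols))
        terms = ",".join(sorted(v.annotation.function_terms))
        lines.append(f"{v.id}\t{genes}\t{terms}")
    return "\n".join(lines) + "\n"


def write_universe(universe: Universe, outdir: str | Path) -> dict[str, Path]:
    """Write a universe as FASTA + BED + VCF + annotation TSV.

    Returns the paths keyed by role.  The files round-trip through the
    io_formats readers: re-ingesting the VCF reproduces the variant
    intervals, and indel spellings keep their normalized digests.
    """
    from .io_formats import write_fasta

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "fasta": outdir / "references.fa",
        "bed": outdir / "features.bed",
        "vcf": outdir / "variants.vcf",
        "annotations": outdir / "annotations.tsv",
    }
    write_fasta(universe.references, paths["fasta"])
    paths["bed"].write_text(_bed_text(universe))
    paths["vcf"].write_text(_vcf_text(universe))
    paths["annotations"].write_text(_annotations_text(universe))
    return paths
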