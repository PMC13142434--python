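"""Domain model for categorical variants and the molecular variants they classify.

A *categorical variant* is an intensional set of genomic alterations: it is
defined by a conjunction of computable constraints rather than by enumerating
members.  A *molecular variant* is one concrete assayed alteration — an allele,
a copy-number observation, or an adjacency (breakend join) — that may or may
not belong to a given category.

Coordinates are inter-residue, 0-based and half-open throughout; format
readers (VCF, BED, 1-based TSV dialects) convert at the boundary.
"""

from __future__ import annotations

import enum
from typing import Annotated, Literal, Optional, Union

from pydantic import BaseModel, ConfigDict, Field

__all__ = [
    "Alphabet",
    "SequenceReference",
    "SequenceRegistry",
    "SequenceLocation",
    "Allele",
    "CopyChange",
    "COPY_CHANGE_PARENT",
    "copy_change_specializes",
    "CopyNumberVariant",
    "AdjacencyOrientation",
    "AdjacencyVariant",
    "VariantAnnotation",
    "VariantKind",
    "MolecularVariant",
    "ConstraintKind",
    "MatchMode",
    "DefiningAlleleConstraint",
    "DefiningLocationConstraint",
    "CopyCountConstraint",
    "CopyChangeConstraint",
    "FeatureContextConstraint",
    "FunctionConstraint",
    "AdjacencySide",
    "AdjacencyConstraint",
    "Constraint",
    "EXPERIMENTAL_CONSTRAINT_KINDS",
    "CategoricalVariant",
    "Severity",
    "Violation",
    "ValidationReport",
    "validate_categorical_variant",
    "DNA_SYMBOLS",
    "PROTEIN_SYMBOLS",
]

DNA_SYMBOLS = frozenset("ACGTN")
PROTEIN_SYMBOLS = frozenset("ACDEFGHIKLMNPQRSTVWYBXZJUO*")


class _Model(BaseModel):
    """Base for all serializable model objects.

    Unknown fields are retained (an extensions bag) so third-party documents
    round-trip losslessly.
    """

    model_config = ConfigDict(
        populate_by_name=True,
        extra="allow",
        validate_assignment=False,
        use_enum_values=False,
    )


class Alphabet(str, enum.Enum):
    DNA = "DNA"
    PROTEIN = "PROTEIN"

    def symbols(self) -> frozenset[str]:
        return DNA_SYMBOLS if self is Alphabet.DNA else PROTEIN_SYMBOLS


class SequenceReference(_Model):
    """A named reference sequence (e.g. an assembly-qualified contig)."""

    id: str
    length: int = Field(ge=0)
    alphabet: Alphabet = Alphabet.DNA


class SequenceRegistry:
    """In-memory registry of reference sequences with residue access.

    Serves subsequences for normalization and bounds/alphabet checks.  Built
    from a dict, a FASTA file (see :mod:`catvar.io_formats`) or a synthetic
    universe.
    """

    def __init__(self) -> None:
        self._seqs: dict[str, str] = {}
        self._refs: dict[str, SequenceReference] = {}

    @classmethod
    def from_dict(cls, seqs: dict[str, str], alphabet: Alphabet = Alphabet.DNA) -> "SequenceRegistry":
        reg = cls()
        for sid, seq in seqs.items():
            reg.add(sid, seq, alphabet)
        return reg

    def add(self, sequence_id: str, sequence: str, alphabet: Alphabet | None = None) -> None:
        if sequence_id in self._seqs:
            raise ValueError(f"duplicate sequence id {sequence_id!r}")
        seq = sequence.upper()
        if alphabet is None:
            alphabet = Alphabet.DNA if set(seq) <= DNA_SYMBOLS else Alphabet.PROTEIN
        self._seqs[sequence_id] = seq
        self._refs[sequence_id] = SequenceReference(id=sequence_id, length=len(seq), alphabet=alphabet)

    def __contains__(self, sequence_id: str) -> bool:
        return sequence_id in self._seqs

    def ids(self) -> list[str]:
        return list(self._seqs)

    def reference(self, sequence_id: str) -> SequenceReference:
        return self._refs[sequence_id]

    def length(self, sequence_id: str) -> int:
        return len(self._seqs[sequence_id])

    def alphabet(self, sequence_id: str) -> Alphabet:
        return self._refs[sequence_id].alphabet

    def fetch(self, sequence_id: str, start: int, end: int) -> str:
        seq = self._seqs[sequence_id]
        if not (0 <= start <= end <= len(seq)):
            raise IndexError(f"[{start},{end}) out of bounds for {sequence_id!r} (length {len(seq)})")
        return seq[start:end]

    def sequence(self, sequence_id: str) -> str:
        return self._seqs[sequence_id]


class SequenceLocation(_Model):
    """Inter-residue interval ``[start, end)`` on a named sequence."""

    sequence_id: str = Field(alias="sequenceId")
    start: int = Field(ge=0)
    end: int = Field(ge=0)

    def width(self) -> int:
        return self.end - self.start

    def key(self) -> tuple[str, int, int]:
        return (self.sequence_id, self.start, self.end)


def interval_contains(outer: SequenceLocation, inner: SequenceLocation) -> bool:
    """``inner`` ⊆ ``outer`` on the same sequence."""
    return (
        inner.sequence_id == outer.sequence_id
        and outer.start <= inner.start
        and inner.end <= outer.end
    )


def interval_overlaps(a: SequenceLocation, b: SequenceLocation) -> bool:
    """Nonempty intersection on the same sequence.

    Zero-width intervals (insertion breakpoints) are treated as closed
    points: the point ``p`` overlaps ``[s, e)`` when ``s <= p <= e``.  Under
    plain half-open intersection a zero-width interval would overlap nothing,
    which would make containment-based reasoning inconsistent for insertions.
    """
    if a.sequence_id != b.sequence_id:
        return False
    if a.width() == 0 and b.width() == 0:
        return a.start == b.start
    if a.width() == 0:
        return b.start <= a.start <= b.end
    if b.width() == 0:
        return a.start <= b.start <= a.end
    return max(a.start, b.start) < min(a.end, b.end)


class Allele(_Model):
    """A literal sequence state replacing the reference at a location."""

    location: SequenceLocation
    state: str


class CopyChange(str, enum.Enum):
    """Relative copy-dosage vocabulary with a two-branch specialization order."""

    COMPLETE_LOSS = "COMPLETE_LOSS"
    LOSS = "LOSS"
    LOW_LEVEL_LOSS = "LOW_LEVEL_LOSS"
    GAIN = "GAIN"
    LOW_LEVEL_GAIN = "LOW_LEVEL_GAIN"
    HIGH_LEVEL_GAIN = "HIGH_LEVEL_GAIN"


#: specialization edges child -> parent; LOSS and GAIN branches are disjoint.
COPY_CHANGE_PARENT: dict[CopyChange, CopyChange] = {
    CopyChange.COMPLETE_LOSS: CopyChange.LOSS,
    CopyChange.LOW_LEVEL_LOSS: CopyChange.LOSS,
    CopyChange.LOW_LEVEL_GAIN: CopyChange.GAIN,
    CopyChange.HIGH_LEVEL_GAIN: CopyChange.GAIN,
}


def copy_change_specializes(child: CopyChange, ancestor: CopyChange) -> bool:
    """Reflexive-transitive specialization test over the copy-change order."""
    node: CopyChange | None = child
    while node is not None:
        if node == ancestor:
            return True
        node = COPY_CHANGE_PARENT.get(node)
    return False


class CopyNumberVariant(_Model):
    """Copy-number observation: absolute count and/or relative change code."""

    location: SequenceLocation
    count: Optional[int] = Field(default=None, ge=0)
    change_code: Optional[CopyChange] = Field(default=None, alias="changeCode")


class AdjacencyOrientation(str, enum.Enum):
    AB = "AB"
    BA = "BA"
    UNORDERED = "UNORDERED"


class AdjacencyVariant(_Model):
    """The join of two sequence breakends (rearrangement / fusion substrate)."""

    breakend_a: SequenceLocation = Field(alias="breakendA")
    breakend_b: SequenceLocation = Field(alias="breakendB")
    orientation: AdjacencyOrientation = AdjacencyOrientation.AB


class VariantAnnotation(_Model):
    """Functional annotation attached to an assayed variant."""

    gene_symbols: set[str] = Field(default_factory=set, alias="geneSymbols")
    function_terms: set[str] = Field(default_factory=set, alias="functionTerms")

    def model_post_init(self, __context) -> None:  # case-normalize terms
        object.__setattr__(self, "gene_symbols", {s.upper() for s in self.gene_symbols})
        object.__setattr__(self, "function_terms", {t.lower() for t in self.function_terms})


class VariantKind(str, enum.Enum):
    ALLELE = "ALLELE"
    COPY_NUMBER = "COPY_NUMBER"
    ADJACENCY = "ADJACENCY"


class MolecularVariant(_Model):
    """One concrete assayed variant, tagged by kind with a matching payload."""

    id: str
    kind: VariantKind
    allele: Optional[Allele] = None
    copy_number: Optional[CopyNumberVariant] = Field(default=None, alias="copyNumber")
    adjacency: Optional[AdjacencyVariant] = None
    annotation: Optional[VariantAnnotation] = None

    @classmethod
    def from_allele(cls, id: str, allele: Allele, annotation: VariantAnnotation | None = None) -> "MolecularVariant":
        return cls(id=id, kind=VariantKind.ALLELE, allele=allele, annotation=annotation)

    @classmethod
    def from_copy_number(cls, id: str, cnv: CopyNumberVariant, annotation: VariantAnnotation | None = None) -> "MolecularVariant":
        return cls(id=id, kind=VariantKind.COPY_NUMBER, copy_number=cnv, annotation=annotation)

    @classmethod
    def from_adjacency(cls, id: str, adj: AdjacencyVariant, annotation: VariantAnnotation | None = None) -> "MolecularVariant":
        return cls(id=id, kind=VariantKind.ADJACENCY, adjacency=adj, annotation=annotation)

    def payload(self):
        return {
            VariantKind.ALLELE: self.allele,
            VariantKind.COPY_NUMBER: self.copy_number,
            VariantKind.ADJACENCY: self.adjacency,
        }[self.kind]

    def payload_kind_consistent(self) -> bool:
        present = [
            self.allele is not None,
            self.copy_number is not None,
            self.adjacency is not None,
        ]
        expected = [
            self.kind == VariantKind.ALLELE,
            self.kind == VariantKind.COPY_NUMBER,
            self.kind == VariantKind.ADJACENCY,
        ]
        return present == expected

    def primary_location(self) -> Optional[SequenceLocation]:
        """The location used for positional constraints; None for adjacencies
        (which expose two breakends instead)."""
        if self.kind == VariantKind.ALLELE and self.allele is not None:
            return self.allele.location
        if self.kind == VariantKind.COPY_NUMBER and self.copy_number is not None:
            return self.copy_number.location
        return None


# --------------------------------------------------------------------------
# Constraints


class ConstraintKind(str, enum.Enum):
    DEFINING_ALLELE = "DEFINING_ALLELE"
    DEFINING_LOCATION = "DEFINING_LOCATION"
    COPY_COUNT = "COPY_COUNT"
    COPY_CHANGE = "COPY_CHANGE"
    FEATURE_CONTEXT = "FEATURE_CONTEXT"
    FUNCTION = "FUNCTION"
    ADJACENCY = "ADJACENCY"


#: Kinds still maturing; the CLI requires --experimental to evaluate them.
EXPERIMENTAL_CONSTRAINT_KINDS = frozenset({ConstraintKind.FUNCTION, ConstraintKind.ADJACENCY})


class MatchMode(str, enum.Enum):
    EXACT = "EXACT"
    CONTAINED = "CONTAINED"
    OVERLAPS = "OVERLAPS"


class DefiningAlleleConstraint(_Model):
    """Members must be (representations of) one specific allele."""

    type: Literal["DefiningAlleleConstraint"] = "DefiningAlleleConstraint"
    allele: Allele
    equivalence_set_id: Optional[str] = Field(default=None, alias="equivalenceSetId")

    @property
    def kind(self) -> ConstraintKind:
        return ConstraintKind.DEFINING_ALLELE


class DefiningLocationConstraint(_Model):
    """Members must relate positionally to one sequence location.

    Default match mode is CONTAINED: a category like "exon 19 deletions"
    intends events within the region.
    """

    type: Literal["DefiningLocationConstraint"] = "DefiningLocationConstraint"
    location: SequenceLocation
    match_mode: MatchMode = Field(default=MatchMode.CONTAINED, alias="matchMode")

    @property
    def kind(self) -> ConstraintKind:
        return ConstraintKind.DEFINING_LOCATION


class CopyCountConstraint(_Model):
    """Members must carry an absolute copy count in ``[min_copies, max_copies]``."""

    type: Literal["CopyCountConstraint"] = "CopyCountConstraint"
    min_copies: int = Field(alias="minCopies", ge=0)
    max_copies: int = Field(alias="maxCopies", ge=0)

    @property
    def kind(self) -> ConstraintKind:
        return ConstraintKind.COPY_COUNT


class CopyChangeConstraint(_Model):
    """Members must carry the given relative copy-change code (or a
    specialization of it)."""

    type: Literal["CopyChangeConstraint"] = "CopyChangeConstraint"
    change: CopyChange

    @property
    def kind(self) -> ConstraintKind:
        return ConstraintKind.COPY_CHANGE


class FeatureContextConstraint(_Model):
    """Members must involve a named feature (gene/exon), by interval overlap
    or by gene-symbol annotation."""

    type: Literal["FeatureContextConstraint"] = "FeatureContextConstraint"
    feature: str

    @property
    def kind(self) -> ConstraintKind:
        return ConstraintKind.FEATURE_CONTEXT


class FunctionConstraint(_Model):
    """Members must be annotated with a functional-consequence term equal to,
    or descending from, the given term."""

    type: Literal["FunctionConstraint"] = "FunctionConstraint"
    term: str
    apply_hierarchy: bool = Field(default=True, alias="applyHierarchy")

    @property
    def kind(self) -> ConstraintKind:
        return ConstraintKind.FUNCTION


class AdjacencySide(_Model):
    """One side of an adjacency constraint: a location or a feature id."""

    location: Optional[SequenceLocation] = None
    feature: Optional[str] = None

    def is_well_formed(self) -> bool:
        return (self.location is None) != (self.feature is None)


class AdjacencyConstraint(_Model):
    """Members must be adjacencies whose breakends satisfy the two sides.

    Sides are ordered by default (5'/3' partner semantics); set
    ``ordered=False`` to allow swapped assignment.
    """

    type: Literal["AdjacencyConstraint"] = "AdjacencyConstraint"
    side_a: AdjacencySide = Field(alias="sideA")
    side_b: AdjacencySide = Field(alias="sideB")
    ordered: bool = True

    @property
    def kind(self) -> ConstraintKind:
        return ConstraintKind.ADJACENCY


Constraint = Annotated[
    Union[
        DefiningAlleleConstraint,
        DefiningLocationConstraint,
        CopyCountConstraint,
        CopyChangeConstraint,
        FeatureContextConstraint,
        FunctionConstraint,
        AdjacencyConstraint,
    ],
    Field(discriminator="type"),
]


class CategoricalVariant(_Model):
    """A category of variation: conjunction of constraints plus identity.

    The constraint list is interpreted conjunctively; a member variant must
    satisfy every constraint.  An empty list is invalid — a property-free
    category has no computable meaning.
    """

    id: str
    label: str = ""
    constraints: list[Constraint] = Field(default_factory=list)
    declared_profile: Optional[str] = Field(default=None, alias="declaredProfile")


# --------------------------------------------------------------------------
# Validation


class Severity(str, enum.Enum):
    ERROR = "ERROR"
    WARNING = "WARNING"
    INFO = "INFO"


class Violation(BaseModel):
    code: str
    message: str
    severity: Severity = Severity.ERROR
    path: str = ""

    def __hash__(self) -> int:
        return hash((self.code, self.message, self.severity, self.path))


class ValidationReport(BaseModel):
    violations: list[Violation] = Field(default_factory=list)

    @property
    def is_valid(self) -> bool:
        return not any(v.severity == Severity.ERROR for v in self.violations)

    def codes(self) -> set[str]:
        return {v.code for v in self.violations}

    def add(self, code: str, message: str, severity: Severity = Severity.ERROR, path: str = "") -> None:
        self.violations.append(Violation(code=code, message=message, severity=severity, path=path))


def _validate_location(
    loc: SequenceLocation, report: ValidationReport, path: str, sequences: SequenceRegistry | None
) -> None:
    if loc.start > loc.end:
        report.add("BAD_LOCATION", f"start {loc.start} > end {loc.end}", path=path)
    if sequences is not None and loc.sequence_id in sequences:
        n = sequences.length(loc.sequence_id)
        if loc.end > n:
            report.add("OUT_OF_BOUNDS", f"end {loc.end} exceeds length {n} of {loc.sequence_id!r}", path=path)


def validate_categorical_variant(
    doc: CategoricalVariant, sequences: SequenceRegistry | None = None
) -> ValidationReport:
    """Check the structural invariants of a categorical variant.

    Violations are data, not exceptions; each carries a stable code.  The
    resulting violation set does not depend on constraint order beyond the
    positional path strings.
    """
    report = ValidationReport()
    if not doc.constraints:
        report.add("EMPTY_CONSTRAINTS", "constraint list must be non-empty", path="constraints")
        return report

    kind_counts: dict[ConstraintKind, int] = {}
    for i, c in enumerate(doc.constraints):
        path = f"constraints[{i}]"
        kind_counts[c.kind] = kind_counts.get(c.kind, 0) + 1
        if isinstance(c, CopyCountConstraint):
            if c.min_copies > c.max_copies:
                report.add("BAD_RANGE", f"min {c.min_copies} > max {c.max_copies}", path=path)
        elif isinstance(c, DefiningLocationConstraint):
            _validate_location(c.location, report, path, sequences)
        elif isinstance(c, DefiningAlleleConstraint):
            _validate_location(c.allele.location, report, path, sequences)
            if sequences is not None and c.allele.location.sequence_id in sequences:
                alpha = sequences.alphabet(c.allele.location.sequence_id)
                if not set(c.allele.state) <= alpha.symbols():
                    report.add(
                        "ALPHABET_MISMATCH",
                        f"state {c.allele.state!r} has symbols outside the {alpha.value} alphabet",
                        path=path,
                    )
        elif isinstance(c, AdjacencyConstraint):
            for side_name, side in (("sideA", c.side_a), ("sideB", c.side_b)):
                if not side.is_well_formed():
                    report.add(
                        "BAD_ADJACENCY_SIDE",
                        f"{side_name} must specify exactly one of location / feature",
                        path=path,
                    )
                elif side.location is not None:
                    _validate_location(side.location, report, f"{path}.{side_name}", sequences)

    for kind, n in sorted(kind_counts.items(), key=lambda kv: kv[0].value):
        if n > 1:
            report.add(
                "REPEATED_KIND",
                f"{n} constraints of kind {kind.value}; conjunction applies to all of them",
                severity=Severity.INFO,
                path="constraints",
            )
    for kind in sorted(kind_counts, key=lambda k: k.value):
        if kind in EXPERIMENTAL_CONSTRAINT_KINDS:
            report.add(
                "EXPERIMENTAL_CONSTRAINT",
                f"constraint kind {kind.value} is experimental",
                severity=Severity.INFO,
                path="constraints",
            )
    return report


def validate_molecular_variant(
    variant: MolecularVariant, sequences: SequenceRegistry | None = None
) -> ValidationReport:
    """Structural checks for an assayed variant (payload/kind agreement,
    locations in bounds, state over the reference alphabet)."""
    report = ValidationReport()
    if not variant.payload_kind_consistent():
        report.add("PAYLOAD_KIND_MISMATCH", f"payload does not match kind {variant.kind.value}")
        return report
    if variant.kind == VariantKind.ALLELE:
        assert variant.allele is not None
        _validate_location(variant.allele.location, report, "allele.location", sequences)
        if sequences is not None and variant.allele.location.sequence_id in sequences:
            alpha = sequences.alphabet(variant.allele.location.sequence_id)
            if not set(variant.allele.state) <= alpha.symbols():
                report.add("ALPHABET_MISMATCH", f"state {variant.allele.state!r} not over {alpha.value}")
    elif variant.kind == VariantKind.COPY_NUMBER:
        assert variant.copy_number is not None
        cnv = variant.copy_number
        _validate_location(cnv.location, report, "copyNumber.location", sequences)
        if cnv.count is None and cnv.change_code is None:
            report.add("EMPTY_COPY_NUMBER", "copy-number variant needs a count or a change code")
    else:
        assert variant.adjacency is not None
        _validate_location(variant.adjacency.breakend_a, report, "adjacency.breakendA", sequences)
        _validate_location(variant.adjacency.breakend_b, report, "adjacency.breakendB", sequences)
        if sequences is not None:
            for name, be in (("breakendA", variant.adjacency.breakend_a), ("breakendB", variant.adjacency.breakend_b)):
                if be.sequence_id not in sequences:
                    report.add("UNKNOWN_SEQUENCE", f"{name} on unknown sequence {be.sequence_id!r}")
    return report
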