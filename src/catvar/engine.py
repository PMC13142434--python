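"""Constraint evaluation: does an assayed variant belong to a category?

Each constraint is evaluated to a three-way verdict:

* ``SATISFIED`` — the variant demonstrably has the required property;
* ``UNSATISFIED`` — the variant carries the tested attribute but its value
  fails the constraint;
* ``INAPPLICABLE`` — the variant lacks the attribute the constraint tests
  (an SNV has no copy-change code, an allele is not an adjacency).

Whether a verdict is INAPPLICABLE rather than UNSATISFIED depends only on
the variant's kind and which attributes are present, never on attribute
values.  Category membership is conjunctive and closed-world: a category's
extension contains only variants for which *every* constraint is SATISFIED,
so INAPPLICABLE counts as a non-match.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Optional

from pydantic import BaseModel, Field

from .core import (
    AdjacencyConstraint,
    AdjacencyOrientation,
    AdjacencySide,
    CategoricalVariant,
    Constraint,
    CopyChangeConstraint,
    CopyCountConstraint,
    DefiningAlleleConstraint,
    DefiningLocationConstraint,
    FeatureContextConstraint,
    FunctionConstraint,
    MatchMode,
    MolecularVariant,
    SequenceLocation,
    SequenceRegistry,
    VariantKind,
    copy_change_specializes,
    interval_contains,
    interval_overlaps,
)
from .features import FeatureRecord, FeatureTable
from .normalize import NormalizationError, allele_digest, normalize_allele

__all__ = [
    "EvaluationContext",
    "VerdictStatus",
    "ConstraintVerdict",
    "MatchReport",
    "UnknownFeatureError",
    "evaluate_constraint",
    "match",
    "match_batch",
]


class UnknownFeatureError(KeyError):
    """A constraint references a feature absent from the evaluation context."""

    code = "UNKNOWN_FEATURE"


@dataclass
class EvaluationContext:
    """Everything constraint evaluation may consult beyond the variant itself.

    Parameters
    ----------
    feature_table
        Resolves feature ids/symbols to sequence intervals.
    sequences
        Reference registry used to normalize allele spellings before digest
        and location comparison; without it alleles are compared as spelled.
    function_hierarchy
        Child term → set of parent terms (acyclic); a variant term satisfies
        a Function constraint when it equals the constraint term or descends
        from it.
    allele_equivalences
        Digest → canonical digest, for user-supplied equivalence classes
        (e.g. liftover or transcript projections computed elsewhere); must be
        idempotent after one application.
    """

    feature_table: FeatureTable = field(default_factory=FeatureTable)
    sequences: Optional[SequenceRegistry] = None
    function_hierarchy: dict[str, set[str]] = field(default_factory=dict)
    allele_equivalences: dict[str, str] = field(default_factory=dict)
    # memo of normalized forms keyed by the allele's identifying tuple;
    # normalization is pure, so caching cannot change any verdict
    _norm_cache: dict = field(default_factory=dict, repr=False)

    def _normalized_form(self, allele):
        key = (allele.location.sequence_id, allele.location.start, allele.location.end, allele.state)
        form = self._norm_cache.get(key)
        if form is None and self.sequences is not None:
            form = normalize_allele(allele, self.sequences)
            self._norm_cache[key] = form
        return form

    def resolve_feature(self, key: str) -> FeatureRecord:
        rec = self.feature_table.get(key)
        if rec is None:
            raise UnknownFeatureError(key)
        return rec

    def canonical_digest(self, digest: str) -> str:
        return self.allele_equivalences.get(digest, digest)

    def normalized_allele_digest(self, variant_or_allele) -> str:
        """Digest of the normalized allele; falls back to the raw spelling
        when no sequences are available or the allele is out of bounds."""
        allele = getattr(variant_or_allele, "allele", variant_or_allele) or variant_or_allele
        try:
            form = self._normalized_form(allele)
        except NormalizationError:
            form = None
        return form.digest_id if form is not None else allele_digest(allele)

    def function_term_matches(self, term: str, target: str, use_hierarchy: bool) -> bool:
        term, target = term.lower(), target.lower()
        if term == target:
            return True
        if not use_hierarchy:
            return False
        seen: set[str] = set()
        frontier = [term]
        while frontier:
            t = frontier.pop()
            if t in seen:
                continue
            seen.add(t)
            for parent in self.function_hierarchy.get(t, set()):
                p = parent.lower()
                if p == target:
                    return True
                frontier.append(p)
        return False


class VerdictStatus(str, enum.Enum):
    SATISFIED = "SATISFIED"
    UNSATISFIED = "UNSATISFIED"
    INAPPLICABLE = "INAPPLICABLE"


class ConstraintVerdict(BaseModel):
    constraint_index: int = Field(alias="constraintIndex")
    status: VerdictStatus
    reason: str = ""
    detail: str = ""

    model_config = {"populate_by_name": True}


class MatchReport(BaseModel):
    """Per-constraint verdicts plus the overall conjunctive decision."""

    categorical_variant_id: str = Field(alias="categoricalVariantId")
    variant_id: str = Field(alias="variantId")
    verdicts: list[ConstraintVerdict]
    overall: bool

    model_config = {"populate_by_name": True}

    def explain(self) -> str:
        lines = [
            f"{self.categorical_variant_id} vs {self.variant_id}: "
            f"{'MATCH' if self.overall else 'NO MATCH'}"
        ]
        for v in self.verdicts:
            lines.append(f"  [{v.constraint_index}] {v.status.value} ({v.reason}) {v.detail}".rstrip())
        return "\n".join(lines)


def _verdict(index: int, status: VerdictStatus, reason: str, detail: str = "") -> ConstraintVerdict:
    return ConstraintVerdict(constraint_index=index, status=status, reason=reason, detail=detail)


def _variant_location(variant: MolecularVariant, ctx: EvaluationContext) -> Optional[SequenceLocation]:
    """Location used for positional tests.  Allele locations are normalized
    first (when references are available) so membership never depends on an
    indel's spelling; adjacencies have no single location."""
    if variant.kind == VariantKind.ALLELE and variant.allele is not None:
        try:
            form = ctx._normalized_form(variant.allele)
        except NormalizationError:
            form = None
        return form.allele.location if form is not None else variant.allele.location
    return variant.primary_location()


def _location_matches(variant_loc: SequenceLocation, target: SequenceLocation, mode: MatchMode) -> bool:
    if mode == MatchMode.EXACT:
        return variant_loc.key() == target.key()
    if mode == MatchMode.CONTAINED:
        return interval_contains(target, variant_loc)
    return interval_overlaps(variant_loc, target)


def _breakend_satisfies_side(
    breakend: SequenceLocation, side: AdjacencySide, ctx: EvaluationContext
) -> bool:
    if side.feature is not None:
        rec = ctx.resolve_feature(side.feature)
        return interval_overlaps(breakend, rec.location)
    assert side.location is not None
    return interval_contains(side.location, breakend)


def evaluate_constraint(
    constraint: Constraint, variant: MolecularVariant, ctx: EvaluationContext, index: int = 0
) -> ConstraintVerdict:
    """Evaluate one constraint against one variant.

    Raises :class:`UnknownFeatureError` when the constraint references a
    feature the context cannot resolve; every other outcome is a verdict.
    """
    if isinstance(constraint, DefiningAlleleConstraint):
        if variant.kind != VariantKind.ALLELE or variant.allele is None:
            return _verdict(index, VerdictStatus.INAPPLICABLE, "NOT_AN_ALLELE")
        want = ctx.canonical_digest(ctx.normalized_allele_digest(constraint.allele))
        got = ctx.canonical_digest(ctx.normalized_allele_digest(variant.allele))
        if got == want:
            return _verdict(index, VerdictStatus.SATISFIED, "ALLELE_DIGEST_EQUAL", got)
        return _verdict(index, VerdictStatus.UNSATISFIED, "ALLELE_DIGEST_DIFFERS", f"{got} != {want}")

    if isinstance(constraint, DefiningLocationConstraint):
        loc = _variant_location(variant, ctx)
        if loc is None:
            return _verdict(index, VerdictStatus.INAPPLICABLE, "NO_LOCATION")
        ok = _location_matches(loc, constraint.location, constraint.match_mode)
        reason = f"LOCATION_{constraint.match_mode.value}"
        return _verdict(index, VerdictStatus.SATISFIED if ok else VerdictStatus.UNSATISFIED, reason)

    if isinstance(constraint, CopyCountConstraint):
        if variant.kind != VariantKind.COPY_NUMBER or variant.copy_number is None:
            return _verdict(index, VerdictStatus.INAPPLICABLE, "NOT_COPY_NUMBER")
        count = variant.copy_number.count
        if count is None:
            return _verdict(index, VerdictStatus.INAPPLICABLE, "NO_COUNT")
        ok = constraint.min_copies <= count <= constraint.max_copies
        detail = f"count {count} vs [{constraint.min_copies},{constraint.max_copies}]"
        return _verdict(index, VerdictStatus.SATISFIED if ok else VerdictStatus.UNSATISFIED, "COPY_COUNT", detail)

    if isinstance(constraint, CopyChangeConstraint):
        if variant.kind != VariantKind.COPY_NUMBER or variant.copy_number is None:
            return _verdict(index, VerdictStatus.INAPPLICABLE, "NOT_COPY_NUMBER")
        code = variant.copy_number.change_code
        if code is None:
            # a bare count is never auto-converted: no baseline ploidy is assumed
            return _verdict(index, VerdictStatus.INAPPLICABLE, "NO_CHANGE_CODE")
        ok = copy_change_specializes(code, constraint.change)
        detail = f"{code.value} vs {constraint.change.value}"
        return _verdict(index, VerdictStatus.SATISFIED if ok else VerdictStatus.UNSATISFIED, "COPY_CHANGE", detail)

    if isinstance(constraint, FeatureContextConstraint):
        rec = ctx.resolve_feature(constraint.feature)
        loc = _variant_location(variant, ctx)
        locs: list[SequenceLocation] = [loc] if loc is not None else []
        if variant.kind == VariantKind.ADJACENCY and variant.adjacency is not None:
            locs = [variant.adjacency.breakend_a, variant.adjacency.breakend_b]
        symbols = variant.annotation.gene_symbols if variant.annotation else set()
        if not locs and not symbols:
            return _verdict(index, VerdictStatus.INAPPLICABLE, "NO_LOCATION_OR_ANNOTATION")
        if any(interval_overlaps(l, rec.location) for l in locs):
            return _verdict(index, VerdictStatus.SATISFIED, "FEATURE_OVERLAP", rec.id)
        if rec.symbol.upper() in symbols:
            return _verdict(index, VerdictStatus.SATISFIED, "FEATURE_SYMBOL", rec.symbol)
        return _verdict(index, VerdictStatus.UNSATISFIED, "FEATURE_MISS", rec.id)

    if isinstance(constraint, FunctionConstraint):
        if variant.annotation is None or not variant.annotation.function_terms:
            return _verdict(index, VerdictStatus.INAPPLICABLE, "NO_FUNCTION_ANNOTATION")
        for term in sorted(variant.annotation.function_terms):
            if ctx.function_term_matches(term, constraint.term, constraint.apply_hierarchy):
                return _verdict(index, VerdictStatus.SATISFIED, "FUNCTION_TERM", term)
        return _verdict(index, VerdictStatus.UNSATISFIED, "FUNCTION_TERM_MISS", constraint.term)

    if isinstance(constraint, AdjacencyConstraint):
        if variant.kind != VariantKind.ADJACENCY or variant.adjacency is None:
            return _verdict(index, VerdictStatus.INAPPLICABLE, "NOT_ADJACENCY")
        adj = variant.adjacency
        forward = _breakend_satisfies_side(adj.breakend_a, constraint.side_a, ctx) and _breakend_satisfies_side(
            adj.breakend_b, constraint.side_b, ctx
        )
        swapped = _breakend_satisfies_side(adj.breakend_b, constraint.side_a, ctx) and _breakend_satisfies_side(
            adj.breakend_a, constraint.side_b, ctx
        )
        swap_allowed = (not constraint.ordered) or adj.orientation == AdjacencyOrientation.UNORDERED
        ok = forward or (swap_allowed and swapped)
        return _verdict(index, VerdictStatus.SATISFIED if ok else VerdictStatus.UNSATISFIED, "ADJACENCY_SIDES")

    raise TypeError(f"unknown constraint type {type(constraint).__name__}")


def match(catvar: CategoricalVariant, variant: MolecularVariant, ctx: EvaluationContext) -> MatchReport:
    """Evaluate every constraint of ``catvar`` against ``variant``.

    The report carries one verdict per constraint, in constraint order, and
    ``overall`` is true iff every verdict is SATISFIED (conjunctive
    semantics).  Deterministic for fixed inputs.
    """
    verdicts = [evaluate_constraint(c, variant, ctx, index=i) for i, c in enumerate(catvar.constraints)]
    overall = bool(verdicts) and all(v.status == VerdictStatus.SATISFIED for v in verdicts)
    return MatchReport(
        categorical_variant_id=catvar.id, variant_id=variant.id, verdicts=verdicts, overall=overall
    )


def match_batch(
    catvars: list[CategoricalVariant], variants: list[MolecularVariant], ctx: EvaluationContext
) -> list[list[MatchReport]]:
    """Matrix of match reports; element ``[i][j]`` equals
    ``match(catvars[i], variants[j], ctx)`` and row/column order follows the
    input order."""
    return [[match(cv, v, ctx) for v in variants] for cv in catvars]
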