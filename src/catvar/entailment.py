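"""Sound (but deliberately incomplete) entailment between categories.

Category A *entails* category B when every variant satisfying A also
satisfies B — extension subset in every universe.  The decision procedure is
syntactic subsumption over constraint pairs: A entails B when every
constraint of B is subsumed by some constraint of A.  The rule set is kept
sound rather than complete: a verdict of ENTAILS is always justified by a
rule chain that holds over all universes; everything the rules cannot decide
is UNKNOWN, which a finite probe universe may upgrade to NOT_ENTAILED by
exhibiting a counterexample variant.
"""

from __future__ import annotations

import enum
from typing import TYPE_CHECKING, Optional

from pydantic import BaseModel, Field

from .core import (
    CategoricalVariant,
    Constraint,
    CopyChangeConstraint,
    CopyCountConstraint,
    DefiningAlleleConstraint,
    DefiningLocationConstraint,
    FeatureContextConstraint,
    MatchMode,
    SequenceLocation,
    copy_change_specializes,
    interval_contains,
    interval_overlaps,
)
from .engine import EvaluationContext
from .normalize import NormalizationError, normalize_allele

if TYPE_CHECKING:  # pragma: no cover
    from .universe import Universe

__all__ = ["EntailmentStatus", "TriVerdict", "subsumes", "entails"]


class EntailmentStatus(str, enum.Enum):
    ENTAILS = "ENTAILS"
    NOT_ENTAILED = "NOT_ENTAILED"
    UNKNOWN = "UNKNOWN"


class TriVerdict(BaseModel):
    status: EntailmentStatus
    justification: list[str] = Field(default_factory=list)
    counterexample: Optional[str] = None


def _entails(just: str) -> TriVerdict:
    return TriVerdict(status=EntailmentStatus.ENTAILS, justification=[just])


def _unknown(just: str = "") -> TriVerdict:
    return TriVerdict(status=EntailmentStatus.UNKNOWN, justification=[just] if just else [])


def _constraints_identical(a: Constraint, b: Constraint) -> bool:
    return type(a) is type(b) and a.model_dump(by_alias=True, exclude_none=True) == b.model_dump(
        by_alias=True, exclude_none=True
    )


def _normalized_allele_location(c: DefiningAlleleConstraint, ctx: EvaluationContext) -> SequenceLocation:
    if ctx.sequences is not None:
        try:
            return normalize_allele(c.allele, ctx.sequences).allele.location
        except NormalizationError:
            pass
    return c.allele.location


def _location_subsumed_by(loc: SequenceLocation, b: DefiningLocationConstraint) -> bool:
    if b.match_mode == MatchMode.EXACT:
        return loc.key() == b.location.key()
    if b.match_mode == MatchMode.CONTAINED:
        return interval_contains(b.location, loc)
    return interval_overlaps(loc, b.location)


def subsumes(a: Constraint, b: Constraint, ctx: EvaluationContext) -> TriVerdict:
    """Decide whether every variant satisfying ``a`` satisfies ``b``.

    Rules (everything else is UNKNOWN):

    * identical constraints subsume each other (reflexivity, all kinds);
    * DefiningAllele ⊑ DefiningAllele: equal canonical digests;
    * DefiningAllele ⊑ DefiningLocation: the (normalized) defining allele's
      location satisfies ``b`` under ``b``'s match mode;
    * DefiningAllele / DefiningLocation(CONTAINED) ⊑ FeatureContext: the
      constraining interval lies within the feature's interval;
    * DefiningLocation(CONTAINED, L1) ⊑ DefiningLocation(CONTAINED/OVERLAPS, L2)
      with L1 ⊆ L2 (CONTAINED) or L1 within-bounds (OVERLAPS via containment);
    * CopyCount range inclusion; CopyChange specialization;
    * FeatureContext ⊑ FeatureContext for the same feature.
    """
    if _constraints_identical(a, b):
        return _entails("identical constraints")

    if isinstance(a, DefiningAlleleConstraint) and isinstance(b, DefiningAlleleConstraint):
        da = ctx.canonical_digest(ctx.normalized_allele_digest(a.allele))
        db = ctx.canonical_digest(ctx.normalized_allele_digest(b.allele))
        if da == db:
            return _entails(f"same canonical allele digest {da}")
        return _unknown("different defining alleles")

    if isinstance(a, DefiningAlleleConstraint) and isinstance(b, DefiningLocationConstraint):
        if ctx.allele_equivalences:
            # an equivalent allele may live on another sequence; positional
            # subsumption from an allele is only sound without equivalences
            return _unknown("allele equivalences present")
        loc = _normalized_allele_location(a, ctx)
        if _location_subsumed_by(loc, b):
            return _entails(
                f"defining allele at [{loc.start},{loc.end}) satisfies location under {b.match_mode.value}"
            )
        return _unknown()

    if isinstance(a, DefiningAlleleConstraint) and isinstance(b, FeatureContextConstraint):
        if ctx.allele_equivalences:
            return _unknown("allele equivalences present")
        rec = ctx.resolve_feature(b.feature)
        loc = _normalized_allele_location(a, ctx)
        if interval_contains(rec.location, loc):
            return _entails(f"defining allele lies within feature {rec.id}")
        return _unknown()

    if isinstance(a, DefiningLocationConstraint) and isinstance(b, DefiningLocationConstraint):
        if a.match_mode == MatchMode.CONTAINED and b.match_mode == MatchMode.CONTAINED:
            if interval_contains(b.location, a.location):
                return _entails("interval containment")
            return _unknown()
        if a.match_mode == MatchMode.CONTAINED and b.match_mode == MatchMode.OVERLAPS:
            # any variant contained in a.location overlaps b.location if a ⊆ b
            if interval_contains(b.location, a.location):
                return _entails("containment implies overlap")
            return _unknown()
        if a.match_mode == MatchMode.EXACT:
            if _location_subsumed_by(a.location, b):
                return _entails("exact location satisfies target mode")
            return _unknown()
        return _unknown()

    if isinstance(a, DefiningLocationConstraint) and isinstance(b, FeatureContextConstraint):
        if a.match_mode == MatchMode.CONTAINED or a.match_mode == MatchMode.EXACT:
            rec = ctx.resolve_feature(b.feature)
            if interval_contains(rec.location, a.location):
                return _entails(f"constraining interval lies within feature {rec.id}")
        return _unknown()

    if isinstance(a, FeatureContextConstraint) and isinstance(b, FeatureContextConstraint):
        ra, rb = ctx.resolve_feature(a.feature), ctx.resolve_feature(b.feature)
        if ra.id == rb.id:
            return _entails(f"same feature {ra.id}")
        return _unknown("different features")

    if isinstance(a, CopyCountConstraint) and isinstance(b, CopyCountConstraint):
        if b.min_copies <= a.min_copies and a.max_copies <= b.max_copies:
            return _entails("copy range inclusion")
        return _unknown("copy ranges not nested")

    if isinstance(a, CopyChangeConstraint) and isinstance(b, CopyChangeConstraint):
        if copy_change_specializes(a.change, b.change):
            return _entails(f"{a.change.value} specializes {b.change.value}")
        return _unknown("unrelated change codes")

    return _unknown()


def entails(
    a: CategoricalVariant,
    b: CategoricalVariant,
    ctx: EvaluationContext,
    probe_universe: "Universe | None" = None,
) -> TriVerdict:
    """Decide whether category ``a`` entails category ``b``.

    ENTAILS when every constraint of ``b`` is subsumed by some constraint of
    ``a`` (sound over all universes).  Otherwise, when a probe universe is
    supplied and contains a variant satisfying ``a`` but not ``b``, the
    verdict is NOT_ENTAILED with that counterexample; else UNKNOWN.
    Reflexive: ``entails(a, a)`` is always ENTAILS.
    """
    justification: list[str] = []
    all_covered = True
    for j, cb in enumerate(b.constraints):
        covered = None
        for i, ca in enumerate(a.constraints):
            verdict = subsumes(ca, cb, ctx)
            if verdict.status == EntailmentStatus.ENTAILS:
                covered = f"b.constraints[{j}] ⊑-covered by a.constraints[{i}]: {verdict.justification[0]}"
                break
        if covered is None:
            all_covered = False
            justification.append(f"b.constraints[{j}] not covered by any constraint of a")
        else:
            justification.append(covered)
    if all_covered and b.constraints:
        return TriVerdict(status=EntailmentStatus.ENTAILS, justification=justification)

    if probe_universe is not None:
        from .universe import extension  # local import to avoid a cycle

        ext_a = extension(a, probe_universe, ctx)
        ext_b = extension(b, probe_universe, ctx)
        missing = sorted(ext_a - ext_b)
        if missing:
            return TriVerdict(
                status=EntailmentStatus.NOT_ENTAILED,
                justification=justification + [f"counterexample in probe universe: {missing[0]}"],
                counterexample=missing[0],
            )
    return TriVerdict(status=EntailmentStatus.UNKNOWN, justification=justification)
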