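"""Categorical-variant type profiles.

A profile is a named structural template over constraint kinds: it states
which kinds must appear, with what multiplicity, which are forbidden, and
any extra predicates (e.g. the defining allele must sit on a DNA reference).
Profiles are *data* held in a registry, not code: adopters can register
local profiles or load a registry from JSON.  The shipped registry contains
the five standard types:

========================== ============ =======================================
profile                    maturity     shape
========================== ============ =======================================
CanonicalAllele            trial_use    one DefiningAllele on a DNA reference
ProteinSequenceConsequence trial_use    one DefiningAllele on a protein reference
CategoricalCNV             draft        ≥1 of {DefiningLocation, FeatureContext}
                                        + exactly one of {CopyCount, CopyChange}
FunctionVariant            in_progress  one FeatureContext + one Function
GeneFusion                 in_progress  one Adjacency with feature sides, or
                                        two FeatureContexts + one Adjacency
========================== ============ =======================================

``in_progress`` profiles are experimental; the CLI requires an explicit flag
to use them.
"""

from __future__ import annotations

import json
from typing import Callable, Optional

from pydantic import BaseModel, Field

from .core import (
    Alphabet,
    CategoricalVariant,
    Constraint,
    ConstraintKind,
    DefiningAlleleConstraint,
    AdjacencyConstraint,
    SequenceRegistry,
    Severity,
    ValidationReport,
    DNA_SYMBOLS,
    PROTEIN_SYMBOLS,
)

__all__ = [
    "CardinalityRule",
    "ProfileDefinition",
    "ProfileRegistry",
    "UnknownProfileError",
    "default_registry",
    "validate_profile",
    "classify_profile",
]


class UnknownProfileError(KeyError):
    code = "UNKNOWN_PROFILE"


class CardinalityRule(BaseModel):
    """Require between ``min_count`` and ``max_count`` constraints whose kind
    is in ``kinds``."""

    kinds: list[ConstraintKind]
    min_count: int = Field(default=1, alias="minCount")
    max_count: Optional[int] = Field(default=None, alias="maxCount")

    model_config = {"populate_by_name": True}


class ProfileShape(BaseModel):
    """One admissible shape: cardinality rules plus the set of allowed kinds."""

    rules: list[CardinalityRule]
    allowed: list[ConstraintKind]
    predicates: list[str] = Field(default_factory=list)


class ProfileDefinition(BaseModel):
    """A profile is satisfied when any one of its shapes is satisfied."""

    name: str
    maturity: str = "draft"  # trial_use / draft / in_progress
    shapes: list[ProfileShape]


# ---------------------------------------------------------------------------
# Extra predicates (referenced from shapes by name)


def _allele_alphabet(
    catvar: CategoricalVariant, sequences: SequenceRegistry | None
) -> Alphabet | None:
    """Alphabet of the defining allele's reference; inferred from the state
    symbols when no registry is supplied (ACGTN-only states read as DNA)."""
    for c in catvar.constraints:
        if isinstance(c, DefiningAlleleConstraint):
            sid = c.allele.location.sequence_id
            if sequences is not None and sid in sequences:
                return sequences.alphabet(sid)
            symbols = set(c.allele.state.upper())
            if symbols <= DNA_SYMBOLS:
                return Alphabet.DNA
            if symbols <= PROTEIN_SYMBOLS:
                return Alphabet.PROTEIN
            return None
    return None


def _pred_allele_on_dna(catvar, sequences):
    alpha = _allele_alphabet(catvar, sequences)
    if alpha is Alphabet.DNA:
        return True, ""
    return False, f"defining allele is not on a DNA reference (saw {alpha.value if alpha else 'nothing'})"


def _pred_allele_on_protein(catvar, sequences):
    alpha = _allele_alphabet(catvar, sequences)
    if alpha is Alphabet.PROTEIN:
        return True, ""
    return False, f"defining allele is not on a protein reference (saw {alpha.value if alpha else 'nothing'})"


def _pred_adjacency_sides_are_features(catvar, sequences):
    for c in catvar.constraints:
        if isinstance(c, AdjacencyConstraint):
            if c.side_a.feature is not None and c.side_b.feature is not None:
                return True, ""
            return False, "adjacency sides must both be feature-specified"
    return False, "no adjacency constraint present"


PREDICATES: dict[str, Callable] = {
    "allele_on_dna": _pred_allele_on_dna,
    "allele_on_protein": _pred_allele_on_protein,
    "adjacency_sides_are_features": _pred_adjacency_sides_are_features,
}


# ---------------------------------------------------------------------------
# Registry


class ProfileRegistry:
    """Ordered registry of profile definitions."""

    def __init__(self, profiles: list[ProfileDefinition] | None = None) -> None:
        self._profiles: dict[str, ProfileDefinition] = {}
        for p in profiles or []:
            self.register(p)

    def register(self, profile: ProfileDefinition) -> None:
        self._profiles[profile.name] = profile

    def get(self, name: str) -> ProfileDefinition:
        if name not in self._profiles:
            raise UnknownProfileError(name)
        return self._profiles[name]

    def __contains__(self, name: str) -> bool:
        return name in self._profiles

    def names(self) -> list[str]:
        return list(self._profiles)

    @classmethod
    def from_json(cls, text: str) -> "ProfileRegistry":
        data = json.loads(text)
        return cls([ProfileDefinition.model_validate(p) for p in data["profiles"]])

    def to_json(self) -> str:
        return json.dumps(
            {"profiles": [p.model_dump(by_alias=True, exclude_none=True, mode="json") for p in self._profiles.values()]},
            indent=2,
            sort_keys=True,
        )


def _shape(rules, allowed, predicates=()):
    return ProfileShape(
        rules=[CardinalityRule(kinds=list(k), min_count=lo, max_count=hi) for k, lo, hi in rules],
        allowed=list(allowed),
        predicates=list(predicates),
    )


_K = ConstraintKind


def default_registry() -> ProfileRegistry:
    """The five shipped categorical-variant types."""
    return ProfileRegistry(
        [
            ProfileDefinition(
                name="CanonicalAllele",
                maturity="trial_use",
                shapes=[_shape([((_K.DEFINING_ALLELE,), 1, 1)], [_K.DEFINING_ALLELE], ["allele_on_dna"])],
            ),
            ProfileDefinition(
                name="ProteinSequenceConsequence",
                maturity="trial_use",
                shapes=[_shape([((_K.DEFINING_ALLELE,), 1, 1)], [_K.DEFINING_ALLELE], ["allele_on_protein"])],
            ),
            ProfileDefinition(
                name="CategoricalCNV",
                maturity="draft",
                shapes=[
                    _shape(
                        [
                            ((_K.DEFINING_LOCATION, _K.FEATURE_CONTEXT), 1, None),
                            ((_K.COPY_COUNT, _K.COPY_CHANGE), 1, 1),
                        ],
                        [_K.DEFINING_LOCATION, _K.FEATURE_CONTEXT, _K.COPY_COUNT, _K.COPY_CHANGE],
                    )
                ],
            ),
            ProfileDefinition(
                name="FunctionVariant",
                maturity="in_progress",
                shapes=[
                    _shape(
                        [((_K.FEATURE_CONTEXT,), 1, 1), ((_K.FUNCTION,), 1, 1)],
                        [_K.FEATURE_CONTEXT, _K.FUNCTION],
                    )
                ],
            ),
            ProfileDefinition(
                name="GeneFusion",
                maturity="in_progress",
                shapes=[
                    _shape(
                        [((_K.ADJACENCY,), 1, 1)],
                        [_K.ADJACENCY],
                        ["adjacency_sides_are_features"],
                    ),
                    _shape(
                        [((_K.FEATURE_CONTEXT,), 2, 2), ((_K.ADJACENCY,), 1, 1)],
                        [_K.FEATURE_CONTEXT, _K.ADJACENCY],
                    ),
                ],
            ),
        ]
    )


# ---------------------------------------------------------------------------
# Validation / classification


def _check_shape(
    catvar: CategoricalVariant, shape: ProfileShape, sequences: SequenceRegistry | None
) -> list[str]:
    """Return a list of violation messages (empty = shape satisfied)."""
    problems: list[str] = []
    kinds = [c.kind for c in catvar.constraints]
    for rule in shape.rules:
        n = sum(1 for k in kinds if k in rule.kinds)
        names = "/".join(k.value for k in rule.kinds)
        if n < rule.min_count:
            problems.append(f"MISSING_CONSTRAINT: needs ≥{rule.min_count} of {names}, found {n}")
        elif rule.max_count is not None and n > rule.max_count:
            problems.append(f"TOO_MANY_CONSTRAINTS: allows ≤{rule.max_count} of {names}, found {n}")
    allowed = set(shape.allowed)
    for i, k in enumerate(kinds):
        if k not in allowed:
            problems.append(f"UNEXPECTED_CONSTRAINT: kind {k.value} at constraints[{i}] not allowed")
    for pname in shape.predicates:
        ok, msg = PREDICATES[pname](catvar, sequences)
        if not ok:
            problems.append(f"PREDICATE_FAILED({pname}): {msg}")
    return problems


def validate_profile(
    catvar: CategoricalVariant,
    profile: str,
    registry: ProfileRegistry | None = None,
    sequences: SequenceRegistry | None = None,
) -> ValidationReport:
    """Validate a category against a named profile.

    The report is empty when the category fits any admissible shape of the
    profile; otherwise it carries the violations of the closest shape (the
    one with fewest violations).  Raises :class:`UnknownProfileError` for an
    unregistered profile name.  The outcome is invariant under permutation
    of the constraint list.
    """
    reg = registry or default_registry()
    definition = reg.get(profile)
    report = ValidationReport()
    best: list[str] | None = None
    for shape in definition.shapes:
        problems = _check_shape(catvar, shape, sequences)
        if not problems:
            return report
        if best is None or len(problems) < len(best):
            best = problems
    for msg in best or []:
        code, _, message = msg.partition(": ")
        report.add(code.split("(")[0], message or msg, path="constraints")
    return report


def classify_profile(
    catvar: CategoricalVariant,
    registry: ProfileRegistry | None = None,
    sequences: SequenceRegistry | None = None,
) -> list[str]:
    """All registered profiles the category validates against, in registry
    order; empty when none match."""
    reg = registry or default_registry()
    return [name for name in reg.names() if validate_profile(catvar, name, reg, sequences).is_valid]
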