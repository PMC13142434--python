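"""Constraint verdict semantics and conjunctive matching."""

import pytest

from catvar import (
    AdjacencyConstraint,
    AdjacencyVariant,
    Allele,
    CategoricalVariant,
    CopyChange,
    CopyChangeConstraint,
    CopyCountConstraint,
    CopyNumberVariant,
    DefiningAlleleConstraint,
    DefiningLocationConstraint,
    EvaluationContext,
    FeatureContextConstraint,
    FunctionConstraint,
    MatchMode,
    MolecularVariant,
    SequenceLocation,
    SequenceRegistry,
    UnknownFeatureError,
    VariantAnnotation,
    VerdictStatus,
    evaluate_constraint,
    match,
    match_batch,
)
from catvar.core import AdjacencySide
from catvar.features import FeatureRecord, FeatureTable


def loc(start, end, sid="r1"):
    return SequenceLocation(sequenceId=sid, start=start, end=end)


@pytest.fixture()
def engine_ctx(toy_registry):
    table = FeatureTable(
        [
            FeatureRecord(id="GENE1", symbol="GENE1", location=loc(2, 10), feature_class="gene"),
            FeatureRecord(id="GENE2", symbol="GENE2", location=loc(4, 12, "r2"), feature_class="gene"),
        ]
    )
    return EvaluationContext(
        feature_table=table,
        sequences=toy_registry,
        function_hierarchy={"stop_gained": {"loss_of_function"}},
    )


def snv(vid="v1", start=4, alt="C", sid="r1", annotation=None):
    return MolecularVariant.from_allele(
        vid, Allele(location=loc(start, start + 1, sid), state=alt), annotation
    )


def cnv(vid="c1", count=None, code=None, start=1, end=9, sid="r1"):
    return MolecularVariant.from_copy_number(
        vid, CopyNumberVariant(location=loc(start, end, sid), count=count, changeCode=code)
    )


class TestDefiningAllele:
    def test_equivalent_spellings_satisfy(self, engine_ctx):
        constraint = DefiningAlleleConstraint(allele=Allele(location=loc(3, 5), state=""))
        shifted = MolecularVariant.from_allele("v", Allele(location=loc(5, 7), state=""))
        assert evaluate_constraint(constraint, shifted, engine_ctx).status == VerdictStatus.SATISFIED

    def test_different_allele_unsatisfied(self, engine_ctx):
        constraint = DefiningAlleleConstraint(allele=Allele(location=loc(4, 5), state="C"))
        assert evaluate_constraint(constraint, snv(alt="T"), engine_ctx).status == VerdictStatus.UNSATISFIED

    def test_non_allele_inapplicable(self, engine_ctx):
        constraint = DefiningAlleleConstraint(allele=Allele(location=loc(4, 5), state="C"))
        assert evaluate_constraint(constraint, cnv(count=1), engine_ctx).status == VerdictStatus.INAPPLICABLE

    def test_equivalence_table_bridges_digests(self, engine_ctx):
        from catvar.normalize import allele_digest

        a = Allele(location=loc(4, 5), state="C")
        b = Allele(location=loc(6, 7, "r2"), state="T")
        engine_ctx.allele_equivalences[allele_digest(b)] = allele_digest(a)
        constraint = DefiningAlleleConstraint(allele=a)
        variant = MolecularVariant.from_allele("v", b)
        assert evaluate_constraint(constraint, variant, engine_ctx).status == VerdictStatus.SATISFIED


class TestDefiningLocation:
    @pytest.mark.parametrize(
        "mode, variant_iv, expected",
        [
            (MatchMode.EXACT, (2, 10), VerdictStatus.SATISFIED),
            (MatchMode.EXACT, (2, 9), VerdictStatus.UNSATISFIED),
            (MatchMode.CONTAINED, (3, 9), VerdictStatus.SATISFIED),
            (MatchMode.CONTAINED, (1, 9), VerdictStatus.UNSATISFIED),
            (MatchMode.OVERLAPS, (9, 11), VerdictStatus.SATISFIED),
            (MatchMode.OVERLAPS, (10, 11), VerdictStatus.UNSATISFIED),
        ],
    )
    def test_match_modes(self, engine_ctx, mode, variant_iv, expected):
        constraint = DefiningLocationConstraint(location=loc(2, 10), matchMode=mode)
        variant = cnv(start=variant_iv[0], end=variant_iv[1], count=2)
        assert evaluate_constraint(constraint, variant, engine_ctx).status == expected

    def test_allele_location_is_normalized_before_comparison(self, engine_ctx):
        # deletion spelled at [5,7) lies in the AGAGAG tract; its canonical
        # window is [3,10), so CONTAINED in [4,11) must fail and [3,10) pass
        variant = MolecularVariant.from_allele("v", Allele(location=loc(5, 7), state=""))
        tight = DefiningLocationConstraint(location=loc(5, 7), matchMode=MatchMode.CONTAINED)
        window = DefiningLocationConstraint(location=loc(3, 10), matchMode=MatchMode.CONTAINED)
        assert evaluate_constraint(tight, variant, engine_ctx).status == VerdictStatus.UNSATISFIED
        assert evaluate_constraint(window, variant, engine_ctx).status == VerdictStatus.SATISFIED

    def test_adjacency_has_no_single_location(self, engine_ctx):
        adj = MolecularVariant.from_adjacency(
            "a", AdjacencyVariant(breakendA=loc(3, 3), breakendB=loc(8, 8, "r2"))
        )
        constraint = DefiningLocationConstraint(location=loc(0, 12), matchMode=MatchMode.OVERLAPS)
        assert evaluate_constraint(constraint, adj, engine_ctx).status == VerdictStatus.INAPPLICABLE


class TestCopyConstraints:
    @pytest.mark.parametrize("count, expected", [(2, VerdictStatus.SATISFIED), (3, VerdictStatus.UNSATISFIED)])
    def test_count_range_boundary(self, engine_ctx, count, expected):
        constraint = CopyCountConstraint(minCopies=2, maxCopies=2)
        assert evaluate_constraint(constraint, cnv(count=count), engine_ctx).status == expected

    def test_count_absent_is_inapplicable(self, engine_ctx):
        constraint = CopyCountConstraint(minCopies=0, maxCopies=2)
        assert evaluate_constraint(constraint, cnv(code=CopyChange.LOSS), engine_ctx).status == VerdictStatus.INAPPLICABLE

    def test_change_specialization_satisfies(self, engine_ctx):
        constraint = CopyChangeConstraint(change=CopyChange.LOSS)
        assert evaluate_constraint(constraint, cnv(code=CopyChange.COMPLETE_LOSS), engine_ctx).status == VerdictStatus.SATISFIED
        assert evaluate_constraint(constraint, cnv(code=CopyChange.GAIN), engine_ctx).status == VerdictStatus.UNSATISFIED

    def test_bare_count_never_satisfies_change(self, engine_ctx):
        constraint = CopyChangeConstraint(change=CopyChange.COMPLETE_LOSS)
        assert evaluate_constraint(constraint, cnv(count=0), engine_ctx).status == VerdictStatus.INAPPLICABLE

    def test_snv_is_inapplicable_for_copy_change(self, engine_ctx):
        constraint = CopyChangeConstraint(change=CopyChange.LOSS)
        assert evaluate_constraint(constraint, snv(), engine_ctx).status == VerdictStatus.INAPPLICABLE


class TestFeatureContext:
    def test_overlap_satisfies(self, engine_ctx):
        constraint = FeatureContextConstraint(feature="GENE1")
        assert evaluate_constraint(constraint, cnv(count=1), engine_ctx).status == VerdictStatus.SATISFIED

    def test_symbol_annotation_satisfies_case_insensitively(self, engine_ctx):
        constraint = FeatureContextConstraint(feature="GENE2")
        variant = snv(annotation=VariantAnnotation(geneSymbols={"gene2"}))
        assert evaluate_constraint(constraint, variant, engine_ctx).status == VerdictStatus.SATISFIED

    def test_miss_is_unsatisfied(self, engine_ctx):
        constraint = FeatureContextConstraint(feature="GENE2")
        assert evaluate_constraint(constraint, snv(), engine_ctx).status == VerdictStatus.UNSATISFIED

    def test_unknown_feature_raises(self, engine_ctx):
        with pytest.raises(UnknownFeatureError):
            evaluate_constraint(FeatureContextConstraint(feature="NOPE"), snv(), engine_ctx)

    def test_adjacency_matches_through_either_breakend(self, engine_ctx):
        adj = MolecularVariant.from_adjacency(
            "a", AdjacencyVariant(breakendA=loc(100, 100), breakendB=loc(5, 5, "r2"))
        )
        constraint = FeatureContextConstraint(feature="GENE2")
        assert evaluate_constraint(constraint, adj, engine_ctx).status == VerdictStatus.SATISFIED


class TestFunction:
    def test_hierarchy_descent_satisfies(self, engine_ctx):
        constraint = FunctionConstraint(term="loss_of_function")
        variant = snv(annotation=VariantAnnotation(functionTerms={"stop_gained"}))
        assert evaluate_constraint(constraint, variant, engine_ctx).status == VerdictStatus.SATISFIED

    def test_hierarchy_flag_off_requires_equality(self, engine_ctx):
        constraint = FunctionConstraint(term="loss_of_function", applyHierarchy=False)
        variant = snv(annotation=VariantAnnotation(functionTerms={"stop_gained"}))
        assert evaluate_constraint(constraint, variant, engine_ctx).status == VerdictStatus.UNSATISFIED

    def test_missing_annotation_is_inapplicable(self, engine_ctx):
        constraint = FunctionConstraint(term="loss_of_function")
        assert evaluate_constraint(constraint, snv(), engine_ctx).status == VerdictStatus.INAPPLICABLE


class TestAdjacency:
    def make(self, a=(3, "r1"), b=(8, "r2")):
        return MolecularVariant.from_adjacency(
            "a",
            AdjacencyVariant(
                breakendA=loc(a[0], a[0], a[1]), breakendB=loc(b[0], b[0], b[1])
            ),
        )

    def test_feature_sides_ordered(self, engine_ctx):
        constraint = AdjacencyConstraint(
            side_a=AdjacencySide(feature="GENE1"), side_b=AdjacencySide(feature="GENE2")
        )
        assert evaluate_constraint(constraint, self.make(), engine_ctx).status == VerdictStatus.SATISFIED
        swapped = self.make(a=(8, "r2"), b=(3, "r1"))
        assert evaluate_constraint(constraint, swapped, engine_ctx).status == VerdictStatus.UNSATISFIED

    def test_unordered_allows_swap(self, engine_ctx):
        constraint = AdjacencyConstraint(
            side_a=AdjacencySide(feature="GENE1"),
            side_b=AdjacencySide(feature="GENE2"),
            ordered=False,
        )
        swapped = self.make(a=(8, "r2"), b=(3, "r1"))
        assert evaluate_constraint(constraint, swapped, engine_ctx).status == VerdictStatus.SATISFIED

    def test_location_side_uses_containment(self, engine_ctx):
        constraint = AdjacencyConstraint(
            side_a=AdjacencySide(location=loc(0, 5)), side_b=AdjacencySide(feature="GENE2")
        )
        assert evaluate_constraint(constraint, self.make(), engine_ctx).status == VerdictStatus.SATISFIED

    def test_non_adjacency_inapplicable(self, engine_ctx):
        constraint = AdjacencyConstraint(
            side_a=AdjacencySide(feature="GENE1"), side_b=AdjacencySide(feature="GENE2")
        )
        assert evaluate_constraint(constraint, snv(), engine_ctx).status == VerdictStatus.INAPPLICABLE


class TestMatch:
    def test_tp53_loss_variant_matches_fixture(self, tp53_catvar, tp53_ctx, tp53_loss_variant):
        report = match(tp53_catvar, tp53_loss_variant, tp53_ctx)
        assert report.overall is True
        assert [v.status for v in report.verdicts] == [VerdictStatus.SATISFIED] * 3

    def test_snv_in_region_fails_copy_change_conjunct(self, tp53_catvar, tp53_ctx):
        variant = MolecularVariant.from_allele(
            "snv", Allele(location=loc(7_670_000, 7_670_001, "GRCh38:chr17"), state="A")
        )
        report = match(tp53_catvar, variant, tp53_ctx)
        assert report.overall is False
        assert report.verdicts[2].status == VerdictStatus.INAPPLICABLE

    def test_verdict_order_follows_constraint_order(self, engine_ctx):
        cv = CategoricalVariant(
            id="c",
            constraints=[
                CopyChangeConstraint(change=CopyChange.LOSS),
                FeatureContextConstraint(feature="GENE1"),
            ],
        )
        report = match(cv, cnv(code=CopyChange.LOSS, count=1), engine_ctx)
        assert [v.constraint_index for v in report.verdicts] == [0, 1]
        assert report.overall is True

    def test_batch_equals_single_and_is_order_stable(self, engine_ctx):
        cvs = [
            CategoricalVariant(id="c1", constraints=[FeatureContextConstraint(feature="GENE1")]),
            CategoricalVariant(id="c2", constraints=[CopyChangeConstraint(change=CopyChange.LOSS)]),
        ]
        vs = [snv("v1"), cnv("v2", code=CopyChange.LOSS), cnv("v3", count=2)]
        matrix = match_batch(cvs, vs, engine_ctx)
        assert matrix[1][1].overall is True
        for i, cv in enumerate(cvs):
            for j, v in enumerate(vs):
                assert matrix[i][j] == match(cv, v, engine_ctx)
        permuted = match_batch(cvs, vs[::-1], engine_ctx)
        for j in range(3):
            assert permuted[0][j] == matrix[0][2 - j]

    def test_match_agrees_with_oracle_on_random_pairs(self, universe, ctx):
        from catvar import extension, generate_random_category

        cats = [generate_random_category(universe, seed=1000 + i) for i in range(12)]
        for cat in cats:
            members = extension(cat, universe, ctx)
            for v in universe.variants:
                assert match(cat, v, ctx).overall == (v.id in members)

    def test_appending_a_constraint_never_enlarges_the_extension(self, universe, ctx):
        from catvar import extension, generate_random_category
        from catvar.universe import _GENERAL_KINDS, _random_constraint
        import numpy as np

        rng = np.random.default_rng(5)
        for i in range(25):
            cat = generate_random_category(universe, seed=2000 + i)
            before = extension(cat, universe, ctx)
            extra = _random_constraint(rng, universe, _GENERAL_KINDS[int(rng.integers(0, len(_GENERAL_KINDS)))])
            bigger = CategoricalVariant(id=cat.id + "+", constraints=list(cat.constraints) + [extra])
            after = extension(bigger, universe, ctx)
            assert after <= before
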