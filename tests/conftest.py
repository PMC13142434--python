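import pytest

from catvar import (
    CategoricalVariant,
    CopyChange,
    CopyChangeConstraint,
    CopyNumberVariant,
    DefiningLocationConstraint,
    EvaluationContext,
    FeatureContextConstraint,
    MatchMode,
    MolecularVariant,
    SequenceLocation,
    SequenceRegistry,
    fixture_text,
    generate_universe,
    load_feature_table,
    read_categorical_variants,
)
from catvar.universe import FUNCTION_HIERARCHY, UniverseConfig


@pytest.fixture(scope="session")
def tp53_catvar() -> CategoricalVariant:
    catvars, report = read_categorical_variants(fixture_text("tp53_cnloss.json"))
    assert report.is_valid
    return catvars[0]


@pytest.fixture(scope="session")
def tp53_ctx() -> EvaluationContext:
    table = load_feature_table(fixture_text("tp53_features.bed"))
    return EvaluationContext(feature_table=table)


@pytest.fixture(scope="session")
def tp53_loss_variant() -> MolecularVariant:
    cnv = CopyNumberVariant(
        location=SequenceLocation(sequenceId="GRCh38:chr17", start=7_600_000, end=7_700_000),
        count=1,
        changeCode=CopyChange.LOSS,
    )
    return MolecularVariant.from_copy_number("sample-del-17p", cnv)


@pytest.fixture(scope="session")
def universe():
    return generate_universe(UniverseConfig(), seed=20260923)


@pytest.fixture(scope="session")
def ctx(universe):
    return universe.context()


@pytest.fixture()
def toy_registry() -> SequenceRegistry:
    # repeat tract AGAGAG at [3, 9); protein sequence for alphabet checks
    reg = SequenceRegistry.from_dict({"r1": "GGCAGAGAGATT", "r2": "TTTTACGTACGTTTTT"})
    reg.add("p1", "MKTAYIAKQR", alphabet=None)
    return reg
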