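"""Normalization collapses equivalent spellings; digests are stable.

The independent oracle: apply each spelling to the reference and compare the
mutated strings directly.  Two spellings are equivalent iff they produce the
same mutated sequence; all equivalent spellings must normalize to one form
with one digest.
"""

import pytest
from hypothesis import given, settings, strategies as st

from catvar import (
    Allele,
    SequenceLocation,
    SequenceRegistry,
    canonical_serialize,
    compute_digest,
    normalize_allele,
)
from catvar.normalize import AlphabetMismatchError, OutOfBoundsError, UnserializableError


def apply_allele(reference: str, allele: Allele) -> str:
    """Oracle: the mutated sequence produced by an allele."""
    loc = allele.location
    return reference[: loc.start] + allele.state + reference[loc.end :]


def mk(start, end, state, sid="r1"):
    return Allele(location=SequenceLocation(sequenceId=sid, start=start, end=end), state=state)


class TestNormalizeAllele:
    def test_shifted_deletion_spellings_share_one_form(self, toy_registry):
        # GGCAGAGAGATT: deleting AG at [3,5) and at [5,7) yields the same string
        a, b = mk(3, 5, ""), mk(5, 7, "")
        ref = toy_registry.sequence("r1")
        assert apply_allele(ref, a) == apply_allele(ref, b)  # oracle agreement first
        na, nb = normalize_allele(a, toy_registry), normalize_allele(b, toy_registry)
        assert na.allele == nb.allele
        assert na.digest_id == nb.digest_id
        # fully justified across the whole AGAGAG tract
        assert (na.allele.location.start, na.allele.location.end) == (3, 10)
        assert na.allele.state == "AGAGA"

    def test_snv_is_returned_trimmed_only(self, toy_registry):
        form = normalize_allele(mk(4, 5, "C"), toy_registry)
        assert form.allele == mk(4, 5, "C")
        assert not form.is_identity

    def test_anchored_vcf_style_spelling_matches_bare_deletion(self, toy_registry):
        # CAG->C at [2,5) is the VCF-anchored spelling of deleting AG at [3,5)
        anchored, bare = mk(2, 5, "C"), mk(3, 5, "")
        ref = toy_registry.sequence("r1")
        assert apply_allele(ref, anchored) == apply_allele(ref, bare)
        assert (
            normalize_allele(anchored, toy_registry).digest_id
            == normalize_allele(bare, toy_registry).digest_id
        )

    def test_identity_allele_is_flagged(self, toy_registry):
        form = normalize_allele(mk(3, 5, "AG"), toy_registry)
        assert form.is_identity

    def test_insertion_spellings_share_one_form(self, toy_registry):
        # inserting AG anywhere in the AGAGAG tract is one event
        spellings = [mk(3, 3, "AG"), mk(5, 5, "AG"), mk(9, 9, "AG"), mk(3, 3, "GA") ]
        ref = toy_registry.sequence("r1")
        mutated = {apply_allele(ref, s) for s in spellings[:3]}
        assert len(mutated) == 1
        digests = {normalize_allele(s, toy_registry).digest_id for s in spellings[:3]}
        assert len(digests) == 1
        # GA inserted at 3 gives a different mutated string -> different digest
        assert apply_allele(ref, spellings[3]) != mutated.pop()

    def test_out_of_bounds_and_alphabet_errors(self, toy_registry):
        with pytest.raises(OutOfBoundsError):
            normalize_allele(mk(5, 99, ""), toy_registry)
        with pytest.raises(OutOfBoundsError):
            normalize_allele(mk(0, 1, "A", sid="nope"), toy_registry)
        with pytest.raises(AlphabetMismatchError):
            normalize_allele(mk(0, 1, "J"), toy_registry)

    def test_protein_deletion_trims_but_does_not_shuffle(self, toy_registry):
        # p1 = MKTAYIAKQR; replacing KT at [1,3) with K trims to deleting T at [2,3)
        form = normalize_allele(mk(1, 3, "K", sid="p1"), toy_registry)
        assert (form.allele.location.start, form.allele.location.end) == (2, 3)
        assert form.allele.state == ""


@st.composite
def reference_and_edit(draw):
    """A random DNA reference plus a random simple edit on it, spelled with
    random extra shared context (so trimming is exercised)."""
    ref = draw(st.text(alphabet="ACGT", min_size=12, max_size=60))
    start = draw(st.integers(0, len(ref) - 2))
    end = draw(st.integers(start, min(len(ref), start + 6)))
    state = draw(st.text(alphabet="ACGT", min_size=0, max_size=6))
    # add shared flanking context to the spelling
    pad_l = draw(st.integers(0, min(3, start)))
    pad_r = draw(st.integers(0, min(3, len(ref) - end)))
    spelled = Allele(
        location=SequenceLocation(sequenceId="R", start=start - pad_l, end=end + pad_r),
        state=ref[start - pad_l : start] + state + ref[end : end + pad_r],
    )
    return ref, spelled


@settings(max_examples=200, deadline=None, derandomize=True)
@given(reference_and_edit())
def test_normalization_is_idempotent_and_preserves_the_edit(data):
    ref, allele = data
    reg = SequenceRegistry.from_dict({"R": ref})
    once = normalize_allele(allele, reg)
    twice = normalize_allele(once.allele, reg)
    assert once.allele == twice.allele
    assert once.digest_id == twice.digest_id
    # the canonical form denotes the same mutated sequence
    assert apply_allele(ref, allele) == apply_allele(ref, once.allele)


@settings(max_examples=100, deadline=None, derandomize=True)
@given(reference_and_edit(), st.integers(-3, 3))
def test_equivalent_random_spellings_normalize_identically(data, shift):
    """Shuffle a pure indel through its context; whenever the mutated strings
    agree (the oracle), the normalized digests agree."""
    ref, allele = data
    reg = SequenceRegistry.from_dict({"R": ref})
    loc = allele.location
    s, e = loc.start + shift, loc.end + shift
    if not (0 <= s <= e <= len(ref)):
        return
    other = Allele(location=SequenceLocation(sequenceId="R", start=s, end=e), state=allele.state)
    if apply_allele(ref, allele) == ref:
        return  # identity (no edit): identity alleles keep their site
    if apply_allele(ref, allele) == apply_allele(ref, other):
        assert normalize_allele(allele, reg).digest_id == normalize_allele(other, reg).digest_id


class TestCanonicalSerialize:
    def test_field_order_does_not_matter(self):
        a = canonical_serialize({"b": 1, "a": [2, 3]})
        b = canonical_serialize({"a": [2, 3], "b": 1})
        assert a == b

    def test_serialize_parse_serialize_fixed_point(self, tp53_catvar):
        import json

        once = canonical_serialize(tp53_catvar)
        again = canonical_serialize(json.loads(once))
        assert once == again

    def test_unicode_normalization(self):
        assert canonical_serialize({"k": "é"}) == canonical_serialize({"k": "é"})

    def test_non_model_input_rejected(self):
        with pytest.raises(UnserializableError):
            canonical_serialize({"x": object()})


class TestDigest:
    def test_determinism_and_shape(self):
        d1 = compute_digest({"a": 1})
        d2 = compute_digest({"a": 1})
        assert d1 == d2
        prefix, _, body = d1.partition(".")
        assert prefix == "dg" and len(body) == 32

    def test_no_collisions_across_random_alleles(self):
        import numpy as np

        rng = np.random.default_rng(0)
        seen = set()
        bases = np.array(list("ACGT"))
        for _ in range(10_000):
            start = int(rng.integers(0, 10_000))
            end = start + int(rng.integers(0, 10))
            state = "".join(bases[rng.integers(0, 4, size=int(rng.integers(0, 8)))])
            a = mk(start, end, state, sid=f"s{int(rng.integers(0, 3))}")
            seen.add(compute_digest(a))
        # distinct inputs may repeat by chance of generation, but digests of
        # *distinct* alleles must not collide: regenerate keys to compare
        assert len(seen) <= 10_000
        keys = set()
        rng = np.random.default_rng(0)
        for _ in range(10_000):
            start = int(rng.integers(0, 10_000))
            end = start + int(rng.integers(0, 10))
            state = "".join(bases[rng.integers(0, 4, size=int(rng.integers(0, 8)))])
            keys.add((f"s{int(rng.integers(0, 3))}", start, end, state))
        assert len(seen) == len(keys)
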