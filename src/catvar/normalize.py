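"""Allele normalization and digest identifiers.

One molecular alteration admits many valid spellings (expression
multiplicity): an indel inside a repeat tract can be written at any offset in
the tract, and VCF anchors add shared context bases.  ``normalize_allele``
collapses all spellings of a simple edit to one *fully justified* form:
shared prefix/suffix context is trimmed, and a pure insertion or deletion is
expanded across the maximal flanking repeat so every left/right-shuffled
spelling maps to the identical location and state.

``compute_digest`` then mints a stable identifier from the canonical
serialization of the normalized allele, so allele identity reduces to string
equality of digests.
"""

from __future__ import annotations

import base64
import hashlib
import json
import unicodedata
from typing import Any

from pydantic import BaseModel

from .core import Allele, Alphabet, SequenceLocation, SequenceRegistry

__all__ = [
    "CanonicalAlleleForm",
    "NormalizationError",
    "OutOfBoundsError",
    "AlphabetMismatchError",
    "UnserializableError",
    "normalize_allele",
    "canonical_serialize",
    "compute_digest",
    "allele_digest",
    "DIGEST_LENGTH",
]

#: digest = first 24 bytes of SHA-512, base64url → 32 URL-safe characters.
DIGEST_LENGTH = 32
_DIGEST_BYTES = 24


class NormalizationError(ValueError):
    code = "NORMALIZATION_ERROR"


class OutOfBoundsError(NormalizationError):
    code = "OUT_OF_BOUNDS"


class AlphabetMismatchError(NormalizationError):
    code = "ALPHABET_MISMATCH"


class UnserializableError(TypeError):
    code = "UNSERIALIZABLE"


class CanonicalAlleleForm(BaseModel):
    """A normalized allele plus its digest identifier."""

    allele: Allele
    digest_id: str
    is_identity: bool = False


def _trim(ref: str, alt: str, start: int) -> tuple[str, str, int, int]:
    """Trim shared prefix then shared suffix; returns (ref, alt, start, end)."""
    p = 0
    while p < len(ref) and p < len(alt) and ref[p] == alt[p]:
        p += 1
    ref, alt = ref[p:], alt[p:]
    start += p
    s = 0
    while s < len(ref) and s < len(alt) and ref[len(ref) - 1 - s] == alt[len(alt) - 1 - s]:
        s += 1
    if s:
        ref, alt = ref[:-s], alt[:-s]
    return ref, alt, start, start + len(ref)


def normalize_allele(allele: Allele, reference: SequenceRegistry) -> CanonicalAlleleForm:
    """Return the fully-justified canonical form of ``allele``.

    The procedure handles a single contiguous edit: (1) trim the common
    prefix, then the common suffix, between the reference subsequence and the
    state; (2) if the remaining edit is a pure insertion or deletion, expand
    the location across the maximal flanking repeat of the inserted/deleted
    unit and respell the state over that window.  Substitutions and delins
    are returned trimmed only, as are protein alleles (residue-level
    justification conventions differ, so no repeat shuffle is applied).

    Idempotent: normalizing a normalized allele returns an equal form.

    Raises
    ------
    OutOfBoundsError
        if the location exceeds the reference.
    AlphabetMismatchError
        if the state contains symbols outside the reference alphabet.
    """
    loc = allele.location
    sid = loc.sequence_id
    if sid not in reference:
        raise OutOfBoundsError(f"unknown sequence {sid!r}")
    seq_len = reference.length(sid)
    if not (0 <= loc.start <= loc.end <= seq_len):
        raise OutOfBoundsError(f"location [{loc.start},{loc.end}) outside {sid!r} (length {seq_len})")
    alphabet = reference.alphabet(sid)
    state = allele.state.upper()
    if not set(state) <= alphabet.symbols():
        bad = sorted(set(state) - alphabet.symbols())
        raise AlphabetMismatchError(f"state contains non-{alphabet.value} symbols {bad}")

    ref_span = reference.fetch(sid, loc.start, loc.end)
    if state == ref_span:
        out = Allele(location=SequenceLocation(sequenceId=sid, start=loc.start, end=loc.end), state=state)
        return CanonicalAlleleForm(allele=out, digest_id=allele_digest(out), is_identity=True)

    ref, alt, start, end = _trim(ref_span, state, loc.start)

    if ref and alt:
        # substitution or delins: trimmed form is canonical
        out = Allele(location=SequenceLocation(sequenceId=sid, start=start, end=end), state=alt)
        return CanonicalAlleleForm(allele=out, digest_id=allele_digest(out))

    if alphabet is Alphabet.PROTEIN:
        out = Allele(location=SequenceLocation(sequenceId=sid, start=start, end=end), state=alt)
        return CanonicalAlleleForm(allele=out, digest_id=allele_digest(out))

    base = reference.sequence(sid)
    if alt and not ref:
        # pure insertion of `alt` at point start == end
        i, j = start, start
        unit_left = alt
        while i > 0 and unit_left[-1] == base[i - 1]:
            unit_left = base[i - 1] + unit_left[:-1]
            i -= 1
        unit_right = alt
        while j < seq_len and unit_right[0] == base[j]:
            unit_right = unit_right[1:] + base[j]
            j += 1
        new_state = base[i:start] + alt + base[start:j]
        out = Allele(location=SequenceLocation(sequenceId=sid, start=i, end=j), state=new_state)
        return CanonicalAlleleForm(allele=out, digest_id=allele_digest(out))

    # pure deletion of base[start:end]
    k = end - start
    i, j = start, end
    while i > 0 and base[i - 1] == base[i + k - 1]:
        i -= 1
    while j < seq_len and base[j] == base[j - k]:
        j += 1
    new_state = base[i:start] + base[end:j]
    out = Allele(location=SequenceLocation(sequenceId=sid, start=i, end=j), state=new_state)
    return CanonicalAlleleForm(allele=out, digest_id=allele_digest(out))


# --------------------------------------------------------------------------
# Canonical serialization and digests


def _plain(value: Any) -> Any:
    if isinstance(value, BaseModel):
        return _plain(value.model_dump(by_alias=True, exclude_none=True, mode="json"))
    if isinstance(value, dict):
        return {_plain_key(k): _plain(v) for k, v in value.items()}
    if isinstance(value, (list, tuple)):
        return [_plain(v) for v in value]
    if isinstance(value, (set, frozenset)):
        return sorted(_plain(v) for v in value)
    if isinstance(value, str):
        return unicodedata.normalize("NFC", value)
    if isinstance(value, bool) or value is None:
        return value
    if isinstance(value, int):
        return value
    if isinstance(value, float):
        if value != value or value in (float("inf"), float("-inf")):
            raise UnserializableError("non-finite floats are not canonically serializable")
        return value
    raise UnserializableError(f"cannot canonically serialize {type(value).__name__}")


def _plain_key(k: Any) -> str:
    if not isinstance(k, str):
        raise UnserializableError("canonical serialization requires string keys")
    return unicodedata.normalize("NFC", k)


def canonical_serialize(value: Any) -> bytes:
    """Key-sorted, whitespace-free, NFC-normalized UTF-8 JSON bytes.

    Equal model objects serialize to identical bytes regardless of field
    construction order; serialize→parse→serialize is a fixed point.
    """
    return json.dumps(
        _plain(value), sort_keys=True, separators=(",", ":"), ensure_ascii=False
    ).encode("utf-8")


def compute_digest(value: Any, prefix: str = "dg") -> str:
    """Deterministic truncated-SHA-512 identifier of the canonical serialization.

    ``prefix.XXXX…`` with 32 URL-safe base64 characters; equal inputs yield
    equal identifiers (up to hash collision).
    """
    payload = value if isinstance(value, bytes) else canonical_serialize(value)
    raw = hashlib.sha512(payload).digest()[:_DIGEST_BYTES]
    return f"{prefix}.{base64.urlsafe_b64encode(raw).decode('ascii')}"


def allele_digest(allele: Allele) -> str:
    """Digest of an allele's identifying fields (sequence, interval, state)."""
    key = {
        "sequenceId": allele.location.sequence_id,
        "start": allele.location.start,
        "end": allele.location.end,
        "state": allele.state,
    }
    return compute_digest(key, prefix="al")
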