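"""Readers and writers for the package's file surfaces.

* categorical-variant JSON documents (camelCase fields, ``type`` constraint
  discriminator, unknown fields preserved and round-tripped);
* assayed variants from VCF (SNVs/indels, symbolic ``<DEL>``/``<DUP>``/
  ``<CNV>`` records, paired BND breakends);
* feature tables from BED or a 1-based TSV dialect;
* per-variant annotation TSV (gene symbols, functional-consequence terms);
* reference sequences from FASTA.

Readers are total over record batches: a malformed entry is reported (JSON)
or sent to the skip report (VCF), and the remaining records are returned.
"""

from __future__ import annotations

import json
import re
from pathlib import Path
from typing import Optional, Union

import pysam
from Bio import SeqIO
from pydantic import BaseModel, ValidationError

from .core import (
    AdjacencyVariant,
    Allele,
    CategoricalVariant,
    CopyChange,
    CopyNumberVariant,
    MolecularVariant,
    SequenceLocation,
    SequenceRegistry,
    Severity,
    ValidationReport,
    VariantAnnotation,
)
from .features import DuplicateFeatureError, FeatureRecord, FeatureTable

__all__ = [
    "read_categorical_variants",
    "write_categorical_variants",
    "SkipRecord",
    "ingest_vcf",
    "load_feature_table",
    "load_annotations",
    "load_fasta",
    "BadIntervalError",
]


class BadIntervalError(ValueError):
    code = "BAD_INTERVAL"


def fixture_text(name: str) -> str:
    """Contents of a packaged example document (e.g. ``tp53_cnloss.json``)."""
    from importlib import resources

    return (resources.files("catvar") / "data" / name).read_text()


# ---------------------------------------------------------------------------
# Categorical-variant JSON


def read_categorical_variants(text: str, strict: bool = False) -> tuple[list[CategoricalVariant], ValidationReport]:
    """Parse a JSON document of categorical variants.

    Accepts a bare JSON array, a single object, or an object with a
    ``categoricalVariants`` array.  Structurally invalid entries are
    reported with their index and the remaining entries are returned; only
    malformed JSON itself raises a report-level PARSE_ERROR (still returned
    as data, with an empty category list).

    With ``strict=True`` unknown fields are violations instead of being
    preserved silently.
    """
    report = ValidationReport()
    try:
        data = json.loads(text)
    except json.JSONDecodeError as exc:
        report.add("PARSE_ERROR", f"malformed JSON: {exc}")
        return [], report

    if isinstance(data, dict) and "categoricalVariants" in data:
        entries = data["categoricalVariants"]
    elif isinstance(data, dict):
        entries = [data]
    elif isinstance(data, list):
        entries = data
    else:
        report.add("PARSE_ERROR", f"expected object or array, got {type(data).__name__}")
        return [], report

    out: list[CategoricalVariant] = []
    for i, entry in enumerate(entries):
        try:
            cv = CategoricalVariant.model_validate(entry)
        except ValidationError as exc:
            first = exc.errors()[0]
            report.add(
                "INVALID_DOCUMENT",
                f"entry {i}: {first.get('msg', 'invalid')} at {'.'.join(str(p) for p in first.get('loc', ()))}",
                path=f"[{i}]",
            )
            continue
        if strict:
            extra = cv.__pydantic_extra__ or {}
            for key in sorted(extra):
                report.add("UNKNOWN_FIELD", f"entry {i}: unknown field {key!r}", path=f"[{i}].{key}")
            for j, c in enumerate(cv.constraints):
                for key in sorted(c.__pydantic_extra__ or {}):
                    report.add(
                        "UNKNOWN_FIELD",
                        f"entry {i}: unknown field {key!r} on constraint {j}",
                        path=f"[{i}].constraints[{j}].{key}",
                    )
        out.append(cv)
    return out, report


def write_categorical_variants(catvars: list[CategoricalVariant]) -> str:
    """Serialize categories as a stable JSON array.

    Keys are sorted and formatting is fixed, so write→read→write is
    byte-identical.
    """
    payload = [cv.model_dump(by_alias=True, exclude_none=True, mode="json") for cv in catvars]
    return json.dumps(payload, indent=2, sort_keys=True, ensure_ascii=False) + "\n"


# ---------------------------------------------------------------------------
# VCF ingestion


class SkipRecord(BaseModel):
    record: str
    reason: str
    message: str = ""


_BND_RE = re.compile(r"^[ACGTN]*[\[\]]([^:\[\]]+):(\d+)[\[\]][ACGTN]*$|^[\[\]]([^:\[\]]+):(\d+)[\[\]][ACGTN]+$")
_SEQ_RE = re.compile(r"^[ACGTN]+$")


def _change_from_cn(cn: int, baseline: int) -> Optional[CopyChange]:
    if cn < baseline:
        return CopyChange.COMPLETE_LOSS if cn == 0 else CopyChange.LOSS
    if cn > baseline:
        return CopyChange.GAIN
    return None


def _first_cn(rec) -> Optional[int]:
    for sample in rec.samples.values():
        cn = sample.get("CN")
        if cn is not None:
            return int(cn)
    cn = rec.info.get("CN")
    if cn is not None:
        return int(cn[0] if isinstance(cn, tuple) else cn)
    return None


def ingest_vcf(
    path: Union[str, Path],
    references: SequenceRegistry | None = None,
    baseline: int | None = None,
) -> tuple[list[MolecularVariant], list[SkipRecord]]:
    """Read assayed variants from a VCF (v4.2+) file.

    Mapping, per ALT of each record (multi-allelic rows are split):

    * sequence REF/ALT → :class:`Allele` over ``[POS-1, POS-1+len(REF))``
      (1-based POS converted to inter-residue coordinates); REF-anchor bases
      are left in place and removed later by normalization;
    * ``<DEL>`` / ``<DUP>`` / ``<CNV>`` with INFO END →
      :class:`CopyNumberVariant` over ``[POS, END)`` in 0-based terms (the
      anchor base at POS is excluded); change code LOSS / GAIN / absent
      respectively, FORMAT or INFO ``CN`` becomes the count, and for
      ``<CNV>`` a code is derived from CN only when an explicit ``baseline``
      ploidy is given;
    * paired BND records (matched through INFO MATEID) → one
      :class:`AdjacencyVariant` whose breakends are zero-width points at the
      record positions;
    * anything unparseable goes to the skip report with a reason — the
      reader never aborts a batch.
    """
    variants: list[MolecularVariant] = []
    skips: list[SkipRecord] = []
    bnd_records: dict[str, tuple] = {}  # id -> (chrom, pos0, mateid)
    seen_ids: set[str] = set()

    def unique_id(base: str) -> str:
        vid, n = base, 1
        while vid in seen_ids:
            n += 1
            vid = f"{base}#{n}"
        seen_ids.add(vid)
        return vid

    with pysam.VariantFile(str(path)) as vf:
        for rec in vf:
            label = f"{rec.chrom}:{rec.pos}"
            if references is not None and rec.chrom not in references:
                skips.append(SkipRecord(record=label, reason="MISSING_REFERENCE", message=rec.chrom))
                continue
            if not rec.alts:
                skips.append(SkipRecord(record=label, reason="NO_ALT"))
                continue
            for alt in rec.alts:
                alt_label = f"{label}:{rec.ref}>{alt}"
                svtype = rec.info.get("SVTYPE")
                if alt in ("<DEL>", "<DUP>", "<CNV>"):
                    # pysam surfaces INFO END as rec.stop; without an END the
                    # stop collapses onto the anchor base
                    start, end = rec.start + 1, rec.stop  # exclude the anchor base at POS
                    if end <= start:
                        skips.append(SkipRecord(record=alt_label, reason="MISSING_END"))
                        continue
                    cn = _first_cn(rec)
                    if alt == "<DEL>":
                        code: Optional[CopyChange] = CopyChange.LOSS
                    elif alt == "<DUP>":
                        code = CopyChange.GAIN
                    else:
                        code = _change_from_cn(cn, baseline) if (cn is not None and baseline is not None) else None
                    if cn is None and code is None:
                        skips.append(SkipRecord(record=alt_label, reason="NO_CN_INFORMATION"))
                        continue
                    cnv = CopyNumberVariant(
                        location=SequenceLocation(sequenceId=rec.chrom, start=start, end=end),
                        count=cn,
                        changeCode=code,
                    )
                    variants.append(MolecularVariant.from_copy_number(unique_id(rec.id or alt_label), cnv))
                elif svtype == "BND" or _BND_RE.match(alt or ""):
                    if rec.id is None or "MATEID" not in rec.info:
                        skips.append(SkipRecord(record=alt_label, reason="UNPAIRED_BREAKEND"))
                        continue
                    mateid = rec.info["MATEID"]
                    if isinstance(mateid, tuple):
                        mateid = mateid[0]
                    bnd_records[rec.id] = (rec.chrom, rec.start, mateid, alt_label)
                elif alt is not None and alt.startswith("<"):
                    skips.append(SkipRecord(record=alt_label, reason="UNSUPPORTED_SYMBOLIC", message=alt))
                elif alt is not None and _SEQ_RE.match(alt.upper()) and _SEQ_RE.match((rec.ref or "").upper()):
                    loc = SequenceLocation(sequenceId=rec.chrom, start=rec.start, end=rec.start + len(rec.ref))
                    if references is not None and loc.end > references.length(rec.chrom):
                        skips.append(SkipRecord(record=alt_label, reason="OUT_OF_BOUNDS"))
                        continue
                    allele = Allele(location=loc, state=alt.upper())
                    variants.append(MolecularVariant.from_allele(unique_id(rec.id or alt_label), allele))
                else:
                    skips.append(SkipRecord(record=alt_label, reason="UNPARSEABLE_ALT", message=str(alt)))

    paired: set[str] = set()
    for rid, (chrom, pos0, mateid, alt_label) in sorted(bnd_records.items()):
        if rid in paired:
            continue
        mate = bnd_records.get(mateid)
        if mate is None or mate[2] != rid:
            skips.append(SkipRecord(record=alt_label, reason="UNPAIRED_BREAKEND", message=f"mate {mateid} missing"))
            continue
        paired.update({rid, mateid})
        adj = AdjacencyVariant(
            breakendA=SequenceLocation(sequenceId=chrom, start=pos0, end=pos0),
            breakendB=SequenceLocation(sequenceId=mate[0], start=mate[1], end=mate[1]),
        )
        variants.append(MolecularVariant.from_adjacency(unique_id(f"{rid}|{mateid}"), adj))
    return variants, skips


# ---------------------------------------------------------------------------
# Feature tables and annotations


def load_feature_table(text: str) -> FeatureTable:
    """Parse a BED or TSV feature table.

    Columns: sequence, start, end, name[, strand[, class]].  BED semantics
    (0-based half-open) by default; a ``#base=1`` pragma line switches to
    1-based inclusive starts.  Duplicate feature ids raise
    :class:`DuplicateFeatureError`; reversed intervals raise
    :class:`BadIntervalError`.
    """
    base = 0
    table = FeatureTable()
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.rstrip("\n")
        if not line.strip():
            continue
        if line.startswith("#"):
            pragma = line.lstrip("#").strip().replace(" ", "")
            if pragma == "base=1":
                base = 1
            continue
        if line.startswith(("browser", "track")):
            continue
        cols = line.split("\t")
        if len(cols) < 4:
            raise BadIntervalError(f"line {lineno}: expected ≥4 tab-separated columns")
        seq, start_s, end_s, name = cols[0], cols[1], cols[2], cols[3]
        try:
            start, end = int(start_s) - base, int(end_s)
        except ValueError as exc:
            raise BadIntervalError(f"line {lineno}: non-integer coordinates") from exc
        if start < 0 or end < start:
            raise BadIntervalError(f"line {lineno}: bad interval [{start},{end})")
        strand = cols[5] if len(cols) > 5 and cols[5] in "+-." else "."
        fclass = cols[6] if len(cols) > 6 else ("exon" if "exon" in name.lower() else "gene")
        table.add(
            FeatureRecord(
                id=name,
                symbol=name.split("_")[0],
                location=SequenceLocation(sequenceId=seq, start=start, end=end),
                strand=strand,
                feature_class=fclass,
            )
        )
    return table


def load_annotations(text: str) -> dict[str, VariantAnnotation]:
    """Parse an annotation TSV: ``variant_id<TAB>gene_symbols<TAB>function_terms``
    with comma-separated multi-values; empty cells allowed."""
    out: dict[str, VariantAnnotation] = {}
    for raw in text.splitlines():
        line = raw.rstrip("\n")
        if not line.strip() or line.startswith("#"):
            continue
        cols = (line.split("\t") + ["", ""])[:3]
        vid, genes, terms = cols
        out[vid] = VariantAnnotation(
            geneSymbols={g.strip() for g in genes.split(",") if g.strip()},
            functionTerms={t.strip() for t in terms.split(",") if t.strip()},
        )
    return out


def load_fasta(path: Union[str, Path]) -> SequenceRegistry:
    """Load reference sequences from a FASTA file into a registry (alphabet
    inferred per record)."""
    registry = SequenceRegistry()
    for record in SeqIO.parse(str(path), "fasta"):
        registry.add(record.id, str(record.seq))
    return registry


def write_fasta(registry: SequenceRegistry, path: Union[str, Path], width: int = 70) -> None:
    with open(path, "w") as fh:
        for sid in registry.ids():
            fh.write(f">{sid}\n")
            seq = registry.sequence(sid)
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")
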