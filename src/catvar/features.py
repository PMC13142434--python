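"""Feature table: gene/exon records mapping symbols to sequence intervals."""

from __future__ import annotations

from typing import Iterator, Optional

from pydantic import BaseModel, Field

from .core import SequenceLocation

__all__ = ["FeatureRecord", "FeatureTable", "DuplicateFeatureError"]


class DuplicateFeatureError(ValueError):
    code = "DUPLICATE_FEATURE"


class FeatureRecord(BaseModel):
    id: str
    symbol: str
    location: SequenceLocation
    strand: str = "."  # '+', '-', or '.'
    feature_class: str = Field(default="gene", alias="featureClass")  # gene / exon / other

    model_config = {"populate_by_name": True}


class FeatureTable:
    """Feature id → record, with case-insensitive symbol lookup.

    Small by design (tens of features); lookups are dict hits and overlap
    queries are linear scans, which is ample at this scale.
    """

    def __init__(self, records: list[FeatureRecord] | None = None) -> None:
        self._by_id: dict[str, FeatureRecord] = {}
        self._by_symbol: dict[str, str] = {}
        for rec in records or []:
            self.add(rec)

    def add(self, rec: FeatureRecord) -> None:
        if rec.id in self._by_id:
            raise DuplicateFeatureError(f"duplicate feature id {rec.id!r}")
        self._by_id[rec.id] = rec
        self._by_symbol.setdefault(rec.symbol.upper(), rec.id)

    def get(self, key: str) -> Optional[FeatureRecord]:
        """Resolve by id first, then by (case-insensitive) symbol."""
        if key in self._by_id:
            return self._by_id[key]
        fid = self._by_symbol.get(key.upper())
        return self._by_id.get(fid) if fid else None

    def __contains__(self, key: str) -> bool:
        return self.get(key) is not None

    def __len__(self) -> int:
        return len(self._by_id)

    def __iter__(self) -> Iterator[FeatureRecord]:
        return iter(self._by_id.values())

    def ids(self) -> list[str]:
        return list(self._by_id)
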