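"""Core sequence containers.

A :class:`ReadRecord` is one DNA sequence (a long read, a bait, a reference
gene or a contig) with optional Phred+33 per-base qualities and provenance
tags; a :class:`SequenceSet` is an ordered, id-unique collection of records.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Optional

from .errors import ValidationError

PLATFORMS = ("nanopore", "pacbio", "unknown")
READ_TYPES = ("template", "complement", "twoD", "subread", "roi", "contig", "unknown")

_DNA_ALPHABET = frozenset("ACGTN")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    """Reverse complement over the {A,C,G,T,N} alphabet."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class ReadRecord:
    """One sequence with optional quality, platform and read-type tags.

    Invariants (enforced at construction): non-empty id, sequence over
    {A,C,G,T,N}, quality string (when present) of equal length.
    """

    id: str
    sequence: str
    quality: Optional[str] = None
    platform: str = "unknown"
    read_type: str = "unknown"

    def __post_init__(self) -> None:
        if not self.id:
            raise ValidationError("record id must be non-empty")
        if not _DNA_ALPHABET.issuperset(self.sequence):
            bad = sorted(set(self.sequence) - _DNA_ALPHABET)
            raise ValidationError(
                f"record {self.id!r}: sequence contains non-DNA characters {bad}"
            )
        if self.quality is not None and len(self.quality) != len(self.sequence):
            raise ValidationError(
                f"record {self.id!r}: quality length {len(self.quality)} != "
                f"sequence length {len(self.sequence)}"
            )
        if self.platform not in PLATFORMS:
            raise ValidationError(f"record {self.id!r}: unknown platform {self.platform!r}")
        if self.read_type not in READ_TYPES:
            raise ValidationError(f"record {self.id!r}: unknown read_type {self.read_type!r}")

    def __len__(self) -> int:
        return len(self.sequence)

    def slice(self, start: int, end: int, new_id: Optional[str] = None) -> "ReadRecord":
        """Sub-record over [start, end); quality sliced identically."""
        return replace(
            self,
            id=new_id or self.id,
            sequence=self.sequence[start:end],
            quality=None if self.quality is None else self.quality[start:end],
        )

    def reverse_complement(self, new_id: Optional[str] = None) -> "ReadRecord":
        return replace(
            self,
            id=new_id or self.id,
            sequence=reverse_complement(self.sequence),
            quality=None if self.quality is None else self.quality[::-1],
        )


@dataclass
class SequenceSet:
    """Ordered collection of :class:`ReadRecord` with unique ids."""

    records: list = field(default_factory=list)
    source_path: str = ""

    def __post_init__(self) -> None:
        self._index = {}
        for i, rec in enumerate(self.records):
            if rec.id in self._index:
                raise ValidationError(f"duplicate record id {rec.id!r}")
            self._index[rec.id] = i

    @classmethod
    def from_records(cls, records: Iterable[ReadRecord], source_path: str = "") -> "SequenceSet":
        return cls(records=list(records), source_path=source_path)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[ReadRecord]:
        return iter(self.records)

    def __contains__(self, record_id: str) -> bool:
        return record_id in self._index

    def __getitem__(self, record_id: str) -> ReadRecord:
        return self.records[self._index[record_id]]

    def ids(self) -> list:
        return [rec.id for rec in self.records]

    def add(self, record: ReadRecord) -> None:
        if record.id in self._index:
            raise ValidationError(f"duplicate record id {record.id!r}")
        self._index[record.id] = len(self.records)
        self.records.append(record)

    def subset(self, ids: Iterable[str]) -> "SequenceSet":
        """Records with the given ids, in this set's order."""
        wanted = set(ids)
        missing = wanted - set(self._index)
        if missing:
            raise ValidationError(f"unknown record ids: {sorted(missing)}")
        return SequenceSet.from_records(
            [rec for rec in self.records if rec.id in wanted], self.source_path
        )

    def total_bases(self) -> int:
        return sum(len(rec) for rec in self.records)
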