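"""Sequence and table I/O.

FASTA/FASTQ reading goes through Biopython's low-level parsers; on ingestion
sequences are normalised (``U``→``T``, lowercase uppercased, any other letter
→``N`` with a warning) so that every in-memory record is over {A,C,G,T,N}.
FASTQ qualities are Phred+33; other encodings are rejected. FASTA output is
wrapped at 80 columns.

Tabular reports are written as TSV (with header) or JSON arrays; fractions in
``percent_fields`` are rendered as percentages with two decimals, half-up.
"""

from __future__ import annotations

import json
import warnings
from decimal import Decimal, ROUND_HALF_UP
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

from Bio.SeqIO.FastaIO import SimpleFastaParser
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from .errors import ParseError, ValidationError
from .records import ReadRecord, SequenceSet

_NORMALISE = str.maketrans("U", "T")
_VALID = frozenset("ACGTN")

# Phred+33 printable quality range: '!' (Q0) .. 'I' is typical but long-read
# callers emit up to '~' (Q93); anything outside 33..126 is not Phred+33.
_QUAL_MIN, _QUAL_MAX = 33, 126


def _normalise_sequence(seq: str, record_id: str) -> str:
    seq = seq.upper().translate(_NORMALISE)
    if _VALID.issuperset(seq):
        return seq
    bad = sorted(set(seq) - _VALID)
    warnings.warn(
        f"record {record_id!r}: non-DNA characters {bad} replaced with 'N'",
        stacklevel=3,
    )
    return "".join(c if c in _VALID else "N" for c in seq)


def _check_quality(qual: str, record_id: str) -> None:
    for ch in qual:
        o = ord(ch)
        if o < _QUAL_MIN or o > _QUAL_MAX:
            raise ParseError(
                f"record {record_id!r}: quality character {ch!r} (ord {o}) "
                "is outside the Phred+33 range"
            )


def sniff_format(path) -> str:
    """Guess fasta/fastq from the first non-blank character."""
    with open(path) as fh:
        for line in fh:
            stripped = line.strip()
            if not stripped:
                continue
            if stripped[0] == ">":
                return "fasta"
            if stripped[0] == "@":
                return "fastq"
            raise ParseError(f"{path}: cannot sniff format from leading {stripped[0]!r}")
    return "fasta"  # empty file: arbitrary but valid


def read_sequences(path, format: str = "auto", platform: str = "unknown",
                   read_type: str = "unknown") -> SequenceSet:
    """Read a FASTA/FASTQ file into a :class:`SequenceSet`.

    ``format='auto'`` sniffs the first non-blank character ('>' vs '@').
    An empty file yields an empty set. Malformed records raise
    :class:`ParseError` naming the offending record.
    """
    path = Path(path)
    if format == "auto":
        format = sniff_format(path)
    if format not in ("fasta", "fastq"):
        raise ValidationError(f"unknown format {format!r}")

    records = []
    with open(path) as fh:
        if format == "fasta":
            for title, seq in SimpleFastaParser(fh):
                rid = title.split()[0] if title.split() else ""
                if not rid:
                    raise ParseError(f"{path}: FASTA record with empty id")
                records.append(
                    ReadRecord(rid, _normalise_sequence(seq, rid),
                               platform=platform, read_type=read_type)
                )
        else:
            try:
                for title, seq, qual in FastqGeneralIterator(fh):
                    rid = title.split()[0] if title.split() else ""
                    if not rid:
                        raise ParseError(f"{path}: FASTQ record with empty id")
                    if len(qual) != len(seq):
                        raise ParseError(
                            f"record {rid!r}: quality length {len(qual)} != "
                            f"sequence length {len(seq)}"
                        )
                    _check_quality(qual, rid)
                    records.append(
                        ReadRecord(rid, _normalise_sequence(seq, rid), quality=qual,
                                   platform=platform, read_type=read_type)
                    )
            except ValueError as exc:  # Biopython structural error; names the record
                raise ParseError(f"{path}: {exc}") from exc
    return SequenceSet.from_records(records, source_path=str(path))


def write_sequences(seqs: SequenceSet, path, format: str = "fasta") -> None:
    """Write a :class:`SequenceSet` as FASTA (80-column wrapped) or FASTQ.

    FASTQ output requires qualities on every record.
    """
    if format not in ("fasta", "fastq"):
        raise ValidationError(f"unknown format {format!r}")
    if format == "fastq":
        missing = [rec.id for rec in seqs if rec.quality is None]
        if missing:
            raise ValidationError(
                f"cannot write FASTQ: records without quality: {missing}"
            )
    with open(path, "w") as fh:
        for rec in seqs:
            if format == "fasta":
                fh.write(f">{rec.id}\n")
                for i in range(0, max(len(rec.sequence), 1), 80):
                    chunk = rec.sequence[i:i + 80]
                    fh.write(chunk + "\n")
                if len(rec.sequence) == 0:
                    pass  # header-only entry for an empty sequence
            else:
                fh.write(f"@{rec.id}\n{rec.sequence}\n+\n{rec.quality}\n")


def format_percent(fraction: float) -> str:
    """Render a fraction as a percentage with two decimals, half-up.

    0.819823 -> '81.98'.
    """
    value = Decimal(repr(float(fraction))) * 100
    return str(value.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


def round_percent(fraction: float) -> float:
    """Same as :func:`format_percent` but as a float (81.98)."""
    return float(format_percent(fraction))


def write_table(rows: Sequence[Mapping], path, format: str = "tsv",
                percent_fields: Iterable[str] = (),
                columns: Optional[Sequence[str]] = None) -> None:
    """Write keyed rows as TSV (header line) or a JSON array.

    All rows must share one key set. Fields named in ``percent_fields`` hold
    fractions and are rendered as two-decimal percentages. ``columns`` fixes
    the column order (default: key order of the first row).
    """
    if format not in ("tsv", "json"):
        raise ValidationError(f"unknown table format {format!r}")
    rows = list(rows)
    percent_fields = set(percent_fields)
    if rows:
        keys = list(rows[0].keys())
        keyset = set(keys)
        for i, row in enumerate(rows):
            if set(row.keys()) != keyset:
                raise ValidationError(
                    f"row {i} keys {sorted(row.keys())} != header keys {sorted(keyset)}"
                )
    else:
        keys = list(columns or [])
    if columns is not None:
        keys = list(columns)

    def render(key, value):
        if value is None:
            return ""
        if key in percent_fields:
            return format_percent(value)
        return str(value)

    if format == "tsv":
        with open(path, "w") as fh:
            fh.write("\t".join(keys) + "\n")
            for row in rows:
                fh.write("\t".join(render(k, row[k]) for k in keys) + "\n")
    else:
        payload = []
        for row in rows:
            out = {}
            for k in keys:
                v = row[k]
                out[k] = float(format_percent(v)) if (k in percent_fields and v is not None) else v
            payload.append(out)
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)
            fh.write("\n")
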