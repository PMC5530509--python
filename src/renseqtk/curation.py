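"""Pre-assembly read curation.

The stages mirror a long-read capture library cleanup: a fixed trim of the
amplification-adapter length from both read ends, approximate adapter
search (both strands, per-platform error rate), removal of reads that fell
below a minimum length, and removal of PCR-chimeric reads — reads carrying
a residual adapter in their interior, the signature of two fragments fused
through an adapter during amplification.

The chimera rule is made precise by a flank criterion: a detected adapter
span with at least ``chimera_flank`` bases on *both* sides marks the read
chimeric; adapter spans closer than that to an end are trimmed off instead
(end-adjacent residue is trimmable, interior adapter implies fusion).
Chimeric reads are removed whole, never split.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Tuple

from .align import Span, semiglobal_locate
from .errors import ValidationError
from .readqc import ReadStats, length_stats
from .records import ReadRecord, SequenceSet

NANOPORE_ADAPTER_ERROR_RATE = 0.20
PACBIO_ADAPTER_ERROR_RATE = 0.05


@dataclass(frozen=True)
class AdapterSpec:
    """One adapter sequence with its allowed error rate.

    ``max_edits`` for a pattern of length L is floor(rate * L).
    """

    name: str
    sequence: str
    max_error_rate: float = NANOPORE_ADAPTER_ERROR_RATE

    def __post_init__(self) -> None:
        if not (0 <= self.max_error_rate < 0.5):
            raise ValidationError("adapter max_error_rate must be in [0, 0.5)")
        if len(self.sequence) < 8:
            raise ValidationError("adapter sequence must be >= 8 bp")

    @property
    def max_edits(self) -> int:
        return int(self.max_error_rate * len(self.sequence))


@dataclass
class CurationConfig:
    end_trim: int = 65
    min_length: int = 150
    adapters: List[AdapterSpec] = field(default_factory=list)
    chimera_flank: int = 50

    def __post_init__(self) -> None:
        if self.end_trim < 0:
            raise ValidationError("end_trim must be >= 0")
        if self.min_length < 1:
            raise ValidationError("min_length must be >= 1")
        if self.chimera_flank < 1:
            raise ValidationError("chimera_flank must be >= 1")


KEPT = "kept"
REMOVED_SHORT = "removed_short"
REMOVED_CHIMERIC = "removed_chimeric"


@dataclass
class CurationOutcome:
    read_id: str
    decision: str
    trimmed_sequence: str = ""
    trimmed_quality: Optional[str] = None
    adapter_spans: List[Span] = field(default_factory=list)
    removed_prefix_len: int = 0
    removed_suffix_len: int = 0
    final_length: int = 0


def trim_fixed_ends(read: ReadRecord, n: int) -> ReadRecord:
    """Remove the first and last ``n`` bases (quality sliced identically).

    A read of length <= 2n becomes empty.
    """
    if n < 0:
        raise ValidationError("trim length must be >= 0")
    if n == 0:
        return read
    end = max(n, len(read) - n)
    return read.slice(n, end) if len(read) > 2 * n else read.slice(len(read), len(read))


def detect_adapters(read: ReadRecord, adapters: List[AdapterSpec]) -> List[Span]:
    """Union of both-strand approximate matches of every adapter.

    Spans are sorted by start; overlapping spans from different adapters are
    all reported.
    """
    if not adapters:
        raise ValidationError("detect_adapters requires at least one adapter")
    spans: List[Span] = []
    for spec in adapters:
        spans.extend(semiglobal_locate(spec.sequence, read.sequence, spec.max_edits))
    spans.sort(key=lambda s: (s.start, s.end))
    return spans


def _merge_spans(spans: List[Span]) -> List[Span]:
    """Merge overlapping spans into maximal intervals (min edits kept)."""
    merged: List[Span] = []
    for span in sorted(spans, key=lambda s: (s.start, s.end)):
        if merged and span.start < merged[-1].end:
            last = merged[-1]
            merged[-1] = Span(last.start, max(last.end, span.end),
                              min(last.edits, span.edits))
        else:
            merged.append(span)
    return merged


def curate(read: ReadRecord, config: CurationConfig) -> CurationOutcome:
    """Apply the full per-read curation cascade.

    Order: fixed end trim; iterated adapter detection where end-proximal
    spans (closer than ``chimera_flank`` to the current read ends) are
    trimmed off and any surviving interior span flags the read chimeric;
    finally the length filter. Re-scanning after each trim guarantees that
    no kept read retains an adapter within its edit threshold.
    """
    L = len(read)
    left = min(config.end_trim, L)
    right = max(left, L - config.end_trim)
    all_spans: List[Span] = []
    chimeric = False
    while right > left and config.adapters:
        sub = read.slice(left, right)
        spans = detect_adapters(sub, config.adapters)
        if not spans:
            break
        all_spans.extend(Span(s.start + left, s.end + left, s.edits) for s in spans)
        merged = _merge_spans(spans)
        sub_len = right - left
        trimmed = False
        for s in merged:
            if s.start < config.chimera_flank:
                left += s.end
                trimmed = True
                break
            if sub_len - s.end < config.chimera_flank:
                right = left + s.start
                trimmed = True
                break
        if not trimmed:
            chimeric = True
            break
    final_len = max(0, right - left)
    outcome = CurationOutcome(
        read_id=read.id,
        decision=KEPT,
        adapter_spans=all_spans,
        removed_prefix_len=left,
        removed_suffix_len=L - right,
        final_length=final_len if not chimeric else 0,
    )
    if chimeric:
        outcome.decision = REMOVED_CHIMERIC
    elif final_len < config.min_length:
        outcome.decision = REMOVED_SHORT
    else:
        kept = read.slice(left, right)
        outcome.trimmed_sequence = kept.sequence
        outcome.trimmed_quality = kept.quality
    return outcome


CURATION_SUMMARY_COLUMNS = [
    "n_input", "n_kept", "n_removed_short", "n_removed_chimeric",
    "kept_total_bases", "kept_n50", "kept_mean_length", "kept_modal_length",
]


def curate_set(reads: SequenceSet, config: CurationConfig) -> Tuple[SequenceSet, dict]:
    """Curate every read; returns (kept reads in input order, summary row)."""
    kept_records = []
    outcomes = []
    counts = {KEPT: 0, REMOVED_SHORT: 0, REMOVED_CHIMERIC: 0}
    for read in reads:
        out = curate(read, config)
        outcomes.append(out)
        counts[out.decision] += 1
        if out.decision == KEPT:
            kept_records.append(
                ReadRecord(read.id, out.trimmed_sequence, quality=out.trimmed_quality,
                           platform=read.platform, read_type=read.read_type)
            )
    kept = SequenceSet.from_records(kept_records, source_path=reads.source_path)
    stats = length_stats(kept) if len(kept) else ReadStats()
    summary = {
        "n_input": len(reads),
        "n_kept": counts[KEPT],
        "n_removed_short": counts[REMOVED_SHORT],
        "n_removed_chimeric": counts[REMOVED_CHIMERIC],
        "kept_total_bases": stats.total_bases,
        "kept_n50": stats.n50,
        "kept_mean_length": round(stats.mean_length, 2),
        "kept_modal_length": stats.modal_length,
        "outcomes": outcomes,
    }
    return kept, summary
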