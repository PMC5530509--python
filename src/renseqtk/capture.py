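"""On-target rate determination for hybridisation-capture libraries.

A read is on-target when some capture bait aligns to it over at least
``min_alignment_length`` columns at ``min_identity`` or better (defaults
96 bp / 80%, the standard RenSeq bait-hit rule). "Over N bases" is counted
in alignment columns, gap columns included — the convention of a filter
applied to tabular alignment output.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Tuple

from .align import (AlignmentHit, AlignmentParams, DEFAULT_PARAMS, EXACT_DP_MAX,
                    KmerIndex, _align_codes, _cluster_diagonals, _hit_from_raw, encode)
from .errors import ValidationError
from .records import ReadRecord, SequenceSet, reverse_complement

CAPTURE_SEED_K = 9  # short seeds: bait hits only need 80% identity


@dataclass(frozen=True)
class BaitHitCriteria:
    min_alignment_length: int = 96
    min_identity: float = 0.80

    def __post_init__(self) -> None:
        if self.min_alignment_length < 1:
            raise ValidationError("min_alignment_length must be >= 1")
        if not (0 < self.min_identity <= 1):
            raise ValidationError("min_identity must be in (0, 1]")


def _bait_alignments(read: ReadRecord, index: KmerIndex,
                     params: AlignmentParams) -> List[AlignmentHit]:
    """Best local alignment of each candidate bait against the read.

    Baits are the queries; candidates are seed-gated per strand. Exhaustive
    DP is used whenever bait and read fit the exact-DP size limit.
    """
    hits = []
    cread = encode(read.sequence)
    read_rc = reverse_complement(read.sequence)
    cread_rc = encode(read_rc)
    seen = {}
    for strand, codes in (("+", cread), ("-", cread_rc)):
        seq = read.sequence if strand == "+" else read_rc
        seeds = index.seed_hits(seq)
        for si in seeds:
            # seed hit of read k-mer inside bait si; align bait vs read
            if (si, strand) in seen:
                continue
            seen[(si, strand)] = True
    for (si, strand) in sorted(seen, key=lambda x: (x[0], x[1])):
        bait = index.subjects.records[si]
        cb = encode(bait.sequence)
        target = cread if strand == "+" else cread_rc
        if len(bait) <= EXACT_DP_MAX and len(read) <= EXACT_DP_MAX:
            raw = _align_codes(cb, target, params)
        else:  # pragma: no cover - baits are short in practice
            raw = _align_codes(cb, target, params)
        if raw is None:
            continue
        # '-' alignments were run against revcomp(read), which is exactly the
        # minus-frame convention _hit_from_raw converts back to forward.
        hit = _hit_from_raw(raw, bait.id, read.id, strand, len(read))
        hits.append(hit)
    return hits


def read_on_target(read: ReadRecord, baits: SequenceSet,
                   criteria: Optional[BaitHitCriteria] = None,
                   params: Optional[AlignmentParams] = None,
                   index: Optional[KmerIndex] = None
                   ) -> Tuple[bool, Optional[AlignmentHit]]:
    """Classify one read; returns (on_target, best qualifying hit or None).

    The best hit is the highest-scoring qualifying bait alignment (ties:
    higher identity, then bait id).
    """
    criteria = criteria or BaitHitCriteria()
    params = params or DEFAULT_PARAMS
    if len(baits) == 0:
        raise ValidationError("read_on_target requires a non-empty bait set")
    if index is None:
        index = KmerIndex(baits, CAPTURE_SEED_K)
    qualifying = [
        h for h in _bait_alignments(read, index, params)
        if h.columns >= criteria.min_alignment_length and h.identity >= criteria.min_identity
    ]
    if not qualifying:
        return False, None
    best = max(qualifying, key=lambda h: (h.score, h.identity, h.query_id))
    return True, best


ON_TARGET_COLUMNS = ["read_id", "on_target", "bait_id", "identity_pct", "aln_columns"]


def on_target_rate(reads: SequenceSet, baits: SequenceSet,
                   criteria: Optional[BaitHitCriteria] = None,
                   params: Optional[AlignmentParams] = None
                   ) -> Tuple[float, List[dict]]:
    """On-target fraction of a read set plus a per-read decision table.

    The fraction is on-target reads / total reads (render as a two-decimal
    percentage via ``format_percent``).
    """
    if len(reads) == 0:
        raise ValidationError("on_target_rate requires a non-empty read set")
    index = KmerIndex(baits, CAPTURE_SEED_K)
    rows = []
    n_on = 0
    for read in reads:
        on, best = read_on_target(read, baits, criteria, params, index=index)
        n_on += on
        rows.append({
            "read_id": read.id,
            "on_target": on,
            "bait_id": best.query_id if best else None,
            "identity_pct": best.identity if best else None,
            "aln_columns": best.columns if best else None,
        })
    return n_on / len(reads), rows
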