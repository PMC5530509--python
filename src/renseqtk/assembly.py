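"""Assembly evaluation against an annotated reference gene set.

Best-hit search of reference genes inside assembled contigs with explicit
length/identity acceptance criteria, hand-curation-style removal of
duplicate hits on the same contig region, Excel-convention (sample, n-1)
summary statistics, read-mapping summaries, and a MUMmer-style match
segment export for dot plotting.

The acceptance criteria (default 500 bp / 85% identity) replace an
"e-value = 0" style cutoff deliberately: e-values depend on database size
and tool internals, whereas explicit thresholds are portable and
configurable.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Tuple

import numpy as np

from .align import (AlignmentHit, AlignmentParams, DEFAULT_PARAMS, KmerIndex,
                    map_reads)
from .errors import ValidationError
from .io import round_percent
from .records import SequenceSet

DOTPLOT_SEED_K = 15


@dataclass(frozen=True)
class AcceptanceCriteria:
    min_alignment_length: int = 500
    min_identity: float = 0.85

    def __post_init__(self) -> None:
        if self.min_alignment_length < 1 or self.min_identity <= 0:
            raise ValidationError("acceptance criteria must be positive")


@dataclass
class BestHitSummary:
    n_hits: int
    n_reference: int
    coverage_pct: float
    mean_identity: Optional[float]
    sd_identity: Optional[float]
    mean_aln_len: Optional[float]
    sd_aln_len: Optional[float]
    mean_query_len_pct: Optional[float] = None
    sd_query_len_pct: Optional[float] = None


def best_hit_search(queries: SequenceSet, subjects: SequenceSet,
                    criteria: Optional[AcceptanceCriteria] = None,
                    params: Optional[AlignmentParams] = None) -> List[AlignmentHit]:
    """At most one accepted hit per query gene against the contig set.

    The best-scoring local alignment per query (both strands, all subjects)
    is accepted iff it spans >= min_alignment_length columns at
    >= min_identity.
    """
    if len(queries) == 0 or len(subjects) == 0:
        raise ValidationError("best_hit_search requires non-empty query and subject sets")
    criteria = criteria or AcceptanceCriteria()
    hits = map_reads(queries, subjects, params)
    return [h for h in hits
            if h.columns >= criteria.min_alignment_length
            and h.identity >= criteria.min_identity]


def dedupe_same_subject(hits: List[AlignmentHit],
                        overlap_fraction: float = 0.5
                        ) -> Tuple[List[AlignmentHit], List[AlignmentHit]]:
    """Remove duplicate hits covering the same contig region.

    Among hits whose subject intervals overlap by more than
    ``overlap_fraction`` of the shorter interval, only the highest-scoring
    survives (ties: higher identity, then query id). Returns
    (kept, removed).
    """
    order = sorted(hits, key=lambda h: (-h.score, -h.identity, h.query_id))
    kept: List[AlignmentHit] = []
    removed: List[AlignmentHit] = []
    for hit in order:
        clash = False
        for other in kept:
            if other.subject_id != hit.subject_id:
                continue
            ov = min(hit.s_end, other.s_end) - max(hit.s_start, other.s_start)
            shorter = min(hit.s_end - hit.s_start, other.s_end - other.s_start)
            if ov > overlap_fraction * shorter:
                clash = True
                break
        (removed if clash else kept).append(hit)
    kept.sort(key=lambda h: h.query_id)
    removed.sort(key=lambda h: h.query_id)
    return kept, removed


def _mean_sd(values) -> Tuple[Optional[float], Optional[float]]:
    arr = np.asarray(list(values), dtype=float)
    if arr.size == 0:
        return None, None
    mean = float(arr.mean())
    sd = float(arr.std(ddof=1)) if arr.size > 1 else 0.0
    return mean, sd


def summarize_hits(hits: List[AlignmentHit], n_reference: int,
                   query_lengths: Optional[Dict[str, int]] = None) -> BestHitSummary:
    """Coverage and mean +/- sample SD of identity and alignment length.

    ``coverage_pct`` is 100 * hits / reference genes. Query-length
    percentage (aligned query span / query length) is reported when
    ``query_lengths`` is given.
    """
    if n_reference < 1:
        raise ValidationError("n_reference must be >= 1")
    if len(hits) > n_reference:
        raise ValidationError("more best hits than reference entries")
    mean_id, sd_id = _mean_sd(h.identity * 100 for h in hits)
    mean_len, sd_len = _mean_sd(h.columns for h in hits)
    mean_q, sd_q = (None, None)
    if query_lengths is not None:
        mean_q, sd_q = _mean_sd(
            100 * (h.q_end - h.q_start) / query_lengths[h.query_id] for h in hits
        )
    return BestHitSummary(
        n_hits=len(hits),
        n_reference=n_reference,
        coverage_pct=round_percent(len(hits) / n_reference),
        mean_identity=mean_id, sd_identity=sd_id,
        mean_aln_len=mean_len, sd_aln_len=sd_len,
        mean_query_len_pct=mean_q, sd_query_len_pct=sd_q,
    )


MAPPING_SUMMARY_COLUMNS = [
    "n_reads", "n_mapped", "mapped_pct", "mean_coverage", "general_error_rate_pct",
]


def mapping_summary(reads: SequenceSet, reference: SequenceSet,
                    params: Optional[AlignmentParams] = None) -> dict:
    """Mapping-QC row: mapped %, mean reference coverage, general error rate.

    Mean coverage is the total aligned reference span divided by total
    reference length; the general error rate is 1 - (total matches / total
    alignment columns) over all best hits.
    """
    hits = map_reads(reads, reference, params)
    total_ref = reference.total_bases()
    span = sum(h.s_end - h.s_start for h in hits)
    columns = sum(h.columns for h in hits)
    matches = sum(h.matches for h in hits)
    return {
        "n_reads": len(reads),
        "n_mapped": len(hits),
        "mapped_pct": len(hits) / len(reads) if len(reads) else 0.0,
        "mean_coverage": round(span / total_ref, 2) if total_ref else 0.0,
        "general_error_rate_pct": (1 - matches / columns) if columns else 0.0,
    }


DOTPLOT_COLUMNS = ["ref_id", "contig_id", "r_start", "r_end", "c_start", "c_end",
                   "strand", "identity_pct"]


def dotplot_export(assembly: SequenceSet, reference: SequenceSet,
                   min_match: int = 500,
                   params: Optional[AlignmentParams] = None) -> List[dict]:
    """Match segments >= ``min_match`` between every contig and reference
    entry, suitable for external dot plotting.

    Seeded diagonal clusters are aligned per (reference, contig, strand);
    forward and reverse matches are distinguished. Exported coordinates are
    1-based inclusive, reference-forward, with a strand column.
    """
    if min_match < 1:
        raise ValidationError("min_match must be >= 1")
    params = params or DEFAULT_PARAMS
    rows = []
    for ref in reference:
        ref_set = SequenceSet.from_records([ref])
        index = KmerIndex(ref_set, DOTPLOT_SEED_K)
        for contig in assembly:
            for strand in "+-":
                seq = contig.sequence if strand == "+" else None
                rec = contig if strand == "+" else contig.reverse_complement()
                segments = _strand_segments(rec.sequence, index, params, min_match)
                for seg in segments:
                    q0, q1 = seg.q_start, seg.q_end
                    if strand == "-":
                        q0 = len(contig) - seg.q_end
                        q1 = len(contig) - seg.q_start
                    rows.append({
                        "ref_id": ref.id,
                        "contig_id": contig.id,
                        "r_start": seg.s_start + 1,
                        "r_end": seg.s_end,
                        "c_start": q0 + 1,
                        "c_end": q1,
                        "strand": strand,
                        "identity_pct": round(seg.identity * 100, 2),
                    })
    rows.sort(key=lambda r: (r["ref_id"], r["contig_id"], r["strand"], r["r_start"]))
    return rows


def _strand_segments(query: str, index: KmerIndex, params: AlignmentParams,
                     min_match: int) -> List[AlignmentHit]:
    """Alignment segments of one query orientation against one indexed
    reference entry: one banded alignment per diagonal cluster."""
    from .align import EXACT_DP_MAX, _align_codes, _hit_from_raw, encode

    seeds = index.seed_hits(query)
    if not seeds:
        return []
    diags = sorted(seeds[0])
    clusters = []
    current = [diags[0]]
    for d in diags[1:]:
        if d - current[-1] <= 2 * params.band:
            current.append(d)
        else:
            clusters.append(current)
            current = [d]
    clusters.append(current)
    cq = encode(query)
    cb = index.codes[0]
    segments = []
    for cluster in clusters:
        lo, hi = cluster[0], cluster[-1]
        diag = (lo + hi) // 2
        band = (hi - lo) // 2 + params.band
        if len(query) <= EXACT_DP_MAX and cb.shape[0] <= EXACT_DP_MAX and len(clusters) == 1:
            raw = _align_codes(cq, cb, params)
        else:
            raw = _align_codes(cq, cb, params, diag=diag, band=band)
        if raw is None or raw["matches"] + raw["mismatches"] + raw["insertions"] + raw["deletions"] < min_match:
            continue
        segments.append(_hit_from_raw(raw, "query", index.subjects.records[0].id,
                                      "+", cb.shape[0]))
    # deduplicate identical segments found by adjacent clusters
    unique = {}
    for seg in segments:
        unique[(seg.q_start, seg.q_end, seg.s_start, seg.s_end)] = seg
    return list(unique.values())
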