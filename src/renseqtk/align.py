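"""Internal pairwise alignment engine.

Three operations back the whole pipeline:

* :func:`local_align` — best-scoring affine-gap local alignment of two DNA
  sequences, both strands of the subject tried. Inputs up to 2 kb per
  sequence are solved by exhaustive DP; larger inputs use a k-mer seeded,
  banded heuristic (documented as such).
* :func:`semiglobal_locate` — all locations of a full pattern (e.g. a PCR
  adapter) within a text at unit-cost edit distance <= max_edits, reduced to
  minimal-edit non-overlapping spans.
* :func:`map_reads` — best-hit-per-read mapping of a read set against a
  reference set, seed-gated: reads sharing no seed k-mer with any reference
  entry are reported unmapped.

Identity is matches / alignment columns, where columns include gap columns —
the percent-identity convention of tabular alignment output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np

from ._kernels import NEG, affine_band_dp, nw_last_row, semiglobal_end_row
from .errors import ValidationError
from .records import ReadRecord, SequenceSet, reverse_complement

EXACT_DP_MAX = 2000  # per-sequence length up to which local_align is exhaustive

_CODE = np.full(256, 4, dtype=np.int8)
for _i, _c in enumerate("ACGT"):
    _CODE[ord(_c)] = _i


def encode(seq: str) -> np.ndarray:
    return _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


@dataclass(frozen=True)
class AlignmentParams:
    """Scoring and heuristic parameters for the engine.

    Defaults (+2/-3/-5/-2) are common nucleotide-search settings. The affine
    model charges ``gap_open`` for the first gap base and ``gap_extend`` per
    additional base, hence ``gap_open <= gap_extend < 0``.
    """

    match: int = 2
    mismatch: int = -3
    gap_open: int = -5
    gap_extend: int = -2
    seed_k: int = 11
    band: int = 100

    def __post_init__(self) -> None:
        if self.match <= 0:
            raise ValidationError("match score must be positive")
        if self.mismatch >= 0 or self.gap_open >= 0 or self.gap_extend >= 0:
            raise ValidationError("mismatch and gap penalties must be negative")
        if self.gap_open > self.gap_extend:
            raise ValidationError("gap_open must be <= gap_extend (affine model)")
        if self.seed_k < 4:
            raise ValidationError("seed_k must be >= 4")
        if self.band < 1:
            raise ValidationError("band must be >= 1")


DEFAULT_PARAMS = AlignmentParams()


@dataclass(frozen=True)
class Span:
    """A located pattern occurrence: [start, end) on the forward text."""

    start: int
    end: int
    edits: int

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValidationError("span end must be > start")
        if self.edits < 0:
            raise ValidationError("span edits must be >= 0")

    def overlaps(self, other: "Span") -> bool:
        return self.start < other.end and other.start < self.end


@dataclass(frozen=True)
class AlignmentHit:
    """A pairwise local alignment result.

    Coordinates are 0-based half-open on the forward strand of each
    sequence; ``strand`` is the subject orientation of the aligned query.
    ``insertions`` are query-only columns, ``deletions`` subject-only.
    """

    query_id: str
    subject_id: str
    q_start: int
    q_end: int
    s_start: int
    s_end: int
    strand: str
    score: int
    matches: int
    mismatches: int
    insertions: int
    deletions: int

    def __post_init__(self) -> None:
        if self.q_end <= self.q_start or self.s_end <= self.s_start:
            raise ValidationError("alignment spans must be non-empty")
        if self.strand not in "+-":
            raise ValidationError("strand must be '+' or '-'")
        if min(self.matches, self.mismatches, self.insertions, self.deletions) < 0:
            raise ValidationError("column counts must be non-negative")

    @property
    def columns(self) -> int:
        return self.matches + self.mismatches + self.insertions + self.deletions

    @property
    def identity(self) -> float:
        return self.matches / self.columns


def _traceback(H, E, F, a, b, diag, band, params, bi, bw):
    """Walk back from the best cell; returns spans and column counts."""
    matches = mismatches = insertions = deletions = 0
    i, w = bi, bw
    state = "H"
    while True:
        j = i + diag - band + w
        if state == "H":
            h = H[i, w]
            if h == 0:
                break
            d = NEG
            if i > 0 and j > 0 and H[i - 1, w] > NEG:
                s = params.match if (a[i - 1] == b[j - 1] and a[i - 1] < 4) else params.mismatch
                d = H[i - 1, w] + s
            if d == h:
                if a[i - 1] == b[j - 1] and a[i - 1] < 4:
                    matches += 1
                else:
                    mismatches += 1
                i -= 1  # diagonal move keeps w
            elif E[i, w] == h:
                state = "E"
            elif F[i, w] == h:
                state = "F"
            else:  # pragma: no cover - DP consistency guard
                raise AssertionError("traceback: inconsistent H cell")
        elif state == "E":  # consume b only: subject-only column
            deletions += 1
            prev_h = H[i, w - 1] if w - 1 >= 0 else NEG
            opened = prev_h > NEG and prev_h + params.gap_open == E[i, w]
            w -= 1
            if opened:
                state = "H"
        else:  # state F: consume a only: query-only column
            insertions += 1
            prev_h = H[i - 1, w + 1] if w + 1 < H.shape[1] else NEG
            opened = prev_h > NEG and prev_h + params.gap_open == F[i, w]
            i -= 1
            w += 1
            if opened:
                state = "H"
    j = i + diag - band + w
    return i, j, matches, mismatches, insertions, deletions


def _align_codes(a: np.ndarray, b: np.ndarray, params: AlignmentParams,
                 diag: Optional[int] = None, band: Optional[int] = None):
    """Run the (banded) DP and return raw hit data or None if best <= 0."""
    m, n = a.shape[0], b.shape[0]
    if diag is None:
        diag = (n - m) // 2
        band = max(m + diag, n - diag)
    H, E, F, best, bi, bw = affine_band_dp(
        a, b, diag, band,
        np.int32(params.match), np.int32(params.mismatch),
        np.int32(params.gap_open), np.int32(params.gap_extend),
    )
    if best <= 0:
        return None
    q0, s0, ma, mm, ins, de = _traceback(H, E, F, a, b, diag, band, params, bi, bw)
    q1 = bi
    s1 = bi + diag - band + bw
    return {
        "score": int(best), "q_start": q0, "q_end": q1, "s_start": s0, "s_end": s1,
        "matches": ma, "mismatches": mm, "insertions": ins, "deletions": de,
    }


def _hit_from_raw(raw: dict, query_id: str, subject_id: str, strand: str,
                  subject_len: int) -> AlignmentHit:
    if strand == "-":
        s0 = subject_len - raw["s_end"]
        s1 = subject_len - raw["s_start"]
    else:
        s0, s1 = raw["s_start"], raw["s_end"]
    return AlignmentHit(
        query_id=query_id, subject_id=subject_id,
        q_start=raw["q_start"], q_end=raw["q_end"], s_start=s0, s_end=s1,
        strand=strand, score=raw["score"], matches=raw["matches"],
        mismatches=raw["mismatches"], insertions=raw["insertions"],
        deletions=raw["deletions"],
    )


def _better(raw_a, strand_a, raw_b, strand_b):
    """Pick the better raw hit; ties prefer '+' strand for determinism."""
    if raw_a is None:
        return raw_b, strand_b
    if raw_b is None:
        return raw_a, strand_a
    if raw_b["score"] > raw_a["score"]:
        return raw_b, strand_b
    return raw_a, strand_a


def local_align(a: str, b: str, params: Optional[AlignmentParams] = None,
                query_id: str = "query", subject_id: str = "subject") -> Optional[AlignmentHit]:
    """Best-scoring local alignment of ``a`` against both strands of ``b``.

    Exhaustive DP when both sequences are <= 2 kb; k-mer seeded banded
    heuristic otherwise. Returns None when no alignment scores > 0.
    """
    params = params or DEFAULT_PARAMS
    if not a or not b:
        raise ValidationError("local_align requires non-empty sequences")
    ca = encode(a)
    cb = encode(b)
    if len(a) <= EXACT_DP_MAX and len(b) <= EXACT_DP_MAX:
        raw_f = _align_codes(ca, cb, params)
        raw_r = _align_codes(ca, encode(reverse_complement(b)), params)
        raw, strand = _better(raw_f, "+", raw_r, "-")
        if raw is None:
            return None
        return _hit_from_raw(raw, query_id, subject_id, strand, len(b))
    return _seeded_align(a, b, params, query_id, subject_id)


# ---------------------------------------------------------------------------
# seeding


class KmerIndex:
    """Exact k-mer index over a set of subject sequences."""

    def __init__(self, subjects: SequenceSet, k: int):
        self.k = k
        self.subjects = subjects
        self.codes = [encode(rec.sequence) for rec in subjects]
        self.index: Dict[str, list] = {}
        for si, rec in enumerate(subjects):
            seq = rec.sequence
            for p in range(len(seq) - k + 1):
                kmer = seq[p:p + k]
                if "N" in kmer:
                    continue
                self.index.setdefault(kmer, []).append((si, p))

    def seed_hits(self, query: str) -> Dict[int, List[int]]:
        """Subject index -> list of diagonals (s_pos - q_pos) of shared k-mers."""
        out: Dict[int, List[int]] = {}
        k = self.k
        for p in range(len(query) - k + 1):
            entry = self.index.get(query[p:p + k])
            if not entry:
                continue
            for si, sp in entry:
                out.setdefault(si, []).append(sp - p)
        return out


def _cluster_diagonals(diags: List[int], width: int) -> Tuple[int, int, int]:
    """Densest diagonal cluster: (count, lo, hi) of diagonals within ``width``."""
    diags = sorted(diags)
    best = (0, 0, 0)
    j = 0
    for i in range(len(diags)):
        while diags[i] - diags[j] > width:
            j += 1
        count = i - j + 1
        if count > best[0]:
            best = (count, diags[j], diags[i])
    return best


def _seeded_raw(query: str, cq: np.ndarray, index: KmerIndex,
                params: AlignmentParams, max_candidates: int = 16):
    """Best raw hit of one query orientation against an indexed subject set.

    Returns (subject_index, raw) or None.
    """
    seeds = index.seed_hits(query)
    if not seeds:
        return None
    clusters = []
    for si, diags in seeds.items():
        count, lo, hi = _cluster_diagonals(diags, 2 * params.band)
        clusters.append((count, index.subjects.records[si].id, si, lo, hi))
    clusters.sort(key=lambda c: (-c[0], c[1]))
    best_count = clusters[0][0]
    keep = [c for c in clusters if c[0] >= max(1, best_count // 2)][:max_candidates]
    best = None
    for count, _sid, si, lo, hi in keep:
        diag = (lo + hi) // 2
        band = (hi - lo) // 2 + params.band
        cb = index.codes[si]
        m, n = cq.shape[0], cb.shape[0]
        if m <= EXACT_DP_MAX and n <= EXACT_DP_MAX:
            raw = _align_codes(cq, cb, params)
        else:
            raw = _align_codes(cq, cb, params, diag=diag, band=band)
        if raw is not None and (best is None or raw["score"] > best[1]["score"]):
            best = (si, raw)
    return best


def _seeded_align(a: str, b: str, params: AlignmentParams,
                  query_id: str, subject_id: str) -> Optional[AlignmentHit]:
    subjects = SequenceSet.from_records([ReadRecord(subject_id, b)])
    index = KmerIndex(subjects, params.seed_k)
    raw_f = _seeded_raw(a, encode(a), index, params)
    a_rc = reverse_complement(a)
    raw_r = _seeded_raw(a_rc, encode(a_rc), index, params)
    # A hit of revcomp(a) on forward b equals a hit of a on revcomp(b):
    # flip the query span to forward-a and store the subject span in
    # revcomp-b frame so that _hit_from_raw('-') restores forward-b coords.
    if raw_r is not None:
        raw = raw_r[1]
        raw_r = dict(
            raw,
            q_start=len(a) - raw["q_end"], q_end=len(a) - raw["q_start"],
            s_start=len(b) - raw["s_end"], s_end=len(b) - raw["s_start"],
        )
    raw_fwd = raw_f[1] if raw_f is not None else None
    raw, strand = _better(raw_fwd, "+", raw_r, "-")
    if raw is None:
        return None
    return _hit_from_raw(raw, query_id, subject_id, strand, len(b))


def map_reads(reads: SequenceSet, reference: SequenceSet,
              params: Optional[AlignmentParams] = None) -> List[AlignmentHit]:
    """Best-hit-per-read mapping against a reference set.

    At most one hit per read: the best-scoring local alignment over all
    reference entries and both strands. Ties break on higher identity, then
    lexicographically smallest subject id. Reads with no seed match or no
    positive-scoring alignment are absent from the result.
    """
    params = params or DEFAULT_PARAMS
    if len(reference) == 0:
        raise ValidationError("map_reads requires a non-empty reference")
    index = KmerIndex(reference, params.seed_k)
    hits = []
    for read in reads:
        hit = _map_one(read, index, params)
        if hit is not None:
            hits.append(hit)
    return hits


def _map_one(read: ReadRecord, index: KmerIndex,
             params: AlignmentParams) -> Optional[AlignmentHit]:
    candidates = []
    for strand in "+-":
        query = read.sequence if strand == "+" else reverse_complement(read.sequence)
        cq = encode(query)
        seeds = index.seed_hits(query)
        for si, diags in seeds.items():
            count, lo, hi = _cluster_diagonals(diags, 2 * params.band)
            candidates.append((count, index.subjects.records[si].id, si, strand, lo, hi))
    if not candidates:
        return None
    candidates.sort(key=lambda c: (-c[0], c[1], c[3]))
    best_count = candidates[0][0]
    keep = [c for c in candidates if c[0] >= max(1, best_count // 2)][:16]
    best_hit = None
    for count, sid, si, strand, lo, hi in keep:
        query = read.sequence if strand == "+" else reverse_complement(read.sequence)
        cq = encode(query)
        cb = index.codes[si]
        m, n = cq.shape[0], cb.shape[0]
        if m <= EXACT_DP_MAX and n <= EXACT_DP_MAX:
            raw = _align_codes(cq, cb, params)
        else:
            diag = (lo + hi) // 2
            band = (hi - lo) // 2 + params.band
            raw = _align_codes(cq, cb, params, diag=diag, band=band)
        if raw is None:
            continue
        if strand == "-":
            # query was revcomp'd, subject span is on forward b: flip the
            # query span to forward coords and pre-flip the subject span so
            # _hit_from_raw('-') restores it.
            qlen = len(read.sequence)
            raw = dict(raw, q_start=qlen - raw["q_end"], q_end=qlen - raw["q_start"],
                       s_start=n - raw["s_end"], s_end=n - raw["s_start"])
        hit = _hit_from_raw(raw, read.id, sid, strand, n)
        if best_hit is None or _hit_rank(hit) > _hit_rank(best_hit):
            best_hit = hit
    return best_hit


def _hit_rank(hit: AlignmentHit):
    """Ordering key: higher score, then higher identity, then smaller
    subject id, then '+' strand."""
    return (hit.score, hit.identity, _NegStr(hit.subject_id), hit.strand == "+")


class _NegStr(str):
    """String whose ordering is reversed, for use inside max-style keys."""

    def __lt__(self, other):
        return str.__gt__(self, other)

    def __gt__(self, other):
        return str.__lt__(self, other)


# ---------------------------------------------------------------------------
# approximate pattern location (adapter search)


def semiglobal_locate(pattern: str, text: str, max_edits: int) -> List[Span]:
    """All spans where the full pattern matches within ``max_edits``.

    Pattern ends are anchored, text ends free; both strands of the pattern
    are searched and spans reported on forward text coordinates. Candidate
    placements are reduced to non-overlapping spans by ascending (edits,
    start, end) — locally minimal-edit, leftmost-first.
    """
    if not pattern:
        raise ValidationError("semiglobal_locate requires a non-empty pattern")
    if max_edits < 0:
        raise ValidationError("max_edits must be >= 0")
    if not text:
        return []
    m = len(pattern)
    candidates: Dict[Tuple[int, int], int] = {}
    patterns = {pattern, reverse_complement(pattern)}
    ct = encode(text)
    for pat in sorted(patterns):
        cp = encode(pat)
        end_row = semiglobal_end_row(cp, ct)
        ends = np.nonzero(end_row[1:] <= max_edits)[0] + 1
        cp_rev = cp[::-1]
        for e in ends:
            e = int(e)
            window_len = min(e, m + max_edits)
            window_rev = ct[e - window_len:e][::-1]
            row = nw_last_row(cp_rev, window_rev)
            j_min = max(1, m - max_edits)
            for j in range(j_min, window_len + 1):
                d = int(row[j])
                if d <= max_edits:
                    key = (e - j, e)
                    if key not in candidates or d < candidates[key]:
                        candidates[key] = d
    emitted: List[Span] = []
    for (s, e), d in sorted(candidates.items(), key=lambda kv: (kv[1], kv[0][0], kv[0][1])):
        span = Span(s, e, d)
        if not any(span.overlaps(prev) for prev in emitted):
            emitted.append(span)
    emitted.sort(key=lambda sp: sp.start)
    return emitted
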