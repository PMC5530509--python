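"""Rapid novel-NLR identification.

The strategy: map reads against a reference NLR gene set from which the
genes of interest are absent; reads that do not map, or map below an
empirical identity threshold of mean - k*SD (default k=2, sample SD over
the best-hit identities of all mapped reads), are candidate carriers of
novel genes. The candidates are pooled, assembled, optionally filtered for
NLR motifs, and the resulting contigs are scored against the withheld genes
to measure recovery.

The bundled assembler is a deterministic greedy overlap-layout-consensus
toy, fixture-grade by design: production use delegates assembly to an
external long-read assembler (reads FASTQ in, contigs FASTA out).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .align import AlignmentHit, AlignmentParams, local_align, map_reads
from .assembly import AcceptanceCriteria, best_hit_search, dedupe_same_subject
from .errors import ValidationError
from .motifs import CALL_NONE, DEFAULT_MOTIFS, classify_sequence
from .records import ReadRecord, SequenceSet

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


@dataclass
class TriageConfig:
    sd_multiplier: float = 2.0
    recovery_criteria: AcceptanceCriteria = field(default_factory=AcceptanceCriteria)
    assembler: str = "toy"
    require_motifs: bool = False

    def __post_init__(self) -> None:
        if self.sd_multiplier <= 0:
            raise ValidationError("sd_multiplier must be > 0")
        if self.assembler not in ("toy", "external", "none"):
            raise ValidationError(f"unknown assembler {self.assembler!r}")


@dataclass
class TriageReport:
    mean_identity: float = 0.0
    sd_identity: float = 0.0
    threshold: float = 0.0
    n_unmapped: int = 0
    n_below_threshold: int = 0
    n_candidates: int = 0
    recovered: List[dict] = field(default_factory=list)
    n_withheld: int = 0
    n_recovered: int = 0
    recovered_mean_identity: Optional[float] = None
    recovered_sd_identity: Optional[float] = None


def reduce_reference(reference: SequenceSet, exclude_ids: Sequence[str]) -> SequenceSet:
    """Reference minus the excluded entries, order preserved."""
    exclude = list(exclude_ids)
    if len(set(exclude)) != len(exclude):
        dupes = sorted({x for x in exclude if exclude.count(x) > 1})
        raise ValidationError(f"duplicate ids in exclusion list: {dupes}")
    missing = [x for x in exclude if x not in reference]
    if missing:
        raise ValidationError(f"exclusion ids not in reference: {missing}")
    excluded = set(exclude)
    return SequenceSet.from_records(
        [rec for rec in reference if rec.id not in excluded],
        source_path=reference.source_path,
    )


def identity_threshold(identities: Sequence[float],
                       multiplier: float = 2.0) -> Tuple[float, float, float]:
    """(mean, sample SD, mean - multiplier*SD) of best-hit identities (%)."""
    arr = np.asarray(list(identities), dtype=float)
    if arr.size < 2:
        raise ValidationError("identity_threshold requires >= 2 identities")
    mean = float(arr.mean())
    sd = float(arr.std(ddof=1))
    return mean, sd, mean - multiplier * sd


def select_candidates(reads: SequenceSet, hits: List[AlignmentHit],
                      threshold: float) -> Tuple[SequenceSet, int, int]:
    """Unmapped reads plus reads whose best-hit identity (%) is strictly
    below the threshold, in input order.

    ``hits`` must be best-hit-per-read (as produced by :func:`map_reads`).
    Returns (candidates, n_unmapped, n_below_threshold).
    """
    best: Dict[str, float] = {}
    for h in hits:
        if h.query_id in best:
            raise ValidationError(f"multiple hits for read {h.query_id!r}")
        best[h.query_id] = h.identity * 100
    records = []
    n_unmapped = n_below = 0
    for read in reads:
        if read.id not in best:
            n_unmapped += 1
            records.append(read)
        elif best[read.id] < threshold:
            n_below += 1
            records.append(read)
    return SequenceSet.from_records(records), n_unmapped, n_below


# ---------------------------------------------------------------------------
# toy greedy overlap-layout-consensus assembler


class _Contig:
    __slots__ = ("id", "columns", "members")

    def __init__(self, id: str, columns: List[dict], members: List[str]):
        self.id = id
        self.columns = columns
        self.members = members

    @classmethod
    def from_read(cls, read: ReadRecord) -> "_Contig":
        return cls(read.id, [{base: 1} for base in read.sequence], [read.id])

    def consensus(self) -> str:
        out = []
        for col in self.columns:
            top = max(col.values())
            out.append(min(b for b, c in col.items() if c == top))
        return "".join(out)

    def reverse_complement(self) -> "_Contig":
        cols = [{_COMP[b]: c for b, c in col.items()} for col in reversed(self.columns)]
        return _Contig(self.id, cols, list(self.members))


@dataclass
class AssemblyResult:
    contigs: SequenceSet
    members: Dict[str, List[str]]


def _shared_kmers(a: str, b: str, k: int = 15) -> int:
    if len(a) < k or len(b) < k:
        return 0
    ka = {a[i:i + k] for i in range(len(a) - k + 1)}
    return sum(1 for i in range(len(b) - k + 1) if b[i:i + k] in ka)


def _merge_plan(a: _Contig, b: _Contig, params: AlignmentParams,
                min_overlap: int, min_identity: float, slack: int = 10):
    """Qualifying merge of two contigs, or None.

    Returns (score, kind, hit, b_oriented) where kind is 'contain_b',
    'contain_a', 'suffix_prefix' (A then B) or 'prefix_suffix' (B then A).
    """
    cons_a = a.consensus()
    cons_b = b.consensus()
    if _shared_kmers(cons_a, cons_b) < 3 and _shared_kmers(
            cons_a, b.reverse_complement().consensus()) < 3:
        return None
    hit = local_align(cons_a, cons_b, params)
    if hit is None or hit.columns < min_overlap or hit.identity < min_identity:
        return None
    b_oriented = b if hit.strand == "+" else b.reverse_complement()
    if hit.strand == "-":
        # express the subject span in the oriented (revcomp) frame of b
        s_start = len(cons_b) - hit.s_end
        s_end = len(cons_b) - hit.s_start
    else:
        s_start, s_end = hit.s_start, hit.s_end
    la, lb = len(cons_a), len(cons_b)
    geometry = {
        "q_start": hit.q_start, "q_end": hit.q_end,
        "s_start": s_start, "s_end": s_end,
    }
    if s_start <= slack and lb - s_end <= slack:
        kind = "contain_b"
    elif hit.q_start <= slack and la - hit.q_end <= slack:
        kind = "contain_a"
    elif la - hit.q_end <= slack and s_start <= slack:
        kind = "suffix_prefix"
    elif hit.q_start <= slack and lb - s_end <= slack:
        kind = "prefix_suffix"
    else:
        return None
    return hit.score, kind, geometry, b_oriented


def _merge_columns(a: _Contig, b: _Contig, kind: str, geo: dict) -> List[dict]:
    qa, qe = geo["q_start"], geo["q_end"]
    sa, se = geo["s_start"], geo["s_end"]
    overlap_a = a.columns[qa:qe]
    overlap_b = b.columns[sa:se]
    if len(overlap_a) == len(overlap_b):
        merged = []
        for ca, cb in zip(overlap_a, overlap_b):
            col = dict(ca)
            for base, c in cb.items():
                col[base] = col.get(base, 0) + c
            merged.append(col)
    else:
        merged = overlap_a  # indel-divergent overlap: keep A's columns
    if kind == "contain_b":
        return a.columns[:qa] + merged + a.columns[qe:]
    if kind == "contain_a":
        return b.columns[:sa] + merged + b.columns[se:]
    if kind == "suffix_prefix":
        return a.columns[:qa] + merged + b.columns[se:]
    return b.columns[:sa] + merged + a.columns[qe:]


def toy_assemble(reads: SequenceSet, min_overlap: int = 300,
                 min_overlap_identity: float = 0.90,
                 params: Optional[AlignmentParams] = None) -> AssemblyResult:
    """Greedy overlap-layout-consensus assembly (test-fixture grade).

    Repeatedly merges the highest-scoring qualifying overlap (dovetail or
    containment, either orientation); consensus is per-column majority with
    lexicographic tie-break. Deterministic given input order: merge ties
    break on the lexicographically smallest contig id pair.
    """
    if len(reads) == 0:
        raise ValidationError("toy_assemble requires at least one read")
    params = params or AlignmentParams()
    contigs: Dict[str, _Contig] = {}
    for read in reads:
        contigs[read.id] = _Contig.from_read(read)

    def plan_key(item):
        score, ida, idb = item[0], item[1], item[2]
        return (-score, ida, idb)

    plans = []
    ids = list(contigs)
    for i, ida in enumerate(ids):
        for idb in ids[i + 1:]:
            plan = _merge_plan(contigs[ida], contigs[idb], params,
                               min_overlap, min_overlap_identity)
            if plan is not None:
                plans.append((plan[0], ida, idb, plan))
    while plans:
        plans.sort(key=plan_key)
        score, ida, idb, plan = plans[0]
        _, kind, geo, b_oriented = plan
        a = contigs.pop(ida)
        b = contigs.pop(idb)
        merged = _Contig(min(ida, idb), _merge_columns(a, b_oriented, kind, geo),
                         sorted(set(a.members) | set(b_oriented.members)))
        plans = [p for p in plans if p[1] not in (ida, idb) and p[2] not in (ida, idb)]
        for other_id, other in contigs.items():
            pa, pb = sorted((merged.id, other_id))
            ca, cb = (merged, other) if pa == merged.id else (other, merged)
            plan = _merge_plan(ca, cb, params, min_overlap, min_overlap_identity)
            if plan is not None:
                plans.append((plan[0], pa, pb, plan))
        contigs[merged.id] = merged

    ordered = sorted(contigs.values(), key=lambda c: (-len(c.columns), c.id))
    records = []
    members = {}
    for i, contig in enumerate(ordered, 1):
        cid = f"contig_{i:05d}"
        records.append(ReadRecord(cid, contig.consensus(), read_type="contig"))
        members[cid] = list(contig.members)
    return AssemblyResult(SequenceSet.from_records(records), members)


# ---------------------------------------------------------------------------
# recovery evaluation and the full triage flow


def evaluate_recovery(contigs: SequenceSet, withheld: SequenceSet,
                      criteria: Optional[AcceptanceCriteria] = None,
                      params: Optional[AlignmentParams] = None) -> TriageReport:
    """Score withheld genes against assembled contigs.

    A withheld gene is recovered iff some contig hits it under the
    acceptance criteria after same-subject deduplication.
    """
    criteria = criteria or AcceptanceCriteria()
    report = TriageReport(n_withheld=len(withheld))
    if len(contigs) == 0 or len(withheld) == 0:
        report.recovered = [
            {"gene_id": g.id, "recovered": False, "identity_pct": None, "aln_len": None}
            for g in withheld
        ]
        return report
    hits = best_hit_search(withheld, contigs, criteria, params)
    kept, _removed = dedupe_same_subject(hits)
    by_gene = {h.query_id: h for h in kept}
    for gene in withheld:
        hit = by_gene.get(gene.id)
        report.recovered.append({
            "gene_id": gene.id,
            "recovered": hit is not None,
            "identity_pct": round(hit.identity * 100, 2) if hit else None,
            "aln_len": hit.columns if hit else None,
        })
    report.n_recovered = sum(1 for r in report.recovered if r["recovered"])
    ids = [r["identity_pct"] for r in report.recovered if r["recovered"]]
    if ids:
        arr = np.asarray(ids, dtype=float)
        report.recovered_mean_identity = float(arr.mean())
        report.recovered_sd_identity = float(arr.std(ddof=1)) if arr.size > 1 else 0.0
    return report


def run_triage(reads: SequenceSet, reduced_reference: SequenceSet,
               config: Optional[TriageConfig] = None,
               withheld: Optional[SequenceSet] = None,
               params: Optional[AlignmentParams] = None
               ) -> Tuple[TriageReport, SequenceSet, Optional[AssemblyResult]]:
    """Full triage: map, threshold, select, assemble, score recovery.

    Returns (report, candidate reads, assembly result or None).
    """
    config = config or TriageConfig()
    hits = map_reads(reads, reduced_reference, params)
    mean, sd, threshold = identity_threshold([h.identity * 100 for h in hits],
                                             config.sd_multiplier)
    candidates, n_unmapped, n_below = select_candidates(reads, hits, threshold)
    report = TriageReport(
        mean_identity=mean, sd_identity=sd, threshold=threshold,
        n_unmapped=n_unmapped, n_below_threshold=n_below,
        n_candidates=len(candidates),
    )
    assembly = None
    if config.assembler == "toy" and len(candidates) > 0:
        assembly = toy_assemble(candidates, params=params)
        contigs = assembly.contigs
        if config.require_motifs:
            keep = [c.id for c in contigs
                    if classify_sequence(c, DEFAULT_MOTIFS).call != CALL_NONE]
            contigs = contigs.subset(keep)
            assembly = AssemblyResult(contigs,
                                      {k: assembly.members[k] for k in contigs.ids()})
    if withheld is not None:
        contig_set = assembly.contigs if assembly else SequenceSet()
        recovery = evaluate_recovery(contig_set, withheld,
                                     config.recovery_criteria, params)
        report.recovered = recovery.recovered
        report.n_withheld = recovery.n_withheld
        report.n_recovered = recovery.n_recovered
        report.recovered_mean_identity = recovery.recovered_mean_identity
        report.recovered_sd_identity = recovery.recovered_sd_identity
    return report, candidates, assembly
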