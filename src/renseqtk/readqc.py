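"""Read-set statistics: counts, yield, N50, mean/modal length and
alignment-derived accuracy.

Accuracy is computed from best-hit alignments against a reference (the
"general error rate" convention of mapping QC), never from quality strings.
Modal accuracy is binned at two decimal places (as a percentage) before
taking the mode; modal length is the unbinned most frequent exact length,
smallest on ties.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Dict, List, Optional, Tuple

import numpy as np

from .align import AlignmentHit, AlignmentParams, map_reads
from .errors import ValidationError
from .records import SequenceSet


@dataclass
class ReadStats:
    n_reads: int = 0
    total_bases: int = 0
    n50: int = 0
    mean_length: float = 0.0
    modal_length: int = 0
    mean_accuracy: Optional[float] = None
    modal_accuracy: Optional[float] = None
    mean_error_rate: Optional[float] = None
    mapped_fraction: Optional[float] = None


def length_stats(reads: SequenceSet) -> ReadStats:
    """Length-derived statistics of a read set.

    N50: length of the smallest read such that reads at least that long
    comprise >= 50% of all bases. Modal length: most frequent exact length,
    smallest on ties.
    """
    if len(reads) == 0:
        raise ValidationError("length_stats requires at least one read")
    lengths = np.array([len(r) for r in reads], dtype=np.int64)
    total = int(lengths.sum())
    desc = np.sort(lengths)[::-1]
    cum = np.cumsum(desc)
    n50 = int(desc[np.searchsorted(cum, total / 2)])
    counts = Counter(int(x) for x in lengths)
    modal = min(
        (length for length, c in counts.items() if c == max(counts.values()))
    )
    return ReadStats(
        n_reads=len(reads),
        total_bases=total,
        n50=n50,
        mean_length=float(lengths.mean()),
        modal_length=modal,
    )


def accuracy_stats(hits: List[AlignmentHit], total_reads: int) -> ReadStats:
    """Alignment-derived accuracy over mapped reads.

    Per-read accuracy is the identity of its best hit; the modal accuracy is
    the mode of accuracies rounded to two decimal places as a percentage
    (smallest on ties). Unmapped reads only enter ``mapped_fraction``.
    """
    if total_reads < len(hits):
        raise ValidationError(
            f"total_reads ({total_reads}) < number of hits ({len(hits)})"
        )
    stats = ReadStats(n_reads=total_reads)
    stats.mapped_fraction = len(hits) / total_reads if total_reads else 0.0
    if not hits:
        return stats
    accs = np.array([h.identity for h in hits])
    stats.mean_accuracy = float(accs.mean())
    stats.mean_error_rate = 1.0 - stats.mean_accuracy
    binned = Counter(round(a * 100, 2) for a in accs)
    top = max(binned.values())
    stats.modal_accuracy = min(v for v, c in binned.items() if c == top) / 100.0
    return stats


QC_COLUMNS = [
    "group", "n_reads", "total_bases", "n50", "mean_length", "modal_length",
    "mapped_pct", "mean_accuracy_pct", "modal_accuracy_pct", "mean_error_rate_pct",
]


def qc_table(groups: Dict[str, Tuple[SequenceSet, Optional[SequenceSet]]],
             params: Optional[AlignmentParams] = None) -> List[dict]:
    """One report row per named group of reads.

    Each group maps a name to ``(reads, reference-or-None)``; accuracy
    columns are filled only when a reference is supplied (fractions are kept
    as fractions; render with ``write_table(percent_fields=...)``).
    """
    if not groups:
        raise ValidationError("qc_table requires at least one group")
    rows = []
    for name, (reads, reference) in groups.items():
        ls = length_stats(reads)
        row = {
            "group": name,
            "n_reads": ls.n_reads,
            "total_bases": ls.total_bases,
            "n50": ls.n50,
            "mean_length": round(ls.mean_length, 2),
            "modal_length": ls.modal_length,
            "mapped_pct": None,
            "mean_accuracy_pct": None,
            "modal_accuracy_pct": None,
            "mean_error_rate_pct": None,
        }
        if reference is not None and len(reference) > 0:
            hits = map_reads(reads, reference, params)
            acc = accuracy_stats(hits, len(reads))
            row["mapped_pct"] = acc.mapped_fraction
            row["mean_accuracy_pct"] = acc.mean_accuracy
            row["modal_accuracy_pct"] = acc.modal_accuracy
            row["mean_error_rate_pct"] = acc.mean_error_rate
        rows.append(row)
    return rows
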