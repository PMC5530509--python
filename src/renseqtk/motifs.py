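"""NLR motif scanning and none/partial/complete classification.

A lightweight, configurable motif scanner over six-frame translations of
DNA (or directly over peptides). Motifs are short degenerate amino-acid
patterns ('x' is a wildcard) matched with a per-motif mismatch budget;
windows containing a stop codon ('*') never match, which is what makes the
classification sensitive to frameshifts: a single indel between motifs
moves the downstream motifs into a different frame, and the completeness
rule must be satisfied within one frame.

Completeness rule (default): within a single frame, at least one P-loop
anchor hit, at least one GLPL-class anchor hit starting after it, and at
least two LRR-category hits starting after both — the ordered NB-ARC → LRR
architecture of an intact NLR. Any NB-ARC or LRR hit anywhere gives a
partial call; otherwise the call is none.

The shipped default motifs are deliberately simple consensus placeholders
(editable via JSON/TOML config); they are not the motif models of any
published scanning tool.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, List, Optional, Sequence, Tuple, Union

import numpy as np
from Bio.Seq import Seq

from .errors import ValidationError
from .records import ReadRecord, SequenceSet, reverse_complement

CATEGORIES = ("pre_NB", "NB_ARC", "LRR")
ANCHORS = ("ploop", "glpl", None)
FRAMES = ("+1", "+2", "+3", "-1", "-2", "-3")


@dataclass(frozen=True)
class MotifDef:
    """A degenerate amino-acid motif pattern.

    ``pattern`` is over one-letter amino-acid codes plus ``x`` (wildcard);
    mismatches are counted at non-wildcard positions only. ``anchor`` marks
    the motifs the completeness rule is phrased in terms of.
    """

    id: str
    pattern: str
    max_mismatches: int = 1
    category: str = "NB_ARC"
    anchor: Optional[str] = None

    def __post_init__(self) -> None:
        if len(self.pattern) < 5:
            raise ValidationError(f"motif {self.id!r}: pattern must be >= 5 residues")
        if self.max_mismatches >= len(self.pattern):
            raise ValidationError(f"motif {self.id!r}: max_mismatches must be < pattern length")
        if self.category not in CATEGORIES:
            raise ValidationError(f"motif {self.id!r}: unknown category {self.category!r}")
        if self.anchor not in ANCHORS:
            raise ValidationError(f"motif {self.id!r}: unknown anchor {self.anchor!r}")


#: Default motif set: consensus-style placeholders for the ordered NB-ARC
#: core (P-loop, Kinase-2, GLPL) and the LRR repeat. The LRR pattern follows
#: the canonical plant extracellular-LRR consensus LxxLxxLxLxxN; leucine is
#: frequent in random translation (6 codons), so the pattern needs the
#: conserved Asn and a zero mismatch budget to stay quiet on random input.
DEFAULT_MOTIFS: Tuple[MotifDef, ...] = (
    MotifDef("ploop", "GGVGKTT", 1, "NB_ARC", anchor="ploop"),
    MotifDef("kinase2", "LLVLDDVW", 1, "NB_ARC"),
    MotifDef("glpl", "GLPLAL", 1, "NB_ARC", anchor="glpl"),
    MotifDef("lrr", "LxxLxxLxLxxN", 0, "LRR"),
)


def load_motifs(path) -> List[MotifDef]:
    """Load a motif set from a JSON or TOML config file.

    The file holds a list (JSON array, or TOML ``[[motif]]`` tables) of
    objects with keys id, pattern, max_mismatches, category, anchor.
    """
    path = Path(path)
    if path.suffix == ".toml":
        import tomllib

        with open(path, "rb") as fh:
            entries = tomllib.load(fh).get("motif", [])
    else:
        with open(path) as fh:
            entries = json.load(fh)
    motifs = [
        MotifDef(
            id=e["id"], pattern=e["pattern"],
            max_mismatches=int(e.get("max_mismatches", 1)),
            category=e.get("category", "NB_ARC"),
            anchor=e.get("anchor"),
        )
        for e in entries
    ]
    if not motifs:
        raise ValidationError(f"{path}: no motifs defined")
    return motifs


@dataclass(frozen=True)
class MotifHit:
    motif_id: str
    frame: str  # one of FRAMES, or "protein" for direct peptide input
    aa_start: int
    aa_end: int
    mismatches: int


CALL_NONE = "none"
CALL_PARTIAL = "partial"
CALL_COMPLETE = "complete"
_CALL_ORDER = {CALL_NONE: 0, CALL_PARTIAL: 1, CALL_COMPLETE: 2}


@dataclass
class NlrCall:
    call: str
    hits: List[MotifHit] = field(default_factory=list)
    frame_used: Optional[str] = None


def six_frame_translate(dna: str) -> List[str]:
    """Translate all six frames (standard code; codons with N give 'X').

    Frames are ordered +1, +2, +3, -1, -2, -3; frame -k is frame +k of the
    reverse complement.
    """
    if len(dna) < 3:
        raise ValidationError("six_frame_translate requires >= 3 bases")
    frames = []
    for strand_seq in (dna, reverse_complement(dna)):
        for off in range(3):
            sub = strand_seq[off:off + 3 * ((len(strand_seq) - off) // 3)]
            frames.append(str(Seq(sub).translate()))
    return frames


def scan_motifs(peptide: str, motifs: Sequence[MotifDef],
                frame: str = "protein") -> List[MotifHit]:
    """All windows of ``peptide`` matching any motif within its mismatch
    budget; windows containing '*' never match. Hits sorted by position."""
    if not motifs:
        raise ValidationError("scan_motifs requires at least one motif")
    hits: List[MotifHit] = []
    if not peptide:
        return hits
    arr = np.frombuffer(peptide.encode("ascii"), dtype=np.uint8)
    for motif in motifs:
        L = len(motif.pattern)
        if len(arr) < L:
            continue
        windows = np.lib.stride_tricks.sliding_window_view(arr, L)
        informative = np.array([c != "x" for c in motif.pattern])
        pat = np.frombuffer(motif.pattern.encode("ascii"), dtype=np.uint8)
        mism = (windows[:, informative] != pat[informative]).sum(axis=1)
        has_stop = (windows == ord("*")).any(axis=1)
        ok = np.nonzero((mism <= motif.max_mismatches) & ~has_stop)[0]
        for start in ok:
            hits.append(MotifHit(motif.id, frame, int(start), int(start) + L,
                                 int(mism[start])))
    hits.sort(key=lambda h: (h.aa_start, h.motif_id))
    return hits


def _frame_complete(hits: List[MotifHit], motifs: Sequence[MotifDef]) -> bool:
    by_id = {m.id: m for m in motifs}
    ploop_hits = [h for h in hits if by_id[h.motif_id].anchor == "ploop"
                  and by_id[h.motif_id].category in ("pre_NB", "NB_ARC")]
    glpl_hits = [h for h in hits if by_id[h.motif_id].anchor == "glpl"]
    lrr_starts = sorted(h.aa_start for h in hits
                        if by_id[h.motif_id].category == "LRR")
    for p in ploop_hits:
        for g in glpl_hits:
            if g.aa_start < p.aa_end:
                continue
            downstream = [s for s in lrr_starts if s >= g.aa_end]
            if len(downstream) >= 2:
                return True
    return False


def classify_sequence(seq: Union[ReadRecord, str],
                      motifs: Sequence[MotifDef] = DEFAULT_MOTIFS,
                      rule: str = "default") -> NlrCall:
    """Classify a DNA record (six frames) or a peptide string.

    complete: the ordered anchor rule holds within one frame; partial: any
    NB_ARC or LRR hit anywhere; none otherwise. For DNA, ``frame_used`` is
    the qualifying frame with the most hits (ties: lowest frame index).
    """
    if rule != "default":
        raise ValidationError(f"unknown classification rule {rule!r}")
    if isinstance(seq, ReadRecord):
        if len(seq) < 3:
            return NlrCall(CALL_NONE)
        peptides = six_frame_translate(seq.sequence)
        frame_hits = {f: scan_motifs(p, motifs, frame=f)
                      for f, p in zip(FRAMES, peptides)}
    else:
        frame_hits = {"protein": scan_motifs(seq, motifs, frame="protein")}
    by_id = {m.id: m for m in motifs}
    all_hits = [h for hits in frame_hits.values() for h in hits]
    complete_frames = [f for f, hits in frame_hits.items()
                       if _frame_complete(hits, motifs)]
    if complete_frames:
        frame_used = max(complete_frames,
                         key=lambda f: (len(frame_hits[f]), -_frame_index(f)))
        return NlrCall(CALL_COMPLETE, all_hits, frame_used)
    partial = any(by_id[h.motif_id].category in ("NB_ARC", "LRR") for h in all_hits)
    if partial:
        frame_used = max(frame_hits,
                         key=lambda f: (len(frame_hits[f]), -_frame_index(f)))
        return NlrCall(CALL_PARTIAL, all_hits, frame_used)
    return NlrCall(CALL_NONE, all_hits, None)


def _frame_index(frame: str) -> int:
    return FRAMES.index(frame) if frame in FRAMES else 0


ANNOTATE_COLUMNS = ["seq_id", "call", "frame_used", "n_hits"]

SUMMARY_COLUMNS = [
    "n_sequences", "n_none", "n_partial", "n_complete", "n_hits",
    "pct_hits_of_total", "pct_partial_of_hits", "pct_complete_of_hits",
]


def annotate_set(seqs: SequenceSet, motifs: Sequence[MotifDef] = DEFAULT_MOTIFS,
                 rule: str = "default") -> Tuple[dict, List[dict]]:
    """Classify every sequence; returns (summary row, per-sequence table).

    "Hits" are motif-positive sequences (partial + complete); the partial
    and complete percentages are fractions of the hits, the hit percentage
    a fraction of all sequences (fractions; render via percent_fields).
    """
    rows = []
    counts = {CALL_NONE: 0, CALL_PARTIAL: 0, CALL_COMPLETE: 0}
    for rec in seqs:
        call = classify_sequence(rec, motifs, rule)
        counts[call.call] += 1
        rows.append({
            "seq_id": rec.id,
            "call": call.call,
            "frame_used": call.frame_used,
            "n_hits": len(call.hits),
        })
    n_hits = counts[CALL_PARTIAL] + counts[CALL_COMPLETE]
    total = len(seqs)
    summary = {
        "n_sequences": total,
        "n_none": counts[CALL_NONE],
        "n_partial": counts[CALL_PARTIAL],
        "n_complete": counts[CALL_COMPLETE],
        "n_hits": n_hits,
        "pct_hits_of_total": (n_hits / total) if total else 0.0,
        "pct_partial_of_hits": (counts[CALL_PARTIAL] / n_hits) if n_hits else 0.0,
        "pct_complete_of_hits": (counts[CALL_COMPLETE] / n_hits) if n_hits else 0.0,
    }
    return summary, rows
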