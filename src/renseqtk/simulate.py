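"""Synthetic RenSeq data generator with ground-truth sidecars.

Emulates the statistical structure a targeted long-read NLR capture
pipeline has to cope with: families of highly similar paralogous genes,
each carrying an ordered, in-frame, stop-free NLR motif cassette
(P-loop → Kinase-2 → GLPL → LRR×3); tiled capture baits; reads with
platform-specific indel-rich error profiles; a fixed 65-bp amplification
adapter decorating both read ends; PCR chimeras joined by that adapter;
and an off-target read fraction. Every read carries a truth record.

Error presets: the nanopore-like 2D profile {sub 0.03, ins 0.02, del 0.04}
gives ~91% per-base accuracy with deletion-heavy indels; the pacbio-like
multi-pass consensus profile {0.002, 0.001, 0.001} gives ~99.6%.

All randomness flows from one seed through per-stage child streams, so the
reference, the read set and the novel-gene spike-in can be regenerated
independently and reproducibly (byte-identical outputs per seed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .errors import ValidationError
from .records import ReadRecord, SequenceSet, reverse_complement

_BASES = "ACGT"
_STOPS = {"TAA", "TAG", "TGA"}

#: Fixed 65-bp amplification adapter used to decorate simulated reads
#: (arbitrary sequence, the length of a typical Illumina adapter construct).
DEFAULT_ADAPTER = (
    "AATGATACGGCGACCACCGAGATCTACACTCTTTCCCTACACGACGCTCTTCCGATCTGTACG"
    "TC"
)

# one codon per amino acid is enough for reverse translation of motifs
_CODON = {
    "A": "GCT", "C": "TGT", "D": "GAT", "E": "GAA", "F": "TTT", "G": "GGT",
    "H": "CAT", "I": "ATT", "K": "AAA", "L": "CTG", "M": "ATG", "N": "AAT",
    "P": "CCT", "Q": "CAA", "R": "CGT", "S": "TCT", "T": "ACT", "V": "GTT",
    "W": "TGG", "Y": "TAT",
}
_AA = "ACDEFGHIKLMNPQRSTVWY"

#: The planted cassette, in architecture order. LRR 'x' positions are
#: randomised per gene; fixed positions match the default motif patterns.
CASSETTE = ("ploop", "kinase2", "glpl", "lrr", "lrr", "lrr")
_MOTIF_PEPTIDE = {
    "ploop": "GGVGKTT",
    "kinase2": "LLVLDDVW",
    "glpl": "GLPLAL",
}


@dataclass(frozen=True)
class ErrorProfile:
    sub_rate: float
    ins_rate: float
    del_rate: float
    name: str = "custom"

    def __post_init__(self) -> None:
        for r in (self.sub_rate, self.ins_rate, self.del_rate):
            if not (0 <= r < 0.3):
                raise ValidationError("each error rate must be in [0, 0.3)")
        if self.total_rate >= 0.5:
            raise ValidationError("total error rate must be < 0.5")

    @property
    def total_rate(self) -> float:
        return self.sub_rate + self.ins_rate + self.del_rate


NANOPORE_2D = ErrorProfile(0.03, 0.02, 0.04, "nanopore_2d")
PACBIO_ROI = ErrorProfile(0.002, 0.001, 0.001, "pacbio_roi")
ERROR_FREE = ErrorProfile(0.0, 0.0, 0.0, "error_free")


@dataclass
class SimConfig:
    """Study conditions for one synthetic dataset. ``seed`` is mandatory."""

    seed: int
    n_families: int = 8
    paralogs_per_family: int = 3
    paralog_divergence: float = 0.03
    gene_length_range: Tuple[int, int] = (2000, 4000)
    novel_genes: int = 0
    novel_divergence: float = 0.12
    novel_insert_len: int = 900
    read_length_mean_log: float = math.log(3000.0)
    read_length_sd_log: float = 0.35
    read_length_bounds: Tuple[int, int] = (200, 20000)
    coverage: float = 30.0
    error_profile: ErrorProfile = field(default_factory=lambda: NANOPORE_2D)
    adapter: str = DEFAULT_ADAPTER
    chimera_rate: float = 0.02
    off_target_fraction: float = 0.20
    platform: str = "nanopore"

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValidationError("SimConfig requires an explicit seed")
        if min(self.n_families, self.paralogs_per_family) < 1 or self.novel_genes < 0:
            raise ValidationError("counts must be >= 1 (novel_genes >= 0)")
        for frac in (self.paralog_divergence, self.novel_divergence,
                     self.chimera_rate, self.off_target_fraction):
            if not (0 <= frac < 1):
                raise ValidationError("fractions must be in [0, 1)")
        if len(self.adapter) != 65:
            raise ValidationError("adapter must be 65 bp")
        if self.coverage <= 0:
            raise ValidationError("coverage must be > 0")


@dataclass
class TruthRecord:
    read_id: str
    source_gene: str  # gene id or "off_target"
    gene_start: int
    gene_end: int
    strand: str
    is_chimera: bool
    second_source: Optional[str]
    n_sub: int
    n_ins: int
    n_del: int
    has_adapters: bool = True


TRUTH_COLUMNS = ["read_id", "source_gene", "gene_start", "gene_end", "strand",
                 "is_chimera", "second_source", "n_sub", "n_ins", "n_del",
                 "has_adapters"]

ANNOTATION_COLUMNS = ["gene_id", "family", "kind", "divergence", "motifs"]


def _stage_rng(seed: int, stage: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed).spawn(4)[stage])


def _random_dna(rng, n: int) -> str:
    return "".join(_BASES[i] for i in rng.integers(0, 4, n))


def _random_nonstop_codons(rng, n: int) -> List[str]:
    out = []
    while len(out) < n:
        codon = _BASES[rng.integers(0, 4)] + _BASES[rng.integers(0, 4)] + _BASES[rng.integers(0, 4)]
        if codon not in _STOPS:
            out.append(codon)
    return out


def _motif_dna(rng, motif: str) -> str:
    if motif in _MOTIF_PEPTIDE:
        pep = _MOTIF_PEPTIDE[motif]
    else:  # lrr: LxxLxxLxLxxN with random x residues
        pep = "".join(c if c in "LN" else _AA[rng.integers(0, len(_AA))]
                      for c in "LxxLxxLxLxxN")
    return "".join(_CODON[aa] for aa in pep)


def _build_ancestor(rng, length: int) -> Tuple[str, List[Tuple[str, int, int]]]:
    """One stop-free (frame +1) gene with the cassette planted in order.

    Returns (dna, [(motif, bp_start, bp_end), ...]).
    """
    n_codons = length // 3
    motif_dna = [_motif_dna(rng, m) for m in CASSETTE]
    motif_codons = [len(d) // 3 for d in motif_dna]
    lead, tail, min_gap = 5, 3, 8
    slack = n_codons - sum(motif_codons) - lead - tail - min_gap * len(CASSETTE)
    if slack < 0:
        raise ValidationError(f"gene length {length} too short for the motif cassette")
    extra = rng.multinomial(slack, np.full(len(CASSETTE), 1 / len(CASSETTE)))
    codons = _random_nonstop_codons(rng, n_codons)
    coords = []
    pos = lead
    for motif, dna, n_mc, ex in zip(CASSETTE, motif_dna, motif_codons, extra):
        pos += min_gap + int(ex)
        for k in range(n_mc):
            codons[pos + k] = dna[3 * k:3 * k + 3]
        coords.append((motif, 3 * pos, 3 * (pos + n_mc)))
        pos += n_mc
    return "".join(codons), coords


def _mutate(rng, seq: str, divergence: float,
            protected: Sequence[Tuple[int, int]]) -> str:
    """Substitute each unprotected position with probability ``divergence``."""
    if divergence == 0:
        return seq
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()
    mask = rng.random(arr.shape[0]) < divergence
    for start, end in protected:
        mask[start:end] = False
    idx = np.nonzero(mask)[0]
    code = np.zeros(arr.shape[0], dtype=np.int64)
    for i, b in enumerate(_BASES):
        code[arr == ord(b)] = i
    new = (code[idx] + rng.integers(1, 4, idx.shape[0])) % 4
    for j, i in enumerate(idx):
        arr[i] = ord(_BASES[new[j]])
    return arr.tobytes().decode("ascii")


def _motif_string(coords) -> str:
    return ";".join(f"{m}:{s}-{e}" for m, s, e in coords)


def simulate_reference(config: SimConfig) -> Tuple[SequenceSet, List[dict]]:
    """Paralog families of NLR-like genes plus an annotation table.

    Each family is one random ancestor with the planted cassette; paralogs
    are independent per-base substitution mutants of the ancestor at half of
    ``paralog_divergence`` (so the expected *pairwise* divergence between
    family members is ``paralog_divergence``), with motif spans protected —
    every generated gene keeps a complete cassette.
    """
    rng = _stage_rng(config.seed, 0)
    records = []
    annotations = []
    lo, hi = config.gene_length_range
    for f in range(1, config.n_families + 1):
        length = int(rng.integers(lo, hi + 1)) // 3 * 3
        ancestor, coords = _build_ancestor(rng, length)
        protected = [(s, e) for _m, s, e in coords]
        for p in range(1, config.paralogs_per_family + 1):
            gene_id = f"fam{f:02d}_g{p:02d}"
            seq = _mutate(rng, ancestor, config.paralog_divergence / 2, protected)
            records.append(ReadRecord(gene_id, seq))
            annotations.append({
                "gene_id": gene_id, "family": f"fam{f:02d}", "kind": "known",
                "divergence": config.paralog_divergence,
                "motifs": _motif_string(coords),
            })
    return SequenceSet.from_records(records), annotations


def spike_novel(genes: SequenceSet, n: int, divergence: float, seed: int,
                annotations: Optional[List[dict]] = None,
                insert_len: int = 900) -> Tuple[SequenceSet, List[str]]:
    """Add ``n`` novel genes derived from random existing genes.

    Novelty is modelled the way novel NLRs typically arise: each novel gene
    is a fusion-domain variant — its backbone diverges from the source at
    ``divergence`` per base (motif cassette protected; coordinates taken
    from ``annotations``) and an in-frame, stop-free integrated domain of
    ``insert_len`` bp of novel sequence is inserted downstream of the
    cassette. The integrated domain has no counterpart in the reference, so
    reads covering it cannot map. Returns (augmented set, withheld ids).
    """
    if n < 1:
        raise ValidationError("spike_novel requires n >= 1")
    if insert_len % 3:
        insert_len += 3 - insert_len % 3
    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(4)[2])
    coords_by_gene: Dict[str, List[Tuple[int, int]]] = {}
    motif_str: Dict[str, str] = {}
    if annotations:
        for row in annotations:
            spans = []
            for item in row["motifs"].split(";"):
                _m, se = item.split(":")
                s, e = se.split("-")
                spans.append((int(s), int(e)))
            coords_by_gene[row["gene_id"]] = spans
            motif_str[row["gene_id"]] = row["motifs"]
    augmented = SequenceSet.from_records(list(genes.records), genes.source_path)
    withheld = []
    source_ids = genes.ids()
    for i in range(1, n + 1):
        src_id = source_ids[int(rng.integers(0, len(source_ids)))]
        src = genes[src_id]
        spans = coords_by_gene.get(src_id, [])
        seq = _mutate(rng, src.sequence, divergence, spans)
        if insert_len:
            cassette_end = max((e for _s, e in spans), default=2 * len(seq) // 3)
            pos = min(len(seq) - 3, cassette_end + 30)
            pos -= pos % 3  # keep the insertion in frame
            domain = "".join(_random_nonstop_codons(rng, insert_len // 3))
            seq = seq[:pos] + domain + seq[pos:]
        novel_id = f"novel{i:02d}"
        augmented.add(ReadRecord(novel_id, seq))
        withheld.append(novel_id)
    return augmented, withheld


def design_baits(genes: SequenceSet, bait_length: int = 120,
                 step: int = 60) -> SequenceSet:
    """Tiled capture baits over every gene; final window right-anchored."""
    if len(genes) == 0:
        raise ValidationError("design_baits requires at least one gene")
    min_len = min(len(g) for g in genes)
    if bait_length > min_len:
        raise ValidationError(
            f"bait_length {bait_length} exceeds shortest gene ({min_len} bp)"
        )
    records = []
    for gene in genes:
        starts = list(range(0, len(gene) - bait_length + 1, step))
        if starts[-1] != len(gene) - bait_length:
            starts.append(len(gene) - bait_length)
        for i, s in enumerate(starts, 1):
            records.append(
                ReadRecord(f"{gene.id}_bait{i:03d}", gene.sequence[s:s + bait_length])
            )
    return SequenceSet.from_records(records)


def _apply_errors(rng, seq: str, profile: ErrorProfile) -> Tuple[str, int, int, int]:
    """Per-base substitution/insertion/deletion process; returns
    (mutated sequence, n_sub, n_ins, n_del)."""
    if profile.total_rate == 0:
        return seq, 0, 0, 0
    L = len(seq)
    u = rng.random(L)
    del_mask = u < profile.del_rate
    sub_mask = (~del_mask) & (u < profile.del_rate + profile.sub_rate)
    ins_mask = rng.random(L) < profile.ins_rate
    sub_shift = rng.integers(1, 4, L)
    ins_base = rng.integers(0, 4, L)
    code = {b: i for i, b in enumerate(_BASES)}
    out = []
    for i, base in enumerate(seq):
        if not del_mask[i]:
            if sub_mask[i] and base in code:
                out.append(_BASES[(code[base] + sub_shift[i]) % 4])
            else:
                out.append(base)
        if ins_mask[i]:
            out.append(_BASES[ins_base[i]])
    return ("".join(out), int(sub_mask.sum()), int(ins_mask.sum()),
            int(del_mask.sum()))


def _quality_char(profile: ErrorProfile) -> str:
    q = 41 if profile.total_rate == 0 else round(-10 * math.log10(profile.total_rate))
    return chr(33 + max(2, min(41, q)))


def _draw_length(rng, config: SimConfig) -> int:
    lo, hi = config.read_length_bounds
    val = rng.lognormal(config.read_length_mean_log, config.read_length_sd_log)
    return int(min(max(val, lo), hi))


def simulate_reads(genes: SequenceSet, config: SimConfig
                   ) -> Tuple[SequenceSet, List[TruthRecord]]:
    """Simulate an adapter-decorated FASTQ read set with truth records.

    Fragments are sampled uniformly from the genes (position uniform, gene
    chosen proportional to length) or, with ``off_target_fraction``
    probability, from random off-target sequence. With ``chimera_rate``
    probability two fragments are joined by the adapter. Every read is
    decorated with the adapter on both ends, then passed through the
    per-base error process; qualities encode the profile's average error.
    Reads are drawn until the on-target fragment bases reach
    coverage x total gene length. Deterministic given the seed.
    """
    if len(genes) == 0:
        raise ValidationError("simulate_reads requires at least one gene")
    rng = _stage_rng(config.seed, 1)
    lengths = np.array([len(g) for g in genes], dtype=float)
    weights = lengths / lengths.sum()
    total_bases = int(lengths.sum())
    budget = config.coverage * total_bases
    qchar = _quality_char(config.error_profile)
    reads = []
    truth = []
    on_target_bases = 0
    i = 0
    while on_target_bases < budget:
        i += 1
        frag, meta = _draw_fragment(rng, genes, weights, config)
        if meta[0] != "off_target":
            on_target_bases += len(frag)
        is_chimera = rng.random() < config.chimera_rate
        second_source = None
        if is_chimera:
            frag2, meta2 = _draw_fragment(rng, genes, weights, config)
            if meta2[0] != "off_target":
                on_target_bases += len(frag2)
            second_source = meta2[0]
            frag = frag + config.adapter + frag2
        decorated = config.adapter + frag + config.adapter
        seq, n_sub, n_ins, n_del = _apply_errors(rng, decorated, config.error_profile)
        read_id = f"read{i:06d}"
        reads.append(ReadRecord(read_id, seq, quality=qchar * len(seq),
                                platform=config.platform))
        truth.append(TruthRecord(
            read_id=read_id, source_gene=meta[0], gene_start=meta[1],
            gene_end=meta[2], strand=meta[3], is_chimera=is_chimera,
            second_source=second_source, n_sub=n_sub, n_ins=n_ins, n_del=n_del,
        ))
    return SequenceSet.from_records(reads), truth


def _draw_fragment(rng, genes: SequenceSet, weights, config: SimConfig):
    """One fragment: (sequence, (source, start, end, strand))."""
    frag_len = _draw_length(rng, config)
    if rng.random() < config.off_target_fraction:
        seq = _random_dna(rng, frag_len)
        return seq, ("off_target", -1, -1, "+")
    gi = int(rng.choice(len(genes), p=weights))
    gene = genes.records[gi]
    frag_len = min(frag_len, len(gene))
    start = int(rng.integers(0, len(gene) - frag_len + 1))
    seq = gene.sequence[start:start + frag_len]
    strand = "+" if rng.random() < 0.5 else "-"
    if strand == "-":
        seq = reverse_complement(seq)
    return seq, (gene.id, start, start + frag_len, strand)


def truth_rows(truth: List[TruthRecord]) -> List[dict]:
    """Truth records as writeable table rows."""
    return [{
        "read_id": t.read_id, "source_gene": t.source_gene,
        "gene_start": t.gene_start, "gene_end": t.gene_end, "strand": t.strand,
        "is_chimera": t.is_chimera, "second_source": t.second_source or "",
        "n_sub": t.n_sub, "n_ins": t.n_ins, "n_del": t.n_del,
        "has_adapters": t.has_adapters,
    } for t in truth]


@dataclass
class SimulatedDataset:
    genes: SequenceSet          # all genes present in the sample
    annotations: List[dict]
    baits: SequenceSet
    reads: SequenceSet
    truth: List[TruthRecord]
    withheld_ids: List[str]     # novel genes absent from the triage reference

    @property
    def reference(self) -> SequenceSet:
        """The known-gene reference (sample genes minus withheld)."""
        withheld = set(self.withheld_ids)
        return SequenceSet.from_records(
            [g for g in self.genes if g.id not in withheld])


def simulate_dataset(config: SimConfig) -> SimulatedDataset:
    """Reference + baits + reads + truth in one call (one seed)."""
    genes, annotations = simulate_reference(config)
    withheld: List[str] = []
    if config.novel_genes:
        genes, withheld = spike_novel(genes, config.novel_genes,
                                      config.novel_divergence, config.seed,
                                      annotations,
                                      insert_len=config.novel_insert_len)
        for wid in withheld:
            annotations.append({
                "gene_id": wid, "family": "novel", "kind": "novel",
                "divergence": config.novel_divergence, "motifs": "",
            })
    known = SequenceSet.from_records(
        [g for g in genes if g.id not in set(withheld)])
    baits = design_baits(known)
    reads, truth = simulate_reads(genes, config)
    return SimulatedDataset(genes, annotations, baits, reads, truth, withheld)
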