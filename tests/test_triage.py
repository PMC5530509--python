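"""Novel-gene triage: reference reduction, empirical threshold, candidate
selection, the toy assembler, and recovery scoring."""

import math

import numpy as np
import pytest

from renseqtk.align import AlignmentHit, local_align, map_reads
from renseqtk.assembly import AcceptanceCriteria
from renseqtk.errors import ValidationError
from renseqtk.records import ReadRecord, SequenceSet, reverse_complement
from renseqtk.simulate import (ERROR_FREE, ErrorProfile, SimConfig,
                               simulate_dataset)
from renseqtk.triage import (evaluate_recovery, identity_threshold,
                             reduce_reference, select_candidates, toy_assemble)

from conftest import make_set, random_dna


def id_set(n, prefix="gene"):
    return SequenceSet.from_records(
        [ReadRecord(f"{prefix}{i:03d}", "ACGTACGTACGT") for i in range(n)])


def test_reduce_reference_counts():
    reference = id_set(649)
    excluded = [f"gene{i:03d}" for i in range(37)]
    reduced = reduce_reference(reference, excluded)
    assert len(reduced) == 612
    assert reduced.ids() == [f"gene{i:03d}" for i in range(37, 649)]


def test_reduce_reference_empty_exclusion_is_identity():
    reference = id_set(5)
    assert reduce_reference(reference, []).ids() == reference.ids()


def test_reduce_reference_rejects_duplicates_and_unknown():
    reference = id_set(5)
    with pytest.raises(ValidationError, match="duplicate"):
        reduce_reference(reference, ["gene001", "gene001"])
    with pytest.raises(ValidationError, match="nope"):
        reduce_reference(reference, ["nope"])


def test_identity_threshold_worked_example():
    mean, sd, thr = identity_threshold([90, 92, 94], 2.0)
    assert (mean, sd, thr) == (92.0, 2.0, 88.0)
    mean, sd, thr = identity_threshold([95.0, 95.0, 95.0])
    assert sd == 0.0 and thr == mean == 95.0
    with pytest.raises(ValidationError):
        identity_threshold([90.0])


def test_identity_threshold_monte_carlo():
    rng = np.random.default_rng(77)
    draws = rng.normal(95.0, 1.5, 10_000)
    _mean, _sd, thr = identity_threshold(draws, 2.0)
    assert thr == pytest.approx(92.0, abs=0.1)


def _best_hit(read_id, identity):
    columns = 1000
    matches = int(round(identity * columns))
    return AlignmentHit(read_id, "ref", 0, columns, 0, columns, "+", 1,
                        matches, columns - matches, 0, 0)


def test_select_candidates_counts_and_order(rng):
    reads = make_set([random_dna(rng, 50) for _ in range(4)], "r")
    hits = [_best_hit("r1", 0.95), _best_hit("r2", 0.94), _best_hit("r3", 0.70)]
    candidates, n_unmapped, n_below = select_candidates(reads, hits, 88.0)
    assert candidates.ids() == ["r3", "r4"]  # r4 never mapped
    assert (n_unmapped, n_below) == (1, 1)
    assert len(candidates) == n_unmapped + n_below


def test_select_candidates_monotone_in_multiplier(rng):
    reads = make_set([random_dna(rng, 50) for _ in range(30)], "r")
    identities = np.clip(np.random.default_rng(3).normal(0.95, 0.03, 28), 0.5, 1.0)
    hits = [_best_hit(f"r{i+1}", identities[i]) for i in range(28)]
    ids = [h.identity * 100 for h in hits]
    small = select_candidates(reads, hits, identity_threshold(ids, 1.0)[2])[0]
    large = select_candidates(reads, hits, identity_threshold(ids, 3.0)[2])[0]
    assert set(large.ids()) <= set(small.ids())


# ---------------------------------------------------------------------------
# toy assembler


def test_two_overlapping_reads_merge(rng):
    genome = random_dna(rng, 2500)
    reads = make_set([genome[:1500], genome[1000:2500]], "read")
    result = toy_assemble(reads)
    assert len(result.contigs) == 1
    contig = result.contigs.records[0]
    assert contig.sequence == genome
    assert sorted(result.members[contig.id]) == ["read1", "read2"]


def test_disjoint_reads_stay_separate(rng):
    reads = make_set([random_dna(rng, 800), random_dna(rng, 800)], "read")
    result = toy_assemble(reads)
    assert len(result.contigs) == 2


def test_reverse_complement_overlap_merges(rng):
    genome = random_dna(rng, 2000)
    reads = make_set([genome[:1200], reverse_complement(genome[800:2000])], "read")
    result = toy_assemble(reads)
    assert len(result.contigs) == 1
    consensus = result.contigs.records[0].sequence
    assert consensus in (genome, reverse_complement(genome))


def test_tiling_reads_reassemble_gene(rng):
    gene = random_dna(rng, 5000)
    starts = list(range(0, 3500, 300)) + [3500]  # right-anchored final tile
    reads = make_set([gene[s:s + 1500] for s in starts], "tile")
    result = toy_assemble(reads)
    assert len(result.contigs) == 1
    contig = result.contigs.records[0].sequence
    hit = local_align(contig, gene)
    assert hit.identity >= 0.999
    assert hit.columns >= 4990


def test_containment_read_absorbed(rng):
    genome = random_dna(rng, 2000)
    reads = make_set([genome, genome[500:1200]], "read")
    result = toy_assemble(reads)
    assert len(result.contigs) == 1
    assert result.contigs.records[0].sequence == genome


# ---------------------------------------------------------------------------
# recovery


def test_recovery_exact_copies(small_genes):
    genes, _ = small_genes
    withheld = genes.subset([genes.records[0].id, genes.records[2].id])
    contigs = SequenceSet.from_records(
        [ReadRecord(f"ctg{i}", g.sequence) for i, g in enumerate(withheld)])
    report = evaluate_recovery(contigs, withheld)
    assert report.n_recovered == 2
    assert report.recovered_mean_identity == pytest.approx(100.0)
    assert report.recovered_sd_identity == pytest.approx(0.0)


def test_recovery_without_contigs_is_zero(small_genes):
    genes, _ = small_genes
    withheld = genes.subset([genes.records[0].id])
    report = evaluate_recovery(SequenceSet(), withheld)
    assert report.n_recovered == 0
    assert report.recovered[0]["recovered"] is False


def test_candidate_selection_truth_low_novel_fraction():
    """Known-gene reads at ~3% error stay above the mean - 2*SD threshold;
    novel fusion-domain reads are selected via unmapped/low-identity routes."""
    cfg = SimConfig(seed=31, n_families=10, paralogs_per_family=2,
                    paralog_divergence=0.03, gene_length_range=(1600, 2200),
                    novel_genes=2, novel_divergence=0.08,
                    error_profile=ErrorProfile(0.015, 0.005, 0.01, "mild"),
                    chimera_rate=0.0, off_target_fraction=0.0, coverage=10.0,
                    read_length_mean_log=math.log(900),
                    read_length_sd_log=0.3, read_length_bounds=(400, 1600))
    ds = simulate_dataset(cfg)
    hits = map_reads(ds.reads, ds.reference)
    _m, _s, thr = identity_threshold([h.identity * 100 for h in hits], 2.0)
    candidates, _nu, _nb = select_candidates(ds.reads, hits, thr)
    source = {t.read_id: t.source_gene for t in ds.truth}
    known_ids = [r for r in ds.reads.ids() if not source[r].startswith("novel")]
    selected = set(candidates.ids())
    known_selected = sum(1 for r in known_ids if r in selected)
    assert known_selected <= 0.10 * len(known_ids)
    # every selected read should be attributable to a novel gene
    novel_selected = sum(1 for r in selected if source[r].startswith("novel"))
    assert novel_selected >= 0.9 * len(selected)
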