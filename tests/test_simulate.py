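"""Generator truth properties: determinism, planted divergence, motif
completeness, error-rate tallies, chimera counts and bait tiling."""

import numpy as np
import pytest

from renseqtk.align import local_align
from renseqtk.errors import ValidationError
from renseqtk.io import write_sequences
from renseqtk.motifs import CALL_COMPLETE, classify_sequence
from renseqtk.records import ReadRecord, SequenceSet
from renseqtk.simulate import (DEFAULT_ADAPTER, ERROR_FREE, NANOPORE_2D,
                               SimConfig, design_baits, simulate_dataset,
                               simulate_reads, simulate_reference, spike_novel)

from conftest import make_set


def test_byte_identical_under_fixed_seed(tmp_path):
    cfg = SimConfig(seed=42, n_families=2, paralogs_per_family=2, coverage=2.0,
                    gene_length_range=(1500, 1800), chimera_rate=0.05)
    paths = []
    for name in ("a", "b"):
        ds = simulate_dataset(cfg)
        fq = tmp_path / f"{name}.fastq"
        fa = tmp_path / f"{name}.fasta"
        write_sequences(ds.reads, fq, format="fastq")
        write_sequences(ds.genes, fa)
        paths.append((fq.read_bytes(), fa.read_bytes()))
    assert paths[0] == paths[1]


def test_zero_divergence_gives_identical_paralogs():
    cfg = SimConfig(seed=9, n_families=2, paralogs_per_family=3,
                    paralog_divergence=0.0, gene_length_range=(1500, 1800))
    genes, _ = simulate_reference(cfg)
    fam1 = [g.sequence for g in genes.records[:3]]
    assert fam1[0] == fam1[1] == fam1[2]


def test_pairwise_paralog_identity_matches_divergence():
    cfg = SimConfig(seed=10, n_families=6, paralogs_per_family=2,
                    paralog_divergence=0.05, gene_length_range=(2800, 3200))
    genes, _ = simulate_reference(cfg)
    identities = []
    for i in range(0, len(genes), 2):
        a, b = genes.records[i], genes.records[i + 1]
        identities.append(local_align(a.sequence, b.sequence).identity)
    assert np.mean(identities) == pytest.approx(0.95, abs=0.01)


def test_every_generated_gene_is_complete(small_genes):
    genes, _ = small_genes
    assert all(classify_sequence(g).call == CALL_COMPLETE for g in genes)


def test_error_free_reads_are_exact_decorated_substrings(small_genes):
    genes, _ = small_genes
    cfg = SimConfig(seed=12, coverage=1.0, error_profile=ERROR_FREE,
                    chimera_rate=0.0, off_target_fraction=0.0)
    reads, truth = simulate_reads(genes, cfg)
    for read, t in zip(reads.records[:10], truth[:10]):
        core = read.sequence[65:-65]
        gene = genes[t.source_gene].sequence
        expected = gene[t.gene_start:t.gene_end]
        if t.strand == "-":
            from renseqtk.records import reverse_complement
            expected = reverse_complement(expected)
        assert core == expected
        assert read.sequence.startswith(DEFAULT_ADAPTER)
        assert read.sequence.endswith(DEFAULT_ADAPTER)


def test_planted_error_rates_and_indel_ratio(small_genes):
    genes, _ = small_genes
    cfg = SimConfig(seed=13, coverage=12.0, error_profile=NANOPORE_2D,
                    chimera_rate=0.0, off_target_fraction=0.0)
    reads, truth = simulate_reads(genes, cfg)
    bases = sum(len(r) for r in reads) + sum(t.n_del for t in truth) \
        - sum(t.n_ins for t in truth)  # original (pre-error) base count
    n_sub = sum(t.n_sub for t in truth)
    n_ins = sum(t.n_ins for t in truth)
    n_del = sum(t.n_del for t in truth)
    assert (n_sub + n_ins + n_del) / bases == pytest.approx(0.09, abs=0.01)
    assert n_ins / n_del == pytest.approx(0.5, rel=0.2)


def test_chimera_count_within_binomial_ci(small_genes):
    genes, _ = small_genes
    cfg = SimConfig(seed=14, coverage=10.0, chimera_rate=0.10,
                    error_profile=ERROR_FREE, off_target_fraction=0.0)
    reads, truth = simulate_reads(genes, cfg)
    n = len(truth)
    observed = sum(t.is_chimera for t in truth)
    half = 2.576 * np.sqrt(0.1 * 0.9 / n)
    assert abs(observed / n - 0.10) <= half


def test_bait_tiling_counts_and_coverage(rng):
    gene = make_set(["A" * 600], "g")
    baits = design_baits(gene, bait_length=120, step=60)
    assert len(baits) == 9
    nonoverlap = design_baits(gene, bait_length=120, step=120)
    starts = [0, 120, 240, 360, 480]
    assert len(nonoverlap) == len(starts)
    # every base covered when step <= bait_length
    covered = np.zeros(600, dtype=bool)
    for i, s in enumerate(range(0, 481, 60)):
        covered[s:s + 120] = True
    assert covered.all()


def test_bait_longer_than_shortest_gene_rejected():
    with pytest.raises(ValidationError):
        design_baits(make_set(["A" * 100], "g"), bait_length=120)


def test_spike_novel_complete_divergent_and_deterministic(small_genes):
    genes, annotations = small_genes
    aug1, withheld1 = spike_novel(genes, 2, 0.12, seed=55,
                                  annotations=annotations)
    aug2, withheld2 = spike_novel(genes, 2, 0.12, seed=55,
                                  annotations=annotations)
    assert withheld1 == withheld2
    assert [aug1[w].sequence for w in withheld1] == \
        [aug2[w].sequence for w in withheld2]
    for wid in withheld1:
        novel = aug1[wid]
        assert classify_sequence(novel).call == CALL_COMPLETE
        # gene-scale alignments only: short perfect matches of the shared
        # motif DNA are not evidence of relatedness
        best = max((h.identity for h in
                    (local_align(novel.sequence, g.sequence) for g in genes)
                    if h is not None and h.columns >= 500), default=0.0)
        assert best <= 0.90
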