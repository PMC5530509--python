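"""Assembly evaluation: best-hit acceptance, same-subject deduplication,
summary statistics and match-segment export."""

import numpy as np
import pytest

from renseqtk.align import AlignmentHit
from renseqtk.assembly import (AcceptanceCriteria, best_hit_search,
                               dedupe_same_subject, dotplot_export,
                               mapping_summary, summarize_hits)
from renseqtk.errors import ValidationError
from renseqtk.records import ReadRecord, SequenceSet

from conftest import make_set, random_dna


def hit(query, subject, s_start, s_end, score, identity=0.99):
    columns = s_end - s_start
    matches = int(round(identity * columns))
    return AlignmentHit(query, subject, 0, columns, s_start, s_end, "+",
                        score, matches, columns - matches, 0, 0)


def test_exact_copy_contig_accepted(small_genes):
    genes, _ = small_genes
    contigs = SequenceSet.from_records(
        [ReadRecord("ctg1", genes.records[0].sequence)])
    hits = best_hit_search(genes.subset([genes.records[0].id]), contigs)
    assert len(hits) == 1
    assert hits[0].identity == 1.0


def test_short_coverage_rejected_by_length_criterion(small_genes):
    genes, _ = small_genes
    gene = genes.records[0]
    contigs = SequenceSet.from_records(
        [ReadRecord("ctg1", gene.sequence[:400])])
    assert best_hit_search(genes.subset([gene.id]), contigs) == []


def test_eight_of_ten_genes_assembled(small_genes, rng):
    genes, _ = small_genes
    queries = genes  # 6 genes
    contigs = SequenceSet.from_records(
        [ReadRecord(f"ctg{i}", g.sequence) for i, g in enumerate(genes.records[:4])]
        + [ReadRecord("junk", random_dna(rng, 2000))])
    hits = best_hit_search(queries, contigs)
    assert len(hits) == 4
    assert all(h.identity == 1.0 for h in hits)


def test_dedupe_same_span_keeps_higher_score():
    a = hit("geneA", "ctg", 100, 1100, score=2000)
    b = hit("geneB", "ctg", 150, 1150, score=1500)
    kept, removed = dedupe_same_subject([a, b])
    assert [h.query_id for h in kept] == ["geneA"]
    assert [h.query_id for h in removed] == ["geneB"]


def test_dedupe_disjoint_spans_both_kept():
    a = hit("geneA", "ctg", 0, 1000, score=2000)
    b = hit("geneB", "ctg", 1500, 2500, score=1500)
    kept, removed = dedupe_same_subject([a, b])
    assert len(kept) == 2 and removed == []


def test_dedupe_chain_of_three_leaves_one():
    a = hit("geneA", "ctg", 0, 1000, score=1800)
    b = hit("geneB", "ctg", 400, 1400, score=2000)
    c = hit("geneC", "ctg", 800, 1800, score=1600)
    kept, removed = dedupe_same_subject([a, b, c])
    assert [h.query_id for h in kept] == ["geneB"]
    assert len(removed) == 2


def test_dedupe_different_subjects_untouched():
    a = hit("geneA", "ctg1", 0, 1000, score=1800)
    b = hit("geneB", "ctg2", 0, 1000, score=1800)
    kept, _ = dedupe_same_subject([a, b])
    assert len(kept) == 2


def test_summary_sample_sd_worked_example():
    hits = [hit("g1", "c1", 0, 100, 10, identity=0.90),
            hit("g2", "c2", 0, 100, 10, identity=0.92),
            hit("g3", "c3", 0, 100, 10, identity=0.94)]
    summary = summarize_hits(hits, 10)
    assert summary.mean_identity == pytest.approx(92.0)
    assert summary.sd_identity == pytest.approx(2.0)
    assert summary.coverage_pct == 30.0


def test_more_hits_than_reference_rejected():
    with pytest.raises(ValidationError):
        summarize_hits([hit("g", "c", 0, 100, 10)], 0)


def test_self_evaluation_identity_case(small_genes):
    genes, _ = small_genes
    hits = best_hit_search(genes, genes)
    kept, _ = dedupe_same_subject(hits)
    summary = summarize_hits(kept, len(genes), {g.id: len(g) for g in genes})
    assert summary.coverage_pct == 100.0
    assert summary.mean_identity == pytest.approx(100.0)
    assert summary.sd_identity == pytest.approx(0.0)
    assert summary.mean_query_len_pct == pytest.approx(100.0)


def test_mapping_summary_error_free_and_unmappable(small_genes, rng):
    genes, _ = small_genes
    tiles = []
    for g in genes:
        for s in range(0, len(g) - 800, 400):
            tiles.append(g.sequence[s:s + 800])
    reads = make_set(tiles, "tile")
    row = mapping_summary(reads, genes)
    assert row["mapped_pct"] == 1.0
    assert row["general_error_rate_pct"] == pytest.approx(0.0)
    assert row["mean_coverage"] > 0

    junk = make_set(["AC" * 150] * 3, "junk")
    row = mapping_summary(junk, genes)
    assert row["n_mapped"] == 0 and row["mapped_pct"] == 0.0


def test_dotplot_self_comparison_single_forward_segment(small_genes):
    genes, _ = small_genes
    gene = genes.records[0]
    one = SequenceSet.from_records([gene])
    rows = dotplot_export(one, one)
    assert len(rows) == 1
    row = rows[0]
    assert row["strand"] == "+"
    assert (row["r_start"], row["r_end"]) == (1, len(gene))
    assert (row["c_start"], row["c_end"]) == (1, len(gene))
    assert row["identity_pct"] == 100.0


def test_dotplot_reverse_complement_segment(small_genes):
    genes, _ = small_genes
    gene = genes.records[0]
    contig = SequenceSet.from_records([gene.reverse_complement(new_id="rc")])
    rows = dotplot_export(contig, SequenceSet.from_records([gene]))
    assert len(rows) == 1
    assert rows[0]["strand"] == "-"
    assert rows[0]["identity_pct"] == 100.0


def test_dotplot_min_match_threshold(rng):
    shared = random_dna(rng, 400)
    ref = make_set([random_dna(rng, 300) + shared + random_dna(rng, 300)], "ref")
    ctg = make_set([random_dna(rng, 200) + shared + random_dna(rng, 200)], "ctg")
    assert dotplot_export(ctg, ref, min_match=500) == []
    assert len(dotplot_export(ctg, ref, min_match=300)) >= 1
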