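"""Read curation: fixed trims, adapter detection, chimera removal and the
no-residual-adapter guarantee (checked against an edlib oracle)."""

import edlib
import numpy as np
import pytest

from renseqtk.curation import (AdapterSpec, CurationConfig, KEPT,
                               REMOVED_CHIMERIC, REMOVED_SHORT, curate,
                               curate_set, detect_adapters, trim_fixed_ends)
from renseqtk.records import ReadRecord, SequenceSet, reverse_complement
from renseqtk.simulate import DEFAULT_ADAPTER, NANOPORE_2D, SimConfig, simulate_reads

from conftest import random_dna

ADAPTER = AdapterSpec("amp", DEFAULT_ADAPTER, 0.20)


def config(**kwargs):
    defaults = dict(end_trim=65, min_length=150, adapters=[ADAPTER],
                    chimera_flank=50)
    defaults.update(kwargs)
    return CurationConfig(**defaults)


def test_trim_fixed_ends_lengths(rng):
    read = ReadRecord("r", random_dna(rng, 200), quality="I" * 200)
    trimmed = trim_fixed_ends(read, 65)
    assert len(trimmed) == 70
    assert len(trimmed.quality) == 70
    assert trimmed.sequence == read.sequence[65:135]
    assert len(trim_fixed_ends(ReadRecord("r", random_dna(rng, 130)), 65)) == 0
    assert trim_fixed_ends(read, 0) == read


def test_detect_adapter_at_read_start(rng):
    read = ReadRecord("r", DEFAULT_ADAPTER + random_dna(rng, 300))
    spans = detect_adapters(read, [ADAPTER])
    assert spans[0].start == 0 and spans[0].end == 65 and spans[0].edits == 0


def test_detect_mutated_internal_adapter(rng):
    mutated = list(DEFAULT_ADAPTER)
    for i in range(0, 60, 6):  # 10 substitutions, within the 13-edit budget
        mutated[i] = {"A": "C", "C": "G", "G": "T", "T": "A"}[mutated[i]]
    read = ReadRecord("r", random_dna(rng, 200) + "".join(mutated) + random_dna(rng, 200))
    spans = detect_adapters(read, [ADAPTER])
    assert any(abs(s.start - 200) <= 2 and s.edits <= 13 for s in spans)


def test_adapter_free_read_has_no_spans(rng):
    read = ReadRecord("r", random_dna(rng, 500))
    spans = detect_adapters(read, [ADAPTER])
    # oracle: best infix edit distance of either strand must exceed budget
    best = min(
        edlib.align(p, read.sequence, mode="HW")["editDistance"]
        for p in (DEFAULT_ADAPTER, reverse_complement(DEFAULT_ADAPTER)))
    assert best > ADAPTER.max_edits
    assert spans == []


def test_clean_read_with_end_adapters_is_kept(rng):
    core = random_dna(rng, 2870)
    read = ReadRecord("r", DEFAULT_ADAPTER + core + DEFAULT_ADAPTER)
    out = curate(read, config())
    assert out.decision == KEPT
    assert len(out.trimmed_sequence) == 2870
    assert out.trimmed_sequence == core


def test_internal_adapter_flags_chimera(rng):
    frag1, frag2 = random_dna(rng, 1500), random_dna(rng, 1500)
    read = ReadRecord("r", DEFAULT_ADAPTER + frag1 + DEFAULT_ADAPTER + frag2
                      + DEFAULT_ADAPTER)
    out = curate(read, config())
    assert out.decision == REMOVED_CHIMERIC
    assert out.trimmed_sequence == ""


def test_short_read_removed_after_end_trim(rng):
    read = ReadRecord("r", random_dna(rng, 250))
    out = curate(read, config(adapters=[]))
    assert out.decision == REMOVED_SHORT
    assert out.final_length == 120


def test_adapter_near_end_is_trimmed_not_chimeric(rng):
    # adapter 20 bp from the start (< chimera_flank) must be trimmed off
    read = ReadRecord("r", random_dna(rng, 20) + DEFAULT_ADAPTER + random_dna(rng, 1000))
    out = curate(read, config(end_trim=0))
    assert out.decision == KEPT
    assert len(out.trimmed_sequence) == 1000


def test_curate_is_idempotent_on_kept_output(rng):
    cfg = config()
    second = config(end_trim=0)
    for _ in range(10):
        core = random_dna(rng, int(rng.integers(400, 2000)))
        read = ReadRecord("r", DEFAULT_ADAPTER + core + DEFAULT_ADAPTER)
        out = curate(read, cfg)
        if out.decision != KEPT:
            continue
        again = curate(ReadRecord("r", out.trimmed_sequence), second)
        assert again.decision == KEPT
        assert again.trimmed_sequence == out.trimmed_sequence


def test_decisions_independent_of_read_order(rng, small_genes):
    genes, _ = small_genes
    cfg_sim = SimConfig(seed=21, coverage=2.0, chimera_rate=0.15,
                        error_profile=NANOPORE_2D)
    reads, _ = simulate_reads(genes, cfg_sim)
    cfg = config()
    forward = {r.id: curate(r, cfg).decision for r in reads}
    backward = {r.id: curate(r, cfg).decision for r in reversed(reads.records)}
    assert forward == backward


def test_curate_set_truth_small(small_genes):
    """Planted chimeras at nanopore error rates are found; kept reads are
    adapter-free by the edlib oracle; the length rule is exact."""
    genes, _ = small_genes
    cfg_sim = SimConfig(seed=22, coverage=4.0, chimera_rate=0.15,
                        error_profile=NANOPORE_2D)
    reads, truth = simulate_reads(genes, cfg_sim)
    kept, summary = curate_set(reads, config())
    outcomes = {o.read_id: o for o in summary["outcomes"]}
    is_chimera = {t.read_id: t.is_chimera for t in truth}
    tp = sum(1 for r, c in is_chimera.items()
             if c and outcomes[r].decision == REMOVED_CHIMERIC)
    fp = sum(1 for r, c in is_chimera.items()
             if not c and outcomes[r].decision == REMOVED_CHIMERIC)
    fn = sum(1 for r, c in is_chimera.items()
             if c and outcomes[r].decision != REMOVED_CHIMERIC)
    assert tp + fn > 0
    assert tp / (tp + fn) >= 0.9  # small-n sanity; full check in acceptance
    assert fp <= max(1, 0.05 * (tp + fp))
    # length rule: kept iff final length >= min_length (non-chimeric)
    for o in outcomes.values():
        if o.decision == REMOVED_SHORT:
            assert o.final_length < 150
        elif o.decision == KEPT:
            assert o.final_length >= 150
    # no kept read retains an adapter within the edit budget (edlib oracle)
    for rec in kept.records[:40]:
        for p in (DEFAULT_ADAPTER, reverse_complement(DEFAULT_ADAPTER)):
            d = edlib.align(p, rec.sequence, mode="HW")["editDistance"]
            assert d > ADAPTER.max_edits
    # input order preserved
    kept_ids = kept.ids()
    original_order = [r.id for r in reads if r.id in set(kept_ids)]
    assert kept_ids == original_order
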