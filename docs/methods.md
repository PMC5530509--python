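# Methods

`renseqtk` re-implements, at desk scale, the bespoke computational stages of
a long-read RenSeq workflow: the targeted capture of plant NLR
(nucleotide-binding leucine-rich-repeat) immune-receptor loci followed by
nanopore- or PacBio-style long-read sequencing. The package covers what sits
*between* the standard external tools — read curation before assembly,
capture-efficiency scoring, motif-based NLR classification, assembly
evaluation against an annotated gene set, and the rapid triage of reads that
may carry novel NLR genes. Base calling, production assembly (Canu/HGAP
class assemblers), signal-level polishing and protein gene prediction are
out of scope; assembly is an explicit shell-out boundary (reads FASTQ in,
contigs FASTA out), with a toy greedy assembler provided for closed-loop
testing.

## Alignment engine

All sequence comparison runs through one internal engine rather than an
external aligner, so that every decision rule is deterministic and testable:

* **Local alignment** is affine-gap Smith–Waterman (Gotoh) with scores
  +2/−3 match/mismatch and −5/−2 gap open/extend — common nucleotide-search
  defaults, configurable. A gap of length L costs `open + (L−1)·extend`,
  hence the engine requires `open ≤ extend < 0`. Both strands of the subject
  are tried. Inputs up to 2 kb per sequence are solved exhaustively; larger
  inputs go through k-mer seeding (k = 11), diagonal clustering and a banded
  DP around the densest diagonal (half-width 100 plus the cluster spread).
  The 2-kb exhaustive guarantee is what makes the engine verifiable against
  an independent exhaustive aligner in the tests.
* **Identity** is matches / alignment columns, gap columns included — the
  convention of tabular alignment output. Coordinates are 0-based half-open
  internally; exports are 1-based inclusive with a strand column.
* **Adapter location** is a separate semiglobal (pattern-anchored,
  text-free) unit-cost edit-distance scan. All placements within the edit
  budget are enumerated and reduced to non-overlapping spans by ascending
  (edits, start, end) — locally minimal-edit, leftmost-first. The budget for
  an error rate r and pattern length L is `floor(r·L)`.
* **Read mapping** is best-hit-per-read and seed-gated: a read sharing no
  seed k-mer with any reference entry is unmapped, as with production
  mappers. Ties break on identity, then lexicographically smallest subject
  id.

N never matches anything, including another N.

## Read curation

The pre-assembly cascade, in fixed order per read: (1) remove a fixed 65 bp
(the amplification-adapter length) from both ends; (2) scan for adapters at
a per-platform error rate (20% nanopore-like, 5% PacBio-like, both
strands); (3) adapter spans closer than `chimera_flank` (50 bp) to a read
end are trimmed off and the read re-scanned until stable; (4) any surviving
span with ≥ 50 bp on both sides marks the read **chimeric** — the signature
of two fragments fused through a PCR adapter — and the read is removed
whole, never split; (5) reads shorter than 150 bp are removed. The re-scan
loop makes curation idempotent and guarantees kept reads retain no adapter
within the edit budget. Decisions depend only on read content, never on
read order.

## On-target scoring

A read is on-target when some bait's best local alignment spans ≥ 96
columns at ≥ 80% identity. "Over 96 bases" counts alignment columns, gap
columns included; the decision is monotone in both thresholds.

## NLR motif classification

Six-frame translation (standard code; codons containing N translate to X)
feeds a degenerate-pattern scanner: patterns over amino-acid letters plus
`x` wildcards, a per-motif mismatch budget at informative positions, and a
hard rule that windows containing a stop (`*`) never match. The default
motif set is a deliberately simple consensus placeholder (editable via
JSON/TOML config; it reproduces no published tool's motif models):

| id      | pattern        | mismatches | category | role         |
|---------|----------------|------------|----------|--------------|
| ploop   | `GGVGKTT`      | 1          | NB_ARC   | P-loop anchor|
| kinase2 | `LLVLDDVW`     | 1          | NB_ARC   |              |
| glpl    | `GLPLAL`       | 1          | NB_ARC   | GLPL anchor  |
| lrr     | `LxxLxxLxLxxN` | 0          | LRR      |              |

The LRR pattern is the canonical plant LRR consensus including the
conserved Asn: leucine alone is too frequent in random translation (six
codons) for an all-L pattern to stay quiet on random sequence. An MHD-class
motif is not shipped by default for the same reason — a 3-residue
informative core fires constantly on random input — but can be added via
config.

**Calls**: *complete* requires, within a single reading frame, a P-loop
anchor hit, a GLPL anchor hit starting after it, and at least two LRR hits
starting after both — the ordered NB-ARC → LRR architecture. *Partial* is
any NB-ARC or LRR hit in any frame; otherwise *none*. Because completeness
is single-frame, one indel between cassette motifs splits the architecture
across frames and demotes the call — the mechanism by which indel-rich
uncorrected long reads depress motif-based NLR recognition, reproduced
faithfully by the synthetic tests (complete-call rates collapse to ~0 under
the indel-rich error preset and recover on error-free input).

## Assembly evaluation

Reference genes are searched against contigs best-hit-per-query and
accepted at explicit thresholds (≥ 500 alignment columns, ≥ 85% identity by
default). This deliberately replaces an "e-value = 0"-style acceptance:
e-values depend on database size and tool internals, while explicit
thresholds are portable and configurable. Accepted hits overlapping on the
same contig by more than half of the shorter interval are deduplicated,
keeping the highest score — the automated analogue of hand-removing
false-positive hits produced by the same subject sequence. Summaries report
coverage (hits / reference genes) and mean ± sample (n−1) standard
deviation of identity, alignment length and query-length percentage —
spreadsheet-convention statistics. Match segments ≥ 500 bp per
(reference, contig, strand) are exportable as a dot-plot table with forward
and reverse matches distinguished.

## Novel-gene triage

Reads are mapped to a reference from which the genes of interest are
absent. The empirical threshold is `mean − k·SD` (k = 2, sample SD) over
the best-hit identities of all mapped reads; candidates are the unmapped
reads plus reads strictly below threshold, assembled and scored against the
withheld genes (recovered = some contig hits the gene under the acceptance
criteria after deduplication). Choices the source procedure left open and
are declared here: sample SD; the threshold is computed from mapped reads
only; candidate selection is monotone in k.

The triage signal is strongest when novelty includes sequence with *no*
counterpart in the reference. The generator therefore models novel genes as
fusion-domain NLRs: a diverged backbone plus an in-frame integrated domain
(900 bp of novel sequence) downstream of the motif cassette. Reads from the
integrated domain cannot map and are always selected; backbone reads map
acceptably and mostly are not — which is why recovery depends on how
densely the novel domains are covered and why partial recovery is the
expected outcome at modest coverage, mirroring the partial recovery the
strategy achieves at full scale. A mean−2·SD threshold mathematically
cannot select a low-identity subpopulation larger than ~20% of the pool
(two-point-mixture algebra), so the triage experiments keep the novel read
fraction below that.

## Toy assembler

`toy_assemble` is a deterministic greedy overlap-layout-consensus
implementation, fixture-grade by design: pairwise overlaps (dovetail or
containment, either orientation) must span ≥ 300 columns at ≥ 90% identity;
the highest-scoring merge is applied repeatedly (ties break on contig ids);
consensus is per-column base-count majority with lexicographic tie-break.
It exists so the pipeline closes the loop on synthetic data and reports
which reads built which contig; production assembly is an external tool
behind a documented shell-out.

## Synthetic data generator

The generator emulates the statistical structure the pipeline assumes, with
a truth record per read:

* **Genes**: families of paralogs from a common ancestor carrying the
  planted in-frame, stop-free cassette P-loop → Kinase-2 → GLPL → 3×LRR.
  `paralog_divergence` (default 0.03) is the expected *pairwise* divergence
  between family members (each paralog mutates at half that rate from the
  ancestor); motif spans are protected, so every gene classifies complete.
  Gene lengths default to 2–4 kb.
* **Baits**: 120-mers tiled every 60 bp per gene, final window
  right-anchored — every base covered.
* **Reads**: fragment positions uniform (genes weighted by length), lengths
  lognormal with mode ≈ 2.8 kb truncated to [200 bp, 20 kb] and clipped to
  the gene; uniform strand; every read decorated with a fixed 65-bp adapter
  on both ends; with probability `chimera_rate` two fragments are joined by
  the adapter; off-target reads are uniform random sequence
  (`off_target_fraction`, default 0.20). Errors are per-base
  substitution/insertion/deletion draws; presets: nanopore-2D-like
  {0.03, 0.02, 0.04} (~91% accuracy, deletion-heavy — chosen to stress the
  frameshift sensitivity above) and PacBio-consensus-like
  {0.002, 0.001, 0.001} (~99.6%). Quality strings encode the profile's
  average error (no positional model). Reads are drawn until on-target
  fragment bases reach coverage × total gene length.
* **Determinism**: one seed, per-stage child streams
  (`SeedSequence.spawn`); outputs are byte-identical per seed.

What the generator does **not** model — and hence what passing tests do not
show about real data: capture-efficiency bias and PCR duplication,
position- and sequence-context-dependent error profiles (homopolymer
errors in particular), genomic context around genes (reads come from gene
space plus uniform off-target sequence), structural variation other than
the planted fusion domains, and real adapter chemistry.

## Numerical conventions and degenerate inputs

Percentages print with two decimals, rounded half-up. Sample statistics use
n−1; an SD over a single value reports 0. Modal read length is the most
frequent exact length (smallest on ties); modal accuracy is binned at two
decimal percentage places before taking the mode, since that is the
precision such tables print. N50 is the length of the smallest read such
that reads at least that long comprise half of all bases. Empty sequence
files parse to empty sets; empty read sets are rejected by the statistics
functions; a FASTQ record whose quality length disagrees with its sequence
is a parse error naming the record. FASTQ qualities are Phred+33 only.

## Problem sizes

The bundled tests and the acceptance script run the pipeline on simulated
datasets of 6–20 genes of 1.2–3 kb, 150–2,000 reads, and bait panels of up
to ~250 120-mers — sizes chosen so the whole suite, including the
exhaustive-DP oracle comparisons, completes in minutes on one core while
still exercising every pipeline branch (all curation decision classes,
both strands, mapped/unmapped, all three motif calls, recovered and
unrecovered genes).

## Known limitations

* The seeded banded path is a heuristic above 2 kb: a true optimum far off
  the seeded diagonal corridor can be missed (the tests pin heuristic =
  exhaustive only where the spec guarantees exactness).
* The motif defaults are placeholders; real screening should load a curated
  motif config. Calibration against published motif-model scanners is
  future validation, not assumed.
* The toy assembler handles substitution-divergent overlaps by majority
  column counts but keeps the first contig's columns for indel-divergent
  overlaps; it is not suitable for real error-rich data.
* `dotplot_export` reports one banded alignment per seeded diagonal
  cluster; highly repetitive sequences may merge adjacent segments.
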