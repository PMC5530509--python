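"""Pipeline orchestration: wire the stages in capture-pipeline order
(curate → qc → ontarget → motifs → assemble → eval → triage) over either a
simulated dataset or user-supplied files, with a manifest recording stage
status, output hashes, seed and version.

Configuration is a nested mapping (JSON/TOML file or dict). Validation
collects *all* errors before reporting and rejects unknown keys.
"""

from __future__ import annotations

import hashlib
import json
import logging
import subprocess
import sys
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Dict, List, Optional

from . import __version__
from .assembly import (AcceptanceCriteria, DOTPLOT_COLUMNS, best_hit_search,
                       dotplot_export, summarize_hits)
from .capture import BaitHitCriteria, ON_TARGET_COLUMNS, on_target_rate
from .curation import (AdapterSpec, CurationConfig, CURATION_SUMMARY_COLUMNS,
                       NANOPORE_ADAPTER_ERROR_RATE, curate_set)
from .errors import ConfigError, RenseqError
from .io import read_sequences, write_sequences, write_table
from .motifs import ANNOTATE_COLUMNS, DEFAULT_MOTIFS, annotate_set, load_motifs
from .readqc import qc_table, QC_COLUMNS
from .records import SequenceSet
from .simulate import (ANNOTATION_COLUMNS, SimConfig, TRUTH_COLUMNS,
                       simulate_dataset, truth_rows)
from .triage import TriageConfig, reduce_reference, run_triage

logger = logging.getLogger("renseqtk")

STAGES = ("curate", "qc", "ontarget", "motifs", "assemble", "eval", "triage")

_SIM_KEYS = {
    "n_families", "paralogs_per_family", "paralog_divergence",
    "gene_length_range", "novel_genes", "novel_divergence", "coverage",
    "chimera_rate", "off_target_fraction", "error_profile",
    "read_length_bounds",
}


@dataclass
class PipelineConfig:
    seed: int
    out_dir: str
    stages: Dict[str, bool]
    simulate: Optional[dict] = None
    inputs: Dict[str, str] = field(default_factory=dict)
    curate: Dict = field(default_factory=dict)
    ontarget: Dict = field(default_factory=dict)
    motifs: Dict = field(default_factory=dict)
    assemble: Dict = field(default_factory=dict)
    eval: Dict = field(default_factory=dict)
    triage: Dict = field(default_factory=dict)
    log_level: str = "INFO"


_TOP_KEYS = {"seed", "out_dir", "stages", "simulate", "inputs", "curate",
             "ontarget", "motifs", "assemble", "eval", "triage", "log_level"}
_SECTION_KEYS = {
    "stages": set(STAGES),
    "inputs": {"reads", "baits", "reference", "contigs", "exclude_ids",
               "adapters"},
    "curate": {"end_trim", "min_length", "error_rate", "chimera_flank"},
    "ontarget": {"min_alignment_length", "min_identity"},
    "motifs": {"config"},
    "assemble": {"assembler", "command"},
    "eval": {"min_alignment_length", "min_identity", "dedupe_overlap",
             "min_match"},
    "triage": {"sd_multiplier", "require_motifs"},
    "simulate": _SIM_KEYS,
}


def _load_mapping(source) -> dict:
    if isinstance(source, dict):
        return dict(source)
    path = Path(source)
    if path.suffix == ".toml":
        import tomllib

        with open(path, "rb") as fh:
            return tomllib.load(fh)
    with open(path) as fh:
        return json.load(fh)


def validate_config(source) -> PipelineConfig:
    """Build a :class:`PipelineConfig`, reporting every problem at once."""
    raw = _load_mapping(source)
    errors: List[str] = []
    for key in raw:
        if key not in _TOP_KEYS:
            errors.append(f"unknown key {key!r}")
    for section, allowed in _SECTION_KEYS.items():
        value = raw.get(section)
        if value is None:
            continue
        if not isinstance(value, dict):
            errors.append(f"{section!r} must be a mapping")
            continue
        for key in value:
            if key not in allowed:
                errors.append(f"unknown key {section}.{key}")

    stages = {name: True for name in STAGES}
    stages.update(raw.get("stages") or {})
    simulate = raw.get("simulate")
    seed = raw.get("seed")
    if seed is None and (simulate is not None or
                         (stages.get("assemble") and
                          (raw.get("assemble") or {}).get("assembler", "toy") == "toy")):
        errors.append("seed is required when a stochastic stage is enabled")
    if seed is not None and not isinstance(seed, int):
        errors.append("seed must be an integer")
    if "out_dir" not in raw:
        errors.append("out_dir is required")

    cur = raw.get("curate") or {}
    if cur.get("end_trim", 65) < 0:
        errors.append("curate.end_trim must be >= 0")
    if cur.get("min_length", 150) < 1:
        errors.append("curate.min_length must be >= 1")
    if not (0 <= cur.get("error_rate", NANOPORE_ADAPTER_ERROR_RATE) < 0.5):
        errors.append("curate.error_rate must be in [0, 0.5)")
    ont = raw.get("ontarget") or {}
    if ont.get("min_alignment_length", 96) < 1:
        errors.append("ontarget.min_alignment_length must be >= 1")
    if not (0 < ont.get("min_identity", 0.80) <= 1):
        errors.append("ontarget.min_identity must be in (0, 1]")
    ev = raw.get("eval") or {}
    if ev.get("min_alignment_length", 500) < 1:
        errors.append("eval.min_alignment_length must be >= 1")
    if ev.get("min_match", 500) < 1:
        errors.append("eval.min_match must be >= 1")
    tri = raw.get("triage") or {}
    if tri.get("sd_multiplier", 2.0) <= 0:
        errors.append("triage.sd_multiplier must be > 0")
    asm = raw.get("assemble") or {}
    if asm.get("assembler", "toy") not in ("toy", "external", "none"):
        errors.append("assemble.assembler must be toy|external|none")
    if asm.get("assembler") == "external" and not asm.get("command"):
        errors.append("assemble.command is required for an external assembler")

    inputs = raw.get("inputs") or {}
    if simulate is None:
        for stage, needed in (("curate", "reads"), ("ontarget", "baits"),
                              ("eval", "reference")):
            if stages.get(stage) and needed not in inputs:
                errors.append(
                    f"stage {stage!r} is enabled but inputs.{needed} is missing")
        for key, value in inputs.items():
            if not Path(value).exists():
                errors.append(f"inputs.{key}: file not found: {value}")
    if errors:
        raise ConfigError(errors)
    return PipelineConfig(
        seed=seed if seed is not None else 0,
        out_dir=raw["out_dir"],
        stages=stages,
        simulate=simulate,
        inputs=inputs,
        curate=cur, ontarget=ont, motifs=raw.get("motifs") or {},
        assemble=asm, eval=ev, triage=tri,
        log_level=raw.get("log_level", "INFO"),
    )


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the enabled stages in fixed order; returns the manifest."""
    logging.basicConfig(stream=sys.stderr, level=config.log_level)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {"seed": config.seed, "version": __version__, "stages": []}

    def record(name: str, status: str, outputs: List[Path]) -> None:
        manifest["stages"].append({
            "name": name, "status": status,
            "outputs": [str(p) for p in outputs],
            "sha256": {p.name: _sha256(p) for p in outputs},
        })

    # --- inputs (simulated or loaded) -------------------------------------
    dataset = None
    genes = baits = reads = None
    withheld_ids: List[str] = []
    adapter_specs: List[AdapterSpec] = []
    error_rate = config.curate.get("error_rate", NANOPORE_ADAPTER_ERROR_RATE)
    if config.simulate is not None:
        sim_cfg = SimConfig(seed=config.seed, **{
            k: (tuple(v) if isinstance(v, list) else v)
            for k, v in config.simulate.items() if k != "error_profile"
        })
        if "error_profile" in config.simulate:
            from . import simulate as _sim

            sim_cfg = SimConfig(**{**asdict_nonprofile(sim_cfg),
                                   "error_profile": getattr(_sim, config.simulate["error_profile"].upper())})
        logger.info("simulating dataset (seed %d)", config.seed)
        dataset = simulate_dataset(sim_cfg)
        genes, baits, reads = dataset.reference, dataset.baits, dataset.reads
        withheld_ids = dataset.withheld_ids
        adapter_specs = [AdapterSpec("amplification", sim_cfg.adapter, error_rate)]
        write_sequences(dataset.genes, out / "genes.fasta")
        write_sequences(baits, out / "baits.fasta")
        write_sequences(reads, out / "reads.fastq", format="fastq")
        write_table(dataset.annotations, out / "annotations.tsv",
                    columns=ANNOTATION_COLUMNS)
        write_table(truth_rows(dataset.truth), out / "truth.tsv",
                    columns=TRUTH_COLUMNS)
        record("simulate", "run", [out / n for n in
                                   ("genes.fasta", "baits.fasta", "reads.fastq",
                                    "annotations.tsv", "truth.tsv")])
    else:
        if "reads" in config.inputs:
            reads = read_sequences(config.inputs["reads"])
        if "baits" in config.inputs:
            baits = read_sequences(config.inputs["baits"])
        if "reference" in config.inputs:
            genes = read_sequences(config.inputs["reference"])
        if "adapters" in config.inputs:
            adapter_specs = [
                AdapterSpec(rec.id, rec.sequence, error_rate)
                for rec in read_sequences(config.inputs["adapters"])
            ]
        if "exclude_ids" in config.inputs:
            withheld_ids = [
                line.strip() for line in
                Path(config.inputs["exclude_ids"]).read_text().splitlines()
                if line.strip()
            ]

    # --- curate ------------------------------------------------------------
    curated = reads
    if config.stages.get("curate") and reads is not None:
        cc = CurationConfig(
            end_trim=config.curate.get("end_trim", 65),
            min_length=config.curate.get("min_length", 150),
            adapters=adapter_specs,
            chimera_flank=config.curate.get("chimera_flank", 50),
        )
        curated, summary = curate_set(reads, cc)
        outcomes = summary.pop("outcomes")
        write_sequences(curated, out / "curated.fastq", format="fastq")
        write_table([summary], out / "curation_summary.tsv",
                    columns=CURATION_SUMMARY_COLUMNS)
        write_table([{"read_id": o.read_id, "decision": o.decision,
                      "final_length": o.final_length,
                      "n_adapter_spans": len(o.adapter_spans)}
                     for o in outcomes], out / "curation_report.tsv")
        record("curate", "run", [out / "curated.fastq",
                                 out / "curation_summary.tsv",
                                 out / "curation_report.tsv"])
    else:
        record("curate", "skipped", [])

    # --- qc ----------------------------------------------------------------
    if config.stages.get("qc") and reads is not None:
        groups = {"raw": (reads, genes)}
        if curated is not reads and len(curated):
            groups["curated"] = (curated, genes)
        rows = qc_table(groups)
        write_table(rows, out / "qc.tsv", columns=QC_COLUMNS,
                    percent_fields={"mapped_pct", "mean_accuracy_pct",
                                    "modal_accuracy_pct", "mean_error_rate_pct"})
        record("qc", "run", [out / "qc.tsv"])
    else:
        record("qc", "skipped", [])

    # --- ontarget ----------------------------------------------------------
    if config.stages.get("ontarget") and baits is not None and curated is not None:
        criteria = BaitHitCriteria(
            min_alignment_length=config.ontarget.get("min_alignment_length", 96),
            min_identity=config.ontarget.get("min_identity", 0.80),
        )
        rate, rows = on_target_rate(curated, baits, criteria)
        write_table(rows, out / "ontarget.tsv", columns=ON_TARGET_COLUMNS,
                    percent_fields={"identity_pct"})
        write_table([{"on_target_rate": rate}], out / "ontarget_summary.tsv",
                    percent_fields={"on_target_rate"})
        record("ontarget", "run", [out / "ontarget.tsv",
                                   out / "ontarget_summary.tsv"])
    else:
        record("ontarget", "skipped", [])

    # --- motifs ------------------------------------------------------------
    if config.stages.get("motifs") and curated is not None:
        motif_set = (load_motifs(config.motifs["config"])
                     if config.motifs.get("config") else DEFAULT_MOTIFS)
        summary, rows = annotate_set(curated, motif_set)
        write_table(rows, out / "motifs.tsv", columns=ANNOTATE_COLUMNS)
        write_table([summary], out / "motif_summary.tsv",
                    percent_fields={"pct_hits_of_total", "pct_partial_of_hits",
                                    "pct_complete_of_hits"})
        record("motifs", "run", [out / "motifs.tsv", out / "motif_summary.tsv"])
    else:
        record("motifs", "skipped", [])

    # --- assemble ----------------------------------------------------------
    contigs = None
    assembler = config.assemble.get("assembler", "toy")
    if config.stages.get("assemble") and curated is not None and len(curated):
        if assembler == "toy":
            from .triage import toy_assemble

            result = toy_assemble(curated)
            contigs = result.contigs
        elif assembler == "external":
            contigs = _external_assemble(config.assemble["command"], curated, out)
        if contigs is not None:
            write_sequences(contigs, out / "contigs.fasta")
            record("assemble", "run", [out / "contigs.fasta"])
        else:
            record("assemble", "skipped", [])
    else:
        if "contigs" in config.inputs:
            contigs = read_sequences(config.inputs["contigs"])
        record("assemble", "skipped", [])

    # --- eval --------------------------------------------------------------
    if config.stages.get("eval") and genes is not None and contigs is not None \
            and len(contigs):
        criteria = AcceptanceCriteria(
            min_alignment_length=config.eval.get("min_alignment_length", 500),
            min_identity=config.eval.get("min_identity", 0.85),
        )
        hits = best_hit_search(genes, contigs, criteria)
        summary = summarize_hits(hits, len(genes),
                                 {g.id: len(g) for g in genes})
        write_table([vars(summary)], out / "eval_summary.tsv")
        dots = dotplot_export(contigs, genes,
                              min_match=config.eval.get("min_match", 500))
        write_table(dots, out / "dotplot.tsv", columns=DOTPLOT_COLUMNS)
        record("eval", "run", [out / "eval_summary.tsv", out / "dotplot.tsv"])
    else:
        record("eval", "skipped", [])

    # --- triage ------------------------------------------------------------
    if config.stages.get("triage") and curated is not None and genes is not None \
            and withheld_ids and dataset is not None:
        tri_cfg = TriageConfig(
            sd_multiplier=config.triage.get("sd_multiplier", 2.0),
            require_motifs=config.triage.get("require_motifs", False),
        )
        withheld = dataset.genes.subset(withheld_ids)
        report, candidates, _assembly = run_triage(
            curated, genes, tri_cfg, withheld=withheld)
        payload = {
            "mean_identity": report.mean_identity,
            "sd_identity": report.sd_identity,
            "threshold": report.threshold,
            "n_unmapped": report.n_unmapped,
            "n_below_threshold": report.n_below_threshold,
            "n_candidates": report.n_candidates,
            "n_withheld": report.n_withheld,
            "n_recovered": report.n_recovered,
            "recovered_mean_identity": report.recovered_mean_identity,
            "recovered_sd_identity": report.recovered_sd_identity,
            "recovered": report.recovered,
        }
        with open(out / "triage.json", "w") as fh:
            json.dump(payload, fh, indent=2)
            fh.write("\n")
        record("triage", "run", [out / "triage.json"])
    else:
        record("triage", "skipped", [])

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
        fh.write("\n")
    return manifest


def asdict_nonprofile(cfg: SimConfig) -> dict:
    d = {k: v for k, v in vars(cfg).items() if k != "error_profile"}
    return d


def _external_assemble(command: str, reads: SequenceSet, out: Path) -> SequenceSet:
    """Shell out to an external assembler.

    Contract: ``command`` is a template with ``{reads}`` and ``{out}``
    placeholders; it must read the FASTQ and write contigs FASTA to {out}.
    """
    reads_path = out / "assembly_input.fastq"
    contigs_path = out / "contigs_external.fasta"
    write_sequences(reads, reads_path, format="fastq")
    cmd = command.format(reads=reads_path, out=contigs_path)
    logger.info("external assembler: %s", cmd)
    proc = subprocess.run(cmd, shell=True)
    if proc.returncode != 0 or not contigs_path.exists():
        raise RenseqError(f"external assembler failed (exit {proc.returncode})")
    return read_sequences(contigs_path)
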