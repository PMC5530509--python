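"""Rapid novel-NLR identification by empirical identity thresholding.

Withholds three fusion-domain genes from the reference, maps all reads
against the reduced reference, selects unmapped and below-threshold
(mean - 2*SD) reads, assembles them with the toy assembler, and scores how
many withheld genes the contigs recover.
"""

import math

from renseqtk import (AdapterSpec, CurationConfig, ERROR_FREE, SimConfig,
                      TriageConfig, curate_set, run_triage, simulate_dataset)

config = SimConfig(seed=12, n_families=5, paralogs_per_family=2,
                   coverage=50.0, novel_genes=3, novel_divergence=0.12,
                   gene_length_range=(1500, 2400), error_profile=ERROR_FREE,
                   chimera_rate=0.0, off_target_fraction=0.0,
                   read_length_mean_log=math.log(700),
                   read_length_sd_log=0.3, read_length_bounds=(300, 1500))
ds = simulate_dataset(config)
kept, _ = curate_set(ds.reads, CurationConfig(
    adapters=[AdapterSpec("amp", config.adapter)]))

report, candidates, assembly = run_triage(
    kept, ds.reference, TriageConfig(),
    withheld=ds.genes.subset(ds.withheld_ids))

print(f"reads mapped against {len(ds.reference)} known genes")
print(f"identity threshold:  {report.mean_identity:.2f}% - 2 x {report.sd_identity:.2f}% "
      f"= {report.threshold:.2f}%")
print(f"candidates:          {report.n_candidates} "
      f"({report.n_unmapped} unmapped + {report.n_below_threshold} low-identity)")
print(f"contigs assembled:   {len(assembly.contigs)}")
print(f"withheld recovered:  {report.n_recovered}/{report.n_withheld}")
for rec in report.recovered:
    status = (f"{rec['identity_pct']}% over {rec['aln_len']} bp"
              if rec["recovered"] else "not recovered")
    print(f"  {rec['gene_id']}: {status}")
print()
print("Reads from the novel integrated domains cannot map to the reduced")
print("reference, so they pool into the candidate set and reassemble the")
print("withheld genes - without assembling the whole dataset. Recovery")
print("depends on how densely the novel domains happen to be covered by")
print("candidate reads; partial recovery is the expected desk-scale")
print("outcome, just as the strategy recovers only a subset at full scale.")
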