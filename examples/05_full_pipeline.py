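"""Run the full regulon-reconstruction pipeline on a synthetic benchmark.

Generates the default 8-genome dataset, trains the motif on the upstream
regions of five known target roles, scans every operon leader in every
genome, confirms targets by cross-genome recurrence, and compares the
confirmed regulon with the planted ground truth.
"""

import warnings

from regulonkit import PlantConfig, config_for_synthetic, generate_genome_set, run_pipeline

dataset = generate_genome_set(PlantConfig(seed=0), outdir="example_output/bench")
config = config_for_synthetic("example_output/bench", "example_output/bench_run")
with warnings.catch_warnings():
    warnings.simplefilter("ignore")
    result = run_pipeline(config)

print(f"model: width {result.model.width}, consensus {result.model.consensus()}")
print(f"threshold {result.model.threshold:.3f} "
      f"(from {len(result.model.training_sites)} training regions)\n")

truth = set(zip(dataset.truth_regulon.genome, dataset.truth_regulon.leader))
confirmed = {(c.genome_id, c.leader_gene_id) for c in result.calls if c.confirmed}
tp = len(truth & confirmed)
print(f"regulon calls: {len(result.calls)} "
      f"({len(confirmed)} confirmed by >=2 genomes)")
print(f"recall    : {tp / len(truth):.3f}  (confirmed members / planted members)")
print(f"precision : {tp / len(confirmed):.3f}  (true members / confirmed members)")
print(f"autoregulation detected in: "
      f"{sorted(g for g, v in result.autoregulation.items() if v)}")
print(f"\nreports written to {result.out_dir}: operons.tsv, occurrence.tsv, "
      "hits.tsv/gff3, regulon.tsv, assignments.tsv, model.json")
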