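"""Generate a small synthetic multi-genome dataset with ground truth.

Builds three AT-rich genomes with operon-structured gene layouts, plants one
25-bp inverted-repeat binding site upstream of each regulated operon leader,
and writes FASTA/GFF3 plus ground-truth tables to ./example_output/dataset.
"""

from regulonkit import PlantConfig, generate_genome_set

config = PlantConfig(n_genomes=3, genes_per_genome=45, n_decoys=2, seed=1)
dataset = generate_genome_set(config, outdir="example_output/dataset")

for gid, genome in dataset.genomes.items():
    contig = next(iter(genome.contigs.values()))
    n_sites = (dataset.truth_sites.genome == gid).sum()
    print(f"{gid}: {len(contig):6d} bp, {len(dataset.features[gid])} genes, "
          f"{n_sites} planted sites")

print(f"\nregulated operons with a planted site: {len(dataset.truth_regulon)}")
print(f"decoy sites (single-genome, should stay unconfirmed): "
      f"{int(dataset.truth_sites.is_decoy.sum())}")
print("\nFirst planted sites (coordinates are 0-based on the forward strand):")
print(dataset.truth_sites.head(4).to_string(index=False))
print("\nEach row records where a site was written into the genome; the "
      "pipeline must rediscover these from sequence alone.")
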