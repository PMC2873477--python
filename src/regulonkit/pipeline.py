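"""End-to-end orchestration: genomes in, regulon report out.

Stages run in a fixed order: I/O -> operon prediction -> ortholog groups ->
per-group training sets (upstream regions of role-labelled known targets)
-> motif discovery -> upstream scanning -> cross-genome consistency ->
autoregulation -> functional assignments -> reports.  Every derived
threshold and seed is logged; re-running with the same config and inputs is
byte-identical (no timestamps are written).
"""

from __future__ import annotations

import dataclasses
import json
import os
from dataclasses import dataclass, field

import pandas as pd

from . import genome_io
from .context import operons_to_tsv, predict_operons, chromosomal_clustering, operon_of_gene
from .genome_io import write_sites_gff
from .motif import PalindromeSearch, discover_motif, logo_data, pfm_text
from .orthology import build_occurrence_matrix, read_ortholog_table
from .regulon import (
    assign_function,
    assignments_to_tsv,
    calls_to_tsv,
    cross_genome_consistency,
    detect_autoregulation,
    resolve_paralog_ambiguity,
)
from .scan import attach_z, scan_genome, standardize_scores, upstream_regions_of_leaders


class PipelineConfigError(ValueError):
    pass


@dataclass
class GenomeInput:
    genome_id: str
    fasta: str
    features: str
    dialect: str = "gff3"


@dataclass
class PipelineConfig:
    """Validated parameters for one pipeline run.

    ``training_roles`` names the roles whose operon leaders seed motif
    discovery (the known targets); scanning then searches every operon
    leader for additional candidates.
    """

    genomes: list[GenomeInput]
    ortholog_table: str
    roles: list[str]
    training_roles: list[str]
    out_dir: str
    regulator_role: str | None = "xylR"
    upstream_window: int = 300
    min_region_len: int = 20
    clip_at_neighbor: bool = True
    max_gap_bp: int = 150
    min_support: int = 2
    width_range: tuple[int, int] = (17, 31)
    arm_range: tuple[int, int] = (7, 13)
    spacers: tuple[int, ...] = (3, 5, 7)
    palindrome: bool = True
    n_restarts: int = 4
    pseudocount: float = 1.0
    upper_thresh: float = 0.9
    lower_thresh: float = 0.5
    window_genes: int = 5
    seed: int = 0

    def validate(self) -> None:
        if not self.genomes:
            raise PipelineConfigError("no genomes configured")
        if not self.roles:
            raise PipelineConfigError("empty role vocabulary")
        if not self.training_roles:
            raise PipelineConfigError("no training roles configured")
        unknown = set(self.training_roles) - set(self.roles)
        if unknown:
            raise PipelineConfigError(f"training roles outside vocabulary: {sorted(unknown)}")
        ids = [g.genome_id for g in self.genomes]
        if len(ids) != len(set(ids)):
            raise PipelineConfigError("duplicate genome ids")
        for g in self.genomes:
            for p in (g.fasta, g.features):
                if not os.path.exists(p):
                    raise PipelineConfigError(f"missing input file: {p}")
        if not os.path.exists(self.ortholog_table):
            raise PipelineConfigError(f"missing ortholog table: {self.ortholog_table}")

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        return json.dumps(d, indent=1, default=list, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "PipelineConfig":
        d = json.loads(text)
        d["genomes"] = [GenomeInput(**g) for g in d["genomes"]]
        for key in ("width_range", "arm_range", "spacers"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


@dataclass
class PipelineResult:
    config: PipelineConfig
    genomes: dict
    features: dict
    operons_by_genome: dict
    ortholog_groups: list
    occurrence: object
    model: object
    hits_by_genome: dict
    calls: list
    autoregulation: dict[str, bool]
    assignments: list
    out_dir: str
    log_lines: list[str] = field(default_factory=list)


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Run every stage and write the output bundle to ``config.out_dir``."""
    config.validate()
    os.makedirs(config.out_dir, exist_ok=True)
    log: list[str] = []

    def stage(name: str):
        log.append(f"[stage] {name}")

    with open(os.path.join(config.out_dir, "config_used.json"), "w") as fh:
        fh.write(config.to_json())

    stage("io")
    genomes, features = {}, {}
    for gi in config.genomes:
        genomes[gi.genome_id] = genome_io.read_fasta(gi.fasta, genome_id=gi.genome_id)
        features[gi.genome_id] = genome_io.read_features(
            gi.features, dialect=gi.dialect, genome=genomes[gi.genome_id],
            genome_id=gi.genome_id,
        )

    stage("operons")
    operons_by_genome = {
        gid: predict_operons(features[gid], max_gap_bp=config.max_gap_bp)
        for gid in genomes
    }
    all_ops = [op for ops in operons_by_genome.values() for op in ops]
    operons_to_tsv(all_ops, os.path.join(config.out_dir, "operons.tsv"))

    stage("orthology")
    groups = read_ortholog_table(config.ortholog_table, genome_ids=list(genomes))
    occurrence = build_occurrence_matrix(groups, sorted(genomes), config.roles)
    occurrence.to_tsv(os.path.join(config.out_dir, "occurrence.tsv"))
    role_of_gene = {
        gene: gr.role
        for gr in groups
        for genes in gr.members.values()
        for gene in genes
        if gr.role
    }

    stage("training_set")
    regions = []
    seen_leaders = set()
    for gid in sorted(genomes):
        gene_to_op = operon_of_gene(operons_by_genome[gid])
        for role in config.training_roles:
            for gene, r in sorted(role_of_gene.items()):
                if r != role:
                    continue
                op = gene_to_op.get(gene)
                if op is None or op.genome_id != gid:
                    continue
                key = (gid, op.leader_gene_id)
                if key in seen_leaders:
                    continue
                seen_leaders.add(key)
                regs = upstream_regions_of_leaders(
                    genomes[gid], features[gid], [op.leader_gene_id],
                    window=config.upstream_window, min_len=config.min_region_len,
                    clip_at_neighbor=config.clip_at_neighbor,
                )
                regions.extend(regs)
    log.append(f"training regions: {len(regions)}")

    stage("discovery")
    palindrome = (
        PalindromeSearch(arm_range=config.arm_range, spacers=config.spacers)
        if config.palindrome
        else None
    )
    model = discover_motif(
        regions,
        width_range=config.width_range,
        palindrome=palindrome,
        n_restarts=config.n_restarts,
        seed=config.seed,
        pseudocount=config.pseudocount,
    )
    log.append(f"selected width: {model.width}")
    log.append(f"palindrome geometry: {model.palindrome}")
    log.append(f"threshold (min training score): {model.threshold!r}")
    log.append(f"consensus: {model.consensus(config.upper_thresh, config.lower_thresh)}")
    with open(os.path.join(config.out_dir, "model.json"), "w") as fh:
        fh.write(model.to_json())
    with open(os.path.join(config.out_dir, "model.pfm"), "w") as fh:
        fh.write(pfm_text(model.pwm))
    logo_data(model.pwm).to_csv(os.path.join(config.out_dir, "logo.tsv"), sep="\t")

    stage("scan")
    mu, sigma = standardize_scores(model)
    log.append(f"background score mean/sd: {mu!r} / {sigma!r}")
    hits_by_genome = {}
    for gid in sorted(genomes):
        hits = scan_genome(
            model, genomes[gid], features[gid], mode="upstream_only",
            operons=operons_by_genome[gid], window=config.upstream_window,
            clip_at_neighbor=config.clip_at_neighbor, group_id="group1",
        )
        attach_z(hits, mu, sigma)
        hits_by_genome[gid] = hits
        log.append(f"hits in {gid}: {len(hits)}")
    all_hits = [h for hits in hits_by_genome.values() for h in hits]
    write_sites_gff(all_hits, os.path.join(config.out_dir, "hits.gff3"))
    _hits_to_tsv(all_hits, os.path.join(config.out_dir, "hits.tsv"))

    stage("regulon")
    calls = cross_genome_consistency(
        hits_by_genome, operons_by_genome, groups, sorted(genomes),
        min_support=config.min_support, group_id="group1",
    )
    calls_to_tsv(calls, os.path.join(config.out_dir, "regulon.tsv"))
    log.append(f"regulon calls: {len(calls)} ({sum(c.confirmed for c in calls)} confirmed)")

    stage("autoregulation")
    regulator_genes = {}
    if config.regulator_role is not None:
        for gene, role in role_of_gene.items():
            if role == config.regulator_role:
                gid = next((g for g in genomes if any(
                    f.gene_id == gene for f in features[g])), None)
                if gid is not None:
                    regulator_genes[gid] = gene
    autoreg = detect_autoregulation(calls, regulator_genes, operons_by_genome)
    pd.DataFrame(
        [{"genome": g, "autoregulation": v} for g, v in sorted(autoreg.items())]
    ).to_csv(os.path.join(config.out_dir, "autoregulation.tsv"), sep="\t", index=False)

    stage("assignments")
    confirmed_by_operon = {
        (c.genome_id, c.operon_id): c for c in calls if c.confirmed
    }
    assignments = []
    for gid in sorted(genomes):
        gene_to_op = operon_of_gene(operons_by_genome[gid])
        feats = features[gid]
        local_genes = {f.gene_id for f in feats}
        for gene, role in sorted(role_of_gene.items()):
            if gene not in local_genes:
                continue
            other_roles = set(config.roles) - {role}
            clustering = chromosomal_clustering(
                feats, gene, other_roles, window_genes=config.window_genes
            )
            op = gene_to_op.get(gene)
            call = confirmed_by_operon.get((gid, op.operon_id)) if op else None
            assignments.append(
                assign_function(
                    gene, gid, role,
                    homology="ortholog-table",
                    clustering=clustering if clustering else None,
                    regulon=call,
                )
            )
    resolve_paralog_ambiguity(assignments)
    assignments_to_tsv(assignments, os.path.join(config.out_dir, "assignments.tsv"))

    log.append(f"seed: {config.seed}")
    with open(os.path.join(config.out_dir, "run_log.txt"), "w") as fh:
        fh.write("\n".join(log) + "\n")

    return PipelineResult(
        config=config,
        genomes=genomes,
        features=features,
        operons_by_genome=operons_by_genome,
        ortholog_groups=groups,
        occurrence=occurrence,
        model=model,
        hits_by_genome=hits_by_genome,
        calls=calls,
        autoregulation=autoreg,
        assignments=assignments,
        out_dir=config.out_dir,
        log_lines=log,
    )


def _hits_to_tsv(hits, path: str) -> None:
    rows = [
        {
            "genome": h.genome_id,
            "contig": h.contig_id,
            "start": h.start + 1,
            "end": h.end,
            "strand": h.strand,
            "score": repr(float(h.score)),
            "z": "" if h.z is None else repr(float(h.z)),
            "sequence": h.sequence,
            "targets": ",".join(h.targets),
        }
        for h in hits
    ]
    pd.DataFrame(
        rows,
        columns=["genome", "contig", "start", "end", "strand", "score", "z", "sequence", "targets"],
    ).to_csv(path, sep="\t", index=False)


def config_for_synthetic(dataset_dir: str, out_dir: str, **overrides) -> PipelineConfig:
    """Build a PipelineConfig for a directory written by the generator.

    Uses the ground-truth ortholog table as the ortholog input and the
    leader roles of the first five regulated operon templates as the known
    training targets (the remaining regulated operons must be recovered by
    scanning).
    """
    with open(os.path.join(dataset_dir, "config.json")) as fh:
        synth_cfg = json.load(fh)
    operon_templates = [tuple(t) for t in synth_cfg["regulated_operons"]]
    if synth_cfg.get("include_regulator", True):
        operon_templates.append(("xylR",))
    roles = [r for op in operon_templates for r in op]
    training_roles = [op[0] for op in operon_templates[:5]]
    genome_inputs = []
    for i in range(synth_cfg["n_genomes"]):
        gid = f"g{i + 1:02d}"
        genome_inputs.append(
            GenomeInput(
                genome_id=gid,
                fasta=os.path.join(dataset_dir, f"{gid}.fna"),
                features=os.path.join(dataset_dir, f"{gid}.gff"),
            )
        )
    cfg = dict(
        genomes=genome_inputs,
        ortholog_table=os.path.join(dataset_dir, "truth_orthologs.tsv"),
        roles=roles,
        training_roles=training_roles,
        out_dir=out_dir,
        upstream_window=synth_cfg["upstream_window"],
        seed=synth_cfg["seed"],
    )
    cfg.update(overrides)
    return PipelineConfig(**cfg)
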