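"""Cross-genome regulon calls, autoregulation, and functional assignments.

A candidate site in one genome becomes a comparative-genomics-confirmed
regulon member when orthologous targets in other genomes of the same
regulator group also carry upstream sites (phylogenetic footprinting).
Functional assignments then combine three evidence legs: homology
(ortholog-group membership), chromosomal clustering with pathway genes, and
membership in the confirmed regulon — the combination that discriminates a
true pathway gene from a functionally divergent paralog.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .context import ClusterEvidence, Operon, operon_of_gene
from .orthology import OrthologGroup
from .scan import SiteHit

EVIDENCE_HOMOLOGY = "HOMOLOGY"
EVIDENCE_CLUSTERING = "CLUSTERING"
EVIDENCE_REGULON = "REGULON"


@dataclass
class RegulonCall:
    """One target operon with an upstream site, plus cross-genome support.

    ``support`` counts the genomes in the regulator group (including this
    one) where an ortholog of any operon member also has an upstream hit.
    """

    group_id: str
    genome_id: str
    operon_id: str
    leader_gene_id: str
    best_hit: SiteHit
    support: int
    confirmed: bool


def cross_genome_consistency(
    hits_by_genome: dict[str, list[SiteHit]],
    operons_by_genome: dict[str, list[Operon]],
    ortholog_groups: list[OrthologGroup],
    group_genomes: list[str],
    min_support: int = 2,
    group_id: str = "group1",
) -> list[RegulonCall]:
    """Turn per-genome hits into cross-genome-validated regulon calls.

    For each operon with an upstream hit, support is the number of genomes
    in the regulator group where an ortholog of any operon member also has
    an upstream hit (counting the genome itself); the call is confirmed iff
    support >= ``min_support``.  Output ordering is deterministic
    (genome, leader).
    """
    gene_to_family: dict[str, int] = {}
    for fam_idx, gr in enumerate(ortholog_groups):
        for genes in gr.members.values():
            for g in genes:
                gene_to_family[g] = fam_idx

    gene_to_operon = {
        genome: operon_of_gene(ops) for genome, ops in operons_by_genome.items()
    }

    # per genome: operons that carry a hit, with the best hit per operon
    hit_operons: dict[str, dict[str, SiteHit]] = {}
    for genome in group_genomes:
        per_op: dict[str, SiteHit] = {}
        for h in hits_by_genome.get(genome, []):
            for target in h.targets:
                op = gene_to_operon.get(genome, {}).get(target)
                if op is None:
                    continue
                cur = per_op.get(op.operon_id)
                if cur is None or (h.score, -h.start) > (cur.score, -cur.start):
                    per_op[op.operon_id] = h
        hit_operons[genome] = per_op

    # families with a hit-bearing operon, per genome
    fams_with_hit: dict[str, set[int]] = {}
    ops_by_id = {
        genome: {op.operon_id: op for op in ops} for genome, ops in operons_by_genome.items()
    }
    for genome in group_genomes:
        fams: set[int] = set()
        for op_id in hit_operons[genome]:
            for gene in ops_by_id[genome][op_id].gene_ids:
                if gene in gene_to_family:
                    fams.add(gene_to_family[gene])
        fams_with_hit[genome] = fams

    calls = []
    for genome in sorted(group_genomes):
        for op_id in sorted(hit_operons[genome]):
            op = ops_by_id[genome][op_id]
            fams = {gene_to_family[g] for g in op.gene_ids if g in gene_to_family}
            support = 0
            for other in group_genomes:
                if other == genome:
                    support += 1  # this operon's own hit
                elif fams & fams_with_hit[other]:
                    support += 1
            calls.append(
                RegulonCall(
                    group_id=group_id,
                    genome_id=genome,
                    operon_id=op_id,
                    leader_gene_id=op.leader_gene_id,
                    best_hit=hit_operons[genome][op_id],
                    support=support,
                    confirmed=support >= min_support,
                )
            )
    calls.sort(key=lambda c: (c.genome_id, c.leader_gene_id))
    return calls


def detect_autoregulation(
    calls: list[RegulonCall],
    regulator_genes: dict[str, str],
    operons_by_genome: dict[str, list[Operon]],
    confirmed_only: bool = False,
) -> dict[str, bool]:
    """Per genome: does a site sit upstream of the regulator's own operon?

    The rule is operon-level: a regulator encoded mid-operon counts when the
    operon leader carries the site.  Genomes without an annotated regulator
    report False.
    """
    out: dict[str, bool] = {}
    for genome, ops in operons_by_genome.items():
        reg_gene = regulator_genes.get(genome)
        if reg_gene is None:
            out[genome] = False
            continue
        op = operon_of_gene(ops).get(reg_gene)
        if op is None:
            out[genome] = False
            continue
        out[genome] = any(
            c.genome_id == genome
            and c.operon_id == op.operon_id
            and (c.confirmed or not confirmed_only)
            for c in calls
        )
    return out


@dataclass
class FunctionalAssignment:
    """A gene-function call with its evidence codes and details."""

    gene_id: str
    genome_id: str
    role: str
    evidence: dict[str, object] = field(default_factory=dict)
    ambiguous_paralog: bool = False
    context_only: bool = False
    resolved_against: list[str] = field(default_factory=list)

    @property
    def codes(self) -> list[str]:
        return sorted(self.evidence)


def assign_function(
    gene_id: str,
    genome_id: str,
    role: str,
    homology=None,
    clustering: ClusterEvidence | None = None,
    regulon: RegulonCall | None = None,
) -> FunctionalAssignment:
    """Attach evidence codes for the sources present; reject empty evidence.

    ``regulon`` evidence requires a confirmed call covering the gene's
    operon.  A clustering-only call is flagged as a context-only prediction.
    """
    evidence: dict[str, object] = {}
    if homology is not None:
        evidence[EVIDENCE_HOMOLOGY] = homology
    if clustering is not None and clustering.neighbors:
        evidence[EVIDENCE_CLUSTERING] = clustering
    if regulon is not None:
        if not regulon.confirmed:
            raise ValueError("REGULON evidence requires a confirmed regulon call")
        evidence[EVIDENCE_REGULON] = regulon
    if not evidence:
        raise ValueError(f"gene {gene_id!r}: no evidence at all")
    return FunctionalAssignment(
        gene_id=gene_id,
        genome_id=genome_id,
        role=role,
        evidence=evidence,
        context_only=EVIDENCE_HOMOLOGY not in evidence,
    )


def resolve_paralog_ambiguity(assignments: list[FunctionalAssignment]) -> list[FunctionalAssignment]:
    """Flag homology-only paralogs when a competing copy has context support.

    When >= 2 genes in one genome carry HOMOLOGY evidence for the same role
    but only one of them also has CLUSTERING or REGULON support, the
    unsupported copies are flagged ``ambiguous_paralog`` and record which
    gene the role was resolved to.
    """
    by_key: dict[tuple[str, str], list[FunctionalAssignment]] = {}
    for a in assignments:
        if EVIDENCE_HOMOLOGY in a.evidence:
            by_key.setdefault((a.genome_id, a.role), []).append(a)
    for group in by_key.values():
        if len(group) < 2:
            continue
        supported = [
            a
            for a in group
            if EVIDENCE_CLUSTERING in a.evidence or EVIDENCE_REGULON in a.evidence
        ]
        if len(supported) == 1:
            winner = supported[0]
            for a in group:
                if a is not winner:
                    a.ambiguous_paralog = True
                    a.resolved_against = [winner.gene_id]
    return assignments


def calls_to_tsv(calls: list[RegulonCall], path: str) -> None:
    rows = [
        {
            "group": c.group_id,
            "genome": c.genome_id,
            "operon_id": c.operon_id,
            "leader": c.leader_gene_id,
            "site_contig": c.best_hit.contig_id,
            "site_start": c.best_hit.start + 1,
            "site_end": c.best_hit.end,
            "site_strand": c.best_hit.strand,
            "site_score": repr(float(c.best_hit.score)),
            "site_z": "" if c.best_hit.z is None else repr(float(c.best_hit.z)),
            "support": c.support,
            "confirmed": c.confirmed,
        }
        for c in calls
    ]
    pd.DataFrame(
        rows,
        columns=[
            "group", "genome", "operon_id", "leader", "site_contig", "site_start",
            "site_end", "site_strand", "site_score", "site_z", "support", "confirmed",
        ],
    ).to_csv(path, sep="\t", index=False)


def assignments_to_tsv(assignments: list[FunctionalAssignment], path: str) -> None:
    rows = [
        {
            "genome": a.genome_id,
            "gene": a.gene_id,
            "role": a.role,
            "evidence": ",".join(a.codes),
            "ambiguous_paralog": a.ambiguous_paralog,
            "context_only": a.context_only,
            "resolved_against": ",".join(a.resolved_against),
        }
        for a in sorted(assignments, key=lambda a: (a.genome_id, a.gene_id, a.role))
    ]
    pd.DataFrame(
        rows,
        columns=["genome", "gene", "role", "evidence", "ambiguous_paralog", "context_only", "resolved_against"],
    ).to_csv(path, sep="\t", index=False)
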