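"""Operon prediction and chromosomal-clustering evidence.

Bacterial genes transcribed as one unit sit adjacently on the same strand
with short intergenic gaps; the standard heuristic merges same-strand
neighbors whose gap is below a cutoff.  Chromosomal clustering of a query
gene with pathway genes (functional coupling) is the first leg of the
genome-context evidence used for functional assignment.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .genome_io import GeneFeature, UnknownGeneError, _feature_sort_key


@dataclass
class Operon:
    """A run of co-transcribed genes; ``gene_ids`` is 5'->3' on the coding
    strand, so the leader (promoter-proximal gene) is the first element."""

    genome_id: str
    operon_id: str
    contig_id: str
    strand: str
    gene_ids: list[str]

    @property
    def leader_gene_id(self) -> str:
        return self.gene_ids[0]


@dataclass
class NeighborEvidence:
    gene_id: str
    role: str
    gene_distance: int
    bp_distance: int
    same_strand: bool


@dataclass
class ClusterEvidence:
    """Role-labelled genes near a query gene on the chromosome."""

    query_gene_id: str
    neighbors: list[NeighborEvidence] = field(default_factory=list)

    def __bool__(self) -> bool:
        return bool(self.neighbors)


def predict_operons(
    features: list[GeneFeature],
    max_gap_bp: int = 150,
    require_same_strand: bool = True,
) -> list[Operon]:
    """Partition genes into operons by adjacency and intergenic gap.

    Adjacent genes on the same contig (and strand, unless
    ``require_same_strand`` is off) whose intergenic gap is <= ``max_gap_bp``
    merge into one operon; every gene belongs to exactly one operon and
    singletons are allowed.  Divergently transcribed pairs are never merged.
    """
    if max_gap_bp < 0:
        raise ValueError("max_gap_bp must be >= 0")
    feats = sorted(features, key=_feature_sort_key)
    operons: list[Operon] = []
    run: list[GeneFeature] = []

    def close_run() -> None:
        if not run:
            return
        genome_id = run[0].genome_id
        strand = run[0].strand
        ordered = [f.gene_id for f in run]
        if strand == "-":
            ordered = ordered[::-1]  # leader is the most 5' gene = rightmost
        operons.append(
            Operon(
                genome_id=genome_id,
                operon_id=f"{genome_id}:{run[0].contig_id}:op{len(operons):04d}",
                contig_id=run[0].contig_id,
                strand=strand,
                gene_ids=ordered,
            )
        )

    for f in feats:
        if run:
            prev = run[-1]
            same_contig = f.contig_id == prev.contig_id
            same_strand = (not require_same_strand) or (f.strand == prev.strand)
            gap = f.start - prev.end
            if same_contig and same_strand and gap <= max_gap_bp:
                run.append(f)
                continue
            close_run()
            run = []
        run.append(f)
    close_run()
    return operons


def operon_of_gene(operons: list[Operon]) -> dict[str, Operon]:
    """gene_id -> containing operon, from an operon partition."""
    mapping: dict[str, Operon] = {}
    for op in operons:
        for g in op.gene_ids:
            mapping[g] = op
    return mapping


def chromosomal_clustering(
    features: list[GeneFeature],
    query_gene_id: str,
    role_set: set[str],
    window_genes: int = 5,
) -> ClusterEvidence:
    """Report role-labelled genes within +/- ``window_genes`` positions.

    Distances are the count of intervening genes (adjacent = 1) and the bp
    gap between intervals (0 when overlapping).  Empty evidence is allowed.
    """
    feats = sorted(features, key=_feature_sort_key)
    idx = next((i for i, f in enumerate(feats) if f.gene_id == query_gene_id), None)
    if idx is None:
        raise UnknownGeneError(query_gene_id)
    query = feats[idx]
    neighbors = []
    for j in range(max(0, idx - window_genes), min(len(feats), idx + window_genes + 1)):
        if j == idx:
            continue
        f = feats[j]
        if f.contig_id != query.contig_id or f.role not in role_set:
            continue
        bp = max(0, max(f.start, query.start) - min(f.end, query.end))
        neighbors.append(
            NeighborEvidence(
                gene_id=f.gene_id,
                role=f.role,
                gene_distance=abs(j - idx),
                bp_distance=bp,
                same_strand=f.strand == query.strand,
            )
        )
    neighbors.sort(key=lambda n: (n.gene_distance, n.gene_id))
    return ClusterEvidence(query_gene_id=query_gene_id, neighbors=neighbors)


def operons_to_tsv(operons: list[Operon], path: str) -> None:
    rows = [
        {
            "genome": op.genome_id,
            "operon_id": op.operon_id,
            "contig": op.contig_id,
            "strand": op.strand,
            "leader": op.leader_gene_id,
            "members": ",".join(op.gene_ids),
        }
        for op in operons
    ]
    pd.DataFrame(rows, columns=["genome", "operon_id", "contig", "strand", "leader", "members"]).to_csv(
        path, sep="\t", index=False
    )
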