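"""Cross-genome ortholog groups, occurrence matrices, and regulator groups.

Orthology uses the bidirectional-best-hit (BBH) criterion on global-alignment
percent identity: two genes in different genomes that are each other's best
hit at or above a minimum identity are orthologs, and groups are the
single-linkage closure of BBH pairs.  Regulator proteins are partitioned
into groups either by cutting a user-supplied phylogenetic tree (Newick) or
by single-linkage identity clustering; each group trains its own DNA motif.

Alignment parameters are fixed (BLOSUM62, gap open -11, gap extend -1,
global mode) so identities are reproducible across runs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from io import StringIO

import networkx as nx
import pandas as pd
from Bio import Phylo
from Bio.Align import PairwiseAligner, substitution_matrices

AA_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWYX")


def _make_aligner() -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11.0
    aligner.extend_gap_score = -1.0
    aligner.mode = "global"
    return aligner


_ALIGNER = _make_aligner()


def pairwise_identity(seq_a: str, seq_b: str) -> float:
    """Global-alignment percent identity, reported to 0.1%.

    Identity = matching columns / alignment columns, excluding terminal gap
    overhangs.  'X' is allowed but never counted as a match.  The sequence
    pair is canonicalized (lexicographic order) before aligning so that
    alignment tie-breaking cannot make the result asymmetric.
    """
    for name, s in (("a", seq_a), ("b", seq_b)):
        if not s:
            raise ValueError(f"empty sequence {name}")
        bad = set(s.upper()) - AA_ALPHABET
        if bad:
            raise ValueError(f"sequence {name}: invalid amino acids {sorted(bad)}")
    seq_a, seq_b = sorted((seq_a.upper(), seq_b.upper()))
    aln = _ALIGNER.align(seq_a, seq_b)[0]
    row_a, row_b = aln[0], aln[1]
    # trim terminal overhang columns (leading/trailing gap in either row)
    lo = 0
    while row_a[lo] == "-" or row_b[lo] == "-":
        lo += 1
    hi = len(row_a)
    while row_a[hi - 1] == "-" or row_b[hi - 1] == "-":
        hi -= 1
    cols = hi - lo
    matches = sum(
        1
        for x, y in zip(row_a[lo:hi], row_b[lo:hi])
        if x == y and x != "-" and x != "X"
    )
    return round(100.0 * matches / cols, 1)


@dataclass(frozen=True)
class SimilarityRecord:
    """Percent identity between two genes of different genomes.

    Stored with the lexicographically smaller gene first so that (a, b) and
    (b, a) are the same record.
    """

    gene_a: str
    gene_b: str
    percent_identity: float
    alignment_length: int = 0

    def __init__(self, gene_a, gene_b, percent_identity, alignment_length=0):
        a, b = (gene_a, gene_b) if gene_a <= gene_b else (gene_b, gene_a)
        object.__setattr__(self, "gene_a", a)
        object.__setattr__(self, "gene_b", b)
        object.__setattr__(self, "percent_identity", float(percent_identity))
        object.__setattr__(self, "alignment_length", int(alignment_length))
        if not 0.0 <= self.percent_identity <= 100.0:
            raise ValueError(f"identity out of range: {self.percent_identity}")


@dataclass
class OrthologGroup:
    """A cross-genome gene family with an optional functional-role label."""

    role: str | None
    members: dict[str, list[str]]  # genome_id -> gene ids
    flagged_paralogs: dict[str, list[str]] = field(default_factory=dict)

    def genomes(self) -> list[str]:
        return sorted(self.members)

    def all_genes(self) -> list[str]:
        return sorted(g for genes in self.members.values() for g in genes)


def bbh_orthologs(
    records: list[SimilarityRecord],
    gene_to_genome: dict[str, str],
    min_identity: float = 30.0,
    max_paralogs_per_genome: int = 1,
) -> list[OrthologGroup]:
    """Ortholog groups as the single-linkage closure of mutual best hits.

    For each gene and each other genome the best hit is the record with the
    highest identity (ties -> lexicographically smaller partner id); a pair
    is kept when mutual and at or above ``min_identity``.  Output is
    independent of record order.  Genomes contributing more than
    ``max_paralogs_per_genome`` genes to a group are flagged, not merged
    away (functionally divergent paralogs are the classic pitfall).
    """
    best: dict[tuple[str, str], tuple[float, str]] = {}
    for rec in sorted(records, key=lambda r: (r.gene_a, r.gene_b)):
        for g, h in ((rec.gene_a, rec.gene_b), (rec.gene_b, rec.gene_a)):
            if g not in gene_to_genome or h not in gene_to_genome:
                raise KeyError(f"gene without genome assignment in records: {g!r} or {h!r}")
            key = (g, gene_to_genome[h])
            cur = best.get(key)
            cand = (rec.percent_identity, h)
            if cur is None or cand[0] > cur[0] or (cand[0] == cur[0] and cand[1] < cur[1]):
                best[key] = cand
    graph = nx.Graph()
    graph.add_nodes_from(gene_to_genome)
    for (g, other_genome), (ident, h) in best.items():
        if ident < min_identity:
            continue
        back = best.get((h, gene_to_genome[g]))
        if back is not None and back[1] == g:
            graph.add_edge(g, h)
    groups = []
    for comp in nx.connected_components(graph):
        if len(comp) < 2:
            continue
        members: dict[str, list[str]] = {}
        for g in sorted(comp):
            members.setdefault(gene_to_genome[g], []).append(g)
        flagged = {
            gen: genes
            for gen, genes in members.items()
            if len(genes) > max_paralogs_per_genome
        }
        groups.append(OrthologGroup(role=None, members=members, flagged_paralogs=flagged))
    groups.sort(key=lambda gr: gr.all_genes()[0])
    return groups


@dataclass
class OccurrenceMatrix:
    """Genome x role presence table; rendered with '+' for presence."""

    table: pd.DataFrame  # bool, index = genomes, columns = roles
    genes: dict[tuple[str, str], list[str]] = field(default_factory=dict)

    def to_tsv(self, path: str) -> None:
        rendered = self.table.map(lambda v: "+" if v else "")
        rendered.rename_axis("genome").to_csv(path, sep="\t")

    def presence_counts(self) -> pd.Series:
        return self.table.sum(axis=0)


def build_occurrence_matrix(
    groups: list[OrthologGroup], genomes: list[str], roles: list[str]
) -> OccurrenceMatrix:
    """Boolean presence of each role in each genome; paralogs collapse to one '+'."""
    table = pd.DataFrame(False, index=list(genomes), columns=list(roles))
    genes: dict[tuple[str, str], list[str]] = {}
    for gr in groups:
        if gr.role is None:
            continue
        if gr.role not in roles:
            raise ValueError(f"role {gr.role!r} not in declared vocabulary")
        for genome_id, gids in gr.members.items():
            if genome_id in table.index:
                table.loc[genome_id, gr.role] = True
                genes.setdefault((genome_id, gr.role), []).extend(sorted(gids))
    return OccurrenceMatrix(table=table, genes=genes)


def read_ortholog_table(path: str, genome_ids: list[str] | None = None) -> list[OrthologGroup]:
    """Read a role-labelled ortholog table (columns: role, genome, gene)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"role", "genome", "gene"}
    if required - set(df.columns):
        raise ValueError(f"ortholog table needs columns {sorted(required)}")
    groups = []
    for role, sub in df.groupby("role", sort=True):
        members: dict[str, list[str]] = {}
        for row in sub.itertuples(index=False):
            if genome_ids is not None and row.genome not in genome_ids:
                continue
            members.setdefault(row.genome, []).append(row.gene)
        for genes in members.values():
            genes.sort()
        if members:
            groups.append(OrthologGroup(role=str(role), members=members))
    return groups


def write_ortholog_table(groups: list[OrthologGroup], path: str) -> None:
    rows = []
    for gr in groups:
        for genome_id in sorted(gr.members):
            for gene in sorted(gr.members[genome_id]):
                rows.append({"role": gr.role or "", "genome": genome_id, "gene": gene})
    pd.DataFrame(rows, columns=["role", "genome", "gene"]).to_csv(path, sep="\t", index=False)


@dataclass
class RegulatorGroup:
    """Regulator proteins sharing one DNA recognition motif."""

    group_id: str
    members: list[str]


def _identity_matrix(proteins: dict[str, str], identities) -> dict[frozenset, float]:
    if identities is not None:
        return {frozenset(k): v for k, v in identities.items()}
    names = sorted(proteins)
    out = {}
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            out[frozenset((a, b))] = pairwise_identity(proteins[a], proteins[b])
    return out


def group_regulators(
    proteins: dict[str, str],
    method: str = "identity_clustering",
    threshold: float = 30.0,
    tree: str | None = None,
    identities: dict[tuple[str, str], float] | None = None,
) -> list[RegulatorGroup]:
    """Partition regulators into motif-sharing groups.

    ``identity_clustering`` takes connected components of the thresholded
    identity graph (single linkage).  ``newick`` cuts a user tree into the
    maximal clades whose internal pairwise identity is all >= threshold
    (a singleton leaf always qualifies).  ``identities`` may supply
    precomputed percent identities keyed by name pairs; otherwise they are
    computed from the protein sequences.
    """
    names = sorted(proteins)
    if not names:
        raise ValueError("no regulator proteins given")
    ident = _identity_matrix(proteins, identities)

    def pair_id(a: str, b: str) -> float:
        return ident.get(frozenset((a, b)), 0.0)

    if method == "identity_clustering":
        graph = nx.Graph()
        graph.add_nodes_from(names)
        for i, a in enumerate(names):
            for b in names[i + 1 :]:
                if pair_id(a, b) >= threshold:
                    graph.add_edge(a, b)
        comps = sorted((sorted(c) for c in nx.connected_components(graph)), key=lambda c: c[0])
        return [RegulatorGroup(f"group{i + 1}", c) for i, c in enumerate(comps)]

    if method != "newick":
        raise ValueError(f"unknown grouping method {method!r}")
    if tree is None:
        raise ValueError("newick method requires a tree")
    handle = StringIO(tree) if tree.strip().startswith("(") else tree
    phylo = Phylo.read(handle, "newick")
    leaves = [t.name for t in phylo.get_terminals()]
    if sorted(leaves) != names:
        raise ValueError(
            f"tree leaves {sorted(leaves)} do not match regulator proteins {names}"
        )

    def coherent(leaf_names: list[str]) -> bool:
        return all(
            pair_id(a, b) >= threshold
            for i, a in enumerate(leaf_names)
            for b in leaf_names[i + 1 :]
        )

    groups: list[list[str]] = []

    def walk(clade) -> None:
        clade_leaves = [t.name for t in clade.get_terminals()]
        if coherent(clade_leaves):
            groups.append(sorted(clade_leaves))
            return
        for child in clade.clades:
            walk(child)

    walk(phylo.root)
    groups.sort(key=lambda c: c[0])
    return [RegulatorGroup(f"group{i + 1}", c) for i, c in enumerate(groups)]
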