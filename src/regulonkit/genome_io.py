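"""Genome, gene-feature and site I/O with explicit coordinate conventions.

Internally all intervals are 0-based half-open on the forward strand of the
contig.  Every file interface (GFF3 in/out, the TSV feature dialect) is
1-based closed, converted at the boundary and nowhere else.

The TSV feature dialect has a header line and the columns
``gene_id  contig  start  end  strand`` (1-based closed) plus optional
``product`` and ``role`` columns.
"""

from __future__ import annotations

import os
import warnings
from dataclasses import dataclass, field

import gffutils
import pandas as pd
from Bio import SeqIO

from .seqs import revcomp

VALID_NT = frozenset("ACGTN")

_FEATURE_TYPES = ("gene", "CDS")


class FastaFormatError(ValueError):
    pass


class FeatureFormatError(ValueError):
    pass


class UnknownGeneError(KeyError):
    pass


class RegionTooShortError(ValueError):
    pass


@dataclass
class Genome:
    """A named set of contigs; sequences are uppercase over {A,C,G,T,N}."""

    genome_id: str
    contigs: dict[str, str]
    circular: dict[str, bool] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for cid, seq in self.contigs.items():
            if not seq:
                raise FastaFormatError(f"contig {cid!r}: empty sequence")
            self.circular.setdefault(cid, False)

    def length(self, contig_id: str) -> int:
        return len(self.contigs[contig_id])


@dataclass
class GeneFeature:
    """A stranded gene on a contig, 0-based half-open internally."""

    gene_id: str
    genome_id: str
    contig_id: str
    start: int
    end: int
    strand: str
    product: str = ""
    role: str | None = None

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise FeatureFormatError(
                f"gene {self.gene_id!r}: invalid interval ({self.start}, {self.end})"
            )
        if self.strand not in "+-":
            raise FeatureFormatError(f"gene {self.gene_id!r}: unknown strand {self.strand!r}")


@dataclass
class UpstreamRegion:
    """Promoter-side slice 5' of a gene, given 5'->3' on the coding strand."""

    gene_id: str
    genome_id: str
    contig_id: str
    start: int
    end: int
    gene_strand: str
    sequence: str
    truncated: bool

    @property
    def interval(self) -> tuple[str, int, int, str]:
        return (self.contig_id, self.start, self.end, self.gene_strand)

    def __len__(self) -> int:
        return len(self.sequence)


def read_fasta(path: str, genome_id: str | None = None, circular: bool = False) -> Genome:
    """Read a nucleotide FASTA into a :class:`Genome`.

    Sequences are uppercased; characters outside {A,C,G,T,N} are rejected with
    an error naming the offending record.  Record order is preserved.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise FastaFormatError(f"{path}: no FASTA records")
    contigs: dict[str, str] = {}
    for rec in records:
        seq = str(rec.seq).upper()
        if not seq:
            raise FastaFormatError(f"record {rec.id!r}: empty sequence")
        bad = set(seq) - VALID_NT
        if bad:
            raise FastaFormatError(
                f"record {rec.id!r}: non-nucleotide characters {sorted(bad)}"
            )
        if rec.id in contigs:
            raise FastaFormatError(f"duplicate contig id {rec.id!r}")
        contigs[rec.id] = seq
    gid = genome_id or os.path.splitext(os.path.basename(str(path)))[0]
    return Genome(gid, contigs, {cid: circular for cid in contigs})


def write_fasta(genome: Genome, path: str, width: int = 70) -> None:
    with open(path, "w") as fh:
        for cid, seq in genome.contigs.items():
            fh.write(f">{cid}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def _feature_sort_key(f: GeneFeature) -> tuple:
    return (f.contig_id, f.start, f.end, f.gene_id)


def read_features(
    path: str,
    dialect: str = "gff3",
    genome: Genome | None = None,
    genome_id: str | None = None,
) -> list[GeneFeature]:
    """Read gene features from GFF3 or the documented TSV dialect.

    Both dialects use 1-based closed coordinates on disk; the returned
    features are 0-based half-open and sorted by (contig, start).
    """
    if dialect == "gff3":
        feats = _read_features_gff3(path, genome_id)
    elif dialect == "tsv":
        feats = _read_features_tsv(path, genome_id)
    else:
        raise ValueError(f"unknown feature dialect {dialect!r}")
    seen: set[str] = set()
    for f in feats:
        if f.gene_id in seen:
            raise FeatureFormatError(f"duplicate gene id {f.gene_id!r}")
        seen.add(f.gene_id)
        if genome is not None:
            if f.contig_id not in genome.contigs:
                raise FeatureFormatError(
                    f"gene {f.gene_id!r}: unknown contig {f.contig_id!r}"
                )
            if f.end > genome.length(f.contig_id):
                raise FeatureFormatError(
                    f"gene {f.gene_id!r}: end {f.end} beyond contig length "
                    f"{genome.length(f.contig_id)}"
                )
    return sorted(feats, key=_feature_sort_key)


def _read_features_gff3(path: str, genome_id: str | None) -> list[GeneFeature]:
    gid = genome_id or os.path.splitext(os.path.basename(str(path)))[0]
    db = gffutils.create_db(str(path), ":memory:", keep_order=True, merge_strategy="error")
    feats = []
    for f in db.all_features():
        if f.featuretype not in _FEATURE_TYPES:
            continue
        fid = f.attributes.get("ID", [f.id])[0]
        if f.strand not in ("+", "-"):
            raise FeatureFormatError(f"gene {fid!r}: unknown strand {f.strand!r}")
        if f.start > f.end:
            raise FeatureFormatError(f"gene {fid!r}: start {f.start} > end {f.end}")
        feats.append(
            GeneFeature(
                gene_id=fid,
                genome_id=gid,
                contig_id=f.seqid,
                start=f.start - 1,
                end=f.end,
                strand=f.strand,
                product=f.attributes.get("product", [""])[0],
                role=f.attributes.get("role", [None])[0],
            )
        )
    return feats


def _read_features_tsv(path: str, genome_id: str | None) -> list[GeneFeature]:
    gid = genome_id or os.path.splitext(os.path.basename(str(path)))[0]
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"gene_id", "contig", "start", "end", "strand"}
    missing = required - set(df.columns)
    if missing:
        raise FeatureFormatError(f"TSV feature file missing columns: {sorted(missing)}")
    feats = []
    for row in df.itertuples(index=False):
        try:
            start1, end1 = int(row.start), int(row.end)
        except ValueError as exc:
            raise FeatureFormatError(f"gene {row.gene_id!r}: non-integer coordinate") from exc
        if row.strand not in ("+", "-"):
            raise FeatureFormatError(f"gene {row.gene_id!r}: unknown strand {row.strand!r}")
        if start1 > end1:
            raise FeatureFormatError(f"gene {row.gene_id!r}: start {start1} > end {end1}")
        feats.append(
            GeneFeature(
                gene_id=str(row.gene_id),
                genome_id=gid,
                contig_id=str(row.contig),
                start=start1 - 1,
                end=end1,
                strand=str(row.strand),
                product=str(getattr(row, "product", "") or ""),
                role=(str(row.role) if "role" in df.columns and pd.notna(row.role) else None),
            )
        )
    return feats


def write_features_tsv(features: list[GeneFeature], path: str) -> None:
    rows = [
        {
            "gene_id": f.gene_id,
            "contig": f.contig_id,
            "start": f.start + 1,
            "end": f.end,
            "strand": f.strand,
            "product": f.product,
            "role": f.role or "",
        }
        for f in sorted(features, key=_feature_sort_key)
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def extract_upstream(
    genome: Genome,
    features: list[GeneFeature],
    gene_id: str,
    window: int = 300,
    min_len: int = 20,
    clip_at_neighbor: bool = True,
    wrap_circular: bool = False,
) -> UpstreamRegion:
    """Extract up to ``window`` bp 5' of a gene, 5'->3' on its coding strand.

    For a + strand gene the slice is [max(0, start-window), start); for a -
    strand gene it is the reverse complement of [end, min(L, end+window)).
    With ``clip_at_neighbor`` the slice additionally stops at the nearest
    annotated gene boundary; ``truncated`` is True iff the window was clipped
    by a neighbor or the contig edge.  Regions shorter than ``min_len`` raise
    :class:`RegionTooShortError`.

    ``wrap_circular`` lets the window wrap the origin of a circular contig
    (recorded with out-of-range interval bounds interpreted modulo the contig
    length); by default extraction never wraps.
    """
    if window <= 0:
        raise ValueError("window must be positive")
    by_id = {f.gene_id: f for f in features}
    if gene_id not in by_id:
        raise UnknownGeneError(gene_id)
    gene = by_id[gene_id]
    contig_seq = genome.contigs[gene.contig_id]
    L = len(contig_seq)
    neighbors = [f for f in features if f.contig_id == gene.contig_id and f.gene_id != gene_id]
    wrap_ok = wrap_circular and genome.circular.get(gene.contig_id, False)

    truncated = False
    if gene.strand == "+":
        lo, hi = gene.start - window, gene.start
        if clip_at_neighbor:
            prev_end = max((f.end for f in neighbors if f.end <= gene.start), default=None)
            if prev_end is not None and prev_end > lo:
                lo, truncated = prev_end, True
        if lo < 0:
            if wrap_ok and not truncated and window < L:
                seq = contig_seq[lo % L :] + contig_seq[:hi]
            else:
                lo, truncated = 0, True
                seq = contig_seq[lo:hi]
        else:
            seq = contig_seq[lo:hi]
    else:
        lo, hi = gene.end, gene.end + window
        if clip_at_neighbor:
            next_start = min((f.start for f in neighbors if f.start >= gene.end), default=None)
            if next_start is not None and next_start < hi:
                hi, truncated = next_start, True
        if hi > L:
            if wrap_ok and not truncated and window < L:
                seq = revcomp(contig_seq[lo:] + contig_seq[: hi % L])
            else:
                hi, truncated = L, True
                seq = revcomp(contig_seq[lo:hi])
        else:
            seq = revcomp(contig_seq[lo:hi])

    if len(seq) < min_len:
        raise RegionTooShortError(
            f"upstream region of {gene_id!r} is {len(seq)} bp < min_len {min_len}"
        )
    return UpstreamRegion(
        gene_id=gene_id,
        genome_id=gene.genome_id,
        contig_id=gene.contig_id,
        start=lo,
        end=hi,
        gene_strand=gene.strand,
        sequence=seq,
        truncated=truncated,
    )


def write_sites_gff(hits: list, path: str) -> None:
    """Write candidate binding sites as GFF3 (type TF_binding_site).

    Coordinates are 1-based closed; the score column carries the additive
    site score and the attributes carry the target operon leader(s), the
    standardized z-score (when set) and the site sequence.  Round-trips
    through :func:`read_sites_gff`.
    """
    ordered = sorted(hits, key=lambda h: (h.genome_id, h.contig_id, h.start, h.strand))
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for i, h in enumerate(ordered):
            attrs = [
                f"ID=site{i:05d}",
                f"genome_id={h.genome_id}",
                f"target={','.join(h.targets)}",
                f"sequence={h.sequence}",
            ]
            if h.z is not None:
                attrs.append(f"z={h.z!r}")
            if h.group_id is not None:
                attrs.append(f"group_id={h.group_id}")
            fh.write(
                "\t".join(
                    [
                        h.contig_id,
                        "regulonkit",
                        "TF_binding_site",
                        str(h.start + 1),
                        str(h.start + h.width),
                        repr(float(h.score)),
                        h.strand,
                        ".",
                        ";".join(attrs),
                    ]
                )
                + "\n"
            )


def read_sites_gff(path: str) -> list:
    """Read a TF_binding_site GFF3 written by :func:`write_sites_gff`."""
    from .scan import SiteHit  # local import: scan depends on this module

    hits = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            cols = line.rstrip("\n").split("\t")
            if len(cols) != 9 or cols[2] != "TF_binding_site":
                continue
            attrs = dict(kv.split("=", 1) for kv in cols[8].split(";") if "=" in kv)
            start1, end1 = int(cols[3]), int(cols[4])
            hits.append(
                SiteHit(
                    genome_id=attrs.get("genome_id", ""),
                    contig_id=cols[0],
                    start=start1 - 1,
                    width=end1 - start1 + 1,
                    strand=cols[6],
                    score=float(cols[5]),
                    sequence=attrs.get("sequence", ""),
                    targets=[t for t in attrs.get("target", "").split(",") if t],
                    group_id=attrs.get("group_id"),
                    z=float(attrs["z"]) if "z" in attrs else None,
                )
            )
    return hits
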