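"""Synthetic multi-genome datasets with known operons, families and sites.

The generator emulates the structure of a clostridial comparative-genomics
study: several AT-rich genomes (default 30% GC) whose genes are laid out in
operons on both strands, a set of role-labelled gene families with
per-genome presence/absence, and exactly one transcription-factor binding
site planted in the upstream window of each regulated operon leader.  Sites
are sampled from a case-coded consensus with an inverted-repeat-plus-spacer
architecture: uppercase positions emit the consensus base with probability
``p_upper``, lowercase with ``p_lower``, and 'n' positions emit the
background.  Decoy sites planted upstream of unrelated singleton genes in a
single genome each exercise the cross-genome consistency filter.

Every pipeline stage can therefore be scored against exact ground truth,
and generation is byte-identical under a fixed seed.
"""

from __future__ import annotations

import dataclasses
import json
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genome_io import GeneFeature, Genome, write_fasta
from .motif import PWM
from .seqs import BASE_INDEX, BASES, background_from_gc, decode, encode, random_sequence, revcomp

#: 25-bp inverted repeat recognized by group-1 clostridial xylose repressors
#: (two 10-bp arms around a 5-bp uninformative spacer).
CLOSTRIDIAL_XYLR_CONSENSUS = "ACTTattAAAnnnnnTTTaaAAAgt"


class ConfigError(ValueError):
    pass


@dataclass
class MotifSpec:
    """Case-coded consensus (or explicit PWM) with emission strengths."""

    consensus: str = CLOSTRIDIAL_XYLR_CONSENSUS
    p_upper: float = 0.95
    p_lower: float = 0.75
    palindrome: tuple[int, int] | None = (10, 5)
    pwm: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.pwm is not None:
            return
        bad = set(self.consensus) - set("ACGTacgtn")
        if bad:
            raise ConfigError(f"consensus characters outside alphabet: {sorted(bad)}")
        if not 0 < self.p_lower <= self.p_upper <= 1:
            raise ConfigError("need 0 < p_lower <= p_upper <= 1")
        if self.palindrome is not None:
            arm, spacer = self.palindrome
            if len(self.consensus) != 2 * arm + spacer:
                raise ConfigError(
                    f"consensus length {len(self.consensus)} != 2*{arm}+{spacer}"
                )

    @property
    def width(self) -> int:
        return self.pwm.shape[0] if self.pwm is not None else len(self.consensus)


def clostridial_xylr_spec() -> MotifSpec:
    """The default 25-bp clostridial inverted-repeat motif specification."""
    return MotifSpec()


def consensus_to_pwm(spec: MotifSpec, background: np.ndarray) -> PWM:
    """Per-column emission distributions implied by a case-coded consensus.

    An uppercase column puts ``p_upper`` on the consensus base and spreads
    the remainder over the other three bases proportionally to the
    background (so AT-rich backgrounds behave realistically); lowercase uses
    ``p_lower``; 'n' columns equal the background.
    """
    q = np.asarray(background, dtype=float)
    if spec.pwm is not None:
        return PWM(np.asarray(spec.pwm, dtype=float), q)
    if max(spec.p_lower, spec.p_upper) < q.max():
        raise ConfigError("emission probabilities must be >= the background maximum")
    rows = []
    for ch in spec.consensus:
        if ch == "n":
            rows.append(q.copy())
            continue
        p = spec.p_upper if ch.isupper() else spec.p_lower
        b = BASE_INDEX[ch.upper()]
        row = np.empty(4)
        others = [i for i in range(4) if i != b]
        rest = q[others] / q[others].sum()
        row[b] = p
        row[others] = (1 - p) * rest
        rows.append(row)
    return PWM(np.vstack(rows), q)


def sample_site(spec: MotifSpec, rng: np.random.Generator, background: np.ndarray | None = None) -> str:
    """Draw one site, each column independently from its emission distribution."""
    q = background_from_gc(0.30) if background is None else np.asarray(background, float)
    freqs = consensus_to_pwm(spec, q).frequencies
    draws = [int(rng.choice(4, p=row / row.sum())) for row in freqs]
    return "".join(BASES[d] for d in draws)


def planted_training_regions(
    n_regions: int = 40,
    length: int = 180,
    spec: MotifSpec | None = None,
    gc: float = 0.30,
    seed: int = 0,
) -> list[str]:
    """Background regions with one sampled site embedded in each.

    The standing benchmark for motif discovery: ``n_regions`` i.i.d.
    background sequences at the given GC, each carrying exactly one site
    drawn from the motif spec at a uniform random offset.  Deterministic
    under the seed.
    """
    spec = spec or clostridial_xylr_spec()
    W = spec.width
    if length < W:
        raise ConfigError(f"region length {length} shorter than motif width {W}")
    rng = np.random.default_rng(seed)
    q = background_from_gc(gc)
    regions = []
    for _ in range(n_regions):
        bg = decode(random_sequence(length, q, rng))
        site = sample_site(spec, rng, q)
        off = int(rng.integers(0, length - W + 1))
        regions.append(bg[:off] + site + bg[off + W :])
    return regions


#: Default regulated operon templates: gene roles in coding (5'->3') order,
#: leader first.  Mirrors a xylose/xyloside-style pathway: isomerase +
#: kinase operon, transporters, xylosidases, an ABC cassette, and generic
#: pathway roles; the regulator itself is appended when
#: ``include_regulator`` is on (autoregulation).
DEFAULT_REGULATED_OPERONS: tuple[tuple[str, ...], ...] = (
    ("xylA-II", "xylB"),
    ("xylT",),
    ("xylA-I",),
    ("xynT", "xynB"),
    ("xylS",),
    ("xynA1", "xynA2", "xynA3"),
    ("xutA",),
    ("xutB",),
    ("xutC", "xutD"),
    ("xutE",),
    ("xutF", "xutG"),
    ("xutH",),
    ("xutI",),
    ("xutJ",),
)

REGULATOR_ROLE = "xylR"


@dataclass
class PlantConfig:
    """Geometry, composition and planting parameters for one dataset.

    ``site_offset`` is the (min, max) distance in bp between the planted
    site's 3' end and the leader gene start, measured along the coding
    strand; together with ``inter_operon_gap`` it guarantees the site lies
    inside the (possibly neighbor-clipped) upstream window.
    """

    n_genomes: int = 8
    genes_per_genome: int = 60
    regulated_operons: tuple[tuple[str, ...], ...] = DEFAULT_REGULATED_OPERONS
    include_regulator: bool = True
    gene_length: tuple[int, int] = (300, 900)
    intra_operon_gap: tuple[int, int] = (20, 120)
    inter_operon_gap: tuple[int, int] = (450, 800)
    filler_operon_size: tuple[int, int] = (1, 3)
    site_offset: tuple[int, int] = (30, 200)
    gc: float = 0.30
    presence_prob: float = 0.9
    n_decoys: int = 5
    upstream_window: int = 300
    seed: int = 0

    def all_operon_templates(self) -> tuple[tuple[str, ...], ...]:
        ops = self.regulated_operons
        if self.include_regulator:
            ops = ops + ((REGULATOR_ROLE,),)
        return ops

    def roles(self) -> list[str]:
        return [r for op in self.all_operon_templates() for r in op]

    def validate(self, motif_width: int) -> None:
        if self.n_genomes < 1 or self.genes_per_genome < 1:
            raise ConfigError("need at least one genome and one gene")
        if not 0 <= self.presence_prob <= 1:
            raise ConfigError("presence_prob must be in [0, 1]")
        max_reach = self.site_offset[1] + motif_width
        if max_reach > min(self.upstream_window, self.inter_operon_gap[0]):
            raise ConfigError(
                f"site placement reaches {max_reach} bp upstream but the window is "
                f"{self.upstream_window} bp and the smallest inter-operon gap is "
                f"{self.inter_operon_gap[0]} bp: the motif cannot fit"
            )
        if 2 * max_reach > self.inter_operon_gap[0]:
            # a divergent leader pair can plant two sites into one gap
            raise ConfigError(
                f"two opposing site placements (2 x {max_reach} bp) can collide in the "
                f"smallest inter-operon gap ({self.inter_operon_gap[0]} bp)"
            )
        n_reg = sum(len(op) for op in self.all_operon_templates())
        if n_reg > self.genes_per_genome:
            raise ConfigError("regulated operons alone exceed genes_per_genome")
        roles = self.roles()
        if len(roles) != len(set(roles)):
            raise ConfigError("duplicate role labels across operon templates")


@dataclass
class SyntheticDataset:
    """Generated genomes, features, and exact ground truth tables."""

    config: PlantConfig
    motif_spec: MotifSpec
    genomes: dict[str, Genome]
    features: dict[str, list[GeneFeature]]
    truth_sites: pd.DataFrame
    truth_operons: pd.DataFrame
    truth_orthologs: pd.DataFrame
    truth_regulon: pd.DataFrame

    def genome_ids(self) -> list[str]:
        return list(self.genomes)

    def write(self, outdir: str) -> dict[str, str]:
        os.makedirs(outdir, exist_ok=True)
        paths: dict[str, str] = {}
        for gid, genome in self.genomes.items():
            fna = os.path.join(outdir, f"{gid}.fna")
            gff = os.path.join(outdir, f"{gid}.gff")
            write_fasta(genome, fna)
            _write_gff(self.features[gid], gff)
            paths[f"{gid}.fna"] = fna
            paths[f"{gid}.gff"] = gff
        for name, df in (
            ("truth_sites", self.truth_sites),
            ("truth_operons", self.truth_operons),
            ("truth_orthologs", self.truth_orthologs),
            ("truth_regulon", self.truth_regulon),
        ):
            p = os.path.join(outdir, f"{name}.tsv")
            df.to_csv(p, sep="\t", index=False)
            paths[f"{name}.tsv"] = p
        cfg = dataclasses.asdict(self.config)
        cfg_path = os.path.join(outdir, "config.json")
        with open(cfg_path, "w") as fh:
            json.dump(cfg, fh, indent=1, default=list)
        paths["config.json"] = cfg_path
        return paths


def _write_gff(features: list[GeneFeature], path: str) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for f in features:
            attrs = [f"ID={f.gene_id}"]
            if f.role:
                attrs.append(f"role={f.role}")
            if f.product:
                attrs.append(f"product={f.product}")
            fh.write(
                "\t".join(
                    [
                        f.contig_id,
                        "regulonkit_synth",
                        "gene",
                        str(f.start + 1),
                        str(f.end),
                        ".",
                        f.strand,
                        ".",
                        ";".join(attrs),
                    ]
                )
                + "\n"
            )


def _draw(rng: np.random.Generator, bounds: tuple[int, int]) -> int:
    return int(rng.integers(bounds[0], bounds[1] + 1))


def generate_genome_set(
    config: PlantConfig, motif_spec: MotifSpec | None = None, outdir: str | None = None
) -> SyntheticDataset:
    """Generate genomes with operon layouts, families and planted sites.

    Exactly one site is planted per regulated operon leader per genome where
    the operon is present; sequence background is i.i.d. at the configured
    GC.  Output is deterministic (byte-identical files) under a fixed seed.
    """
    spec = motif_spec or clostridial_xylr_spec()
    W = spec.width
    config.validate(W)
    rng = np.random.default_rng(config.seed)
    q = background_from_gc(config.gc)
    templates = config.all_operon_templates()

    decoy_genomes = rng.integers(0, config.n_genomes, size=config.n_decoys)

    genomes: dict[str, Genome] = {}
    features: dict[str, list[GeneFeature]] = {}
    site_rows, operon_rows, ortho_rows, regulon_rows = [], [], [], []

    for g_idx in range(config.n_genomes):
        gid = f"g{g_idx + 1:02d}"
        contig = f"{gid}_c1"
        present = rng.random(len(templates)) < config.presence_prob

        # operon slots: (roles tuple or None for filler)
        slots: list[tuple[str, ...] | None] = [
            templates[i] for i in range(len(templates)) if present[i]
        ]
        n_regulated_genes = sum(len(t) for t in slots)
        n_filler = config.genes_per_genome - n_regulated_genes
        while n_filler > 0:
            size = min(_draw(rng, config.filler_operon_size), n_filler)
            slots.append(None if size == 1 else tuple([None] * size))
            n_filler -= size
        order = rng.permutation(len(slots))

        feats: list[GeneFeature] = []
        plant_jobs = []  # (leader feature, roles tuple, is_decoy)
        filler_leaders: list[GeneFeature] = []
        counter = 0
        pos = _draw(rng, config.inter_operon_gap)
        for slot_i in order:
            slot = slots[slot_i]
            size = 1 if slot is None else len(slot)
            roles = slot if isinstance(slot, tuple) and slot and isinstance(slot[0], str) else None
            strand = "+" if rng.random() < 0.5 else "-"
            boxes = []
            for k in range(size):
                glen = _draw(rng, config.gene_length)
                boxes.append((pos, pos + glen))
                pos += glen
                if k < size - 1:
                    pos += _draw(rng, config.intra_operon_gap)
            pos += _draw(rng, config.inter_operon_gap)
            operon_feats = []
            for k, (s, e) in enumerate(boxes):
                coding_index = k if strand == "+" else size - 1 - k
                role = roles[coding_index] if roles else None
                counter += 1
                f = GeneFeature(
                    gene_id=f"{gid}_g{counter:03d}",
                    genome_id=gid,
                    contig_id=contig,
                    start=s,
                    end=e,
                    strand=strand,
                    product=(f"{role} protein" if role else "hypothetical protein"),
                    role=role,
                )
                feats.append(f)
                operon_feats.append(f)
            coding = operon_feats if strand == "+" else operon_feats[::-1]
            leader = coding[0]
            operon_rows.append(
                {
                    "genome": gid,
                    "contig": contig,
                    "strand": strand,
                    "leader": leader.gene_id,
                    "members": ",".join(f.gene_id for f in coding),
                    "regulated": bool(roles),
                    "roles": ",".join(roles) if roles else "",
                }
            )
            if roles:
                plant_jobs.append((leader, roles, False))
                for f in coding:
                    ortho_rows.append({"role": f.role, "genome": gid, "gene": f.gene_id})
            elif size == 1:
                filler_leaders.append(leader)

        n_decoys_here = int((decoy_genomes == g_idx).sum())
        if n_decoys_here > len(filler_leaders):
            raise ConfigError("not enough singleton filler genes to host decoy sites")
        if n_decoys_here:
            picks = rng.choice(len(filler_leaders), size=n_decoys_here, replace=False)
            for p in sorted(int(x) for x in picks):
                plant_jobs.append((filler_leaders[p], None, True))

        L = pos
        seq = random_sequence(L, q, rng)
        for leader, roles, is_decoy in plant_jobs:
            site = sample_site(spec, rng, q)
            u = _draw(rng, config.site_offset)
            if leader.strand == "+":
                start = leader.start - u - W
                strand = "+"
                seq[start : start + W] = encode(site)
            else:
                start = leader.end + u
                strand = "-"
                seq[start : start + W] = encode(revcomp(site))
            site_rows.append(
                {
                    "genome": gid,
                    "contig": contig,
                    "start": start,
                    "end": start + W,
                    "strand": strand,
                    "sequence": site,
                    "leader": leader.gene_id,
                    "roles": ",".join(roles) if roles else "",
                    "is_decoy": is_decoy,
                }
            )
            if not is_decoy:
                regulon_rows.append(
                    {"genome": gid, "leader": leader.gene_id, "roles": ",".join(roles)}
                )

        genomes[gid] = Genome(gid, {contig: decode(seq)})
        features[gid] = feats

    cols_sites = ["genome", "contig", "start", "end", "strand", "sequence", "leader", "roles", "is_decoy"]
    dataset = SyntheticDataset(
        config=config,
        motif_spec=spec,
        genomes=genomes,
        features=features,
        truth_sites=pd.DataFrame(site_rows, columns=cols_sites),
        truth_operons=pd.DataFrame(
            operon_rows,
            columns=["genome", "contig", "strand", "leader", "members", "regulated", "roles"],
        ),
        truth_orthologs=pd.DataFrame(ortho_rows, columns=["role", "genome", "gene"]),
        truth_regulon=pd.DataFrame(regulon_rows, columns=["genome", "leader", "roles"]),
    )
    if outdir is not None:
        dataset.write(outdir)
    return dataset
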