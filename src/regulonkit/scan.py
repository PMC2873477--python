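"""Genome scanning for candidate binding sites above the training threshold.

Scanning scores every width-W window on both strands and reports windows at
or above the model threshold (the lowest training-site score).  The default
mode scans only the upstream regions of operon leaders, which is where
bacterial regulatory sites live; whole-genome scanning is available for a
second "additional candidate sites" pass.  Both the raw additive score and
a background-standardized z-score are reported; thresholding is always on
the raw score.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .context import predict_operons
from .genome_io import Genome, GeneFeature, RegionTooShortError, UpstreamRegion, extract_upstream
from .motif import MotifModel, window_scores
from .seqs import encode, revcomp


@dataclass
class SiteHit:
    """A scored candidate site mapped back to genome coordinates.

    ``start`` is 0-based on the forward strand of the contig; ``sequence``
    is the site as read on ``strand`` (i.e. the scored orientation).
    ``targets`` lists the operon leader gene(s) whose upstream window
    contains the site — two leaders for a shared divergent promoter.
    """

    genome_id: str
    contig_id: str
    start: int
    width: int
    strand: str
    score: float
    sequence: str
    targets: list[str] = field(default_factory=list)
    group_id: str | None = None
    z: float | None = None

    @property
    def end(self) -> int:
        return self.start + self.width


def _sort_key(h: SiteHit) -> tuple:
    return (h.genome_id, h.contig_id, h.start, h.strand, tuple(h.targets))


def _resolve_overlaps(cands: list[SiteHit], min_overlap_frac: float = 0.5) -> list[SiteHit]:
    """Greedy best-first: keep a hit unless it overlaps a kept hit >= 50%.

    Candidate order is by descending score, then lowest coordinate, then +
    strand, making tie resolution deterministic.
    """
    kept: list[SiteHit] = []
    for h in sorted(cands, key=lambda h: (-h.score, h.start, h.strand != "+")):
        min_ov = min_overlap_frac * h.width
        ok = True
        for k in kept:
            if k.contig_id != h.contig_id:
                continue
            ov = min(k.end, h.end) - max(k.start, h.start)
            if ov >= min_ov:
                ok = False
                break
        if ok:
            kept.append(h)
    return kept


def _region_to_genome(region: UpstreamRegion, offset: int, strand_idx: int, W: int):
    """Map a window (offset, scanned strand) in region space to genome space."""
    L = len(region.sequence)
    if region.gene_strand == "+":
        if strand_idx == 0:
            return region.start + offset, "+"
        return region.start + (L - offset - W), "-"
    # region sequence is the reverse complement of the genome slice
    if strand_idx == 0:
        return region.end - offset - W, "-"
    return region.start + offset, "+"


def scan_regions(
    model: MotifModel,
    regions: list[UpstreamRegion],
    resolve_overlaps: bool = True,
    min_overlap_frac: float = 0.5,
    group_id: str | None = None,
) -> list[SiteHit]:
    """Scan upstream regions on both strands; report windows >= threshold.

    Per region, overlapping hits are resolved to the best-scoring one
    (ties -> lowest coordinate, then + strand).  Coordinates are mapped back
    to genome space.  Regions shorter than the motif width are skipped with
    a warning.
    """
    W = model.width
    hits: list[SiteHit] = []
    for region in regions:
        if len(region.sequence) < W:
            warnings.warn(
                f"region {region.gene_id!r} shorter than motif width {W}; skipped",
                stacklevel=2,
            )
            continue
        cands: list[SiteHit] = []
        for strand_idx, seq in ((0, region.sequence), (1, revcomp(region.sequence))):
            scores = window_scores(model.pwm, encode(seq))
            for off in np.flatnonzero(scores >= model.threshold):
                off = int(off)
                gstart, gstrand = _region_to_genome(region, off, strand_idx, W)
                cands.append(
                    SiteHit(
                        genome_id=region.genome_id,
                        contig_id=region.contig_id,
                        start=gstart,
                        width=W,
                        strand=gstrand,
                        score=float(scores[off]),
                        sequence=seq[off : off + W],
                        targets=[region.gene_id],
                        group_id=group_id,
                    )
                )
        if resolve_overlaps:
            cands = _resolve_overlaps(cands, min_overlap_frac)
        hits.extend(cands)
    return sorted(hits, key=_sort_key)


def _merge_duplicate_hits(hits: list[SiteHit]) -> list[SiteHit]:
    """Merge hits at identical coordinates (shared divergent promoters)."""
    merged: dict[tuple, SiteHit] = {}
    for h in hits:
        key = (h.genome_id, h.contig_id, h.start, h.strand)
        if key in merged:
            merged[key].targets = sorted(set(merged[key].targets) | set(h.targets))
        else:
            merged[key] = h
    return sorted(merged.values(), key=_sort_key)


def upstream_regions_of_leaders(
    genome: Genome,
    features: list[GeneFeature],
    leaders: list[str],
    window: int = 300,
    min_len: int = 20,
    clip_at_neighbor: bool = True,
) -> list[UpstreamRegion]:
    """Upstream regions for a list of operon leaders; too-short ones skipped."""
    regions = []
    for leader in leaders:
        try:
            regions.append(
                extract_upstream(
                    genome, features, leader, window=window, min_len=min_len,
                    clip_at_neighbor=clip_at_neighbor,
                )
            )
        except RegionTooShortError:
            warnings.warn(f"upstream region of {leader!r} too short; skipped", stacklevel=2)
    return regions


def scan_genome(
    model: MotifModel,
    genome: Genome,
    features: list[GeneFeature],
    mode: str = "upstream_only",
    operons=None,
    window: int = 300,
    clip_at_neighbor: bool = True,
    max_gap_bp: int = 150,
    resolve_overlaps: bool = True,
    group_id: str | None = None,
) -> list[SiteHit]:
    """Scan one genome in ``upstream_only`` or ``whole_genome`` mode.

    ``upstream_only`` composes upstream extraction over operon leaders with
    region scanning; a site falling in the shared window of a divergent gene
    pair is reported once with both leaders as targets.  ``whole_genome``
    scans contigs directly and assigns targets only to hits contained in an
    upstream window.  Output is sorted by (contig, start).
    """
    W = model.width
    if operons is None:
        operons = predict_operons(features, max_gap_bp=max_gap_bp)
    leaders = [op.leader_gene_id for op in operons]

    if mode == "upstream_only":
        regions = upstream_regions_of_leaders(
            genome, features, leaders, window=window, min_len=W,
            clip_at_neighbor=clip_at_neighbor,
        )
        hits = scan_regions(
            model, regions, resolve_overlaps=resolve_overlaps, group_id=group_id
        )
        return _merge_duplicate_hits(hits)

    if mode != "whole_genome":
        raise ValueError(f"unknown scan mode {mode!r}")

    windows_by_leader = {}
    for r in upstream_regions_of_leaders(
        genome, features, leaders, window=window, min_len=W,
        clip_at_neighbor=clip_at_neighbor,
    ):
        windows_by_leader[r.gene_id] = (r.contig_id, r.start, r.end)

    hits = []
    for contig_id, seq in genome.contigs.items():
        L = len(seq)
        cands = []
        for strand_idx, s in ((0, seq), (1, revcomp(seq))):
            scores = window_scores(model.pwm, encode(s))
            for off in np.flatnonzero(scores >= model.threshold):
                off = int(off)
                gstart = off if strand_idx == 0 else L - off - W
                cands.append(
                    SiteHit(
                        genome_id=genome.genome_id,
                        contig_id=contig_id,
                        start=gstart,
                        width=W,
                        strand="+" if strand_idx == 0 else "-",
                        score=float(scores[off]),
                        sequence=s[off : off + W],
                        group_id=group_id,
                    )
                )
        if resolve_overlaps:
            cands = _resolve_overlaps(cands)
        for h in cands:
            targets = [
                leader
                for leader, (cid, lo, hi) in windows_by_leader.items()
                if cid == contig_id and lo <= h.start and h.end <= hi
            ]
            h.targets = sorted(targets)
        hits.extend(cands)
    return sorted(hits, key=_sort_key)


def standardize_scores(
    model: MotifModel,
    background: np.ndarray | None = None,
    method: str = "analytic",
    n_samples: int = 10000,
    seed: int = 0,
) -> tuple[float, float]:
    """Mean and SD of the window score under the background model.

    ``analytic`` computes mu = sum_i sum_b q_b w(b,i) and the exact variance
    of the sum of independent per-position terms; ``monte_carlo`` estimates
    both from random width-W windows.  Raises on a degenerate (zero-variance)
    model.
    """
    w = model.pwm.weights
    q = model.pwm.background if background is None else np.asarray(background, dtype=float)
    if method == "analytic":
        mu_pos = (q * w).sum(axis=1)
        var_pos = (q * w**2).sum(axis=1) - mu_pos**2
        mu, var = float(mu_pos.sum()), float(var_pos.sum())
    elif method == "monte_carlo":
        rng = np.random.default_rng(seed)
        draws = rng.choice(4, size=(n_samples, model.width), p=q / q.sum())
        scores = w[np.arange(model.width), draws].sum(axis=1)
        mu, var = float(scores.mean()), float(scores.var())
    else:
        raise ValueError(f"unknown method {method!r}")
    if var <= 0 or not math.isfinite(var):
        raise ValueError("degenerate model: zero background score variance")
    return mu, math.sqrt(var)


def attach_z(hits: list[SiteHit], mu: float, sigma: float) -> list[SiteHit]:
    """Set the standardized z-score on each hit; the raw score is retained."""
    for h in hits:
        h.z = (h.score - mu) / sigma
    return hits
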