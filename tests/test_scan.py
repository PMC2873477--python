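"""Scanner semantics: oracle equivalence, coordinate mapping, z-scores."""

import math

import numpy as np
import pytest

from regulonkit.genome_io import GeneFeature, Genome, UpstreamRegion
from regulonkit.motif import MotifModel, PWM, symmetrize_palindrome
from regulonkit.scan import (
    attach_z,
    scan_genome,
    scan_regions,
    standardize_scores,
)
from regulonkit.seqs import background_from_gc, decode, random_sequence, revcomp
from regulonkit.synthetic import clostridial_xylr_spec, consensus_to_pwm, sample_site


def _toy_model(threshold_quantile=0.6, seed=0):
    """Model built from sampled sites of the clostridial inverted repeat."""
    q = background_from_gc(0.30)
    spec = clostridial_xylr_spec()
    rng = np.random.default_rng(seed)
    counts = np.zeros((25, 4))
    sites = [sample_site(spec, rng, q) for _ in range(60)]
    for s in sites:
        for i, b in enumerate(s):
            counts[i, "ACGT".index(b)] += 1
    pwm = symmetrize_palindrome(PWM.from_counts(counts, q), 10, 5)
    scores = sorted(
        math.fsum(pwm.weights[i, "ACGT".index(b)] for i, b in enumerate(s)) for s in sites
    )
    thr = scores[int(threshold_quantile * len(scores))]
    return MotifModel(pwm=pwm, palindrome=(10, 5), threshold=thr, training_sites=[])


def _region(seq, gene_id="lead", strand="+", start=0, genome_id="g", contig="c1"):
    return UpstreamRegion(
        gene_id=gene_id, genome_id=genome_id, contig_id=contig,
        start=start, end=start + len(seq), gene_strand=strand,
        sequence=seq, truncated=False,
    )


def _oracle_scores(model, seq):
    """Exhaustive both-strand window enumeration with direct weight sums."""
    w = model.pwm.weights
    W = model.width
    out = []
    for p in range(len(seq) - W + 1):
        win = seq[p : p + W]
        for strand, s in (("+", win), ("-", revcomp(win))):
            if "N" in s:
                continue
            out.append((p, strand, math.fsum(w[i, "ACGT".index(b)] for i, b in enumerate(s))))
    return out


class TestScanRegions:
    def test_equals_bruteforce_enumeration(self):
        model = _toy_model()
        rng = np.random.default_rng(12)
        seq = decode(random_sequence(10_000, background_from_gc(0.30), rng))
        hits = scan_regions(model, [_region(seq)], resolve_overlaps=False)
        got = {(h.start, h.strand): h.score for h in hits}
        expected = {
            (p, strand): sc
            for p, strand, sc in _oracle_scores(model, seq)
            if sc >= model.threshold
        }
        assert got == expected  # positions, strands and exact scores

    def test_overlap_resolution_keeps_best(self):
        model = _toy_model()
        rng = np.random.default_rng(12)
        seq = decode(random_sequence(10_000, background_from_gc(0.30), rng))
        resolved = scan_regions(model, [_region(seq)])
        raw = sorted(
            (sc, p, strand)
            for p, strand, sc in _oracle_scores(model, seq)
            if sc >= model.threshold
        )
        # independent greedy: best score first, keep if <50% overlap with kept
        kept = []
        for sc, p, strand in sorted(raw, key=lambda t: (-t[0], t[1], t[2] != "+")):
            if all(min(k[1] + 25, p + 25) - max(k[1], p) < 12.5 for k in kept):
                kept.append((sc, p, strand))
        assert {(h.start, h.strand, h.score) for h in resolved} == {
            (p, strand, sc) for sc, p, strand in kept
        }

    def test_threshold_above_maximum_gives_no_hits(self):
        model = _toy_model()
        model.threshold = float(model.pwm.weights.max(axis=1).sum()) + 1.0
        rng = np.random.default_rng(5)
        seq = decode(random_sequence(2_000, background_from_gc(0.30), rng))
        assert scan_regions(model, [_region(seq)]) == []

    def test_planted_consensus_found_at_planted_offset(self):
        model = _toy_model(threshold_quantile=0.05)
        q = background_from_gc(0.30)
        rng = np.random.default_rng(8)
        site = sample_site(clostridial_xylr_spec(), rng, q)
        bg = decode(random_sequence(300, q, rng))
        seq = bg[:100] + site + bg[125:]
        hits = scan_regions(model, [_region(seq)])
        assert [h.start for h in hits] == [100]
        assert hits[0].sequence == site

    def test_short_region_skipped_with_warning(self):
        model = _toy_model()
        with pytest.warns(UserWarning, match="shorter"):
            assert scan_regions(model, [_region("ACGT" * 5)]) == []

    @pytest.mark.parametrize("gene_strand", ["+", "-"])
    def test_hit_sequence_equals_genome_slice(self, gene_strand):
        model = _toy_model(threshold_quantile=0.1)
        q = background_from_gc(0.30)
        rng = np.random.default_rng(21)
        site = sample_site(clostridial_xylr_spec(), rng, q)
        bg = decode(random_sequence(260, q, rng))
        genome_slice = bg[:80] + site + bg[105:]
        region_seq = genome_slice if gene_strand == "+" else revcomp(genome_slice)
        region = _region(region_seq, strand=gene_strand, start=1000)
        hits = scan_regions(model, [region])
        assert hits
        for h in hits:
            raw = genome_slice[h.start - 1000 : h.end - 1000]
            assert h.sequence == (raw if h.strand == "+" else revcomp(raw))


def _mini_genome(site, gap_layout="divergent"):
    """Two genes sharing one intergenic gap with a planted site in it."""
    q = background_from_gc(0.30)
    rng = np.random.default_rng(17)
    left = decode(random_sequence(500, q, rng))
    gapbg = decode(random_sequence(400, q, rng))
    right = decode(random_sequence(500, q, rng))
    gap = gapbg[:180] + site + gapbg[180 + len(site):]
    seq = left + gap + right
    if gap_layout == "divergent":
        strands = ("-", "+")
    else:
        strands = ("+", "+")
    feats = [
        GeneFeature("gL", "g", "c1", 0, 500, strands[0]),
        GeneFeature("gR", "g", "c1", 900, 1400, strands[1]),
    ]
    return Genome("g", {"c1": seq}), feats


class TestScanGenome:
    def test_no_annotation_upstream_only_gives_no_hits(self):
        model = _toy_model()
        genome = Genome("g", {"c1": "ACGT" * 300})
        assert scan_genome(model, genome, [], mode="upstream_only") == []

    def test_shared_divergent_promoter_lists_both_targets(self):
        model = _toy_model(threshold_quantile=0.1)
        rng = np.random.default_rng(30)
        site = sample_site(clostridial_xylr_spec(), rng, background_from_gc(0.30))
        genome, feats = _mini_genome(site, "divergent")
        hits = scan_genome(model, genome, feats, mode="upstream_only", window=300)
        site_hits = [h for h in hits if h.start == 680]
        assert len(site_hits) == 1
        assert site_hits[0].targets == ["gL", "gR"]

    def test_whole_genome_mirrors_under_reverse_complement(self):
        model = _toy_model(threshold_quantile=0.2)
        rng = np.random.default_rng(9)
        seq = decode(random_sequence(4_000, background_from_gc(0.30), rng))
        genome = Genome("g", {"c1": seq})
        flipped = Genome("g", {"c1": revcomp(seq)})
        fwd = scan_genome(model, genome, [], mode="whole_genome", resolve_overlaps=False)
        rev = scan_genome(model, flipped, [], mode="whole_genome", resolve_overlaps=False)
        L = len(seq)
        mirrored = {
            (L - h.end, "-" if h.strand == "+" else "+", h.score) for h in rev
        }
        assert {(h.start, h.strand, h.score) for h in fwd} == mirrored

    def test_recall_of_planted_sites_on_benchmark(self, benchmark_run):
        # upstream-only scanning with the min-training-score threshold
        ds, result = benchmark_run
        recovered = 0
        planted = ds.truth_sites[~ds.truth_sites.is_decoy]
        for r in planted.itertuples():
            hits = result.hits_by_genome.get(r.genome, [])
            if any(h.contig_id == r.contig and h.start == r.start for h in hits):
                recovered += 1
        assert recovered / len(planted) >= 0.9


class TestStandardizeScores:
    def test_analytic_matches_monte_carlo(self):
        model = _toy_model()
        mu_a, sd_a = standardize_scores(model, method="analytic")
        n = 20_000
        mu_m, sd_m = standardize_scores(model, method="monte_carlo", n_samples=n, seed=2)
        se_mu = sd_a / math.sqrt(n)
        assert abs(mu_a - mu_m) <= 3 * se_mu
        assert abs(sd_a - sd_m) <= 3 * sd_a / math.sqrt(n)  # generous SE for sd

    def test_z_is_affine_and_order_preserving(self):
        model = _toy_model(threshold_quantile=0.1)
        rng = np.random.default_rng(3)
        seq = decode(random_sequence(3_000, background_from_gc(0.30), rng))
        hits = scan_regions(model, [_region(seq)], resolve_overlaps=False)
        mu, sd = standardize_scores(model)
        attach_z(hits, mu, sd)
        assert all(h.z == (h.score - mu) / sd for h in hits)
        by_score = sorted(hits, key=lambda h: h.score)
        by_z = sorted(hits, key=lambda h: h.z)
        assert [id(h) for h in by_score] == [id(h) for h in by_z]

    def test_score_at_background_mean_is_zero(self):
        from regulonkit.scan import SiteHit

        model = _toy_model()
        mu, sd = standardize_scores(model)
        h = SiteHit(genome_id="g", contig_id="c1", start=0, width=25,
                    strand="+", score=mu, sequence="A" * 25)
        attach_z([h], mu, sd)
        assert h.z == 0.0

    def test_degenerate_model_rejected(self):
        q = np.full(4, 0.25)
        pwm = PWM(np.tile(q, (6, 1)), q)
        model = MotifModel(pwm=pwm, palindrome=None, threshold=0.0, training_sites=[])
        with pytest.raises(ValueError, match="degenerate"):
            standardize_scores(model)
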