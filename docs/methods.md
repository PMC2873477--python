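# Methods

This note records the models, the tunable parameters and their defaults,
the numerical choices, and what the synthetic benchmark does and does not
demonstrate. Nothing here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Recognition profile and scoring

Sites are modelled by an independent-columns positional weight matrix. From
counts `n(b, i)` over `N` aligned sites, with pseudocount `c > 0` and a
strictly positive background `q`:

    f(b, i) = (n(b, i) + c·q_b) / (N + c)        (regularized frequency)
    w(b, i) = ln( f(b, i) / q_b )                (positional weight)

A width-`W` window scores `S = Σ_i w(s_i, i)`. Natural log is used for
weights; information content is in bits (`IC_i = Σ_b f log2(f/q_b)`). The
background-proportional pseudocount makes a background-distributed column
exactly neutral (`w = 0`) and keeps weights monotone in counts; any
positive `c` preserves these properties, and `c = 1` is the default.

**Exact arithmetic.** Site scores are computed with correctly rounded
summation (`math.fsum`), so the score of a symmetrized palindromic profile
is bitwise identical under reverse complement (the summands are the same
multiset in reversed order) and scanning is reproducible against naive
enumeration with zero tolerance. The discovery inner loop uses fast
floating-point sums — it only compares windows against each other — and the
final training-site scores and threshold are recomputed exactly.

**N handling.** Genomes may contain `N`; any scan window containing `N`
scores −∞ (skipped) rather than being guessed, and `score_site` rejects
ambiguous bases outright.

## Inverted repeats

Homodimer-bound sites are two reverse-complementary arms around a
low-information spacer. The palindrome constraint is the projection
`P ← ½(P + revcomp-transform(P))` applied to frequencies (and counts), with
the background symmetrized the same way. The projection is a fixed point of
itself and maps spacer columns to spacer columns. Note that the transform
depends only on total width: the arm/spacer split is architectural metadata
used to enumerate candidate widths, not a separate constraint on the fit.

## Motif discovery

For each candidate geometry (total width `W`; by default all arm lengths
7–13 crossed with odd spacers 3, 5, 7 whose width falls in 17–31):

1. **Seeding (best-scoring common word).** Sample 40 candidate windows
   (both strands, all regions); for each, align every region to it by
   minimum Hamming distance and total the agreement `Σ (W − min_dist)`;
   seed the profile from the per-region closest windows to the best
   candidate. Restarts (default 4) draw independent candidate samples.
2. **Iteration.** Alternate: rebuild the profile from the current picks;
   re-pick the best-scoring window per region on either strand (ties →
   lowest offset, then + strand). Stop at a fixed point or when any
   previous assignment state recurs (hard-assignment iterations settle
   into short cycles), or after `max_iter = 200` rounds; non-convergence
   returns the best-so-far with a warning.
3. **Phase polish.** Try shifting the whole alignment by ±1, ±2 columns
   and re-fit if total information improves. A consistently off-by-one
   alignment is a genuine local optimum of step 2.
4. **Symmetrization last.** The alignment itself is fit *without* the
   palindrome constraint; the final profile is then symmetrized.
   Symmetrizing inside the loop creates a phase-blur attractor: an
   alignment globally shifted by one column symmetrizes into a smeared
   profile under which every site is ambiguous between two placements,
   and the smear is self-reinforcing.

Per geometry the restart with the highest total information is kept; the
model is assumed to place exactly one site per region (regions that never
fit are reported, not force-fitted; regions shorter than `W` are excluded
with a warning; at least 4 usable regions are required).

**Width selection.** The selected width maximizes the column-adjusted
information criterion: total IC minus 0.4 bits per column. A column is
kept only if it adds at least 0.4 bits — about half the information of a
weakly conserved position at a 30%-GC background (≈0.5 bits), an order of
magnitude above the positive sampling bias of a background column
estimated from tens of sites (≈0.05 bits at N = 40). A per-column *mean*
criterion was rejected because it is structurally indifferent between
keeping and dropping a strong-plus-weak flank pair (their mean equals the
motif's overall mean), which makes the width decision a coin flip exactly
where it matters.

**Threshold.** The scan threshold is the minimum training-site score of
the selected model. Every training site therefore scores ≥ threshold by
construction, and scan sensitivity degrades gracefully as the training set
becomes more heterogeneous.

## Scanning and z-scores

Default mode scans only upstream regions of operon leaders (where bacterial
regulatory sites act); whole-genome mode exists for a second, exploratory
pass. Overlapping hits within a region are resolved best-first, dropping
any hit that overlaps a kept one by ≥ 50% of the width (ties → lowest
coordinate, then + strand); for a palindromic profile this collapses the
two identical strand readings of one site into the + reading. A site
falling in the shared window of a divergently transcribed pair is reported
once with both leaders as targets.

The z-score standardizes the raw score against the background window
distribution; the analytic moments are `μ = Σ_i Σ_b q_b w(b,i)` and
`σ² = Σ_i Var_q[w(·,i)]` (independent columns), with a Monte-Carlo
estimator available as a cross-check. A zero-variance (degenerate) profile
is an error.

## Upstream regions and operons

Upstream windows default to 300 bp (covering typical bacterial promoter
regions with margin), clipped at the nearest annotated gene boundary by
default (`truncated` flags clipping by a neighbor or contig edge), minimum
20 bp. Whether a window may run into upstream coding sequence is
configurable because conventions differ between studies. Windows never
wrap a circular contig's origin unless explicitly enabled. Internal
coordinates are 0-based half-open; all file interfaces are 1-based closed.

Operons merge adjacent same-strand genes with intergenic gaps ≤ 150 bp, a
standard prokaryotic heuristic; divergent pairs never merge, but a shared
intergenic region can serve both flanking leaders during scanning. The
leader is the most 5' gene on the coding strand. Chromosomal-clustering
evidence reports role-labelled genes within ±5 gene positions by default.

## Orthology and regulator groups

Percent identity comes from global protein alignment with fixed parameters
(BLOSUM62, gap open −11, extend −1), counted over alignment columns
excluding terminal overhangs; `X` never counts as a match; the pair is
canonicalized by lexicographic order before aligning so tie-broken
alternative alignments cannot make identity asymmetric. Orthologs are
mutual best hits at ≥ 30% identity (configurable), closed under single
linkage; genomes contributing more than one gene to a group are flagged as
paralog-ambiguous rather than silently merged. Regulator groups — the
units that train separate motifs — come either from cutting a user-supplied
Newick tree into maximal clades whose internal pairwise identities all
clear the threshold, or from single-linkage identity clustering as the
no-tree fallback. Tree *inference* is out of scope by design.

## Cross-genome confirmation and assignments

For each operon with an upstream hit, support counts the genomes in the
regulator group (including its own) where an ortholog of any operon member
also has an upstream hit; `min_support = 2` by default — one recurrence in
a second genome is what separates a conserved site from a background hit,
and raising the value can only shrink the confirmed set (asserted as a
monotonicity property). Unconfirmed single-genome hits are emitted with
`confirmed = False` rather than suppressed. Autoregulation is operon-level:
a regulator encoded mid-operon counts when its operon leader carries the
site.

Functional assignments attach up to three evidence codes — HOMOLOGY,
CLUSTERING, REGULON (the last requiring a confirmed call) — and a
clustering-only call is flagged as a context-only prediction. When two
genes of one genome share homology for a role but only one has context
support, the unsupported copy is flagged `ambiguous_paralog` with a pointer
to the resolved copy.

## Synthetic benchmark

The generator emulates the structure of an AT-rich multi-genome study:
i.i.d. background at 30% GC; genes laid out in operons on both strands
(gene lengths 300–900 bp, within-operon gaps 20–120 bp, between-operon gaps
450–800 bp — the lower bound guarantees two opposing site placements cannot
collide in one gap); 15 regulated operon templates per genome (pathway-like
role labels, including the regulator itself so autoregulation is testable),
each present per genome with probability 0.9; exactly one site planted per
present regulated leader, 30–200 bp upstream; and 5 decoy sites, each
planted upstream of an orphan gene in a single genome, which exercise the
cross-genome filter. Sites are sampled from the case-coded consensus with
uppercase positions emitting the consensus base at 0.95, lowercase at 0.75
and `n` at background — values chosen to make the three conservation bands
visibly distinct in logos; the non-consensus mass is split proportionally
to the background so AT-rich genomes behave realistically. Generation is
byte-identical under a fixed seed.

What passing the benchmark does **not** show: the generator has no codon
structure, no phylogenetically correlated sequence evolution, no indels in
sites, no overlapping or nested genes, and presence/absence is independent
across genomes rather than tree-shaped. Real-genome performance therefore
hinges on annotation quality and on how well a single additive PWM fits the
real site population, neither of which this benchmark measures.

## Problem sizes

Discovery benchmarks use 40 training regions of 180 bp over the full
geometry grid (a few seconds of CPU); parameter-recovery curves use 20–200
regions of 120 bp at the true geometry; the end-to-end benchmark uses 8
genomes of 60 genes (~50 kb each). These sizes give stable statistics —
recovery error at n = 200 sits near the sampling floor — while keeping the
whole suite fast enough to run on every change.

## Known limitations

Single motif per regulator group (no mixture of motif variants within a
group); one site per region during training (tandem sites are found at scan
time but not modelled jointly); no p-value calibration of scores (z-scores
are moments-based, not tail-calibrated); identity-based regulator grouping
is a crude stand-in for a real phylogeny; BBH orthology ignores synteny and
domain architecture.
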