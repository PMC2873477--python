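"""Recognition profiles (PWMs) and iterative motif discovery.

The model is the classical additive positional-weight profile used in
phylogenetic-footprinting pipelines for bacterial regulons.  A binding-site
alignment of N sites gives per-position counts n(b, i); with pseudocount c
and background base probabilities q_b the positional weight is

    w(b, i) = ln[ (n(b, i) + c * q_b) / ((N + c) * q_b) ]

and a candidate site of width W scores sum_i w(s_i, i).  The scan threshold
is the lowest score observed among the training sites, so every training
site is recovered by construction and the scanner's sensitivity is tied
directly to the heterogeneity of the training alignment.

Homodimeric regulators bind inverted repeats (two arms that are reverse
complements of each other around a low-information spacer); for such motifs
the profile is symmetrized by averaging with its own reverse-complement
transform, which makes site scores strand-invariant.

Weights use natural log; information content uses log2 (bits).
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .seqs import BASES, N_INDEX, encode, revcomp

#: Per-column cost (bits) in the width-selection criterion: a column is
#: worth keeping only if it contributes at least this much information.
#: About half the information of a weakly conserved position at an AT-rich
#: background, and an order of magnitude above the positive sampling bias
#: of a background column estimated from tens of sites.
COLUMN_COST_BITS = 0.4


class DiscoveryError(ValueError):
    pass


@dataclass
class PWM:
    """Per-position base frequencies plus background; weights are derived.

    ``frequencies`` is (W, 4) with rows (positions) summing to 1 in the
    order A, C, G, T.  When built from counts, ``counts`` is retained and
    frequencies are the pseudocount-regularized estimates above.
    """

    frequencies: np.ndarray
    background: np.ndarray
    counts: np.ndarray | None = None
    pseudocount: float = 1.0

    def __post_init__(self) -> None:
        self.frequencies = np.asarray(self.frequencies, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.frequencies.ndim != 2 or self.frequencies.shape[1] != 4:
            raise ValueError("frequencies must have shape (W, 4)")
        if self.background.shape != (4,) or (self.background <= 0).any():
            raise ValueError("background must be 4 strictly positive probabilities")
        sums = self.frequencies.sum(axis=1)
        if np.abs(sums - 1.0).max() > 1e-6:
            raise ValueError("frequency rows must each sum to 1")

    @classmethod
    def from_counts(
        cls, counts: np.ndarray, background: np.ndarray, pseudocount: float = 1.0
    ) -> "PWM":
        counts = np.asarray(counts, dtype=float)
        if pseudocount <= 0:
            raise ValueError("pseudocount must be positive")
        if (counts < 0).any():
            raise ValueError("counts must be non-negative")
        n_sites = counts.sum(axis=1, keepdims=True)
        if (n_sites <= 0).any():
            raise ValueError("zero-site training set")
        q = np.asarray(background, dtype=float)
        freq = (counts + pseudocount * q) / (n_sites + pseudocount)
        return cls(freq, q, counts=counts, pseudocount=pseudocount)

    @property
    def width(self) -> int:
        return self.frequencies.shape[0]

    @property
    def weights(self) -> np.ndarray:
        """(W, 4) natural-log odds; a background-distributed column is all 0."""
        return np.log(self.frequencies / self.background)

    def reverse_complement(self) -> "PWM":
        counts = None if self.counts is None else self.counts[::-1, ::-1].copy()
        return PWM(
            self.frequencies[::-1, ::-1].copy(),
            self.background[::-1].copy(),
            counts=counts,
            pseudocount=self.pseudocount,
        )


def pwm_weights(counts: np.ndarray, pseudocount: float, background: np.ndarray) -> np.ndarray:
    """Positional nucleotide weights from a count matrix (natural log)."""
    return PWM.from_counts(counts, background, pseudocount).weights


def symmetrize_palindrome(pwm: PWM, arm_len: int, spacer_len: int) -> PWM:
    """Project a profile onto the inverted-repeat (palindromic) subspace.

    Averages the matrix with its reverse-complement transform.  The result
    is a fixed point of the operation, and spacer columns map to spacer
    columns.  The background is symmetrized the same way so that weights
    inherit the palindrome exactly.
    """
    if pwm.width != 2 * arm_len + spacer_len:
        raise ValueError(
            f"width {pwm.width} != 2*{arm_len} + {spacer_len} (arm/spacer geometry)"
        )
    q = 0.5 * (pwm.background + pwm.background[::-1])
    freq = 0.5 * (pwm.frequencies + pwm.frequencies[::-1, ::-1])
    counts = None
    if pwm.counts is not None:
        counts = 0.5 * (pwm.counts + pwm.counts[::-1, ::-1])
    return PWM(freq, q, counts=counts, pseudocount=pwm.pseudocount)


def information_content(pwm: PWM) -> tuple[np.ndarray, float]:
    """Per-position relative entropy vs background, in bits, and its total."""
    f, q = pwm.frequencies, pwm.background
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(f > 0, f * np.log2(f / q), 0.0)
    per_pos = terms.sum(axis=1)
    return per_pos, float(per_pos.sum())


def consensus_string(pwm: PWM, upper_thresh: float = 0.9, lower_thresh: float = 0.5) -> str:
    """Case-coded consensus: upper = strong, lower = weak, 'n' = uninformative."""
    if not 0.25 < lower_thresh < upper_thresh <= 1.0:
        raise ValueError("need 0.25 < lower_thresh < upper_thresh <= 1")
    out = []
    for row in pwm.frequencies:
        b = int(np.argmax(row))
        if row[b] >= upper_thresh:
            out.append(BASES[b])
        elif row[b] >= lower_thresh:
            out.append(BASES[b].lower())
        else:
            out.append("n")
    return "".join(out)


def score_site(model_or_pwm, seq: str) -> float:
    """Additive score of one site: the sum of positional nucleotide weights.

    Uses exact (correctly rounded) summation so that for a symmetrized
    palindromic profile score(s) == score(revcomp(s)) bitwise.
    """
    pwm = model_or_pwm.pwm if isinstance(model_or_pwm, MotifModel) else model_or_pwm
    if len(seq) != pwm.width:
        raise ValueError(f"sequence length {len(seq)} != motif width {pwm.width}")
    enc = encode(seq.upper())
    if (enc == N_INDEX).any():
        raise ValueError("sequence contains N; scores are undefined for ambiguous bases")
    w = pwm.weights
    return math.fsum(w[i, enc[i]] for i in range(pwm.width))


def window_scores(pwm: PWM, enc: np.ndarray) -> np.ndarray:
    """Exact scores of every width-W window of an encoded sequence.

    Windows containing N score -inf.  Summation matches :func:`score_site`.
    """
    W = pwm.width
    L = enc.size
    n_win = L - W + 1
    if n_win <= 0:
        return np.empty(0)
    wins = np.lib.stride_tricks.sliding_window_view(enc, W)
    valid = (wins != N_INDEX).all(axis=1)
    w = pwm.weights
    out = np.full(n_win, -np.inf)
    cols = np.arange(W)
    gathered = w[cols, np.where(wins == N_INDEX, 0, wins)]
    for i in np.flatnonzero(valid):
        out[i] = math.fsum(gathered[i])
    return out


@dataclass
class TrainingSite:
    """Where the model placed its site in one training region."""

    region_id: str
    offset: int
    strand: str
    score: float
    sequence: str


@dataclass
class MotifModel:
    """A trained recognition profile with its scan threshold.

    ``threshold`` is the minimum score over the training sites; every
    training site therefore scores >= threshold by construction.
    """

    pwm: PWM
    palindrome: tuple[int, int] | None
    threshold: float
    training_sites: list[TrainingSite]
    converged: bool = True
    excluded_regions: list[str] = field(default_factory=list)
    selection_score: float | None = None

    @property
    def width(self) -> int:
        return self.pwm.width

    def score(self, seq: str) -> float:
        return score_site(self.pwm, seq)

    def consensus(self, upper_thresh: float = 0.9, lower_thresh: float = 0.5) -> str:
        return consensus_string(self.pwm, upper_thresh, lower_thresh)

    def information_content(self) -> tuple[np.ndarray, float]:
        return information_content(self.pwm)

    def to_json(self) -> str:
        per_pos, total = self.information_content()
        payload = {
            "width": self.width,
            "palindrome": list(self.palindrome) if self.palindrome else None,
            "threshold": self.threshold,
            "background": self.pwm.background.tolist(),
            "pseudocount": self.pwm.pseudocount,
            "frequencies": self.pwm.frequencies.tolist(),
            "counts": None if self.pwm.counts is None else self.pwm.counts.tolist(),
            "information_bits": {"per_position": per_pos.tolist(), "total": total},
            "consensus": self.consensus(),
            "converged": self.converged,
            "excluded_regions": self.excluded_regions,
            "selection_score": self.selection_score,
            "training_sites": [
                {
                    "region_id": t.region_id,
                    "offset": t.offset,
                    "strand": t.strand,
                    "score": t.score,
                    "sequence": t.sequence,
                }
                for t in self.training_sites
            ],
        }
        return json.dumps(payload, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "MotifModel":
        d = json.loads(text)
        counts = None if d["counts"] is None else np.asarray(d["counts"])
        pwm = PWM(
            np.asarray(d["frequencies"]),
            np.asarray(d["background"]),
            counts=counts,
            pseudocount=d["pseudocount"],
        )
        return cls(
            pwm=pwm,
            palindrome=tuple(d["palindrome"]) if d["palindrome"] else None,
            threshold=d["threshold"],
            training_sites=[TrainingSite(**t) for t in d["training_sites"]],
            converged=d["converged"],
            excluded_regions=d["excluded_regions"],
            selection_score=d["selection_score"],
        )


def pfm_text(pwm: PWM, name: str = "motif") -> str:
    """TRANSFAC-like position frequency matrix rendering."""
    lines = [f"ID {name}", f"BF background A:{pwm.background[0]:.4f} C:{pwm.background[1]:.4f} "
             f"G:{pwm.background[2]:.4f} T:{pwm.background[3]:.4f}", "P0\tA\tC\tG\tT"]
    mat = pwm.counts if pwm.counts is not None else pwm.frequencies
    for i, row in enumerate(mat, start=1):
        lines.append(f"{i:02d}\t" + "\t".join(f"{v:.4f}" for v in row))
    lines.append("XX")
    return "\n".join(lines) + "\n"


def logo_data(pwm: PWM):
    """Per-column letter heights (frequency x column IC, bits) as a DataFrame."""
    import pandas as pd

    per_pos, _ = information_content(pwm)
    heights = pwm.frequencies * per_pos[:, None]
    return pd.DataFrame(heights, columns=list(BASES)).rename_axis("position")


@dataclass
class PalindromeSearch:
    """Inverted-repeat geometry grid for discovery: arm lengths x spacers."""

    arm_range: tuple[int, int] = (7, 13)
    spacers: tuple[int, ...] = (3, 5, 7)


# ---------------------------------------------------------------------------
# iterative discovery


def _fast_window_scores(weights: np.ndarray, wins: np.ndarray, valid: np.ndarray) -> np.ndarray:
    W = weights.shape[0]
    safe = np.where(wins == N_INDEX, 0, wins)
    s = weights[np.arange(W), safe].sum(axis=1)
    s[~valid] = -np.inf
    return s


def _region_windows(enc: np.ndarray, W: int):
    wins = np.lib.stride_tricks.sliding_window_view(enc, W)
    valid = (wins != N_INDEX).all(axis=1)
    return wins, valid


def _counts_from_picks(wins_by_strand, picks, W: int) -> np.ndarray:
    counts = np.zeros((W, 4))
    cols = np.arange(W)
    for k, pick in enumerate(picks):
        if pick is None:
            continue
        strand, pos = pick
        counts[cols, wins_by_strand[k][strand][0][pos]] += 1
    return counts


def _pick_best(sf: np.ndarray, sr: np.ndarray):
    """Best window over both strands; ties -> lowest offset, then + strand."""
    best = None
    if sf.size:
        i = int(np.argmax(sf))
        best = (sf[i], 0, i)
    if sr.size:
        j = int(np.argmax(sr))
        cand = (sr[j], 1, j)
        if best is None or cand[0] > best[0]:
            best = cand
    if best is None or not np.isfinite(best[0]):
        return None
    return (best[1], best[2])


def _fit_geometry(
    region_wins,
    W: int,
    palindrome: tuple[int, int] | None,
    background: np.ndarray,
    pseudocount: float,
    n_restarts: int,
    max_iter: int,
    rng: np.random.Generator,
):
    """EM-style alternation: rebuild profile from picks, re-pick best windows.

    The alignment itself is fit *without* palindromic symmetrization:
    symmetrizing during the iteration creates a phase-blur attractor (an
    alignment globally shifted by one column symmetrizes into a smeared
    profile under which every site is ambiguous between two placements,
    and the smear is self-reinforcing).  The palindrome constraint is
    applied to the final profile instead, after a phase-polish step that
    tries small global shifts of the whole alignment.
    """
    n_regions = len(region_wins)

    def plain_pwm(counts):
        return PWM.from_counts(counts, background, pseudocount)

    def final_pwm(counts):
        pwm = plain_pwm(counts)
        if palindrome is not None:
            pwm = symmetrize_palindrome(pwm, *palindrome)
        return pwm

    # flatten every valid window of every region into one matrix so that
    # common-word seeding can align all regions to a candidate in one pass
    row_mats, row_ranges = [], []
    lo = 0
    for strands in region_wins:
        parts = [strands[s][0][strands[s][1]] for s in (0, 1)]
        block = np.concatenate(parts) if any(p.size for p in parts) else np.empty((0, W), np.int8)
        if block.shape[0]:
            row_mats.append(block)
            row_ranges.append((lo, lo + block.shape[0]))
            lo += block.shape[0]
        else:
            row_ranges.append(None)
    if not row_mats:
        raise DiscoveryError("no scannable windows at this width")
    mats = np.concatenate(row_mats)
    starts = np.array([r[0] for r in row_ranges if r is not None])

    def seed_counts(n_candidates: int = 40):
        # best-scoring common word: among sampled candidate windows, pick the
        # one with the greatest total cross-region agreement (sum over regions
        # of W minus the minimum Hamming distance), then seed the profile from
        # each region's closest window to it
        cand_rows = rng.choice(mats.shape[0], size=min(n_candidates, mats.shape[0]), replace=False)
        best_tot, best_row = -1, None
        for r in cand_rows:
            dist = (mats != mats[r]).sum(axis=1)
            mins = np.minimum.reduceat(dist, starts)
            tot = int((W - mins).sum())
            if tot > best_tot:
                best_tot, best_row = tot, r
        dist = (mats != mats[best_row]).sum(axis=1)
        counts = np.zeros((W, 4))
        cols = np.arange(W)
        for rr in row_ranges:
            if rr is None:
                continue
            j = rr[0] + int(np.argmin(dist[rr[0] : rr[1]]))
            counts[cols, mats[j]] += 1
        return counts

    def e_step(weights):
        new_picks = []
        for strands in region_wins:
            sf = _fast_window_scores(weights, *strands[0])
            sr = _fast_window_scores(weights, *strands[1])
            new_picks.append(_pick_best(sf, sr))
        return new_picks

    def run_em(counts):
        picks = [None] * n_regions
        seen: set = set()
        converged = False
        for _ in range(max_iter):
            new_picks = e_step(plain_pwm(counts).weights)
            # a fixed point, or any revisited assignment state (a cycle of
            # the hard-assignment map), counts as stable
            key = tuple(new_picks)
            if new_picks == picks or key in seen:
                converged = True
                picks = new_picks
                break
            seen.add(key)
            picks = new_picks
            counts = _counts_from_picks(region_wins, picks, W)
            if counts.sum() == 0:
                break
        return _counts_from_picks(region_wins, picks, W), picks, converged

    def plain_ic(counts):
        return information_content(plain_pwm(counts))[1]

    def shift_all(picks, delta):
        out = []
        for k, pick in enumerate(picks):
            if pick is None:
                out.append(None)
                continue
            s, p = pick
            wins, valid = region_wins[k][s]
            p2 = p + delta
            out.append((s, p2) if 0 <= p2 < wins.shape[0] and valid[p2] else pick)
        return out

    best = None
    for restart in range(n_restarts):
        counts, picks, converged = run_em(seed_counts())
        if counts.sum() == 0:
            continue
        # phase polish: a consistently off-by-one alignment is a local
        # optimum; try shifting the whole alignment a little and re-fit
        for _ in range(3):
            base = plain_ic(counts)
            moved = False
            for delta in (-2, -1, 1, 2):
                shifted = _counts_from_picks(region_wins, shift_all(picks, delta), W)
                if shifted.sum() and plain_ic(shifted) > base + 1e-9:
                    counts, picks, converged = run_em(shifted)
                    moved = True
                    break
            if not moved:
                break
        if counts.sum() == 0:
            continue
        _, total_ic = information_content(final_pwm(counts))
        if best is None or total_ic > best[0]:
            best = (total_ic, counts, picks, converged)
    if best is None:
        raise DiscoveryError("discovery failed at this geometry (no usable picks)")
    return best[1], best[2], best[3]


def _selection_score(pwm: PWM) -> float:
    """Column-adjusted information criterion for width selection.

    Total information content minus a fixed per-column cost: widening the
    window pays off only while the added columns each contribute more than
    :data:`COLUMN_COST_BITS`.  This keeps weakly conserved true flanking
    positions (worth ~0.5-1.7 bits at an AT-rich background) while
    rejecting near-background padding columns, whose estimated information
    is only sampling bias.  A per-column *mean* cannot separate these
    cases: dropping one strong and one weak flank together is mean-neutral.
    """
    _, total = information_content(pwm)
    return float(total - COLUMN_COST_BITS * pwm.width)


def discover_motif(
    training_set,
    width_range: tuple[int, int] = (17, 31),
    palindrome: PalindromeSearch | tuple[int, int] | None = None,
    n_restarts: int = 4,
    seed: int = 0,
    pseudocount: float = 1.0,
    background: np.ndarray | None = None,
    max_iter: int = 200,
) -> MotifModel:
    """Discover a common motif in a training set of upstream regions.

    For each candidate width (or inverted-repeat arm/spacer geometry) the
    procedure seeds a profile from the best-scoring common word (the sampled
    window with the greatest total cross-region agreement), then alternates
    between picking the best-scoring window per region on either strand and
    rebuilding the profile from the picks, until the picks are stable or
    ``max_iter`` is reached; a phase-polish step retries small global shifts
    of the alignment.  When a palindrome geometry is given the final profile
    is symmetrized with its reverse-complement transform.  The best of
    ``n_restarts`` by total information content is kept per geometry; the
    final width maximizes the column-adjusted information criterion (total
    information content minus :data:`COLUMN_COST_BITS` per column).  The
    scan threshold is the lowest training-site score of the selected model.

    ``training_set`` is a list of UpstreamRegion objects or plain strings.
    Regions shorter than a candidate width are excluded from that width with
    a warning.  Requires at least 4 usable regions.
    """
    seqs, ids = [], []
    for i, r in enumerate(training_set):
        seq = getattr(r, "sequence", r).upper()
        seqs.append(seq)
        ids.append(getattr(r, "gene_id", f"region{i:03d}"))
    if len(seqs) < 4:
        raise DiscoveryError(f"need at least 4 training regions, got {len(seqs)}")

    if background is None:
        counts4 = np.zeros(4)
        for s in seqs:
            enc = encode(s)
            counts4 += np.bincount(enc[enc != N_INDEX], minlength=4)
        q = counts4 / counts4.sum()
        background = 0.5 * (q + q[::-1])  # strand-symmetric
    background = np.asarray(background, dtype=float)

    lo_w, hi_w = width_range
    if palindrome is None:
        geometries = [(w, None) for w in range(lo_w, hi_w + 1)]
    elif isinstance(palindrome, PalindromeSearch):
        geometries = []
        for arm in range(palindrome.arm_range[0], palindrome.arm_range[1] + 1):
            for sp in palindrome.spacers:
                w = 2 * arm + sp
                if lo_w <= w <= hi_w:
                    geometries.append((w, (arm, sp)))
    else:
        arm, sp = palindrome
        geometries = [(2 * arm + sp, (arm, sp))]
    if not geometries:
        raise DiscoveryError("no candidate widths in range")

    enc_f = [encode(s) for s in seqs]
    enc_r = [encode(revcomp(s)) for s in seqs]

    results = []
    for W, palin in geometries:
        usable = [k for k in range(len(seqs)) if len(seqs[k]) >= W]
        excluded = [ids[k] for k in range(len(seqs)) if len(seqs[k]) < W]
        if excluded:
            warnings.warn(
                f"{len(excluded)} region(s) shorter than width {W} excluded", stacklevel=2
            )
        if len(usable) < 4:
            continue
        region_wins = [
            (_region_windows(enc_f[k], W), _region_windows(enc_r[k], W)) for k in usable
        ]
        rng = np.random.default_rng(
            [seed % (2**31), W, 0 if palin is None else palin[0], 0 if palin is None else palin[1]]
        )
        try:
            counts, picks, converged = _fit_geometry(
                region_wins, W, palin, background, pseudocount, n_restarts, max_iter, rng
            )
        except DiscoveryError:
            continue
        pwm = PWM.from_counts(counts, background, pseudocount)
        if palin is not None:
            pwm = symmetrize_palindrome(pwm, *palin)
        results.append(
            (_selection_score(pwm), -W, W, palin, pwm, counts, picks, usable, excluded, converged)
        )
    if not results:
        raise DiscoveryError("discovery failed for every candidate width")

    results.sort(key=lambda r: (r[0], r[1]), reverse=True)
    _, _, W, palin, pwm, counts, picks, usable, excluded, converged = results[0]
    if not converged:
        warnings.warn("motif discovery did not converge; returning best-so-far", stacklevel=2)

    training_sites = []
    for k, pick in zip(usable, picks):
        if pick is None:
            continue
        strand_idx, pos = pick
        seq = seqs[k] if strand_idx == 0 else revcomp(seqs[k])
        site_seq = seq[pos : pos + W]
        offset = pos if strand_idx == 0 else len(seq) - pos - W
        training_sites.append(
            TrainingSite(
                region_id=ids[k],
                offset=offset,
                strand="+" if strand_idx == 0 else "-",
                score=score_site(pwm, site_seq),
                sequence=site_seq,
            )
        )
    if not training_sites:
        raise DiscoveryError("no training sites placed")
    threshold = min(t.score for t in training_sites)
    return MotifModel(
        pwm=pwm,
        palindrome=palin,
        threshold=threshold,
        training_sites=training_sites,
        converged=converged,
        excluded_regions=excluded,
        selection_score=results[0][0],
    )
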