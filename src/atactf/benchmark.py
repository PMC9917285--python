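"""Precision-recall benchmarking at fixed 200 bp genomic bins, plus the two
reference baselines: PWM motif-count ranking and arcsinh-averaged ChIP
signal.

Chromosomes are tiled into non-overlapping fixed-width bins (trailing
partial bin dropped). A bin's prediction score is the maximum signal value
it overlaps; a bin is gold-positive if it overlaps a ChIP-seq peak by at
least 1 bp (contrast with the stricter >50% rule used for training labels).
Bins overlapping the blacklist are excluded from every count. At each
unique positive score threshold (tied scores enter together; score-0 bins
are unscored and never count as predictions):

    precision        = gold-positive predicted bins / predicted bins
    recall           = gold-positive predicted bins / gold-positive bins
    random precision = gold-positive bins / all (non-excluded) bins

AUPR uses the average-precision step sum, sum_i (R_i - R_{i-1}) P_i.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np

from .genomics_io import ChromSizes, GenomicInterval, IntervalSet, SignalTrack

COMPLEMENT = str.maketrans("ACGT", "TGCA")


@dataclass
class BinnedEvaluation:
    """Fixed-width bins with prediction scores, gold labels and exclusion
    flags — the object all precision-recall statistics are computed on."""

    bin_width: int
    chroms: List[str]
    starts: np.ndarray  # global bin start coords (per flattened bin)
    chrom_index: np.ndarray  # index into `chroms` per bin
    scores: np.ndarray
    labels: np.ndarray
    excluded: np.ndarray

    def kept(self) -> Tuple[np.ndarray, np.ndarray]:
        """(scores, labels) of non-excluded bins."""
        keep = ~self.excluded
        return self.scores[keep], self.labels[keep]


def make_bins(chrom_sizes: ChromSizes, chroms: Sequence[str], bin_width: int = 200):
    """Per-chromosome bin start arrays; trailing partial bins are dropped so
    every bin has identical width."""
    out = {}
    for chrom in chroms:
        n = chrom_sizes[chrom] // bin_width
        out[chrom] = np.arange(n, dtype=np.int64) * bin_width
    return out


def bin_scores(track: SignalTrack, chrom: str, bin_width: int = 200) -> np.ndarray:
    """Max per-base value per fixed-width bin (trailing partial dropped)."""
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    v = track.values[chrom]
    n = len(v) // bin_width
    if n == 0:
        return np.zeros(0, dtype=np.float64)
    return v[: n * bin_width].reshape(n, bin_width).max(axis=1)


def label_bins(
    starts: np.ndarray, bin_width: int, chrom: str, chip_peaks: IntervalSet
) -> np.ndarray:
    """Gold label per bin: positive iff >= 1 bp overlap with a ChIP peak."""
    overlap = chip_peaks.overlap_bp(chrom, starts, starts + bin_width)
    return overlap > 0


def evaluate_track(
    track: SignalTrack,
    chip_peaks: IntervalSet,
    chroms: Sequence[str],
    blacklist: IntervalSet = IntervalSet(),
    bin_width: int = 200,
) -> BinnedEvaluation:
    """Bin a score track against a gold standard over `chroms`."""
    sizes = track.chrom_sizes()
    all_starts, all_ci, all_scores, all_labels, all_excl = [], [], [], [], []
    for ci, chrom in enumerate(chroms):
        scores = bin_scores(track, chrom, bin_width)
        starts = np.arange(len(scores), dtype=np.int64) * bin_width
        labels = label_bins(starts, bin_width, chrom, chip_peaks)
        excl = blacklist.overlap_bp(chrom, starts, starts + bin_width) > 0
        all_starts.append(starts)
        all_ci.append(np.full(len(starts), ci))
        all_scores.append(scores)
        all_labels.append(labels)
        all_excl.append(excl)
    return BinnedEvaluation(
        bin_width=bin_width,
        chroms=list(chroms),
        starts=np.concatenate(all_starts),
        chrom_index=np.concatenate(all_ci),
        scores=np.concatenate(all_scores),
        labels=np.concatenate(all_labels),
        excluded=np.concatenate(all_excl),
    )


def pr_curve(scores: np.ndarray, labels: np.ndarray):
    """Precision/recall at every unique positive score, descending.

    Tied scores enter together; bins scoring exactly 0 are unscored (never
    predictions). Returns (thresholds, precision, recall). Errors if the
    instance has no positive label.
    """
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels).astype(bool)
    n_pos = int(labels.sum())
    if n_pos == 0:
        raise ValueError("precision-recall undefined with zero gold positives")
    mask = scores > 0
    s, y = scores[mask], labels[mask]
    order = np.argsort(-s, kind="stable")
    s, y = s[order], y[order]
    if s.size == 0:
        return (np.zeros(0), np.zeros(0), np.zeros(0))
    # indices where a threshold group (tie block) ends
    distinct = np.flatnonzero(np.diff(s) != 0)
    block_ends = np.concatenate([distinct, [s.size - 1]])
    tp = np.cumsum(y)[block_ends].astype(np.float64)
    npred = (block_ends + 1).astype(np.float64)
    thresholds = s[block_ends]
    precision = tp / npred
    recall = tp / n_pos
    return thresholds, precision, recall


def auprc(curve) -> float:
    """Average-precision step sum over the descending-threshold curve."""
    _, precision, recall = curve
    if len(recall) == 0:
        return 0.0
    prev = np.concatenate([[0.0], recall[:-1]])
    return float(np.sum((recall - prev) * precision))


def precision_at_recall(curve, r: float = 0.05) -> float:
    """Precision at the highest threshold whose recall reaches r."""
    _, precision, recall = curve
    idx = np.flatnonzero(recall >= r)
    if idx.size == 0:
        raise ValueError(f"recall {r} is never reached by the ranking")
    return float(precision[idx[0]])


def random_precision(labels: np.ndarray) -> float:
    """Positive fraction among (non-excluded) bins — the precision a random
    ranking converges to."""
    labels = np.asarray(labels).astype(bool)
    if labels.size == 0:
        raise ValueError("no bins to evaluate")
    return float(labels.sum() / labels.size)


def log2_fold_change(a: float, b: float, pseudocount: float = 0.1) -> float:
    """log2((a + c) / (b + c)); the pseudocount moderates fold changes
    between small performance numbers."""
    return float(np.log2((a + pseudocount) / (b + pseudocount)))


def evaluate(
    track: SignalTrack,
    chip_peaks: IntervalSet,
    chroms: Sequence[str],
    blacklist: IntervalSet = IntervalSet(),
    bin_width: int = 200,
    recall_point: float = 0.05,
) -> Dict[str, float]:
    """One-call benchmark: AUPR, precision at `recall_point`, random
    precision and bin counts for a score track vs a gold standard."""
    ev = evaluate_track(track, chip_peaks, chroms, blacklist, bin_width)
    scores, labels = ev.kept()
    curve = pr_curve(scores, labels)
    out = {
        "aupr": auprc(curve),
        "random_precision": random_precision(labels),
        "n_bins": int(labels.size),
        "n_positives": int(labels.sum()),
    }
    try:
        out["precision_at_recall"] = precision_at_recall(curve, recall_point)
    except ValueError:
        out["precision_at_recall"] = float("nan")
    return out


# ---------------------------------------------------------------------------
# PWM motif scanning
# ---------------------------------------------------------------------------

@dataclass
class Pwm:
    """Position weight matrix with background model.

    `matrix` is (L, 4) per-position probabilities over A, C, G, T;
    the pseudocount regularizes zero entries before log-odds scoring.
    """

    motif_id: str
    matrix: np.ndarray
    background: np.ndarray = field(default_factory=lambda: np.full(4, 0.25))
    pseudocount: float = 0.01

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=np.float64)
        self.background = np.asarray(self.background, dtype=np.float64)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != 4:
            raise ValueError("PWM matrix must be (length, 4)")
        if not np.allclose(self.matrix.sum(axis=1), 1.0, atol=1e-3):
            raise ValueError("PWM rows must sum to 1")

    def __len__(self):
        return self.matrix.shape[0]

    def log_odds(self) -> np.ndarray:
        """Pseudocount-regularized log2 odds vs the background."""
        p = self.matrix + self.pseudocount
        p /= p.sum(axis=1, keepdims=True)
        return np.log2(p / self.background)

    def reverse_complement(self) -> "Pwm":
        return Pwm(self.motif_id, self.matrix[::-1, ::-1].copy(),
                   self.background[::-1].copy(), self.pseudocount)


def read_meme_motifs(path) -> List[Pwm]:
    """Read PWMs from a MEME minimal-format motif file.

    Parsed directly so letter probabilities are kept at full precision
    (count-based round-trips lose small probabilities).
    """
    out: List[Pwm] = []
    background = np.full(4, 0.25)
    name = None
    rows: List[List[float]] = []
    expecting = 0
    with open(path) as fh:
        for line in fh:
            tokens = line.split()
            if not tokens:
                continue
            if tokens[0] == "Background" and "frequencies" in line:
                expecting = -1  # next line holds the frequencies
                continue
            if expecting == -1:
                freq = {tokens[i]: float(tokens[i + 1])
                        for i in range(0, len(tokens) - 1, 2)}
                background = np.array([freq.get(b, 0.25) for b in "ACGT"])
                expecting = 0
                continue
            if tokens[0] == "MOTIF":
                name = tokens[1]
                continue
            if tokens[0] == "letter-probability":
                fields = dict(zip(tokens[2::2], tokens[3::2]))
                expecting = int(fields.get("w=", fields.get("w", 0)) or 0)
                rows = []
                continue
            if expecting > 0:
                rows.append([float(t) for t in tokens[:4]])
                expecting -= 1
                if expecting == 0:
                    out.append(Pwm(name or f"motif{len(out) + 1}",
                                   np.array(rows), background.copy()))
    return out


def _discretized_log_odds(pwm: Pwm, granularity: float) -> np.ndarray:
    """Integer log-odds scores (units of `granularity`); the DP threshold
    and the scanner both work in this exact score space."""
    return np.round(pwm.log_odds() / granularity).astype(np.int64)


def pwm_score_threshold(pwm: Pwm, p_threshold: float, granularity: float = 1e-3) -> float:
    """Log-odds score threshold for a match p-value, by exact dynamic
    programming over the discretized score distribution under the
    background model.

    Returns the smallest score t with P(score >= t) < p_threshold under the
    background; +inf when even the maximal attainable score is too probable
    (no position can then match).
    """
    q = _discretized_log_odds(pwm, granularity)
    row_min = q.min(axis=1)
    row_max = q.max(axis=1)
    total_min = int(row_min.sum())
    span = int((row_max - row_min).sum()) + 1
    dist = np.zeros(span, dtype=np.float64)  # index = score - running min
    dist[0] = 1.0
    for i in range(len(pwm)):
        new = np.zeros_like(dist)
        for b in range(4):
            shift = int(q[i, b] - row_min[i])
            if shift:
                new[shift:] += pwm.background[b] * dist[: span - shift]
            else:
                new += pwm.background[b] * dist
        dist = new
    sf = np.cumsum(dist[::-1])[::-1]  # P(score - total_min >= k)
    ok = np.flatnonzero(sf < p_threshold)
    if ok.size == 0:
        return float("inf")
    return (int(ok[0]) + total_min) * granularity


def _scan_one_strand(seq_idx: np.ndarray, lo: np.ndarray, threshold: float) -> np.ndarray:
    """Positions where the motif log-odds score meets the threshold.
    `seq_idx` holds base indices 0-3, -1 for non-ACGT (scored as -inf)."""
    length = len(lo)
    n = seq_idx.size - length + 1
    if n <= 0:
        return np.zeros(0, dtype=np.int64)
    scores = np.zeros(n, dtype=np.float64)
    valid = np.ones(n, dtype=bool)
    for j in range(length):
        idx = seq_idx[j:j + n]
        bad = idx < 0
        valid &= ~bad
        scores += np.where(bad, 0.0, lo[j, np.maximum(idx, 0)])
    return np.flatnonzero(valid & (scores >= threshold - 1e-12))


def _seq_to_idx(seq: str) -> np.ndarray:
    arr = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)
    out = np.full(arr.size, -1, dtype=np.int64)
    for i, b in enumerate(b"ACGT"):
        out[arr == b] = i
    return out


def pwm_scan(
    sequences: Iterable[Tuple[GenomicInterval, str]],
    pwm: Pwm,
    p_threshold: float = 1e-5,
    granularity: float = 1e-3,
) -> IntervalSet:
    """Scan peak sequences on both strands for motif occurrences with match
    p-value below `p_threshold`; exact-coordinate duplicate hits are removed
    (overlapping non-identical hits are kept)."""
    threshold = pwm_score_threshold(pwm, p_threshold, granularity)
    if not np.isfinite(threshold):
        return IntervalSet()
    # score in the same discretized space the threshold was derived in
    lo_fwd = _discretized_log_odds(pwm, granularity) * granularity
    lo_rev = _discretized_log_odds(pwm.reverse_complement(), granularity) * granularity
    length = len(pwm)
    seen = set()
    hits = []
    for interval, seq in sequences:
        idx = _seq_to_idx(seq)
        for lo, strand in ((lo_fwd, "+"), (lo_rev, "-")):
            for p in _scan_one_strand(idx, lo, threshold):
                g_start = interval.start + int(p)
                key = (interval.chrom, g_start, g_start + length)
                if key in seen:
                    continue
                seen.add(key)
                hits.append(
                    GenomicInterval(interval.chrom, g_start, g_start + length,
                                    strand, name=pwm.motif_id)
                )
    return IntervalSet(hits)


def motif_rank_bins(
    hits: IntervalSet, starts: np.ndarray, bin_width: int, chrom: str
) -> np.ndarray:
    """Count motif hits overlapping each bin by >= 1 bp (a hit straddling
    two bins counts in both); counts are the PR ranking scores."""
    counts = np.zeros(len(starts), dtype=np.float64)
    h_starts, h_ends = hits.arrays(chrom)
    if len(h_starts) == 0 or len(starts) == 0:
        return counts
    ends = starts + bin_width
    for hs, he in zip(h_starts, h_ends):
        counts += (hs < ends) & (starts < he)
    return counts


def average_chip_baseline(chip_signal_tracks: Sequence[SignalTrack]) -> SignalTrack:
    """Per-base mean of arcsinh-transformed ChIP -log10 p-value tracks from
    the training cell types; ranked via bin_scores -> pr_curve it is the
    'how far does ChIP in other cell types get you' baseline."""
    if not chip_signal_tracks:
        raise ValueError("need at least one ChIP signal track")
    chroms = set(chip_signal_tracks[0].values)
    for t in chip_signal_tracks[1:]:
        if set(t.values) != chroms:
            raise ValueError("ChIP tracks cover different chromosome sets")
    values = {
        c: np.mean([np.arcsinh(t.values[c]) for t in chip_signal_tracks], axis=0)
        for c in chroms
    }
    return SignalTrack(values, "raw")
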