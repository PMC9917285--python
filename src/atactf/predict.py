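"""Genome-tiled TFBS prediction, score calibration, and BED thresholding.

Chromosomes are tiled into non-overlapping 1,024 bp windows starting at
position 0; the trailing partial window is padded with N sequence (all-zero
one-hot) and zero signal, and predictions past the chromosome end are
discarded. Every window contributes 32 scores (one per 32 bp bin), stored
densely per base so the result behaves like any other signal track.

Calibration maps scores to validation precision/recall/F1 on a fixed
threshold grid, collapsing duplicate precision values to the threshold of
maximal recall so the score -> precision mapping is one-to-one.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence

import numpy as np

from . import benchmark
from .genomics_io import (
    ChromSizes,
    GenomicInterval,
    IntervalSet,
    SignalTrack,
    one_hot_encode,
)
from .model import ModelHandle


@dataclass(frozen=True)
class Variant:
    """A donor genotype call at one reference position (0-based)."""

    chrom: str
    position: int
    ref: str
    alt: str
    genotype: str = "hom-alt"  # hom-ref | het | hom-alt


@dataclass(frozen=True)
class CalibrationRow:
    threshold: float
    precision: float
    recall: float
    f1: float
    log2_precision_over_random: float


def read_variants(path) -> List[Variant]:
    """Read a VCF-like TSV: chrom, 1-based position, ref, alt, genotype."""
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            chrom, pos, ref, alt, *rest = line.split("\t")
            gt = rest[0] if rest else "hom-alt"
            out.append(Variant(chrom, int(pos) - 1, ref.upper(), alt.upper(), gt))
    return out


def apply_variants(sequence: str, variants: Sequence[Variant], offset: int = 0) -> str:
    """Substitute homozygous-alternate SNVs into a reference sequence.

    `offset` is the genomic coordinate of sequence position 0. Reference
    mismatches and indels are errors; non-hom-alt calls are ignored (only
    homozygous substitutions are phase-free).
    """
    seq = list(sequence)
    for v in variants:
        if len(v.ref) != 1 or len(v.alt) != 1:
            raise ValueError(
                f"indel at {v.chrom}:{v.position + 1} unsupported (SNVs only)"
            )
        if v.genotype != "hom-alt":
            continue
        i = v.position - offset
        if not 0 <= i < len(seq):
            continue
        if seq[i].upper() != v.ref:
            raise ValueError(
                f"reference mismatch at {v.chrom}:{v.position + 1}: "
                f"sequence has {seq[i]!r}, variant claims {v.ref!r}"
            )
        seq[i] = v.alt
    return "".join(seq)


def predict_genome(
    model: ModelHandle,
    genome: Dict[str, str],
    signal_track: SignalTrack,
    chroms: Sequence[str],
    blacklist: IntervalSet = IntervalSet(),
    batch_size: int = 128,
) -> SignalTrack:
    """Tile `chroms` with non-overlapping input windows and score every
    32 bp bin; returns a dense per-base track of scores in [0, 1] with
    blacklist-overlapping bins zeroed."""
    window = model.spec.input_length
    bin_width = window // model.spec.output_bins
    n_ch = model.spec.input_channels
    values: Dict[str, np.ndarray] = {}
    for chrom in chroms:
        sig = signal_track.values[chrom]
        if sig.size and sig.max() > 1.0 + 1e-9:
            raise ValueError(
                f"signal on {chrom} has values > 1; min-max normalize it first"
            )
        seq = genome[chrom]
        length = len(seq)
        n_windows = (length + window - 1) // window
        scores = np.zeros(n_windows * model.spec.output_bins, dtype=np.float64)
        for b0 in range(0, n_windows, batch_size):
            batch_idx = range(b0, min(b0 + batch_size, n_windows))
            x = np.zeros((len(batch_idx), n_ch, window), dtype=np.float32)
            for j, wi in enumerate(batch_idx):
                s = wi * window
                e = min(s + window, length)
                x[j, :4, : e - s] = one_hot_encode(seq[s:e])
                x[j, 4, : e - s] = sig[s:e]
            pred = model.predict(x)
            scores[b0 * model.spec.output_bins:
                   b0 * model.spec.output_bins + pred.size] = pred.ravel()
        # expand bin scores to per-base, trim to chromosome length
        dense = np.repeat(scores, bin_width)[:length]
        # zero blacklisted bins (>= 1 bp overlap)
        n_bins = (length + bin_width - 1) // bin_width
        b_starts = np.arange(n_bins, dtype=np.int64) * bin_width
        b_ends = np.minimum(b_starts + bin_width, length)
        bad = blacklist.overlap_bp(chrom, b_starts, b_ends) > 0
        for bs, be in zip(b_starts[bad], b_ends[bad]):
            dense[bs:be] = 0.0
        values[chrom] = dense
    return SignalTrack(values, "minmax")


def calibrate(
    prediction_track: SignalTrack,
    gold_standard: IntervalSet,
    chroms: Sequence[str],
    blacklist: IntervalSet = IntervalSet(),
    grid_step: float = 0.001,
    bin_width: int = 200,
) -> List[CalibrationRow]:
    """Map score thresholds to validation precision/recall/F1.

    Precision and recall follow the benchmark module's fixed-width-bin
    procedure at every threshold on a regular grid. Precision is not
    necessarily monotone in score, so duplicate precision values are
    collapsed keeping the threshold of maximal recall, making the returned
    table one-to-one in precision. F1 at P=R=0 is defined as 0; the log2
    precision/random ratio uses a 0.1 pseudocount for totality.
    """
    if len(gold_standard) == 0:
        raise ValueError("empty gold standard")
    ev = benchmark.evaluate_track(
        prediction_track, gold_standard, chroms, blacklist, bin_width
    )
    scores, labels = ev.kept()
    n_pos = labels.sum()
    if n_pos == 0:
        raise ValueError("gold standard has no positive bins on these chromosomes")
    rand_p = benchmark.random_precision(labels)
    rows: List[CalibrationRow] = []
    thresholds = np.arange(grid_step, 1.0 + grid_step / 2, grid_step)
    order = np.argsort(-scores, kind="stable")
    s_sorted = scores[order]
    tp_cum = np.cumsum(labels[order])
    for t in thresholds:
        n_pred = int(np.searchsorted(-s_sorted, -t, side="right"))
        if n_pred == 0:
            continue
        tp = float(tp_cum[n_pred - 1])
        precision = tp / n_pred
        recall = tp / n_pos
        f1 = 0.0 if precision + recall == 0 else 2 * precision * recall / (precision + recall)
        rows.append(
            CalibrationRow(
                threshold=float(t),
                precision=precision,
                recall=recall,
                f1=f1,
                log2_precision_over_random=benchmark.log2_fold_change(precision, rand_p),
            )
        )
    # collapse duplicate precision values: keep max recall; on recall ties
    # prefer the lower threshold (it implies the same performance at wider
    # coverage of the score range)
    best: Dict[float, CalibrationRow] = {}
    for row in rows:
        key = round(row.precision, 12)
        cur = best.get(key)
        if cur is None or row.recall > cur.recall or (
            row.recall == cur.recall and row.threshold < cur.threshold
        ):
            best[key] = row
    return sorted(best.values(), key=lambda r: r.threshold)


def write_calibration(rows: Sequence[CalibrationRow], path) -> None:
    with open(path, "w") as fh:
        fh.write("threshold\tprecision\trecall\tF1\tlog2_prec_over_random\n")
        for r in rows:
            fh.write(
                f"{r.threshold:.3f}\t{r.precision:.6g}\t{r.recall:.6g}\t"
                f"{r.f1:.6g}\t{r.log2_precision_over_random:.6g}\n"
            )


def read_calibration(path) -> List[CalibrationRow]:
    rows = []
    with open(path) as fh:
        next(fh)  # header
        for line in fh:
            t, p, r, f1, l2 = line.split("\t")
            rows.append(CalibrationRow(float(t), float(p), float(r),
                                       float(f1), float(l2)))
    return rows


def select_threshold(rows: Sequence[CalibrationRow], by: str = "f1") -> float:
    """Pick the score cutoff maximizing a calibration statistic."""
    key = {"f1": lambda r: r.f1, "precision": lambda r: r.precision,
           "recall": lambda r: r.recall}[by.lower()]
    return max(rows, key=key).threshold


def threshold_to_bed(
    prediction_track: SignalTrack, cutoff: float, bin_width: int = 32
) -> IntervalSet:
    """Merge maximal runs of consecutive bins scoring >= cutoff into
    intervals carrying each run's maximum score."""
    if not 0 <= cutoff <= 1:
        raise ValueError("cutoff must be in [0, 1]")
    out = []
    for chrom in prediction_track.chroms():
        v = prediction_track.values[chrom]
        length = len(v)
        n_bins = (length + bin_width - 1) // bin_width
        bin_scores = v[np.minimum(np.arange(n_bins) * bin_width, length - 1)]
        passing = bin_scores >= cutoff
        if not passing.any():
            continue
        edges = np.diff(passing.astype(np.int8))
        starts = list(np.flatnonzero(edges == 1) + 1)
        ends = list(np.flatnonzero(edges == -1) + 1)
        if passing[0]:
            starts.insert(0, 0)
        if passing[-1]:
            ends.append(n_bins)
        for bs, be in zip(starts, ends):
            out.append(
                GenomicInterval(
                    chrom,
                    bs * bin_width,
                    min(be * bin_width, length),
                    score=float(bin_scores[bs:be].max()),
                )
            )
    return IntervalSet(out)
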