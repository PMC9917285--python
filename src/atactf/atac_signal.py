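"""Tn5 cut-site inference and ATAC-seq signal normalization.

Pipeline: aligned reads (or pre-shifted fragments) -> Tn5 insertion points
-> +/-20 bp smoothing -> depth-scaled coverage (reads-per-20-million, RP20M)
-> robust min-max normalization to [0, 1] against the p-th percentile of the
nonzero signal.

The Tn5 transposase dimer inserts adapters with a 9 bp strand-specific
offset, so plus-strand read starts are shifted +4 and minus-strand read ends
-5 to center on the actual cut site. Both cut sites of every fragment are
retained (duplicate cut sites included). Insertion points are treated as
between-base points, so the +/-flank smoothing of a point c yields the
half-open window [c-flank, c+flank) of width exactly 2*flank.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Sequence, Tuple, Union

import numpy as np

from .genomics_io import (
    ChromSizes,
    Fragment,
    GenomicInterval,
    IntervalSet,
    SignalTrack,
)

TARGET_DEPTH_DEFAULT = 20_000_000

CutSite = Tuple[str, int]


@dataclass
class SignalConfig:
    """Parameters of the cut-site signal pipeline.

    shift_plus / shift_minus: bp corrections applied to plus-strand starts /
    minus-strand (exclusive) ends of aligned reads.
    smooth_flank: half-width in bp of the smoothing window around each cut
    site (default 20, giving a 40 bp window matched to the ~38 bp Tn5 dimer).
    target_depth: read count the coverage is scaled to (RP20M).
    minmax_percentile: percentile of the nonzero signal used as the robust
    max (99 by default; 95 and 100 are the other supported choices, 100
    being standard min-max).
    clip_max: clip normalized values above 1 back to 1.
    """

    shift_plus: int = 4
    shift_minus: int = 5
    smooth_flank: int = 20
    target_depth: int = TARGET_DEPTH_DEFAULT
    minmax_percentile: float = 99.0
    clip_max: bool = True

    def __post_init__(self):
        if self.smooth_flank < 0:
            raise ValueError("smooth_flank must be >= 0")
        if not (0 < self.minmax_percentile <= 100):
            raise ValueError("minmax_percentile must be in (0, 100]")


@dataclass(frozen=True)
class MinMaxParams:
    """Fitted robust min-max parameters: min (fixed at 0) and the
    percentile-defined max of the RP20M signal."""

    min: float
    max_p: float
    percentile: float

    def __post_init__(self):
        if self.max_p <= self.min:
            raise ValueError("max_p must exceed min")


def infer_cut_sites(
    reads_or_fragments: Iterable[Union[GenomicInterval, Fragment]],
    config: SignalConfig = SignalConfig(),
) -> List[CutSite]:
    """Infer Tn5 insertion points.

    Aligned reads (``GenomicInterval`` with strand) yield one point each:
    plus-strand start+shift_plus, minus-strand end-shift_minus. Fragments
    (10x fragments-TSV dialect, ends already Tn5-corrected) yield two points,
    one per end, with no additional shift; the end point is ``end - 1``
    (the last base of the half-open fragment). Each fragment contributes its
    ``count`` copies of both points.
    """
    points: List[CutSite] = []
    for item in reads_or_fragments:
        if isinstance(item, Fragment):
            for _ in range(item.count):
                points.append((item.chrom, item.start))
                points.append((item.chrom, item.end - 1))
        else:
            if item.strand == "+":
                points.append((item.chrom, item.start + config.shift_plus))
            elif item.strand == "-":
                points.append((item.chrom, item.end - config.shift_minus))
            else:
                raise ValueError(
                    f"read {item.chrom}:{item.start}-{item.end} has no strand; "
                    "strand is required to infer the Tn5 cut site"
                )
    return points


def cut_sites_from_bam(path, config: SignalConfig = SignalConfig()) -> List[CutSite]:
    """Infer cut sites directly from a coordinate-accessible BAM/SAM file."""
    import pysam

    points: List[CutSite] = []
    with pysam.AlignmentFile(str(path)) as bam:
        for read in bam.fetch(until_eof=True):
            if read.is_unmapped:
                continue
            if read.is_reverse:
                points.append((read.reference_name, read.reference_end - config.shift_minus))
            else:
                points.append((read.reference_name, read.reference_start + config.shift_plus))
    return points


def smooth_cut_sites(
    points: Sequence[CutSite],
    chrom_sizes: ChromSizes,
    config: SignalConfig = SignalConfig(),
) -> IntervalSet:
    """Extend each insertion point c to the window [c-flank, c+flank),
    clamped to chromosome bounds. flank=0 degenerates to a 1 bp window."""
    flank = config.smooth_flank
    intervals = []
    for chrom, c in points:
        length = chrom_sizes[chrom]
        if flank == 0:
            start, end = c, c + 1
        else:
            start, end = c - flank, c + flank
        start = max(0, start)
        end = min(length, end)
        if start < end:
            intervals.append(GenomicInterval(chrom, start, end))
    return IntervalSet(intervals)


def rp20m_scale_factor(depth: int, target_depth: int = TARGET_DEPTH_DEFAULT) -> float:
    """Depth scale factor: target_depth / sequencing depth."""
    if depth <= 0:
        raise ValueError(f"sequencing depth must be positive, got {depth}")
    return target_depth / depth


def coverage_track(
    intervals: IntervalSet,
    chrom_sizes: ChromSizes,
    scale: float = 1.0,
) -> SignalTrack:
    """Per-base coverage: value at base b = scale * #intervals covering b."""
    values: Dict[str, np.ndarray] = {}
    for chrom, length in chrom_sizes.items():
        diff = np.zeros(length + 1, dtype=np.float64)
        starts, ends = intervals.arrays(chrom)
        np.add.at(diff, starts, 1.0)
        np.add.at(diff, ends, -1.0)
        values[chrom] = np.cumsum(diff[:-1]) * scale
    normalization = "raw" if scale == 1.0 else "rp20m"
    return SignalTrack(values, normalization)


def average_replicates(tracks: Sequence[SignalTrack]) -> SignalTrack:
    """Per-base arithmetic mean across replicate tracks."""
    if not tracks:
        raise ValueError("need at least one track")
    chroms = set(tracks[0].values)
    for t in tracks[1:]:
        if set(t.values) != chroms:
            raise ValueError("replicate tracks cover different chromosome sets")
    values = {
        c: np.mean([t.values[c] for t in tracks], axis=0) for c in chroms
    }
    return SignalTrack(values, tracks[0].normalization)


def fit_minmax(track: SignalTrack, percentile: float = 99.0) -> MinMaxParams:
    """Fit robust min-max parameters on a track.

    The max is the nearest-rank `percentile` of the *nonzero* per-base
    values (the genome is mostly zeros, so a percentile over all bases would
    degenerate to 0); the min is fixed at 0.
    """
    nonzero = np.concatenate(
        [v[v > 0] for v in track.values.values()]
    )
    if nonzero.size == 0:
        raise ValueError("cannot fit min-max parameters on an all-zero track")
    if percentile >= 100:
        max_p = float(nonzero.max())
    else:
        # nearest-rank: ceil(p/100 * n)-th smallest value
        nonzero.sort()
        rank = int(np.ceil(percentile / 100.0 * nonzero.size))
        max_p = float(nonzero[max(rank, 1) - 1])
    return MinMaxParams(min=0.0, max_p=max_p, percentile=percentile)


def minmax_normalize(
    track: SignalTrack, params: MinMaxParams, clip: bool = True
) -> SignalTrack:
    """Apply (v - min) / (max_p - min), optionally clipping to 1."""
    denom = params.max_p - params.min
    values = {}
    for chrom, v in track.values.items():
        out = (v - params.min) / denom
        out = np.maximum(out, 0.0)
        if clip:
            out = np.minimum(out, 1.0)
        values[chrom] = out
    return SignalTrack(values, "minmax" if clip else "rp20m")


def apply_blacklist(x, blacklist: IntervalSet):
    """Remove blacklist-overlapping content.

    Accepts a cut-site collection (points inside the blacklist are dropped),
    an :class:`IntervalSet` (>=1 bp overlappers dropped), or a
    :class:`SignalTrack` (blacklisted bases zeroed). Idempotent.
    """
    if isinstance(x, SignalTrack):
        out = x.copy()
        for chrom, v in out.values.items():
            starts, ends = blacklist.merged_arrays(chrom)
            for s, e in zip(starts, ends):
                v[max(0, s):min(len(v), e)] = 0.0
        return out
    if isinstance(x, IntervalSet):
        return x.subtract_overlapping(blacklist)
    # collection of (chrom, pos) points
    points = list(x)
    kept = []
    by_chrom: Dict[str, List[int]] = {}
    for i, (chrom, pos) in enumerate(points):
        by_chrom.setdefault(chrom, []).append(i)
    keep_mask = np.ones(len(points), dtype=bool)
    for chrom, idxs in by_chrom.items():
        pos = np.array([points[i][1] for i in idxs])
        inside = blacklist.overlaps_point(chrom, pos)
        for j, i in enumerate(idxs):
            keep_mask[i] = not inside[j]
    return [p for i, p in enumerate(points) if keep_mask[i]]


def downsample_fragments(
    fragments: Sequence[Fragment], n: int, seed: int
) -> List[Fragment]:
    """Uniform sample of `n` fragments without replacement (deterministic)."""
    if n > len(fragments):
        raise ValueError(f"cannot sample {n} of {len(fragments)} fragments")
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(fragments), size=n, replace=False)
    idx.sort()
    return [fragments[i] for i in idx]


def prepare_signal(
    reads_or_fragments,
    chrom_sizes: ChromSizes,
    blacklist: IntervalSet = IntervalSet(),
    config: SignalConfig = SignalConfig(),
):
    """Full signal pipeline: cut sites -> blacklist -> smooth -> RP20M ->
    robust min-max.

    Returns (raw_track, rp20m_track, minmax_track, params, depth) where
    depth is the number of retained cut sites.
    """
    points = infer_cut_sites(reads_or_fragments, config)
    points = apply_blacklist(points, blacklist)
    windows = smooth_cut_sites(points, chrom_sizes, config)
    depth = len(points)
    raw = coverage_track(windows, chrom_sizes, scale=1.0)
    scale = rp20m_scale_factor(depth, config.target_depth)
    rp20m = coverage_track(windows, chrom_sizes, scale=scale)
    rp20m.normalization = "rp20m"
    params = fit_minmax(rp20m, config.minmax_percentile)
    normed = minmax_normalize(rp20m, params, clip=config.clip_max)
    return raw, rp20m, normed, params, depth
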