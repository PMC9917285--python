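"""Deterministic toy-scale data generator for end-to-end testing.

Emulates the structure of a multi-cell-type TFBS benchmark: a small random
genome, per-cell-type accessible regions (ATAC peaks), a planted consensus
motif whose accessible occurrences define true binding sites (ChIP gold
standard), sequencing fragments enriched over accessible chromatin, a ChIP
-log10 p-value track, and a small blacklist.

Cell-type specificity arises from partially shared accessible regions: a
region is bound in a cell type iff it carries the planted motif AND is
accessible in that cell type, so binding is a joint function of sequence
and accessibility — the signal the model is meant to learn.

What this emulates (and what it does not): coverage enrichment over open
chromatin, pan-cell positive/negative structure and chromosome splits are
represented; GC composition, fragment-length periodicity, duplication
artifacts and footprint shape are not.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .genomics_io import (
    ChromSizes,
    Fragment,
    GenomicInterval,
    IntervalSet,
    SignalTrack,
    write_bed,
    write_chrom_sizes,
    write_fragments,
    write_track,
)

BASES = np.array(list("ACGT"))


@dataclass
class FixtureConfig:
    """Study conditions of the synthetic benchmark.

    Defaults: two 100 kb training chromosomes plus one validation and one
    test chromosome (named to match the default chromosome split), two cell
    types sharing half their accessible regions, half of the accessible
    regions carrying the planted 8-mer motif (hence bound where accessible),
    ~10x fragment-coverage enrichment inside accessible chromatin.
    """

    seed: int = 0
    chrom_lengths: Dict[str, int] = field(
        default_factory=lambda: {
            "chr1": 50_000,   # test
            "chr2": 50_000,   # validation
            "chr3": 100_000,  # train
            "chr4": 100_000,  # train
        }
    )
    motif: str = "TGACTCAG"
    n_cell_types: int = 2
    region_spacing: int = 4000  # one accessible candidate per this many bp
    region_width: int = 300
    motif_fraction: float = 0.5  # accessible regions carrying the motif
    shared_fraction: float = 0.5  # regions accessible in every cell type
    n_fragments: int = 40_000  # per cell type
    enrichment: float = 10.0  # fragment rate ratio accessible vs background
    fragment_length: Tuple[int, int] = (60, 140)
    chip_peak_halfwidth: int = 60
    chip_noise: float = 0.05
    blacklist_per_chrom: int = 1
    blacklist_width: int = 400

    def __post_init__(self):
        for chrom, length in self.chrom_lengths.items():
            if self.region_spacing >= length:
                raise ValueError(f"region_spacing exceeds length of {chrom}")


@dataclass
class FixtureTruth:
    """Ground truth and generated inputs for every cell type."""

    config: FixtureConfig
    genome: Dict[str, str]
    chrom_sizes: ChromSizes
    blacklist: IntervalSet
    cell_names: List[str]
    atac_peaks: Dict[str, IntervalSet]
    chip_peaks: Dict[str, IntervalSet]  # true TFBS = gold standard
    fragments: Dict[str, List[Fragment]]
    chip_signal: Dict[str, SignalTrack]  # -log10 p-value style


def _random_genome(rng: np.random.Generator, chrom_lengths: Dict[str, int]) -> Dict[str, str]:
    return {
        c: "".join(BASES[rng.integers(0, 4, size=n)])
        for c, n in chrom_lengths.items()
    }


def generate(config: FixtureConfig, out_dir=None) -> FixtureTruth:
    """Generate the full fixture; byte-identical for a fixed seed.

    When `out_dir` is given, writes ref.fa, chrom.sizes, blacklist.bed,
    truth.json and per-cell-type atac.fragments.tsv, atac_peaks.bed,
    chip_peaks.bed and chip_pval.bedgraph.
    """
    rng = np.random.default_rng(config.seed)
    genome = _random_genome(rng, config.chrom_lengths)
    chrom_sizes = ChromSizes.from_dict(config.chrom_lengths)
    cell_names = [f"cell{i + 1}" for i in range(config.n_cell_types)]

    # master accessible candidate regions, one per spacing slot, jittered
    master: List[GenomicInterval] = []
    has_motif: List[bool] = []
    accessible_in: List[List[str]] = []
    for chrom, length in config.chrom_lengths.items():
        n_slots = length // config.region_spacing
        for s in range(n_slots):
            lo = s * config.region_spacing
            hi = min((s + 1) * config.region_spacing, length) - config.region_width
            if hi <= lo:
                continue
            start = int(rng.integers(lo, hi))
            master.append(GenomicInterval(chrom, start, start + config.region_width))
            has_motif.append(bool(rng.random() < config.motif_fraction))
            if rng.random() < config.shared_fraction:
                accessible_in.append(list(cell_names))
            else:
                accessible_in.append([cell_names[rng.integers(len(cell_names))]])

    # plant the motif verbatim at the center of motif-carrying regions
    motif = config.motif.upper()
    genome_mut = {c: list(s) for c, s in genome.items()}
    motif_pos: List[Optional[int]] = []
    for region, carries in zip(master, has_motif):
        if not carries:
            motif_pos.append(None)
            continue
        center = (region.start + region.end) // 2
        pos = center - len(motif) // 2
        genome_mut[region.chrom][pos:pos + len(motif)] = list(motif)
        motif_pos.append(pos)
    genome = {c: "".join(s) for c, s in genome_mut.items()}

    # blacklist: background slots away from accessible regions
    accessible_union = IntervalSet(master)
    bl: List[GenomicInterval] = []
    for chrom, length in config.chrom_lengths.items():
        placed = 0
        while placed < config.blacklist_per_chrom:
            start = int(rng.integers(0, length - config.blacklist_width))
            iv = GenomicInterval(chrom, start, start + config.blacklist_width)
            if accessible_union.overlap_bp(chrom, [iv.start], [iv.end])[0] == 0:
                bl.append(iv)
                placed += 1
    blacklist = IntervalSet(bl)

    atac_peaks: Dict[str, IntervalSet] = {}
    chip_peaks: Dict[str, IntervalSet] = {}
    fragments: Dict[str, List[Fragment]] = {}
    chip_signal: Dict[str, SignalTrack] = {}
    for cell in cell_names:
        acc = [r for r, cells in zip(master, accessible_in) if cell in cells]
        atac_peaks[cell] = IntervalSet(acc)
        bound = []
        for region, cells, pos in zip(master, accessible_in, motif_pos):
            if pos is None or cell not in cells:
                continue
            center = pos + len(motif) // 2
            bound.append(
                GenomicInterval(
                    region.chrom,
                    max(0, center - config.chip_peak_halfwidth),
                    min(chrom_sizes[region.chrom], center + config.chip_peak_halfwidth),
                )
            )
        chip_peaks[cell] = IntervalSet(bound)
        fragments[cell] = _sample_fragments(rng, config, chrom_sizes, acc)
        chip_signal[cell] = _chip_track(rng, config, chrom_sizes, chip_peaks[cell])

    truth = FixtureTruth(
        config=config,
        genome=genome,
        chrom_sizes=chrom_sizes,
        blacklist=blacklist,
        cell_names=cell_names,
        atac_peaks=atac_peaks,
        chip_peaks=chip_peaks,
        fragments=fragments,
        chip_signal=chip_signal,
    )
    if out_dir is not None:
        _write_fixture(truth, Path(out_dir))
    return truth


def _sample_fragments(
    rng: np.random.Generator,
    config: FixtureConfig,
    chrom_sizes: ChromSizes,
    accessible: Sequence[GenomicInterval],
) -> List[Fragment]:
    """Fragment midpoints land in accessible regions with `enrichment`-fold
    higher rate per bp than background."""
    chroms = list(chrom_sizes)
    lengths = np.array([chrom_sizes[c] for c in chroms], dtype=np.float64)
    acc_by_chrom = {c: [r for r in accessible if r.chrom == c] for c in chroms}
    acc_bp = np.array(
        [sum(len(r) for r in acc_by_chrom[c]) for c in chroms], dtype=np.float64
    )
    # per-chrom weight: background bp * 1 + accessible bp * enrichment
    weights = (lengths - acc_bp) + acc_bp * config.enrichment
    probs = weights / weights.sum()
    counts = rng.multinomial(config.n_fragments, probs)
    frags: List[Fragment] = []
    fid = 0
    lmin, lmax = config.fragment_length
    for c_i, chrom in enumerate(chroms):
        n = counts[c_i]
        if n == 0:
            continue
        acc = acc_by_chrom[chrom]
        acc_total = sum(len(r) for r in acc)
        p_acc = acc_total * config.enrichment / weights[c_i]
        in_acc = rng.random(n) < p_acc
        mids = np.empty(n, dtype=np.int64)
        n_acc = int(in_acc.sum())
        if acc and n_acc:
            # uniform over accessible bp
            offsets = rng.integers(0, acc_total, size=n_acc)
            bounds = np.cumsum([len(r) for r in acc])
            which = np.searchsorted(bounds, offsets, side="right")
            within = offsets - np.concatenate([[0], bounds[:-1]])[which]
            mids[in_acc] = np.array([acc[w].start for w in which]) + within
        mids[~in_acc] = rng.integers(0, chrom_sizes[chrom], size=n - n_acc)
        lens = rng.integers(lmin, lmax + 1, size=n)
        for m, flen in zip(mids, lens):
            start = max(0, int(m) - int(flen) // 2)
            end = min(chrom_sizes[chrom], start + int(flen))
            if end - start < 2:
                continue
            frags.append(Fragment(chrom, start, end, f"BC{fid:06d}", 1))
            fid += 1
    return frags


def _chip_track(
    rng: np.random.Generator,
    config: FixtureConfig,
    chrom_sizes: ChromSizes,
    peaks: IntervalSet,
) -> SignalTrack:
    """Smoothed -log10 p-value style track: triangular bump per true TFBS
    plus half-normal background noise."""
    values = {}
    for chrom, length in chrom_sizes.items():
        v = np.abs(rng.normal(0, config.chip_noise, size=length))
        starts, ends = peaks.arrays(chrom)
        for s, e in zip(starts, ends):
            w = e - s
            height = 5.0 + 10.0 * rng.random()
            bump = height * (1.0 - np.abs(np.linspace(-1, 1, w)))
            v[s:e] += bump
        values[chrom] = v
    return SignalTrack(values, "raw")


def oracle_scores(truth: FixtureTruth, cell_type: str, bin_width: int = 32) -> SignalTrack:
    """The cheating score track: 1 on every 32 bp bin overlapping a true
    TFBS, 0 elsewhere — calibrates the benchmark ceiling (AUPR exactly 1)."""
    peaks = truth.chip_peaks[cell_type]
    values = {}
    for chrom, length in truth.chrom_sizes.items():
        n_bins = (length + bin_width - 1) // bin_width
        starts = np.arange(n_bins, dtype=np.int64) * bin_width
        ends = np.minimum(starts + bin_width, length)
        hot = peaks.overlap_bp(chrom, starts, ends) > 0
        dense = np.repeat(hot.astype(np.float64), bin_width)[:length]
        values[chrom] = dense
    return SignalTrack(values, "minmax")


def _write_fixture(truth: FixtureTruth, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    with open(out_dir / "ref.fa", "w") as fh:
        for chrom, seq in truth.genome.items():
            fh.write(f">{chrom}\n")
            for i in range(0, len(seq), 80):
                fh.write(seq[i:i + 80] + "\n")
    write_chrom_sizes(truth.chrom_sizes, out_dir / "chrom.sizes")
    write_bed(truth.blacklist, out_dir / "blacklist.bed")
    summary = {"cells": {}, "motif": truth.config.motif, "seed": truth.config.seed}
    for cell in truth.cell_names:
        cdir = out_dir / cell
        cdir.mkdir(exist_ok=True)
        write_fragments(truth.fragments[cell], cdir / "atac.fragments.tsv")
        write_bed(truth.atac_peaks[cell], cdir / "atac_peaks.bed")
        write_bed(truth.chip_peaks[cell], cdir / "chip_peaks.bed")
        write_track(truth.chip_signal[cell], cdir / "chip_pval.bedgraph")
        summary["cells"][cell] = {
            "n_atac_peaks": len(truth.atac_peaks[cell]),
            "n_tfbs": len(truth.chip_peaks[cell]),
            "n_fragments": len(truth.fragments[cell]),
        }
    with open(out_dir / "truth.json", "w") as fh:
        json.dump(summary, fh, indent=1)


def build_cell_data(
    truth: FixtureTruth,
    cells: Optional[Sequence[str]] = None,
    percentile: float = 99.0,
):
    """Run the signal pipeline on each cell type's fragments and package
    the result as training-ready CellTypeData."""
    from .atac_signal import SignalConfig, prepare_signal
    from .training import CellTypeData

    config = SignalConfig(minmax_percentile=percentile)
    out = []
    for cell in cells or truth.cell_names:
        _, _, normed, _, _ = prepare_signal(
            truth.fragments[cell], truth.chrom_sizes, truth.blacklist, config
        )
        out.append(
            CellTypeData(
                name=cell,
                atac_track=normed,
                atac_peaks=truth.atac_peaks[cell],
                chip_peaks=truth.chip_peaks[cell],
                chip_signal=truth.chip_signal[cell],
            )
        )
    return out
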