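"""Training-example sampling and the model training loop.

Training examples are 1,024 bp windows pairing one-hot DNA sequence with a
cell type's normalized ATAC-seq signal, labeled per 32 bp bin against that
same cell type's ChIP-seq peaks (>50% bin overlap = positive).

Windows are drawn peak-centric by default: centered on intervals from the
"regions of interest" pool, the union of ATAC and ChIP peaks across all
training cell types. Under pan-cell sampling the cell type that supplies
signal AND labels is drawn uniformly from the training cell types,
independent of which cell type contributed the pool interval — so a region
bound in one cell type is equally likely to be shown with another cell
type's (possibly closed, unbound) accessibility, enriching hard negatives.

Chromosomes are split into disjoint train/validation/test sets so DNA
sequence is never shared across phases; the epoch with maximal validation
dice coefficient supplies the returned parameters.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .genomics_io import (
    ChromSizes,
    GenomicInterval,
    IntervalSet,
    SignalTrack,
    one_hot_encode,
)
from .model import ModelHandle, dice_coefficient
from . import nn

DEFAULT_TRAIN_CHROMS = (
    "chr3", "chr4", "chr5", "chr6", "chr7", "chr9", "chr10", "chr11",
    "chr13", "chr14", "chr15", "chr16", "chr17", "chr18", "chr20",
)
DEFAULT_VALIDATION_CHROMS = ("chr2", "chr19")
DEFAULT_TEST_CHROMS = ("chr1", "chr8")


@dataclass
class ChromosomeSplit:
    """Disjoint chromosome sets for training, validation and testing."""

    train: Tuple[str, ...] = DEFAULT_TRAIN_CHROMS
    validation: Tuple[str, ...] = DEFAULT_VALIDATION_CHROMS
    test: Tuple[str, ...] = DEFAULT_TEST_CHROMS

    def __post_init__(self):
        sets = [set(self.train), set(self.validation), set(self.test)]
        if sets[0] & sets[1] or sets[0] & sets[2] or sets[1] & sets[2]:
            raise ValueError("train/validation/test chromosome sets must be disjoint")

    def chroms_for(self, partition: str) -> Tuple[str, ...]:
        if partition not in ("train", "validation", "test"):
            raise ValueError(f"unknown partition {partition!r}")
        return getattr(self, partition)


@dataclass
class CellTypeData:
    """Per-cell-type training inputs: normalized accessibility + TF peaks."""

    name: str
    atac_track: SignalTrack  # minmax-normalized
    atac_peaks: IntervalSet
    chip_peaks: IntervalSet  # for the modeled TF
    chip_signal: Optional[SignalTrack] = None  # -log10 p-value, baseline use


@dataclass(frozen=True)
class RoiEntry:
    interval: GenomicInterval
    origin_cell: str
    origin_class: str  # "ATAC" | "ChIP"


@dataclass
class RoiPool:
    """Regions of interest: union of ATAC and ChIP peaks of every training
    cell type, restricted to one chromosome partition."""

    entries: List[RoiEntry]
    partition: str

    def __len__(self):
        return len(self.entries)


@dataclass
class TrainingExample:
    sequence: np.ndarray  # (4, window) one-hot
    signal: np.ndarray  # (window,) in [0, 1]
    labels: np.ndarray  # (bins,) binary
    cell_type: str
    window: GenomicInterval

    def model_input(self) -> np.ndarray:
        """Stack sequence and signal into the (5, window) model input."""
        return np.concatenate(
            [self.sequence, self.signal[None, :].astype(np.float32)], axis=0
        )


@dataclass
class TrainConfig:
    """Optimization and sampling configuration.

    Defaults follow the published regime (ADAM, lr 1e-3, 100 epochs of 100
    batches x 1000 examples, fully peak-centric pan-cell sampling);
    desk-scale runs shrink epochs/batches/batch_size.
    """

    optimizer: str = "adam"
    learning_rate: float = 0.001
    epochs: int = 100
    batch_size: int = 1000
    batches_per_epoch: int = 100
    random_ratio: float = 0.0  # 0 = fully peak-centric
    pan_cell: bool = True
    rc_augment: bool = False
    # Uniform window-center jitter around the peak center. Without jitter a
    # same-padded CNN learns the absolute in-window position of binding
    # (peaks always sit at the center during training but anywhere during
    # tiled prediction); 448 keeps the peak center inside a 1024 bp window.
    jitter_bp: int = 448
    seed: int = 0
    validation_examples: int = 512

    def __post_init__(self):
        if not 0 <= self.random_ratio <= 1:
            raise ValueError("random_ratio must be in [0, 1]")
        for v in (self.epochs, self.batch_size, self.batches_per_epoch):
            if v < 1:
                raise ValueError("epochs/batch_size/batches_per_epoch must be >= 1")


def make_labels(
    chip_peaks: IntervalSet, window: GenomicInterval, bin_width: int = 32
) -> np.ndarray:
    """Binary label per bin: positive iff the bin's bp overlap with the
    ChIP peak set strictly exceeds half the bin (>50%; exactly half is
    negative)."""
    if len(window) % bin_width:
        raise ValueError("window length must be divisible by bin_width")
    n_bins = len(window) // bin_width
    starts = window.start + bin_width * np.arange(n_bins)
    ends = starts + bin_width
    overlap = chip_peaks.overlap_bp(window.chrom, starts, ends)
    return (overlap > bin_width / 2).astype(np.float32)


def build_roi_pool(
    cell_types: Sequence[CellTypeData],
    split: ChromosomeSplit,
    partition: str,
    blacklist: IntervalSet = IntervalSet(),
) -> RoiPool:
    """Pool every ATAC and ChIP peak of every cell type on the partition's
    chromosomes, dropping blacklist-overlapping entries."""
    chroms = set(split.chroms_for(partition))
    entries: List[RoiEntry] = []
    for ct in cell_types:
        for origin_class, peaks in (("ATAC", ct.atac_peaks), ("ChIP", ct.chip_peaks)):
            for iv in peaks:
                if iv.chrom not in chroms:
                    continue
                if blacklist.overlap_bp(iv.chrom, [iv.start], [iv.end])[0] > 0:
                    continue
                entries.append(RoiEntry(iv, ct.name, origin_class))
    if not entries:
        raise ValueError(
            f"empty region-of-interest pool for partition {partition!r}; "
            "regenerate fixtures or check peak inputs"
        )
    return RoiPool(entries, partition)


def _clamp_window(center: int, length: int, chrom_len: int) -> Tuple[int, int]:
    start = center - length // 2
    start = min(max(start, 0), max(chrom_len - length, 0))
    return start, start + length


def sample_windows(
    pool: RoiPool,
    cell_types: Sequence[CellTypeData],
    split: ChromosomeSplit,
    chrom_sizes: ChromSizes,
    config: TrainConfig,
    n: int,
    rng: np.random.Generator,
    window_length: int = 1024,
    blacklist: IntervalSet = IntervalSet(),
) -> List[Tuple[GenomicInterval, str]]:
    """Draw n (window, cell_type) pairs.

    A fraction `random_ratio` of windows is uniform over the partition's
    chromosomes (length-weighted, blacklist-center-excluded); the rest are
    centered on a uniformly drawn pool interval. Under pan-cell sampling
    the cell type is uniform over all training cell types; otherwise it is
    the pool interval's origin cell type (random windows always draw a
    uniform cell type).
    """
    chroms = [c for c in split.chroms_for(pool.partition) if c in chrom_sizes]
    lengths = np.array([chrom_sizes[c] for c in chroms], dtype=np.float64)
    probs = lengths / lengths.sum()
    names = [ct.name for ct in cell_types]
    out: List[Tuple[GenomicInterval, str]] = []
    while len(out) < n:
        if rng.random() < config.random_ratio:
            ci = rng.choice(len(chroms), p=probs)
            chrom = chroms[ci]
            hi = max(chrom_sizes[chrom] - window_length, 1)
            start = int(rng.integers(0, hi))
            center = start + window_length // 2
            if blacklist.overlaps_point(chrom, [center])[0]:
                continue
            window = GenomicInterval(chrom, start, start + window_length)
            cell = names[rng.integers(len(names))]
        else:
            entry = pool.entries[rng.integers(len(pool.entries))]
            center = (entry.interval.start + entry.interval.end) // 2
            if config.jitter_bp:
                center += int(rng.integers(-config.jitter_bp, config.jitter_bp + 1))
            s, e = _clamp_window(center, window_length, chrom_sizes[entry.interval.chrom])
            window = GenomicInterval(entry.interval.chrom, s, e)
            cell = names[rng.integers(len(names))] if config.pan_cell else entry.origin_cell
        out.append((window, cell))
    return out


def materialize_example(
    genome: Dict[str, str],
    cell: CellTypeData,
    window: GenomicInterval,
    bin_width: int = 32,
) -> TrainingExample:
    seq = genome[window.chrom][window.start:window.end]
    signal = cell.atac_track.values[window.chrom][window.start:window.end]
    labels = make_labels(cell.chip_peaks, window, bin_width)
    return TrainingExample(
        sequence=one_hot_encode(seq),
        signal=signal.astype(np.float32),
        labels=labels,
        cell_type=cell.name,
        window=window,
    )


def sample_examples(
    pool: RoiPool,
    cell_types: Sequence[CellTypeData],
    split: ChromosomeSplit,
    genome: Dict[str, str],
    chrom_sizes: ChromSizes,
    config: TrainConfig,
    n: int,
    rng: np.random.Generator,
    window_length: int = 1024,
    bin_width: int = 32,
) -> List[TrainingExample]:
    by_name = {ct.name: ct for ct in cell_types}
    windows = sample_windows(
        pool, cell_types, split, chrom_sizes, config, n, rng, window_length
    )
    return [
        materialize_example(genome, by_name[cell], window, bin_width)
        for window, cell in windows
    ]


def reverse_complement_augment(example: TrainingExample) -> TrainingExample:
    """Reverse-complement the sequence (A<->T, C<->G channel swap + position
    reversal), reverse the signal and the labels. An involution."""
    seq = example.sequence[[3, 2, 1, 0], ::-1].copy()
    return TrainingExample(
        sequence=seq,
        signal=example.signal[::-1].copy(),
        labels=example.labels[::-1].copy(),
        cell_type=example.cell_type,
        window=example.window,
    )


def _batch_arrays(examples: Sequence[TrainingExample]):
    x = np.stack([ex.model_input() for ex in examples])
    y = np.stack([ex.labels for ex in examples])
    return x.astype(np.float32), y.astype(np.float32)


def train(
    model: ModelHandle,
    cell_types: Sequence[CellTypeData],
    split: ChromosomeSplit,
    config: TrainConfig,
    genome: Dict[str, str],
    chrom_sizes: ChromSizes,
    blacklist: IntervalSet = IntervalSet(),
) -> Tuple[ModelHandle, List[Dict[str, float]]]:
    """Train with Adam on binary cross-entropy; return the parameters of the
    epoch with maximal validation dice plus the per-epoch history.

    Validation examples are drawn once, peak-centric pan-cell on the
    validation chromosomes, and reused every epoch so dice values are
    comparable across epochs.
    """
    rng = np.random.default_rng(config.seed)
    window_length = model.spec.input_length
    bin_width = window_length // model.spec.output_bins

    train_pool = build_roi_pool(cell_types, split, "train", blacklist)
    val_pool = build_roi_pool(cell_types, split, "validation", blacklist)
    # validation examples mirror the training distribution (incl. jitter)
    # so dice-based epoch selection reflects deployment conditions
    val_config = TrainConfig(
        random_ratio=0.0, pan_cell=True, jitter_bp=config.jitter_bp,
        seed=config.seed, epochs=1, batch_size=1, batches_per_epoch=1,
    )
    val_examples = sample_examples(
        val_pool, cell_types, split, genome, chrom_sizes, val_config,
        config.validation_examples, rng, window_length, bin_width,
    )
    xv, yv = _batch_arrays(val_examples)

    optimizer = nn.Adam(model.net, lr=config.learning_rate)
    history: List[Dict[str, float]] = []
    best_dice = -np.inf
    best_state = model.net.copy_state()
    for epoch in range(1, config.epochs + 1):
        losses = []
        for _ in range(config.batches_per_epoch):
            examples = sample_examples(
                train_pool, cell_types, split, genome, chrom_sizes, config,
                config.batch_size, rng, window_length, bin_width,
            )
            if config.rc_augment:
                examples = examples + [reverse_complement_augment(e) for e in examples]
            x, y = _batch_arrays(examples)
            logits = model.forward_logits(x, training=True)
            loss, grad = nn.bce_with_logits(logits, y)
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"non-finite loss at epoch {epoch}; try a lower learning rate"
                )
            model.net.backward(grad[:, None, :])
            optimizer.step()
            losses.append(loss)
        val_pred = _predict_in_batches(model, xv)
        val_dice = dice_coefficient(val_pred, yv)
        val_aupr = _flat_aupr(val_pred.ravel(), yv.ravel())
        history.append(
            {"epoch": epoch, "loss": float(np.mean(losses)),
             "val_dice": val_dice, "val_aupr": val_aupr}
        )
        if val_dice > best_dice:
            best_dice = val_dice
            best_state = model.net.copy_state()
    model.net.load_state(best_state)
    return model, history


def _predict_in_batches(model: ModelHandle, x: np.ndarray, batch: int = 256) -> np.ndarray:
    preds = [model.predict(x[i:i + batch]) for i in range(0, len(x), batch)]
    return np.concatenate(preds, axis=0)


def _flat_aupr(scores: np.ndarray, labels: np.ndarray) -> float:
    """Average precision over flattened validation bins (0 if no positives)."""
    if labels.sum() == 0:
        return 0.0
    from sklearn.metrics import average_precision_score

    return float(average_precision_score(labels, scores))
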