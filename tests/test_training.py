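import numpy as np
import pytest

from atactf import fixtures, training
from atactf.genomics_io import ChromSizes, GenomicInterval, IntervalSet, SignalTrack
from atactf.model import ArchitectureSpec, build_model
from atactf.training import (
    CellTypeData,
    ChromosomeSplit,
    RoiPool,
    TrainConfig,
    build_roi_pool,
    make_labels,
    materialize_example,
    reverse_complement_augment,
    sample_examples,
    sample_windows,
)


class TestChromosomeSplit:
    def test_defaults_are_disjoint(self):
        split = ChromosomeSplit()
        assert "chr3" in split.train and split.validation == ("chr2", "chr19")
        assert split.test == ("chr1", "chr8")

    def test_overlapping_sets_rejected(self):
        with pytest.raises(ValueError):
            ChromosomeSplit(train=("chr1",), validation=("chr1",), test=("chr2",))


class TestMakeLabels:
    def window(self):
        return GenomicInterval("chr3", 1000, 2024)

    def test_bin_inside_peak_positive(self):
        peaks = IntervalSet([GenomicInterval("chr3", 1000, 1100)])
        labels = make_labels(peaks, self.window())
        assert labels[0] == 1 and labels.sum() == 3  # bins 0,1,2 fully/mostly in

    def test_exactly_half_overlap_is_negative(self):
        # peak covers exactly 16 bp of the first 32 bp bin
        peaks = IntervalSet([GenomicInterval("chr3", 1016, 1032)])
        assert make_labels(peaks, self.window())[0] == 0

    def test_seventeen_bp_overlap_is_positive(self):
        peaks = IntervalSet([GenomicInterval("chr3", 1015, 1032)])
        assert make_labels(peaks, self.window())[0] == 1

    def test_matches_brute_force_bp_counting(self, rng):
        for _ in range(20):
            starts = rng.integers(900, 2100, 5)
            peaks = IntervalSet(
                [GenomicInterval("chr3", int(s), int(s + rng.integers(5, 90)))
                 for s in starts]
            )
            covered = np.zeros(4000, dtype=bool)
            for p in peaks:
                covered[p.start:p.end] = True
            win = self.window()
            expected = [
                covered[s:s + 32].sum() > 16
                for s in range(win.start, win.end, 32)
            ]
            np.testing.assert_array_equal(make_labels(peaks, win), expected)


def _tiny_cells():
    cs = ChromSizes.from_dict({"chr1": 4000, "chr2": 4000, "chr3": 4000})
    track = SignalTrack({c: np.zeros(n) for c, n in cs.items()}, "minmax")
    a = CellTypeData(
        "A", track,
        IntervalSet([GenomicInterval("chr3", 100, 300),
                     GenomicInterval("chr1", 100, 300)]),
        IntervalSet([GenomicInterval("chr3", 500, 600)]),
    )
    b = CellTypeData(
        "B", track,
        IntervalSet([GenomicInterval("chr3", 1000, 1200)]),
        IntervalSet([GenomicInterval("chr2", 500, 600)]),
    )
    return cs, [a, b]


class TestRoiPool:
    def test_partition_restriction_and_origin_tags(self):
        cs, cells = _tiny_cells()
        pool = build_roi_pool(cells, ChromosomeSplit(), "train")
        # chr1 ATAC peak of A excluded (test chromosome); chr2 ChIP of B excluded
        assert len(pool) == 3
        assert {(e.origin_cell, e.origin_class) for e in pool.entries} == {
            ("A", "ATAC"), ("A", "ChIP"), ("B", "ATAC")
        }

    def test_blacklist_overlap_excluded(self):
        cs, cells = _tiny_cells()
        bl = IntervalSet([GenomicInterval("chr3", 550, 560)])
        pool = build_roi_pool(cells, ChromosomeSplit(), "train", bl)
        assert all(e.interval.start != 500 for e in pool.entries)

    def test_empty_pool_rejected(self):
        cs, cells = _tiny_cells()
        # cell A has peaks on chr1/chr3 only, so its validation pool is empty
        with pytest.raises(ValueError, match="empty"):
            build_roi_pool(cells[:1], ChromosomeSplit(), "validation")


class TestSampling:
    def test_origin_cell_when_not_pan_cell(self):
        cs, cells = _tiny_cells()
        pool = build_roi_pool(cells, ChromosomeSplit(), "train")
        cfg = TrainConfig(pan_cell=False, random_ratio=0.0, jitter_bp=0)
        rng = np.random.default_rng(0)
        windows = sample_windows(pool, cells, ChromosomeSplit(), cs, cfg, 200, rng,
                                 window_length=1024)
        origin_by_center = {}
        for e in pool.entries:
            c = (e.interval.start + e.interval.end) // 2
            origin_by_center.setdefault((e.interval.chrom, c), set()).add(e.origin_cell)
        for win, cell in windows:
            center_options = set()
            for (chrom, c), cells_at in origin_by_center.items():
                if chrom == win.chrom and win.start <= c < win.end:
                    center_options |= cells_at
            assert cell in center_options

    def test_windows_stay_on_partition_chromosomes(self):
        cs, cells = _tiny_cells()
        pool = build_roi_pool(cells, ChromosomeSplit(), "train")
        cfg = TrainConfig(random_ratio=0.5)
        rng = np.random.default_rng(1)
        windows = sample_windows(pool, cells, ChromosomeSplit(), cs, cfg, 300, rng,
                                 window_length=1024)
        assert {w.chrom for w, _ in windows} == {"chr3"}

    def test_labels_and_signal_share_cell_type(self, toy_truth, toy_cells):
        """Pan-cell pairs signal and labels jointly from one cell type."""
        split = ChromosomeSplit()
        pool = build_roi_pool(toy_cells, split, "train")
        cfg = TrainConfig(pan_cell=True)
        rng = np.random.default_rng(5)
        examples = sample_examples(
            pool, toy_cells, split, toy_truth.genome, toy_truth.chrom_sizes,
            cfg, 25, rng,
        )
        by_name = {c.name: c for c in toy_cells}
        for ex in examples:
            cell = by_name[ex.cell_type]
            np.testing.assert_allclose(
                ex.signal,
                cell.atac_track.values[ex.window.chrom][ex.window.start:ex.window.end],
                rtol=1e-6,  # examples hold float32 copies of the track
            )
            np.testing.assert_array_equal(
                ex.labels, make_labels(cell.chip_peaks, ex.window)
            )


class TestReverseComplement:
    def test_involution_and_channel_swap(self, toy_truth, toy_cells):
        split = ChromosomeSplit()
        pool = build_roi_pool(toy_cells, split, "train")
        rng = np.random.default_rng(2)
        ex = sample_examples(
            pool, toy_cells, split, toy_truth.genome, toy_truth.chrom_sizes,
            TrainConfig(), 1, rng,
        )[0]
        rc = reverse_complement_augment(ex)
        back = reverse_complement_augment(rc)
        np.testing.assert_array_equal(back.sequence, ex.sequence)
        np.testing.assert_array_equal(back.signal, ex.signal)
        np.testing.assert_array_equal(back.labels, ex.labels)
        # A-channel of forward equals reversed T-channel of the complement
        np.testing.assert_array_equal(rc.sequence[3], ex.sequence[0][::-1])

    def test_all_a_becomes_all_t(self):
        from atactf.genomics_io import one_hot_encode

        ex = training.TrainingExample(
            sequence=one_hot_encode("A" * 64),
            signal=np.zeros(64, dtype=np.float32),
            labels=np.zeros(2, dtype=np.float32),
            cell_type="x",
            window=GenomicInterval("chr3", 0, 64),
        )
        rc = reverse_complement_augment(ex)
        np.testing.assert_array_equal(rc.sequence, one_hot_encode("T" * 64))

    def test_label_reversal(self):
        labels = np.zeros(32, dtype=np.float32)
        labels[0] = 1
        ex = training.TrainingExample(
            sequence=np.zeros((4, 1024), dtype=np.float32),
            signal=np.zeros(1024, dtype=np.float32),
            labels=labels,
            cell_type="x",
            window=GenomicInterval("chr3", 0, 1024),
        )
        rc = reverse_complement_augment(ex)
        assert rc.labels[-1] == 1 and rc.labels.sum() == 1


class TestTrainLoop:
    def test_same_seed_identical_history(self, toy_truth, toy_cells):
        split = ChromosomeSplit()
        cfg = TrainConfig(epochs=2, batches_per_epoch=3, batch_size=16,
                          seed=4, validation_examples=32)
        hists = []
        for _ in range(2):
            model = build_model(ArchitectureSpec(base_filters=4), seed=4)
            _, hist = training.train(
                model, toy_cells[:2], split, cfg, toy_truth.genome,
                toy_truth.chrom_sizes, toy_truth.blacklist,
            )
            hists.append(hist)
        assert hists[0] == hists[1]

    def test_learning_progress_on_planted_motif(self, toy_truth, toy_cells):
        """Dice at the selected epoch beats epoch 1 on the toy fixture."""
        split = ChromosomeSplit()
        cfg = TrainConfig(epochs=6, batches_per_epoch=10, batch_size=64,
                          seed=0, validation_examples=128)
        model = build_model(ArchitectureSpec(base_filters=8), seed=0)
        _, hist = training.train(
            model, toy_cells[:2], split, cfg, toy_truth.genome,
            toy_truth.chrom_sizes, toy_truth.blacklist,
        )
        assert len(hist) == cfg.epochs
        best = max(h["val_dice"] for h in hist)
        assert best > hist[0]["val_dice"]

    def test_all_negative_labels_push_predictions_low(self, toy_truth, toy_cells):
        """With an empty gold standard the model converges to low scores."""
        split = ChromosomeSplit()
        empty = IntervalSet()
        cells = [
            CellTypeData(c.name, c.atac_track, c.atac_peaks, empty)
            for c in toy_cells[:2]
        ]
        # Adam's per-step displacement is ~learning_rate, so driving the
        # sigmoid output to near-0 needs enough steps x step size
        cfg = TrainConfig(epochs=6, batches_per_epoch=50, batch_size=16,
                          learning_rate=0.02, seed=1, validation_examples=64)
        model = build_model(ArchitectureSpec(base_filters=4), seed=1)
        model, _ = training.train(
            model, cells, split, cfg, toy_truth.genome, toy_truth.chrom_sizes,
        )
        pool = build_roi_pool(cells, split, "train")
        rng = np.random.default_rng(3)
        examples = sample_examples(
            pool, cells, split, toy_truth.genome, toy_truth.chrom_sizes,
            cfg, 32, rng,
        )
        x = np.stack([e.model_input() for e in examples])
        assert model.predict(x).mean() < 0.1
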