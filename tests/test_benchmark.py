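import numpy as np
import pytest

from atactf import benchmark
from atactf.benchmark import (
    Pwm,
    auprc,
    average_chip_baseline,
    bin_scores,
    evaluate,
    evaluate_track,
    label_bins,
    log2_fold_change,
    motif_rank_bins,
    pr_curve,
    precision_at_recall,
    pwm_scan,
    pwm_score_threshold,
    random_precision,
    read_meme_motifs,
)
from atactf.genomics_io import GenomicInterval, IntervalSet, SignalTrack


def brute_pr(scores, labels):
    """Independent recount of precision/recall at every unique positive
    score, straight from the definitions."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, bool)
    n_pos = labels.sum()
    thresholds = np.unique(scores[scores > 0])[::-1]
    precision, recall = [], []
    for t in thresholds:
        pred = scores >= t
        tp = (pred & labels).sum()
        precision.append(tp / pred.sum())
        recall.append(tp / n_pos)
    return thresholds, np.array(precision), np.array(recall)


def brute_auprc(curve):
    _, p, r = curve
    total, prev = 0.0, 0.0
    for pi, ri in zip(p, r):
        total += (ri - prev) * pi
        prev = ri
    return total


class TestBinning:
    def test_constant_track(self):
        t = SignalTrack({"c": np.full(1000, 0.3)})
        np.testing.assert_array_equal(bin_scores(t, "c"), np.full(5, 0.3))

    def test_single_spike(self):
        v = np.zeros(1000)
        v[457] = 0.9
        t = SignalTrack({"c": v})
        b = bin_scores(t, "c")
        assert b[2] == 0.9 and (b != 0).sum() == 1

    def test_trailing_partial_bin_dropped(self):
        t = SignalTrack({"c": np.ones(450)})
        assert len(bin_scores(t, "c")) == 2

    def test_matches_brute_force_max(self, rng):
        v = rng.random(2_000)
        t = SignalTrack({"c": v})
        got = bin_scores(t, "c")
        expected = [v[i * 200:(i + 1) * 200].max() for i in range(10)]
        np.testing.assert_allclose(got, expected)


class TestLabels:
    def test_one_bp_overlap_is_positive(self):
        peaks = IntervalSet([GenomicInterval("c", 399, 401)])
        starts = np.array([0, 200, 400])
        np.testing.assert_array_equal(
            label_bins(starts, 200, "c", peaks), [False, True, True]
        )

    def test_adjacent_half_open_is_negative(self):
        peaks = IntervalSet([GenomicInterval("c", 200, 400)])
        starts = np.array([0, 400])
        np.testing.assert_array_equal(
            label_bins(starts, 200, "c", peaks), [False, False]
        )

    def test_peak_spanning_three_bins(self):
        peaks = IntervalSet([GenomicInterval("c", 150, 550)])
        starts = np.arange(5) * 200
        assert label_bins(starts, 200, "c", peaks).sum() == 3


class TestPrCurve:
    def test_hand_enumerated_four_bins(self):
        curve = pr_curve([0.9, 0.8, 0.7, 0.6], [1, 0, 1, 0])
        t, p, r = curve
        assert p[-1] == 0.5 and r[-1] == 1.0
        assert auprc(curve) == pytest.approx(0.5 * 1.0 + 0.5 * (2 / 3))

    def test_perfect_ranking(self):
        curve = pr_curve([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0])
        assert auprc(curve) == 1.0
        t, p, r = curve
        assert p[1] == 1.0 and r[1] == 1.0

    def test_tied_scores_enter_together(self):
        t, p, r = pr_curve([0.5, 0.5], [1, 0])
        assert len(t) == 1 and p[0] == 0.5 and r[0] == 1.0

    def test_zero_positives_rejected(self):
        with pytest.raises(ValueError):
            pr_curve([0.5, 0.1], [0, 0])

    def test_oracle_equivalence_many_instances(self, rng):
        """Implementation matches a from-scratch recount on 120 random
        instances to 1e-9."""
        for _ in range(120):
            n = int(rng.integers(5, 80))
            scores = np.round(rng.random(n), 2)  # rounding forces ties
            labels = rng.random(n) < 0.3
            if labels.sum() == 0:
                labels[0] = True
            curve = pr_curve(scores, labels)
            bt, bp, br = brute_pr(scores, labels)
            np.testing.assert_allclose(curve[0], bt, atol=1e-12)
            np.testing.assert_allclose(curve[1], bp, atol=1e-9)
            np.testing.assert_allclose(curve[2], br, atol=1e-9)
            assert auprc(curve) == pytest.approx(brute_auprc(curve), abs=1e-9)
            assert random_precision(labels) == pytest.approx(
                labels.sum() / n, abs=1e-12
            )

    def test_auprc_matches_sklearn_average_precision(self, rng):
        from sklearn.metrics import average_precision_score

        for _ in range(20):
            scores = rng.uniform(0.01, 1.0, 200)
            labels = rng.random(200) < 0.15
            if labels.sum() == 0:
                labels[0] = True
            ours = auprc(pr_curve(scores, labels))
            theirs = average_precision_score(labels, scores)
            assert ours == pytest.approx(theirs, abs=1e-9)

    def test_random_scores_aupr_approaches_positive_fraction(self, rng):
        scores = rng.uniform(0.01, 1, 20_000)
        labels = rng.random(20_000) < 0.1
        a = auprc(pr_curve(scores, labels))
        assert abs(a - labels.mean()) < 0.02


class TestPrecisionAtRecall:
    def test_picks_first_crossing(self):
        curve = pr_curve([0.9, 0.8, 0.7, 0.6], [1, 0, 1, 0])
        assert precision_at_recall(curve, 0.05) == 1.0
        assert precision_at_recall(curve, 0.9) == pytest.approx(2 / 3)

    def test_unreachable_recall_rejected(self):
        t = np.array([0.9])
        curve = (t, np.array([1.0]), np.array([0.5]))
        with pytest.raises(ValueError):
            precision_at_recall(curve, 0.9)


class TestRandomPrecision:
    def test_basic_fraction(self):
        assert random_precision([1] * 5 + [0] * 95) == 0.05
        assert random_precision([1, 1]) == 1.0

    def test_excluded_bins_out_of_both_counts(self):
        v = np.zeros(2_000)
        v[:200] = 0.9
        track = SignalTrack({"c": v})
        gold = IntervalSet([GenomicInterval("c", 0, 200)])
        bl = IntervalSet([GenomicInterval("c", 400, 600)])
        ev = evaluate_track(track, gold, ["c"], bl)
        scores, labels = ev.kept()
        assert len(labels) == 9  # 10 bins minus 1 excluded
        assert random_precision(labels) == pytest.approx(1 / 9)


class TestLog2FoldChange:
    @pytest.mark.parametrize(
        "a,b,expected", [(0.4, 0.4, 0.0), (0.3, 0.1, 1.0), (0.0, 0.0, 0.0)]
    )
    def test_pseudocounted_ratio(self, a, b, expected):
        assert log2_fold_change(a, b) == pytest.approx(expected)


def consensus_pwm(consensus="ACGT", certainty=1.0):
    mat = np.full((len(consensus), 4), (1 - certainty) / 3)
    for i, base in enumerate(consensus):
        mat[i, "ACGT".index(base)] = certainty
    return Pwm("test", mat)


class TestPwmScan:
    def test_consensus_hits_by_exhaustive_enumeration(self):
        """At p=1e-2 a 4-mer consensus PWM hits exactly its consensus (and
        reverse-complement) occurrences: match probability 4^-4 < 1e-2 and
        any mismatch is too likely."""
        pwm = consensus_pwm("ACGT")
        threshold = pwm_score_threshold(pwm, 1e-2)
        lo = benchmark._discretized_log_odds(pwm, 1e-3) * 1e-3
        # full enumeration of all 256 4-mers
        passing = []
        for code in range(256):
            kmer = [(code >> (2 * i)) & 3 for i in range(4)]
            score = sum(lo[i, b] for i, b in enumerate(kmer))
            if score >= threshold - 1e-12:
                passing.append("".join("ACGT"[b] for b in kmer))
        assert passing == ["ACGT"]

    def test_p_1e5_unattainable_for_4mer(self):
        """Minimum possible p-value of a 4-mer match is 4^-4 > 1e-5, so no
        threshold exists and scanning returns no hits."""
        pwm = consensus_pwm("ACGT")
        assert pwm_score_threshold(pwm, 1e-5) == float("inf")
        seqs = [(GenomicInterval("c", 0, 12), "AAAACGTAAAAA")]
        assert len(pwm_scan(seqs, pwm, 1e-5)) == 0

    def test_scan_finds_planted_occurrences_both_strands(self):
        pwm = consensus_pwm("ACGG")
        #            ACGG at 2          CCGT = revcomp(ACGG) at 10
        seq = "TTACGGTTTTCCGTTT"
        hits = pwm_scan([(GenomicInterval("c", 100, 116), seq)], pwm, 1e-2)
        assert {(h.start, h.strand) for h in hits} == {(102, "+"), (110, "-")}

    def test_exact_duplicate_coordinates_removed(self):
        # palindromic consensus matches both strands at one locus
        pwm = consensus_pwm("ACGT")
        hits = pwm_scan([(GenomicInterval("c", 0, 8), "TTACGTTT")], pwm, 1e-2)
        assert len(hits) == 1

    def test_uniform_pwm_never_hits(self):
        pwm = Pwm("flat", np.full((4, 4), 0.25))
        assert pwm_score_threshold(pwm, 0.5) == float("inf")

    def test_meme_minimal_round_trip(self, tmp_path):
        meme = (
            "MEME version 4\n\nALPHABET= ACGT\n\nstrands: + -\n\n"
            "Background letter frequencies\nA 0.25 C 0.25 G 0.25 T 0.25\n\n"
            "MOTIF m1\nletter-probability matrix: alength= 4 w= 3 nsites= 10 E= 0\n"
            " 0.9 0.05 0.03 0.02\n 0.1 0.8 0.05 0.05\n 0.25 0.25 0.25 0.25\n"
        )
        p = tmp_path / "m.meme"
        p.write_text(meme)
        pwms = read_meme_motifs(p)
        assert len(pwms) == 1 and len(pwms[0]) == 3
        assert pwms[0].matrix[0, 0] == pytest.approx(0.9, abs=1e-6)


class TestMotifRankBins:
    def test_counting_and_straddling(self):
        hits = IntervalSet([
            GenomicInterval("c", 10, 18),
            GenomicInterval("c", 30, 38),
            GenomicInterval("c", 195, 205),  # straddles bins 0 and 1
        ])
        starts = np.array([0, 200, 400])
        counts = motif_rank_bins(hits, starts, 200, "c")
        np.testing.assert_array_equal(counts, [3, 1, 0])

    def test_no_hits_all_zero(self):
        counts = motif_rank_bins(IntervalSet(), np.array([0, 200]), 200, "c")
        np.testing.assert_array_equal(counts, [0, 0])


class TestAverageChip:
    def test_single_track_is_arcsinh(self):
        t = SignalTrack({"c": np.array([0.0, 1.0, 5.0])})
        out = average_chip_baseline([t]).values["c"]
        assert out[0] == 0.0
        assert out[1] == pytest.approx(np.log(1 + np.sqrt(2)))
        np.testing.assert_allclose(out, np.arcsinh(t.values["c"]))

    def test_mean_across_cell_types(self, rng):
        tracks = [SignalTrack({"c": rng.random(50) * 10}) for _ in range(3)]
        out = average_chip_baseline(tracks).values["c"]
        expected = np.mean([np.arcsinh(t.values["c"]) for t in tracks], axis=0)
        np.testing.assert_allclose(out, expected)

    def test_baseline_ranks_true_sites_well(self, toy_truth):
        """Averaged training-cell ChIP ranks a held-out cell's shared sites
        above background (AUPR above random)."""
        cells = toy_truth.cell_names
        baseline = average_chip_baseline(
            [toy_truth.chip_signal[c] for c in cells[:2]]
        )
        m = evaluate(baseline, toy_truth.chip_peaks[cells[2]], ["chr1"],
                     toy_truth.blacklist)
        assert m["aupr"] > 2 * m["random_precision"]
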