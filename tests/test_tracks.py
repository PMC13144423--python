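"""Homopolymer runs, non-overlapping motif counts, window frequencies and
poly-tract anchors."""

import itertools

import numpy as np
import pytest
from scipy import stats

import polvterm as pv
from polvterm.tracks import extract_window_sequences

Run = pv.RunAnnotation


class TestFindRuns:
    @pytest.mark.parametrize(
        "seq,min_length,expected",
        [
            ("AAATTG", 3, [Run("A", 0, 3)]),
            ("AAATTG", 2, [Run("A", 0, 3), Run("T", 3, 2)]),
            ("ANAAA", 3, [Run("A", 2, 3)]),  # N breaks runs and never forms one
            ("NNNN", 1, []),
            ("", 1, []),
        ],
    )
    def test_maximal_runs(self, seq, min_length, expected):
        assert pv.find_runs(seq, min_length) == expected

    def test_runs_disjoint_and_cover_maximal_segments(self):
        rng = np.random.default_rng(5)
        seq = "".join(rng.choice(list("ACGTN"), size=300))
        runs = pv.find_runs(seq, 1)
        # disjoint and ascending
        for a, b in zip(runs, runs[1:]):
            assert a.start + a.length <= b.start
        # every non-N position covered by exactly one run of its own base
        covered = {}
        for r in runs:
            for p in range(r.start, r.start + r.length):
                assert p not in covered
                covered[p] = r.base
        for p, b in enumerate(seq):
            if b != "N":
                assert covered[p] == b


class TestCountNonOverlapping:
    @pytest.mark.parametrize(
        "seq,base,length,expected",
        [("TTTT", "T", 2, 2), ("TTTTT", "T", 2, 2), ("TTATT", "T", 3, 0)],
    )
    def test_examples(self, seq, base, length, expected):
        assert pv.count_nonoverlapping(seq, base, length) == expected

    def test_exhaustive_matches_greedy_scan(self):
        """floor(run/l) equals a literal greedy left-to-right scan for every
        {A,T} sequence up to length 12."""

        def greedy(seq, base, ell):
            count = i = 0
            while i + ell <= len(seq):
                if seq[i : i + ell] == base * ell:
                    count += 1
                    i += ell
                else:
                    i += 1
            return count

        for n in range(0, 13):
            for chars in itertools.product("AT", repeat=n):
                seq = "".join(chars)
                for ell in (2, 3):
                    assert pv.count_nonoverlapping(seq, "T", ell) == greedy(seq, "T", ell), seq

    def test_exact_mode_counts_maximal_runs_of_exact_length(self):
        assert pv.count_nonoverlapping("TTTTT", "T", 5, mode="exact") == 1
        assert pv.count_nonoverlapping("TTTTT", "T", 2, mode="exact") == 0


class TestWindowFrequencies:
    def test_single_motif_per_window(self, tmp_path):
        genome = pv.GenomeSequence(["c1"], {"c1": "AC" * 10 + "TTT" + "CA" * 10 + "GGTTTGG" + "C" * 10})
        w1 = pv.StrandedInterval("c1", 17, 27, "+")  # contains the first TTT
        w2 = pv.StrandedInterval("c1", 40, 50, "+")  # contains the second TTT
        table = pv.window_track_frequencies(genome, [w1, w2], lengths=[3], bases="T")
        row = table.iloc[0]
        assert (row["count"], row["n_windows"], row["frequency"]) == (2, 2, 1.0)

    def test_all_g_genome_zero_frequencies(self):
        genome = pv.GenomeSequence(["c1"], {"c1": "G" * 200})
        windows = [pv.StrandedInterval("c1", i, i + 40, "+") for i in (0, 50, 100)]
        table = pv.window_track_frequencies(genome, windows, bases="ACT")
        assert (table["frequency"] == 0).all()

    def test_matches_per_window_recount(self):
        rng = np.random.default_rng(7)
        seq = "".join(rng.choice(list("ACGT"), size=5000, p=[0.3, 0.2, 0.2, 0.3]))
        genome = pv.GenomeSequence(["c1"], {"c1": seq})
        starts = rng.integers(0, 5000 - 40, size=50)
        strands = rng.choice(["+", "-"], size=50)
        windows = [pv.StrandedInterval("c1", int(s), int(s) + 40, st) for s, st in zip(starts, strands)]
        table = pv.window_track_frequencies(genome, windows)
        seqs, _ = extract_window_sequences(genome, windows)
        for _, row in table.iterrows():
            recount = sum(
                pv.count_nonoverlapping(s, row["base"], int(row["length"])) for s in seqs
            )
            assert row["count"] == recount
            assert row["frequency"] == recount / len(seqs)

    def test_strand_awareness_via_reverse_complement(self):
        rng = np.random.default_rng(9)
        seq = "".join(rng.choice(list("ACGT"), size=500))
        genome = pv.GenomeSequence(["c1"], {"c1": seq})
        rc_genome = pv.GenomeSequence(["c1"], {"c1": pv.reverse_complement(seq)})
        minus = [pv.StrandedInterval("c1", 100, 140, "-")]
        plus_on_rc = [pv.StrandedInterval("c1", 500 - 140, 500 - 100, "+")]
        t1 = pv.window_track_frequencies(genome, minus)
        t2 = pv.window_track_frequencies(rc_genome, plus_on_rc)
        assert t1.equals(t2)

    def test_out_of_bounds_windows_dropped(self):
        genome = pv.GenomeSequence(["c1"], {"c1": "A" * 100})
        windows = [
            pv.StrandedInterval("c1", 0, 40, "+"),
            pv.StrandedInterval("c1", 80, 120, "+"),  # overruns
        ]
        table = pv.window_track_frequencies(genome, windows, lengths=[2], bases="A")
        assert (table["n_windows"] == 1).all()

    def test_empty_window_set_rejected(self, toy_genome):
        with pytest.raises(ValueError):
            pv.window_track_frequencies(toy_genome, [])


class TestTesWindows:
    def test_centred_on_tes_both_strands(self):
        plus = pv.Transcript(pv.StrandedInterval("c1", 100, 200, "+"), "a")
        minus = pv.Transcript(pv.StrandedInterval("c1", 100, 200, "-"), "b")
        (wp,) = pv.tes_windows([plus])
        (wm,) = pv.tes_windows([minus])
        # + strand TES=199: window covers relative offsets -20..+19
        assert (wp.start, wp.end) == (179, 219)
        # - strand TES=100: mirrored in transcription direction
        assert (wm.start, wm.end) == (81, 121)


class TestBodyWindows:
    def test_transcript_length_equal_width_single_window(self):
        tx = pv.Transcript(pv.StrandedInterval("c1", 10, 50, "+"), "a")
        for seed in range(5):
            (w,) = pv.sample_body_windows([tx], width=40, seed=seed)
            assert (w.start, w.end) == (10, 50)

    def test_deterministic_under_seed(self):
        tx = pv.Transcript(pv.StrandedInterval("c1", 0, 1000, "+"), "a")
        a = pv.sample_body_windows([tx], n_per_transcript=20, seed=3)
        b = pv.sample_body_windows([tx], n_per_transcript=20, seed=3)
        assert a == b

    def test_windows_inside_body_and_away_from_tes(self):
        tx = pv.Transcript(pv.StrandedInterval("c1", 100, 600, "-"), "a")
        windows = pv.sample_body_windows([tx], width=40, n_per_transcript=200, seed=1)
        for w in windows:
            assert 100 <= w.start and w.end <= 600
            centre = (w.start + w.end) / 2
            assert abs(tx.tes - centre) >= 20

    def test_starts_approximately_uniform(self):
        tx = pv.Transcript(pv.StrandedInterval("c1", 0, 141, "+"), "a")
        # valid starts are 0..100 (length-1-width)
        windows = pv.sample_body_windows([tx], width=40, n_per_transcript=5000, seed=2)
        starts = np.array([w.start for w in windows])
        observed = np.bincount(starts, minlength=101)
        assert stats.chisquare(observed).pvalue > 0.01

    def test_short_transcripts_skipped(self):
        tx = pv.Transcript(pv.StrandedInterval("c1", 0, 30, "+"), "a")
        assert pv.sample_body_windows([tx], width=40, seed=0) == []


class TestPolytractAnchor:
    def test_longest_qualifying_run_wins(self):
        seq = "CC" + "T" * 6 + "CC" + "T" * 8 + "CC"
        assert pv.locate_polytract_anchor(seq, "T") == 10

    def test_absent_when_no_run_long_enough(self):
        assert pv.locate_polytract_anchor("TTTTTCTTTTT", "T") is None  # runs of 5 only

    def test_tie_breaks_leftmost_vs_exhaustive_scan(self):
        rng = np.random.default_rng(13)
        for _ in range(50):
            seq = "".join(rng.choice(list("AT"), size=60, p=[0.4, 0.6]))
            result = pv.locate_polytract_anchor(seq, "T")
            runs = [r for r in pv.find_runs(seq, 1) if r.base == "T" and r.length >= 6]
            if not runs:
                assert result is None
            else:
                best_len = max(r.length for r in runs)
                assert result == min(r.start for r in runs if r.length == best_len)
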