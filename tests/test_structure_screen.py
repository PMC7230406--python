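"""Windowing, z-score, SCI, window classification and locus merging."""

from __future__ import annotations

import numpy as np
import pytest

from lncscreen.candidate_discovery import AlignmentBlock, REFERENCE_SPECIES
from lncscreen.genome_io import GenomicInterval
from lncscreen.structure_screen import (
    NcrnaLocus,
    Window,
    WindowScore,
    classify_window,
    merge_positive_windows,
    read_rnaz_text,
    read_rnaz_tsv,
    structure_conservation_index,
    tile_windows,
    zscore,
)
from lncscreen.thermo import dinucleotide_shuffle


def _block(span: int, n_rows: int = 3, seed: int = 0) -> AlignmentBlock:
    rng = np.random.default_rng(seed)
    seq = "".join(rng.choice(list("ACGT"), span))
    rows = [(REFERENCE_SPECIES, seq)] + [
        (f"sp{i}", seq) for i in range(n_rows - 1)]
    return AlignmentBlock("b", GenomicInterval("chr1", 1000, 1000 + span),
                          "intron", rows=rows, mean_pairwise_identity=1.0)


class TestTiling:
    def test_span_400_gives_8_windows(self):
        # span 400 is the oversized boundary: tiles into exactly 8 windows
        wins400 = tile_windows(_block(400))
        assert len(wins400) == 8
        starts = [w.reference_interval.start - 1000 for w in wins400]
        assert starts == [0, 40, 80, 120, 160, 200, 240, 280]
        # span 401: 8 grid windows + 1 end-anchored remainder
        assert len(tile_windows(_block(401))) == 9
        # span 399: a single full-span window
        assert len(tile_windows(_block(399))) == 1

    def test_oversized_grid(self):
        wins = tile_windows(_block(480))
        starts = [w.reference_interval.start - 1000 for w in wins]
        assert starts == [0, 40, 80, 120, 160, 200, 240, 280, 320, 360]
        assert all(len(w.reference_interval) == 120 for w in wins)

    def test_span_300_single_window(self):
        wins = tile_windows(_block(300))
        assert len(wins) == 1
        assert len(wins[0].reference_interval) == 300

    def test_end_anchored_remainder(self):
        wins = tile_windows(_block(401))
        last = wins[-1].reference_interval
        assert (last.start - 1000, last.end - 1000) == (281, 401)

    @pytest.mark.parametrize("span", [405, 430, 487, 520, 561, 799])
    def test_window_invariants_random_spans(self, span):
        wins = tile_windows(_block(span, seed=span))
        starts = [w.reference_interval.start for w in wins]
        for w in wins:
            assert len(w.reference_interval) <= 120
        grid = starts[:-1] if starts[-1] - starts[-2] != 40 else starts
        assert all(b - a == 40 for a, b in zip(grid, grid[1:]))
        assert wins[-1].reference_interval.end == 1000 + span

    def test_windows_map_back_through_gaps(self):
        seq = "ACGTACGTACGTACGTACGTACGTACGTACGTACGTACGTACGTACGTACGT"
        gapped_ref = seq[:20] + "-" * 5 + seq[20:]
        other = seq[:20] + "TTTTT" + seq[20:]
        block = AlignmentBlock(
            "b", GenomicInterval("chr1", 0, len(seq)), "intron",
            rows=[(REFERENCE_SPECIES, gapped_ref), ("sp1", other)])
        [win] = tile_windows(block)
        assert win.reference_sequence == seq
        assert len(win.rows[0][1]) == len(win.rows[1][1])


class TestZscore:
    def test_null_calibration(self):
        # scoring a shuffled sequence against its own shuffle null gives a
        # standardized score: mean ~ 0, sd ~ 1, |z| < 2 in >= 95% of trials
        rng = np.random.default_rng(0)
        zs = []
        for _ in range(120):
            seq = "".join(rng.choice(list("ACGU"), 120))
            seq = dinucleotide_shuffle(seq, rng)
            zs.append(zscore(seq, n_shuffles=100, rng=rng))
        zs = np.array(zs)
        assert abs(zs.mean()) < 0.3
        assert 0.7 < zs.std() < 1.4
        assert np.mean(np.abs(zs) < 2) >= 0.95

    def test_planted_hairpin_strongly_negative(self):
        rng = np.random.default_rng(1)
        comp = str.maketrans("ACGU", "UGCA")
        arm = "".join(rng.choice(list("ACGU"), 30))
        seq = arm + "GAAA" + arm.translate(comp)[::-1]
        z = zscore(seq, n_shuffles=100, rng=rng)
        assert z < -2

    def test_too_short_warns_zero(self):
        rng = np.random.default_rng(0)
        with pytest.warns(UserWarning):
            assert zscore("ACG", n_shuffles=30, rng=rng) == 0.0

    def test_requires_minimum_shuffles(self):
        with pytest.raises(ValueError, match="30"):
            zscore("ACGUACGUACGU", n_shuffles=10)


class TestSci:
    def test_identical_rows_unity(self):
        assert structure_conservation_index(-10.0, [-10.0, -10.0]) == \
            pytest.approx(1.0, abs=1e-9)

    def test_zero_individual_energy_clamped(self):
        assert structure_conservation_index(-5.0, [0.0, 0.0]) == 0.0

    def test_nonnegative(self):
        assert structure_conservation_index(0.0, [-8.0]) >= 0.0


class TestClassifier:
    def test_strong_signal_high_confidence(self):
        assert classify_window(z=-4.0, sci=1.0, identity=0.9) > 0.9

    def test_negative_window(self):
        assert classify_window(z=2.0, sci=0.2, identity=0.9) < 0.5

    def test_calibration_point(self):
        from lncscreen.structure_screen import LOGIT_I0, LOGIT_S0

        assert classify_window(0.0, LOGIT_S0, LOGIT_I0) == pytest.approx(0.5)

    def test_monotone_in_minus_z_and_sci(self):
        zs = np.linspace(-6, 6, 13)
        ps = [classify_window(z, 1.0, 0.8) for z in zs]
        assert all(a >= b for a, b in zip(ps, ps[1:]))
        scis = np.linspace(0, 1.5, 10)
        ps = [classify_window(-1.0, s, 0.8) for s in scis]
        assert all(a <= b for a, b in zip(ps, ps[1:]))


def _score(start, end, p, block="b", category="intron"):
    win = Window(block, GenomicInterval("chr1", start, end), (0, end - start),
                 [(REFERENCE_SPECIES, "A" * (end - start))], category)
    return WindowScore(win, [0.0], 0.0, 0.0, 0.0, 1.0, p)


class TestMerging:
    def test_overlapping_positive_windows_merge(self):
        loci = merge_positive_windows([_score(0, 120, 0.6),
                                       _score(40, 160, 0.95)])
        assert len(loci) == 1
        locus = loci[0]
        assert (locus.interval.start, locus.interval.end) == (0, 160)
        assert locus.probability == pytest.approx(0.95)
        assert locus.high_confidence
        assert locus.n_windows == 2

    def test_disjoint_windows_two_loci(self):
        loci = merge_positive_windows([_score(0, 120, 0.7),
                                       _score(200, 320, 0.8)])
        assert len(loci) == 2

    def test_no_positive_windows(self):
        assert merge_positive_windows([_score(0, 120, 0.5),
                                       _score(40, 160, 0.3)]) == []

    def test_touching_windows_merge(self):
        loci = merge_positive_windows([_score(0, 120, 0.6),
                                       _score(120, 240, 0.7)])
        assert len(loci) == 1

    @pytest.mark.parametrize("seed", range(4))
    def test_merge_invariants_random_sets(self, seed):
        rng = np.random.default_rng(seed)
        scores = []
        for _ in range(250):
            start = int(rng.integers(0, 5000))
            scores.append(_score(start, start + 120,
                                 float(rng.uniform(0.0, 1.0))))
        loci = merge_positive_windows(scores)
        # disjoint, sorted, P = max of members, members all covered
        for a, b in zip(loci, loci[1:]):
            assert a.interval.end < b.interval.start
        for locus in loci:
            members = [s for s in scores if s.probability > 0.5
                       and s.window.reference_interval.overlaps(locus.interval)]
            assert members
            assert locus.probability == pytest.approx(
                max(s.probability for s in members))
            assert all(locus.probability >= s.probability for s in members)
        # every positive window is inside exactly one locus
        for s in scores:
            if s.probability > 0.5:
                containing = [l for l in loci
                              if l.interval.contains(s.window.reference_interval)]
                assert len(containing) == 1

    def test_locus_probability_bounds(self):
        with pytest.raises(ValueError):
            NcrnaLocus("x", GenomicInterval("c", 0, 10), probability=0.5,
                       n_windows=1, category="intron", sci=1.0, zscore=0.0)


class TestRnazImport:
    def test_text_passthrough(self, tmp_path):
        p = tmp_path / "rnaz.out"
        p.write_text(
            "\n Prediction: RNA\n Probability: 0.981234\n"
            "\n Prediction: OTHER\n Probability: 0.120000\n")
        records = read_rnaz_text(p)
        assert [r["probability"] for r in records] == [0.981234, 0.12]
        assert [r["prediction"] for r in records] == ["RNA", "OTHER"]

    def test_tsv_dialect(self, tmp_path):
        p = tmp_path / "rnaz.tsv"
        p.write_text("block_id\tstart\tend\tprobability\nb1\t0\t120\t0.93\n")
        [rec] = read_rnaz_tsv(p)
        assert rec["probability"] == 0.93
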