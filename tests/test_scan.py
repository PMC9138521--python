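"""MATCH-style scoring: information weights, core location, similarity scores,
scanning, and equivalence with the brute-force oracle."""

import math

import numpy as np
import pytest

from oracle import oracle_prepare, oracle_scan, oracle_score

from conftest import random_counts, random_seq
from rsnpscan.scan import prepare, scan_library, scan_sequence, score_window
from rsnpscan.types import Pwm, revcomp


def pwm_from_counts(counts, core=0.0, matrix=0.0, pwm_id="P$X_01", core_start=None):
    return Pwm(pwm_id, np.asarray(counts, dtype=float), core, matrix, core_start=core_start)


class TestPrepare:
    def test_uniform_row_zero_information(self):
        spwm = prepare(pwm_from_counts([[1, 1, 1, 1]] * 5))
        assert np.allclose(spwm.info, 0.0)
        assert np.allclose(spwm.freqs, 0.25)

    def test_degenerate_row_approaches_ln4(self):
        counts = [[10_000, 0, 0, 0]] * 5
        spwm = prepare(pwm_from_counts(counts), pseudocount=1e-9)
        assert spwm.info[0] == pytest.approx(math.log(4), abs=1e-5)

    def test_core_is_max_information_window(self):
        # informative positions 1..4, weak ends -> best 5-window starts at 1
        counts = [[1, 1, 1, 1]] + [[50, 0, 0, 0]] * 4 + [[2, 1, 1, 1]]
        spwm = prepare(pwm_from_counts(counts))
        sums = [spwm.info[i : i + 5].sum() for i in range(2)]
        assert spwm.core_start == int(np.argmax(sums)) == 1

    def test_leftmost_on_ties(self):
        spwm = prepare(pwm_from_counts([[10, 0, 0, 0]] * 8))
        assert spwm.core_start == 0

    def test_annotated_core_overrides(self):
        spwm = prepare(pwm_from_counts([[10, 0, 0, 0]] * 8, core_start=2))
        assert spwm.core_start == 2

    def test_zero_rows_need_pseudocount(self):
        with pytest.raises(ValueError, match="pseudocount"):
            prepare(pwm_from_counts([[0, 0, 0, 0]] * 5), pseudocount=0.0)

    def test_rows_are_stochastic(self):
        rng = np.random.default_rng(7)
        spwm = prepare(pwm_from_counts(random_counts(rng, 9)))
        assert np.allclose(spwm.freqs.sum(axis=1), 1.0, atol=1e-12)
        assert (spwm.info >= 0).all()


class TestScoreWindow:
    def test_consensus_scores_one(self):
        rng = np.random.default_rng(11)
        counts = random_counts(rng, 7) + 1
        spwm = prepare(pwm_from_counts(counts))
        consensus = "".join("ACGT"[i] for i in counts.argmax(axis=1))
        core, matrix = score_window(spwm, consensus)
        assert matrix == pytest.approx(1.0, abs=1e-12)
        assert core == pytest.approx(1.0, abs=1e-12)

    def test_anticonsensus_scores_zero(self):
        rng = np.random.default_rng(12)
        counts = random_counts(rng, 7) + 1
        spwm = prepare(pwm_from_counts(counts))
        anti = "".join("ACGT"[i] for i in counts.argmin(axis=1))
        core, matrix = score_window(spwm, anti)
        assert matrix == pytest.approx(0.0, abs=1e-12)

    def test_uninformative_matrix_scores_one(self):
        spwm = prepare(pwm_from_counts([[3, 3, 3, 3]] * 6))
        assert score_window(spwm, "ACGTAC") == (1.0, 1.0)

    def test_wrong_window_length(self):
        spwm = prepare(pwm_from_counts([[1, 0, 0, 0]] * 6))
        with pytest.raises(ValueError, match="length"):
            score_window(spwm, "ACGT")

    def test_matches_oracle_on_random_8mers(self):
        rng = np.random.default_rng(13)
        counts = random_counts(rng, 8)
        spwm = prepare(pwm_from_counts(counts))
        for _ in range(50):
            window = random_seq(rng, 8)
            got = score_window(spwm, window)
            want = oracle_score(counts.tolist(), 0.8, window)
            assert got == pytest.approx(want, abs=1e-12)


class TestScanSequence:
    def test_planted_consensus_found_once(self):
        rng = np.random.default_rng(21)
        counts = np.zeros((6, 4))
        for i, b in enumerate("TATAAA"):
            counts[i, "ACGT".index(b)] = 10
        spwm = prepare(pwm_from_counts(counts, core=0.75, matrix=0.85, pwm_id="P$TATA_01"))
        # C/G background cannot contain TATAAA by chance
        seq = "".join(rng.choice(list("CG"), size=51))
        seq = seq[:20] + "TATAAA" + seq[26:]
        matches = [m for m in scan_sequence(spwm, seq) if m.matrix_score > 0.999]
        assert len(matches) == 1
        m = matches[0]
        assert (m.seq_offset, m.orientation) == (20, "forward")
        assert m.matrix_score == pytest.approx(1.0, abs=1e-12)
        assert m.site_seq == "TATAA" + "a"  # 5-position core upper-case

    def test_strand_symmetry(self):
        rng = np.random.default_rng(22)
        counts = random_counts(rng, 7)
        spwm = prepare(pwm_from_counts(counts, core=0.3, matrix=0.3))
        seq = random_seq(rng, 51)
        fwd = scan_sequence(spwm, seq)
        rev = scan_sequence(spwm, revcomp(seq))
        flip = {"forward": "reverse", "reverse": "forward"}
        as_set = lambda ms: {
            (round(m.core_score, 12), round(m.matrix_score, 12), m.orientation)
            for m in ms
        }
        mirrored = {
            (c, s, flip[o]) for (c, s, o) in as_set(rev)
        }
        assert as_set(fwd) == mirrored
        # offsets mirror too: offset' = 51 - width - offset
        assert sorted(51 - 7 - m.seq_offset for m in rev) == sorted(
            m.seq_offset for m in fwd
        )

    def test_impossible_cutoffs_give_empty(self):
        counts = [[10, 0, 0, 0]] * 6  # consensus AAAAAA, absent from background
        spwm = prepare(pwm_from_counts(counts, core=1.0, matrix=1.0))
        assert scan_sequence(spwm, "CG" * 25 + "C") == []

    def test_cutoff_monotonicity(self):
        rng = np.random.default_rng(23)
        counts = random_counts(rng, 6)
        seq = random_seq(rng, 51)
        keys = None
        for cut in (0.0, 0.25, 0.5, 0.75, 0.9, 1.0):
            spwm = prepare(pwm_from_counts(counts, core=cut, matrix=cut))
            got = {(m.seq_offset, m.orientation) for m in scan_sequence(spwm, seq)}
            if keys is not None:
                assert got <= keys
            keys = got

    def test_scores_at_least_cutoff(self):
        rng = np.random.default_rng(24)
        counts = random_counts(rng, 5)
        spwm = prepare(pwm_from_counts(counts, core=0.4, matrix=0.5))
        for m in scan_sequence(spwm, random_seq(rng, 51)):
            assert m.core_score >= 0.4 and m.matrix_score >= 0.5
            assert m.core_score <= 1.0 and m.matrix_score <= 1.0

    def test_exhaustive_oracle_equivalence(self):
        rng = np.random.default_rng(25)
        for _ in range(20):
            width = int(rng.integers(5, 13))
            counts = random_counts(rng, width)
            seq = random_seq(rng, 51)
            spwm = prepare(pwm_from_counts(counts))  # zero cutoffs: all emitted
            got = {
                (m.seq_offset, m.orientation): (m.core_score, m.matrix_score)
                for m in scan_sequence(spwm, seq)
            }
            want = oracle_scan(counts.tolist(), 0.8, seq)
            assert got.keys() == want.keys()
            for key in want:
                assert got[key] == pytest.approx(want[key], abs=1e-12)

    def test_unknown_orientation_rejected(self):
        spwm = prepare(pwm_from_counts([[1, 0, 0, 0]] * 6))
        with pytest.raises(ValueError, match="orientation"):
            scan_sequence(spwm, "A" * 51, orientations=("backwards",))

    def test_scan_library_concatenates(self):
        rng = np.random.default_rng(26)
        c1, c2 = random_counts(rng, 5), random_counts(rng, 6)
        s1 = prepare(pwm_from_counts(c1, pwm_id="P$A_01"))
        s2 = prepare(pwm_from_counts(c2, pwm_id="P$B_01"))
        seq = random_seq(rng, 51)
        both = scan_library([s1, s2], seq)
        assert len(both) == len(scan_sequence(s1, seq)) + len(scan_sequence(s2, seq))
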