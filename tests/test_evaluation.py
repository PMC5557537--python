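import itertools
import math
import random

import numpy as np
import pytest

from tandemq.core import AlignmentRecord
from tandemq.evaluation import (
    EvalSeries,
    cid,
    compare,
    correct,
    csed_plot_scale,
    cumulative_incorrect,
    cumulative_squared_error,
    rca,
    rce,
    series_from_sams,
    sse,
)
from tandemq.tandem_sim import Origin


def _rec(pos, cigar="100M", refname="chrT"):
    seq = "A" * 100
    return AlignmentRecord(
        ["r", "0", refname, str(pos), "30", cigar, "*", "0", "0", seq, "I" * 100]
    )


class TestCorrectness:
    def test_exact_position(self):
        assert correct(_rec(100), Origin("chrT", 100, "+", "unp")) == 1

    @pytest.mark.parametrize("offset,expected", [(30, 1), (-30, 1), (31, 0), (-31, 0)])
    def test_threshold_boundary(self, offset, expected):
        truth = Origin("chrT", 100, "+", "unp")
        assert correct(_rec(100 + offset), truth) == expected

    def test_soft_clip_adjustment(self):
        # a leading 5S means the alignment's leftmost involved base is pos-5
        truth = Origin("chrT", 100, "+", "unp")
        rec = AlignmentRecord(
            ["r", "0", "chrT", "105", "30", "5S95M", "*", "0", "0",
             "A" * 100, "I" * 100]
        )
        assert correct(rec, truth) == 1

    def test_wrong_contig(self):
        assert correct(_rec(100, refname="chrU"), Origin("chrT", 100, "+", "unp")) == 0


# ---------------------------------------------------------------------------
# Brute-force oracle: direct evaluation of the tie-group definitions using
# plain Python loops, independent of the vectorized implementation.


def oracle_C(correctness, Q):
    order = sorted(range(len(Q)), key=lambda i: -Q[i])
    C, prev, i = [], 0.0, 0
    while i < len(order):
        j = i
        while j < len(order) and Q[order[j]] == Q[order[i]]:
            j += 1
        group = order[i:j]
        inc = sum(1 - correctness[g] for g in group) / len(group)
        for _ in group:
            prev += inc
            C.append(prev)
        i = j
    return C


def oracle_E(correctness, P):
    order = sorted(range(len(P)), key=lambda i: -P[i])
    E, prev, i = [], 0.0, 0
    while i < len(order):
        j = i
        while j < len(order) and P[order[j]] == P[order[i]]:
            j += 1
        group = order[i:j]
        mse = sum((correctness[g] - P[g]) ** 2 for g in group) / len(group)
        for _ in group:
            prev += mse
            E.append(prev)
        i = j
    return E


class TestCumulativeVectors:
    def test_worked_incorrect_example(self):
        C = cumulative_incorrect([1, 0, 1], [30, 20, 10])
        assert C.tolist() == [0, 1, 1]

    def test_tie_group_averaging(self):
        C = cumulative_incorrect([0, 1], [10, 10])
        assert C.tolist() == [0.5, 1.0]

    def test_all_correct_is_zero(self):
        assert cumulative_incorrect([1, 1, 1], [5, 10, 1]).tolist() == [0, 0, 0]

    def test_final_element_counts_all_incorrect(self):
        rng = random.Random(0)
        for _ in range(20):
            n = rng.randint(1, 50)
            corr = [rng.randint(0, 1) for _ in range(n)]
            Q = [rng.choice([0, 5, 5, 10, 40]) for _ in range(n)]
            C = cumulative_incorrect(corr, Q)
            assert C[-1] == pytest.approx(n - sum(corr), abs=1e-12)
            assert np.all(np.diff(C) >= -1e-12)

    def test_squared_error_tie_group(self):
        E = cumulative_squared_error([1, 0], [0.9, 0.9])
        assert E.tolist() == pytest.approx([0.41, 0.82])

    def test_final_equals_unsorted_sse(self):
        rng = random.Random(1)
        corr = [rng.randint(0, 1) for _ in range(40)]
        P = [rng.choice([0.1, 0.5, 0.9, 0.99]) for _ in range(40)]
        E = cumulative_squared_error(corr, P)
        assert E[-1] == pytest.approx(sse(corr, P), abs=1e-12)

    def test_shuffle_invariance_within_ties(self):
        # group semantics make within-group input order irrelevant
        corr = [1, 0, 1, 0, 1, 1]
        Q = [10, 10, 10, 20, 20, 5]
        base = cumulative_incorrect(corr, Q)
        rng = random.Random(2)
        idx = list(range(6))
        for _ in range(10):
            rng.shuffle(idx)
            shuffled = cumulative_incorrect([corr[i] for i in idx],
                                            [Q[i] for i in idx])
            assert shuffled.tolist() == pytest.approx(base.tolist())


class TestDifferencesAndRatios:
    def test_identical_predictions_zero(self):
        s = EvalSeries.from_qualities([1, 0, 1], [30, 20, 10], [30, 20, 10])
        assert cid(s).tolist() == [0, 0, 0]
        res = compare([1, 0, 1], [30, 20, 10], [30, 20, 10])
        assert res["rca"] == 0 and res["rce"] == 0

    def test_worked_cid_and_rca(self):
        corr = [1, 0, 1]
        C = cumulative_incorrect(corr, [30, 20, 10])
        Cp = cumulative_incorrect(corr, [10, 30, 20])
        assert Cp.tolist() == [1, 1, 1]
        assert (Cp - C).tolist() == [1, 0, 0]
        assert rca(C, Cp) == pytest.approx(0.5)

    def test_swapping_roles_negates_cid(self):
        corr = [1, 0, 1, 0]
        Q, Qp = [30, 20, 10, 5], [5, 30, 10, 20]
        s1 = EvalSeries.from_qualities(corr, Q, Qp)
        s2 = EvalSeries.from_qualities(corr, Qp, Q)
        assert np.allclose(cid(s1), -cid(s2))

    def test_rce_limit(self):
        eps = 1e-9
        val = rce([1, 0], [0.9, 0.5], [1 - eps, eps])
        assert val == pytest.approx(-1.0, abs=1e-6)

    def test_zero_denominator_is_nan(self):
        assert math.isnan(rca([0, 0], [1, 1]))
        assert math.isnan(rce([1], [1.0], [0.5]))

    def test_rca_invariant_under_monotone_transform(self):
        rng = random.Random(3)
        for _ in range(10):
            n = 50
            corr = [rng.randint(0, 1) for _ in range(n)]
            Q = [float(rng.choice([0, 3, 7, 7, 22, 40])) for _ in range(n)]
            Qp = [float(rng.choice([0, 1, 5, 12, 60])) for _ in range(n)]
            base = compare(corr, Q, Qp)["rca"]
            a, b = rng.uniform(0.5, 3), rng.uniform(0, 10)
            f = lambda q: a * q + b + 0.1 * q**2  # strictly increasing on q>=0
            trans = compare(corr, [f(q) for q in Q], [f(q) for q in Qp])["rca"]
            assert trans == pytest.approx(base, abs=1e-9)


class TestBruteForceOracleEquivalence:
    def test_exhaustive_small_instances(self):
        # every correctness pattern for n <= 8, qualities with forced ties
        qualities = [0, 10, 10, 20]
        for n in range(1, 9):
            Q = [qualities[i % 4] for i in range(n)]
            Qp = [qualities[(i * 3 + 1) % 4] for i in range(n)]
            P = [1 - 10 ** (-q / 10) for q in Q]
            Pp = [1 - 10 ** (-q / 10) for q in Qp]
            for bits in itertools.product([0, 1], repeat=n):
                corr = list(bits)
                C = cumulative_incorrect(corr, Q)
                Cp = cumulative_incorrect(corr, Qp)
                E = cumulative_squared_error(corr, P)
                Ep = cumulative_squared_error(corr, Pp)
                assert np.allclose(C, oracle_C(corr, Q), atol=1e-12)
                assert np.allclose(Cp, oracle_C(corr, Qp), atol=1e-12)
                assert np.allclose(E, oracle_E(corr, P), atol=1e-12)
                assert np.allclose(Ep, oracle_E(corr, Pp), atol=1e-12)
                if sum(C) > 0:
                    assert rca(C, Cp) == pytest.approx(
                        (sum(oracle_C(corr, Qp)) - sum(oracle_C(corr, Q)))
                        / sum(oracle_C(corr, Q)),
                        abs=1e-12,
                    )


class TestPlotScale:
    @pytest.mark.parametrize("y,expected", [(0, 0), (9, 1), (-99, -2), (99, 2)])
    def test_examples(self, y, expected):
        assert csed_plot_scale(y) == pytest.approx(expected)

    def test_odd_function(self):
        ys = np.array([-1000, -3.7, -0.2, 0.0, 0.2, 3.7, 1000])
        assert np.allclose(csed_plot_scale(-ys), -csed_plot_scale(ys))
        assert np.all(np.diff(csed_plot_scale(ys)) > 0)


class TestSeriesFromSams:
    def test_challenger_sam(self, tmp_path):
        head = "@HD\tVN:1.6\n@SQ\tSN:chrT\tLN:10000\n"
        body = []
        for i, (pos, mapq) in enumerate([(100, 30), (300, 20)]):
            body.append(
                f"qt!chrT!{pos}!+!unp!s\t0\tchrT\t{pos}\t{mapq}\t100M\t*\t0\t0\t"
                + "A" * 100 + "\t" + "I" * 100
            )
        body.append("qt!chrT!900!+!unp!s\t4\t*\t0\t0\t*\t*\t0\t0\t"
                    + "A" * 100 + "\t" + "I" * 100)
        orig = tmp_path / "orig.sam"
        orig.write_text(head + "\n".join(body) + "\n")
        chall = tmp_path / "chall.sam"
        chall.write_text(
            head + "\n".join(
                l.split("\t")[0] + "\t" + "\t".join(l.split("\t")[1:4])
                + "\t42\t" + "\t".join(l.split("\t")[5:]) for l in body
            ) + "\n"
        )
        series = series_from_sams(orig, chall)
        assert len(series) == 2  # the unaligned record is excluded
        assert series.Q.tolist() == [30, 20]
        assert series.Qp.tolist() == [42, 42]
        assert series.correctness.tolist() == [1, 1]
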