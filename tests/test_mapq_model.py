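import random

import numpy as np
import pytest

from tandemq.core import AlignmentRecord, Category, q_from_p
from tandemq.mapq_model import (
    CategoryModel,
    FeatureRecord,
    aggregate_votes,
    build_training_records,
    feature_importances,
    feature_matrix,
    format_feature_tag,
    mapq_int,
    parse_feature_tag,
    predict_p,
    rewrite_mapq,
    train,
)


def _aligned_rec(zt, seq="A" * 100, flag=0, tlen=0):
    qual = "I" * len(seq)
    fields = [
        "r", str(flag), "chrT", "500", "30", f"{len(seq)}M", "*", "0",
        str(tlen), seq, qual, f"ZT:Z:{zt}",
    ]
    return AlignmentRecord(fields)


class TestFeatureTag:
    def test_parse_with_second(self):
        f = parse_feature_tag(_aligned_rec("87,62,3210,0"))
        assert f.best_score == 87
        assert f.has_second and f.score_diff == 25
        assert f.read_len == 100
        assert f.qsum_aligned == 3210 and f.qsum_clipped == 0

    def test_parse_no_second(self):
        f = parse_feature_tag(_aligned_rec("100,NA,3500,40"))
        assert not f.has_second and f.score_diff is None

    def test_missing_tag_excluded(self):
        rec = AlignmentRecord(
            ["r", "0", "chrT", "1", "30", "4M", "*", "0", "0", "ACGT", "IIII"]
        )
        assert parse_feature_tag(rec) is None

    def test_extras_pass_through(self):
        f = parse_feature_tag(_aligned_rec("87,62,3210,0,3,1.5"))
        assert f.extras == (3.0, 1.5)

    def test_conc_records_carry_tlen(self):
        f = parse_feature_tag(_aligned_rec("87,62,3210,0", flag=99, tlen=-300))
        assert f.category is Category.CONC and f.tlen_abs == 300

    def test_format_parse_roundtrip(self):
        rng = random.Random(0)
        for _ in range(1000):
            has2 = rng.random() < 0.7
            best = float(rng.randint(-50, 100))
            f = FeatureRecord(
                category=Category.UNP,
                best_score=best,
                has_second=has2,
                score_diff=float(rng.randint(0, 80)) if has2 else None,
                read_len=100,
                qsum_aligned=rng.randint(0, 4000),
                qsum_clipped=rng.randint(0, 400),
                extras=(float(rng.randint(1, 5)),),
            )
            back = parse_feature_tag(_aligned_rec(format_feature_tag(f)))
            assert back.best_score == f.best_score
            assert back.has_second == f.has_second
            assert back.score_diff == f.score_diff
            assert back.qsum_aligned == f.qsum_aligned
            assert back.qsum_clipped == f.qsum_clipped
            assert back.extras == f.extras

    def test_tlen_only_for_conc(self):
        with pytest.raises(ValueError):
            FeatureRecord(Category.UNP, 10, False, None, 100, 0, 0, tlen_abs=5)


def _records(n, seed=0, sep_at=20.0):
    """Labeled records where correctness is driven by score_diff."""
    rng = random.Random(seed)
    recs = []
    for _ in range(n):
        diff = rng.uniform(0, 40)
        recs.append(
            FeatureRecord(
                category=Category.UNP,
                best_score=rng.uniform(80, 100),
                has_second=True,
                score_diff=diff,
                read_len=100,
                qsum_aligned=rng.randint(2900, 3200),
                qsum_clipped=0,
                label=diff > sep_at,
            )
        )
    return recs


class TestTraining:
    def test_separable_records_ranked(self):
        recs = _records(2000, seed=1)
        model = train(recs, seed=0, min_leaf=5)
        test = _records(500, seed=2)
        p = model.predict_matrix(feature_matrix(test))
        labels = np.array([f.label for f in test])
        assert p[labels].min() > p[~labels].max()

    def test_deterministic_given_seed(self):
        recs = _records(500, seed=3)
        test = feature_matrix(_records(100, seed=4))
        p1 = train(recs, seed=7).predict_matrix(test)
        p2 = train(recs, seed=7).predict_matrix(test)
        assert np.array_equal(p1, p2)

    def test_all_correct_degenerates_to_p_max(self):
        recs = [
            FeatureRecord(Category.UNP, 90, False, None, 100, 3000, 0, label=True)
            for _ in range(10)
        ]
        model = train(recs, q_cap=60.0)
        assert model.constant == pytest.approx(1 - 1e-6)
        p = predict_p(model, recs[0])
        assert q_from_p(p) == pytest.approx(60.0)

    def test_empty_records_no_model(self):
        assert train([]) is None

    def test_wrong_arity_rejected(self):
        model = train(_records(200, seed=5))
        with pytest.raises(ValueError):
            model.predict_matrix(np.zeros((3, 9)))


class TestVotesAndClamping:
    def test_mean_of_votes(self):
        assert aggregate_votes([0.2, 0.4, 0.6]) == pytest.approx(0.4)

    def test_unanimous_votes_clamped_to_q_cap(self):
        p = aggregate_votes([1.0] * 100, q_cap=60.0)
        assert p == pytest.approx(1 - 1e-6)
        assert q_from_p(p) == pytest.approx(60.0)

    def test_zero_votes(self):
        assert aggregate_votes([0.0, 0.0]) == 0.0

    @pytest.mark.parametrize("q,expected", [(3.0103, 3), (0.49, 0), (0.5, 1),
                                            (36.5, 37)])
    def test_mapq_round_half_up(self, q, expected):
        assert mapq_int(q) == expected


class TestImportances:
    def test_sum_to_one_and_separating_feature_leads(self):
        model = train(_records(2000, seed=6), seed=0, min_leaf=5)
        imps = feature_importances(model)
        assert sum(v for _, v in imps) == pytest.approx(1.0, abs=1e-9)
        assert all(v >= 0 for _, v in imps)
        assert imps == sorted(imps, key=lambda kv: -kv[1])
        assert imps[0][0] == "score_diff"


class TestTrainingRecordsAndRewrite:
    @pytest.fixture()
    def tandem_sam(self, tmp_path):
        # two correct and one incorrect tandem alignment, one stray name
        lines = [
            "@HD\tVN:1.6",
            "@SQ\tSN:chrT\tLN:100000",
            "qt!chrT!500!+!unp!s\t0\tchrT\t500\t40\t100M\t*\t0\t0\t" + "A" * 100
            + "\t" + "I" * 100 + "\tZT:Z:100,NA,3000,0",
            "qt!chrT!600!+!unp!s\t0\tchrT\t615\t40\t100M\t*\t0\t0\t" + "A" * 100
            + "\t" + "I" * 100 + "\tZT:Z:98,90,3000,0",
            "qt!chrT!700!+!unp!s\t0\tchrT\t1700\t40\t100M\t*\t0\t0\t" + "A" * 100
            + "\t" + "I" * 100 + "\tZT:Z:95,95,3000,0",
            "stray_read\t0\tchrT\t900\t40\t100M\t*\t0\t0\t" + "A" * 100
            + "\t" + "I" * 100 + "\tZT:Z:90,NA,3000,0",
            "qt!chrT!800!+!unp!s\t4\t*\t0\t0\t*\t*\t0\t0\t" + "A" * 100
            + "\t" + "I" * 100,
        ]
        path = tmp_path / "tandem.sam"
        path.write_text("\n".join(lines) + "\n")
        return path

    def test_labels_and_conservation(self, tandem_sam):
        recs = build_training_records(tandem_sam)
        unp = recs[Category.UNP]
        # stray and unaligned records contribute nothing
        assert sum(len(v) for v in recs.values()) == 3
        assert [f.label for f in unp] == [True, True, False]

    def test_rewrite_touches_only_mapq_and_header(self, tandem_sam, tmp_path):
        model = CategoryModel(
            category=Category.UNP,
            feature_names_=["best_score", "has_second", "score_diff",
                            "read_len", "qsum_aligned", "qsum_clipped"],
            n_train=1,
            constant=0.5,
        )
        out = tmp_path / "out.sam"
        report = rewrite_mapq(tandem_sam, {Category.UNP: model}, out)
        in_lines = tandem_sam.read_text().splitlines()
        out_lines = out.read_text().splitlines()
        assert len(out_lines) == len(in_lines) + 1  # added @PG
        assert out_lines[2].startswith("@PG")
        header_in = [l for l in in_lines if l.startswith("@")]
        header_out = [l for l in out_lines if l.startswith("@")]
        assert header_out[: len(header_in)] == header_in
        body_in = [l for l in in_lines if not l.startswith("@")]
        body_out = [l for l in out_lines if not l.startswith("@")]
        assert report["records"] == len(body_in)
        for li, lo in zip(body_in, body_out):
            fi, fo = li.split("\t"), lo.split("\t")
            assert fi[:4] == fo[:4] and fi[5:] == fo[5:]
        # p = 0.5 must round to MAPQ 3; the unaligned record is untouched
        assert body_out[0].split("\t")[4] == "3"
        assert body_out[-1] == body_in[-1]

    def test_missing_model_passes_mapq_through(self, tandem_sam, tmp_path):
        out = tmp_path / "out.sam"
        report = rewrite_mapq(tandem_sam, {}, out)
        assert report["predicted"] == 0 and report["passed_through"] == 4
        body_in = [l for l in tandem_sam.read_text().splitlines()
                   if not l.startswith("@")]
        body_out = [l for l in out.read_text().splitlines()
                    if not l.startswith("@")]
        assert body_in == body_out
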