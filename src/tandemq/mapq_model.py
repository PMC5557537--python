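"""Per-category correctness models and MAPQ rewriting.

Aligned tandem reads become labeled training records; one random-forest
model is trained per alignment category (unp/conc/disc/bad_end); the
trained model predicts, for each input alignment, the probability p that
the reported placement is correct, and the SAM MAPQ field is rewritten
with round-half-up(-10*log10(1-p)).

Features, taken from the aligner's ZT tag plus the record itself:
best alignment score, presence and value of the best-minus-second score
difference, aligned read length, summed base qualities of aligned and of
soft-clipped bases, and (for concordant pairs only) |TLEN|.  Extra
comma-separated tag fields pass through as anonymous numeric features.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from sklearn.ensemble import RandomForestClassifier

from . import evaluation
from .core import (
    AlignmentRecord,
    Category,
    classify_category,
    q_from_p,
    read_sam,
    write_sam,
)
from .tandem_sim import decode_origin

log = logging.getLogger(__name__)

DEFAULT_TREES = 100
DEFAULT_MIN_LEAF = 25
DEFAULT_Q_CAP = 60.0

# Per-base floor used to encode "no second-best alignment was found":
# score_diff defaults to best_score - MISMATCH_FLOOR*read_len, the largest
# difference the builtin scoring scheme could produce.
MISMATCH_FLOOR = -2.0


@dataclass(frozen=True)
class FeatureRecord:
    """The model's input vector for one alignment."""

    category: Category
    best_score: float
    has_second: bool
    score_diff: Optional[float]      # best - second, defined when has_second
    read_len: int
    qsum_aligned: int
    qsum_clipped: int
    tlen_abs: Optional[int] = None   # concordant pairs only
    extras: Tuple[float, ...] = ()
    label: Optional[bool] = None     # correct/incorrect; None for test records

    def __post_init__(self):
        if self.has_second and self.score_diff is None:
            raise ValueError("score_diff required when has_second is set")
        if (self.tlen_abs is not None) != (self.category is Category.CONC):
            raise ValueError("tlen_abs present iff category is conc")


# ---------------------------------------------------------------------------
# ZT tag contract: "ZT:Z:best,second_or_NA,qsum_aligned,qsum_clipped[,...]"


def format_feature_tag(f: FeatureRecord) -> str:
    """Tag payload for a feature record (inverse of parse_feature_tag)."""
    second = "NA" if not f.has_second else _fmt_num(f.best_score - f.score_diff)
    parts = [_fmt_num(f.best_score), second, str(f.qsum_aligned), str(f.qsum_clipped)]
    parts.extend(_fmt_num(x) for x in f.extras)
    return ",".join(parts)


def _fmt_num(x: float) -> str:
    return str(int(x)) if float(x).is_integer() else repr(float(x))


def parse_feature_tag(
    rec: AlignmentRecord, category: Optional[Category] = None
) -> Optional[FeatureRecord]:
    """Unlabeled feature record from an aligned SAM record's ZT tag.

    Read length and |TLEN| come from the record itself.  The category
    defaults to the record's flags but can be overridden: tandem training
    records belong to the category they were simulated for, which the
    read-name origin carries.  Returns None (record excluded from
    modeling) when the tag is absent.
    """
    payload = rec.feature_tag
    if payload is None:
        log.warning("aligned record %s lacks a ZT tag; excluded", rec.qname)
        return None
    parts = payload.split(",")
    if len(parts) < 4:
        raise ValueError(f"ZT tag needs >= 4 fields, got {payload!r}")
    best = float(parts[0])
    has_second = parts[1] != "NA"
    diff = best - float(parts[1]) if has_second else None
    cat = classify_category(rec) if category is None else category
    return FeatureRecord(
        category=cat,
        best_score=best,
        has_second=has_second,
        score_diff=diff,
        read_len=len(rec.seq),
        qsum_aligned=int(float(parts[2])),
        qsum_clipped=int(float(parts[3])),
        tlen_abs=abs(rec.tlen) if cat is Category.CONC else None,
        extras=tuple(float(x) for x in parts[4:]),
    )


# ---------------------------------------------------------------------------
# Feature matrix construction


def feature_names(cat: Category, n_extras: int = 0) -> List[str]:
    names = [
        "best_score",
        "has_second",
        "score_diff",
        "read_len",
        "qsum_aligned",
        "qsum_clipped",
    ]
    if cat is Category.CONC:
        names.append("tlen_abs")
    names.extend(f"extra_{i}" for i in range(n_extras))
    return names


def _encode_diff(f: FeatureRecord) -> float:
    if f.has_second:
        return float(f.score_diff)
    return float(f.best_score - MISMATCH_FLOOR * f.read_len)


def feature_matrix(records: Sequence[FeatureRecord]) -> np.ndarray:
    if not records:
        return np.zeros((0, 0))
    cat = records[0].category
    n_extras = len(records[0].extras)
    rows = []
    for f in records:
        if f.category is not cat:
            raise ValueError("mixed categories in one feature matrix")
        if len(f.extras) != n_extras:
            raise ValueError("inconsistent extra-feature arity")
        row = [
            f.best_score,
            1.0 if f.has_second else 0.0,
            _encode_diff(f),
            float(f.read_len),
            float(f.qsum_aligned),
            float(f.qsum_clipped),
        ]
        if cat is Category.CONC:
            row.append(float(f.tlen_abs))
        row.extend(f.extras)
        rows.append(row)
    return np.asarray(rows, dtype=float)


# ---------------------------------------------------------------------------
# Training records from tandem alignments


def build_training_records(
    tandem_sam,
    threshold: int = evaluation.DEFAULT_CORRECT_THRESHOLD,
) -> Dict[Category, List[FeatureRecord]]:
    """Labeled feature records per category from an aligned-tandem SAM.

    Each aligned tandem read contributes one record labeled by comparing
    the alignment with the origin decoded from the read name.  Unaligned
    tandem reads contribute nothing (failures-to-align are not modeled);
    names that fail to decode are skipped with a warning.
    """
    _, recs = read_sam(tandem_sam)
    out: Dict[Category, List[FeatureRecord]] = {c: [] for c in Category}
    for rec in recs:
        if not rec.is_aligned:
            continue
        try:
            truth = decode_origin(
                rec.qname, first_end=not rec.is_paired or rec.is_first_end
            )
        except ValueError:
            truth = None
        if truth is None:
            log.warning("tandem SAM record %s has no decodable origin", rec.qname)
            continue
        try:
            cat_override = Category(truth.category)
        except ValueError:
            cat_override = None
        f = parse_feature_tag(rec, category=cat_override)
        if f is None:
            continue
        label = bool(evaluation.correct(rec, truth, threshold))
        out[f.category].append(replace(f, label=label))
    return out


# ---------------------------------------------------------------------------
# Model


def aggregate_votes(votes: Sequence[float], q_cap: float = DEFAULT_Q_CAP) -> float:
    """Average per-tree votes and clamp so that q never exceeds q_cap."""
    p = float(np.mean(votes))
    return min(max(p, 0.0), 1.0 - 10.0 ** (-q_cap / 10.0))


@dataclass
class CategoryModel:
    """Trained tree ensemble mapping feature records to probability-correct.

    Each tree votes the Laplace-corrected fraction of correct training
    records in the leaf the query falls into, (c + 1) / (n + 2); the
    prediction is the average vote.  The correction matters at the
    confident end of the scale: raw leaf fractions saturate at exactly 1,
    collapsing every confident alignment onto a single quality, whereas
    the corrected vote keeps p graded by the amount of leaf evidence, so
    large homogeneous groups earn higher q than thin ones.
    """

    category: Category
    feature_names_: List[str]
    n_train: int
    q_cap: float = DEFAULT_Q_CAP
    forest: Optional[RandomForestClassifier] = None
    constant: Optional[float] = None  # degenerate single-label training sets
    leaf_probs_: Optional[List[np.ndarray]] = None

    @property
    def p_max(self) -> float:
        return 1.0 - 10.0 ** (-self.q_cap / 10.0)

    def _build_leaf_probs(self) -> None:
        idx = int(np.nonzero(self.forest.classes_)[0][0])
        probs = []
        for est in self.forest.estimators_:
            t = est.tree_
            n = t.weighted_n_node_samples
            c = t.value[:, 0, idx] * n
            probs.append((c + 1.0) / (n + 2.0))
        self.leaf_probs_ = probs

    def predict_matrix(self, X: np.ndarray) -> np.ndarray:
        if X.ndim != 2 or X.shape[1] != len(self.feature_names_):
            raise ValueError(
                f"feature matrix has {X.shape[1] if X.ndim == 2 else '?'} columns, "
                f"model expects {len(self.feature_names_)}"
            )
        if self.forest is None:
            p = np.full(X.shape[0], self.constant)
        else:
            if self.leaf_probs_ is None:
                self._build_leaf_probs()
            X = np.ascontiguousarray(X, dtype=np.float32)
            p = np.zeros(X.shape[0])
            for est, lp in zip(self.forest.estimators_, self.leaf_probs_):
                p += lp[est.apply(X)]
            p /= len(self.forest.estimators_)
        return np.clip(p, 0.0, self.p_max)


def train(
    records: Sequence[FeatureRecord],
    trees: int = DEFAULT_TREES,
    max_depth: Optional[int] = None,
    min_leaf: int = DEFAULT_MIN_LEAF,
    seed: int = 0,
    q_cap: float = DEFAULT_Q_CAP,
) -> Optional[CategoryModel]:
    """Train one category's model on labeled records.

    Returns None for an empty record set (no model for that category).
    Single-label sets yield a constant predictor: p = p_max when every
    training record was correct, p = 0 when every one was incorrect.
    ``min_leaf`` defaults to 25: vote averages are used as probabilities,
    and leaves that isolate single training points produce memorized,
    overconfident p (q pinned at the cap) for genuinely ambiguous
    alignments; a floor on leaf size keeps the votes calibrated.
    """
    if not records:
        return None
    if any(f.label is None for f in records):
        raise ValueError("training records must be labeled")
    cat = records[0].category
    names = feature_names(cat, len(records[0].extras))
    X = feature_matrix(records)
    y = np.asarray([bool(f.label) for f in records])
    model = CategoryModel(
        category=cat, feature_names_=names, n_train=len(records), q_cap=q_cap
    )
    if y.all() or not y.any():
        model.constant = (1.0 - 10.0 ** (-q_cap / 10.0)) if y.all() else 0.0
        return model
    forest = RandomForestClassifier(
        n_estimators=trees,
        max_depth=max_depth,
        min_samples_leaf=min_leaf,
        bootstrap=True,
        random_state=seed,
        n_jobs=1,
    )
    forest.fit(X, y)
    model.forest = forest
    return model


def predict_p(model: CategoryModel, f: FeatureRecord) -> float:
    """Probability-correct for one record: mean of tree votes, clamped."""
    if f.category is not model.category:
        raise ValueError(
            f"record category {f.category} does not match model {model.category}"
        )
    return float(model.predict_matrix(feature_matrix([f]))[0])


def feature_importances(model: CategoryModel) -> List[Tuple[str, float]]:
    """(feature, importance) pairs, non-negative, summing to 1, descending."""
    if model.forest is None:
        return []
    pairs = list(zip(model.feature_names_, map(float, model.forest.feature_importances_)))
    pairs.sort(key=lambda kv: -kv[1])
    return pairs


# ---------------------------------------------------------------------------
# MAPQ rewriting


def mapq_int(q: float) -> int:
    """Round-half-up integerization for the SAM MAPQ field."""
    return int(math.floor(q + 0.5))


def rewrite_mapq(
    input_sam,
    models: Dict[Category, Optional[CategoryModel]],
    output_sam,
    threshold: int = evaluation.DEFAULT_CORRECT_THRESHOLD,
    pg_line: str = "@PG\tID:tandemq\tPN:tandemq",
) -> Dict[str, object]:
    """Rewrite the MAPQ of every aligned record using the trained models.

    Everything outside the MAPQ column passes through byte-identically;
    a @PG line is appended to the header.  Categories without a model (or
    records without a ZT tag) keep their original MAPQ and are counted in
    the returned report.
    """
    header, recs = read_sam(input_sam)
    per_cat_idx: Dict[Category, List[int]] = {c: [] for c in Category}
    per_cat_feats: Dict[Category, List[FeatureRecord]] = {c: [] for c in Category}
    passed_through = 0
    for i, rec in enumerate(recs):
        if not rec.is_aligned:
            continue
        cat = classify_category(rec)
        model = models.get(cat)
        if model is None:
            log.warning("no model for category %s; MAPQ passed through", cat.value)
            passed_through += 1
            continue
        f = parse_feature_tag(rec)
        if f is None:
            passed_through += 1
            continue
        per_cat_idx[cat].append(i)
        per_cat_feats[cat].append(f)
    predicted = 0
    for cat in Category:
        feats = per_cat_feats[cat]
        if not feats:
            continue
        p = models[cat].predict_matrix(feature_matrix(feats))
        for i, pi in zip(per_cat_idx[cat], p):
            recs[i].mapq = mapq_int(q_from_p(float(pi)))
            predicted += 1
    write_sam(header + [pg_line], recs, output_sam)
    return {
        "records": len(recs),
        "aligned": sum(1 for r in recs if r.is_aligned),
        "predicted": predicted,
        "passed_through": passed_through,
        "per_category": {c.value: len(per_cat_feats[c]) for c in Category},
    }
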