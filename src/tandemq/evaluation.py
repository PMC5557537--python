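"""Correctness determination and comparison statistics for MAPQ predictions.

Given a set of alignments with known true origins and two competing
mapping-quality assignments (the aligner's Q and a challenger's Q'), this
module computes:

* the cumulative incorrect vectors C/C' (alignments sorted by descending
  quality; ties share the group-average penalty) and their difference
  D = C' - C (the CID curve);
* the cumulative squared-error vectors E/E' over the probability scale
  p = 1 - 10^(-q/10), each sorted by its own P, with tie groups sharing
  the group mean squared error, and their difference S = E' - E (CSED);
* RCA = (sum C' - sum C) / sum C and RCE = (SSE(P') - SSE(P)) / SSE(P).

Negative values favour the challenger.  CID/RCA depend only on ranking
and are invariant under strictly monotone transforms of the qualities;
CSED/RCE judge the probabilities themselves.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence

import numpy as np

from .core import AlignmentRecord, MAPQ_UNAVAILABLE, read_sam
from .tandem_sim import Origin, decode_origin

DEFAULT_CORRECT_THRESHOLD = 30


def correct(rec: AlignmentRecord, truth: Origin, threshold: int = DEFAULT_CORRECT_THRESHOLD) -> int:
    """1 if the alignment is within ``threshold`` nt of its true origin.

    The leftmost base involved in the alignment is the SAM POS adjusted
    for leading soft clipping (POS minus the leading clip length), so
    clipped and unclipped placements of the same read are comparable.
    Only position is compared, not strand.
    """
    if rec.refname != truth.refname:
        return 0
    implied_start = rec.pos - rec.leading_softclip
    return 1 if abs(implied_start - truth.start) <= threshold else 0


# ---------------------------------------------------------------------------
# Cumulative vectors with tie-group averaging


def _tie_group_cumsum(sorted_keys: np.ndarray, sorted_contrib: np.ndarray) -> np.ndarray:
    """Cumulative sum where tie groups share their average contribution.

    ``sorted_keys`` must already be in descending order; elements with
    equal keys form maximal groups, and each member of a group of size g
    with total contribution t adds t/g.
    """
    n = len(sorted_keys)
    if n == 0:
        return np.zeros(0)
    new_group = np.empty(n, dtype=bool)
    new_group[0] = True
    new_group[1:] = sorted_keys[1:] != sorted_keys[:-1]
    gid = np.cumsum(new_group) - 1
    totals = np.bincount(gid, weights=sorted_contrib)
    sizes = np.bincount(gid)
    return np.cumsum((totals / sizes)[gid])


def _descending_order(keys: np.ndarray) -> np.ndarray:
    return np.argsort(-keys, kind="stable")


def cumulative_incorrect(correctness: Sequence[float], Q: Sequence[float]) -> np.ndarray:
    """C: cumulative count of incorrect alignments, sorted by descending Q."""
    corr = np.asarray(correctness, dtype=float)
    q = np.asarray(Q, dtype=float)
    if corr.shape != q.shape:
        raise ValueError("correctness and Q must have the same length")
    order = _descending_order(q)
    return _tie_group_cumsum(q[order], 1.0 - corr[order])


def cumulative_squared_error(correctness: Sequence[float], P: Sequence[float]) -> np.ndarray:
    """E: cumulative squared error (correct - p)^2, sorted by descending P."""
    corr = np.asarray(correctness, dtype=float)
    p = np.asarray(P, dtype=float)
    if corr.shape != p.shape:
        raise ValueError("correctness and P must have the same length")
    order = _descending_order(p)
    return _tie_group_cumsum(p[order], (corr[order] - p[order]) ** 2)


# ---------------------------------------------------------------------------
# Series container and difference curves


def p_from_q_array(Q: Sequence[float]) -> np.ndarray:
    q = np.asarray(Q, dtype=float)
    if np.any(q < 0):
        raise ValueError("mapping qualities must be non-negative")
    return 1.0 - 10.0 ** (-q / 10.0)


@dataclass
class EvalSeries:
    """Correctness plus the two competing quality/probability vectors."""

    correctness: np.ndarray
    Q: np.ndarray
    Qp: np.ndarray
    P: np.ndarray
    Pp: np.ndarray

    @classmethod
    def from_qualities(cls, correctness, Q, Qp) -> "EvalSeries":
        corr = np.asarray(correctness, dtype=float)
        q = np.asarray(Q, dtype=float)
        qp = np.asarray(Qp, dtype=float)
        if not (corr.shape == q.shape == qp.shape):
            raise ValueError("all series must have the same length")
        if not np.all((corr == 0) | (corr == 1)):
            raise ValueError("correctness must be 0/1")
        return cls(corr, q, qp, p_from_q_array(q), p_from_q_array(qp))

    def __len__(self) -> int:
        return len(self.correctness)


def cid(series: EvalSeries) -> np.ndarray:
    """D = C' - C; negative values favour the challenger's ranking."""
    C = cumulative_incorrect(series.correctness, series.Q)
    Cp = cumulative_incorrect(series.correctness, series.Qp)
    return Cp - C


def csed(series: EvalSeries) -> np.ndarray:
    """S = E' - E; negative values favour the challenger's probabilities."""
    E = cumulative_squared_error(series.correctness, series.P)
    Ep = cumulative_squared_error(series.correctness, series.Pp)
    return Ep - E


def rca(C: Sequence[float], Cp: Sequence[float]) -> float:
    """Relative change in area under CID: (sum C' - sum C) / sum C.

    Returns NaN (reported as NA) when there are no incorrect alignments.
    """
    C = np.asarray(C, dtype=float)
    Cp = np.asarray(Cp, dtype=float)
    if C.shape != Cp.shape:
        raise ValueError("C and C' must have the same length")
    denom = C.sum()
    if denom == 0:
        return math.nan
    return float((Cp.sum() - denom) / denom)


def sse(correctness: Sequence[float], P: Sequence[float]) -> float:
    corr = np.asarray(correctness, dtype=float)
    p = np.asarray(P, dtype=float)
    return float(np.sum((corr - p) ** 2))


def rce(correctness: Sequence[float], P: Sequence[float], Pp: Sequence[float]) -> float:
    """Relative change in sum of squared errors: (SSE(P') - SSE(P)) / SSE(P)."""
    denom = sse(correctness, P)
    if denom == 0:
        return math.nan
    return (sse(correctness, Pp) - denom) / denom


def csed_plot_scale(y):
    """Signed log scaling for CSED plots: sign(y) * log10(|y| + 1)."""
    y = np.asarray(y, dtype=float)
    out = np.sign(y) * np.log10(np.abs(y) + 1.0)
    return float(out) if out.ndim == 0 else out


def compare(correctness, Q, Qp) -> Dict[str, object]:
    """All comparison statistics for one pair of quality assignments."""
    series = EvalSeries.from_qualities(correctness, Q, Qp)
    C = cumulative_incorrect(series.correctness, series.Q)
    Cp = cumulative_incorrect(series.correctness, series.Qp)
    D = Cp - C
    S = csed(series)
    rca_val = rca(C, Cp)
    rce_val = rce(series.correctness, series.P, series.Pp)
    return {
        "n": len(series),
        "n_incorrect": float(np.sum(1.0 - series.correctness)),
        "rca": rca_val,
        "rce": rce_val,
        "rca_pct": rca_val * 100.0,
        "rce_pct": rce_val * 100.0,
        "D": D,
        "S": S,
        "series": series,
    }


# ---------------------------------------------------------------------------
# Assembling series from SAM files


def series_from_sams(
    original_sam,
    challenger_sam=None,
    challenger_tag: Optional[str] = None,
    threshold: int = DEFAULT_CORRECT_THRESHOLD,
) -> EvalSeries:
    """Build an EvalSeries from SAM files with truth-encoded read names.

    ``original_sam`` supplies the aligner's MAPQ (Q).  The challenger's
    quality (Q') comes either from a second SAM over the same records, or
    from a tag (e.g. ``Zq``) on the original records.  Records that are
    unaligned, lack a decodable truth name, or carry MAPQ 255 in either
    source are excluded.
    """
    _, recs = read_sam(original_sam)
    if challenger_sam is not None:
        _, challenger_recs = read_sam(challenger_sam)
        if len(challenger_recs) != len(recs):
            raise ValueError("original and challenger SAMs differ in record count")
    elif challenger_tag is None:
        raise ValueError("provide challenger_sam or challenger_tag")
    corr: List[int] = []
    Q: List[float] = []
    Qp: List[float] = []
    for i, rec in enumerate(recs):
        if not rec.is_aligned:
            continue
        truth = decode_origin(rec.qname, first_end=not rec.is_paired or rec.is_first_end)
        if truth is None:
            continue
        if challenger_sam is not None:
            crec = challenger_recs[i]
            if crec.qname != rec.qname:
                raise ValueError(
                    f"record {i}: QNAME mismatch between SAMs "
                    f"({rec.qname!r} vs {crec.qname!r})"
                )
            qp = float(crec.mapq)
        else:
            payload = rec.get_tag(challenger_tag)
            if payload is None:
                continue
            qp = float(payload)
        if rec.mapq == MAPQ_UNAVAILABLE or qp == MAPQ_UNAVAILABLE:
            continue
        corr.append(correct(rec, truth, threshold))
        Q.append(float(rec.mapq))
        Qp.append(qp)
    return EvalSeries.from_qualities(corr, Q, Qp)


# ---------------------------------------------------------------------------
# Output: TSV and plots


def write_difference_tsv(D: np.ndarray, S: np.ndarray, path) -> None:
    with open(path, "w") as fh:
        fh.write("rank\tcid_d\tcsed_s\n")
        for i, (d, s) in enumerate(zip(D, S)):
            fh.write(f"{i}\t{d:.10g}\t{s:.10g}\n")


def plot_cid(D: np.ndarray, path, title: str = "CID") -> None:
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    ax.plot(np.arange(len(D)), D, lw=1)
    ax.axhline(0, color="grey", lw=0.5)
    ax.set_xlabel("alignments passing threshold")
    ax.set_ylabel("C' - C")
    ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def plot_csed(S: np.ndarray, path, title: str = "CSED", scaled: bool = True) -> None:
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    y = csed_plot_scale(S) if scaled else S
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.plot(np.arange(len(y)), y, lw=1)
    ax.axhline(0, color="grey", lw=0.5)
    ax.set_xlabel("alignments passing threshold")
    ax.set_ylabel("sign(s) log10(|s|+1)" if scaled else "E' - E")
    ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
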