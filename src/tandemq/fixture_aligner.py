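"""Self-contained test surface: synthetic genome, read simulator, toy aligner.

These stand in for a real genome, a third-party read simulator, and a
production aligner, at desk scale.  The genome generator plants mutated
copies of earlier segments to control repetitiveness; the read simulator
draws truth-labeled reads with a quality-driven substitution model; and
the toy aligner is a deterministic seed-and-extend mapper that emits the
ZT feature tag the quality model consumes, plus a deliberately coarse
native MAPQ heuristic (a MAQ-like two-score formula) for the trained
model to compete against.
"""

from __future__ import annotations

import math
import random
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Tuple

import numpy as np

from .core import (
    AlignmentRecord,
    FLAG_FIRST,
    FLAG_MATE_REVERSE,
    FLAG_MATE_UNMAPPED,
    FLAG_PAIRED,
    FLAG_PROPER_PAIR,
    FLAG_REVERSE,
    FLAG_SECOND,
    FLAG_UNMAPPED,
    Genome,
    PHRED_OFFSET,
    cigar_to_str,
    read_fastq,
    revcomp,
    write_sam,
)
from .tandem_sim import Origin, encode_origin, encode_pair_origin, ref_span

_BASE_BYTES = np.frombuffer(b"ACGT", dtype=np.uint8)


# ---------------------------------------------------------------------------
# Synthetic genome


@dataclass
class SyntheticGenome:
    """A generated reference with an annotation of its planted repeats."""

    genome: Genome
    repeat_annotation: List[Tuple[int, int, int, float]] = field(default_factory=list)
    # entries: (source_start0, copy_start0, unit_len, divergence)


def generate_genome(
    length: int,
    repeat_fraction: float = 0.0,
    unit_len: int = 500,
    divergence: float = 0.02,
    gc: float = 0.5,
    seed: int = 0,
    name: str = "chr1",
) -> SyntheticGenome:
    """Random genome with a controlled fraction of diverged repeat copies.

    The backbone is i.i.d. with the requested GC content.  Then
    round(repeat_fraction*length/unit_len) non-overlapping unit_len slots
    are overwritten with copies of uniformly chosen earlier segments, each
    base of a copy substituted with probability ``divergence``.  Sources
    may themselves lie in repeats, so repeat families arise naturally.
    """
    if not 0 <= repeat_fraction < 1:
        raise ValueError("repeat_fraction must be in [0, 1)")
    if unit_len > length:
        raise ValueError("unit_len exceeds genome length")
    rng = np.random.default_rng(seed)
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    arr = _BASE_BYTES[rng.choice(4, size=length, p=probs)]
    annotation: List[Tuple[int, int, int, float]] = []
    n_copies = int(round(repeat_fraction * length / unit_len))
    n_slots = length // unit_len
    if n_copies > 0:
        if n_copies > n_slots - 1:
            raise ValueError("repeat_fraction too high for this unit_len")
        # slot 0 is never a copy target: sources must be earlier segments
        targets = np.sort(rng.choice(np.arange(1, n_slots), size=n_copies, replace=False))
        for slot in targets:
            start = int(slot) * unit_len
            src = int(rng.integers(0, start - unit_len + 1))
            copy = arr[src : src + unit_len].copy()
            if divergence > 0:
                mask = rng.random(unit_len) < divergence
                n_mut = int(mask.sum())
                if n_mut:
                    shift = rng.integers(1, 4, size=n_mut)
                    old = np.searchsorted(_BASE_BYTES, copy[mask])
                    copy[mask] = _BASE_BYTES[(old + shift) % 4]
            arr[start : start + unit_len] = copy
            annotation.append((src, start, unit_len, divergence))
    seq = arr.tobytes().decode("ascii")
    return SyntheticGenome(Genome({name: seq}), annotation)


# ---------------------------------------------------------------------------
# Input-read simulation (truth-labeled, quality-driven substitution errors)


def default_quality_profile(read_len: int, rng: np.random.Generator) -> np.ndarray:
    """Illumina-like profile: high qualities decaying along the read."""
    base = np.linspace(35.0, 27.0, read_len)
    q = base + rng.normal(0.0, 3.0, size=read_len)
    return np.clip(np.rint(q), 2, 40).astype(int)


def _apply_errors(
    seq: str, quals: np.ndarray, sub_rate: float, rng: np.random.Generator
) -> str:
    if sub_rate <= 0:
        return seq
    err_p = sub_rate * 10.0 ** (-quals / 10.0)
    mask = rng.random(len(seq)) < err_p
    if not mask.any():
        return seq
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()
    n_mut = int(mask.sum())
    old = np.searchsorted(_BASE_BYTES, arr[mask])
    shift = rng.integers(1, 4, size=n_mut)
    arr[mask] = _BASE_BYTES[(old + shift) % 4]
    return arr.tobytes().decode("ascii")


def _quals_to_str(quals: np.ndarray) -> str:
    return "".join(chr(int(q) + PHRED_OFFSET) for q in quals)


def simulate_input_reads(
    genome: Genome,
    n: int,
    read_len: int,
    sub_rate: float = 1.0,
    quality_profile=default_quality_profile,
    paired: bool = False,
    frag_range: Optional[Tuple[int, int]] = None,
    seed: int = 0,
    max_redraws: int = 1000,
):
    """Simulate n truth-labeled reads (or pairs) as (name, seq, qual) tuples.

    Positions are uniform over the genome; each base is substituted with
    probability sub_rate * 10^(-q/10) where q is its emitted quality.
    Paired mode draws FR fragments with length uniform on ``frag_range``
    (default (2L, 4L) with L the read length).  Truth is encoded in the
    read name with category marker "input".
    """
    rng = random.Random(seed)
    nprng = np.random.default_rng(seed)
    if paired and frag_range is None:
        frag_range = (2 * read_len, 4 * read_len)
    out = []
    for _ in range(n):
        if not paired:
            for _ in range(max_redraws):
                contig, start0 = genome.draw_position(read_len, rng)
                sub = genome.slice(contig, start0, read_len)
                if "N" not in sub:
                    break
            else:
                raise RuntimeError("could not draw an N-free read position")
            strand = "+" if rng.random() < 0.5 else "-"
            read = sub if strand == "+" else revcomp(sub)
            quals = quality_profile(read_len, nprng)
            read = _apply_errors(read, quals, sub_rate, nprng)
            o = Origin(contig, start0 + 1, strand, "input", "single")
            out.append((encode_origin(o), read, _quals_to_str(quals)))
        else:
            frag_len = rng.randint(frag_range[0], frag_range[1])
            frag_len = max(frag_len, read_len)
            for _ in range(max_redraws):
                contig, start0 = genome.draw_position(frag_len, rng)
                frag = genome.slice(contig, start0, frag_len)
                if "N" not in frag:
                    break
            else:
                raise RuntimeError("could not draw an N-free fragment")
            left = frag[:read_len]
            right = revcomp(frag[-read_len:])
            left_start = start0 + 1
            right_start = start0 + frag_len - read_len + 1
            if rng.random() < 0.5:  # which physical strand end 1 comes from
                o1 = Origin(contig, left_start, "+", "input", "end1")
                o2 = Origin(contig, right_start, "-", "input", "end2")
                s1, s2 = left, right
            else:
                o1 = Origin(contig, right_start, "-", "input", "end1")
                o2 = Origin(contig, left_start, "+", "input", "end2")
                s1, s2 = right, left
            q1 = quality_profile(read_len, nprng)
            q2 = quality_profile(read_len, nprng)
            s1 = _apply_errors(s1, q1, sub_rate, nprng)
            s2 = _apply_errors(s2, q2, sub_rate, nprng)
            name = encode_pair_origin(o1, o2)
            out.append(
                ((name, s1, _quals_to_str(q1)), (name, s2, _quals_to_str(q2)))
            )
    return out


# ---------------------------------------------------------------------------
# Toy seed-and-extend aligner


@dataclass
class ToyAlignment:
    """The best alignment the toy aligner found for one read."""

    refname: str
    pos: int                 # 1-based leftmost
    strand: str
    score: float
    cigar: List[Tuple[str, int]]
    md: str
    second_score: Optional[float]
    n_best_ties: int


@dataclass
class Scoring:
    match: float = 1.0
    mismatch: float = -2.0
    gap_open: float = -4.0   # a gap of length g costs gap_open + g*gap_extend
    gap_extend: float = -1.0


class ToyAligner:
    """Deterministic k-mer seed-and-extend aligner emitting ZT feature tags.

    Candidates come from exact k-mer seeds at three read offsets, both
    strands.  Each candidate is scored ungapped on the seed diagonal; when
    enough mismatches accumulate that a gap could pay for itself, the
    candidate is refined with a banded glocal alignment.  The reported
    alignment is the highest-scoring candidate (ties broken by smallest
    (refname, position), then forward strand); the second-best score is
    the best score at a locus more than a read length away.  The native
    MAPQ is the deliberately coarse floor(min(40, 2*(best-second))), or 40
    when no second-best exists; alignments scoring below
    min_score_frac * read_len * match are suppressed.
    """

    def __init__(
        self,
        genome: Genome,
        k: int = 21,
        scoring: Scoring = Scoring(),
        min_score_frac: float = 0.5,
        band: int = 8,
        mapq_max: int = 40,
        gap_trigger: int = 3,
    ):
        if len(set(genome.names)) != len(genome.names):
            raise ValueError("duplicate contig names in genome")
        self.genome = genome
        self.k = k
        self.scoring = scoring
        self.min_score_frac = min_score_frac
        self.band = band
        self.mapq_max = mapq_max
        self.gap_trigger = gap_trigger
        self.names = genome.names
        self.arrays = [
            np.frombuffer(genome.contigs[n].encode("ascii"), dtype=np.uint8)
            for n in self.names
        ]
        self.index: Dict[str, List[Tuple[int, int]]] = {}
        for ci, nm in enumerate(self.names):
            s = genome.contigs[nm]
            for i in range(len(s) - k + 1):
                kmer = s[i : i + k]
                if "N" in kmer:
                    continue
                self.index.setdefault(kmer, []).append((ci, i))
        self._pw = None

    # -- gapped refinement ------------------------------------------------
    def _pairwise(self):
        if self._pw is None:
            from Bio import Align

            a = Align.PairwiseAligner()
            a.mode = "global"
            a.match_score = self.scoring.match
            a.mismatch_score = self.scoring.mismatch
            a.open_gap_score = self.scoring.gap_open + self.scoring.gap_extend
            a.extend_gap_score = self.scoring.gap_extend
            a.end_deletion_score = 0  # reference-window flanks are free
            self._pw = a
        return self._pw

    def _refine(self, ci: int, start: int, s: str):
        """Banded glocal alignment of read ``s`` around candidate start.

        Returns (score, new_start, cigar) or None if no gapped alignment
        beats the ungapped diagonal.
        """
        L = len(s)
        arr = self.arrays[ci]
        w0 = max(0, start - self.band)
        w1 = min(len(arr), start + L + self.band)
        window = arr[w0:w1].tobytes().decode("ascii")
        aln = self._pairwise().align(window, s)
        best = aln[0]
        tblocks, qblocks = best.aligned
        if len(qblocks) == 0 or qblocks[0][0] != 0 or qblocks[-1][1] != L:
            return None  # read not fully aligned; keep the ungapped diagonal
        cigar: List[Tuple[str, int]] = []

        def push(op, n):
            if n <= 0:
                return
            if cigar and cigar[-1][0] == op:
                cigar[-1] = (op, cigar[-1][1] + n)
            else:
                cigar.append((op, n))

        prev_t, prev_q = None, None
        for (t0, t1), (q0, q1) in zip(tblocks, qblocks):
            if prev_t is not None:
                push("D", t0 - prev_t)
                push("I", q0 - prev_q)
            push("M", t1 - t0)
            prev_t, prev_q = t1, q1
        new_start = w0 + int(tblocks[0][0])
        return float(best.score), new_start, cigar

    # -- scoring helpers --------------------------------------------------
    def _score_cigar(self, ci: int, start: int, s: str, cigar) -> float:
        """Recompute the alignment score from CIGAR + sequences."""
        arr = self.arrays[ci]
        sc = self.scoring
        tpos, qpos, score = start, 0, 0.0
        q = np.frombuffer(s.encode("ascii"), dtype=np.uint8)
        for op, n in cigar:
            if op == "M":
                mism = int((arr[tpos : tpos + n] != q[qpos : qpos + n]).sum())
                score += (n - mism) * sc.match + mism * sc.mismatch
                tpos += n
                qpos += n
            elif op == "D":
                score += sc.gap_open + n * sc.gap_extend
                tpos += n
            elif op == "I":
                score += sc.gap_open + n * sc.gap_extend
                qpos += n
        return score

    def _md_for(self, ci: int, start: int, s: str, cigar) -> str:
        from .core import format_md

        arr = self.arrays[ci]
        tokens = []
        tpos, qpos = start, 0
        run = 0
        for op, n in cigar:
            if op == "M":
                ref = arr[tpos : tpos + n]
                qry = np.frombuffer(s.encode("ascii"), dtype=np.uint8)[qpos : qpos + n]
                for j in range(n):
                    if ref[j] == qry[j]:
                        run += 1
                    else:
                        if run:
                            tokens.append(("m", run))
                            run = 0
                        tokens.append(("x", chr(ref[j])))
                tpos += n
                qpos += n
            elif op == "D":
                if run:
                    tokens.append(("m", run))
                    run = 0
                tokens.append(("d", arr[tpos : tpos + n].tobytes().decode("ascii")))
                tpos += n
            elif op == "I":
                qpos += n
        if run:
            tokens.append(("m", run))
        return format_md(tokens)

    # -- the aligner proper ----------------------------------------------
    def align(self, seq: str) -> Optional[ToyAlignment]:
        L = len(seq)
        k = self.k
        if L < k:
            return None
        seqs = {"+": seq, "-": revcomp(seq)}
        offsets = sorted({0, (L - k) // 2, L - k})
        candidates = {}
        for strand in ("+", "-"):
            s = seqs[strand]
            for off in offsets:
                for ci, p in self.index.get(s[off : off + k], ()):
                    start = p - off
                    if 0 <= start <= len(self.arrays[ci]) - L:
                        candidates.setdefault((ci, start, strand), None)
        if not candidates:
            return None
        scored = []
        for ci, start, strand in candidates:
            s = seqs[strand]
            q = np.frombuffer(s.encode("ascii"), dtype=np.uint8)
            mism = int((self.arrays[ci][start : start + L] != q).sum())
            score = (L - mism) * self.scoring.match + mism * self.scoring.mismatch
            cigar = [("M", L)]
            if mism >= self.gap_trigger:
                refined = self._refine(ci, start, s)
                if refined is not None:
                    # recompute under our gap convention; keep only if better
                    g_score = self._score_cigar(ci, refined[1], s, refined[2])
                    if g_score > score:
                        score, start, cigar = g_score, refined[1], refined[2]
            scored.append((score, ci, start, strand, cigar))
        scored.sort(key=lambda t: (-t[0], self.names[t[1]], t[2], t[3]))
        best_score, ci, start, strand, cigar = scored[0]
        if best_score < self.min_score_frac * L * self.scoring.match:
            return None
        second = None
        ties = 1
        for sc, ci2, st2, _strand2, _ in scored[1:]:
            distant = ci2 != ci or abs(st2 - start) > L
            if distant:
                if second is None or sc > second:
                    second = sc
                if sc == best_score:
                    ties += 1
        md = self._md_for(ci, start, seqs[strand], cigar)
        return ToyAlignment(
            refname=self.names[ci],
            pos=start + 1,
            strand=strand,
            score=best_score,
            cigar=cigar,
            md=md,
            second_score=second,
            n_best_ties=ties,
        )

    def native_mapq(self, aln: ToyAlignment) -> int:
        """MAQ-like two-score heuristic, deliberately coarse."""
        if aln.second_score is None:
            return self.mapq_max
        return max(0, min(self.mapq_max, int(math.floor(2 * (aln.score - aln.second_score)))))

    # -- SAM emission -----------------------------------------------------
    def header(self) -> List[str]:
        lines = ["@HD\tVN:1.6\tSO:unknown"]
        for nm in self.names:
            lines.append(f"@SQ\tSN:{nm}\tLN:{self.genome.lengths[nm]}")
        lines.append("@PG\tID:toyalign\tPN:tandemq-toyalign")
        return lines

    def _zt(self, aln: ToyAlignment, qsum: int) -> str:
        # best, second-or-NA, aligned qsum, clipped qsum, plus the tie count
        # as an extensible extra feature (the native heuristic ignores it)
        second = "NA" if aln.second_score is None else f"{aln.second_score:g}"
        return f"ZT:Z:{aln.score:g},{second},{qsum},0,{aln.n_best_ties}"

    def _record(
        self,
        name: str,
        seq: str,
        qual: str,
        aln: Optional[ToyAlignment],
        flag_extra: int = 0,
        rnext: str = "*",
        pnext: int = 0,
        tlen: int = 0,
        mate_aligned: bool = True,
        placeholder: Optional[Tuple[str, int]] = None,
    ) -> AlignmentRecord:
        if aln is None:
            flag = FLAG_UNMAPPED | flag_extra
            ref, pos = placeholder if placeholder else ("*", 0)
            fields = [
                name, str(flag), ref, str(pos), "0", "*",
                rnext, str(pnext), "0", seq, qual,
            ]
            return AlignmentRecord(fields)
        flag = flag_extra
        if aln.strand == "-":
            flag |= FLAG_REVERSE
            seq_out, qual_out = revcomp(seq), qual[::-1]
        else:
            seq_out, qual_out = seq, qual
        qsum = sum(ord(c) - PHRED_OFFSET for c in qual)
        fields = [
            name,
            str(flag),
            aln.refname,
            str(aln.pos),
            str(self.native_mapq(aln)),
            cigar_to_str(aln.cigar),
            rnext,
            str(pnext),
            str(tlen),
            seq_out,
            qual_out,
            f"MD:Z:{aln.md}",
            self._zt(aln, qsum),
        ]
        return AlignmentRecord(fields)

    def align_unpaired(self, reads: Iterable[Tuple[str, str, str]]) -> List[AlignmentRecord]:
        return [self._record(nm, sq, ql, self.align(sq)) for nm, sq, ql in reads]

    def align_pairs(
        self,
        pairs: Iterable[Tuple[Tuple[str, str, str], Tuple[str, str, str]]],
        conc_range: Tuple[int, int],
    ) -> List[AlignmentRecord]:
        """Align both ends independently, then set pair flags and TLEN.

        A pair is flagged proper (concordant) when both ends align to the
        same contig in FR orientation with an inferred fragment length
        inside ``conc_range``.
        """
        out: List[AlignmentRecord] = []
        for (n1, s1, q1), (n2, s2, q2) in pairs:
            a1 = self.align(s1)
            a2 = self.align(s2)
            proper = False
            tlen1 = tlen2 = 0
            if a1 is not None and a2 is not None and a1.refname == a2.refname:
                left, right = (a1, a2) if a1.pos <= a2.pos else (a2, a1)
                frag = (right.pos + ref_span(right.cigar) - 1) - left.pos + 1
                fr = (
                    a1.strand != a2.strand
                    and left.strand == "+"
                    and right.strand == "-"
                )
                if fr and conc_range[0] <= frag <= conc_range[1]:
                    proper = True
                if a1.pos <= a2.pos:
                    tlen1, tlen2 = frag, -frag
                else:
                    tlen1, tlen2 = -frag, frag
            base1 = FLAG_PAIRED | FLAG_FIRST
            base2 = FLAG_PAIRED | FLAG_SECOND
            if proper:
                base1 |= FLAG_PROPER_PAIR
                base2 |= FLAG_PROPER_PAIR
            if a2 is None:
                base1 |= FLAG_MATE_UNMAPPED
            elif a2.strand == "-":
                base1 |= FLAG_MATE_REVERSE
            if a1 is None:
                base2 |= FLAG_MATE_UNMAPPED
            elif a1.strand == "-":
                base2 |= FLAG_MATE_REVERSE
            # SAM convention: an unaligned end with an aligned mate is
            # placed at the mate's coordinates
            if a1 is not None and a2 is not None:
                out.append(self._record(n1, s1, q1, a1, base1, "=", a2.pos, tlen1))
                out.append(self._record(n2, s2, q2, a2, base2, "=", a1.pos, tlen2))
            elif a1 is not None:
                out.append(self._record(n1, s1, q1, a1, base1, "=", a1.pos, 0))
                out.append(
                    self._record(
                        n2, s2, q2, None, base2, "=", a1.pos, 0,
                        placeholder=(a1.refname, a1.pos),
                    )
                )
            elif a2 is not None:
                out.append(
                    self._record(
                        n1, s1, q1, None, base1, "=", a2.pos, 0,
                        placeholder=(a2.refname, a2.pos),
                    )
                )
                out.append(self._record(n2, s2, q2, a2, base2, "=", a2.pos, 0))
            else:
                out.append(self._record(n1, s1, q1, None, base1))
                out.append(self._record(n2, s2, q2, None, base2))
        return out

    # -- file-level drivers ------------------------------------------------
    def align_fastq(self, fastq, out_sam) -> None:
        write_sam(self.header(), self.align_unpaired(read_fastq(fastq)), out_sam)

    def align_fastq_pair(self, fastq1, fastq2, out_sam, conc_range) -> None:
        pairs = list(zip(read_fastq(fastq1), read_fastq(fastq2)))
        write_sam(self.header(), self.align_pairs(pairs, conc_range), out_sam)
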