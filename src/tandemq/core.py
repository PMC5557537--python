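"""Core domain types shared by every pipeline stage.

This module holds the SAM record abstraction, mapping-quality arithmetic
(q = -10*log10(1-p)), the four alignment categories, and the low-level
CIGAR/MD utilities that the input-model and simulation stages build on.

SAM I/O here is deliberately conservative: records keep their raw
tab-separated fields so that writing a file back out is byte-identical,
and the downstream MAPQ rewrite can guarantee it touches nothing but the
MAPQ column and the header.  Coordinates follow SAM conventions (1-based,
leftmost); helpers that slice genome strings use 0-based half-open
internally and convert at the boundary.
"""

from __future__ import annotations

import enum
import math
import re
from dataclasses import dataclass
from typing import Dict, Iterable, Iterator, List, Optional, Sequence, Tuple, Union

# ---------------------------------------------------------------------------
# SAM flag bits

FLAG_PAIRED = 0x1
FLAG_PROPER_PAIR = 0x2
FLAG_UNMAPPED = 0x4
FLAG_MATE_UNMAPPED = 0x8
FLAG_REVERSE = 0x10
FLAG_MATE_REVERSE = 0x20
FLAG_FIRST = 0x40
FLAG_SECOND = 0x80

PHRED_OFFSET = 33

MAPQ_UNAVAILABLE = 255  # "unavailable" sentinel; excluded from evaluation


class Category(str, enum.Enum):
    """Alignment category; each category gets its own quality model."""

    UNP = "unp"          # unpaired
    CONC = "conc"        # paired, concordantly aligned
    DISC = "disc"        # paired, discordantly aligned
    BAD_END = "bad_end"  # paired, opposite end failed to align

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


# ---------------------------------------------------------------------------
# Mapping-quality arithmetic


def q_from_p(p: float) -> float:
    """Convert probability-correct p into a mapping quality q.

    q = -10*log10(1-p).  Monotone increasing in p; p must lie in [0, 1).
    """
    if p < 0.0 or p >= 1.0:
        raise ValueError(f"p must be in [0, 1), got {p!r}")
    return -10.0 * math.log10(1.0 - p)


def p_from_q(q: float) -> float:
    """Inverse of :func:`q_from_p`: p = 1 - 10**(-q/10), q >= 0."""
    if q < 0.0:
        raise ValueError(f"q must be non-negative, got {q!r}")
    return 1.0 - 10.0 ** (-q / 10.0)


@dataclass(frozen=True)
class MappingQuality:
    """A (q, p) pair kept consistent under q = -10*log10(1-p).

    Rounding of q to an integer happens only at SAM output.
    """

    p: float

    @property
    def q(self) -> float:
        return q_from_p(self.p)

    @classmethod
    def from_q(cls, q: float) -> "MappingQuality":
        return cls(p_from_q(q))

    @property
    def mapq(self) -> int:
        """SAM integer MAPQ: round-half-up of q."""
        return int(math.floor(self.q + 0.5))


# ---------------------------------------------------------------------------
# CIGAR utilities

_CIGAR_RE = re.compile(r"(\d+)([MIDNSHP=X])")

READ_CONSUMING = frozenset("MIS=X")
REF_CONSUMING = frozenset("MDN=X")

Cigar = List[Tuple[str, int]]


def parse_cigar(cigar: str) -> Cigar:
    """Parse a CIGAR string into a list of (op, length) tuples."""
    if cigar == "*":
        return []
    ops: Cigar = []
    pos = 0
    for m in _CIGAR_RE.finditer(cigar):
        if m.start() != pos:
            raise ValueError(f"malformed CIGAR {cigar!r}")
        ops.append((m.group(2), int(m.group(1))))
        pos = m.end()
    if pos != len(cigar) or not ops:
        raise ValueError(f"malformed CIGAR {cigar!r}")
    return ops


def cigar_to_str(ops: Sequence[Tuple[str, int]]) -> str:
    return "".join(f"{n}{op}" for op, n in ops) if ops else "*"


def normalize_cigar(ops: Sequence[Tuple[str, int]]) -> Cigar:
    """Collapse '=' and 'X' into 'M', merging adjacent equal ops.

    MD remains authoritative for mismatch placement; span arithmetic only
    needs the M/I/D/S structure.
    """
    out: Cigar = []
    for op, n in ops:
        if op in "=X":
            op = "M"
        if out and out[-1][0] == op:
            out[-1] = (op, out[-1][1] + n)
        else:
            out.append((op, n))
    return out


def read_length_of(ops: Sequence[Tuple[str, int]]) -> int:
    return sum(n for op, n in ops if op in READ_CONSUMING)


# ---------------------------------------------------------------------------
# MD-string utilities
#
# An MD string records, for the aligned (M/D) portion of a read, runs of
# matches (integers), mismatched reference bases (letters), and deleted
# reference bases ('^' + letters).  Tokens: ("m", count), ("x", base),
# ("d", bases).

_MD_RE = re.compile(r"(\d+)|\^([A-Za-z]+)|([A-Za-z])")

MdTokens = List[Tuple[str, Union[int, str]]]

_COMPLEMENT = str.maketrans("ACGTacgtNn", "TGCAtgcaNn")


def revcomp(seq: str) -> str:
    """Reverse complement of a nucleotide string (N passes through)."""
    return seq.translate(_COMPLEMENT)[::-1]


def parse_md(md: str) -> MdTokens:
    tokens: MdTokens = []
    pos = 0
    for m in _MD_RE.finditer(md):
        if m.start() != pos:
            raise ValueError(f"malformed MD string {md!r}")
        if m.group(1) is not None:
            n = int(m.group(1))
            if n > 0:
                tokens.append(("m", n))
        elif m.group(2) is not None:
            tokens.append(("d", m.group(2).upper()))
        else:
            tokens.append(("x", m.group(3).upper()))
        pos = m.end()
    if pos != len(md):
        raise ValueError(f"malformed MD string {md!r}")
    return tokens


def format_md(tokens: MdTokens) -> str:
    """Render MD tokens canonically (0 separates adjacent non-match events)."""
    parts: List[str] = []
    need_zero = True  # MD strings start with a (possibly 0) match count
    for kind, val in tokens:
        if kind == "m":
            if int(val) == 0:
                continue
            parts.append(str(val))
            need_zero = False
        elif kind == "x":
            if need_zero:
                parts.append("0")
            parts.append(str(val))
            need_zero = True
        else:  # deletion
            if need_zero:
                parts.append("0")
            parts.append("^" + str(val))
            need_zero = True
    if need_zero:
        parts.append("0")
    return "".join(parts)


def reverse_complement_md(md: str) -> str:
    """MD string of the same alignment read in the opposite orientation."""
    rev: MdTokens = []
    for kind, val in reversed(parse_md(md)):
        if kind == "m":
            rev.append((kind, val))
        elif kind == "x":
            rev.append(("x", str(val).translate(_COMPLEMENT)))
        else:
            rev.append(("d", str(val).translate(_COMPLEMENT)[::-1]))
    return format_md(rev)


# ---------------------------------------------------------------------------
# SAM records


class SamParseError(ValueError):
    pass


class AlignmentRecord:
    """One SAM alignment line.

    The raw tab-separated fields are retained verbatim so that output is
    byte-identical to input except for deliberate edits (the MAPQ field).
    """

    __slots__ = ("fields", "_cigar_cache")

    def __init__(self, fields: List[str]):
        self.fields = fields
        self._cigar_cache: Optional[Cigar] = None

    # -- construction -------------------------------------------------
    @classmethod
    def from_line(cls, line: str, lineno: Optional[int] = None) -> "AlignmentRecord":
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 11:
            where = f" at line {lineno}" if lineno is not None else ""
            raise SamParseError(f"SAM record with {len(fields)} fields{where}")
        rec = cls(fields)
        try:
            rec.flag, rec.pos, rec.mapq, rec.tlen  # mandatory integer fields
            ops = rec.cigar
        except ValueError as e:
            where = f" at line {lineno}" if lineno is not None else ""
            raise SamParseError(f"malformed SAM field{where}: {e}") from e
        if rec.seq != "*":
            where = f" at line {lineno}" if lineno is not None else ""
            if len(rec.seq) != len(rec.qual_str) and rec.qual_str != "*":
                raise SamParseError(f"SEQ/QUAL length mismatch{where}")
            if ops and read_length_of(ops) != len(rec.seq):
                raise SamParseError(f"CIGAR does not span SEQ{where}")
        return rec

    def to_line(self) -> str:
        return "\t".join(self.fields)

    # -- mandatory fields ---------------------------------------------
    @property
    def qname(self) -> str:
        return self.fields[0]

    @property
    def flag(self) -> int:
        return int(self.fields[1])

    @property
    def refname(self) -> str:
        return self.fields[2]

    @property
    def pos(self) -> int:
        """1-based leftmost reference coordinate."""
        return int(self.fields[3])

    @property
    def mapq(self) -> int:
        return int(self.fields[4])

    @mapq.setter
    def mapq(self, value: int) -> None:
        if not 0 <= value <= 255:
            raise ValueError(f"MAPQ out of range: {value}")
        self.fields[4] = str(int(value))

    @property
    def cigar_str(self) -> str:
        return self.fields[5]

    @property
    def cigar(self) -> Cigar:
        if self._cigar_cache is None:
            self._cigar_cache = parse_cigar(self.fields[5])
        return self._cigar_cache

    @property
    def seq(self) -> str:
        return self.fields[9]

    @property
    def qual_str(self) -> str:
        return self.fields[10]

    @property
    def quals(self) -> List[int]:
        """Per-base Phred qualities (read as stored, reference orientation)."""
        return [ord(c) - PHRED_OFFSET for c in self.fields[10]]

    @property
    def tlen(self) -> int:
        return int(self.fields[8])

    # -- flag helpers --------------------------------------------------
    @property
    def is_paired(self) -> bool:
        return bool(self.flag & FLAG_PAIRED)

    @property
    def is_first_end(self) -> bool:
        return bool(self.flag & FLAG_FIRST)

    @property
    def is_reverse(self) -> bool:
        return bool(self.flag & FLAG_REVERSE)

    @property
    def is_aligned(self) -> bool:
        return not self.flag & FLAG_UNMAPPED

    @property
    def mate_aligned(self) -> bool:
        return not self.flag & FLAG_MATE_UNMAPPED

    @property
    def is_proper_pair(self) -> bool:
        return bool(self.flag & FLAG_PROPER_PAIR)

    # -- optional tags --------------------------------------------------
    def get_tag(self, name: str) -> Optional[str]:
        prefix = name + ":"
        for f in self.fields[11:]:
            if f.startswith(prefix):
                return f.split(":", 2)[2]
        return None

    @property
    def md(self) -> Optional[str]:
        return self.get_tag("MD")

    @property
    def feature_tag(self) -> Optional[str]:
        """Payload of the aligner feature field (ZT:Z:...)."""
        return self.get_tag("ZT")

    @property
    def leading_softclip(self) -> int:
        ops = self.cigar
        return ops[0][1] if ops and ops[0][0] == "S" else 0

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"AlignmentRecord({self.qname!r} {self.refname}:{self.fields[3]})"


def classify_category(rec: AlignmentRecord) -> Category:
    """Assign an aligned record to exactly one of the four categories.

    Concordance is read from the proper-pair flag as set by the aligner,
    not recomputed.
    """
    if not rec.is_aligned:
        raise ValueError("categories apply to aligned records only")
    if not rec.is_paired:
        return Category.UNP
    if not rec.mate_aligned:
        return Category.BAD_END
    if rec.is_proper_pair:
        return Category.CONC
    return Category.DISC


# ---------------------------------------------------------------------------
# SAM file I/O


def iter_sam(source) -> Iterator[Union[str, AlignmentRecord]]:
    """Yield header lines (str, without newline) then AlignmentRecords."""
    close = False
    if isinstance(source, (str, bytes)) or hasattr(source, "__fspath__"):
        source = open(source, "r")
        close = True
    try:
        for lineno, line in enumerate(source, start=1):
            if not line.strip():
                continue
            if line.startswith("@"):
                yield line.rstrip("\n")
            else:
                yield AlignmentRecord.from_line(line, lineno)
    finally:
        if close:
            source.close()


def read_sam(source) -> Tuple[List[str], List[AlignmentRecord]]:
    """Read a SAM file into (header_lines, records), preserving order."""
    header: List[str] = []
    records: List[AlignmentRecord] = []
    for item in iter_sam(source):
        if isinstance(item, str):
            header.append(item)
        else:
            records.append(item)
    return header, records


# ---------------------------------------------------------------------------
# FASTA / FASTQ


class Genome:
    """Reference genome: named contigs with length-weighted position draws."""

    def __init__(self, contigs: Dict[str, str]):
        for name in contigs:
            if "!" in name or any(c.isspace() for c in name):
                raise ValueError(
                    f"contig name {name!r} contains '!' or whitespace; "
                    "these clash with the read-name origin encoding"
                )
        if len(contigs) == 0:
            raise ValueError("genome has no contigs")
        self.contigs = {n: s.upper() for n, s in contigs.items()}
        self.names = list(self.contigs)
        self.lengths = {n: len(s) for n, s in self.contigs.items()}

    @classmethod
    def from_fasta(cls, path) -> "Genome":
        from Bio import SeqIO

        return cls({rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")})

    def to_fasta(self, path, width: int = 70) -> None:
        with open(path, "w") as fh:
            for name, seq in self.contigs.items():
                fh.write(f">{name}\n")
                for i in range(0, len(seq), width):
                    fh.write(seq[i : i + width] + "\n")

    def total_length(self) -> int:
        return sum(self.lengths.values())

    def draw_position(self, span: int, rng) -> Tuple[str, int]:
        """Uniform draw of a 0-based start over all valid placements.

        Contigs are implicitly weighted by the number of valid start
        positions (length - span + 1), so genomic positions are uniform
        overall.
        """
        valid = [(n, self.lengths[n] - span + 1) for n in self.names]
        total = sum(v for _, v in valid if v > 0)
        if total <= 0:
            raise ValueError(f"no contig can host a span of {span} nt")
        r = rng.randrange(total)
        for name, v in valid:
            if v <= 0:
                continue
            if r < v:
                return name, r
            r -= v
        raise AssertionError("unreachable")  # pragma: no cover

    def slice(self, name: str, start0: int, length: int) -> str:
        """0-based half-open substring of a contig."""
        return self.contigs[name][start0 : start0 + length]


def read_fastq(path) -> Iterator[Tuple[str, str, str]]:
    """Yield (name, seq, qual) from an uncompressed FASTQ file."""
    with open(path) as fh:
        while True:
            head = fh.readline()
            if not head:
                return
            if not head.startswith("@"):
                raise ValueError(f"bad FASTQ header line: {head!r}")
            seq = fh.readline().rstrip("\n")
            plus = fh.readline()
            qual = fh.readline().rstrip("\n")
            if not plus.startswith("+") or len(seq) != len(qual):
                raise ValueError(f"malformed FASTQ record {head.strip()!r}")
            yield head[1:].split()[0], seq, qual


def write_fastq(reads: Iterable[Tuple[str, str, str]], dest) -> None:
    close = False
    if isinstance(dest, (str, bytes)) or hasattr(dest, "__fspath__"):
        dest = open(dest, "w")
        close = True
    try:
        for name, seq, qual in reads:
            dest.write(f"@{name}\n{seq}\n+\n{qual}\n")
    finally:
        if close:
            dest.close()


def write_sam(header: Iterable[str], records: Iterable[AlignmentRecord], dest) -> None:
    close = False
    if isinstance(dest, (str, bytes)) or hasattr(dest, "__fspath__"):
        dest = open(dest, "w")
        close = True
    try:
        for line in header:
            dest.write(line + "\n")
        for rec in records:
            dest.write(rec.to_line() + "\n")
    finally:
        if close:
            dest.close()
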