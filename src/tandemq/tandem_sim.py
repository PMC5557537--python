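"""Simulation of tandem reads from the input model and a reference genome.

A tandem read is drawn from a random genomic location but shaped by a
template learned from the input alignments: the extracted substring is
(optionally) reverse-complemented according to the template strand, then
mutated by replaying the template's CIGAR/MD pattern, and finally given
the template's quality string verbatim.  The true point of origin is
encoded in the read name so downstream steps can label each alignment
correct or incorrect.
"""

from __future__ import annotations

import random
from dataclasses import dataclass
from typing import Iterator, List, Optional, Sequence, Tuple, Union

from .core import Genome, revcomp
from .input_model import InputModel, PairedTemplate, UnpairedTemplate

_BASES = "ACGT"

SENTINEL = "qt"
DELIM = "!"
_ROLE_CODE = {"single": "s", "end1": "1", "end2": "2"}
_ROLE_DECODE = {v: k for k, v in _ROLE_CODE.items()}


class TemplateCorruptError(ValueError):
    """CIGAR and MD of a template disagree."""


class SimulationError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# Span arithmetic


def ref_span(cigar: Sequence[Tuple[str, int]]) -> int:
    """Reference bases consumed by an alignment: sum of M/D/=/X lengths."""
    span = 0
    for op, n in cigar:
        if op in "MD=X":
            span += n
        elif op == "H":
            raise ValueError("hard-clipped CIGARs are not supported")
    return span


def extraction_span(cigar: Sequence[Tuple[str, int]]) -> int:
    """Genome bases to extract for replay: ref span plus soft-clip lengths.

    Soft-clipped read bases are drawn from the flanking reference so the
    simulated read has sequence at every position.
    """
    return ref_span(cigar) + sum(n for op, n in cigar if op == "S")


# ---------------------------------------------------------------------------
# Origins and read names


@dataclass(frozen=True)
class Origin:
    """True point of origin of a simulated read.

    ``start`` is the 1-based leftmost reference coordinate of the simulated
    substring (clip flanks included), matching what a correct aligner
    placement implies after the soft-clip adjustment.
    """

    refname: str
    start: int
    strand: str
    category: str          # unp/conc/disc/bad_end, or "input" for fixtures
    mate_role: str = "single"  # single / end1 / end2

    def __post_init__(self):
        if self.start < 1:
            raise ValueError("origin start is 1-based and must be >= 1")
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r}")


def encode_origin(o: Origin) -> str:
    """Read name for an unpaired simulated read: qt!ref!start!strand!cat!s."""
    if DELIM in o.refname or any(c.isspace() for c in o.refname):
        raise ValueError(f"refname {o.refname!r} clashes with the name encoding")
    return DELIM.join(
        [SENTINEL, o.refname, str(o.start), o.strand, o.category,
         _ROLE_CODE[o.mate_role]]
    )


def encode_pair_origin(o1: Origin, o2: Origin) -> str:
    """Shared QNAME for both ends of a simulated pair.

    Both ends of a pair must carry the same SAM QNAME, so the name encodes
    both origins: qt!ref!start1!strand1!start2!strand2!cat!p.
    """
    if o1.refname != o2.refname or o1.category != o2.category:
        raise ValueError("pair ends must share refname and category")
    if DELIM in o1.refname or any(c.isspace() for c in o1.refname):
        raise ValueError(f"refname {o1.refname!r} clashes with the name encoding")
    return DELIM.join(
        [SENTINEL, o1.refname, str(o1.start), o1.strand,
         str(o2.start), o2.strand, o1.category, "p"]
    )


def decode_origin(name: str, first_end: bool = True) -> Optional[Origin]:
    """Recover the Origin encoded in a read name.

    Returns None for names without the ``qt!`` sentinel (not a tandem
    read; step 5 uses this to ignore strays).  For pair-encoded names,
    ``first_end`` selects which end's origin is returned.
    """
    parts = name.split(DELIM)
    if parts[0] != SENTINEL or len(parts) < 6:
        return None
    try:
        if parts[-1] == "p":
            if len(parts) != 8:
                raise ValueError(name)
            ref, s1, st1, s2, st2, cat = parts[1:7]
            if first_end:
                return Origin(ref, int(s1), st1, cat, "end1")
            return Origin(ref, int(s2), st2, cat, "end2")
        if len(parts) != 6:
            raise ValueError(name)
        ref, start, strand, cat, role = parts[1:6]
        return Origin(ref, int(start), strand, cat, _ROLE_DECODE[role])
    except (KeyError, ValueError) as e:
        raise ValueError(f"malformed tandem read name {name!r}") from e


@dataclass(frozen=True)
class SimulatedRead:
    name: str
    seq: str
    quals: str
    truth: Origin


# ---------------------------------------------------------------------------
# Mutation replay


def apply_template_mutations(substring: str, t: UnpairedTemplate, rng) -> str:
    """Replay a template's CIGAR/MD pattern onto a genome substring.

    Walks the CIGAR left to right (read orientation): matches copy the
    substring base, MD mismatches substitute a base drawn uniformly from
    the three alternatives, deletions skip reference bases, insertions
    emit uniform random bases, and soft-clipped positions copy substring
    bases unmutated.  Templates without an MD string replay structure only
    (all M positions copy).
    """
    if len(substring) != extraction_span(t.cigar):
        raise ValueError(
            f"substring length {len(substring)} != extraction span "
            f"{extraction_span(t.cigar)}"
        )
    md_tokens = None
    if t.md is not None:
        from .core import parse_md

        md_tokens = parse_md(t.md)
    ti = 0           # index into md_tokens
    trun = 0         # bases consumed from current match token
    out: List[str] = []
    spos = 0

    def next_aligned_event() -> str:
        # returns "=" for a matched position or the mismatch marker "X"
        nonlocal ti, trun
        if md_tokens is None:
            return "="
        while ti < len(md_tokens):
            kind, val = md_tokens[ti]
            if kind == "m":
                if trun < int(val):
                    trun += 1
                    if trun == int(val):
                        ti += 1
                        trun = 0
                    return "="
                ti += 1
                trun = 0
            elif kind == "x":
                ti += 1
                return "X"
            else:
                raise TemplateCorruptError(
                    f"MD deletion where CIGAR has aligned bases (md={t.md!r})"
                )
        raise TemplateCorruptError(f"MD string {t.md!r} shorter than CIGAR")

    def consume_deletion(n: int) -> None:
        nonlocal ti
        if md_tokens is None:
            return
        if ti >= len(md_tokens) or md_tokens[ti][0] != "d":
            raise TemplateCorruptError(
                f"CIGAR deletion not mirrored in MD (md={t.md!r})"
            )
        if len(md_tokens[ti][1]) != n:
            raise TemplateCorruptError(
                f"deletion length mismatch between CIGAR and MD (md={t.md!r})"
            )
        ti += 1

    for op, n in t.cigar:
        if op == "S":
            out.append(substring[spos : spos + n])
            spos += n
        elif op == "M":
            for _ in range(n):
                base = substring[spos]
                spos += 1
                if next_aligned_event() == "X":
                    choices = [b for b in _BASES if b != base] or list(_BASES)
                    base = rng.choice(choices)
                out.append(base)
        elif op == "D":
            consume_deletion(n)
            spos += n
        elif op == "I":
            out.append("".join(rng.choice(_BASES) for _ in range(n)))
        else:
            raise ValueError(f"unsupported CIGAR op {op!r} in template")
    if md_tokens is not None and (trun != 0 or ti != len(md_tokens)):
        raise TemplateCorruptError(f"MD string {t.md!r} longer than CIGAR")
    result = "".join(out)
    assert len(result) == len(t.quals)
    return result


# ---------------------------------------------------------------------------
# Ambiguous-base policy


def handle_ambiguous_bases(substring: str, policy: str = "redraw") -> bool:
    """Return True if the substring is acceptable under the policy.

    ``redraw`` rejects substrings containing any non-ACGT character (the
    caller draws a new position); ``keep`` accepts everything.
    """
    if policy not in ("redraw", "keep"):
        raise ValueError(f"unknown N policy {policy!r}")
    if policy == "keep":
        return True
    return all(c in _BASES for c in substring)


def _draw_clean(genome: Genome, span: int, rng, n_policy: str, max_redraws: int):
    for _ in range(max_redraws):
        name, start0 = genome.draw_position(span, rng)
        sub = genome.slice(name, start0, span)
        if handle_ambiguous_bases(sub, n_policy):
            return name, start0, sub
    raise SimulationError(
        f"could not draw an N-free substring of {span} nt in {max_redraws} attempts"
    )


# ---------------------------------------------------------------------------
# Read simulation


def _replay_end(
    sub: str, t: UnpairedTemplate, rng
) -> Tuple[str, str]:
    """(seq, quals) for one end given its extracted genome substring."""
    if t.strand == "-":
        sub = revcomp(sub)
    return apply_template_mutations(sub, t, rng), t.quals


def simulate_unpaired(
    model: InputModel,
    genome: Genome,
    cat,
    rng: random.Random,
    n_policy: str = "redraw",
    max_redraws: int = 1000,
) -> SimulatedRead:
    """Simulate one unpaired tandem read for a category.

    The template is drawn uniformly with replacement from the category
    reservoir; the genome position uniformly over all valid placements.
    """
    from .core import Category

    cat = Category(cat)
    res = model.reservoirs[cat]
    if not res.items:
        raise SimulationError(f"no templates in the {cat.value} reservoir")
    t = res.items[rng.randrange(len(res.items))]
    assert isinstance(t, UnpairedTemplate)
    span = extraction_span(t.cigar)
    name0, start0, sub = _draw_clean(genome, span, rng, n_policy, max_redraws)
    seq, quals = _replay_end(sub, t, rng)
    truth = Origin(name0, start0 + 1, t.strand, cat.value, "single")
    return SimulatedRead(encode_origin(truth), seq, quals, truth)


def simulate_pair(
    model: InputModel,
    genome: Genome,
    cat,
    rng: random.Random,
    n_policy: str = "redraw",
    max_redraws: int = 1000,
) -> Tuple[SimulatedRead, SimulatedRead]:
    """Simulate one tandem pair: fragment placed uniformly, ends at its extremes."""
    from .core import Category

    cat = Category(cat)
    res = model.reservoirs[cat]
    if not res.items:
        raise SimulationError(f"no templates in the {cat.value} reservoir")
    t = res.items[rng.randrange(len(res.items))]
    assert isinstance(t, PairedTemplate)
    e1_span = extraction_span(t.end1.cigar)
    e2_span = extraction_span(t.end2.cigar)
    span = max(t.frag_len, e1_span, e2_span)
    for _ in range(max_redraws):
        name0, start0 = genome.draw_position(span, rng)
        frag = genome.slice(name0, start0, span)
        if handle_ambiguous_bases(frag, n_policy):
            break
    else:
        raise SimulationError(
            f"could not place a {span} nt fragment without Ns in "
            f"{max_redraws} attempts"
        )
    if t.first_end_upstream:
        up_t, down_t = t.end1, t.end2
        up_span, down_span = e1_span, e2_span
    else:
        up_t, down_t = t.end2, t.end1
        up_span, down_span = e2_span, e1_span
    up_sub = frag[:up_span]
    down_sub = frag[span - down_span :]
    up_seq, up_quals = _replay_end(up_sub, up_t, rng)
    down_seq, down_quals = _replay_end(down_sub, down_t, rng)
    up_origin = Origin(
        name0, start0 + 1, up_t.strand, cat.value,
        "end1" if t.first_end_upstream else "end2",
    )
    down_origin = Origin(
        name0, start0 + span - down_span + 1, down_t.strand, cat.value,
        "end2" if t.first_end_upstream else "end1",
    )
    if t.first_end_upstream:
        o1, o2 = up_origin, down_origin
        r1 = (up_seq, up_quals)
        r2 = (down_seq, down_quals)
    else:
        o1, o2 = down_origin, up_origin
        r1 = (down_seq, down_quals)
        r2 = (up_seq, up_quals)
    name = encode_pair_origin(o1, o2)
    return (
        SimulatedRead(name, r1[0], r1[1], o1),
        SimulatedRead(name, r2[0], r2[1], o2),
    )


def simulate_category(
    model: InputModel,
    genome: Genome,
    cat,
    n: int,
    rng: random.Random,
    n_policy: str = "redraw",
    max_redraws: int = 1000,
) -> Iterator[Union[SimulatedRead, Tuple[SimulatedRead, SimulatedRead]]]:
    """Yield n tandem reads (or pairs, for conc/disc) for one category."""
    from .core import Category

    cat = Category(cat)
    paired = cat in (Category.CONC, Category.DISC)
    for _ in range(n):
        if paired:
            yield simulate_pair(model, genome, cat, rng, n_policy, max_redraws)
        else:
            yield simulate_unpaired(model, genome, cat, rng, n_policy, max_redraws)
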