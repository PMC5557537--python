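"""Input model: templates extracted from input alignments plus reservoirs.

The input model captures what the input reads and their alignments look
like — strand, quality string, and the mismatch/gap pattern encoded by
CIGAR and MD — so that the simulator can generate new reads from random
genome locations that nonetheless mimic the input.  One bounded reservoir
per alignment category keeps memory constant for arbitrarily large inputs.

Templates are stored in *read orientation*: for reverse-strand alignments
the CIGAR is reversed, the quality string is reversed, and the MD string
is reverse-complemented at extraction time, so replay never needs to know
the strand of the source alignment.
"""

from __future__ import annotations

import json
import math
import random
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Tuple, Union

from .core import (
    AlignmentRecord,
    Category,
    cigar_to_str,
    classify_category,
    normalize_cigar,
    parse_cigar,
    read_length_of,
    reverse_complement_md,
)

DEFAULT_RESERVOIR_CAPACITY = 10_000
DEFAULT_SIM_FACTOR = 45.0
DEFAULT_SIM_FUNCTION = "sqrt"
DEFAULT_MINIMUMS: Dict[Category, int] = {
    Category.UNP: 30_000,
    Category.CONC: 30_000,
    Category.DISC: 10_000,
    Category.BAD_END: 10_000,
}

_SIM_FUNCTIONS = {
    "sqrt": math.sqrt,
    "linear": lambda x: float(x),
    "const": lambda x: 1.0,
}


@dataclass(frozen=True)
class UnpairedTemplate:
    """Strand + quality string + CIGAR/MD mutation pattern of one alignment."""

    strand: str               # '+' or '-'
    quals: str                # Phred string, read orientation
    cigar: Tuple[Tuple[str, int], ...]
    md: Optional[str] = None  # read-orientation MD, or None (replay disabled)

    def __post_init__(self):
        if self.strand not in "+-":
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if read_length_of(self.cigar) != len(self.quals):
            raise ValueError("CIGAR read length does not match quality string")

    @property
    def read_len(self) -> int:
        return len(self.quals)


@dataclass(frozen=True)
class PairedTemplate:
    """Templates for both ends plus fragment geometry."""

    end1: UnpairedTemplate
    end2: UnpairedTemplate
    frag_len: int             # |TLEN| of the pair
    first_end_upstream: bool  # True when end1 aligned upstream on the genome

    def __post_init__(self):
        if self.frag_len <= 0:
            raise ValueError("fragment length must be positive")


Template = Union[UnpairedTemplate, PairedTemplate]


def _to_read_orientation(rec: AlignmentRecord) -> UnpairedTemplate:
    strand = "-" if rec.is_reverse else "+"
    cigar = normalize_cigar(rec.cigar)
    quals = rec.qual_str
    md = rec.md
    if strand == "-":
        cigar = list(reversed(cigar))
        quals = quals[::-1]
        if md is not None:
            md = reverse_complement_md(md)
    return UnpairedTemplate(strand=strand, quals=quals, cigar=tuple(cigar), md=md)


def extract_template(
    rec: AlignmentRecord, mate: Optional[AlignmentRecord] = None
) -> Template:
    """Build a template from one aligned record (or an aligned pair).

    For pairs, fragment length is |TLEN| and ``first_end_upstream`` comes
    from the sign of the first end's TLEN (positive = upstream per SAM).
    Records without an MD tag yield templates with ``md=None``; mismatch
    replay is disabled for them downstream.
    """
    if not rec.is_aligned:
        raise ValueError("cannot extract a template from an unaligned record")
    if mate is None:
        return _to_read_orientation(rec)
    if not mate.is_aligned:
        raise ValueError("paired extraction requires both ends aligned")
    first, second = (rec, mate) if rec.is_first_end else (mate, rec)
    if abs(first.tlen) != abs(second.tlen):
        raise ValueError(
            f"inconsistent TLEN for pair {rec.qname!r}: "
            f"{first.tlen} vs {second.tlen}"
        )
    frag_len = abs(first.tlen)
    return PairedTemplate(
        end1=_to_read_orientation(first),
        end2=_to_read_orientation(second),
        frag_len=frag_len,
        first_end_upstream=first.tlen > 0,
    )


# ---------------------------------------------------------------------------
# Reservoir sampling (Algorithm R)


class Reservoir:
    """Uniform fixed-size subsample of a stream (Algorithm R).

    The first ``capacity`` offered items are kept; afterwards the i-th item
    replaces a uniformly chosen slot with probability capacity/i, so every
    offered item is retained with equal probability capacity/seen.
    """

    def __init__(self, capacity: int = DEFAULT_RESERVOIR_CAPACITY, seed: int = 0):
        if capacity <= 0:
            raise ValueError("reservoir capacity must be positive")
        self.capacity = capacity
        self.items: List[Template] = []
        self.seen = 0
        self._rng = random.Random(seed)

    def offer(self, item: Template) -> None:
        self.seen += 1
        if len(self.items) < self.capacity:
            self.items.append(item)
        else:
            j = self._rng.randrange(self.seen)
            if j < self.capacity:
                self.items[j] = item

    def __len__(self) -> int:
        return len(self.items)


def reservoir_offer(res: Reservoir, item: Template) -> Reservoir:
    """Functional-style wrapper around :meth:`Reservoir.offer`."""
    res.offer(item)
    return res


# ---------------------------------------------------------------------------
# Tandem-read count targets


def target_tandem_count(
    x: int,
    cat: Category,
    factor: float = DEFAULT_SIM_FACTOR,
    fn: str = DEFAULT_SIM_FUNCTION,
    minimums: Optional[Dict[Category, int]] = None,
) -> int:
    """Number of tandem reads/pairs to simulate for a category.

    Default is ceil(factor * fn(x)) with fn = sqrt and factor = 45, subject
    to per-category minimums (30,000 for unp/conc, 10,000 for disc/bad_end).
    A category with no input alignments gets no simulation and no model.
    """
    if factor <= 0:
        raise ValueError("sim factor must be positive")
    if fn not in _SIM_FUNCTIONS:
        raise ValueError(f"unknown sim function {fn!r}; use sqrt, linear or const")
    if x < 0:
        raise ValueError("alignment count cannot be negative")
    if x == 0:
        return 0
    minimums = DEFAULT_MINIMUMS if minimums is None else minimums
    return int(math.ceil(max(factor * _SIM_FUNCTIONS[fn](x), minimums.get(cat, 0))))


# ---------------------------------------------------------------------------
# Model construction from a SAM stream


_CATEGORY_INDEX = {
    Category.UNP: 0,
    Category.CONC: 1,
    Category.DISC: 2,
    Category.BAD_END: 3,
}


@dataclass
class InputModel:
    """Per-category reservoirs plus input alignment counts."""

    reservoirs: Dict[Category, Reservoir]
    counts: Dict[Category, int] = field(
        default_factory=lambda: {c: 0 for c in Category}
    )

    @classmethod
    def empty(
        cls, capacity: int = DEFAULT_RESERVOIR_CAPACITY, seed: int = 0
    ) -> "InputModel":
        # one reservoir per category, each with its own derived seed
        return cls(
            reservoirs={
                c: Reservoir(capacity, seed=(seed + _CATEGORY_INDEX[c]) % 2**31)
                for c in Category
            }
        )

    def targets(
        self,
        factor: float = DEFAULT_SIM_FACTOR,
        fn: str = DEFAULT_SIM_FUNCTION,
        minimums: Optional[Dict[Category, int]] = None,
    ) -> Dict[Category, int]:
        return {
            c: target_tandem_count(self.counts[c], c, factor, fn, minimums)
            for c in Category
        }


def build_input_model(
    records: Iterable[AlignmentRecord],
    capacity: int = DEFAULT_RESERVOIR_CAPACITY,
    seed: int = 0,
) -> InputModel:
    """Stream alignments into per-category template reservoirs.

    Pairs are matched by QNAME.  Pair templates are extracted only when both
    ends aligned (conc/disc); when the mate failed to align the aligned end
    is stored as an unpaired template in the bad-end reservoir.
    """
    model = InputModel.empty(capacity=capacity, seed=seed)
    pending: Dict[str, AlignmentRecord] = {}
    for rec in records:
        if not rec.is_aligned:
            continue
        cat = classify_category(rec)
        model.counts[cat] += 1
        if cat is Category.UNP:
            model.reservoirs[cat].offer(extract_template(rec))
        elif cat is Category.BAD_END:
            model.reservoirs[cat].offer(extract_template(rec))
        else:
            mate = pending.pop(rec.qname, None)
            if mate is None:
                pending[rec.qname] = rec
            else:
                model.reservoirs[cat].offer(extract_template(rec, mate))
    return model


# ---------------------------------------------------------------------------
# JSON-lines serialization (inspection / reuse)


def _template_to_dict(t: Template) -> dict:
    if isinstance(t, PairedTemplate):
        return {
            "kind": "pair",
            "end1": _template_to_dict(t.end1),
            "end2": _template_to_dict(t.end2),
            "frag_len": t.frag_len,
            "first_end_upstream": t.first_end_upstream,
        }
    return {
        "kind": "unp",
        "strand": t.strand,
        "quals": t.quals,
        "cigar": cigar_to_str(t.cigar),
        "md": t.md,
    }


def _template_from_dict(d: dict) -> Template:
    if d["kind"] == "pair":
        return PairedTemplate(
            end1=_template_from_dict(d["end1"]),
            end2=_template_from_dict(d["end2"]),
            frag_len=d["frag_len"],
            first_end_upstream=d["first_end_upstream"],
        )
    return UnpairedTemplate(
        strand=d["strand"],
        quals=d["quals"],
        cigar=tuple(parse_cigar(d["cigar"])),
        md=d["md"],
    )


def save_input_model(model: InputModel, path) -> None:
    """Write the model as JSON lines: one header line, then one per template."""
    with open(path, "w") as fh:
        header = {
            "counts": {c.value: model.counts[c] for c in Category},
            "capacities": {c.value: model.reservoirs[c].capacity for c in Category},
            "seen": {c.value: model.reservoirs[c].seen for c in Category},
        }
        fh.write(json.dumps(header) + "\n")
        for cat in Category:
            for t in model.reservoirs[cat].items:
                d = _template_to_dict(t)
                d["category"] = cat.value
                fh.write(json.dumps(d) + "\n")


def load_input_model(path) -> InputModel:
    with open(path) as fh:
        header = json.loads(fh.readline())
        model = InputModel.empty()
        for c in Category:
            model.counts[c] = header["counts"][c.value]
            model.reservoirs[c].capacity = header["capacities"][c.value]
            model.reservoirs[c].seen = header["seen"][c.value]
        for line in fh:
            d = json.loads(line)
            cat = Category(d.pop("category"))
            model.reservoirs[cat].items.append(_template_from_dict(d))
    return model
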