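"""Shared primitives: genomic intervals, strands and sequence helpers.

Coordinates are 0-based half-open on the plus strand throughout the package;
the 1-based inclusive convention only appears in the GFF3/TSV writers.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator

GeneType = str  # "V" | "D" | "J"
Strand = str  # "+" | "-"

_COMPLEMENT = str.maketrans("acgtnACGTN", "tgcanTGCAN")

_CODON_TABLE = {
    "ttt": "F", "ttc": "F", "tta": "L", "ttg": "L",
    "ctt": "L", "ctc": "L", "cta": "L", "ctg": "L",
    "att": "I", "atc": "I", "ata": "I", "atg": "M",
    "gtt": "V", "gtc": "V", "gta": "V", "gtg": "V",
    "tct": "S", "tcc": "S", "tca": "S", "tcg": "S",
    "cct": "P", "ccc": "P", "cca": "P", "ccg": "P",
    "act": "T", "acc": "T", "aca": "T", "acg": "T",
    "gct": "A", "gcc": "A", "gca": "A", "gcg": "A",
    "tat": "Y", "tac": "Y", "taa": "*", "tag": "*",
    "cat": "H", "cac": "H", "caa": "Q", "cag": "Q",
    "aat": "N", "aac": "N", "aaa": "K", "aag": "K",
    "gat": "D", "gac": "D", "gaa": "E", "gag": "E",
    "tgt": "C", "tgc": "C", "tga": "*", "tgg": "W",
    "cgt": "R", "cgc": "R", "cga": "R", "cgg": "R",
    "agt": "S", "agc": "S", "aga": "R", "agg": "R",
    "ggt": "G", "ggc": "G", "gga": "G", "ggg": "G",
}

STOP_CODONS = frozenset(c for c, aa in _CODON_TABLE.items() if aa == "*")


def revcomp(seq: str) -> str:
    """Reverse complement (case preserved, 'n' allowed)."""
    return seq.translate(_COMPLEMENT)[::-1]


def translate(seq: str) -> str:
    """Translate complete codons; unknown/ambiguous codons become 'X'."""
    return "".join(
        _CODON_TABLE.get(seq[i : i + 3].lower(), "X")
        for i in range(0, len(seq) - len(seq) % 3, 3)
    )


@dataclass(frozen=True, order=True)
class Interval:
    """0-based half-open genomic interval, plus-strand coordinates."""

    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"empty-ordered interval [{self.start}, {self.end})")

    def __len__(self) -> int:
        return self.end - self.start

    def __iter__(self) -> Iterator[int]:
        return iter((self.start, self.end))

    def overlaps(self, other: "Interval") -> bool:
        return self.start < other.end and other.start < self.end

    def contains(self, other: "Interval") -> bool:
        return self.start <= other.start and other.end <= self.end

    def intersect(self, other: "Interval") -> "Interval | None":
        lo, hi = max(self.start, other.start), min(self.end, other.end)
        return Interval(lo, hi) if lo < hi else None

    def union_span(self, other: "Interval") -> "Interval":
        return Interval(min(self.start, other.start), max(self.end, other.end))

    def expand(self, left: int, right: int, bound: int | None = None) -> "Interval":
        """Grow by `left`/`right` nt, clamped to [0, bound)."""
        lo = max(0, self.start - left)
        hi = self.end + right
        if bound is not None:
            hi = min(hi, bound)
            lo = min(lo, hi)
        return Interval(lo, hi)

    def mirror(self, seq_length: int) -> "Interval":
        """The same physical interval in reverse-complement coordinates."""
        return Interval(seq_length - self.end, seq_length - self.start)


def oriented_start(iv: Interval, strand: Strand, seq_length: int) -> int:
    """5' start of `iv` in gene-orientation coordinates."""
    return iv.start if strand == "+" else seq_length - iv.end


def feature_seq(seq: str, iv: Interval, strand: Strand) -> str:
    """Gene-oriented (sense) sequence of a plus-strand interval."""
    sub = seq[iv.start : iv.end]
    return sub if strand == "+" else revcomp(sub)
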