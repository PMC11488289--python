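"""Core domain types: genomic features and annotated mitogenomes.

Coordinate convention
---------------------
All positions are 0-based half-open intervals on the deposited plus strand.
On circular genomes a feature that spans the origin of the deposited sequence
is represented with ``end > genome_length`` (e.g. a CDS written in GenBank as
``join(150..200,1..40)`` on a 200 bp circle becomes ``start=149, end=240``).
This keeps one arithmetic rule for everything: a feature always covers
``[start, end)`` read modulo the genome length.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace

from . import vocab

FTYPES = ("PCG", "rRNA", "tRNA", "NCR", "other")

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement over the {A,C,G,T,N} alphabet."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class Feature:
    """One annotated feature on a mitogenome.

    ``flags`` records curation provenance ("unmapped", "evidence:dual",
    "putative duplication", ...) and is carried through every edit.
    """

    label: str
    ftype: str
    strand: str  # '+' or '-'
    start: int
    end: int
    source: str = ""
    structure: str | None = None
    flags: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.ftype not in FTYPES:
            raise ValueError(f"unknown feature type {self.ftype!r}")
        if self.strand not in "+-":
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if self.start < 0 or self.end <= self.start:
            raise ValueError(f"bad span [{self.start}, {self.end})")

    @property
    def length(self) -> int:
        return self.end - self.start

    def spans_origin(self, genome_length: int) -> bool:
        return self.end > genome_length

    def validate(self, genome_length: int) -> None:
        """Enforce the coordinate invariants against a genome length."""
        if not 0 <= self.start < genome_length:
            raise ValueError(f"{self.label}: start {self.start} outside genome")
        if self.end > self.start + genome_length:
            raise ValueError(f"{self.label}: span longer than genome")

    def with_flags(self, *extra: str) -> "Feature":
        new = tuple(dict.fromkeys(self.flags + extra))  # ordered de-dup
        return replace(self, flags=new)


@dataclass
class AnnotatedGenome:
    """Circular (or linear) mitogenome sequence plus its feature set.

    ``contig_breaks`` lists the start positions of placeholder-N runs
    (>= 100 consecutive ``N``) used to join two-contig submissions into one
    deposited sequence; the sequence is kept joined and composition
    statistics simply skip ``N``.
    """

    id: str
    sequence: str
    circular: bool = True
    features: list[Feature] = field(default_factory=list)
    contig_breaks: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        if not self.contig_breaks:
            self.contig_breaks = find_contig_breaks(self.sequence)

    @property
    def length(self) -> int:
        return len(self.sequence)

    def span_seq(self, start: int, end: int) -> str:
        """Plus-strand sequence of ``[start, end)``, wrapping on circles."""
        n = self.length
        if end <= n:
            return self.sequence[start:end]
        if not self.circular:
            raise ValueError("span exceeds linear genome")
        return self.sequence[start:] + self.sequence[: end - n]

    def feature_seq(self, feature: Feature) -> str:
        """Coding-strand sequence of a feature (reverse-complemented for '-')."""
        s = self.span_seq(feature.start, feature.end)
        return revcomp(s) if feature.strand == "-" else s

    def sorted_features(self) -> list[Feature]:
        return sorted(self.features, key=lambda f: (f.start, f.end, f.label))


def find_contig_breaks(sequence: str, min_run: int = 100) -> list[int]:
    """Start positions of runs of at least ``min_run`` consecutive N."""
    return [m.start() for m in re.finditer("N{%d,}" % min_run, sequence.upper())]


def make_feature(
    name: str,
    ftype_hint: str | None,
    strand: str,
    start: int,
    end: int,
    source: str = "",
    structure: str | None = None,
) -> Feature:
    """Build a Feature, mapping ``name`` through the canonical vocabulary.

    Unmappable names are kept (label = raw name) and flagged ``unmapped``;
    the feature type falls back to the hint or ``other``.
    """
    label = vocab.canonical_label(name)
    if label is None:
        ftype = ftype_hint if ftype_hint in FTYPES else "other"
        return Feature(name, ftype, strand, start, end, source, structure, ("unmapped",))
    return Feature(
        label, vocab.feature_type(label), strand, start, end, source, structure
    )
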