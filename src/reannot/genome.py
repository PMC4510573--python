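"""Genome data model, ORF enumeration, locus-tag naming and category census.

A re-annotation run views a bacterial chromosome as an ordered list of CDS
records, each carrying one of five curation categories:

* ``KNOWN`` — a protein with an accepted function,
* ``HYPOTHETICAL`` — a predicted protein with no supported function,
* ``PUTATIVE`` — function inferred only from a motif, structural feature or
  limited similarity,
* ``NEW`` — a CDS absent from the original annotation, found by maximal-ORF
  enumeration, and
* ``PSEUDOGENE`` — a gene remnant, excluded from functional re-annotation.

The ORF finder returns *maximal* open reading frames: in every frame, on both
strands, the segment between two stop codons contributes at most one ORF,
running from the first start codon after the upstream stop through the
downstream stop codon (stop included in the length).
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Iterable, Mapping, Sequence

__all__ = [
    "Category",
    "GeneRecord",
    "CategoryCensus",
    "GenomeAnnotation",
    "find_orfs",
    "assign_locus_tags",
    "census",
    "gc_content",
    "reverse_complement",
    "START_CODONS",
    "STOP_CODONS",
]

# Bacterial translation table 11 start/stop codons.
START_CODONS = frozenset({"ATG", "GTG", "TTG"})
STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
_LOCUS_RE = re.compile(r"^[A-Za-z0-9.]+_\d{4,}$")
_VALID_NT = frozenset("ACGTN")


class Category(str, Enum):
    """CDS curation category."""

    KNOWN = "KNOWN"
    HYPOTHETICAL = "HYPOTHETICAL"
    PUTATIVE = "PUTATIVE"
    NEW = "NEW"
    PSEUDOGENE = "PSEUDOGENE"


@dataclass(frozen=True)
class GeneRecord:
    """One CDS with coordinates, category, product and confidence.

    Coordinates are 1-based inclusive on the forward strand; minus-strand
    features keep forward-strand coordinates with ``strand='-'``.
    """

    locus_tag: str
    genome_id: str
    start: int
    end: int
    strand: str
    product: str = ""
    category: Category = Category.HYPOTHETICAL
    confidence: int = 0
    cog_ids: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if not _LOCUS_RE.match(self.locus_tag):
            raise ValueError(f"malformed locus tag: {self.locus_tag!r}")
        if self.start < 1 or self.end < self.start:
            raise ValueError(
                f"{self.locus_tag}: invalid coordinates {self.start}..{self.end}"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.locus_tag}: strand must be '+' or '-'")
        if self.category is not Category.PSEUDOGENE and self.length % 3 != 0:
            raise ValueError(
                f"{self.locus_tag}: CDS length {self.length} not a multiple of 3"
            )
        if not 0 <= self.confidence <= 5:
            raise ValueError(f"{self.locus_tag}: confidence must be 0..5")
        if self.confidence > 0 and self.category not in (
            Category.KNOWN,
            Category.PUTATIVE,
        ):
            raise ValueError(
                f"{self.locus_tag}: confidence > 0 requires KNOWN or PUTATIVE"
            )

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def with_call(
        self, category: Category, product: str, confidence: int
    ) -> "GeneRecord":
        return replace(
            self, category=category, product=product, confidence=confidence
        )


@dataclass(frozen=True)
class CategoryCensus:
    """Counts of genes per category; ``total`` is always their sum.

    Keys are free strings so reports can split categories further (for
    example ``HYPOTHETICAL_NEW`` for newly predicted CDSs that stayed
    uncharacterised).
    """

    counts: Mapping[str, int]

    def __post_init__(self) -> None:
        for key, n in self.counts.items():
            if n < 0:
                raise ValueError(f"negative count for {key}: {n}")

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    def get(self, key: str) -> int:
        return self.counts.get(str(key), 0)

    def as_dict(self) -> dict[str, int]:
        out = {k: int(v) for k, v in self.counts.items()}
        out["total"] = self.total
        return out


@dataclass
class GenomeAnnotation:
    """A genome with its ordered gene list."""

    genome_id: str
    sequence_length: int
    gc_fraction: float
    genes: list[GeneRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.genes = sorted(self.genes, key=lambda g: (g.start, g.strand, g.end))
        tags = [g.locus_tag for g in self.genes]
        if len(tags) != len(set(tags)):
            raise ValueError(f"{self.genome_id}: duplicate locus tags")
        for g in self.genes:
            if g.end > self.sequence_length:
                raise ValueError(
                    f"{g.locus_tag}: end {g.end} beyond sequence length "
                    f"{self.sequence_length}"
                )


def reverse_complement(dna: str) -> str:
    return dna.translate(_COMPLEMENT)[::-1]


def _check_nucleotides(dna: str) -> str:
    dna = dna.upper()
    bad = set(dna) - _VALID_NT
    if bad:
        raise ValueError(f"non-nucleotide characters in sequence: {sorted(bad)}")
    return dna


def _scan_strand(seq: str, min_len_nt: int) -> list[tuple[int, int]]:
    """Maximal ORFs on the given strand, 1-based inclusive, stop included.

    In each frame an ORF runs from the first start codon after the previous
    stop to the next stop codon; ORFs containing N are discarded.
    """
    n = len(seq)
    orfs: list[tuple[int, int]] = []
    for frame in range(3):
        first_start: int | None = None  # 0-based codon start
        has_n = False
        for pos in range(frame, n - 2, 3):
            codon = seq[pos : pos + 3]
            if codon in STOP_CODONS:
                if first_start is not None:
                    length = pos + 3 - first_start
                    if length > min_len_nt and not has_n:
                        orfs.append((first_start + 1, pos + 3))
                first_start = None
                has_n = False
            elif first_start is None:
                if codon in START_CODONS:
                    first_start = pos
                    has_n = "N" in codon
            elif "N" in codon:
                has_n = True
    return orfs


def find_orfs(
    dna: str, min_len_nt: int = 60, circular: bool = False
) -> list[tuple[int, int, str]]:
    """Enumerate maximal ORFs longer than ``min_len_nt`` on both strands.

    Returns (start, end, strand) triples in forward-strand coordinates,
    1-based inclusive, sorted by start ('+' before '-' on ties). The
    length cut is strict: an ORF of exactly ``min_len_nt`` nucleotides is
    rejected. With ``circular=True`` ORFs spanning the origin are also
    reported; their ``end`` exceeds the sequence length and should be read
    modulo the length.
    """
    dna = _check_nucleotides(dna)
    if min_len_nt < 3:
        raise ValueError("min_len_nt must be >= 3")
    L = len(dna)
    results: list[tuple[int, int, str]] = []
    for s, e in _scan_strand(dna, min_len_nt):
        results.append((s, e, "+"))
    rc = reverse_complement(dna)
    for s, e in _scan_strand(rc, min_len_nt):
        results.append((L - e + 1, L - s + 1, "-"))
    if circular and L >= 6:
        doubled = dna + dna
        for s, e in _scan_strand(doubled, min_len_nt):
            if s <= L < e and e - s + 1 <= L:
                results.append((s, e, "+"))
        rc2 = reverse_complement(doubled)
        L2 = 2 * L
        for s, e in _scan_strand(rc2, min_len_nt):
            fs, fe = L2 - e + 1, L2 - s + 1
            if fs <= L < fe and fe - fs + 1 <= L:
                results.append((fs, fe, "-"))
    results.sort(key=lambda t: (t[0], 0 if t[2] == "+" else 1, t[1]))
    return results


def assign_locus_tags(
    orfs: Sequence[tuple[int, int, str]],
    prefix: str,
    genome_id: str | None = None,
) -> list[GeneRecord]:
    """Name ORFs ``<prefix>_0001``… in start order, category ``NEW``.

    Tags are zero-padded to four digits (e.g. CALS8_0355); with more than
    9,999 ORFs the width grows to five digits and a warning is issued.
    """
    ordered = sorted(orfs, key=lambda t: (t[0], 0 if t[2] == "+" else 1, t[1]))
    width = 4
    if len(ordered) > 9999:
        width = 5
        warnings.warn(
            f"{len(ordered)} ORFs exceed 9999; widening locus tags to 5 digits",
            stacklevel=2,
        )
    gid = genome_id or prefix
    return [
        GeneRecord(
            locus_tag=f"{prefix}_{i:0{width}d}",
            genome_id=gid,
            start=s,
            end=e,
            strand=strand,
            product="hypothetical protein",
            category=Category.NEW,
        )
        for i, (s, e, strand) in enumerate(ordered, start=1)
    ]


def census(annotation: GenomeAnnotation | Iterable[GeneRecord]) -> CategoryCensus:
    """Tally genes per category; counts partition the gene list."""
    genes = (
        annotation.genes
        if isinstance(annotation, GenomeAnnotation)
        else list(annotation)
    )
    counts = {c.value: 0 for c in Category}
    for g in genes:
        counts[g.category.value] += 1
    return CategoryCensus(counts=counts)


def gc_content(dna: str) -> float:
    """(G+C) / (A+C+G+T); N is excluded from the denominator."""
    dna = _check_nucleotides(dna)
    if not dna:
        raise ValueError("empty sequence")
    gc = dna.count("G") + dna.count("C")
    denom = gc + dna.count("A") + dna.count("T")
    if denom == 0:
        raise ValueError("no unambiguous bases; GC content undefined")
    return gc / denom
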