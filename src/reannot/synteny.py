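"""Synteny-group detection and genomic-context association scoring.

Synteny groups are maximal chains of ortholog pairs whose gene indices
progress monotonically on both genomes (uniformly reversed chains capture
inverted blocks), with at most ``max_gap`` intervening genes between
consecutive pairs on either genome.

Context association between two gene families combines two evidence
channels — conserved neighborhood (co-localised, co-oriented members) and
phylogenetic co-occurrence (Jaccard of presence profiles) — with the noisy-or
combination 1 − ∏(1 − s_i). An association is accepted when the combined
confidence strictly exceeds the threshold (default 0.4, "medium confidence").
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import prod
from typing import Mapping, Sequence

__all__ = [
    "SyntenyGroup",
    "GenomeContext",
    "PhyloProfile",
    "AssociationScore",
    "build_synteny_groups",
    "synteny_membership",
    "neighborhood_score",
    "cooccurrence_score",
    "combine_scores",
    "associate_unknowns",
]


@dataclass(frozen=True)
class SyntenyGroup:
    group_id: int
    genome_a: str
    genome_b: str
    pairs: tuple[tuple[str, str], ...]
    span_a: tuple[int, int]
    span_b: tuple[int, int]
    orientation: int  # +1 collinear, -1 inverted, 0 singleton

    @property
    def singleton(self) -> bool:
        return len(self.pairs) == 1


def build_synteny_groups(
    pairs: Sequence[tuple[str, str]],
    order_a: Mapping[str, int],
    order_b: Mapping[str, int],
    max_gap: int = 5,
    genome_a: str = "A",
    genome_b: str = "B",
) -> list[SyntenyGroup]:
    """Chain ortholog pairs into maximal collinear (or uniformly inverted) runs.

    ``order_a``/``order_b`` map locus tags to 0-based gene indices along each
    genome. Consecutive chained pairs may skip at most ``max_gap`` genes on
    both genomes. Singleton chains are returned too (flagged via
    ``SyntenyGroup.singleton``).
    """
    if max_gap < 0:
        raise ValueError("max_gap must be >= 0")
    for a, b in pairs:
        if a not in order_a:
            raise KeyError(f"gene {a!r} missing from genome-A order map")
        if b not in order_b:
            raise KeyError(f"gene {b!r} missing from genome-B order map")
    indexed = sorted(((order_a[a], order_b[b], a, b) for a, b in pairs))
    groups: list[SyntenyGroup] = []
    chain: list[tuple[int, int, str, str]] = []
    direction = 0

    def flush() -> None:
        nonlocal chain, direction
        if not chain:
            return
        ia = [c[0] for c in chain]
        ib = [c[1] for c in chain]
        groups.append(
            SyntenyGroup(
                group_id=len(groups),
                genome_a=genome_a,
                genome_b=genome_b,
                pairs=tuple((c[2], c[3]) for c in chain),
                span_a=(min(ia), max(ia)),
                span_b=(min(ib), max(ib)),
                orientation=direction if len(chain) > 1 else 0,
            )
        )
        chain = []
        direction = 0

    for entry in indexed:
        if not chain:
            chain.append(entry)
            continue
        pa, pb = chain[-1][0], chain[-1][1]
        ia, ib = entry[0], entry[1]
        gap_a = ia - pa - 1
        step_b = ib - pb
        gap_b = abs(step_b) - 1
        new_dir = 1 if step_b > 0 else -1 if step_b < 0 else 0
        compatible = (
            0 <= gap_a <= max_gap
            and gap_b <= max_gap
            and new_dir != 0
            and (direction == 0 or new_dir == direction)
        )
        if compatible:
            chain.append(entry)
            direction = new_dir
        else:
            flush()
            chain.append(entry)
    flush()
    return groups


def synteny_membership(groups: Sequence[SyntenyGroup]) -> dict[str, int]:
    """Map every gene (both genomes) to its synteny group id."""
    out: dict[str, int] = {}
    for g in groups:
        for a, b in g.pairs:
            out[a] = g.group_id
            out[b] = g.group_id
    return out


@dataclass(frozen=True)
class GenomeContext:
    """One genome's gene order, strands, and gene→family mapping."""

    genome_id: str
    order: Mapping[str, int]  # locus -> index
    strand: Mapping[str, str]  # locus -> '+'/'-'
    family_of: Mapping[str, str]  # locus -> family id

    def members(self, family: str) -> list[str]:
        return sorted(g for g, f in self.family_of.items() if f == family)


@dataclass(frozen=True)
class PhyloProfile:
    """Presence/absence of a gene family across an ordered genome list."""

    family_id: str
    presence: tuple[bool, ...]


@dataclass(frozen=True)
class AssociationScore:
    gene_a: str
    gene_b: str
    neighborhood: float
    cooccurrence: float
    combined: float
    passes_threshold: bool


def neighborhood_score(
    family_a: str,
    family_b: str,
    genomes: Sequence[GenomeContext],
    max_dist: int = 3,
) -> float:
    """Fraction of co-hosting genomes where the families sit within
    ``max_dist`` gene indices on the same strand.

    Genomes lacking either family do not enter the denominator; with no
    co-hosting genome at all the score is 0 (no evidence).
    """
    hosting = 0
    close = 0
    for g in genomes:
        mem_a = g.members(family_a)
        mem_b = g.members(family_b)
        if not mem_a or not mem_b:
            continue
        hosting += 1
        if any(
            abs(g.order[x] - g.order[y]) <= max_dist and g.strand[x] == g.strand[y]
            for x in mem_a
            for y in mem_b
        ):
            close += 1
    return close / hosting if hosting else 0.0


def cooccurrence_score(pa: PhyloProfile, pb: PhyloProfile) -> float:
    """Jaccard similarity of the two presence sets; 0 when both are empty."""
    if len(pa.presence) != len(pb.presence):
        raise ValueError(
            f"profile length mismatch: {len(pa.presence)} vs {len(pb.presence)}"
        )
    sa = {i for i, p in enumerate(pa.presence) if p}
    sb = {i for i, p in enumerate(pb.presence) if p}
    if not sa and not sb:
        return 0.0
    return len(sa & sb) / len(sa | sb)


def combine_scores(
    components: Sequence[float],
    threshold: float = 0.4,
    gene_a: str = "a",
    gene_b: str = "b",
) -> AssociationScore:
    """Noisy-or combination 1 − ∏(1 − s_i); passes iff strictly above threshold."""
    for s in components:
        if not 0.0 <= s <= 1.0:
            raise ValueError(f"component score {s} outside [0, 1]")
    combined = 1.0 - prod(1.0 - s for s in components)
    comp = list(components) + [0.0, 0.0]
    return AssociationScore(
        gene_a=gene_a,
        gene_b=gene_b,
        neighborhood=comp[0],
        cooccurrence=comp[1],
        combined=combined,
        passes_threshold=combined > threshold,
    )


def associate_unknowns(
    unknown_genes: Sequence[str],
    edges: Sequence[AssociationScore],
    labels: Mapping[str, str],
) -> dict[str, str | None]:
    """Predict a process label for each unknown gene by majority vote among
    labelled partners on passing edges; ties and isolated genes yield None."""
    adjacency: dict[str, list[str]] = {g: [] for g in unknown_genes}
    for e in edges:
        if not e.passes_threshold:
            continue
        for gene, partner in ((e.gene_a, e.gene_b), (e.gene_b, e.gene_a)):
            if gene in adjacency and partner in labels:
                adjacency[gene].append(labels[partner])
    out: dict[str, str | None] = {}
    for gene, partner_labels in adjacency.items():
        if not partner_labels:
            out[gene] = None
            continue
        freq: dict[str, int] = {}
        for lab in partner_labels:
            freq[lab] = freq.get(lab, 0) + 1
        top = max(freq.values())
        winners = [lab for lab, n in freq.items() if n == top]
        out[gene] = winners[0] if len(winners) == 1 else None
    return out
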