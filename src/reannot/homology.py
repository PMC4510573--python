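"""Protein homology: local alignment, minLrap/maxLrap coverage, BBH orthology,
core-genome and essential-gene detection, and best-hit-count COG assignment.

Alignment-length ratios summarise how much of each protein a local alignment
covers::

    minLrap = Lmatch / min(Lprot1, Lprot2)
    maxLrap = Lmatch / max(Lprot1, Lprot2)

with the three interpretive cases: minLrap = 1 and maxLrap = 1 means both
proteins align over their whole length (FULL); minLrap = 1 and maxLrap < 1
means one protein is longer or the alignment is partial (PARTIAL);
minLrap < 1 and maxLrap < 1 means the sequences align poorly (POOR).

A bidirectional best hit (BBH) joins two genes, one per genome, that are
each other's best-scoring hit — the standard working proxy for orthology.
COG membership follows the best-hit-counting rule: a protein is assigned to
a COG when at least ``bet_cutoff`` (default 3) of its genome-specific best
hits (BeTs) in labelled reference proteomes belong to that COG.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Sequence

from Bio import Align
from Bio.Align import substitution_matrices

__all__ = [
    "Scoring",
    "AlignmentResult",
    "AlignClass",
    "LrapMetrics",
    "OrthologPair",
    "OrthologTable",
    "EssentialReference",
    "local_align",
    "lrap",
    "best_hit",
    "bbh",
    "homolog_pairs",
    "core_genome",
    "essential_genes",
    "cognitor_assign",
    "cog_census",
    "CogCensus",
]

Proteome = Mapping[str, str]  # locus tag -> protein sequence


@dataclass(frozen=True)
class Scoring:
    """Substitution matrix plus linear gap penalty for local alignment."""

    matrix: str = "BLOSUM62"
    gap: float = -8.0
    # Lmatch convention: count all alignment columns including gap columns
    # (set False to count aligned residue pairs only).
    count_gap_columns: bool = True

    def make_aligner(self) -> Align.PairwiseAligner:
        aligner = Align.PairwiseAligner(
            mode="local", open_gap_score=self.gap, extend_gap_score=self.gap
        )
        aligner.substitution_matrix = substitution_matrices.load(self.matrix)
        return aligner


DEFAULT_SCORING = Scoring()


@dataclass(frozen=True)
class AlignmentResult:
    query_id: str
    subject_id: str
    raw_score: float
    Lmatch: int
    identity_pct: float
    query_len: int
    subject_len: int


class AlignClass(str, Enum):
    FULL = "FULL"
    PARTIAL = "PARTIAL"
    POOR = "POOR"


@dataclass(frozen=True)
class LrapMetrics:
    minLrap: float
    maxLrap: float
    align_class: AlignClass


@dataclass(frozen=True)
class OrthologPair:
    a_id: str
    b_id: str
    alignment: AlignmentResult
    metrics: LrapMetrics


@dataclass(frozen=True)
class OrthologTable:
    genome_a: str
    genome_b: str
    pairs: tuple[OrthologPair, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        a_ids = [p.a_id for p in self.pairs]
        b_ids = [p.b_id for p in self.pairs]
        if len(a_ids) != len(set(a_ids)) or len(b_ids) != len(set(b_ids)):
            raise ValueError("a gene may appear in at most one BBH pair")

    def a_to_b(self) -> dict[str, str]:
        return {p.a_id: p.b_id for p in self.pairs}


@dataclass(frozen=True)
class EssentialReference:
    """A curated minimal gene set used as the essential-gene reference."""

    proteins: Mapping[str, str]  # id -> protein sequence
    source_tag: str = "minimal-gene-set"
    species: Mapping[str, str] = field(default_factory=dict)  # id -> species

    def __post_init__(self) -> None:
        if not self.proteins:
            raise ValueError("essential reference must be non-empty")


def _aligner_for(scoring: Scoring) -> Align.PairwiseAligner:
    return scoring.make_aligner()


def local_align(
    a: str,
    b: str,
    scoring: Scoring = DEFAULT_SCORING,
    query_id: str = "query",
    subject_id: str = "subject",
    aligner: Align.PairwiseAligner | None = None,
) -> AlignmentResult:
    """Optimal Smith–Waterman local alignment of two proteins.

    Lmatch counts alignment columns (including gap columns by default);
    identity is the fraction of identical aligned columns. A pair with no
    positive-scoring alignment yields Lmatch 0 and score 0.
    """
    if not a or not b:
        raise ValueError("cannot align an empty sequence")
    if aligner is None:
        aligner = _aligner_for(scoring)
    alignments = aligner.align(a.upper(), b.upper())
    if len(alignments) == 0 or alignments.score <= 0:
        return AlignmentResult(query_id, subject_id, 0.0, 0, 0.0, len(a), len(b))
    aln = alignments[0]
    counts = aln.counts()
    lmatch = aln.length if scoring.count_gap_columns else counts.aligned
    identity = 100.0 * counts.identities / lmatch if lmatch else 0.0
    return AlignmentResult(
        query_id, subject_id, float(aln.score), int(lmatch), identity, len(a), len(b)
    )


def lrap(aln: AlignmentResult) -> LrapMetrics:
    """minLrap/maxLrap coverage ratios and the three-way alignment class."""
    if aln.query_len <= 0 or aln.subject_len <= 0:
        raise ValueError("protein lengths must be positive")
    min_lrap = aln.Lmatch / min(aln.query_len, aln.subject_len)
    max_lrap = aln.Lmatch / max(aln.query_len, aln.subject_len)
    if min_lrap >= 1.0 and max_lrap >= 1.0:
        cls = AlignClass.FULL
    elif min_lrap >= 1.0:
        cls = AlignClass.PARTIAL
    else:
        cls = AlignClass.POOR
    return LrapMetrics(min_lrap, max_lrap, cls)


def _score_row(
    aligner: Align.PairwiseAligner, query: str, targets: Sequence[tuple[str, str]]
) -> list[float]:
    return [aligner.score(query, seq) for _, seq in targets]


def best_hit(
    query_seq: str,
    targets: Proteome,
    scoring: Scoring = DEFAULT_SCORING,
    query_id: str = "query",
    aligner: Align.PairwiseAligner | None = None,
) -> AlignmentResult | None:
    """The genome-specific best hit (BeT) of a query in one proteome.

    Ties on raw score are broken by higher identity, then by lexicographic
    subject id; returns None when no target scores above zero.
    """
    if not targets:
        raise ValueError("target proteome is empty")
    if aligner is None:
        aligner = _aligner_for(scoring)
    items = sorted(targets.items())
    scores = _score_row(aligner, query_seq.upper(), items)
    best_score = max(scores)
    if best_score <= 0:
        return None
    tied = [items[i] for i, s in enumerate(scores) if s == best_score]
    results = [
        local_align(query_seq, seq, scoring, query_id, sid, aligner=aligner)
        for sid, seq in tied
    ]
    results.sort(key=lambda r: (-r.identity_pct, r.subject_id))
    return results[0]


def bbh(
    genome_a: Proteome,
    genome_b: Proteome,
    scoring: Scoring = DEFAULT_SCORING,
    genome_a_id: str = "A",
    genome_b_id: str = "B",
) -> OrthologTable:
    """Bidirectional best hits between two proteomes."""
    if not genome_a or not genome_b:
        raise ValueError("both proteomes must be non-empty")
    aligner = _aligner_for(scoring)
    best_ab: dict[str, AlignmentResult] = {}
    for aid, aseq in sorted(genome_a.items()):
        hit = best_hit(aseq, genome_b, scoring, aid, aligner=aligner)
        if hit is not None:
            best_ab[aid] = hit
    best_ba: dict[str, str] = {}
    for bid, bseq in sorted(genome_b.items()):
        hit = best_hit(bseq, genome_a, scoring, bid, aligner=aligner)
        if hit is not None:
            best_ba[bid] = hit.subject_id
    pairs = []
    for aid, hit in sorted(best_ab.items()):
        bid = hit.subject_id
        if best_ba.get(bid) == aid:
            pairs.append(OrthologPair(aid, bid, hit, lrap(hit)))
    return OrthologTable(genome_a_id, genome_b_id, tuple(pairs))


def homolog_pairs(
    genome_a: Proteome,
    genome_b: Proteome,
    min_minlrap: float = 0.8,
    min_identity: float = 30.0,
    scoring: Scoring = DEFAULT_SCORING,
    genome_a_id: str = "A",
    genome_b_id: str = "B",
    table: OrthologTable | None = None,
) -> OrthologTable:
    """BBH pairs passing the homology constraints minLrap > 0.8 and identity > 30%.

    Both thresholds are strict; a precomputed BBH table may be supplied to
    avoid re-alignment.
    """
    if table is None:
        table = bbh(genome_a, genome_b, scoring, genome_a_id, genome_b_id)
    kept = tuple(
        p
        for p in table.pairs
        if p.metrics.minLrap > min_minlrap and p.alignment.identity_pct > min_identity
    )
    return OrthologTable(table.genome_a, table.genome_b, kept)


def core_genome(
    pivot: Proteome,
    others: Sequence[Proteome],
    min_minlrap: float = 0.8,
    min_identity: float = 30.0,
    scoring: Scoring = DEFAULT_SCORING,
) -> tuple[set[str], set[str]]:
    """Split pivot genes into core (homolog in every other genome) and
    genome-specific (homolog in none)."""
    if not others:
        raise ValueError("need at least one comparison genome")
    hit_counts = {gid: 0 for gid in pivot}
    for other in others:
        table = homolog_pairs(pivot, other, min_minlrap, min_identity, scoring)
        for p in table.pairs:
            hit_counts[p.a_id] += 1
    n = len(others)
    core = {g for g, c in hit_counts.items() if c == n}
    specific = {g for g, c in hit_counts.items() if c == 0}
    return core, specific


def essential_genes(
    genome: Proteome,
    reference: EssentialReference,
    synteny_groups: Mapping[str, object] | None = None,
    min_minlrap: float = 0.5,
    scoring: Scoring = DEFAULT_SCORING,
) -> tuple[set[str], set[str]]:
    """Partition reference essential genes into (found, missing).

    A reference gene is found when some genome gene shares a BBH with it at
    minLrap > 0.5, or when a genome gene belongs to the same synteny group
    (``synteny_groups`` maps gene ids of either side to group ids; an empty
    map reduces the criterion to pure BBH + minLrap).
    """
    groups = synteny_groups or {}
    table = bbh(genome, dict(reference.proteins), scoring, "genome", reference.source_tag)
    found: set[str] = set()
    for p in table.pairs:
        if p.metrics.minLrap > min_minlrap:
            found.add(p.b_id)
    if groups:
        genome_groups = {groups[g] for g in genome if g in groups}
        for rid in reference.proteins:
            if rid in groups and groups[rid] in genome_groups:
                found.add(rid)
    missing = set(reference.proteins) - found
    return found, missing


@dataclass(frozen=True)
class CogReferenceGenome:
    """A COG-labelled reference proteome."""

    genome_id: str
    proteins: Mapping[str, str]
    cog_labels: Mapping[str, frozenset[str]]  # protein id -> COG ids


def cognitor_assign(
    protein: str,
    cog_reference: Sequence[CogReferenceGenome],
    scoring: Scoring = DEFAULT_SCORING,
    bet_cutoff: int = 3,
) -> set[str]:
    """Assign COG membership by counting genome-specific best hits (BeTs).

    The protein joins every COG supported by BeTs from at least
    ``bet_cutoff`` distinct reference genomes.
    """
    if len(cog_reference) < bet_cutoff:
        raise ValueError(
            f"need at least bet_cutoff={bet_cutoff} reference genomes, "
            f"got {len(cog_reference)}"
        )
    aligner = _aligner_for(scoring)
    support: dict[str, int] = {}
    for ref in cog_reference:
        hit = best_hit(protein, ref.proteins, scoring, aligner=aligner)
        if hit is None:
            continue
        for cog in ref.cog_labels.get(hit.subject_id, frozenset()):
            support[cog] = support.get(cog, 0) + 1
    return {cog for cog, n in support.items() if n >= bet_cutoff}


@dataclass(frozen=True)
class CogCensus:
    """Per-functional-category gene counts with an old/new CDS split."""

    per_category: Mapping[str, tuple[int, int]]  # letter -> (old, new)
    classified: int
    unclassified: int

    def combined(self, letter: str) -> int:
        old, new = self.per_category.get(letter, (0, 0))
        return old + new


def cog_census(
    assignments: Mapping[str, Iterable[str]],
    cog_categories: Mapping[str, str],
    is_new: Mapping[str, bool] | None = None,
) -> CogCensus:
    """Tally genes per COG functional category letter, split old/new CDSs.

    A gene contributes once to each distinct category letter among its COGs;
    ``classified`` counts genes with at least one COG. An assigned COG id
    missing from the category map is an error naming the id.
    """
    is_new = is_new or {}
    per_cat: dict[str, list[int]] = {}
    classified = 0
    for gene, cogs in assignments.items():
        cogs = set(cogs)
        if not cogs:
            continue
        classified += 1
        letters = set()
        for cog in cogs:
            if cog not in cog_categories:
                raise KeyError(f"COG id {cog!r} has no functional category")
            letters.update(cog_categories[cog])
        slot = 1 if is_new.get(gene, False) else 0
        for letter in letters:
            per_cat.setdefault(letter, [0, 0])[slot] += 1
    return CogCensus(
        per_category={k: (v[0], v[1]) for k, v in sorted(per_cat.items())},
        classified=classified,
        unclassified=len(assignments) - classified,
    )
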