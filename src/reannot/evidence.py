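"""Evidence filtering, consensus function calls and category reclassification.

Each CDS accumulates hits from up to five annotation sources (PSI-BLAST,
BLASTO, Pfam, InterProScan, ANNIE). After source-specific filtering, the
sources vote: the confidence level of a consensus call is the number of
independent sources agreeing on the function ("k/5"). Integrated sources
(InterProScan, ANNIE) can re-report a member database's signature; such hits
are de-duplicated so a Pfam domain seen twice does not count as two votes.

Agreement between free-text descriptions is operationalised as Jaccard
similarity of normalised token sets (lower-cased, punctuation-stripped,
generic words removed) at a configurable threshold, default 0.6.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from enum import Enum
from itertools import combinations
from typing import Iterable, Sequence

from .genome import Category, CategoryCensus, GeneRecord

__all__ = [
    "Source",
    "CallClass",
    "EvidenceRecord",
    "FunctionCall",
    "filter_psiblast",
    "filter_pfam",
    "normalize_description",
    "jaccard",
    "dedupe_sources",
    "assign_confidence",
    "reclassify",
    "update_census",
    "PSIBLAST_MIN_IDENTITY",
    "PSIBLAST_MAX_EVALUE",
    "PFAM_MAX_EVALUE",
]

# Best-hit filters used for the alignment and domain sources.
PSIBLAST_MIN_IDENTITY = 40.0  # strict >
PSIBLAST_MAX_EVALUE = 1e-52  # strict <
PFAM_MAX_EVALUE = 1e-02  # inclusive <=

STOPWORDS = frozenset(
    {
        "protein",
        "domain",
        "containing",
        "family",
        "putative",
        "probable",
        "like",
        # uninformative product names carry no functional signal either
        "hypothetical",
        "uncharacterized",
        "unknown",
        "conserved",
    }
)
_PUTATIVE_MARKERS = ("putative", "probable")
_TOKEN_RE = re.compile(r"[a-z0-9]+")


class Source(str, Enum):
    PSI_BLAST = "PSI_BLAST"
    BLASTO = "BLASTO"
    PFAM = "PFAM"
    INTERPROSCAN = "INTERPROSCAN"
    ANNIE = "ANNIE"


# Sources that wrap other methods and may re-emit their signatures.
INTEGRATED_SOURCES = frozenset({Source.INTERPROSCAN, Source.ANNIE})
# Sources whose evidence is motif/domain-level rather than full-length similarity.
MOTIF_SOURCES = frozenset({Source.PFAM, Source.INTERPROSCAN})


class CallClass(str, Enum):
    DEFINED = "DEFINED"
    PUTATIVE = "PUTATIVE"
    NONE = "NONE"


@dataclass(frozen=True)
class EvidenceRecord:
    """One tool hit for one CDS."""

    cds_id: str
    source: Source
    description: str
    e_value: float | None = None
    identity_pct: float | None = None
    member_database: str = ""
    score: float | None = None

    def __post_init__(self) -> None:
        if self.member_database and self.source not in INTEGRATED_SOURCES:
            raise ValueError(
                f"{self.cds_id}: member_database only valid for integrated "
                f"sources, not {self.source.value}"
            )
        if self.e_value is not None and self.e_value < 0:
            raise ValueError(f"{self.cds_id}: negative e-value")
        if self.identity_pct is not None and not 0 <= self.identity_pct <= 100:
            raise ValueError(f"{self.cds_id}: identity_pct outside [0, 100]")


@dataclass(frozen=True)
class FunctionCall:
    """Consensus function for one CDS with its k/5 confidence."""

    cds_id: str
    consensus_description: str = ""
    confidence: int = 0
    supporting_sources: frozenset[Source] = field(default_factory=frozenset)
    call_class: CallClass = CallClass.NONE

    def __post_init__(self) -> None:
        if self.call_class is CallClass.NONE and (
            self.confidence != 0 or self.consensus_description
        ):
            raise ValueError(f"{self.cds_id}: NONE call must be empty")

    @property
    def confidence_label(self) -> str:
        return f"{self.confidence}/5"


def _has_values(rec: EvidenceRecord, need_identity: bool) -> bool:
    if rec.e_value is None or (need_identity and rec.identity_pct is None):
        warnings.warn(
            f"{rec.cds_id}: {rec.source.value} hit missing e-value/identity; skipped",
            stacklevel=3,
        )
        return False
    return True


def filter_psiblast(
    hits: Iterable[EvidenceRecord],
    min_identity: float = PSIBLAST_MIN_IDENTITY,
    max_evalue: float = PSIBLAST_MAX_EVALUE,
) -> list[EvidenceRecord]:
    """Keep hits with identity strictly above 40% and e-value strictly below 1e-52."""
    out = []
    for h in hits:
        if h.source is not Source.PSI_BLAST:
            raise ValueError(f"{h.cds_id}: expected PSI_BLAST hit, got {h.source}")
        if not _has_values(h, need_identity=True):
            continue
        if h.identity_pct > min_identity and h.e_value < max_evalue:
            out.append(h)
    return out


def filter_pfam(
    hits: Iterable[EvidenceRecord], max_evalue: float = PFAM_MAX_EVALUE
) -> list[EvidenceRecord]:
    """Keep Pfam-A hits with e-value at most 1e-02 (inclusive)."""
    out = []
    for h in hits:
        if h.source is not Source.PFAM:
            raise ValueError(f"{h.cds_id}: expected PFAM hit, got {h.source}")
        if not _has_values(h, need_identity=False):
            continue
        if h.e_value <= max_evalue:
            out.append(h)
    return out


def normalize_description(text: str) -> frozenset[str]:
    """Canonical token set: lower-case, punctuation-free, generic words dropped."""
    tokens = _TOKEN_RE.findall(text.lower())
    return frozenset(t for t in tokens if t not in STOPWORDS)


def jaccard(a: frozenset[str], b: frozenset[str]) -> float:
    """Token-set Jaccard similarity; empty-vs-empty counts as 0 (uninformative)."""
    if not a or not b:
        return 0.0
    return len(a & b) / len(a | b)


def _equivalent(a: str, b: str, threshold: float) -> bool:
    return jaccard(normalize_description(a), normalize_description(b)) >= threshold


def dedupe_sources(
    evidence: Sequence[EvidenceRecord], agree_threshold: float = 0.6
) -> list[tuple[Source, str]]:
    """Collapse evidence for one CDS to at most one vote per independent method.

    An InterProScan or ANNIE record whose ``member_database`` names a source
    that already votes with an equivalent description adds no vote. Within a
    source, the lowest e-value record speaks for it.
    """
    ids = {e.cds_id for e in evidence}
    if len(ids) > 1:
        raise ValueError(f"evidence spans multiple CDSs: {sorted(ids)}")

    def rank(e: EvidenceRecord) -> tuple:
        return (e.e_value if e.e_value is not None else float("inf"), e.description)

    direct: dict[Source, EvidenceRecord] = {}
    integrated: list[EvidenceRecord] = []
    for e in sorted(evidence, key=rank):
        if e.source in INTEGRATED_SOURCES:
            integrated.append(e)
        elif e.source not in direct:
            direct[e.source] = e

    votes: dict[Source, str] = {s: e.description for s, e in direct.items()}
    for e in integrated:
        member = e.member_database.strip().upper().replace("-", "_")
        try:
            wrapped = Source(member) if member else None
        except ValueError:
            wrapped = None
        if (
            wrapped is not None
            and wrapped in votes
            and _equivalent(votes[wrapped], e.description, agree_threshold)
        ):
            continue  # intrinsic overlap: same underlying method, same call
        if e.source not in votes:
            votes[e.source] = e.description
    order = list(Source)
    return sorted(votes.items(), key=lambda sv: order.index(sv[0]))


def assign_confidence(
    evidence: Sequence[EvidenceRecord],
    agree_threshold: float = 0.6,
    cds_id: str | None = None,
) -> FunctionCall:
    """Vote a consensus function; confidence = size of the largest agreeing clique.

    Votes (one per independent method) are clustered by pairwise token-set
    Jaccard >= ``agree_threshold``; with at most five votes the largest
    mutually-agreeing subset is found exactly by subset enumeration. The
    consensus description is the most frequent raw description in that
    subset (ties broken lexicographically).
    """
    if not evidence and cds_id is None:
        raise ValueError("empty evidence requires an explicit cds_id")
    cid = cds_id if cds_id is not None else evidence[0].cds_id
    votes = dedupe_sources(evidence, agree_threshold) if evidence else []
    informative = [
        (s, d, normalize_description(d)) for s, d in votes if normalize_description(d)
    ]
    if not informative:
        return FunctionCall(cds_id=cid)

    n = len(informative)
    best: tuple[int, tuple[int, ...]] | None = None
    for size in range(n, 0, -1):
        for combo in combinations(range(n), size):
            ok = all(
                jaccard(informative[i][2], informative[j][2]) >= agree_threshold
                for i, j in combinations(combo, 2)
            )
            if ok:
                cand = (size, combo)
                if best is None or cand[0] > best[0]:
                    best = cand
                break  # combinations() is lexicographic; first hit is canonical
        if best is not None:
            break
    assert best is not None
    cluster = [informative[i] for i in best[1]]
    descriptions = sorted(d for _, d, _ in cluster)
    freq: dict[str, int] = {}
    for d in descriptions:
        freq[d] = freq.get(d, 0) + 1
    top = max(freq.values())
    consensus = min(d for d, c in freq.items() if c == top)
    sources = frozenset(s for s, _, _ in cluster)

    if any(m in consensus.lower() for m in _PUTATIVE_MARKERS) or sources <= MOTIF_SOURCES:
        call_class = CallClass.PUTATIVE
    else:
        call_class = CallClass.DEFINED
    return FunctionCall(
        cds_id=cid,
        consensus_description=consensus,
        confidence=len(cluster),
        supporting_sources=sources,
        call_class=call_class,
    )


def reclassify(
    record: GeneRecord, call: FunctionCall, min_conf_known: int = 2
) -> GeneRecord:
    """Apply a consensus call to a gene's category.

    Hypothetical, new and putative genes gain ``KNOWN`` status when a DEFINED
    call is supported by at least ``min_conf_known`` independent methods;
    weaker DEFINED calls and PUTATIVE calls yield ``PUTATIVE`` with the
    product prefixed "putative ". Known genes are never demoted and
    pseudogenes are never reclassified.
    """
    if not 1 <= min_conf_known <= 5:
        raise ValueError("min_conf_known must be in 1..5")
    if record.category is Category.PSEUDOGENE or call.call_class is CallClass.NONE:
        return record
    if record.category is Category.KNOWN:
        if call.call_class is CallClass.DEFINED:
            return record.with_call(
                Category.KNOWN, call.consensus_description, call.confidence
            )
        return record
    if call.call_class is CallClass.DEFINED and call.confidence >= min_conf_known:
        return record.with_call(
            Category.KNOWN, call.consensus_description, call.confidence
        )
    product = call.consensus_description
    if not product.lower().startswith("putative"):
        product = f"putative {product}"
    return record.with_call(Category.PUTATIVE, product, call.confidence)


def update_census(
    before: CategoryCensus, moves: Sequence[tuple[str, str, int]]
) -> CategoryCensus:
    """Replay category reassignments; the total is conserved.

    Each move is ``(from_category, to_category, count)``; drawing more genes
    from a category than it currently holds is a contract violation.
    """
    counts = {str(k): int(v) for k, v in before.counts.items()}
    for src, dst, n in moves:
        src, dst = str(src), str(dst)
        if n < 0:
            raise ValueError(f"negative move count {n} ({src} -> {dst})")
        have = counts.get(src, 0)
        if n > have:
            raise ValueError(
                f"cannot move {n} genes from {src}: only {have} present"
            )
        counts[src] = have - n
        counts[dst] = counts.get(dst, 0) + n
    return CategoryCensus(counts=counts)
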