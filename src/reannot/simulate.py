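"""Synthetic genome families with known ground truth.

The generator emulates, at desk scale, the inputs of a whole-genome
re-annotation study of a thermophilic bacterium compared against its close
relatives: a pivot proteome whose genes carry curation categories, a family
of related genomes derived from a common ancestral gene set by per-branch
substitution, duplication, loss and block inversion, a curated essential-gene
reference, per-source function-evidence tables with planted correctness
rates, and binary-truth/ordinal-rating evaluation cases.

Every sub-generator draws from its own child of a single seed sequence, so
outputs are reproducible bit-for-bit under a fixed seed and enlarging one
component does not perturb the others.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .evidence import EvidenceRecord, Source
from .genome import Category
from .homology import EssentialReference
from .roc import RatingCase

__all__ = [
    "SourceParams",
    "RatingModel",
    "SimulationConfig",
    "GroundTruth",
    "GenomeFamily",
    "simulate_genome_family",
    "simulate_evidence",
    "simulate_rating_cases",
    "expected_auc",
    "apply_inversion",
    "apply_translocation",
]

AA = "ACDEFGHIKLMNPQRSTVWY"

# Category mix of the emulated proteome (known / hypothetical / putative /
# new / pseudogene), matching a typical re-annotated bacterial chromosome.
CATEGORY_WEIGHTS = {
    Category.KNOWN: 1854,
    Category.HYPOTHETICAL: 781,
    Category.PUTATIVE: 47,
    Category.NEW: 231,
    Category.PSEUDOGENE: 104,
}

_TRUE_NOUNS = [
    "ABC transporter ATP-binding",
    "glycoside hydrolase",
    "iron-sulfur oxidoreductase",
    "two-component sensor kinase",
    "ribosomal subunit assembly factor",
    "sugar phosphotransferase",
    "ferredoxin hydrogenase",
    "peptidoglycan synthase",
    "transcriptional regulator",
    "tRNA modification enzyme",
]
_DECOY_NOUNS = [
    "flagellar export chaperone",
    "nitrate reductase accessory",
    "capsule export translocase",
    "phage tail fiber",
    "sporulation sigma factor",
]


@dataclass(frozen=True)
class SourceParams:
    """Per-source evidence behaviour: correct / wrong / silent must sum to 1."""

    p_correct: float = 0.9
    p_wrong: float = 0.05
    p_nocall: float = 0.05
    # probability that an integrated source labels its hit with the wrapped
    # member database (creating an intrinsic overlap with that source's vote)
    p_overlap: float = 0.0

    def __post_init__(self) -> None:
        total = self.p_correct + self.p_wrong + self.p_nocall
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"p_correct + p_wrong + p_nocall must be 1, got {total}")
        for p in (self.p_correct, self.p_wrong, self.p_nocall, self.p_overlap):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")


@dataclass(frozen=True)
class RatingModel:
    """Rating distributions over the ordinal scale for each truth class."""

    scale: tuple[int, ...] = (2, 3, 4, 5)
    positive: tuple[float, ...] = (0.05, 0.10, 0.25, 0.60)
    negative: tuple[float, ...] = (0.60, 0.25, 0.10, 0.05)
    prevalence: float = 0.5

    def __post_init__(self) -> None:
        for dist in (self.positive, self.negative):
            if len(dist) != len(self.scale) or abs(sum(dist) - 1.0) > 1e-9:
                raise ValueError("rating distribution must match scale and sum to 1")


@dataclass(frozen=True)
class SimulationConfig:
    seed: int = 0
    n_genomes: int = 4
    genes_per_genome: int = 60
    mean_protein_len: int = 120
    substitution_rate: float = 0.05  # substitutions per site per branch
    duplication_prob: float = 0.0
    loss_prob: float = 0.08
    inversion_prob: float = 0.3
    pivot_private_fraction: float = 0.10
    essential_fraction: float = 0.15
    essential_missing: int = 0  # essential families deleted from the pivot
    sources: Mapping[Source, SourceParams] = field(
        default_factory=lambda: {s: SourceParams() for s in Source}
    )
    rating_model: RatingModel = field(default_factory=RatingModel)
    n_rating_cases: int = 500

    def __post_init__(self) -> None:
        if self.n_genomes < 2:
            raise ValueError("need at least two genomes")
        if self.genes_per_genome < 1:
            raise ValueError("need at least one gene family")
        if not 0.0 <= self.loss_prob < 1.0:
            raise ValueError("loss_prob must lie in [0, 1)")
        n_private = round(self.pivot_private_fraction * self.genes_per_genome)
        if self.essential_missing > self.genes_per_genome - n_private:
            raise ValueError("more missing essentials than shared families")

    def streams(self) -> dict[str, np.random.Generator]:
        ss = np.random.SeedSequence(self.seed)
        names = ["ancestral", "evolution", "evidence", "ratings", "labels"]
        return {
            n: np.random.default_rng(c) for n, c in zip(names, ss.spawn(len(names)))
        }


@dataclass
class GroundTruth:
    pivot: str
    family_of: dict[str, str]  # gene id -> family id
    function_label: dict[str, str]  # family id -> true product
    decoy_labels: list[str]
    category: dict[str, Category]  # pivot gene id -> category
    essential_families: set[str]
    essential_missing: set[str]
    presence: dict[str, set[str]]  # family id -> genomes carrying a copy
    ancestral_seqs: dict[str, str]

    def core_families(self, genome_ids: Sequence[str]) -> set[str]:
        all_g = set(genome_ids)
        return {f for f, p in self.presence.items() if p >= all_g}

    def specific_families(self) -> set[str]:
        return {f for f, p in self.presence.items() if p == {self.pivot}}

    def pivot_genes_of(self, families: set[str]) -> set[str]:
        return {g for g, f in self.family_of.items() if f in families and g.startswith(self.pivot)}

    def true_ortholog_pairs(
        self, orders_a: Sequence[tuple[str, str]], orders_b: Sequence[tuple[str, str]]
    ) -> list[tuple[str, str]]:
        """Single-copy family pairs between two genomes (gene_a, gene_b)."""
        by_fam_a: dict[str, list[str]] = {}
        for gene, _ in orders_a:
            by_fam_a.setdefault(self.family_of[gene], []).append(gene)
        by_fam_b: dict[str, list[str]] = {}
        for gene, _ in orders_b:
            by_fam_b.setdefault(self.family_of[gene], []).append(gene)
        pairs = []
        for fam, genes_a in by_fam_a.items():
            genes_b = by_fam_b.get(fam, [])
            if len(genes_a) == 1 and len(genes_b) == 1:
                pairs.append((genes_a[0], genes_b[0]))
        return sorted(pairs)


@dataclass
class GenomeFamily:
    config: SimulationConfig
    genome_ids: list[str]
    genomes: dict[str, dict[str, str]]  # genome -> gene id -> protein
    orders: dict[str, list[tuple[str, str]]]  # genome -> [(gene id, strand)]
    truth: GroundTruth

    @property
    def pivot(self) -> str:
        return self.truth.pivot

    def essential_reference(self) -> EssentialReference:
        species = [f"species_{i + 1}" for i in range(7)]
        proteins = {}
        labels = {}
        for i, fam in enumerate(sorted(self.truth.essential_families)):
            rid = f"ESS_{fam}"
            proteins[rid] = self.truth.ancestral_seqs[fam]
            labels[rid] = species[i % len(species)]
        return EssentialReference(
            proteins=proteins, source_tag="minimal-gene-set", species=labels
        )


def _random_protein(rng: np.random.Generator, mean_len: int) -> str:
    length = max(30, int(rng.poisson(mean_len)))
    body = rng.choice(list(AA), size=length - 1)
    return "M" + "".join(body)


def _mutate(rng: np.random.Generator, seq: str, rate: float) -> str:
    if rate <= 0:
        return seq
    chars = list(seq)
    hits = np.nonzero(rng.random(len(chars)) < rate)[0]
    for i in hits:
        choices = [a for a in AA if a != chars[i]]
        chars[i] = choices[rng.integers(len(choices))]
    return "".join(chars)


def apply_inversion(
    order: list[tuple[str, str]], start: int, end: int
) -> list[tuple[str, str]]:
    """Invert genes [start, end) in place order, flipping strands."""
    flipped = [(g, "-" if s == "+" else "+") for g, s in reversed(order[start:end])]
    return order[:start] + flipped + order[end:]


def apply_translocation(
    order: list[tuple[str, str]], start: int, end: int, dest: int
) -> list[tuple[str, str]]:
    """Move the block [start, end) so it begins at index ``dest`` of the remainder."""
    block = order[start:end]
    rest = order[:start] + order[end:]
    return rest[:dest] + block + rest[dest:]


def simulate_genome_family(config: SimulationConfig) -> GenomeFamily:
    """Evolve a star-topology genome family from a random ancestral proteome.

    Per non-pivot branch each family is lost with ``loss_prob`` and duplicated
    with ``duplication_prob``; every surviving copy accumulates i.i.d. residue
    substitutions at ``substitution_rate`` per site; with ``inversion_prob``
    a random gene block is inverted. A ``pivot_private_fraction`` of families
    exists only in the pivot. Deterministic under a fixed seed.
    """
    streams = config.streams()
    rng_anc = streams["ancestral"]
    rng_lab = streams["labels"]
    n_fam = config.genes_per_genome
    fams = [f"FAM{i:04d}" for i in range(n_fam)]
    anc_seqs = {f: _random_protein(rng_anc, config.mean_protein_len) for f in fams}
    anc_strand = {f: ("+" if rng_anc.random() < 0.5 else "-") for f in fams}

    labels = {
        f: f"{_TRUE_NOUNS[i % len(_TRUE_NOUNS)]} csx{i:04d}"
        for i, f in enumerate(fams)
    }
    decoys = [
        f"{_DECOY_NOUNS[i % len(_DECOY_NOUNS)]} dcy{i:04d}" for i in range(n_fam)
    ]

    n_private = round(config.pivot_private_fraction * n_fam)
    private = set(rng_lab.choice(fams, size=n_private, replace=False).tolist())

    shared = [f for f in fams if f not in private]
    n_ess = round(config.essential_fraction * n_fam)
    n_ess = min(n_ess, len(shared))
    essential = set(rng_lab.choice(shared, size=n_ess, replace=False).tolist())
    missing = set(
        sorted(essential)[: config.essential_missing]
    )  # deterministic choice of deleted essentials

    genome_ids = [f"G{i}" for i in range(config.n_genomes)]
    pivot = genome_ids[0]
    ss_evo = np.random.SeedSequence(config.seed).spawn(6)[5]
    branch_rngs = [
        np.random.default_rng(c) for c in ss_evo.spawn(config.n_genomes)
    ]

    genomes: dict[str, dict[str, str]] = {}
    orders: dict[str, list[tuple[str, str]]] = {}
    family_of: dict[str, str] = {}
    presence: dict[str, set[str]] = {f: set() for f in fams}

    for gi, gid in enumerate(genome_ids):
        rng = branch_rngs[gi]
        is_pivot = gid == pivot
        order: list[tuple[str, str]] = []  # (family, strand) before naming
        for f in fams:
            if is_pivot:
                if f in missing:
                    continue
            else:
                if f in private or rng.random() < config.loss_prob:
                    continue
            order.append((f, anc_strand[f]))
            if not is_pivot and rng.random() < config.duplication_prob:
                order.append((f, anc_strand[f]))
        if not is_pivot and len(order) >= 4 and rng.random() < config.inversion_prob:
            length = int(rng.integers(2, min(10, len(order)) + 1))
            start = int(rng.integers(0, len(order) - length + 1))
            order = apply_inversion(order, start, start + length)
        genes: dict[str, str] = {}
        named: list[tuple[str, str]] = []
        for idx, (f, strand) in enumerate(order):
            gene_id = f"{gid}_{idx:04d}"
            genes[gene_id] = _mutate(rng, anc_seqs[f], config.substitution_rate)
            named.append((gene_id, strand))
            family_of[gene_id] = f
            presence[f].add(gid)
        genomes[gid] = genes
        orders[gid] = named

    # curation categories for pivot genes, drawn at the emulated proportions
    cats = list(CATEGORY_WEIGHTS)
    weights = np.array(list(CATEGORY_WEIGHTS.values()), dtype=float)
    weights /= weights.sum()
    category = {
        gene: cats[int(i)]
        for gene, i in zip(
            [g for g, _ in orders[pivot]],
            rng_lab.choice(len(cats), size=len(orders[pivot]), p=weights),
        )
    }

    truth = GroundTruth(
        pivot=pivot,
        family_of=family_of,
        function_label=labels,
        decoy_labels=decoys,
        category=category,
        essential_families=essential,
        essential_missing=missing,
        presence=presence,
        ancestral_seqs=anc_seqs,
    )
    return GenomeFamily(config, genome_ids, genomes, orders, truth)


_PSIBLAST_GOOD = (55.0, 120.0)  # -log10 e-value range passing the <1e-52 filter
_PFAM_GOOD = (3.0, 30.0)
_OTHER_GOOD = (5.0, 50.0)


def _good_hit(rng: np.random.Generator, source: Source) -> tuple[float, float | None]:
    if source is Source.PSI_BLAST:
        e = 10.0 ** -rng.uniform(*_PSIBLAST_GOOD)
        ident = float(rng.uniform(45.0, 95.0))
        return e, ident
    if source is Source.PFAM:
        return 10.0 ** -rng.uniform(*_PFAM_GOOD), None
    return 10.0 ** -rng.uniform(*_OTHER_GOOD), None


def simulate_evidence(
    config: SimulationConfig, family: GenomeFamily
) -> tuple[dict[Source, list[EvidenceRecord]], dict[str, dict]]:
    """Per-source evidence for the pivot's non-pseudogene genes.

    For each gene and source: with ``p_correct`` a hit carrying the family's
    true product (statistics passing the source filter), with ``p_wrong`` a
    decoy product, with ``p_nocall`` nothing. The expected-call table records,
    per gene, the true label and the number of correct votes — the consensus
    confidence the pipeline should recover.
    """
    rng = config.streams()["evidence"]
    truth = family.truth
    records: dict[Source, list[EvidenceRecord]] = {s: [] for s in Source}
    expected: dict[str, dict] = {}
    decoy_cycle = truth.decoy_labels
    pivot_genes = [
        g
        for g, _ in family.orders[family.pivot]
        if truth.category.get(g) is not Category.PSEUDOGENE
    ]
    for gene in pivot_genes:
        fam = truth.family_of[gene]
        true_label = truth.function_label[fam]
        correct_sources: list[Source] = []
        for source in Source:
            params = config.sources[source]
            u = rng.random()
            if u < params.p_nocall:
                continue
            wrong = u < params.p_nocall + params.p_wrong
            e_value, ident = _good_hit(rng, source)
            desc = (
                decoy_cycle[int(rng.integers(len(decoy_cycle)))] if wrong else true_label
            )
            member = ""
            if (
                source in (Source.INTERPROSCAN, Source.ANNIE)
                and not wrong
                and rng.random() < params.p_overlap
            ):
                member = Source.PFAM.value
            records[source].append(
                EvidenceRecord(
                    cds_id=gene,
                    source=source,
                    description=desc,
                    e_value=e_value,
                    identity_pct=ident,
                    member_database=member,
                )
            )
            if not wrong:
                correct_sources.append(source)
        expected[gene] = {
            "true_label": true_label,
            "n_correct": len(correct_sources),
            "correct_sources": correct_sources,
        }
    return records, expected


def simulate_rating_cases(
    config: SimulationConfig, n_cases: int | None = None
) -> dict[Source, list[RatingCase]]:
    """Binary-truth / ordinal-rating cases per source for ROC evaluation."""
    rng = config.streams()["ratings"]
    model = config.rating_model
    n = n_cases if n_cases is not None else config.n_rating_cases
    out: dict[Source, list[RatingCase]] = {}
    scale = list(model.scale)
    for source in Source:
        cases = []
        for i in range(n):
            truth = int(rng.random() < model.prevalence)
            dist = model.positive if truth else model.negative
            rating = int(rng.choice(scale, p=dist))
            cases.append(RatingCase(f"{source.value}_{i:05d}", truth, rating))
        out[source] = cases
    return out


def expected_auc(model: RatingModel) -> float:
    """Closed-form empirical AUC: P(r₁ > r₀) + ½ P(r₁ = r₀)."""
    auc = 0.0
    for i, p1 in enumerate(model.positive):
        for j, p0 in enumerate(model.negative):
            if model.scale[i] > model.scale[j]:
                auc += p1 * p0
            elif model.scale[i] == model.scale[j]:
                auc += 0.5 * p1 * p0
    return auc
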