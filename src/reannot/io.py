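"""File formats: FASTA, gene tables (TSV/GFF3), evidence, orthologs, ratings.

All tabular formats are headered, tab-separated text; FASTA wraps at 60
columns. Writers sort or preserve deterministic ordering so identical inputs
produce byte-identical files.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .evidence import EvidenceRecord, FunctionCall, Source
from .genome import Category, CategoryCensus, GeneRecord
from .homology import OrthologTable
from .roc import EvalSummary, RatingCase

GENE_TSV_COLUMNS = [
    "locus_tag",
    "genome_id",
    "start",
    "end",
    "strand",
    "category",
    "confidence",
    "product",
    "cog_ids",
]

EVIDENCE_TSV_COLUMNS = [
    "cds_id",
    "source",
    "member_database",
    "description",
    "e_value",
    "identity_pct",
    "score",
]


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(path: str | Path, sequences: Mapping[str, str]) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=60)
        writer.write_file(records)


def write_gene_tsv(path: str | Path, genes: Sequence[GeneRecord]) -> None:
    rows = [
        {
            "locus_tag": g.locus_tag,
            "genome_id": g.genome_id,
            "start": g.start,
            "end": g.end,
            "strand": g.strand,
            "category": g.category.value,
            "confidence": g.confidence,
            "product": g.product,
            "cog_ids": ";".join(sorted(g.cog_ids)),
        }
        for g in genes
    ]
    pd.DataFrame(rows, columns=GENE_TSV_COLUMNS).to_csv(path, sep="\t", index=False)


def read_gene_tsv(path: str | Path) -> list[GeneRecord]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    genes = []
    for row in df.itertuples(index=False):
        cogs = frozenset(c for c in row.cog_ids.split(";") if c)
        genes.append(
            GeneRecord(
                locus_tag=row.locus_tag,
                genome_id=row.genome_id,
                start=int(row.start),
                end=int(row.end),
                strand=row.strand,
                product=row.product,
                category=Category(row.category),
                confidence=int(row.confidence),
                cog_ids=cogs,
            )
        )
    return genes


def write_gff3(path: str | Path, genes: Sequence[GeneRecord], seq_length: int) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        if genes:
            fh.write(f"##sequence-region {genes[0].genome_id} 1 {seq_length}\n")
        for g in genes:
            attrs = (
                f"ID={g.locus_tag};product={g.product};category={g.category.value};"
                f"confidence={g.confidence}"
            )
            fh.write(
                "\t".join(
                    [
                        g.genome_id,
                        "reannot",
                        "CDS",
                        str(g.start),
                        str(g.end),
                        ".",
                        g.strand,
                        "0",
                        attrs,
                    ]
                )
                + "\n"
            )


def write_evidence_tsv(path: str | Path, records: Iterable[EvidenceRecord]) -> None:
    rows = [
        {
            "cds_id": r.cds_id,
            "source": r.source.value,
            "member_database": r.member_database,
            "description": r.description,
            "e_value": "" if r.e_value is None else repr(r.e_value),
            "identity_pct": "" if r.identity_pct is None else repr(r.identity_pct),
            "score": "" if r.score is None else repr(r.score),
        }
        for r in records
    ]
    pd.DataFrame(rows, columns=EVIDENCE_TSV_COLUMNS).to_csv(path, sep="\t", index=False)


def read_evidence_tsv(path: str | Path) -> list[EvidenceRecord]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = set(EVIDENCE_TSV_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"evidence TSV missing columns: {sorted(missing)}")
    out = []
    for row in df.itertuples(index=False):
        out.append(
            EvidenceRecord(
                cds_id=row.cds_id,
                source=Source(row.source),
                member_database=row.member_database,
                description=row.description,
                e_value=float(row.e_value) if row.e_value else None,
                identity_pct=float(row.identity_pct) if row.identity_pct else None,
                score=float(row.score) if row.score else None,
            )
        )
    return out


def write_calls_tsv(path: str | Path, calls: Sequence[FunctionCall]) -> None:
    rows = [
        {
            "cds_id": c.cds_id,
            "consensus_description": c.consensus_description,
            "confidence": c.confidence_label,
            "call_class": c.call_class.value,
            "supporting_sources": ";".join(sorted(s.value for s in c.supporting_sources)),
        }
        for c in calls
    ]
    pd.DataFrame(
        rows,
        columns=[
            "cds_id",
            "consensus_description",
            "confidence",
            "call_class",
            "supporting_sources",
        ],
    ).to_csv(path, sep="\t", index=False)


def write_census_json(path: str | Path, census: CategoryCensus) -> None:
    with open(path, "w") as fh:
        json.dump(census.as_dict(), fh, indent=2, sort_keys=True)
        fh.write("\n")


def write_ortholog_tsv(path: str | Path, table: OrthologTable) -> None:
    rows = [
        {
            "query": p.a_id,
            "subject": p.b_id,
            "score": p.alignment.raw_score,
            "identity_pct": round(p.alignment.identity_pct, 4),
            "Lmatch": p.alignment.Lmatch,
            "minLrap": round(p.metrics.minLrap, 6),
            "maxLrap": round(p.metrics.maxLrap, 6),
            "align_class": p.metrics.align_class.value,
        }
        for p in table.pairs
    ]
    pd.DataFrame(
        rows,
        columns=[
            "query",
            "subject",
            "score",
            "identity_pct",
            "Lmatch",
            "minLrap",
            "maxLrap",
            "align_class",
        ],
    ).to_csv(path, sep="\t", index=False)


def write_gene_order_tsv(
    path: str | Path, genome_id: str, order: Sequence[tuple[str, str]]
) -> None:
    rows = [
        {"genome_id": genome_id, "locus_tag": g, "index": i, "strand": s}
        for i, (g, s) in enumerate(order)
    ]
    pd.DataFrame(rows, columns=["genome_id", "locus_tag", "index", "strand"]).to_csv(
        path, sep="\t", index=False
    )


def read_gene_order_tsv(path: str | Path) -> tuple[dict[str, int], dict[str, str]]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    order = {t: int(i) for t, i in zip(df["locus_tag"], df["index"])}
    strand = dict(zip(df["locus_tag"], df["strand"]))
    return order, strand


def write_rating_tsv(path: str | Path, cases: Sequence[RatingCase]) -> None:
    """'Format 1' rating file: truth<TAB>rating, one case per line, no header."""
    with open(path, "w") as fh:
        for c in cases:
            fh.write(f"{c.truth}\t{c.rating}\n")


def read_rating_tsv(path: str | Path, source: str = "") -> list[RatingCase]:
    cases = []
    with open(path) as fh:
        for i, line in enumerate(fh):
            line = line.strip()
            if not line:
                continue
            truth, rating = line.split("\t")
            cases.append(RatingCase(f"{source}_{i:05d}", int(truth), int(rating)))
    return cases


def write_roc_summary_tsv(path: str | Path, summaries: Sequence[EvalSummary]) -> None:
    rows = [
        {
            "source": s.source,
            "n_cases": s.n_cases,
            "accuracy": round(s.accuracy, 6),
            "sensitivity": round(s.sensitivity, 6),
            "specificity": round(s.specificity, 6),
            "empiric_area": round(s.empiric_area, 6),
            "operating_threshold": s.operating_threshold,
        }
        for s in summaries
    ]
    pd.DataFrame(
        rows,
        columns=[
            "source",
            "n_cases",
            "accuracy",
            "sensitivity",
            "specificity",
            "empiric_area",
            "operating_threshold",
        ],
    ).to_csv(path, sep="\t", index=False)
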