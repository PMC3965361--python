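"""Readers and writers for the tabular knowledgebase formats.

All record tables are headered TSV; gene-set databases are GMT.  Lines
starting with ``#`` are provenance comments and are skipped.  Readers
preserve input order and never silently drop rows: a row that violates a
load-time invariant is diverted to a parse report (row number, field,
reason) which callers can write next to their outputs for audit.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .records import (
    ChemicalDiseaseAssociation,
    ChemicalProteinInteraction,
    ChemicalRecord,
    DiseaseGeneRecord,
    DiseasomeEdge,
    EvidenceScoreRow,
    GeneSetDatabase,
    LiteratureChemicalList,
    RelatedDiseaseSet,
    normalize_symbol,
)

__all__ = [
    "ParseReport",
    "read_disease_genes",
    "read_chemicals",
    "read_protein_interactions",
    "read_disease_associations",
    "read_diseasome",
    "read_related_diseases",
    "read_literature_list",
    "read_gene_sets",
    "write_gene_sets",
    "write_score_table",
    "read_score_table",
]


class ParseError(ValueError):
    """A row that cannot be parsed at all (as opposed to one rejected
    by a validation rule, which lands in the parse report)."""


@dataclass
class ParseReport:
    """Rejected rows and the reason each was rejected."""

    entries: list[tuple[int, str, str]] = field(default_factory=list)

    def reject(self, row: int, column: str, reason: str) -> None:
        self.entries.append((row, column, reason))

    def __len__(self) -> int:
        return len(self.entries)

    def write(self, path: str | Path) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh, delimiter="\t", lineterminator="\n")
            w.writerow(["row", "field", "reason"])
            w.writerows(self.entries)


def _read_tsv(path: str | Path, required: Sequence[str]) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str, keep_default_na=False)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing required columns {missing}")
    return df


def _float_or_none(value: str, path: str | Path, row: int, column: str) -> float | None:
    if value == "":
        return None
    try:
        return float(value)
    except ValueError:
        raise ParseError(f"{path} row {row}: non-numeric {column} {value!r}") from None


def read_disease_genes(
    path: str | Path, report: ParseReport | None = None
) -> list[DiseaseGeneRecord]:
    """Read disease-associated gene records.

    GWA-literature rows must carry a MAF strictly above 0.05 (common
    variants only); violating rows are diverted to ``report``.  A
    non-numeric MAF is a parse error naming the row.
    """
    report = report if report is not None else ParseReport()
    df = _read_tsv(path, ["gene_symbol", "snp_id", "maf", "source"])
    records: list[DiseaseGeneRecord] = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        maf = _float_or_none(row.maf, path, i, "maf")
        rec = DiseaseGeneRecord(
            gene_symbol=normalize_symbol(row.gene_symbol),
            source=row.source,
            snp_id=row.snp_id or None,
            maf=maf,
        )
        if rec.violates_maf_rule():
            report.reject(i, "maf", f"MAF {row.maf or 'absent'} not > 0.05 for gwa_literature row")
            continue
        records.append(rec)
    return records


def read_chemicals(path: str | Path) -> list[ChemicalRecord]:
    df = _read_tsv(path, ["chemical_id", "name", "chem_class"])
    seen: set[str] = set()
    records = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        if row.chemical_id in seen:
            raise ParseError(f"{path} row {i}: duplicate chemical_id {row.chemical_id!r}")
        seen.add(row.chemical_id)
        records.append(ChemicalRecord(row.chemical_id, row.name, row.chem_class))
    return records


_TRUE = {"1", "true", "yes"}
_FALSE = {"0", "false", "no", ""}


def _bool(value: str, path: str | Path, row: int, column: str) -> bool:
    v = value.strip().lower()
    if v in _TRUE:
        return True
    if v in _FALSE:
        return False
    raise ParseError(f"{path} row {row}: non-boolean {column} {value!r}")


def read_protein_interactions(path: str | Path) -> list[ChemicalProteinInteraction]:
    df = _read_tsv(
        path,
        ["chemical_id", "gene_symbol", "species", "confidence", "negated", "cotreatment"],
    )
    return [
        ChemicalProteinInteraction(
            chemical_id=row.chemical_id,
            gene_symbol=normalize_symbol(row.gene_symbol),
            species=row.species,
            confidence=row.confidence,
            negated=_bool(row.negated, path, i, "negated"),
            cotreatment=_bool(row.cotreatment, path, i, "cotreatment"),
        )
        for i, row in enumerate(df.itertuples(index=False), start=2)
    ]


def read_disease_associations(
    path: str | Path, report: ParseReport | None = None
) -> list[ChemicalDiseaseAssociation]:
    """Read chemical-disease associations, enforcing on load that an
    inference score is present iff the evidence is literature-inferred."""
    report = report if report is not None else ParseReport()
    df = _read_tsv(path, ["chemical_id", "disease_id", "evidence_type", "inference_score"])
    records = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        score = _float_or_none(row.inference_score, path, i, "inference_score")
        assoc = ChemicalDiseaseAssociation(
            chemical_id=row.chemical_id,
            disease_id=row.disease_id,
            evidence_type=row.evidence_type,
            inference_score=score,
        )
        if not assoc.score_consistent():
            report.reject(
                i,
                "inference_score",
                f"score {'present' if score is not None else 'absent'} "
                f"inconsistent with evidence_type {row.evidence_type}",
            )
            continue
        records.append(assoc)
    return records


def read_diseasome(path: str | Path) -> list[DiseasomeEdge]:
    df = _read_tsv(path, ["disease_a", "disease_b", "shared_gene_count"])
    return [
        DiseasomeEdge(row.disease_a, row.disease_b, int(row.shared_gene_count))
        for row in df.itertuples(index=False)
    ]


def read_related_diseases(path: str | Path) -> RelatedDiseaseSet:
    """Read the curated related-disease subset: TSV with columns
    ``target_disease`` and ``member``, one member per row."""
    df = _read_tsv(path, ["target_disease", "member"])
    targets = set(df["target_disease"])
    if len(targets) != 1:
        raise ParseError(f"{path}: expected exactly one target disease, got {sorted(targets)}")
    return RelatedDiseaseSet(target_disease=targets.pop(), members=frozenset(df["member"]))


def read_literature_list(path: str | Path) -> LiteratureChemicalList:
    df = _read_tsv(path, ["chemical_id"])
    return LiteratureChemicalList(chemical_ids=frozenset(df["chemical_id"]))


def read_gene_sets(
    path: str | Path,
    universe_size: int,
    db_name: str | None = None,
    universe_genes: Iterable[str] | None = None,
    report: ParseReport | None = None,
) -> GeneSetDatabase:
    """Read a GMT gene-set file into a :class:`GeneSetDatabase`.

    GMT lines are ``category<TAB>description<TAB>member...``.  Members
    are symbol-normalised and deduplicated.  Empty categories are
    rejected into the report; duplicate category names are an error.
    The universe size is declared by the caller, not inferred from the
    file (source databases annotate more genes than any one export).
    """
    report = report if report is not None else ParseReport()
    categories: dict[str, frozenset[str]] = {}
    with open(path) as fh:
        for i, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ParseError(f"{path} line {i}: GMT line needs name and description")
            name = fields[0].strip()
            if name in categories:
                raise ParseError(f"{path} line {i}: duplicate category {name!r}")
            members = frozenset(normalize_symbol(g) for g in fields[2:] if g.strip())
            if not members:
                report.reject(i, name, "category has no members")
                continue
            categories[name] = members
    return GeneSetDatabase(
        db_name=db_name or Path(path).stem,
        universe_size=universe_size,
        categories=categories,
        universe_genes=frozenset(normalize_symbol(g) for g in universe_genes)
        if universe_genes is not None
        else None,
    )


def write_gene_sets(db: GeneSetDatabase, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name in sorted(db.categories):
            members = "\t".join(sorted(db.categories[name]))
            fh.write(f"{name}\t{db.db_name}\t{members}\n")


_SCORE_COLUMNS = ["chemical", "d_score", "gwas_score", "combined_score", "ntp_evidence", "rank"]


def write_score_table(
    rows: Sequence[EvidenceScoreRow], path: str | Path, decimals: int = 3
) -> None:
    """Serialise the ranked candidate table as TSV, scores to ``decimals``."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(_SCORE_COLUMNS)
        for r in rows:
            w.writerow(
                [
                    r.chemical_id,
                    f"{r.d_score:.{decimals}f}",
                    f"{r.gwas_score:.{decimals}f}",
                    f"{r.combined_score:.{decimals}f}",
                    r.ntp_flag,
                    r.rank if r.rank is not None else "",
                ]
            )


def read_score_table(path: str | Path) -> list[EvidenceScoreRow]:
    df = _read_tsv(path, _SCORE_COLUMNS)
    return [
        EvidenceScoreRow(
            chemical_id=row.chemical,
            d_score=float(row.d_score),
            gwas_score=float(row.gwas_score),
            combined_score=float(row.combined_score),
            ntp_flag=int(row.ntp_evidence),
            rank=int(row.rank) if row.rank != "" else None,
        )
        for row in df.itertuples(index=False)
    ]
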