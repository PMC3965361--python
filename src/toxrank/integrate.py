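"""Integration of the evidence layers into the ranked candidate table.

The two computational layer scores are averaged (the literature layer
is a retention filter, not a summand); drugs and natural compounds are
excluded; chemicals are ranked by combined score descending with a
deterministic name-ascending tie-break.  Combined scores are computed
from the unrounded layer fractions and rounded only on output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .records import ChemicalRecord, EvidenceScoreRow

__all__ = [
    "IntegrationConfig",
    "combined_score",
    "build_score_table",
    "count_unique_chemicals",
]


@dataclass(frozen=True)
class IntegrationConfig:
    exclude_classes: frozenset[str] = frozenset({"drug", "natural"})
    require_literature: bool = True
    score_decimals: int = 3

    def __post_init__(self) -> None:
        if self.score_decimals < 1:
            raise ValueError("score_decimals must be >= 1")


def combined_score(d_score: float, gwas_score: float) -> float:
    """Mean of the disease-similarity and GWA layer scores."""
    for name, value in (("d_score", d_score), ("gwas_score", gwas_score)):
        if not 0.0 <= value <= 1.0:
            raise ValueError(f"{name} {value} outside [0, 1]")
    return (d_score + gwas_score) / 2.0


def build_score_table(
    chemicals: list[ChemicalRecord],
    d: dict[str, float],
    g: dict[str, float],
    lit: dict[str, int],
    config: IntegrationConfig = IntegrationConfig(),
) -> list[EvidenceScoreRow]:
    """Assemble and rank the candidate table.

    Chemicals absent from a layer score 0 in it.  Excluded classes are
    dropped; when ``require_literature`` only literature-documented
    chemicals remain.  Rows are sorted by combined score descending,
    ties broken by chemical name ascending, and ranked 1..n.
    """
    seen: set[str] = set()
    for chem in chemicals:
        if chem.chemical_id in seen:
            raise ValueError(f"duplicate chemical_id {chem.chemical_id!r}")
        seen.add(chem.chemical_id)

    rows = []
    for chem in chemicals:
        if chem.chem_class in config.exclude_classes:
            continue
        flag = lit.get(chem.chemical_id, 0)
        if config.require_literature and flag != 1:
            continue
        ds = d.get(chem.chemical_id, 0.0)
        gs = g.get(chem.chemical_id, 0.0)
        rows.append((chem.chemical_id, ds, gs, combined_score(ds, gs), flag))

    rows.sort(key=lambda r: (-r[3], r[0]))
    return [
        EvidenceScoreRow(
            chemical_id=cid,
            d_score=ds,
            gwas_score=gs,
            combined_score=cs,
            ntp_flag=flag,
            rank=i,
        )
        for i, (cid, ds, gs, cs, flag) in enumerate(rows, start=1)
    ]


def count_unique_chemicals(
    gwa_layer: set[str], disease_layer: set[str], literature_layer: set[str]
) -> int:
    """Number of distinct chemicals appearing in any of the three layers."""
    return len(gwa_layer | disease_layer | literature_layer)
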