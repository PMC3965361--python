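"""Domain types for the chemical-disease evidence knowledgebase.

The pipeline integrates three kinds of evidence linking environmental
chemicals to a disease of interest (type 2 diabetes in the motivating
case study):

* disease-associated genes from genome-wide association studies and
  OMIM, connected to chemicals through chemical-protein interactions;
* chemical-disease associations for diseases genetically similar to the
  target disease (diseasome neighbours), with curated and
  literature-inferred evidence types;
* a binary literature layer from a systematic epidemiological review.

All types here are plain frozen dataclasses; filter semantics live in
:mod:`toxrank.layers` and downstream modules.
"""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = [
    "normalize_symbol",
    "DiseaseGeneRecord",
    "ChemicalRecord",
    "ChemicalProteinInteraction",
    "ChemicalDiseaseAssociation",
    "DiseasomeEdge",
    "RelatedDiseaseSet",
    "LiteratureChemicalList",
    "GeneSetDatabase",
    "ChemicalGeneNetwork",
    "EvidenceScoreRow",
    "EnrichmentResult",
]

#: sources a disease gene can come from
GENE_SOURCES = ("gwa_literature", "omim")
#: chemical classes; drugs and natural compounds are excluded from ranking
CHEM_CLASSES = ("environmental", "drug", "natural")
#: chemical-disease evidence types (CTD-style)
EVIDENCE_TYPES = ("marker_mechanism", "therapeutic", "inferred_literature")


def normalize_symbol(symbol: str) -> str:
    """Normalise a gene symbol for matching: trim whitespace, upper-case.

    Source databases mix symbol casings; all set operations in the
    pipeline go through this normalisation.
    """
    return symbol.strip().upper()


@dataclass(frozen=True)
class DiseaseGeneRecord:
    """One disease-associated gene, from a GWA variant or OMIM.

    GWA-literature records carry the SNP and its minor allele frequency;
    only common variants (MAF strictly above 0.05) are admissible.
    """

    gene_symbol: str
    source: str  # gwa_literature | omim
    snp_id: str | None = None
    maf: float | None = None

    def __post_init__(self) -> None:
        if not self.gene_symbol.strip():
            raise ValueError("gene_symbol must be non-empty")
        if self.source not in GENE_SOURCES:
            raise ValueError(f"unknown source {self.source!r}")

    def violates_maf_rule(self) -> bool:
        """True when a GWA-literature record lacks a MAF or has MAF <= 0.05."""
        if self.source != "gwa_literature":
            return False
        return self.maf is None or not self.maf > 0.05


@dataclass(frozen=True)
class ChemicalRecord:
    chemical_id: str
    name: str
    chem_class: str  # environmental | drug | natural

    def __post_init__(self) -> None:
        if self.chem_class not in CHEM_CLASSES:
            raise ValueError(f"unknown chem_class {self.chem_class!r}")


@dataclass(frozen=True)
class ChemicalProteinInteraction:
    """A chemical-protein interaction record (ChemProt-style).

    Carries the flags its filter needs: species, experimental-support
    confidence, and the statement qualifiers (negation, co-treatment)
    that disqualify an interaction from evidence counting.
    """

    chemical_id: str
    gene_symbol: str
    species: str = "human"
    confidence: str = "high"  # high | low
    negated: bool = False
    cotreatment: bool = False

    def __post_init__(self) -> None:
        if not self.chemical_id.strip() or not self.gene_symbol.strip():
            raise ValueError("chemical_id and gene_symbol must be non-empty")


@dataclass(frozen=True)
class ChemicalDiseaseAssociation:
    """A chemical-disease link (CTD-style).

    Curated links (marker/mechanism, therapeutic) carry no inference
    score; literature-inferred links must carry one.  The invariant is
    enforced on load, not construction, so parse reports can enumerate
    violations.
    """

    chemical_id: str
    disease_id: str
    evidence_type: str
    inference_score: float | None = None

    def __post_init__(self) -> None:
        if self.evidence_type not in EVIDENCE_TYPES:
            raise ValueError(f"unknown evidence_type {self.evidence_type!r}")

    def score_consistent(self) -> bool:
        """Score present iff the link is literature-inferred."""
        inferred = self.evidence_type == "inferred_literature"
        return inferred == (self.inference_score is not None)


@dataclass(frozen=True)
class DiseasomeEdge:
    """Two diseases sharing at least one associated gene (diseasome edge)."""

    disease_a: str
    disease_b: str
    shared_gene_count: int

    def __post_init__(self) -> None:
        if self.disease_a == self.disease_b:
            raise ValueError("diseasome edge endpoints must differ")
        if self.shared_gene_count < 1:
            raise ValueError("shared_gene_count must be >= 1")


@dataclass(frozen=True)
class RelatedDiseaseSet:
    """The curated subset of diseasome neighbours used as the
    disease-similarity layer's denominator (eight in the case study)."""

    target_disease: str
    members: frozenset[str]

    def __post_init__(self) -> None:
        if self.target_disease in self.members:
            raise ValueError("members must exclude the target disease")

    def __len__(self) -> int:
        return len(self.members)


@dataclass(frozen=True)
class LiteratureChemicalList:
    """Chemicals named in the systematic literature review (binary layer)."""

    chemical_ids: frozenset[str] = field(default_factory=frozenset)

    def __contains__(self, chemical_id: str) -> bool:
        return chemical_id in self.chemical_ids


@dataclass(frozen=True)
class GeneSetDatabase:
    """A named gene-set collection with an explicitly declared universe size.

    The universe is declared, not inferred from the member union: the
    source databases annotate more genes than any one export lists
    (e.g. 5515 disease-annotated genes of which 206 belong to the
    diabetes mellitus category).  ``universe_genes`` optionally lists
    the universe membership, enabling draw-size restriction during
    enrichment.
    """

    db_name: str
    universe_size: int
    categories: dict[str, frozenset[str]]
    universe_genes: frozenset[str] | None = None

    def __post_init__(self) -> None:
        if self.universe_size < 1:
            raise ValueError("universe_size must be positive")
        for name, members in self.categories.items():
            if len(members) > self.universe_size:
                raise ValueError(
                    f"category {name!r} has {len(members)} members, "
                    f"exceeding universe size {self.universe_size}"
                )


@dataclass(frozen=True)
class ChemicalGeneNetwork:
    """The deduplicated gene/protein set curated for one chemical,
    treated as a small biological network for enrichment."""

    chemical_id: str
    gene_symbols: frozenset[str]

    def __len__(self) -> int:
        return len(self.gene_symbols)


@dataclass(frozen=True)
class EvidenceScoreRow:
    """One row of the ranked candidate table.

    ``combined_score`` is the mean of the two computational layer scores;
    ``ntp_flag`` is the binary literature evidence.
    """

    chemical_id: str
    d_score: float
    gwas_score: float
    combined_score: float
    ntp_flag: int
    rank: int | None = None


@dataclass(frozen=True)
class EnrichmentResult:
    """One enrichment test: a chemical's network against one category.

    ``p_raw`` is the upper-tail hypergeometric probability of drawing at
    least ``overlap_k`` category members in ``draw_n`` draws from a
    universe of ``universe_N`` containing ``category_K`` members;
    ``p_corrected`` is Bonferroni-adjusted.
    """

    chemical_id: str
    db_name: str
    category: str
    overlap_k: int
    draw_n: int
    category_K: int
    universe_N: int
    p_raw: float
    p_corrected: float
    overlap_genes: frozenset[str]

    def __post_init__(self) -> None:
        if self.overlap_k > min(self.draw_n, self.category_K):
            raise ValueError("overlap cannot exceed draw or category size")
        if self.p_corrected < self.p_raw - 1e-15:
            raise ValueError("corrected p-value cannot be below raw p-value")
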