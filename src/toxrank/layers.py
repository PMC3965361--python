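"""The three per-chemical evidence layers.

* GWA layer: fraction of chemically-annotated disease genes a chemical
  interacts with, after restricting interactions to high-confidence
  human records without negation or co-treatment qualifiers.
* Disease-similarity layer: fraction of the curated related diseases a
  chemical is linked to, after the curated/inferred evidence filter and
  the inference-score cutoff.
* Literature layer: binary membership in the review chemical list.

Both fractional layers use set semantics — duplicated evidence rows
never change a score — and are monotone in the evidence set.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .records import (
    ChemicalDiseaseAssociation,
    ChemicalProteinInteraction,
    DiseaseGeneRecord,
    LiteratureChemicalList,
    RelatedDiseaseSet,
    normalize_symbol,
)

__all__ = [
    "LayerConfig",
    "filter_protein_interactions",
    "filter_disease_associations",
    "annotated_disease_genes",
    "gwas_layer_score",
    "disease_layer_score",
    "literature_score",
    "gwas_layer_scores",
    "disease_layer_scores",
]


@dataclass(frozen=True)
class LayerConfig:
    """Filter settings for the evidence layers.

    inference_cutoff
        Minimum CTD-style inference score for literature-inferred
        chemical-disease links.  The cutoff is inclusive by default
        (a score of exactly 5 is retained); set ``strict_cutoff`` for
        the exclusive reading.
    require_high_confidence / restrict_species
        Chemical-protein interactions must be experimentally supported
        high-confidence records for the given species.
    """

    inference_cutoff: float = 5.0
    strict_cutoff: bool = False
    require_high_confidence: bool = True
    restrict_species: str = "human"
    related_diseases: RelatedDiseaseSet | None = None

    def __post_init__(self) -> None:
        if self.inference_cutoff < 0:
            raise ValueError("inference_cutoff must be non-negative")

    def score_passes(self, score: float) -> bool:
        if self.strict_cutoff:
            return score > self.inference_cutoff
        return score >= self.inference_cutoff


def filter_protein_interactions(
    interactions: list[ChemicalProteinInteraction], config: LayerConfig
) -> list[ChemicalProteinInteraction]:
    """Keep only unambiguous evidence rows: right species, high
    confidence (when required), not negated, not a co-treatment
    statement.  Order-preserving."""
    kept = []
    for rec in interactions:
        if rec.species != config.restrict_species:
            continue
        if config.require_high_confidence and rec.confidence != "high":
            continue
        if rec.negated or rec.cotreatment:
            continue
        kept.append(rec)
    return kept


def filter_disease_associations(
    associations: list[ChemicalDiseaseAssociation], config: LayerConfig
) -> list[ChemicalDiseaseAssociation]:
    """Retain curated links unconditionally and inferred links passing
    the score cutoff, restricted to the related-disease set."""
    if config.related_diseases is None:
        raise ValueError("LayerConfig.related_diseases is required for the disease layer")
    members = config.related_diseases.members
    kept = []
    for rec in associations:
        if rec.disease_id not in members:
            continue
        if rec.evidence_type == "inferred_literature":
            assert rec.inference_score is not None
            if not config.score_passes(rec.inference_score):
                continue
        kept.append(rec)
    return kept


def annotated_disease_genes(
    interactions: list[ChemicalProteinInteraction],
    disease_genes: list[DiseaseGeneRecord],
) -> frozenset[str]:
    """Disease genes with at least one (filtered) chemical interaction.

    This set's size is the GWA layer denominator: SNPs collapse to
    genes first, and genes never touched by any chemical do not count
    (54 of the case study's 60 SNP-derived genes).
    """
    disease_set = {normalize_symbol(g.gene_symbol) for g in disease_genes}
    touched = {normalize_symbol(i.gene_symbol) for i in interactions}
    return frozenset(disease_set & touched)


def gwas_layer_score(
    chemical_id: str,
    interactions: list[ChemicalProteinInteraction],
    disease_genes: list[DiseaseGeneRecord],
) -> float:
    """GWA weight score: the fraction of chemically-annotated disease
    genes this chemical interacts with.

    ``interactions`` must already be filtered.  Genes are counted once
    regardless of SNP multiplicity.  Raises if no disease gene has any
    chemical interaction (denominator zero).
    """
    denominator_genes = annotated_disease_genes(interactions, disease_genes)
    if not denominator_genes:
        raise ValueError("no chemically annotated disease genes (GWA denominator is zero)")
    own = {
        normalize_symbol(i.gene_symbol)
        for i in interactions
        if i.chemical_id == chemical_id
    }
    return len(own & denominator_genes) / len(denominator_genes)


def disease_layer_score(
    chemical_id: str,
    associations: list[ChemicalDiseaseAssociation],
    related: RelatedDiseaseSet,
) -> float:
    """Disease-similarity weight score: fraction of related diseases the
    chemical is linked to (any retained evidence type).  With eight
    related diseases the score is a multiple of 0.125."""
    if not related.members:
        raise ValueError("related disease set is empty")
    linked = {
        a.disease_id
        for a in associations
        if a.chemical_id == chemical_id and a.disease_id in related.members
    }
    return len(linked) / len(related.members)


def literature_score(chemical_id: str, lit: LiteratureChemicalList) -> int:
    """Binary literature layer: 1 iff the chemical appears in the review list."""
    return 1 if chemical_id in lit else 0


@dataclass
class LayerAudit:
    """Per-chemical numerator/denominator detail for a fractional layer."""

    scores: dict[str, float]
    numerators: dict[str, int]
    denominator: int
    rows: list[tuple[str, float, int, int]] = field(init=False)

    def __post_init__(self) -> None:
        self.rows = [
            (chem, self.scores[chem], self.numerators[chem], self.denominator)
            for chem in sorted(self.scores)
        ]


def gwas_layer_scores(
    interactions: list[ChemicalProteinInteraction],
    disease_genes: list[DiseaseGeneRecord],
) -> LayerAudit:
    """GWA scores for every chemical present in the filtered interaction
    table, with audit numerators and the shared denominator."""
    denominator_genes = annotated_disease_genes(interactions, disease_genes)
    if not denominator_genes:
        raise ValueError("no chemically annotated disease genes (GWA denominator is zero)")
    per_chem: dict[str, set[str]] = {}
    for rec in interactions:
        per_chem.setdefault(rec.chemical_id, set()).add(normalize_symbol(rec.gene_symbol))
    numerators = {
        chem: len(genes & denominator_genes) for chem, genes in per_chem.items()
    }
    d = len(denominator_genes)
    return LayerAudit(
        scores={chem: k / d for chem, k in numerators.items()},
        numerators=numerators,
        denominator=d,
    )


def disease_layer_scores(
    associations: list[ChemicalDiseaseAssociation], related: RelatedDiseaseSet
) -> LayerAudit:
    """Disease-similarity scores for every chemical in the filtered
    association table."""
    if not related.members:
        raise ValueError("related disease set is empty")
    per_chem: dict[str, set[str]] = {}
    for rec in associations:
        if rec.disease_id in related.members:
            per_chem.setdefault(rec.chemical_id, set()).add(rec.disease_id)
    numerators = {chem: len(ds) for chem, ds in per_chem.items()}
    d = len(related.members)
    return LayerAudit(
        scores={chem: k / d for chem, k in numerators.items()},
        numerators=numerators,
        denominator=d,
    )
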