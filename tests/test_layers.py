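"""Evidence-layer filters and weight scores.

The GWA and disease-similarity scores are validated against the
published candidate table through an enumeration oracle: for each
printed three-decimal score, the integer numerator k (out of 54
annotated disease genes, or 8 related diseases) whose fraction rounds
to it is recovered and shown to be unique.
"""

import pytest
from hypothesis import given, settings, strategies as st

from toxrank.layers import (
    LayerConfig,
    disease_layer_score,
    filter_disease_associations,
    filter_protein_interactions,
    gwas_layer_score,
    gwas_layer_scores,
    literature_score,
)
from toxrank.records import (
    ChemicalDiseaseAssociation,
    ChemicalProteinInteraction,
    DiseaseGeneRecord,
    LiteratureChemicalList,
    RelatedDiseaseSet,
)

RELATED = RelatedDiseaseSet("T2D", frozenset(f"d{i}" for i in range(8)))
CFG = LayerConfig(related_diseases=RELATED)


def interaction(chem="c1", gene="GCK", **kw):
    return ChemicalProteinInteraction(chem, gene, **kw)


class TestProteinInteractionFilter:
    @pytest.mark.parametrize(
        "record, kept",
        [
            (interaction(), True),
            (interaction(negated=True), False),
            (interaction(cotreatment=True), False),
            (interaction(species="rat"), False),
            (interaction(confidence="low"), False),
        ],
        ids=["clean", "negated", "cotreatment", "wrong-species", "low-confidence"],
    )
    def test_retention_rules(self, record, kept):
        assert (filter_protein_interactions([record], CFG) == [record]) is kept

    def test_low_confidence_kept_when_not_required(self):
        cfg = LayerConfig(require_high_confidence=False, related_diseases=RELATED)
        assert filter_protein_interactions([interaction(confidence="low")], cfg)

    def test_order_preserved(self):
        recs = [interaction(gene=g) for g in ("B", "A", "C")]
        assert filter_protein_interactions(recs, CFG) == recs


class TestDiseaseAssociationFilter:
    def assoc(self, ev="marker_mechanism", score=None, disease="d0"):
        return ChemicalDiseaseAssociation("c1", disease, ev, score)

    @pytest.mark.parametrize(
        "score, kept",
        [(5.0, True), (4.2, False), (5.1, True)],
        ids=["at-cutoff", "below", "above"],
    )
    def test_inclusive_inference_cutoff(self, score, kept):
        rec = self.assoc("inferred_literature", score)
        assert bool(filter_disease_associations([rec], CFG)) is kept

    def test_strict_cutoff_drops_boundary(self):
        cfg = LayerConfig(strict_cutoff=True, related_diseases=RELATED)
        rec = self.assoc("inferred_literature", 5.0)
        assert not filter_disease_associations([rec], cfg)

    def test_curated_links_always_retained(self):
        for ev in ("marker_mechanism", "therapeutic"):
            assert filter_disease_associations([self.assoc(ev)], CFG)

    def test_unrelated_disease_dropped(self):
        rec = self.assoc(disease="elsewhere")
        assert not filter_disease_associations([rec], CFG)


DISEASE_GENES = [
    DiseaseGeneRecord(f"G{i:02d}", "gwa_literature", snp_id=f"rs{i}", maf=0.1)
    for i in range(54)
]
# anchor chemical touching every panel gene fixes the denominator at 54
ANCHOR = [interaction("anchor", g.gene_symbol) for g in DISEASE_GENES]

# printed GWA scores and their unique recovered numerators out of 54
GWAS_PRINTED = [(31, 0.574), (9, 0.167), (7, 0.130), (6, 0.111), (1, 0.019)]


class TestGwasScore:
    @pytest.mark.parametrize("k, printed", GWAS_PRINTED)
    def test_published_scores_from_recovered_numerators(self, k, printed):
        ints = ANCHOR + [interaction("c1", f"G{i:02d}") for i in range(k)]
        assert round(gwas_layer_score("c1", ints, DISEASE_GENES), 3) == printed

    @pytest.mark.parametrize("k, printed", GWAS_PRINTED)
    def test_recovered_numerator_is_unique(self, k, printed):
        matches = [j for j in range(55) if round(j / 54, 3) == printed]
        assert matches == [k]

    def test_no_interactions_scores_zero(self):
        assert gwas_layer_score("ghost", ANCHOR, DISEASE_GENES) == 0.0

    def test_full_coverage_scores_one(self):
        assert gwas_layer_score("anchor", ANCHOR, DISEASE_GENES) == 1.0

    def test_snp_multiplicity_does_not_inflate(self):
        # two SNP records on the same gene still count one gene
        genes = DISEASE_GENES + [
            DiseaseGeneRecord("G00", "gwa_literature", snp_id="rs999", maf=0.3)
        ]
        ints = ANCHOR + [interaction("c1", "G00")]
        assert gwas_layer_score("c1", ints, genes) == pytest.approx(1 / 54)

    def test_zero_denominator_is_error(self):
        with pytest.raises(ValueError, match="denominator"):
            gwas_layer_score("c1", [], DISEASE_GENES)

    def test_duplicate_rows_do_not_change_scores(self):
        ints = ANCHOR + [interaction("c1", "G00")]
        audit1 = gwas_layer_scores(ints, DISEASE_GENES)
        audit2 = gwas_layer_scores(ints * 3, DISEASE_GENES)
        assert audit1.scores == audit2.scores

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.sets(st.integers(min_value=0, max_value=53), max_size=20), st.integers(0, 53))
    def test_adding_an_interaction_never_lowers_the_score(self, genes, extra):
        base = ANCHOR + [interaction("c1", f"G{i:02d}") for i in genes]
        more = base + [interaction("c1", f"G{extra:02d}")]
        assert gwas_layer_score("c1", more, DISEASE_GENES) >= gwas_layer_score(
            "c1", base, DISEASE_GENES
        )


class TestDiseaseScore:
    def link(self, chem, i):
        return ChemicalDiseaseAssociation(chem, f"d{i}", "marker_mechanism")

    @pytest.mark.parametrize(
        "k, printed", [(4, 0.500), (3, 0.375), (2, 0.250), (1, 0.125), (0, 0.0)]
    )
    def test_published_scores_are_eighths(self, k, printed):
        assocs = [self.link("c1", i) for i in range(k)]
        assert disease_layer_score("c1", assocs, RELATED) == pytest.approx(printed)

    def test_every_printed_d_score_recovers_a_unique_numerator(self):
        for printed in (0.500, 0.375, 0.250, 0.125):
            matches = [k for k in range(9) if round(k / 8, 3) == printed]
            assert len(matches) == 1

    def test_mixed_evidence_types_all_count(self):
        assocs = [
            ChemicalDiseaseAssociation("c1", "d0", "therapeutic"),
            ChemicalDiseaseAssociation("c1", "d1", "inferred_literature", 8.0),
        ]
        assert disease_layer_score("c1", assocs, RELATED) == pytest.approx(0.25)

    def test_empty_related_set_is_error(self):
        empty = RelatedDiseaseSet("T2D", frozenset())
        with pytest.raises(ValueError):
            disease_layer_score("c1", [], empty)


class TestLiteratureScore:
    LIT = LiteratureChemicalList(frozenset({"TCDD", "HCB"}))

    def test_listed_chemical_scores_one(self):
        assert literature_score("TCDD", self.LIT) == 1

    def test_absent_chemical_scores_zero(self):
        assert literature_score("unknown", self.LIT) == 0

    def test_empty_list_scores_all_zero(self):
        assert literature_score("TCDD", LiteratureChemicalList()) == 0
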