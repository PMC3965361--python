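"""Synthetic knowledgebase generator: determinism, validity, planted truth."""

import hashlib
from pathlib import Path

import numpy as np
import pytest

from toxrank import io as tio
from toxrank.enrich import enrich_network
from toxrank.integrate import IntegrationConfig, build_score_table
from toxrank.layers import (
    LayerConfig,
    filter_protein_interactions,
    gwas_layer_scores,
)
from toxrank.records import ChemicalGeneNetwork
from toxrank.simulate import (
    SyntheticConfig,
    generate_knowledgebase,
    generate_network,
    table1_fixture,
    table2_fixture,
    TABLE1_NUMERATORS,
)

SMALL = SyntheticConfig(n_chemicals=30, universe_N=400, category_sizes=(40,),
                        network_size=15, seed=3)


def _dir_hashes(d: Path) -> dict[str, str]:
    return {p.name: hashlib.sha256(p.read_bytes()).hexdigest() for p in sorted(d.iterdir())}


class TestGenerator:
    def test_same_seed_gives_byte_identical_files(self, tmp_path):
        generate_knowledgebase(SMALL, outdir=tmp_path / "a")
        generate_knowledgebase(SMALL, outdir=tmp_path / "b")
        assert _dir_hashes(tmp_path / "a") == _dir_hashes(tmp_path / "b")

    def test_different_seed_changes_output(self, tmp_path):
        generate_knowledgebase(SMALL, outdir=tmp_path / "a")
        other = SyntheticConfig(**{**SMALL.__dict__, "seed": 4})
        generate_knowledgebase(other, outdir=tmp_path / "b")
        assert _dir_hashes(tmp_path / "a") != _dir_hashes(tmp_path / "b")

    def test_emitted_tables_pass_validation_with_zero_rejections(self, tmp_path):
        kb, _ = generate_knowledgebase(SMALL, outdir=tmp_path)
        gene_report, assoc_report = tio.ParseReport(), tio.ParseReport()
        genes = tio.read_disease_genes(tmp_path / "disease_genes.tsv", gene_report)
        assocs = tio.read_disease_associations(
            tmp_path / "disease_associations.tsv", assoc_report
        )
        assert len(gene_report) == 0 and len(assoc_report) == 0
        assert len(genes) == len(kb.disease_genes)
        assert len(assocs) == len(kb.associations)

    def test_ground_truth_consistent_with_emitted_tables(self, tmp_path):
        kb, truth = generate_knowledgebase(SMALL, outdir=tmp_path)
        fint = filter_protein_interactions(
            kb.interactions, LayerConfig(related_diseases=kb.related)
        )
        audit = gwas_layer_scores(fint, kb.disease_genes)
        assert audit.numerators == truth.gwas_numerators
        assert audit.denominator == truth.gwas_denominator
        for cid, net in kb.networks.items():
            for db in kb.gene_sets:
                for name, members in db.categories.items():
                    assert truth.network_overlaps[cid][name] == len(
                        net.gene_symbols & members
                    )

    def test_union_count_matches_ground_truth(self):
        _, truth = generate_knowledgebase(SMALL)
        union = set().union(*(set(v) for v in truth.layer_chemicals.values()))
        assert truth.n_unique_chemicals == len(union)

    def test_infeasible_category_rejected(self):
        with pytest.raises(ValueError, match="exceeds universe"):
            SyntheticConfig(universe_N=50, category_sizes=(60,))

    def test_planted_positive_beats_median_background(self):
        kb, truth = generate_knowledgebase(SyntheticConfig(seed=12))
        cfg = LayerConfig(related_diseases=kb.related)
        from toxrank.layers import (
            disease_layer_scores,
            filter_disease_associations,
            literature_score,
        )

        g = gwas_layer_scores(filter_protein_interactions(kb.interactions, cfg),
                              kb.disease_genes)
        d = disease_layer_scores(filter_disease_associations(kb.associations, cfg),
                                 kb.related)
        lit = {c.chemical_id: literature_score(c.chemical_id, kb.literature)
               for c in kb.chemicals}
        rows = build_score_table(
            kb.chemicals, d.scores, g.scores, lit,
            IntegrationConfig(require_literature=False),
        )
        scores = {r.chemical_id: r.combined_score for r in rows}
        planted = set(truth.planted_positive_ids)
        bg = [s for c, s in scores.items() if c not in planted]
        for cid in planted & set(scores):
            assert scores[cid] > float(np.median(bg))


class TestGenerateNetwork:
    def test_enrichment_factor_inflates_overlap(self):
        universe = [f"g{i}" for i in range(400)]
        cat = frozenset(universe[:40])
        rng_null, rng_rho = np.random.default_rng(5), np.random.default_rng(5)
        null_k = [len(generate_network(rng_null, universe, cat, 15, 1.0) & cat)
                  for _ in range(40)]
        rho_k = [len(generate_network(rng_rho, universe, cat, 15, 4.0) & cat)
                 for _ in range(40)]
        assert np.mean(rho_k) > np.mean(null_k)

    def test_draw_is_without_replacement(self):
        rng = np.random.default_rng(0)
        net = generate_network(rng, [f"g{i}" for i in range(30)], frozenset(), 30, 1.0)
        assert len(net) == 30


class TestTable1Fixture:
    def test_sensitivity_to_numerators(self):
        """Perturbing a planted numerator by +1 must change a printed score."""
        from toxrank.layers import (
            disease_layer_scores,
            filter_disease_associations,
        )

        def scores(kb):
            cfg = LayerConfig(related_diseases=kb.related)
            g = gwas_layer_scores(
                filter_protein_interactions(kb.interactions, cfg), kb.disease_genes
            )
            return {c: round(s, 3) for c, s in g.scores.items()}

        base = scores(table1_fixture())
        k_genes, k_dis = TABLE1_NUMERATORS["TCDD"]
        bumped = scores(table1_fixture({"TCDD": (k_genes + 1, k_dis)}))
        assert base["TCDD"] != bumped["TCDD"]

    def test_snp_rows_collapse_onto_gene_panel(self, table1_kb):
        assert len(table1_kb.disease_genes) == 60  # SNP rows
        assert len({g.gene_symbol for g in table1_kb.disease_genes}) == 54


class TestTable2Fixture:
    def test_network_sizes_match_published_counts(self, table2_networks_db):
        networks, _ = table2_networks_db
        sizes = {c: len(net) for c, net in networks.items()}
        assert sizes == {"Arsenic": 16, "HCB": 8, "TCDD": 65, "PFOA": 27}

    def test_category_sizes_and_universe(self, table2_networks_db):
        _, db = table2_networks_db
        assert db.universe_size == 5515
        assert len(db.categories["diabetes_mellitus"]) == 206
        assert len(db.categories["niddm"]) == 228

    def test_overlap_invariants_hold(self, table2_networks_db):
        networks, db = table2_networks_db
        for net in networks.values():
            for r in enrich_network(net, db):
                assert r.overlap_k <= min(r.draw_n, r.category_K)

    def test_published_overlap_counts(self, table2_networks_db):
        networks, db = table2_networks_db
        expected = {
            ("Arsenic", "diabetes_mellitus"): 9, ("Arsenic", "niddm"): 7,
            ("PFOA", "diabetes_mellitus"): 12, ("PFOA", "niddm"): 13,
            ("TCDD", "diabetes_mellitus"): 26, ("TCDD", "niddm"): 26,
            ("HCB", "diabetes_mellitus"): 5, ("HCB", "niddm"): 3,
        }
        for (chem, cat), k in expected.items():
            overlap = networks[chem].gene_symbols & db.categories[cat]
            assert len(overlap) == k
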