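"""Seeded synthetic knowledgebases with planted ground truth.

No deposited snapshot of the source databases (disease-gene lists,
chemical-protein interactions, chemical-disease associations, the
diseasome, the review chemical list, gene-set collections) exists, so
every pipeline stage is exercised against generated knowledgebases that
emulate their statistical structure:

* a disease-gene panel of SNP-derived and OMIM genes, all with
  admissible minor allele frequencies;
* chemicals with classes (environmental / drug / natural), a planted
  subset of true positives whose interaction and association
  probabilities are elevated over background;
* literature-inferred association scores drawn from a right-skewed
  gamma distribution straddling the score cutoff, so a predictable
  fraction of inferred links survives filtering;
* gene-set databases whose planted networks draw members from target
  categories with probability inflated by an enrichment factor rho
  (rho = 1 is the null).

Ground truth (which chemicals were planted, their layer memberships and
category overlaps) is emitted as a JSON sidecar so tests never
reverse-engineer the generator.  Identical seeds give byte-identical
output files.

Two deterministic fixtures reproduce the published case-study tables:
:func:`table1_fixture` (the ranked ten-candidate table) and
:func:`table2_fixture` (the four chemical networks and the disease
gene-set database they were tested against).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from . import io as tio
from .layers import (
    LayerConfig,
    disease_layer_scores,
    filter_disease_associations,
    filter_protein_interactions,
    gwas_layer_scores,
)
from .records import (
    ChemicalDiseaseAssociation,
    ChemicalGeneNetwork,
    ChemicalProteinInteraction,
    ChemicalRecord,
    DiseaseGeneRecord,
    DiseasomeEdge,
    EvidenceScoreRow,
    GeneSetDatabase,
    LiteratureChemicalList,
    RelatedDiseaseSet,
)

__all__ = [
    "SyntheticConfig",
    "KnowledgeBase",
    "GroundTruth",
    "generate_knowledgebase",
    "generate_network",
    "table1_fixture",
    "table2_fixture",
    "TABLE1_NUMERATORS",
    "TABLE1_EXPECTED",
]


@dataclass(frozen=True)
class SyntheticConfig:
    """Generator settings; defaults mirror the case study's conditions
    (60 SNPs collapsing to 54 chemically annotated genes, 8 related
    diseases, a 5515-gene disease universe with 206/228-gene
    categories) with a planted signal strong enough to be recoverable
    (hit probability 5x background, enrichment factor 3)."""

    n_snps: int = 60
    n_disease_genes: int = 54
    n_chemicals: int = 60
    n_related_diseases: int = 8
    n_diseasome_neighbors: int = 22
    n_planted_positives: int = 10
    universe_N: int = 5515
    category_sizes: tuple[int, ...] = (206, 228)
    network_size: int = 25
    enrichment_factor: float = 3.0  # rho; 1.0 is the null
    p_hit_planted: float = 0.10
    p_hit_background: float = 0.02
    p_disease_planted: float = 0.50
    p_disease_background: float = 0.08
    inference_shape: float = 2.0  # gamma shape
    inference_scale: float = 3.0  # gamma scale: mean 6, substantial mass < 5
    literature_noise: float = 0.10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_planted_positives > self.n_chemicals:
            raise ValueError("cannot plant more positives than chemicals")
        if self.n_disease_genes > self.n_snps:
            raise ValueError("SNPs collapse onto genes: need n_snps >= n_disease_genes")
        for size in self.category_sizes:
            if size > self.universe_N:
                raise ValueError(f"category size {size} exceeds universe {self.universe_N}")
        if self.enrichment_factor < 1.0:
            raise ValueError("enrichment_factor must be >= 1 (1 = null)")


@dataclass
class KnowledgeBase:
    """All tables of one synthetic knowledgebase, in memory, plus a
    writer emitting the exact file formats the readers consume."""

    disease_genes: list[DiseaseGeneRecord]
    chemicals: list[ChemicalRecord]
    interactions: list[ChemicalProteinInteraction]
    associations: list[ChemicalDiseaseAssociation]
    diseasome: list[DiseasomeEdge]
    related: RelatedDiseaseSet
    literature: LiteratureChemicalList
    gene_sets: list[GeneSetDatabase] = field(default_factory=list)
    networks: dict[str, ChemicalGeneNetwork] = field(default_factory=dict)
    provenance: str = ""

    def write(self, outdir: str | Path) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        header = f"# {self.provenance}\n" if self.provenance else ""
        paths: dict[str, Path] = {}

        def _table(name: str, columns: list[str], rows: list[list]) -> None:
            p = outdir / f"{name}.tsv"
            with open(p, "w") as fh:
                fh.write(header)
                fh.write("\t".join(columns) + "\n")
                for row in rows:
                    fh.write("\t".join("" if v is None else str(v) for v in row) + "\n")
            paths[name] = p

        _table(
            "disease_genes",
            ["gene_symbol", "snp_id", "maf", "source"],
            [[g.gene_symbol, g.snp_id, g.maf, g.source] for g in self.disease_genes],
        )
        _table(
            "chemicals",
            ["chemical_id", "name", "chem_class"],
            [[c.chemical_id, c.name, c.chem_class] for c in self.chemicals],
        )
        _table(
            "protein_interactions",
            ["chemical_id", "gene_symbol", "species", "confidence", "negated", "cotreatment"],
            [
                [i.chemical_id, i.gene_symbol, i.species, i.confidence,
                 int(i.negated), int(i.cotreatment)]
                for i in self.interactions
            ],
        )
        _table(
            "disease_associations",
            ["chemical_id", "disease_id", "evidence_type", "inference_score"],
            [
                [a.chemical_id, a.disease_id, a.evidence_type, a.inference_score]
                for a in self.associations
            ],
        )
        _table(
            "diseasome",
            ["disease_a", "disease_b", "shared_gene_count"],
            [[e.disease_a, e.disease_b, e.shared_gene_count] for e in self.diseasome],
        )
        _table(
            "related_diseases",
            ["target_disease", "member"],
            [[self.related.target_disease, m] for m in sorted(self.related.members)],
        )
        _table(
            "literature_chemicals",
            ["chemical_id"],
            [[c] for c in sorted(self.literature.chemical_ids)],
        )
        for db in self.gene_sets:
            p = outdir / f"{db.db_name}.gmt"
            tio.write_gene_sets(db, p)
            paths[db.db_name] = p
            sidecar = outdir / f"{db.db_name}.universe.json"
            sidecar.write_text(
                json.dumps(
                    {
                        "db_name": db.db_name,
                        "universe_size": db.universe_size,
                        "universe_genes": sorted(db.universe_genes)
                        if db.universe_genes is not None
                        else None,
                    },
                    indent=1,
                )
            )
            paths[f"{db.db_name}_universe"] = sidecar
        if self.networks:
            _table(
                "chemical_networks",
                ["chemical_id", "gene_symbol"],
                [
                    [cid, g]
                    for cid in sorted(self.networks)
                    for g in sorted(self.networks[cid].gene_symbols)
                ],
            )
        return paths


@dataclass
class GroundTruth:
    """What the generator planted, recorded for recovery tests."""

    planted_positive_ids: list[str]
    layer_chemicals: dict[str, list[str]]  # layer name -> chemical ids
    gwas_numerators: dict[str, int]
    gwas_denominator: int
    disease_degrees: dict[str, int]
    network_overlaps: dict[str, dict[str, int]]  # chemical -> category -> k
    n_unique_chemicals: int

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        return cls(**json.loads(Path(path).read_text()))


def _draw_without_replacement(
    rng: np.random.Generator, pool: list[str], k: int
) -> list[str]:
    idx = rng.choice(len(pool), size=k, replace=False)
    return [pool[i] for i in sorted(idx)]


def generate_network(
    rng: np.random.Generator,
    universe: list[str],
    target_category: frozenset[str],
    size: int,
    rho: float,
) -> frozenset[str]:
    """Draw one chemical gene network of ``size`` genes without
    replacement, with per-gene probability of coming from the target
    category inflated by ``rho`` (rho = 1 reduces to a uniform draw)."""
    in_cat = [g for g in universe if g in target_category]
    out_cat = [g for g in universe if g not in target_category]
    p_cat = min(1.0, rho * len(in_cat) / len(universe))
    chosen: set[str] = set()
    cat_pool = list(in_cat)
    out_pool = list(out_cat)
    for _ in range(size):
        take_cat = rng.random() < p_cat and cat_pool
        pool = cat_pool if take_cat else out_pool
        if not pool:
            pool = cat_pool or out_pool
        i = int(rng.integers(len(pool)))
        chosen.add(pool.pop(i))
    return frozenset(chosen)


def generate_knowledgebase(
    config: SyntheticConfig, outdir: str | Path | None = None
) -> tuple[KnowledgeBase, GroundTruth]:
    """Generate a full synthetic knowledgebase and its ground truth.

    All emitted tables pass the readers' validation with zero rejected
    rows.  Flagged interaction rows (wrong species, low confidence,
    negated, co-treatment) are planted as filterable noise, never as
    invalid rows.  When ``outdir`` is given, tables and the ground-truth
    sidecar are written there; the same seed yields byte-identical files.
    """
    rng = np.random.default_rng(config.seed)

    # --- disease-gene panel: n_snps SNPs collapsing onto n_disease_genes genes
    genes = [f"DGENE{i + 1:03d}" for i in range(config.n_disease_genes)]
    snp_genes = genes + [
        genes[i % len(genes)] for i in range(config.n_snps - len(genes))
    ]
    disease_genes = []
    for j, gene in enumerate(snp_genes):
        maf = float(np.round(rng.uniform(0.055, 0.5), 4))
        disease_genes.append(
            DiseaseGeneRecord(gene, "gwa_literature", snp_id=f"rs{7000 + j}", maf=maf)
        )
    # a few OMIM-sourced duplicates (no SNP, no MAF requirement)
    for gene in genes[:3]:
        disease_genes.append(DiseaseGeneRecord(gene, "omim"))

    # --- chemicals and classes
    chem_ids = [f"CHEM{i + 1:03d}" for i in range(config.n_chemicals)]
    planted = chem_ids[: config.n_planted_positives]
    chemicals = []
    for cid in chem_ids:
        if cid in planted:
            cls = "environmental"
        else:
            cls = rng.choice(["environmental", "drug", "natural"], p=[0.6, 0.25, 0.15])
        chemicals.append(ChemicalRecord(cid, f"compound {cid.lower()}", str(cls)))

    # --- chemical-protein interactions
    interactions: list[ChemicalProteinInteraction] = []
    for cid in chem_ids:
        p = config.p_hit_planted if cid in planted else config.p_hit_background
        hits = [g for g in genes if rng.random() < p]
        if cid in planted and not hits:
            hits = [genes[int(rng.integers(len(genes)))]]
        for g in hits:
            interactions.append(ChemicalProteinInteraction(cid, g))
        # filterable noise: low-confidence, non-human, negated statements
        if rng.random() < 0.3:
            g = genes[int(rng.integers(len(genes)))]
            kind = int(rng.integers(3))
            interactions.append(
                ChemicalProteinInteraction(
                    cid,
                    g,
                    species="rat" if kind == 0 else "human",
                    confidence="low" if kind == 1 else "high",
                    negated=kind == 2,
                )
            )
    # guarantee every disease gene is chemically annotated (stable denominator)
    covered = {i.gene_symbol for i in filter_protein_interactions(interactions, LayerConfig())}
    background = [c for c in chem_ids if c not in planted] or chem_ids
    for j, g in enumerate(gene for gene in genes if gene not in covered):
        interactions.append(ChemicalProteinInteraction(background[j % len(background)], g))

    # --- diseasome and related diseases
    target = "T2D"
    neighbors = [f"DIS{i + 1:02d}" for i in range(config.n_diseasome_neighbors)]
    diseasome = [
        DiseasomeEdge(target, d, int(rng.integers(1, 11))) for d in neighbors
    ]
    related = RelatedDiseaseSet(
        target_disease=target, members=frozenset(neighbors[: config.n_related_diseases])
    )

    # --- chemical-disease associations (curated + score-bearing inferred)
    associations: list[ChemicalDiseaseAssociation] = []
    for cid in chem_ids:
        p = config.p_disease_planted if cid in planted else config.p_disease_background
        for dis in neighbors:
            p_eff = p if dis in related.members else config.p_disease_background / 2
            if rng.random() >= p_eff:
                continue
            u = rng.random()
            if u < 0.3:
                associations.append(ChemicalDiseaseAssociation(cid, dis, "marker_mechanism"))
            elif u < 0.5:
                associations.append(ChemicalDiseaseAssociation(cid, dis, "therapeutic"))
            else:
                score = float(
                    np.round(rng.gamma(config.inference_shape, config.inference_scale), 3)
                )
                associations.append(
                    ChemicalDiseaseAssociation(cid, dis, "inferred_literature", score)
                )

    # --- literature list: planted positives plus noise
    n_noise = int(round(config.literature_noise * (config.n_chemicals - len(planted))))
    noise = _draw_without_replacement(rng, background, min(n_noise, len(background)))
    literature = LiteratureChemicalList(chemical_ids=frozenset(planted) | frozenset(noise))

    # --- gene-set database and per-chemical networks
    universe = [f"GENE{i + 1:05d}" for i in range(config.universe_N)]
    categories: dict[str, frozenset[str]] = {}
    for ci, size in enumerate(config.category_sizes):
        categories[f"category_{ci + 1:02d}"] = frozenset(
            _draw_without_replacement(rng, universe, size)
        )
    db = GeneSetDatabase(
        db_name="synthetic_gene_sets",
        universe_size=config.universe_N,
        categories=categories,
        universe_genes=frozenset(universe),
    )
    target_cat = categories[next(iter(sorted(categories)))]
    networks = {}
    for cid in chem_ids:
        rho = config.enrichment_factor if cid in planted else 1.0
        networks[cid] = ChemicalGeneNetwork(
            cid, generate_network(rng, universe, target_cat, config.network_size, rho)
        )

    kb = KnowledgeBase(
        disease_genes=disease_genes,
        chemicals=chemicals,
        interactions=interactions,
        associations=associations,
        diseasome=diseasome,
        related=related,
        literature=literature,
        gene_sets=[db],
        networks=networks,
        provenance=(
            "toxrank.simulate generate_knowledgebase "
            + " ".join(f"{k}={v}" for k, v in sorted(asdict(config).items()))
        ),
    )

    # --- ground truth, derived from the emitted tables under default filters
    layer_cfg = LayerConfig(related_diseases=related)
    fint = filter_protein_interactions(interactions, layer_cfg)
    fassoc = filter_disease_associations(associations, layer_cfg)
    gaudit = gwas_layer_scores(fint, disease_genes)
    daudit = disease_layer_scores(fassoc, related)
    layer_chems = {
        "gwa": sorted({i.chemical_id for i in fint}),
        "disease": sorted({a.chemical_id for a in fassoc}),
        "literature": sorted(literature.chemical_ids),
    }
    truth = GroundTruth(
        planted_positive_ids=list(planted),
        layer_chemicals=layer_chems,
        gwas_numerators=dict(sorted(gaudit.numerators.items())),
        gwas_denominator=gaudit.denominator,
        disease_degrees=dict(sorted(daudit.numerators.items())),
        network_overlaps={
            cid: {
                name: len(networks[cid].gene_symbols & members)
                for name, members in sorted(categories.items())
            }
            for cid in chem_ids
        },
        n_unique_chemicals=len(set().union(*map(set, layer_chems.values()))),
    )

    if outdir is not None:
        kb.write(outdir)
        truth.to_json(Path(outdir) / "ground_truth.json")
    return kb, truth


# ---------------------------------------------------------------------------
# Case-study fixtures
# ---------------------------------------------------------------------------

#: Layer numerators reproducing the published ranked table: for each
#: chemical, (disease genes interacted with, of 54; related diseases
#: linked, of 8).  Each numerator is the unique integer whose fraction
#: rounds to the printed three-decimal layer score.
TABLE1_NUMERATORS: dict[str, tuple[int, int]] = {
    "TCDD": (31, 2),
    "HCB": (1, 4),
    "Bisphenol A": (9, 2),
    "DDT": (1, 3),
    "PFOA": (7, 2),
    "PFOS": (7, 2),
    "MBP": (1, 2),
    "Arsenic": (6, 1),
    "Dioxins": (1, 1),
    "MEHP": (1, 1),
}

#: The published ranked table: printed three-decimal scores and ranks.
TABLE1_EXPECTED: list[EvidenceScoreRow] = [
    EvidenceScoreRow("TCDD", 0.250, 0.574, 0.412, 1, 1),
    EvidenceScoreRow("HCB", 0.500, 0.019, 0.259, 1, 2),
    EvidenceScoreRow("Bisphenol A", 0.250, 0.167, 0.208, 1, 3),
    EvidenceScoreRow("DDT", 0.375, 0.019, 0.197, 1, 4),
    EvidenceScoreRow("PFOA", 0.250, 0.130, 0.190, 1, 5),
    EvidenceScoreRow("PFOS", 0.250, 0.130, 0.190, 1, 6),
    EvidenceScoreRow("MBP", 0.250, 0.019, 0.134, 1, 7),
    EvidenceScoreRow("Arsenic", 0.125, 0.111, 0.118, 1, 8),
    EvidenceScoreRow("Dioxins", 0.125, 0.019, 0.072, 1, 9),
    EvidenceScoreRow("MEHP", 0.125, 0.019, 0.072, 1, 10),
]


def table1_fixture(
    numerator_override: dict[str, tuple[int, int]] | None = None,
) -> KnowledgeBase:
    """Minimal knowledgebase reproducing the published candidate table.

    The ten case-study chemicals carry exactly the recovered layer
    numerators (gene interactions out of 54 annotated disease genes,
    disease links out of 8 related diseases).  A drug-class anchor
    chemical interacts with all 54 genes so the GWA denominator is 54
    even though the candidates' gene sets do not cover the panel; the
    class filter removes it from the ranked output.
    ``numerator_override`` perturbs numerators for sensitivity checks.
    """
    numerators = dict(TABLE1_NUMERATORS)
    if numerator_override:
        numerators.update(numerator_override)

    genes = [f"G{i + 1:02d}" for i in range(54)]
    snp_genes = genes + genes[:6]  # 60 SNPs over 54 genes
    disease_genes = [
        DiseaseGeneRecord(g, "gwa_literature", snp_id=f"rs{i + 1:04d}", maf=0.10)
        for i, g in enumerate(snp_genes)
    ]
    diseases = [f"related_disease_{i + 1}" for i in range(8)]
    related = RelatedDiseaseSet(target_disease="T2D", members=frozenset(diseases))

    chemicals = [ChemicalRecord(name, name, "environmental") for name in numerators]
    chemicals.append(ChemicalRecord("Metformin", "Metformin", "drug"))

    interactions = []
    for name, (k_genes, _) in numerators.items():
        for g in genes[:k_genes]:
            interactions.append(ChemicalProteinInteraction(name, g))
    for g in genes:  # anchor: makes every panel gene chemically annotated
        interactions.append(ChemicalProteinInteraction("Metformin", g))

    associations = []
    for name, (_, k_dis) in numerators.items():
        for d in diseases[:k_dis]:
            associations.append(ChemicalDiseaseAssociation(name, d, "marker_mechanism"))
    associations.append(
        ChemicalDiseaseAssociation("Metformin", diseases[0], "therapeutic")
    )

    diseasome = [DiseasomeEdge("T2D", d, 3) for d in diseases] + [
        DiseasomeEdge("T2D", f"other_disease_{i}", 1) for i in range(1, 15)
    ]
    return KnowledgeBase(
        disease_genes=disease_genes,
        chemicals=chemicals,
        interactions=interactions,
        associations=associations,
        diseasome=diseasome,
        related=related,
        literature=LiteratureChemicalList(frozenset(numerators)),
        provenance="toxrank.simulate table1_fixture",
    )


# Printed per-chemical overlap gene lists for the disease database
# (diabetes mellitus: 206 of 5515 genes; NIDDM: 228 of 5515).
_T2_DIABETES_OVERLAPS: dict[str, frozenset[str]] = {
    "Arsenic": frozenset(
        "GCK HMOX1 LEP LEPR NFKB1 PPARA TNFRSF1A CAT ADIPOQ".split()
    ),
    "PFOA": frozenset(
        "CPT1A GCK HMOX1 LEPR NFKB1 PPARA PPARG SLC2A2 TNFRSF1A C3 UCP2 CAT".split()
    ),
    "TCDD": frozenset(
        "CPT1A EDN1 AKT2 GCK HMOX1 HNF4A HP IRS1 KCNJ11 LEP LEPR NFKB1 ENPP1 "
        "PPARA PPARG RETN PTPN1 SLC2A1 SLC2A2 SLC2A4 TNFRSF1A C3 UCP2 WFS1 "
        "CAT ADIPOQ".split()
    ),
    "HCB": frozenset("HMOX1 HP IRS1 TNFRSF1A CAT".split()),
}
_T2_NIDDM_OVERLAPS: dict[str, frozenset[str]] = {
    "Arsenic": frozenset("PPARGC1A GCK LEP LEPR PPARA CAT ADIPOQ".split()),
    "PFOA": frozenset(
        "PPARGC1A CPT1A GCGR GCK GCKR GPD2 LEPR LIPC PPARA PPARG SLC2A2 "
        "UCP2 CAT".split()
    ),
    "TCDD": frozenset(
        "PPARGC1A CPT1A EDN1 GCK GCKR GPD2 HNF4A IRS1 KCNJ11 LEP LEPR LIPC "
        "PAX4 ENPP1 PPARA PPARG RETN PTPN1 SLC2A1 SLC2A2 SLC2A4 TCF7L2 UCP2 "
        "CAT IRS2 ADIPOQ".split()
    ),
    "HCB": frozenset("IL6 IRS1 CAT".split()),
}
#: published curated-network sizes for the four focus chemicals
TABLE2_NETWORK_SIZES = {"Arsenic": 16, "HCB": 8, "TCDD": 65, "PFOA": 27}
_T2_UNIVERSE_N = 5515
_T2_CATEGORY_SIZES = {"diabetes_mellitus": 206, "niddm": 228}


def table2_fixture() -> tuple[dict[str, ChemicalGeneNetwork], GeneSetDatabase]:
    """Networks and gene-set database reproducing the published
    enrichment table.

    Each chemical's network contains exactly the printed overlap genes
    for both disease categories, padded to its published size with
    synthetic filler genes outside both categories; each category is
    padded to its published size (206 / 228 genes, universe 5515) with
    synthetic fillers outside every network.  Construction asserts the
    resulting overlaps equal the printed gene lists.
    """
    categories = {}
    for name, size, overlaps in (
        ("diabetes_mellitus", 206, _T2_DIABETES_OVERLAPS),
        ("niddm", 228, _T2_NIDDM_OVERLAPS),
    ):
        printed = frozenset().union(*overlaps.values())
        fillers = frozenset(
            f"SYN_{name.upper()}_{i + 1:04d}" for i in range(size - len(printed))
        )
        categories[name] = printed | fillers

    networks = {}
    for chem, size in TABLE2_NETWORK_SIZES.items():
        core = _T2_DIABETES_OVERLAPS[chem] | _T2_NIDDM_OVERLAPS[chem]
        fillers = frozenset(
            f"SYN_{chem.upper()}_NET_{i + 1:04d}" for i in range(size - len(core))
        )
        networks[chem] = ChemicalGeneNetwork(chem, core | fillers)

    db = GeneSetDatabase(
        db_name="synthetic_disease_db",
        universe_size=_T2_UNIVERSE_N,
        categories={k: frozenset(v) for k, v in categories.items()},
        universe_genes=None,  # draw size = full network size against declared N
    )
    for chem, net in networks.items():
        assert net.gene_symbols & db.categories["diabetes_mellitus"] == _T2_DIABETES_OVERLAPS[chem]
        assert net.gene_symbols & db.categories["niddm"] == _T2_NIDDM_OVERLAPS[chem]
        assert len(net.gene_symbols) == TABLE2_NETWORK_SIZES[chem]
    return networks, db
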