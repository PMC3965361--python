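"""End-to-end workflow stages behind the command-line interface.

The workflow is a fixed DAG — simulate (optional) → filter → layer
scores → integration → ranked table, and separately network enrichment
and bipartite-network export — so it is configured declaratively: one
YAML/JSON file with per-stage sections rather than per-stage flags.
Every stage logs its input/output row counts (the filter audit trail),
writes parse reports next to its outputs, and never mutates its inputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

from . import io as tio
from .enrich import EnrichmentConfig, enrich_network, write_enrichment_report
from .integrate import IntegrationConfig, build_score_table, count_unique_chemicals
from .layers import (
    LayerConfig,
    disease_layer_scores,
    filter_disease_associations,
    filter_protein_interactions,
    gwas_layer_scores,
    literature_score,
)
from .network import build_network, chemical_gene_matrix, degree_clusters, export_network
from .records import ChemicalGeneNetwork, EvidenceScoreRow
from .simulate import SyntheticConfig, generate_knowledgebase

__all__ = ["PipelineConfig", "run_simulate", "run_rank", "run_enrich", "run_export_network"]

log = logging.getLogger("toxrank")


@dataclass
class PipelineConfig:
    """Parsed pipeline configuration (see ``PipelineConfig.load``)."""

    inputs: dict[str, Any] = field(default_factory=dict)
    output_dir: Path = Path("toxrank_out")
    layer: dict[str, Any] = field(default_factory=dict)
    integration: dict[str, Any] = field(default_factory=dict)
    enrichment: dict[str, Any] = field(default_factory=dict)
    simulate: dict[str, Any] = field(default_factory=dict)
    log_level: str = "INFO"
    config_hash: str = ""

    @classmethod
    def load(cls, path: str | Path) -> "PipelineConfig":
        text = Path(path).read_text()
        data = yaml.safe_load(text) or {}
        cfg = cls(
            inputs=data.get("inputs", {}),
            output_dir=Path(data.get("output_dir", "toxrank_out")),
            layer=data.get("layer", {}),
            integration=data.get("integration", {}),
            enrichment=data.get("enrichment", {}),
            simulate=data.get("simulate", {}),
            log_level=data.get("log_level", "INFO"),
            config_hash=hashlib.sha256(text.encode()).hexdigest()[:16],
        )
        logging.basicConfig(level=cfg.log_level)
        log.info("config %s loaded (sha256 %s)", path, cfg.config_hash)
        return cfg

    def input_path(self, key: str) -> Path:
        try:
            p = Path(self.inputs[key])
        except KeyError:
            raise FileNotFoundError(f"config inputs.{key} is not set") from None
        if not p.exists():
            raise FileNotFoundError(f"input {key}: {p} does not exist")
        log.info("input %s = %s (sha256 %s)", key, p, _checksum(p))
        return p

    def layer_config(self, related) -> LayerConfig:
        return LayerConfig(
            inference_cutoff=float(self.layer.get("inference_cutoff", 5.0)),
            strict_cutoff=bool(self.layer.get("strict_cutoff", False)),
            require_high_confidence=bool(self.layer.get("require_high_confidence", True)),
            restrict_species=self.layer.get("restrict_species", "human"),
            related_diseases=related,
        )

    def integration_config(self) -> IntegrationConfig:
        return IntegrationConfig(
            exclude_classes=frozenset(
                self.integration.get("exclude_classes", ["drug", "natural"])
            ),
            require_literature=bool(self.integration.get("require_literature", True)),
            score_decimals=int(self.integration.get("score_decimals", 3)),
        )

    def enrichment_config(self) -> EnrichmentConfig:
        return EnrichmentConfig(
            bonferroni_m=self.enrichment.get("bonferroni_m", "auto"),
            restrict_to_universe=bool(self.enrichment.get("restrict_to_universe", True)),
            alpha_report=float(self.enrichment.get("alpha_report", 0.05)),
        )


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def run_simulate(config: PipelineConfig, seed_override: int | None = None) -> Path:
    """Generate a synthetic knowledgebase into the output directory."""
    params = dict(config.simulate)
    if seed_override is not None:
        params["seed"] = seed_override
    if "category_sizes" in params:
        params["category_sizes"] = tuple(params["category_sizes"])
    syn = SyntheticConfig(**params)
    outdir = config.output_dir
    generate_knowledgebase(syn, outdir=outdir)
    log.info("synthetic knowledgebase written to %s (seed %s)", outdir, syn.seed)
    return outdir


def run_rank(config: PipelineConfig) -> list[EvidenceScoreRow]:
    """Filters → layer scores → integration → ranked candidate table.

    Writes the ranked table, per-layer audit tables, the chemical-gene
    incidence matrix and parse reports into the output directory.
    """
    outdir = config.output_dir
    outdir.mkdir(parents=True, exist_ok=True)

    gene_report = tio.ParseReport()
    assoc_report = tio.ParseReport()
    disease_genes = tio.read_disease_genes(config.input_path("disease_genes"), gene_report)
    chemicals = tio.read_chemicals(config.input_path("chemicals"))
    interactions = tio.read_protein_interactions(config.input_path("protein_interactions"))
    associations = tio.read_disease_associations(
        config.input_path("disease_associations"), assoc_report
    )
    related = tio.read_related_diseases(config.input_path("related_diseases"))
    literature = tio.read_literature_list(config.input_path("literature"))
    gene_report.write(outdir / "parse_report_disease_genes.tsv")
    assoc_report.write(outdir / "parse_report_disease_associations.tsv")

    layer_cfg = config.layer_config(related)
    fint = filter_protein_interactions(interactions, layer_cfg)
    log.info("protein interactions: %d in, %d after filters", len(interactions), len(fint))
    fassoc = filter_disease_associations(associations, layer_cfg)
    log.info("disease associations: %d in, %d after filters", len(associations), len(fassoc))

    if not chemicals:
        log.warning("chemical table is empty; writing header-only score table")
        tio.write_score_table([], outdir / "score_table.tsv")
        return []

    gaudit = gwas_layer_scores(fint, disease_genes)
    daudit = disease_layer_scores(fassoc, related)
    log.info(
        "GWA layer: %d chemicals, denominator %d annotated disease genes",
        len(gaudit.scores), gaudit.denominator,
    )
    log.info(
        "disease layer: %d chemicals, denominator %d related diseases",
        len(daudit.scores), daudit.denominator,
    )
    lit_scores = {c.chemical_id: literature_score(c.chemical_id, literature) for c in chemicals}
    n_union = count_unique_chemicals(
        set(gaudit.scores), set(daudit.scores), set(literature.chemical_ids)
    )
    log.info("unique chemicals across the three layers: %d", n_union)

    for name, audit in (("gwa", gaudit), ("disease", daudit)):
        with open(outdir / f"layer_{name}_audit.tsv", "w") as fh:
            fh.write("chemical\tscore\tnumerator\tdenominator\n")
            for chem, score, num, den in audit.rows:
                fh.write(f"{chem}\t{score:.6f}\t{num}\t{den}\n")

    decimals = config.integration_config().score_decimals
    rows = build_score_table(
        chemicals, daudit.scores, gaudit.scores, lit_scores, config.integration_config()
    )
    tio.write_score_table(rows, outdir / "score_table.tsv", decimals=decimals)
    chemical_gene_matrix(fint, outdir / "chemical_gene_matrix.tsv")
    log.info("ranked %d candidate chemicals -> %s", len(rows), outdir / "score_table.tsv")
    return rows


def _load_networks(path: Path) -> dict[str, ChemicalGeneNetwork]:
    import pandas as pd

    df = pd.read_csv(path, sep="\t", comment="#", dtype=str, keep_default_na=False)
    grouped: dict[str, set[str]] = {}
    for row in df.itertuples(index=False):
        grouped.setdefault(row.chemical_id, set()).add(row.gene_symbol)
    return {cid: ChemicalGeneNetwork(cid, frozenset(genes)) for cid, genes in grouped.items()}


def _load_gene_sets(config: PipelineConfig) -> list:
    dbs = []
    for entry in config.inputs.get("gene_sets", []):
        gmt = Path(entry["gmt"])
        universe_genes = None
        universe_size = entry.get("universe_size")
        if "universe_json" in entry:
            meta = json.loads(Path(entry["universe_json"]).read_text())
            universe_size = meta["universe_size"]
            universe_genes = meta.get("universe_genes")
        if universe_size is None:
            raise ValueError(f"gene set {gmt}: universe_size is required")
        dbs.append(
            tio.read_gene_sets(
                gmt,
                universe_size=int(universe_size),
                db_name=entry.get("db_name"),
                universe_genes=universe_genes,
            )
        )
    if not dbs:
        raise FileNotFoundError("config inputs.gene_sets lists no databases")
    return dbs


def run_enrich(config: PipelineConfig) -> dict[tuple[str, str], list]:
    """Per-chemical, per-database over-representation reports.

    Each database is an independent Bonferroni family.  Raises when a
    network exceeds a database's declared universe, naming the chemical.
    """
    outdir = config.output_dir
    outdir.mkdir(parents=True, exist_ok=True)
    networks = _load_networks(config.input_path("networks"))
    dbs = _load_gene_sets(config)
    ecfg = config.enrichment_config()
    all_results: dict[tuple[str, str], list] = {}
    for db in dbs:
        db_rows = []
        for cid in sorted(networks):
            results = enrich_network(networks[cid], db, ecfg)
            all_results[(cid, db.db_name)] = results
            db_rows.extend(results)
            log.info(
                "enrichment %s vs %s: %d categories, min corrected p %.3g",
                cid, db.db_name, len(results),
                min(r.p_corrected for r in results),
            )
        write_enrichment_report(db_rows, outdir / f"enrichment_{db.db_name}.tsv",
                                alpha=ecfg.alpha_report)
    return all_results


def run_export_network(config: PipelineConfig, format: str = "sif") -> Path:
    """Filtered associations → bipartite network file + degree clusters."""
    outdir = config.output_dir
    outdir.mkdir(parents=True, exist_ok=True)
    associations = tio.read_disease_associations(config.input_path("disease_associations"))
    related = tio.read_related_diseases(config.input_path("related_diseases"))
    layer_cfg = config.layer_config(related)
    fassoc = filter_disease_associations(associations, layer_cfg)
    net = build_network(fassoc, related)
    out = outdir / f"disease_chemical_network.{format if format != 'tsv' else 'edges.tsv'}"
    export_network(net, out, format=format)
    clusters = degree_clusters(net)
    with open(outdir / "degree_clusters.tsv", "w") as fh:
        fh.write("degree\tchemical\n")
        for deg, chems in clusters.items():
            for chem in chems:
                fh.write(f"{deg}\t{chem}\n")
    log.info(
        "network: %d diseases, %d chemicals, %d edges -> %s",
        len(net.disease_nodes), len(net.chemical_nodes), len(net.edges), out,
    )
    return out
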