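from pathlib import Path

import pytest

from toxrank.layers import LayerConfig
from toxrank.simulate import table1_fixture, table2_fixture


@pytest.fixture(scope="session")
def table1_kb():
    return table1_fixture()


@pytest.fixture(scope="session")
def table2_networks_db():
    return table2_fixture()


@pytest.fixture()
def table1_dir(tmp_path, table1_kb):
    """The candidate-table knowledgebase written to disk."""
    table1_kb.write(tmp_path / "kb")
    return tmp_path / "kb"


@pytest.fixture()
def table1_config(tmp_path, table1_dir) -> Path:
    """A pipeline config YAML pointing at the on-disk fixture tables."""
    cfg = tmp_path / "config.yaml"
    kb = table1_dir
    cfg.write_text(
        f"""
output_dir: {tmp_path / "out"}
inputs:
  disease_genes: {kb / "disease_genes.tsv"}
  chemicals: {kb / "chemicals.tsv"}
  protein_interactions: {kb / "protein_interactions.tsv"}
  disease_associations: {kb / "disease_associations.tsv"}
  related_diseases: {kb / "related_diseases.tsv"}
  literature: {kb / "literature_chemicals.tsv"}
"""
    )
    return cfg


@pytest.fixture()
def default_layer_config(table1_kb) -> LayerConfig:
    return LayerConfig(related_diseases=table1_kb.related)
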