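"""Shared fixtures: one small synthetic panel reused across test modules."""

import pyfaidx
import pytest

from polyarray.panel_io import GeneModelSet, PanelConfig, load_panel
from polyarray.synthetic import SimConfig, generate_panel


@pytest.fixture(scope="session")
def small_config():
    return SimConfig(seed=11, ref_length=60_000, n_chromosomes=2)


@pytest.fixture(scope="session")
def panel(small_config, tmp_path_factory):
    out = tmp_path_factory.mktemp("panel")
    return generate_panel(small_config, out)


@pytest.fixture(scope="session")
def panel_table(panel):
    config = PanelConfig.from_yaml(panel.panel_yaml)
    paths = dict(zip(panel.file_ids, panel.vcf_paths))
    return load_panel(paths, config)


@pytest.fixture(scope="session")
def reference(panel):
    return pyfaidx.Fasta(str(panel.reference_fasta))


@pytest.fixture(scope="session")
def gene_models(panel):
    return GeneModelSet.from_gff3(panel.gff3)


@pytest.fixture(scope="session")
def diploid_table(panel):
    config = PanelConfig(file_ids=["F1D"], coverages=[36.0])
    return load_panel({"F1D": panel.diploid_vcf}, config)
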