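import pytest

from umicall import (PipelineConfig, SimulationParams, bundled_panel_path,
                     load_panel, simulate_sample, write_fastq)


@pytest.fixture(scope="session")
def nb_panel():
    return load_panel(bundled_panel_path("nb_alk"))


@pytest.fixture(scope="session")
def hras_panel():
    return load_panel(bundled_panel_path("hras_q61"))


@pytest.fixture(scope="session")
def clean_sim(hras_panel):
    """Error-free single-assay simulation: 500 molecules at VAF 0.1."""
    params = SimulationParams(
        molecules_per_assay=500, vaf_by_hotspot={"HRAS_Q61L": 0.1}, seed=11)
    reads, manifest = simulate_sample(hras_panel, params, sample_id="clean")
    return reads, manifest, params


@pytest.fixture()
def fastq_writer(tmp_path):
    def _write(reads, name="reads.fastq"):
        path = tmp_path / name
        write_fastq(reads, path)
        return path
    return _write


@pytest.fixture(scope="session")
def default_config():
    return PipelineConfig()
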