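import pytest

from spatialeqtl import SimConfig, generate_dataset, run_pipeline


@pytest.fixture(scope="session")
def dataset(tmp_path_factory):
    """One default synthetic study (12 traits, 3 clusters, 2 cell lines x 2 reps)."""
    root = tmp_path_factory.mktemp("study")
    return generate_dataset(SimConfig(seed=1), root)


@pytest.fixture(scope="session")
def pipeline_result(dataset):
    """Full pipeline run on the default study, including biclustering."""
    return run_pipeline(
        dataset.fasta,
        dataset.gtf,
        dataset.gwas,
        dataset.root / "interactions",
        dataset.eqtl,
        seed=1,
    )
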