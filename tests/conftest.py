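import warnings

import pytest

from splnet.pipeline import PipelineConfig, run_pipeline
from splnet.synthetic import (SimulationConfig, generate_protein_set,
                              generate_transcriptome, simulate_counts)


@pytest.fixture(scope="session")
def small_config():
    """Desk-scale synthetic study used by most unit tests."""
    return SimulationConfig(
        n_mrna=60, n_lncrna=20, n_circrna=8, n_mirna=6,
        n_background_mirna=30, n_spl_loci=6, n_truncated_decoys=3,
        n_random_decoys=3, seed=11,
    )


@pytest.fixture(scope="session")
def small_dataset(small_config):
    transcripts, truth = generate_transcriptome(small_config)
    counts = simulate_counts(truth, small_config)
    return transcripts, truth, counts


@pytest.fixture(scope="session")
def small_proteins(small_config):
    return generate_protein_set(small_config)


@pytest.fixture(scope="session")
def default_run(tmp_path_factory):
    """One full pipeline run at the default study size (300 mRNA /
    100 lncRNA / 30 circRNA / 12 miR156 members, 4 stages x 3 reps)."""
    outdir = tmp_path_factory.mktemp("default_run")
    config = PipelineConfig(
        synthetic=SimulationConfig(), outdir=str(outdir), seed=1,
        n_bootstrap=300,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        summary = run_pipeline(config)
    return config, summary
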