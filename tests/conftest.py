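import pytest

from mendiag import synthdata
from mendiag.mpps import fit_region_weights


@pytest.fixture(scope="session")
def small_benchmark():
    """400-variant labeled benchmark with random per-tool accuracies and
    missingness, plus fitted region weights (all seeded)."""
    truth, records = synthdata.simulate_truth_set(200, 200, seed=11)
    spec = synthdata.ToolAccuracySpec.random(seed=12)
    profiled = synthdata.simulate_tool_profiles(truth, records, spec, seed=13)
    weights = fit_region_weights(truth, profiled, min_n=50, seed=14)
    return truth, profiled, spec, weights


@pytest.fixture(scope="session")
def pheno_db():
    return synthdata.build_gene_phenotype_db(n_genes=120, n_diseases=80, seed=21)
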