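import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def toy_genome():
    from methylmorph import synthetic

    return synthetic.make_genome(
        n_chrom=1, chrom_len=30_000, gc_frac=0.4, n_genes=8, seed=11
    )


@pytest.fixture(scope="session")
def toy_study(toy_genome):
    """One small simulated study shared across read-only tests."""
    from methylmorph import pipeline, synthetic

    truth = synthetic.simulate_methylome(toy_genome, seed=12)
    wgbs = synthetic.simulate_wgbs(truth, toy_genome, mean_cov=30.0, n_reps=3, seed=13)
    return toy_genome, truth, wgbs


@pytest.fixture(scope="session")
def toy_result(toy_study):
    from methylmorph import pipeline

    return pipeline.run_methylation_pipeline(*toy_study)
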