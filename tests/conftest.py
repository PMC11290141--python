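import numpy as np
import pytest

from verncre.pipeline import RunConfig, run_pipeline
from verncre.synthetic import SyntheticConfig, generate_genome


@pytest.fixture(scope="session")
def tiny_config() -> SyntheticConfig:
    """A minimal hexaploid experiment (~150 kb chromosomes) for fast tests."""
    return SyntheticConfig(
        n_triads=20, n_singletons=3, chrom_length=150_000,
        n_gwas=40, n_te_per_chrom=40, seed=0,
    )


@pytest.fixture(scope="session")
def tiny_genome(tiny_config):
    return generate_genome(tiny_config)


@pytest.fixture(scope="session")
def default_run(tmp_path_factory):
    """One full pipeline run at the default study conditions, shared by the
    acceptance checks (seed fixed at 0)."""
    outdir = tmp_path_factory.mktemp("default_run")
    return run_pipeline(RunConfig(outdir=str(outdir), seed=0))


def nb_counts(rng: np.random.Generator, mean, dispersion, size):
    """Gamma-Poisson NB draws used across differential-engine tests."""
    g = rng.gamma(1.0 / dispersion, np.asarray(mean) * dispersion, size=size)
    return rng.poisson(g)
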