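import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "deterministic",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("deterministic")


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def small_dataset(tmp_path_factory):
    """A reduced synthetic dataset shared by pipeline-level tests: three
    strata of eight 5 kb contigs each, two male/female pairs at 10x."""
    from ystrata import synthetic_data as sd

    cfg = sd.default_config(
        11,
        strata=[
            sd.StratumSpec("s1", 40_000, 0.01),
            sd.StratumSpec("s2", 40_000, 0.0033),
            sd.StratumSpec("s3", 40_000, 0.0011),
        ],
        contig_length=5_000,
        autosome_length=50_000,
        coverage=10,
        n_pairs=2,
    )
    outdir = tmp_path_factory.mktemp("small_dataset")
    return sd.simulate_dataset(cfg, outdir)


@pytest.fixture(scope="session")
def small_run(small_dataset, tmp_path_factory):
    """Full pipeline output over the small dataset."""
    from ystrata.pipeline import PipelineConfig, run_pipeline

    cfg = PipelineConfig.from_dict(
        {
            "samples": small_dataset.sample_manifest(),
            "assembly": {"path": str(small_dataset.assembly_path)},
        }
    )
    outdir = tmp_path_factory.mktemp("small_run")
    manifest = run_pipeline(cfg, outdir)
    return outdir, manifest
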