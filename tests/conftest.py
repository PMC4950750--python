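import pytest
from hypothesis import HealthCheck, settings

from conswes.pipeline import PipelineConfig, run_pipeline
from conswes.simulate import SimulationConfig, simulate_cohort

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def cohort31(tmp_path_factory):
    """Full-size synthetic cohort: 31 trio families, 28 consanguineous."""
    outdir = tmp_path_factory.mktemp("cohort31")
    return simulate_cohort(SimulationConfig(n_families=31, seed=73), outdir)


@pytest.fixture(scope="session")
def cohort8(tmp_path_factory):
    """Small cohort for fast unit/pipeline tests."""
    outdir = tmp_path_factory.mktemp("cohort8")
    return simulate_cohort(SimulationConfig(n_families=8, seed=5), outdir)


def pipeline_config(cohort, outdir, seed=11) -> PipelineConfig:
    return PipelineConfig(
        vcf=str(cohort.vcf),
        ped=str(cohort.ped),
        exon_bed=str(cohort.exon_bed),
        counts=str(cohort.counts_tsv),
        library_sizes=str(cohort.library_tsv),
        panel_rpkm=str(cohort.panel_tsv),
        external_cnv=str(cohort.outdir / "external_cnv.tsv"),
        outcomes=str(cohort.outdir / "outcomes.tsv"),
        outdir=str(outdir),
        seed=seed,
    )


@pytest.fixture(scope="session")
def pipeline31(cohort31, tmp_path_factory):
    """Full pipeline results on the 31-family cohort (computed once)."""
    outdir = tmp_path_factory.mktemp("pipeline31")
    cfg = pipeline_config(cohort31, outdir)
    return run_pipeline(cfg)
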