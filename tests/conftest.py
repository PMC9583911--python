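"""Shared fixtures: a small simulated cohort and a finished pipeline run."""

from types import SimpleNamespace

import pytest
from hypothesis import HealthCheck, settings

from skinprint.pipeline import PipelineConfig, run_pipeline
from skinprint.simulate import CohortSpec, simulate_cohort

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

# compact cohort: 3 donors sharing one background species, enough depth for
# presence (count >= 3) at every planted locus
TINY = dict(
    n_individuals=3,
    n_body_sites=2,
    n_timepoints=2,
    resident_length=12_000,
    backgrounds=((6_000, 1 / 3),),
    resident_abundance=2 / 3,
    mean_depth=15,
    seed=7,
)


@pytest.fixture(scope="session")
def tiny_spec():
    return CohortSpec(**TINY)


@pytest.fixture(scope="session")
def tiny_cohort(tiny_spec, tmp_path_factory):
    out = tmp_path_factory.mktemp("tiny_cohort")
    manifest, truth = simulate_cohort(tiny_spec, out)
    return SimpleNamespace(dir=out, manifest=manifest, truth=truth, spec=tiny_spec)


@pytest.fixture(scope="session")
def tiny_run(tiny_cohort, tmp_path_factory):
    wd = tmp_path_factory.mktemp("tiny_run")
    cfg = PipelineConfig(seed=7, cv_folds=3)
    result = run_pipeline(cfg, tiny_cohort.dir / "manifest.tsv", wd)
    return SimpleNamespace(cohort=tiny_cohort, config=cfg, result=result, workdir=wd)
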