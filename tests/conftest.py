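import pytest
from hypothesis import HealthCheck, settings

from exposcreen.msdata import Spectrum

settings.register_profile(
    "ci", derandomize=True, deadline=None, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


def make_spectrum(peaks, **kw):
    return Spectrum(peaks=list(peaks), **kw)


@pytest.fixture
def spectrum_factory():
    return make_spectrum


@pytest.fixture(scope="session")
def default_cohort(tmp_path_factory):
    """One default synthetic cohort plus a full pipeline run, shared across
    tests that only read it."""
    from exposcreen.config import RunConfig
    from exposcreen.pipeline import run_pipeline
    from exposcreen.synth import SynthConfig, generate_cohort

    root = tmp_path_factory.mktemp("cohort")
    truth = generate_cohort(SynthConfig(), seed=11, outdir=root / "ds")
    res = run_pipeline(RunConfig(dataset_dir=str(root / "ds"), out_dir=str(root / "run")))
    return {"truth": truth, "results": res, "dataset": root / "ds", "run": root / "run"}
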