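import warnings

import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from sodims.calibration import (
    extract_calibrant_times,
    fit_single_field,
    load_reference_calibrants,
)
from sodims.synthetic import (
    InstrumentTruth,
    condition_presets,
    default_hypotheses,
    synth_calibrant_frame,
)


@pytest.fixture(scope="session")
def truth():
    return InstrumentTruth()


@pytest.fixture(scope="session")
def hypotheses():
    return default_hypotheses()


@pytest.fixture(scope="session")
def presets():
    return {c.name: c for c in condition_presets()}


@pytest.fixture(scope="session")
def reference_calibrants():
    return load_reference_calibrants()


@pytest.fixture(scope="session")
def fitted_calibration(truth, reference_calibrants):
    """Calibration recovered from a noiseless synthetic tune-mix frame."""
    frame, _ = synth_calibrant_frame(
        truth,
        [(c.mz, c.charge, c.reference_ccs) for c in reference_calibrants],
        seed=0,
    )
    measured = extract_calibrant_times(frame, reference_calibrants)
    return fit_single_field(measured, truth.gas_mass)


@pytest.fixture(scope="session")
def noiseless_run(tmp_path_factory):
    """One full noiseless pipeline run over the three presets, shared by the
    tests that inspect its artifacts."""
    from sodims.pipeline import RunConfig, run_pipeline

    out = tmp_path_factory.mktemp("run")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        summary = run_pipeline(RunConfig(seed=0, out_dir=str(out)))
    artifacts = {
        "summary": summary,
        "conformers": pd.read_csv(out / "conformers.csv"),
        "assignments": pd.read_csv(out / "assignments.csv"),
        "profile": pd.read_csv(out / "profile.csv"),
        "truth": {
            cond: pd.read_csv(out / f"truth_{cond}.csv")
            for cond in ("native", "intermediate", "harsh")
        },
        "out_dir": out,
    }
    return artifacts
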