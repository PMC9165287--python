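"""Shared fixtures: noiseless acquisition setups and a processed cohort."""
from __future__ import annotations

import pytest

from cest_subtyper import synthetic_cohort as sc
from cest_subtyper.pipeline import RunConfig, run_analyze, run_simulate


@pytest.fixture(scope="session")
def acq_noiseless() -> sc.AcquisitionParams:
    return sc.AcquisitionParams(noise_sd=0.0)


@pytest.fixture(scope="session")
def acq_flat() -> sc.AcquisitionParams:
    """Noiseless acquisition with flat field maps (no B0 shift, relB1 = 1)."""
    return sc.AcquisitionParams(noise_sd=0.0, b0_shift_range_ppm=0.0,
                                relb1_range=(1.0, 1.0))


@pytest.fixture(scope="session")
def water_pool() -> sc.PoolParams:
    return sc.PoolParams("water", 0.0, 0.40, 1.4, 0.7)


@pytest.fixture(scope="session")
def default_subject(acq_noiseless):
    """One default-preset subject with a prominent fluid compartment."""
    preset = sc.default_presets()[sc.GROUP_RET_MM]
    return sc.simulate_subject(preset, acq_noiseless, seed=5)


@pytest.fixture(scope="session")
def processed_cohort():
    """A default 9/15/7/13 cohort run through the full pipeline once."""
    cfg = RunConfig(seed=11)
    cohort = run_simulate(cfg)
    table, extras = run_analyze(cfg, cohort=cohort)
    return {"config": cfg, "cohort": cohort, "table": table, "extras": extras}
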