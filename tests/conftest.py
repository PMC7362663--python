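"""Shared fixtures: small seeded phantom cohorts and pipeline runs.

All fixtures are generated programmatically; the heavier leave-one-out
runs are session-scoped so classifier, evaluation and acceptance tests
share a single computation.
"""

from __future__ import annotations

import numpy as np
import pytest

from penumbra import (
    PhantomSpec,
    compute_metrics,
    fit_cbf_map,
    generate_cohort,
)
from penumbra.pipeline import RunConfig, run_pipeline


@pytest.fixture(scope="session")
def noiseless_spec() -> PhantomSpec:
    return PhantomSpec(
        n_rats=2, n_slices=3, grid=(32, 32), noise_sd_eigen=0.0, noise_sd_signal=0.0, seed=5
    )


@pytest.fixture(scope="session")
def noiseless_cohort(noiseless_spec):
    return generate_cohort(noiseless_spec)


@pytest.fixture(scope="session")
def rat0(noiseless_cohort):
    return noiseless_cohort[0]


@pytest.fixture(scope="session")
def rat0_metrics(rat0):
    return compute_metrics(rat0.eigen)


@pytest.fixture(scope="session")
def rat0_cbf(rat0):
    return fit_cbf_map(rat0.dsc, rat0.brain_mask)


@pytest.fixture(scope="session")
def loocv_run(tmp_path_factory):
    """Noiseless, well-separated 8-animal cohort evaluated by LOOCV."""
    cfg = RunConfig(
        phantom=PhantomSpec(
            n_rats=8, n_slices=3, grid=(48, 48), noise_sd_eigen=0.0, noise_sd_signal=0.0, seed=7
        ),
        seed=7,
        smoothing_sigma=1.0,
        outdir=str(tmp_path_factory.mktemp("loocv_run")),
    )
    return cfg, run_pipeline(cfg)


@pytest.fixture(scope="session")
def contrast_run(tmp_path_factory):
    """Imbalanced thin-rim cohort at realistic DTI noise for the
    single-level vs two-level penumbra-sensitivity comparison."""
    cfg = RunConfig(
        phantom=PhantomSpec(
            n_rats=8,
            n_slices=3,
            grid=(48, 48),
            noise_sd_eigen=1.2e-4,
            noise_sd_signal=0.0,
            ip_rim_voxels=(1, 1),
            seed=11,
        ),
        seed=11,
        smoothing_sigma=1.0,
        outdir=str(tmp_path_factory.mktemp("contrast_run")),
    )
    return cfg, run_pipeline(cfg)
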