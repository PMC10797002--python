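from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("ci", deadline=None)
settings.load_profile("ci")

from voxparc import (
    SyntheticConfig,
    VoxelTimeSeriesRun,
    generate_rest_dataset,
)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def make_run(
    data,
    nuisance=None,
    tr=2.0,
    subject="S01",
    run_id="S01_run01",
    fixation=1.0,
):
    data = np.asarray(data, dtype=float)
    if nuisance is None:
        nuisance = np.zeros((data.shape[1], 0))
    return VoxelTimeSeriesRun(
        data=data,
        nuisance=np.asarray(nuisance, dtype=float),
        tr_seconds=tr,
        subject_id=subject,
        run_id=run_id,
        fixation_fraction=fixation,
    )


def run_with_pairwise_corr(r, n_t=60, run_id="r", subject="S01"):
    """Two-voxel run whose mean pairwise correlation is exactly ``r``.

    Built from two exactly orthonormal basis vectors so the sample
    correlation equals ``r`` by construction.
    """
    t = np.arange(n_t)
    e1 = np.cos(2 * np.pi * t / n_t)
    e2 = np.sin(2 * np.pi * t / n_t)
    e1 = (e1 - e1.mean()) / np.linalg.norm(e1 - e1.mean())
    e2 = (e2 - e2.mean()) / np.linalg.norm(e2 - e2.mean())
    v1 = e1
    v2 = r * e1 + np.sqrt(1 - r**2) * e2
    return make_run(np.vstack([v1, v2]), run_id=run_id, subject=subject)


@pytest.fixture(scope="session")
def small_rest_dataset():
    """Small but fully structured dataset reused by read-only tests."""
    cfg = SyntheticConfig(
        n_voxels=40,
        k_true=4,
        n_seeds=12,
        n_subjects=4,
        n_runs_per_subject=2,
        n_volumes=150,
        community_snr=2.0,
        rng_seed=7,
    )
    return generate_rest_dataset(cfg)
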