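"""Shared fixtures: fixed physiology, rank-1 parameters, noise-free study data.

The expensive cluster Gauss-Newton recovery runs are session-scoped so the
unit, property and acceptance tests share one fit per protein.
"""

from __future__ import annotations

import numpy as np
import pytest

import fcrnpk as f
from fcrnpk.cgnm_fit import CGNMConfig, FitProblem, cgnm_run
from fcrnpk.nca import pool_naive
from fcrnpk.synthetic_study import ErrorModel, generate_pk_dataset


@pytest.fixture(scope="session")
def fixed():
    return f.FixedPhysiology()


@pytest.fixture(scope="session")
def mdtcs_rank1():
    return f.rank1_params(f.MDTCS)


@pytest.fixture(scope="session")
def fc_rank1():
    return f.rank1_params(f.MDTCS_FC)


@pytest.fixture(scope="session")
def noise_free_pooled(fixed):
    """Pooled noise-free study profiles simulated at the rank-1 truth."""
    ds = generate_pk_dataset(error_model=ErrorModel(cv=0.0), seed=1, fixed=fixed)
    return pool_naive(ds)


def _recovery_cloud(protein, pooled, fixed, **cfg_kw):
    sub = pooled[pooled["protein"] == protein]
    problem = FitProblem(protein_id=protein, pooled=sub, fixed=fixed)
    config = CGNMConfig(**cfg_kw)
    return problem, cgnm_run(problem, config)


@pytest.fixture(scope="session")
def mdtcs_recovery(noise_free_pooled, fixed):
    """Noise-free MDTCS fit: 60 iterates x 12 sweeps plus local polish."""
    return _recovery_cloud(f.MDTCS, noise_free_pooled, fixed,
                           n_iterates=60, n_iterations=12, seed=7,
                           polish_ssr_factor=np.inf, polish_max_nfev=120)


@pytest.fixture(scope="session")
def fc_recovery(noise_free_pooled, fixed):
    """Noise-free MDTCS-Fc fit; the multimodal four-parameter problem."""
    return _recovery_cloud(f.MDTCS_FC, noise_free_pooled, fixed,
                           n_iterates=100, n_iterations=8, seed=7,
                           polish_ssr_factor=np.inf, polish_max_nfev=300)
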