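import logging

import numpy as np
import pytest

import connpred as cp


@pytest.fixture(autouse=True)
def _quiet_fold_warnings(caplog):
    # fold-level fallback warnings are expected noise in null-calibration runs
    logging.getLogger("connpred.crossval").setLevel(logging.ERROR)
    yield
    logging.getLogger("connpred.crossval").setLevel(logging.NOTSET)


@pytest.fixture(scope="session")
def small_truth():
    """R=12, two LOFC edges + one HOFC edge, strong signal."""
    return cp.make_default_truth(
        n_regions=12, n_lofc_edges=2, n_hofc_edges=1, target_r2=0.9, seed=7
    )


@pytest.fixture(scope="session")
def small_cohort(small_truth):
    return cp.generate_connectome_cohort(24, 12, small_truth, master_seed=7)


def random_symmetric_unit_diag(rng, R):
    """A random symmetric matrix with unit diagonal and entries in [-1, 1]."""
    A = rng.uniform(-0.8, 0.8, size=(R, R))
    A = (A + A.T) / 2.0
    np.fill_diagonal(A, 1.0)
    return A
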