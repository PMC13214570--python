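import numpy as np
import pytest

import datnorm as dn


@pytest.fixture(scope="session")
def small_cohort():
    """Tiny cohort for structural tests (not for effect-recovery statistics)."""
    cfg = dn.CohortConfig(
        n_hc=4, n_pd=2, n_voxels_per_subject=600, n_features=12, seed=11
    )
    table, truth = dn.generate_cohort(cfg)
    return cfg, table, truth


@pytest.fixture(scope="session")
def small_preprocessed(small_cohort):
    _, table, _ = small_cohort
    out, stats = dn.preprocess_table(table)
    return out, stats


def finite_difference_grads(fn, params, eps=1e-6):
    """Central finite differences of scalar fn(params) w.r.t. every entry."""
    grads = {}
    for name, arr in params.items():
        g = np.zeros_like(arr)
        flat = arr.ravel()
        gflat = g.ravel()
        for i in range(flat.size):
            orig = flat[i]
            flat[i] = orig + eps
            hi = fn()
            flat[i] = orig - eps
            lo = fn()
            flat[i] = orig
            gflat[i] = (hi - lo) / (2 * eps)
        grads[name] = g
    return grads
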