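"""Shared fixtures: small harmonized sets built directly from arrays."""

import numpy as np
import pytest

from cardiomr.sumstats import HarmonizedSet


def make_harmonized(theta, J, seed, n=100_000, z_range=(5.5, 30.0),
                    outlier_ratio=None, outlier_index=0):
    """One-exposure harmonized set drawn from the two-sample model.

    Optionally plants a single variant whose outcome effect follows a
    different ratio (``outlier_ratio``) with a third of the nominal noise.
    """
    rng = np.random.default_rng(seed)
    maf = rng.uniform(0.05, 0.5, J)
    se = 1.0 / np.sqrt(2 * n * maf * (1 - maf))
    bx_true = rng.uniform(*z_range, J) * se * rng.choice([-1.0, 1.0], J)
    bx = bx_true + rng.normal(0, se)
    by = theta * bx_true + rng.normal(0, se)
    if outlier_ratio is not None:
        j = outlier_index
        by[j] = outlier_ratio * bx_true[j] + rng.normal(0, se[j] / 3)
    ids = [f"rs{j + 1}" for j in range(J)]
    return HarmonizedSet(["X"], "Y", ids, bx[:, None], se[:, None], by, se)


@pytest.fixture
def harmonized_null():
    return make_harmonized(0.0, 50, seed=101)


@pytest.fixture
def harmonized_causal():
    return make_harmonized(0.3, 50, seed=202)
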