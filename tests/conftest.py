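"""Shared fixtures: simulated matrices for normal and folded insertions."""

import numpy as np
import pytest

from tfoscan import (
    ArrayFamily,
    EFIMatrix,
    FaultSpec,
    ImpedanceKernel,
    make_geometry,
    simulate_efi,
)


def simulated_matrix(
    fold_at=None,
    family=ArrayFamily.PRE_CURVED,
    noise_sigma=0.0,
    seed=0,
    faults=None,
):
    geom = make_geometry(family, fold_at=fold_at)
    kern = ImpedanceKernel(noise_sigma=noise_sigma, seed=seed)
    return simulate_efi(geom, kern, faults or FaultSpec())


@pytest.fixture
def normal_matrix():
    """Noiseless normal insertion, pre-curved family."""
    return simulated_matrix()


@pytest.fixture
def fold5_matrix():
    """Noiseless fold-over at electrode 5."""
    return simulated_matrix(fold_at=5)


@pytest.fixture
def tiny_matrix():
    """Minimal 5-contact matrix with clean monotone decay."""
    n = 5
    vals = np.empty((n, n))
    for i in range(n):
        for j in range(n):
            vals[i, j] = 6.0 if i == j else 0.5 + 1.5 * np.exp(-abs(i - j) / 3.0)
    return EFIMatrix(values=vals, labels=tuple(range(1, n + 1)))
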