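from __future__ import annotations

import numpy as np
import pytest

from refstab.qpcr_data import QuantityMatrix


def random_quantity_matrix(
    rng: np.random.Generator, n_assays: int, n_samples: int
) -> QuantityMatrix:
    """Log-normal random quantities with heterogeneous per-assay noise."""
    sigmas = rng.uniform(0.05, 1.0, n_assays)
    logq = rng.normal(0.0, 1.0, (n_assays, n_samples)) * sigmas[:, None]
    return QuantityMatrix(
        [f"A{i}" for i in range(n_assays)],
        [f"S{j}" for j in range(n_samples)],
        np.exp2(logq),
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


@pytest.fixture
def toy_quantities() -> QuantityMatrix:
    """3 assays x 2 samples with known hand-computed statistics."""
    return QuantityMatrix(
        ["A1", "A2", "A3"],
        ["S1", "S2"],
        np.array([[1.0, 2.0], [1.0, 2.0], [1.0, 8.0]]),
    )
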