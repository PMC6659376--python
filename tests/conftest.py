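import numpy as np
import pytest

from mrmodq import SummaryData


def make_dataset(
    beta_exposure,
    se_exposure,
    beta_outcome,
    se_outcome,
    ids=None,
) -> SummaryData:
    beta_exposure = np.asarray(beta_exposure, float)
    n = beta_exposure.shape[0]
    if ids is None:
        ids = np.array([f"rs{j + 1}" for j in range(n)], dtype=object)
    return SummaryData(
        np.asarray(ids, dtype=object),
        beta_exposure,
        np.broadcast_to(np.asarray(se_exposure, float), (n,)).copy(),
        np.asarray(beta_outcome, float),
        np.broadcast_to(np.asarray(se_outcome, float), (n,)).copy(),
    )


def random_dataset(rng: np.random.Generator, L: int = 8, beta: float = 0.1,
                   mean_f: float = 25.0, sigma_y: float = 0.05) -> SummaryData:
    """Small random two-sample summary dataset with known true effect."""
    sx = 1.0 / np.sqrt(mean_f - 1.0)
    gx = rng.normal(1.0, sx, L)
    gy = rng.normal(beta, sigma_y, L)
    return make_dataset(gx, sx, gy, sigma_y)


@pytest.fixture
def rng():
    return np.random.default_rng(20260921)


@pytest.fixture
def small_ds(rng):
    return random_dataset(rng, L=8)


@pytest.fixture
def homogeneous_ds():
    """All ratio estimates exactly equal (beta = 0.3), heterogeneity-free."""
    gx = np.array([0.2, 0.5, 0.8, 1.1, 0.6, 0.9])
    return make_dataset(gx, 0.05, 0.3 * gx, np.array([0.02, 0.03, 0.05, 0.04, 0.02, 0.06]))


@pytest.fixture
def outlier_ds():
    """Ten homogeneous SNPs plus one whose ratio is displaced by 6 first-order SDs.

    The first-order SD of a ratio estimate is se_outcome/|beta_exposure|.
    """
    gx = np.full(11, 1.0)
    sy = 0.05
    gy = np.full(11, 0.1)
    gy[5] += 6 * sy  # ratio displaced by 6 first-order SDs
    return make_dataset(gx, 0.01, gy, sy)
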