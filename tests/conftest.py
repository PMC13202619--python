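import numpy as np
import pytest

from bwage.preprocess import Connectome
from bwage.synthdata import default_cohort_spec, default_planted_model, generate_cohort


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_spd(n: int, rng: np.random.Generator, cond: float = 10.0) -> np.ndarray:
    """Random SPD matrix with eigenvalues in [1/cond, 1]."""
    Q, _ = np.linalg.qr(rng.standard_normal((n, n)))
    vals = rng.uniform(1.0 / cond, 1.0, size=n)
    return (Q * vals) @ Q.T


@pytest.fixture
def spd_factory(rng):
    return lambda n=5: random_spd(n, rng)


@pytest.fixture(scope="session")
def small_cohort():
    """~200-participant four-study cohort, deterministic."""
    spec = default_cohort_spec(scale=0.005, seed=7)
    return generate_cohort(spec, seed=7)


@pytest.fixture(scope="session")
def planted():
    """Small planted model + cohort + connectomes for downstream tests."""
    from bwage.synthdata import generate_connectomes

    spec = default_cohort_spec(scale=0.01, seed=3)
    model = default_planted_model(
        n_regions=8, site_effect=spec.site_effect, noise_df=150, seed=4
    )
    records = generate_cohort(spec, seed=5)
    conns = generate_connectomes(records, model, seed=6)
    return {"spec": spec, "model": model, "records": records, "connectomes": conns}


@pytest.fixture
def correlation_connectome(spd_factory):
    C = spd_factory(6)
    d = np.sqrt(np.diag(C))
    C = C / np.outer(d, d)
    np.fill_diagonal(C, 1.0)
    return Connectome(C, "correlation", "p0")
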