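import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def planted_model():
    """k=4 model fit to a planted 4-prototype mixture (shared across tests)."""
    from vfarch.aa import fit_archetypes
    from vfarch.synthetic import generate_mixture_matrix

    X, W, P = generate_mixture_matrix(300, dirichlet_alpha=0.3, noise_sd_db=1.0, seed=11)
    model = fit_archetypes(X, 4, seed=11, n_restarts=3, max_iter=120)
    return model, X, W, P


@pytest.fixture(scope="session")
def triangle_data():
    """200 points strictly inside a known triangle in a 2-coordinate space."""
    rng = np.random.default_rng(7)
    verts = np.array([[0.0, 0.0], [10.0, 0.0], [0.0, 10.0]])
    W = rng.dirichlet([0.4, 0.4, 0.4], size=200)
    return W @ verts, verts


@pytest.fixture()
def small_cohort():
    from vfarch.synthetic import generate_cohort

    series, gt = generate_cohort(n_eyes=12, seed=21)
    return series, gt


@pytest.fixture()
def control_cohort():
    from vfarch.synthetic import generate_controls

    return generate_controls(n_eyes=15, visits_per_eye=5, seed=22)
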