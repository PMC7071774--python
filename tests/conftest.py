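import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

import dosiflare as df


@pytest.fixture(scope="session")
def lib():
    return df.load_extinction_library()


@pytest.fixture
def geom():
    return df.ProbeGeometry()


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


@pytest.fixture(scope="session")
def small_phantom():
    """Compact noise-free phantom spec for fast exact round trips."""
    from dosiflare.synthetic import PhantomSpec

    return PhantomSpec(
        nx=7,
        ny=5,
        lesion_center=(3, 2),
        lesion_diameter_cm=2.5,
        amplitude_noise_rel=0.0,
        phase_noise_deg=0.0,
        broadband_noise_rel=0.0,
        broadband_step_nm=2.0,
    )


def make_clustered_data(rng, n_clusters=200, size=5, alpha=0.5, beta=(1.0, 2.0)):
    """Exchangeable clusters: random intercept u + iid noise, unit total variance."""
    sd_b, sd_w = np.sqrt(alpha), np.sqrt(1 - alpha)
    X, y, g = [], [], []
    for i in range(n_clusters):
        u = rng.normal(0, sd_b)
        x = rng.normal(size=size)
        X.append(np.column_stack([np.ones(size), x]))
        y.append(beta[0] + beta[1] * x + u + rng.normal(0, sd_w, size))
        g.append(np.full(size, i))
    return np.vstack(X), np.concatenate(y), np.concatenate(g)
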