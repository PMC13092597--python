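import numpy as np
import pytest

import strandsep as ss


@pytest.fixture(scope="session")
def wt():
    return ss.reference_rate_constants("WT")


@pytest.fixture(scope="session")
def truth_coeffs():
    return ss.default_truth_coefficients()


@pytest.fixture(scope="session")
def wt_noiseless_dataset():
    """Noise-free WT dataset on a reduced grid, shared across tests."""
    cfg = ss.SyntheticConfig(seed=0, sigma_fluor=0.0, sigma_radio=0.0,
                             n_points_fluor=150)
    return ss.generate_full_dataset(cfg)


@pytest.fixture(scope="session")
def wt_noisy_dataset():
    """Default-noise WT dataset on a reduced grid."""
    cfg = ss.SyntheticConfig(seed=42, n_points_fluor=150)
    return ss.generate_full_dataset(cfg)


def random_rate_sets(n, seed, lo=1e-3, hi=1e2, irreversible=False):
    """Seeded random parameter sets, every constant log-uniform in [lo, hi]."""
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n):
        vals = dict(zip(
            ("k1", "k1r", "k2", "k2r", "k3", "k3r", "k4", "k4r"),
            np.exp(rng.uniform(np.log(lo), np.log(hi), 8)),
        ))
        if irreversible:
            vals["k3r"] = 0.0
            vals["k4r"] = min(vals["k4r"], 1e-6)
        out.append(ss.RateConstants(**vals, locked=frozenset()))
    return out
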