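import numpy as np
import pytest

from hemicam.allosteric import LobeParams
from hemicam.synthetic import NoiseModel, fixtures, generate_titration, make_benchmark_suite

TABLE_TR2C = {"L": 8.616e3, "K_R": 1.979e-8, "K_T": 6.241e-5, "K_T_NaV": 6.095e-10}
TABLE_NLOBE = {"L_N": 3.226e5, "K_T_N": 9.192e-5, "K_R_N": 1.979e-8}


@pytest.fixture(scope="session")
def tr2c() -> LobeParams:
    return fixtures("tr2c")["params"]


@pytest.fixture(scope="session")
def nlobe() -> LobeParams:
    return fixtures("nlobe")["params"]


@pytest.fixture(scope="session")
def intact():
    return fixtures("intact")["params"]


@pytest.fixture(scope="session")
def benchmark_suite():
    """The seeded 3-fit + 2-validation benchmark at sigma_Y = 0.02."""
    return make_benchmark_suite(seed=1)


@pytest.fixture(scope="session")
def noiseless_fit_datasets(tr2c):
    """Noiseless versions of the three fitting titrations."""
    quiet = NoiseModel(sigma_Y=0.0, sigma_logCa=0.0)
    wff = fixtures("wff_lobe")
    nav = fixtures("nav_fitted")
    return {
        "alone": generate_titration(tr2c, targets=[], noise=quiet, seed=11, label="alone"),
        "wff": generate_titration(tr2c, targets=[(wff, 7e-6)], noise=quiet, seed=12, label="wff"),
        "nav": generate_titration(tr2c, targets=[(nav, 7e-6)], noise=quiet, seed=13, label="nav"),
    }


@pytest.fixture(scope="session")
def noisy_tr2c_fit(benchmark_suite):
    """One seeded run of the full constrained fit on the noisy benchmark."""
    from hemicam.fitting import fit_tr2c

    return fit_tr2c(benchmark_suite["fit"], seed=1)
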