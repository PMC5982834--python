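import numpy as np
import pytest

from sigmacomp import ModelParameters, default_spec, generate
from sigmacomp.pipeline import estimate_dispersion


@pytest.fixture(scope="session")
def params():
    return ModelParameters()


@pytest.fixture(scope="session")
def default_expt():
    """One draw of the default planted-effect template (seed 1)."""
    return generate(default_spec(seed=1))


@pytest.fixture(scope="session")
def default_dispersion(default_expt):
    return estimate_dispersion(default_expt)


def random_parameter_sets(n, seed, within_fold=10.0):
    """Log-uniform parameter sets within ``within_fold`` of the defaults.

    Varies the totals and dissociation constants of the binding network
    (the holoenzyme variant's parameters).
    """
    rng = np.random.default_rng(seed)
    names = (
        "E_total",
        "sigma70_total",
        "sigma38_total",
        "Rsd_total",
        "RNA6S_total",
        "K_E_sigma70",
        "K_E_sigma38",
        "K_Rsd",
        "K_6S",
    )
    base = ModelParameters()
    out = []
    for _ in range(n):
        changes = {
            name: getattr(base, name) * 10 ** rng.uniform(-np.log10(within_fold), np.log10(within_fold))
            for name in names
        }
        out.append(base.replace(**changes))
    return out
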