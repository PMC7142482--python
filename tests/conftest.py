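import numpy as np
import pytest

from nmrflux import synthdata
from nmrflux.quantify import SpectralLibrary


@pytest.fixture(scope="session")
def grid():
    """Reduced 4096-point grid over the standard -0.5..10 ppm window."""
    return synthdata.default_grid(4096)


@pytest.fixture(scope="session")
def panel():
    return synthdata.default_library_definitions()


@pytest.fixture(scope="session")
def small_defs(panel):
    """Three well-separated metabolites for exact-fit tests."""
    by_name = {m.name: m for m in panel}
    return [by_name["lactate"], by_name["creatine"], by_name["tryptophan"]]


@pytest.fixture(scope="session")
def small_library(small_defs, grid):
    return SpectralLibrary.from_definitions(small_defs, grid)


@pytest.fixture(scope="session")
def panel_library(panel, grid):
    return SpectralLibrary.from_definitions(panel, grid)


@pytest.fixture(params=synthdata.TOY_NETWORK_KINDS)
def toy_model(request):
    return synthdata.make_toy_network(request.param)


def random_lorentzian_defs(rng, n_metabolites=20, grid_span=(-0.4, 9.9)):
    """Random synthetic metabolite definitions for stress/oracle tests."""
    defs = []
    for i in range(n_metabolites):
        n_peaks = int(rng.integers(1, 5))
        peaks = tuple(
            synthdata.PeakSpec(
                center=float(rng.uniform(*grid_span)),
                amplitude=float(rng.uniform(0.5, 3.0)),
                fwhm=float(rng.uniform(0.01, 0.04)),
            )
            for _ in range(n_peaks)
        )
        defs.append(synthdata.MetaboliteDef(f"met{i:02d}", peaks))
    return defs
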