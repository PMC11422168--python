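import numpy as np
import pytest
from hypothesis import settings

from lipotrace.isotope_model import FattyAcidDefinition

settings.register_profile("ci", deadline=None, derandomize=True)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def c16():
    return FattyAcidDefinition.from_name("C16:0")


@pytest.fixture(scope="session")
def c18():
    return FattyAcidDefinition.from_name("C18:0")


@pytest.fixture(scope="session")
def small_field():
    """A 40-cell simulated field with spectra, shared across tests."""
    from lipotrace.synthetic_fixtures import simulate_cell_field, simulate_spectra

    labels, grid, truth = simulate_cell_field(40, seed=11)
    panel = [FattyAcidDefinition.from_name("C16:0")]
    pixels, marks = simulate_spectra(truth, labels, grid, panel,
                                     noise_cv=0.15, seed=12)
    return {"labels": labels, "grid": grid, "truth": truth,
            "pixels": pixels, "marks": marks, "panel": panel}
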