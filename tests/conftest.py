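import numpy as np
import pytest

from spectransfer.spectra import (
    PreprocessingState,
    SpectralLibrary,
    WavenumberGrid,
)
from spectransfer.synthetic import SyntheticConfig, generate_scenario


def make_library(
    absorbance,
    wn=None,
    instrument="primary",
    state=PreprocessingState.RAW,
    ids=None,
):
    absorbance = np.asarray(absorbance, dtype=float)
    n, p = absorbance.shape
    if wn is None:
        wn = 628.0 + 2.0 * np.arange(p)
    if ids is None:
        ids = [f"S{i}" for i in range(n)]
    return SpectralLibrary(
        grid=WavenumberGrid(np.asarray(wn, dtype=float)),
        absorbance=absorbance,
        sample_ids=ids,
        instrument=instrument,
        state=state,
    )


@pytest.fixture(scope="session")
def small_scenario():
    """A reduced-size synthetic two-instrument study shared across tests."""
    cfg = SyntheticConfig(n_calibration=400, n_transfer=50, n_prediction=80, seed=42)
    return generate_scenario(cfg)
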