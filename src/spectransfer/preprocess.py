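"""Spectral pretreatments: baseline-offset correction and first derivative.

Two pretreatments are used throughout the pipeline.  Baseline-offset
correction subtracts each spectrum's minimum so every row touches zero,
removing a constant instrumental offset.  The first derivative is a lag-1
finite difference of adjacent channels (ascending wavenumber order),
which removes any additive baseline entirely and sharpens overlapping
bands.  The difference is not divided by the channel spacing: on a
uniform grid the two conventions differ by a constant factor that the
downstream regression absorbs.
"""

from __future__ import annotations

import numpy as np

from .spectra import PreprocessingState, SpectralLibrary, WavenumberGrid

__all__ = ["baseline_offset", "first_derivative", "apply_pretreatment"]


def baseline_offset(lib: SpectralLibrary) -> SpectralLibrary:
    """Subtract each row's minimum; output row minima are exactly zero."""
    if lib.state is not PreprocessingState.RAW:
        raise ValueError(
            f"baseline_offset requires raw spectra, got state {lib.state.value!r}"
        )
    corrected = lib.absorbance - lib.absorbance.min(axis=1, keepdims=True)
    return lib.with_absorbance(corrected, state=PreprocessingState.BASELINE_OFFSET)


def first_derivative(lib: SpectralLibrary) -> SpectralLibrary:
    """Lag-1 finite difference along the ascending wavenumber axis.

    Output channel j is ``x[j+1] - x[j]``; the output grid holds the
    midpoints of adjacent input channels, so N input channels become N-1
    on an unbroken uniform grid.  A grid that is uniform except for gaps
    (e.g. after removing the atmospheric CO2 region) is differenced per
    contiguous block — no difference spans a gap, and each gap costs one
    further channel.
    """
    if lib.state is PreprocessingState.FIRST_DERIVATIVE:
        raise ValueError("spectra are already first-derivative transformed")
    if lib.n_channels < 2:
        raise ValueError("first derivative requires at least 2 channels")
    wn = lib.grid.values
    diffs = np.diff(wn)
    step = np.min(diffs)
    breaks = np.flatnonzero(diffs > step * (1 + 1e-9))
    keep = np.ones(wn.size - 1, dtype=bool)
    keep[breaks] = False
    if not keep.any():
        raise ValueError("first derivative requires a (piecewise-)uniform grid")
    within = np.abs(diffs[keep] - step) <= 1e-9 * max(1.0, step)
    if not within.all():
        raise ValueError("first derivative requires a (piecewise-)uniform grid")
    mid = 0.5 * (wn[:-1] + wn[1:])[keep]
    deriv = np.diff(lib.absorbance, axis=1)[:, keep]
    return lib.with_absorbance(
        deriv, grid=WavenumberGrid(mid), state=PreprocessingState.FIRST_DERIVATIVE
    )


def apply_pretreatment(lib: SpectralLibrary, pretreatment: str) -> SpectralLibrary:
    """Dispatch by name: ``"baseline_offset"`` or ``"first_derivative"``.

    A no-op when the library is already in the requested state (so that
    derivative-PDS output can feed derivative models directly).
    """
    target = PreprocessingState(pretreatment)
    if lib.state is target:
        return lib
    if target is PreprocessingState.BASELINE_OFFSET:
        return baseline_offset(lib)
    if target is PreprocessingState.FIRST_DERIVATIVE:
        return first_derivative(lib)
    raise ValueError(f"cannot convert spectra back to state {pretreatment!r}")
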