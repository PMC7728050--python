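"""Core spectral containers and grid operations.

Mid-infrared diffuse-reflectance spectra are represented as a
:class:`SpectralLibrary`: an absorbance matrix (samples x wavenumber
channels) on a shared :class:`WavenumberGrid`, tagged with the instrument
that produced it and the pretreatment state of the rows.  Laboratory
property measurements ride alongside in a :class:`PropertyTable`.

The wavenumber axis is stored ascending internally even though FTIR
instruments emit spectra from high to low wavenumber; writers emit the
descending instrument convention.  One canonical order removes any sign
ambiguity in derivative pretreatments.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "PreprocessingState",
    "WavenumberGrid",
    "SpectralLibrary",
    "PropertyTable",
    "read_library",
    "write_library",
    "resample",
    "remove_region",
    "DEFAULT_WN_MIN",
    "DEFAULT_WN_MAX",
    "DEFAULT_WN_STEP",
    "CO2_REGION",
    "SOIL_PROPERTIES",
]

#: Common spectral range and resolution used throughout: 4000-628 cm^-1 at 2 cm^-1.
DEFAULT_WN_MIN = 628.0
DEFAULT_WN_MAX = 4000.0
DEFAULT_WN_STEP = 2.0

#: Atmospheric CO2 absorption region removed before modelling (cm^-1).
CO2_REGION = (2268.0, 2389.0)

#: Soil properties the study predicts, with units.
SOIL_PROPERTIES = {
    "BD": "g/cm^3",
    "CaCO3": "wt %",
    "clay": "wt %",
    "OC": "wt %",
    "pH": "",
}


class PreprocessingState(str, enum.Enum):
    """Pretreatment state of the absorbance rows."""

    RAW = "raw"
    BASELINE_OFFSET = "baseline_offset"
    FIRST_DERIVATIVE = "first_derivative"


@dataclass(frozen=True)
class WavenumberGrid:
    """An ordered wavenumber axis in cm^-1, stored strictly ascending."""

    values: np.ndarray

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 1:
            raise ValueError("wavenumber grid must be one-dimensional")
        if values.size >= 2 and not np.all(np.diff(values) > 0):
            raise ValueError("wavenumber grid must be strictly ascending")
        object.__setattr__(self, "values", values)

    @property
    def step(self) -> float | str:
        """Nominal spacing in cm^-1, or ``"irregular"``."""
        if self.values.size < 2:
            return "irregular"
        diffs = np.diff(self.values)
        if np.allclose(diffs, diffs[0], rtol=0.0, atol=1e-9):
            return float(diffs[0])
        return "irregular"

    @property
    def is_uniform(self) -> bool:
        return self.step != "irregular"

    def __len__(self) -> int:
        return int(self.values.size)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, WavenumberGrid):
            return NotImplemented
        return self.values.shape == other.values.shape and bool(
            np.array_equal(self.values, other.values)
        )

    def __hash__(self) -> int:  # frozen dataclass with array field
        return hash((self.values.tobytes(), self.values.shape))


@dataclass
class SpectralLibrary:
    """Absorbance spectra for a set of samples on a shared grid.

    Parameters
    ----------
    grid : WavenumberGrid
        Shared wavenumber axis (ascending, cm^-1).
    absorbance : ndarray, shape (n_samples, n_channels)
        Absorbance values; must be finite.
    sample_ids : sequence of str
        Unique sample identifiers, one per row.
    instrument : str
        Label of the spectrometer that produced the rows
        (e.g. ``"primary"``, ``"secondary"``, ``"secondary_pds"``).
    state : PreprocessingState
        Pretreatment state of the rows.
    """

    grid: WavenumberGrid
    absorbance: np.ndarray
    sample_ids: list[str]
    instrument: str = "primary"
    state: PreprocessingState = PreprocessingState.RAW

    def __post_init__(self) -> None:
        self.absorbance = np.asarray(self.absorbance, dtype=float)
        if self.absorbance.ndim != 2:
            raise ValueError("absorbance must be a 2-D matrix")
        self.sample_ids = [str(s) for s in self.sample_ids]
        n, p = self.absorbance.shape
        if n != len(self.sample_ids):
            raise ValueError(
                f"absorbance has {n} rows but {len(self.sample_ids)} sample ids"
            )
        if p != len(self.grid):
            raise ValueError(
                f"absorbance has {p} columns but grid has {len(self.grid)} channels"
            )
        if not np.all(np.isfinite(self.absorbance)):
            raise ValueError("absorbance contains non-finite values")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            dupes = sorted(
                {s for s in self.sample_ids if self.sample_ids.count(s) > 1}
            )
            raise ValueError(f"duplicate sample id: {dupes[0]}")
        if isinstance(self.state, str):
            self.state = PreprocessingState(self.state)

    @property
    def n_samples(self) -> int:
        return self.absorbance.shape[0]

    @property
    def n_channels(self) -> int:
        return self.absorbance.shape[1]

    def subset(self, indices) -> "SpectralLibrary":
        """Row subset by positional indices (order preserved as given)."""
        indices = np.asarray(indices)
        if indices.dtype == bool:
            indices = np.flatnonzero(indices)
        return replace(
            self,
            absorbance=self.absorbance[indices].copy(),
            sample_ids=[self.sample_ids[i] for i in indices],
        )

    def with_absorbance(
        self,
        absorbance: np.ndarray,
        grid: WavenumberGrid | None = None,
        instrument: str | None = None,
        state: PreprocessingState | None = None,
    ) -> "SpectralLibrary":
        return SpectralLibrary(
            grid=grid if grid is not None else self.grid,
            absorbance=absorbance,
            sample_ids=list(self.sample_ids),
            instrument=instrument if instrument is not None else self.instrument,
            state=state if state is not None else self.state,
        )


@dataclass
class PropertyTable:
    """Per-sample laboratory soil-property values.

    Stored as a DataFrame indexed by sample id with one column per
    property; missing cells are NaN.  Invariants: every non-missing value
    is finite, bulk density is positive and the concentration-like
    properties (CaCO3, clay, OC) are non-negative.
    """

    data: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        self.data = pd.DataFrame(self.data)
        self.data.index = self.data.index.astype(str)
        if self.data.index.has_duplicates:
            dupes = self.data.index[self.data.index.duplicated()]
            raise ValueError(f"duplicate sample id: {dupes[0]}")
        for col in self.data.columns:
            vals = pd.to_numeric(self.data[col], errors="coerce")
            bad = vals.isna() & self.data[col].notna()
            if bad.any():
                raise ValueError(
                    f"non-numeric property value in column {col!r}, "
                    f"sample {self.data.index[bad.argmax()]!r}"
                )
            self.data[col] = vals
        finite = self.data.apply(lambda c: np.isfinite(c) | c.isna())
        if not finite.all().all():
            raise ValueError("property table contains non-finite values")
        if "BD" in self.data.columns and (self.data["BD"].dropna() <= 0).any():
            raise ValueError("BD must be positive")
        for col in ("CaCO3", "clay", "OC"):
            if col in self.data.columns and (self.data[col].dropna() < 0).any():
                raise ValueError(f"{col} must be non-negative")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def properties(self) -> list[str]:
        return list(self.data.columns)

    def values_for(self, prop: str, sample_ids=None) -> np.ndarray:
        col = self.data[prop]
        if sample_ids is not None:
            col = col.reindex([str(s) for s in sample_ids])
        return col.to_numpy(dtype=float)

    def subset(self, sample_ids) -> "PropertyTable":
        return PropertyTable(self.data.loc[[str(s) for s in sample_ids]])


# ---------------------------------------------------------------------------
# I/O: wide CSV with property columns followed by numeric wavenumber headers
# ---------------------------------------------------------------------------


def _split_columns(columns) -> tuple[list[str], list[str]]:
    """Split header names into (property columns, wavenumber columns)."""
    prop_cols, wn_cols = [], []
    for c in columns:
        try:
            float(c)
        except (TypeError, ValueError):
            prop_cols.append(c)
        else:
            wn_cols.append(c)
    return prop_cols, wn_cols


def read_library(
    path,
    format: str = "csv_wide",
    instrument: str = "primary",
    state: PreprocessingState = PreprocessingState.RAW,
) -> tuple[SpectralLibrary, PropertyTable | None]:
    """Read a wide-format spectral CSV.

    The header row names an ``id`` column, zero or more property columns,
    and then one numeric header per wavenumber channel (either axis
    direction; stored ascending).  Returns the library and, when property
    columns are present, a :class:`PropertyTable` (otherwise ``None``).
    """
    if format != "csv_wide":
        raise ValueError(f"unsupported format: {format!r}")
    df = pd.read_csv(path, dtype={0: str})
    if df.columns[0].lower() != "id":
        raise ValueError("first column of a csv_wide file must be 'id'")
    ids = df.iloc[:, 0].astype(str).tolist()
    prop_cols, wn_cols = _split_columns(df.columns[1:])
    if not wn_cols:
        raise ValueError("no numeric wavenumber columns found")
    wn = np.array([float(c) for c in wn_cols])
    spec = df[wn_cols].to_numpy()
    if spec.dtype == object or not np.issubdtype(spec.dtype, np.number):
        for j, c in enumerate(wn_cols):
            col = pd.to_numeric(df[c], errors="coerce")
            if col.isna().any():
                i = int(col.isna().argmax())
                raise ValueError(
                    f"non-numeric absorbance at row {ids[i]!r}, column {c!r}"
                )
        spec = df[wn_cols].apply(pd.to_numeric).to_numpy()
    order = np.argsort(wn)
    lib = SpectralLibrary(
        grid=WavenumberGrid(wn[order]),
        absorbance=spec[:, order].astype(float),
        sample_ids=ids,
        instrument=instrument,
        state=state,
    )
    props = None
    if prop_cols:
        props = PropertyTable(pd.DataFrame(df[prop_cols].to_numpy(), index=ids, columns=prop_cols))
    return lib, props


def write_library(
    lib: SpectralLibrary, path, props: PropertyTable | None = None
) -> None:
    """Write a library (and optional properties) as a wide CSV.

    Wavenumber columns are emitted descending (instrument convention);
    :func:`read_library` restores the internal ascending order.
    """
    cols = {}
    if props is not None:
        aligned = props.data.reindex(lib.sample_ids)
        for c in aligned.columns:
            cols[c] = aligned[c].to_numpy()
    desc = slice(None, None, -1)
    for j, wn in enumerate(lib.grid.values[desc]):
        label = f"{wn:g}"
        cols[label] = lib.absorbance[:, ::-1][:, j]
    out = pd.DataFrame(cols, index=pd.Index(lib.sample_ids, name="id"))
    out.to_csv(path, float_format="%.12g")


# ---------------------------------------------------------------------------
# Grid operations
# ---------------------------------------------------------------------------


def resample(
    lib: SpectralLibrary,
    wn_min: float = DEFAULT_WN_MIN,
    wn_max: float = DEFAULT_WN_MAX,
    step: float = DEFAULT_WN_STEP,
) -> SpectralLibrary:
    """Truncate and interpolate spectra onto a uniform grid.

    The target axis is ``wn_min, wn_min+step, ..., wn_max``; absorbances
    are piecewise-linearly interpolated.  No extrapolation: the requested
    range must lie within the source grid span.
    """
    if step <= 0:
        raise ValueError("step must be positive")
    src = lib.grid.values
    if wn_min < src[0] - 1e-9 or wn_max > src[-1] + 1e-9:
        raise ValueError(
            f"requested range [{wn_min}, {wn_max}] exceeds source span "
            f"[{src[0]}, {src[-1]}]; extrapolation is not supported"
        )
    n_steps = int(round((wn_max - wn_min) / step))
    target = wn_min + step * np.arange(n_steps + 1)
    target = target[target <= wn_max + 1e-9]
    if np.array_equal(target, src):
        return lib.with_absorbance(lib.absorbance.copy())
    out = np.empty((lib.n_samples, target.size))
    for i in range(lib.n_samples):
        out[i] = np.interp(target, src, lib.absorbance[i])
    return lib.with_absorbance(out, grid=WavenumberGrid(target))


def remove_region(lib: SpectralLibrary, lo: float, hi: float) -> SpectralLibrary:
    """Drop all channels with ``lo <= wavenumber <= hi`` (inclusive bounds).

    An empty intersection is a no-op; removing every channel is an error.
    """
    if lo >= hi:
        raise ValueError("require lo < hi")
    keep = (lib.grid.values < lo) | (lib.grid.values > hi)
    if keep.all():
        return lib.with_absorbance(lib.absorbance.copy())
    if not keep.any():
        raise ValueError("removal covers entire grid")
    return lib.with_absorbance(
        lib.absorbance[:, keep].copy(), grid=WavenumberGrid(lib.grid.values[keep])
    )
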