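"""Synthetic two-instrument soil MIR spectra with known ground truth.

The study's real spectra (a >50k-sample national MIR library plus
prediction sets scanned on a second spectrometer) are proprietary, so
this module generates paired primary/secondary libraries that reproduce
the *structure* the pipeline relies on:

* skewed soil-property distributions (organic carbon strongly
  right-skewed, mean more than twice the median);
* absorbance spectra on the 4000–628 cm⁻¹ grid at 2 cm⁻¹, built as a
  linear-in-properties mixture of Gaussian absorption bands placed at
  soil-relevant wavenumbers, over a smooth per-sample baseline, plus
  channel noise;
* an inter-instrument distortion dominated by a *shared* smooth
  baseline shift and gain curve (so the first principal component of
  pooled raw spectra separates the instruments, and a first derivative
  collapses that separation), with a sub-grid wavelength shift and small
  per-sample components that a transfer model cannot remove.

Because the shared instrument signature dominates the distortion, a
piecewise transfer operator estimated on a ~100-sample transfer set
generalises to unseen samples — the property that makes calibration
transfer worthwhile in the first place.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml

from .spectra import (
    DEFAULT_WN_MAX,
    DEFAULT_WN_MIN,
    DEFAULT_WN_STEP,
    PropertyTable,
    SpectralLibrary,
    WavenumberGrid,
)
from .transfer import select_transfer_indices

__all__ = [
    "SyntheticConfig",
    "SyntheticScenario",
    "generate_properties",
    "generate_primary_spectra",
    "distort_to_secondary",
    "generate_scenario",
]


#: Per-property marginal distributions (family, parameters).
DEFAULT_PROPERTY_DISTRIBUTIONS = {
    # right-skewed: lognormal median 1.5 wt%, sigma 1.4 -> mean/median ~ 2.7
    "OC": {"family": "lognormal", "mu": float(np.log(1.5)), "sigma": 1.4},
    "CaCO3": {"family": "lognormal", "mu": float(np.log(3.0)), "sigma": 1.2},
    "clay": {"family": "beta_scaled", "a": 2.0, "b": 5.0, "scale": 60.0},
    "pH": {"family": "normal", "mean": 6.4, "sd": 1.2, "lo": 3.5, "hi": 9.5},
    "BD": {"family": "normal", "mean": 1.25, "sd": 0.30, "lo": 0.5, "hi": 2.2},
}

#: Gaussian absorption bands per property: (center cm^-1, width cm^-1,
#: intensity per property unit).  Centers sit at soil-relevant regions
#: (aliphatic C-H ~2920/2850, amide/aromatic ~1630, carbonate ~1450/880/2515,
#: clay O-H/Si-O ~3620/1030/915) for interpretability only.
DEFAULT_BAND_TABLE = {
    "OC": [(2920.0, 60.0, 0.012), (2850.0, 40.0, 0.006), (1630.0, 80.0, 0.010), (1720.0, 50.0, 0.004)],
    "CaCO3": [(1450.0, 110.0, 0.010), (880.0, 20.0, 0.008), (2515.0, 35.0, 0.004)],
    "clay": [(3620.0, 30.0, 0.004), (1030.0, 90.0, 0.005), (915.0, 25.0, 0.003)],
    "pH": [(3400.0, 200.0, 0.008), (1400.0, 90.0, 0.006)],
    "BD": [(1100.0, 300.0, 0.002)],
}


@dataclass
class SyntheticConfig:
    """Everything that determines a synthetic scenario, plus its seed."""

    n_calibration: int = 2000
    n_transfer: int = 100
    n_prediction: int = 300
    seed: int = 0
    grid: tuple[float, float, float] = (DEFAULT_WN_MIN, DEFAULT_WN_MAX, DEFAULT_WN_STEP)
    property_distributions: dict = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_PROPERTY_DISTRIBUTIONS.items()}
    )
    band_table: dict = field(
        default_factory=lambda: {k: [tuple(b) for b in v] for k, v in DEFAULT_BAND_TABLE.items()}
    )
    baseline_degree: int = 2
    baseline_scale: float = 0.06
    baseline_level: float = 0.3
    noise_sd: float = 0.003
    # secondary-instrument distortion
    baseline_shift_scale: float = 1.0
    baseline_wiggle_sd: float = 0.003
    gain_curve_amp: float = 0.25
    gain_mean: float = 1.0
    gain_sd: float = 0.003
    wavelength_shift: float = 1.0
    distortion_noise_sd: float = 0.002

    def __post_init__(self) -> None:
        for prop, bands in self.band_table.items():
            for center, width, intensity in bands:
                if width <= 0:
                    raise ValueError(f"band width must be positive ({prop})")
        if self.noise_sd < 0 or self.distortion_noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if abs(self.wavelength_shift) > 4.0:
            raise ValueError("wavelength shift must be within +/-4 cm^-1")

    @property
    def wavenumbers(self) -> np.ndarray:
        lo, hi, step = self.grid
        return lo + step * np.arange(int(round((hi - lo) / step)) + 1)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh)

    @classmethod
    def from_yaml(cls, path) -> "SyntheticConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh)
        if "grid" in payload:
            payload["grid"] = tuple(payload["grid"])
        if "band_table" in payload:
            payload["band_table"] = {
                k: [tuple(b) for b in v] for k, v in payload["band_table"].items()
            }
        return cls(**payload)


def _draw_property(rng: np.random.Generator, dist: dict, n: int) -> np.ndarray:
    family = dist["family"]
    if family == "lognormal":
        return rng.lognormal(dist["mu"], dist["sigma"], n)
    if family == "beta_scaled":
        return dist["scale"] * rng.beta(dist["a"], dist["b"], n)
    if family == "normal":
        vals = rng.normal(dist["mean"], dist["sd"], n)
        return np.clip(vals, dist.get("lo", -np.inf), dist.get("hi", np.inf))
    raise ValueError(f"unknown distribution family {family!r}")


def generate_properties(
    config: SyntheticConfig, n: int | None = None, seed: int | None = None
) -> PropertyTable:
    """Draw a seeded property table from the configured marginals."""
    n = config.n_calibration if n is None else int(n)
    rng = np.random.default_rng(config.seed if seed is None else seed)
    data = {}
    for prop, dist in config.property_distributions.items():
        data[prop] = _draw_property(rng, dist, n)
    ids = [f"S{i:05d}" for i in range(n)]
    return PropertyTable(pd.DataFrame(data, index=ids))


def _band_templates(config: SyntheticConfig) -> dict[str, np.ndarray]:
    wn = config.wavenumbers
    templates = {}
    for prop, bands in config.band_table.items():
        t = np.zeros_like(wn)
        for center, width, intensity in bands:
            t += intensity * np.exp(-0.5 * ((wn - center) / width) ** 2)
        templates[prop] = t
    return templates


def _legendre_basis(wn: np.ndarray, degree: int) -> np.ndarray:
    u = 2.0 * (wn - wn[0]) / (wn[-1] - wn[0]) - 1.0
    return np.polynomial.legendre.legvander(u, degree)  # (n_channels, degree+1)


def generate_primary_spectra(
    props: PropertyTable, config: SyntheticConfig, seed: int | None = None
) -> SpectralLibrary:
    """Forward-model absorbance spectra on the primary instrument.

    Absorbance is the property-weighted sum of the Gaussian band
    templates, plus a constant level, a smooth random per-sample
    baseline (Legendre polynomial) and white channel noise; values are
    clipped at zero.
    """
    rng = np.random.default_rng(config.seed + 1 if seed is None else seed)
    wn = config.wavenumbers
    n = len(props.sample_ids)
    templates = _band_templates(config)
    spectra = np.zeros((n, wn.size))
    for prop, template in templates.items():
        if prop in props.properties:
            vals = np.nan_to_num(props.values_for(prop), nan=0.0)
            spectra += vals[:, None] * template[None, :]
    basis = _legendre_basis(wn, config.baseline_degree)
    coefs = rng.normal(0.0, config.baseline_scale, (n, config.baseline_degree + 1))
    spectra += config.baseline_level + coefs @ basis.T
    if config.noise_sd > 0:
        spectra += rng.normal(0.0, config.noise_sd, spectra.shape)
    spectra = np.clip(spectra, 0.0, None)
    return SpectralLibrary(
        grid=WavenumberGrid(wn),
        absorbance=spectra,
        sample_ids=props.sample_ids,
        instrument="primary",
    )


def _shared_signature(config: SyntheticConfig, wn: np.ndarray):
    """Deterministic instrument signature: baseline shift and gain curve."""
    u = 2.0 * (wn - wn[0]) / (wn[-1] - wn[0]) - 1.0
    baseline = config.baseline_shift_scale * (0.9 + 0.25 * u - 0.15 * u**2)
    gain = 1.0 + config.gain_curve_amp * (0.5 * u + 0.3 * (u**2 - 1.0 / 3.0))
    return baseline, gain


def distort_to_secondary(
    lib: SpectralLibrary, config: SyntheticConfig, seed: int | None = None
) -> SpectralLibrary:
    """Re-scan a primary library on the simulated secondary instrument.

    The distortion is: sub-grid wavelength shift (edge values held),
    shared smooth gain curve times a per-sample scalar gain, shared
    smooth baseline shift, per-sample smooth baseline wiggle, and white
    noise.  With every scale at zero the output equals the input.
    """
    if lib.instrument != "primary":
        raise ValueError("distortion applies to a primary-instrument library")
    rng = np.random.default_rng(config.seed + 2 if seed is None else seed)
    wn = lib.grid.values
    shift = config.wavelength_shift
    span = wn[-1] - wn[0]
    if abs(shift) >= span:
        raise ValueError("wavelength shift exceeds the grid span")
    x = lib.absorbance
    if shift != 0.0:
        shifted = np.empty_like(x)
        for i in range(x.shape[0]):
            shifted[i] = np.interp(wn + shift, wn, x[i])
        x = shifted
    baseline, gain_curve = _shared_signature(config, wn)
    gains = rng.normal(config.gain_mean, config.gain_sd, x.shape[0])
    out = x * gain_curve[None, :] * gains[:, None] + baseline[None, :]
    if config.baseline_wiggle_sd > 0:
        basis = _legendre_basis(wn, 2)
        coefs = rng.normal(0.0, config.baseline_wiggle_sd, (x.shape[0], 3))
        out += coefs @ basis.T
    if config.distortion_noise_sd > 0:
        out += rng.normal(0.0, config.distortion_noise_sd, out.shape)
    return lib.with_absorbance(out, instrument="secondary")


@dataclass
class SyntheticScenario:
    """A complete simulated study: library, transfer set and prediction set.

    The transfer set is Kennard–Stone-selected from the generated
    library and withheld from calibration (mirroring how a transfer set
    is carved out of a real library); transfer and prediction samples
    exist on both instruments, calibration samples only on the primary.
    """

    config: SyntheticConfig
    calibration: SpectralLibrary
    calibration_props: PropertyTable
    transfer_primary: SpectralLibrary
    transfer_secondary: SpectralLibrary
    transfer_props: PropertyTable
    prediction_primary: SpectralLibrary
    prediction_secondary: SpectralLibrary
    prediction_props: PropertyTable


def generate_scenario(config: SyntheticConfig | None = None) -> SyntheticScenario:
    """Generate the default two-instrument study from one master seed."""
    config = config if config is not None else SyntheticConfig()
    ss = np.random.SeedSequence(config.seed)
    seeds = [int(s.generate_state(1)[0] % 2**31) for s in ss.spawn(6)]
    n_total = config.n_calibration
    props = generate_properties(config, n=n_total, seed=seeds[0])
    primary = generate_primary_spectra(props, config, seed=seeds[1])
    transfer_idx = select_transfer_indices(primary, config.n_transfer)
    mask = np.ones(n_total, dtype=bool)
    mask[transfer_idx] = False
    calibration = primary.subset(np.flatnonzero(mask))
    cal_props = props.subset(calibration.sample_ids)
    transfer_primary = primary.subset(transfer_idx)
    transfer_props = props.subset(transfer_primary.sample_ids)
    transfer_secondary = distort_to_secondary(transfer_primary, config, seed=seeds[2])
    pred_props = generate_properties(config, n=config.n_prediction, seed=seeds[3])
    pred_props = PropertyTable(
        pred_props.data.set_axis(
            [f"P{i:05d}" for i in range(config.n_prediction)], axis=0
        )
    )
    prediction_primary = generate_primary_spectra(pred_props, config, seed=seeds[4])
    prediction_secondary = distort_to_secondary(
        prediction_primary, config, seed=seeds[5]
    )
    return SyntheticScenario(
        config=config,
        calibration=calibration,
        calibration_props=cal_props,
        transfer_primary=transfer_primary,
        transfer_secondary=transfer_secondary,
        transfer_props=transfer_props,
        prediction_primary=prediction_primary,
        prediction_secondary=prediction_secondary,
        prediction_props=pred_props,
    )
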