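"""End-to-end experiment orchestration.

Runs the full calibration-transfer study on either a synthetic scenario
or user-supplied wide-CSV files: resample to the common grid, screen the
calibration library for outliers (per property), fit PDS on the transfer
set (raw and/or first-derivative variants), remove the atmospheric CO2
region, pretreat, fit the property models, predict every evaluation arm
(primary where available, secondary, PDS-transferred secondary), flag
prediction spectra outside the calibration space with the F-ratio, run
the direct-calibration leave-one-out arm, and emit tidy report tables.

Stage ordering pins the ambiguities deliberately: PDS is fitted and
applied *before* CO2-region removal; outlier screening happens before
any model fit; F-ratio flags annotate predictions as potentially
unreliable but never remove them.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import evaluate as ev
from .preprocess import apply_pretreatment, first_derivative
from .regression import (
    MBLConfig,
    ModelSpec,
    fit_plsr,
    fit_plugin_model,
    mbl_predict,
    registered_plugins,
)
from .screening import f_ratio_flags, screen_calibration_outliers
from .spectra import (
    CO2_REGION,
    DEFAULT_WN_MAX,
    DEFAULT_WN_MIN,
    DEFAULT_WN_STEP,
    SpectralLibrary,
    read_library,
    remove_region,
    resample,
    write_library,
)
from .synthetic import SyntheticConfig, generate_scenario
from .transfer import PiecewiseDirectStandardization

__all__ = ["ExperimentConfig", "ExperimentReport", "run_experiment"]

log = logging.getLogger(__name__)


@dataclass
class ExperimentConfig:
    """Declarative description of one experiment run."""

    scenario: SyntheticConfig | None = None
    files: dict = field(default_factory=dict)
    properties: list = field(default_factory=lambda: ["OC"])
    models: list = field(default_factory=lambda: ["plsr", "mbl"])
    plugin_name: str = "cubist"
    pretreatments: list = field(
        default_factory=lambda: ["baseline_offset", "first_derivative"]
    )
    pds_variants: list = field(default_factory=lambda: ["raw"])
    pds_half_window: int = 1
    pds_n_pc: int = 1
    max_ncomp: int = 20
    mbl: dict = field(default_factory=dict)
    screen_outliers: bool = True
    direct_calibration_models: list = field(default_factory=lambda: ["plsr"])
    resample_grid: tuple = (DEFAULT_WN_MIN, DEFAULT_WN_MAX, DEFAULT_WN_STEP)
    seed: int = 0

    def __post_init__(self) -> None:
        for v in self.pds_variants:
            if v not in ("raw", "first_derivative"):
                raise ValueError(f"unknown PDS variant {v!r}")
        for p in self.pretreatments:
            if p not in ("baseline_offset", "first_derivative"):
                raise ValueError(f"unknown pretreatment {p!r}")

    def mbl_config(self) -> MBLConfig:
        return MBLConfig(**self.mbl)

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh) or {}
        if payload.get("scenario") is not None:
            payload["scenario"] = SyntheticConfig(**payload["scenario"])
        if "resample_grid" in payload:
            payload["resample_grid"] = tuple(payload["resample_grid"])
        return cls(**payload)


@dataclass
class ExperimentReport:
    """Tidy outputs of one experiment run."""

    reports: pd.DataFrame
    rmse_diff: pd.DataFrame
    flags: pd.DataFrame
    screen_summary: pd.DataFrame
    skipped: list

    def summary(self) -> str:
        lines = ["Experiment report", "=" * 60]
        cols = ["property", "model", "pretreatment", "arm", "n", "r2", "rmse", "rpiq", "category"]
        present = [c for c in cols if c in self.reports.columns]
        lines.append(self.reports[present].to_string(index=False))
        if len(self.rmse_diff):
            lines.append("")
            lines.append("Percent RMSE difference (positive = improvement):")
            lines.append(self.rmse_diff.to_string(index=False))
        for note in self.skipped:
            lines.append(f"skipped: {note}")
        return "\n".join(lines)


def _stage_seed(master: int, label: str) -> int:
    """Deterministic per-stage seed derived from the master seed."""
    import zlib

    h = np.random.SeedSequence([master, zlib.crc32(label.encode())])
    return int(h.generate_state(1)[0] % 2**31)


class _Stage:
    """Context manager that logs stage timings and names failures."""

    def __init__(self, name: str):
        self.name = name

    def __enter__(self):
        self.t0 = time.perf_counter()
        log.info("stage %s: start", self.name)
        return self

    def __exit__(self, exc_type, exc, tb):
        dt = time.perf_counter() - self.t0
        if exc_type is not None:
            log.error("stage %s: FAILED after %.1fs: %s", self.name, dt, exc)
            raise RuntimeError(f"stage {self.name!r} failed: {exc}") from exc
        log.info("stage %s: done in %.1fs", self.name, dt)


def _load_inputs(config: ExperimentConfig):
    """Return (calibration, cal_props, transfer pair, prediction arms, pred_props)."""
    if config.scenario is not None:
        sc = generate_scenario(config.scenario)
        return (
            sc.calibration,
            sc.calibration_props,
            sc.transfer_primary,
            sc.transfer_secondary,
            sc.prediction_primary,
            sc.prediction_secondary,
            sc.prediction_props,
        )
    f = config.files
    required = ("calibration", "transfer_primary", "transfer_secondary", "prediction_secondary")
    missing = [k for k in required if k not in f]
    if missing:
        raise ValueError(f"experiment files missing: {missing}")
    cal, cal_props = read_library(f["calibration"], instrument="primary")
    tp, _ = read_library(f["transfer_primary"], instrument="primary")
    ts, _ = read_library(f["transfer_secondary"], instrument="secondary")
    ps, pred_props = read_library(f["prediction_secondary"], instrument="secondary")
    pp = None
    if "prediction_primary" in f:
        pp, props2 = read_library(f["prediction_primary"], instrument="primary")
        pred_props = pred_props if pred_props is not None else props2
    if cal_props is None or pred_props is None:
        raise ValueError("calibration and prediction files must carry property columns")
    return cal, cal_props, tp, ts, pp, ps, pred_props


def _trim_edges(lib: SpectralLibrary, k: int, grid) -> SpectralLibrary:
    return lib.with_absorbance(lib.absorbance[:, k : lib.n_channels - k], grid=grid)


def run_experiment(config: ExperimentConfig, out_dir=None) -> ExperimentReport:
    """Execute the full experiment grid; optionally write a report bundle."""
    seed = config.seed
    with _Stage("load"):
        cal, cal_props, tp, ts, pp, ps, pred_props = _load_inputs(config)
    with _Stage("resample"):
        lo, hi, step = config.resample_grid
        cal = resample(cal, lo, hi, step)
        tp, ts = resample(tp, lo, hi, step), resample(ts, lo, hi, step)
        ps = resample(ps, lo, hi, step)
        pp = resample(pp, lo, hi, step) if pp is not None else None

    # calibration outlier screen, per property, on baseline-offset spectra
    kept: dict[str, np.ndarray] = {}
    screen_rows = []
    with _Stage("outlier-screen"):
        X_screen = apply_pretreatment(cal, "baseline_offset").absorbance
        for prop in config.properties:
            y = cal_props.values_for(prop, cal.sample_ids)
            ok = np.isfinite(y)
            if config.screen_outliers and ok.sum() >= 50:
                res = screen_calibration_outliers(
                    X_screen[ok], y[ok], seed=_stage_seed(seed, f"screen:{prop}")
                )
                keep_local = ~res.flags
                kept[prop] = np.flatnonzero(ok)[keep_local]
                screen_rows.append(
                    {
                        "property": prop,
                        "n_before": int(ok.sum()),
                        "n_after": int(keep_local.sum()),
                        "chosen_threshold": res.chosen_threshold,
                        "flagged_fraction": res.flagged_fraction,
                    }
                )
            else:
                kept[prop] = np.flatnonzero(ok)
                screen_rows.append(
                    {
                        "property": prop,
                        "n_before": int(ok.sum()),
                        "n_after": int(ok.sum()),
                        "chosen_threshold": np.nan,
                        "flagged_fraction": 0.0,
                    }
                )

    # PDS variants (fitted before CO2 removal)
    pds_models = {}
    with _Stage("pds-fit"):
        for variant in config.pds_variants:
            if variant == "raw":
                prim, sec = tp, ts
            else:
                prim, sec = first_derivative(tp), first_derivative(ts)
            pds_models[variant] = PiecewiseDirectStandardization(
                prim, sec, half_window=config.pds_half_window, n_pc=config.pds_n_pc
            ).fit()

    # feature spaces: (variant, pretreatment) -> aligned arm libraries
    reports, diffs, flag_rows, skipped = [], [], [], []
    plugin_available = config.plugin_name in registered_plugins()
    if "plugin" in config.models and not plugin_available:
        skipped.append(
            f"plugin arm: no model registered under {config.plugin_name!r}"
        )

    def _arms_for(variant: str, pretreatment: str):
        """Calibration features and per-arm prediction features."""
        pds = pds_models[variant]
        k = pds.half_window
        if variant == "raw":
            base_cal, base_pp, base_ps = cal, pp, ps
            pds_in = ps
        else:
            base_cal = first_derivative(cal)
            base_pp = first_derivative(pp) if pp is not None else None
            base_ps = first_derivative(ps)
            pds_in = base_ps
        g = pds.retained_grid
        out = {}
        cal_t = _trim_edges(base_cal, k, g)
        arms = {"secondary": _trim_edges(base_ps, k, g), "secondary_pds": pds.transform(pds_in)}
        if base_pp is not None:
            arms["primary"] = _trim_edges(base_pp, k, g)
        cal_t = remove_region(cal_t, *CO2_REGION)
        arms = {a: remove_region(l, *CO2_REGION) for a, l in arms.items()}
        cal_t = apply_pretreatment(cal_t, pretreatment)
        arms = {a: apply_pretreatment(l, pretreatment) for a, l in arms.items()}
        return cal_t, arms

    combos = []
    for variant in config.pds_variants:
        if variant == "raw":
            combos += [("raw", p) for p in config.pretreatments]
        else:
            # derivative-PDS output feeds derivative models directly
            if "first_derivative" in config.pretreatments:
                combos.append(("first_derivative", "first_derivative"))

    with _Stage("model-grid"):
        for variant, pretreatment in combos:
            cal_t, arms = _arms_for(variant, pretreatment)
            # F-ratio screen of each prediction arm against the calibration space
            for arm, lib in arms.items():
                fr = f_ratio_flags(cal_t.absorbance, lib.absorbance)
                for sid, flag, pv in zip(lib.sample_ids, fr.flags, fr.p_value):
                    if flag:
                        flag_rows.append(
                            {
                                "sample_id": sid,
                                "arm": arm,
                                "variant": variant,
                                "pretreatment": pretreatment,
                                "p_value": pv,
                                "note": "potentially unreliable",
                            }
                        )
            for prop in config.properties:
                idx = kept[prop]
                X_cal = cal_t.absorbance[idx]
                y_cal = cal_props.values_for(prop, cal_t.sample_ids)[idx]
                y_pred = pred_props.values_for(prop, ps.sample_ids)
                okp = np.isfinite(y_pred)
                for model_name in config.models:
                    label = f"{prop}:{model_name}:{variant}:{pretreatment}"
                    preds_by_arm = {}
                    if model_name == "plsr":
                        m = fit_plsr(
                            X_cal,
                            y_cal,
                            max_ncomp=config.max_ncomp,
                            seed=_stage_seed(seed, "plsr:" + label),
                        )
                        for arm, lib in arms.items():
                            preds_by_arm[arm] = m.predict(lib.absorbance[okp])
                    elif model_name == "mbl":
                        cfg_mbl = config.mbl_config()
                        for arm, lib in arms.items():
                            res = mbl_predict(
                                X_cal,
                                y_cal,
                                lib.absorbance[okp],
                                config=cfg_mbl,
                                seed=_stage_seed(seed, "mbl:" + label + ":" + arm),
                            )
                            preds_by_arm[arm] = res.predictions
                    elif model_name == "plugin":
                        if not plugin_available:
                            continue
                        spec = ModelSpec(
                            family="plugin",
                            pretreatment=pretreatment,
                            plugin_name=config.plugin_name,
                        )
                        m = fit_plugin_model(X_cal, y_cal, spec)
                        for arm, lib in arms.items():
                            preds_by_arm[arm] = m.predict(lib.absorbance[okp])
                    else:
                        raise ValueError(f"unknown model {model_name!r}")
                    armreps = {}
                    for arm, pred in preds_by_arm.items():
                        rep = ev.metrics(
                            y_pred[okp],
                            pred,
                            arm=arm,
                            property=prop,
                            model=model_name,
                            pretreatment=pretreatment,
                        )
                        rep.note = (rep.note + f" pds_variant={variant}").strip()
                        armreps[arm] = rep
                        reports.append(rep)
                    ref_arm = "primary" if "primary" in armreps else "secondary"
                    for alt in ("secondary", "secondary_pds"):
                        if alt in armreps and alt != ref_arm:
                            diffs.append(
                                {
                                    "property": prop,
                                    "model": model_name,
                                    "pretreatment": pretreatment,
                                    "variant": variant,
                                    "reference": ref_arm,
                                    "alternative": alt,
                                    "pct_rmse_diff": ev.pct_rmse_diff(
                                        armreps[ref_arm].rmse, armreps[alt].rmse
                                    ),
                                }
                            )
                    if "secondary" in armreps and "secondary_pds" in armreps:
                        diffs.append(
                            {
                                "property": prop,
                                "model": model_name,
                                "pretreatment": pretreatment,
                                "variant": variant,
                                "reference": "secondary",
                                "alternative": "secondary_pds",
                                "pct_rmse_diff": ev.pct_rmse_diff(
                                    armreps["secondary"].rmse,
                                    armreps["secondary_pds"].rmse,
                                ),
                            }
                        )

    # direct calibration on the secondary prediction spectra (LOOCV)
    with _Stage("direct-calibration"):
        for pretreatment in config.pretreatments:
            lib = apply_pretreatment(remove_region(ps, *CO2_REGION), pretreatment)
            for prop in config.properties:
                y = pred_props.values_for(prop, lib.sample_ids)
                okp = np.isfinite(y)
                for model_name in config.direct_calibration_models:
                    if okp.sum() < 10:
                        continue
                    try:
                        rep = ev.loocv(
                            lib.absorbance[okp],
                            y[okp],
                            ModelSpec(family=model_name, pretreatment=pretreatment)
                            if model_name != "plugin"
                            else ModelSpec(
                                family="plugin",
                                pretreatment=pretreatment,
                                plugin_name=config.plugin_name,
                            ),
                            seed=_stage_seed(seed, f"dc:{prop}:{model_name}:{pretreatment}"),
                            max_ncomp=config.max_ncomp,
                            mbl_config=config.mbl_config() if model_name == "mbl" else None,
                            property=prop,
                            model=model_name,
                            pretreatment=pretreatment,
                        )
                        reports.append(rep)
                    except LookupError as exc:
                        skipped.append(f"direct calibration {model_name}: {exc}")

    report = ExperimentReport(
        reports=ev.reports_to_frame(reports),
        rmse_diff=pd.DataFrame(diffs),
        flags=pd.DataFrame(
            flag_rows,
            columns=["sample_id", "arm", "variant", "pretreatment", "p_value", "note"],
        ),
        screen_summary=pd.DataFrame(screen_rows),
        skipped=skipped,
    )
    if out_dir is not None:
        _write_bundle(report, pds_models, out_dir)
    return report


def _write_bundle(report: ExperimentReport, pds_models, out_dir) -> None:
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    fmt = "%.10g"
    report.reports.to_csv(out / "reports.csv", index=False, float_format=fmt)
    report.rmse_diff.to_csv(out / "rmse_diff.csv", index=False, float_format=fmt)
    report.flags.to_csv(out / "prediction_flags.csv", index=False, float_format=fmt)
    report.screen_summary.to_csv(out / "outlier_screen.csv", index=False, float_format=fmt)
    for variant, model in pds_models.items():
        model.save(out / f"pds_{variant}.json")
    (out / "summary.txt").write_text(report.summary() + "\n")


def simulate_to_files(config: SyntheticConfig, out_dir) -> dict:
    """Generate a scenario and write it as csv_wide files; return the paths."""
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    sc = generate_scenario(config)
    paths = {}

    def _w(name, lib, props=None):
        p = out / f"{name}.csv"
        write_library(lib, p, props)
        paths[name] = str(p)

    _w("calibration", sc.calibration, sc.calibration_props)
    _w("transfer_primary", sc.transfer_primary)
    _w("transfer_secondary", sc.transfer_secondary)
    _w("prediction_primary", sc.prediction_primary, sc.prediction_props)
    _w("prediction_secondary", sc.prediction_secondary, sc.prediction_props)
    config.to_yaml(out / "scenario.yaml")
    return paths
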