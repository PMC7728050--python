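"""Model evaluation: fit statistics, quality bins and between-arm deltas.

Performance is summarised with four statistics — R², RMSE, bias and
RPIQ — plus a qualitative R² category.  RPIQ (ratio of performance to
interquartile distance) divides the observed interquartile range
``Q3 - Q1`` by RMSE, so it is comparable across properties with
different spreads; quartiles use linear interpolation between order
statistics (the convention matters and is pinned here).  Between-arm
comparisons use the percent RMSE difference, positive when the
alternative arm improves on the reference.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

from .regression import (
    MBLConfig,
    ModelSpec,
    PLSRegressionCV,
    fit_plugin_model,
    mbl_predict,
)

__all__ = [
    "EvalReport",
    "metrics",
    "categorize_r2",
    "pct_rmse_diff",
    "loocv",
    "reports_to_frame",
]

log = logging.getLogger(__name__)

#: R² quality bins, lower-inclusive as printed.
R2_CATEGORIES = (
    (0.85, "excellent"),
    (0.75, "good"),
    (0.65, "fair"),
    (-np.inf, "non_reliable"),
)


@dataclass
class EvalReport:
    """Fit statistics for one (property, model, pretreatment, arm) cell."""

    n: int
    r2: float
    rmse: float
    bias: float
    rpiq: float
    category: str
    arm: str = ""
    property: str = ""
    model: str = ""
    pretreatment: str = ""
    note: str = ""

    def to_dict(self) -> dict:
        return asdict(self)

    def summary(self) -> str:
        rpiq = "inf" if np.isinf(self.rpiq) else f"{self.rpiq:.3g}"
        head = " / ".join(
            s for s in (self.property, self.model, self.pretreatment, self.arm) if s
        )
        return (
            f"{head + ': ' if head else ''}n={self.n}  R2={self.r2:.3f}  "
            f"RMSE={self.rmse:.4g}  bias={self.bias:.4g}  RPIQ={rpiq}  "
            f"[{self.category}]"
        )


def categorize_r2(r2: float) -> str:
    """Map an R² value onto the four-quality scale."""
    if r2 > 1 + 1e-12:
        raise ValueError("R2 cannot exceed 1")
    for lower, name in R2_CATEGORIES:
        if r2 >= lower:
            return name
    return "non_reliable"  # pragma: no cover


def metrics(
    obs: np.ndarray,
    pred: np.ndarray,
    r2_method: str = "one_minus_sse_sst",
    **labels,
) -> EvalReport:
    """Compute R², RMSE, bias and RPIQ of predictions against observations.

    ``r2_method`` selects the R² convention: the coefficient of
    determination ``1 - SSE/SST`` (default) or ``"squared_correlation"``.
    Perfect predictions give RMSE 0 and an infinite RPIQ sentinel.
    """
    obs = np.asarray(obs, dtype=float).ravel()
    pred = np.asarray(pred, dtype=float).ravel()
    if obs.size != pred.size:
        raise ValueError("obs and pred must have equal length")
    if obs.size < 3:
        raise ValueError("need at least 3 observations")
    if not (np.all(np.isfinite(obs)) and np.all(np.isfinite(pred))):
        raise ValueError("obs and pred must be finite")
    err = pred - obs
    rmse = float(np.sqrt(np.mean(err**2)))
    bias = float(np.mean(err))
    sst = float(np.sum((obs - obs.mean()) ** 2))
    if r2_method == "one_minus_sse_sst":
        r2 = 1.0 - float(np.sum(err**2)) / sst if sst > 0 else np.nan
    elif r2_method == "squared_correlation":
        r2 = float(np.corrcoef(obs, pred)[0, 1] ** 2) if sst > 0 else np.nan
    else:
        raise ValueError(f"unknown r2_method {r2_method!r}")
    q1, q3 = np.quantile(obs, [0.25, 0.75])  # linear interpolation
    note = ""
    if rmse == 0.0:
        rpiq = np.inf
        note = "perfect fit: RPIQ reported as +inf"
    else:
        rpiq = float((q3 - q1) / rmse)
    return EvalReport(
        n=obs.size,
        r2=r2,
        rmse=rmse,
        bias=bias,
        rpiq=rpiq,
        category=categorize_r2(r2) if np.isfinite(r2) else "non_reliable",
        note=note,
        **labels,
    )


def pct_rmse_diff(rmse_ref: float, rmse_alt: float) -> float:
    """Percent RMSE change of the alternative arm relative to the reference.

    ``100 * (rmse_ref - rmse_alt) / rmse_ref``; positive values mean the
    alternative improved on the reference.
    """
    if rmse_ref <= 0:
        raise ValueError("reference RMSE must be positive")
    return 100.0 * (rmse_ref - rmse_alt) / rmse_ref


def loocv(
    X: np.ndarray,
    y: np.ndarray,
    spec: ModelSpec,
    seed: int = 0,
    max_ncomp: int = 20,
    mbl_config: MBLConfig | None = None,
    **labels,
) -> EvalReport:
    """Leave-one-out cross-validation of a direct-calibration model.

    Each sample is predicted by a model fitted on the remaining n-1.
    For PLSR the component count is selected once on the full set (the
    one-sigma rule) and held fixed across folds; MBL performs LOO
    naturally by excluding zero-distance neighbours.  Failed folds are
    dropped from the report with a logged notice.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n = y.size
    if n < 10:
        raise ValueError("LOOCV requires at least 10 samples")
    labels.setdefault("arm", "direct_calibration")
    if spec.family == "plsr":
        from .regression import _fit_pls

        # one-sigma component selection once on the full set; folds refit
        # at that fixed complexity
        ncomp = PLSRegressionCV(X, y, max_ncomp=max_ncomp).fit(seed).n_components
        preds = np.full(n, np.nan)
        idx = np.arange(n)
        for i in range(n):
            m = idx != i
            try:
                pls = _fit_pls(X[m], y[m], ncomp)
                preds[i] = pls.predict(X[i : i + 1]).ravel()[0]
            except Exception as exc:  # pragma: no cover - defensive
                log.warning("LOOCV fold %d failed: %s", i, exc)
        ok = np.isfinite(preds)
        return metrics(y[ok], preds[ok], **labels)
    if spec.family == "mbl":
        res = mbl_predict(X, y, X, config=mbl_config, seed=seed, exclude_self=True)
        return metrics(y, res.predictions, **labels)
    if spec.family == "plugin":
        preds = np.full(n, np.nan)
        idx = np.arange(n)
        for i in range(n):
            m = idx != i
            try:
                model = fit_plugin_model(X[m], y[m], spec)
                preds[i] = model.predict(X[i : i + 1])[0]
            except LookupError:
                raise
            except Exception as exc:  # pragma: no cover - defensive
                log.warning("LOOCV fold %d failed: %s", i, exc)
        ok = np.isfinite(preds)
        return metrics(y[ok], preds[ok], **labels)
    raise ValueError(f"unknown model family {spec.family!r}")


def reports_to_frame(reports) -> pd.DataFrame:
    """Stack :class:`EvalReport` objects into a tidy DataFrame."""
    return pd.DataFrame([r.to_dict() for r in reports])
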