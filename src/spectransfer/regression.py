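"""Property-prediction models for soil spectra.

Three model families are used to predict soil properties from MIR
absorbance:

* **Global PLSR** — partial least squares regression on the whole
  calibration library, with the number of latent variables chosen by the
  one-sigma rule on a 10-segment cross-validation: take the smallest
  component count whose mean CV-RMSE is within one standard error of the
  overall minimum.
* **Memory-based learning (MBL)** — a local model per prediction target:
  spectral neighbours are found by Mahalanobis distance in standardized
  principal-component score space under a grid of distance thresholds
  (clamped to a minimum/maximum neighbourhood size), a weighted-average
  PLSR is fitted to each candidate neighbourhood, and the threshold with
  the smallest local cross-validated RMSE supplies the prediction.
* **Plugin slot** — a registry for a third, rule-based model family
  (Cubist-style); a depth-limited model tree with per-leaf linear models
  is shipped as ``"model_tree"``.  The declared capacity limits
  (committees = 1, at most 100 rules) are honoured as constructor
  defaults so an external Cubist implementation can slot in unchanged.

All fits are deterministic given (data, configuration, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.linear_model import Ridge
from sklearn.tree import DecisionTreeRegressor

from .transfer import _n_pc_for_variance, pca_fit, pca_scores

__all__ = [
    "PLSRegressionCV",
    "PLSRResults",
    "LoadedPLSR",
    "fit_plsr",
    "predict_plsr",
    "MBLConfig",
    "MemoryBasedLearner",
    "MBLResults",
    "mbl_predict",
    "weighted_average_pls",
    "ModelSpec",
    "register_plugin",
    "registered_plugins",
    "fit_plugin_model",
    "ModelTreeRegressor",
]


# ---------------------------------------------------------------------------
# PLS backbone: one NIPALS fit, predictions nested over component counts
# ---------------------------------------------------------------------------


class _PLS1:
    """Single-response NIPALS partial least squares.

    For one response the NIPALS inner loop converges in a single pass,
    so each component is three matrix–vector products and a rank-one
    deflation.  ``x_rotations_`` and ``y_loadings_`` expose the standard
    nested-coefficient identity: the coefficient vector for ``a``
    components is ``x_rotations_[:, :a] @ y_loadings_[:a]``, which makes
    predictions at every component count available from one fit (used by
    the cross-validation curve and the weighted-average predictions).
    """

    def __init__(self, X: np.ndarray, y: np.ndarray, n_comp: int):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float).ravel()
        self._x_mean = X.mean(axis=0)
        self._y_mean = float(y.mean())
        E = X - self._x_mean
        f = y - self._y_mean
        n, p = E.shape
        A = max(1, int(min(n_comp, n - 1, p)))
        W = np.empty((p, A))
        P = np.empty((p, A))
        Q = np.empty(A)
        scale = float(np.sqrt(np.sum(E * E))) or 1.0
        tol = (np.finfo(float).eps * max(n, p) * scale) ** 2
        a = 0
        while a < A:
            w = E.T @ f
            nw = float(np.linalg.norm(w))
            if nw * nw <= tol:
                break
            w /= nw
            t = E @ w
            tt = float(t @ t)
            if tt <= tol:
                break
            pl = E.T @ t / tt
            q = float(f @ t) / tt
            E -= np.outer(t, pl)
            f = f - q * t
            W[:, a], P[:, a], Q[a] = w, pl, q
            a += 1
        if a == 0:  # constant response: intercept-only model
            W, P, Q = np.zeros((p, 1)), np.zeros((p, 1)), np.zeros(1)
            a = 1
        W, P, Q = W[:, :a], P[:, :a], Q[:a]
        # rotations R = W (P'W)^-1; P'W is unit upper triangular
        self.x_rotations_ = np.linalg.solve((P.T @ W).T, W.T).T
        self.y_loadings_ = Q
        self.n_components = a

    @property
    def coef_(self) -> np.ndarray:
        return (self.x_rotations_ @ self.y_loadings_)[None, :]

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        return self._y_mean + (X - self._x_mean) @ (
            self.x_rotations_ @ self.y_loadings_
        )


def _fit_pls(X: np.ndarray, y: np.ndarray, n_comp: int) -> _PLS1:
    return _PLS1(X, y, n_comp)


def _nested_predictions(pls: _PLS1, X: np.ndarray) -> np.ndarray:
    """Predictions at every component count 1..A from a single fit."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    T = (X - pls._x_mean) @ pls.x_rotations_
    steps = T * pls.y_loadings_[None, :]
    return pls._y_mean + np.cumsum(steps, axis=1)


# ---------------------------------------------------------------------------
# Global PLSR with one-sigma component selection
# ---------------------------------------------------------------------------


class PLSRegressionCV:
    """Global PLSR whose component count is set by the one-sigma rule.

    Parameters
    ----------
    X : ndarray (n_samples, n_channels)
        Pretreated calibration spectra.
    y : ndarray (n_samples,)
        Property values; must be complete and non-constant.
    max_ncomp : int, default 20
        Largest candidate number of latent variables.
    n_segments : int, default 10
        Cross-validation segments; assignment is a seeded random
        permutation (no contiguity assumption).
    """

    def __init__(
        self,
        X: np.ndarray,
        y: np.ndarray,
        max_ncomp: int = 20,
        n_segments: int = 10,
    ):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float).ravel()
        if X.shape[0] != y.size:
            raise ValueError("X and y have different sample counts")
        if not np.all(np.isfinite(y)):
            raise ValueError("y contains missing or non-finite values")
        if np.ptp(y) == 0:
            raise ValueError("zero-variance response")
        if X.shape[0] < n_segments:
            raise ValueError("need at least one sample per CV segment")
        self.X, self.y = X, y
        self.max_ncomp = int(min(max_ncomp, X.shape[0] - 1, X.shape[1]))
        self.n_segments = int(n_segments)

    def fit(self, seed: int = 0) -> "PLSRResults":
        rng = np.random.default_rng(seed)
        n = self.X.shape[0]
        assignment = rng.permutation(n) % self.n_segments
        A = self.max_ncomp
        seg_rmse = np.full((self.n_segments, A), np.nan)
        for s in range(self.n_segments):
            val = assignment == s
            Xtr, ytr = self.X[~val], self.y[~val]
            a_fold = int(min(A, Xtr.shape[0] - 1))
            pls = _fit_pls(Xtr, ytr, a_fold)
            preds = _nested_predictions(pls, self.X[val])
            errs = preds - self.y[val][:, None]
            rmse = np.sqrt(np.mean(errs**2, axis=0))
            seg_rmse[s, : rmse.size] = rmse
            if rmse.size < A:  # fold too small for the full range
                seg_rmse[s, rmse.size :] = rmse[-1]
        mean_rmse = seg_rmse.mean(axis=0)
        se = seg_rmse.std(axis=0, ddof=1) / np.sqrt(self.n_segments)
        best = int(np.argmin(mean_rmse))
        # tiny absolute floor so numerically-zero CV errors (exact low-rank
        # fits) compare as equal instead of chasing rounding noise
        floor = 1e-8 * float(np.std(self.y))
        threshold = max(mean_rmse[best] + se[best], floor)
        selected = int(np.flatnonzero(mean_rmse <= threshold)[0]) + 1
        final = _fit_pls(self.X, self.y, selected)
        cv_curve = pd.DataFrame(
            {
                "ncomp": np.arange(1, A + 1),
                "mean_rmse": mean_rmse,
                "se": se,
            }
        )
        return PLSRResults(
            n_components=selected,
            argmin_components=best + 1,
            cv_curve=cv_curve,
            _pls=final,
            n_channels=self.X.shape[1],
            n_samples=n,
            seed=seed,
        )


@dataclass
class PLSRResults:
    """Fitted global PLSR with its cross-validation curve."""

    n_components: int
    argmin_components: int
    cv_curve: pd.DataFrame
    _pls: _PLS1
    n_channels: int
    n_samples: int
    seed: int

    @property
    def coef_(self) -> np.ndarray:
        return self._pls.coef_.ravel()

    @property
    def x_mean_(self) -> np.ndarray:
        return self._pls._x_mean

    @property
    def y_mean_(self) -> float:
        return float(self._pls._y_mean)

    def predict(self, X_new: np.ndarray) -> np.ndarray:
        X_new = np.asarray(X_new, dtype=float)
        if X_new.ndim == 1:
            X_new = X_new[None, :]
        if X_new.shape[1] != self.n_channels:
            raise ValueError(
                f"X_new has {X_new.shape[1]} channels, model expects {self.n_channels}"
            )
        return self._pls.predict(X_new).ravel()

    def save(self, path) -> None:
        """Serialize the fitted predictor to a portable JSON container."""
        import json

        coef = self.coef_
        intercept = self.y_mean_ - float(self.x_mean_ @ coef)
        payload = {
            "n_components": self.n_components,
            "coef": coef.tolist(),
            "intercept": intercept,
            "cv_curve": {
                "ncomp": self.cv_curve["ncomp"].tolist(),
                "mean_rmse": self.cv_curve["mean_rmse"].tolist(),
                "se": self.cv_curve["se"].tolist(),
            },
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @staticmethod
    def load(path) -> "LoadedPLSR":
        return LoadedPLSR.load(path)

    def summary(self) -> str:
        row = self.cv_curve.iloc[self.n_components - 1]
        best = self.cv_curve.iloc[self.argmin_components - 1]
        lines = [
            "PLSR (one-sigma component selection)",
            "=" * 44,
            f"calibration samples:   {self.n_samples}",
            f"channels:              {self.n_channels}",
            f"candidate components:  1..{len(self.cv_curve)}",
            f"CV minimum:            ncomp={self.argmin_components}, "
            f"RMSE={best.mean_rmse:.4g} (SE {best.se:.2g})",
            f"selected (one-sigma):  ncomp={self.n_components}, "
            f"RMSE={row.mean_rmse:.4g}",
        ]
        return "\n".join(lines)


@dataclass
class LoadedPLSR:
    """A deserialized PLSR predictor (coefficients and intercept only)."""

    n_components: int
    coef: np.ndarray
    intercept: float

    def predict(self, X_new: np.ndarray) -> np.ndarray:
        X_new = np.atleast_2d(np.asarray(X_new, dtype=float))
        if X_new.shape[1] != self.coef.size:
            raise ValueError(
                f"X_new has {X_new.shape[1]} channels, model expects {self.coef.size}"
            )
        return X_new @ self.coef + self.intercept

    @classmethod
    def load(cls, path) -> "LoadedPLSR":
        import json

        with open(path) as fh:
            payload = json.load(fh)
        return cls(
            n_components=int(payload["n_components"]),
            coef=np.asarray(payload["coef"], dtype=float),
            intercept=float(payload["intercept"]),
        )


def fit_plsr(
    X: np.ndarray,
    y: np.ndarray,
    max_ncomp: int = 20,
    n_segments: int = 10,
    seed: int = 0,
) -> PLSRResults:
    """Fit a one-sigma-selected PLSR (functional alias)."""
    return PLSRegressionCV(X, y, max_ncomp=max_ncomp, n_segments=n_segments).fit(seed)


def predict_plsr(model: PLSRResults, X_new: np.ndarray) -> np.ndarray:
    return model.predict(X_new)


# ---------------------------------------------------------------------------
# Weighted-average PLSR (the local model family used inside MBL)
# ---------------------------------------------------------------------------


def _wapls_weights(pls: _PLS1, X: np.ndarray, y: np.ndarray, factors) -> np.ndarray:
    """Factor weights inversely proportional to the fitted-residual norm."""
    fitted = _nested_predictions(pls, X)
    norms = np.sqrt(np.sum((fitted - y[:, None]) ** 2, axis=0))[
        np.asarray(factors) - 1
    ]
    floor = max(1e-12, 1e-10 * np.abs(y).max())
    w = 1.0 / np.maximum(norms, floor)
    return w / w.sum()


def weighted_average_pls(
    X: np.ndarray,
    y: np.ndarray,
    X_new: np.ndarray,
    factor_range: tuple[int, int] = (5, 20),
) -> np.ndarray:
    """Weighted-average PLSR prediction.

    One PLS fit at the largest factor count; predictions at each factor
    in ``factor_range`` (clamped to the data's capacity) are averaged
    with weights inversely proportional to the fitted-residual norm at
    that factor, normalized to sum to one.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    X_new = np.atleast_2d(np.asarray(X_new, dtype=float))
    cap = min(X.shape[0] - 1, X.shape[1])
    min_f = max(1, min(factor_range[0], cap))
    max_f = max(min_f, min(factor_range[1], cap))
    pls = _fit_pls(X, y, max_f)
    avail = pls.x_rotations_.shape[1]
    factors = np.arange(min(min_f, avail), avail + 1)
    w = _wapls_weights(pls, X, y, factors)
    preds = _nested_predictions(pls, X_new)[:, factors - 1]
    return preds @ w


# ---------------------------------------------------------------------------
# Memory-based learning
# ---------------------------------------------------------------------------


@dataclass
class MBLConfig:
    """Configuration of the memory-based learner.

    Distance thresholds span 0.4–5.0 (Mahalanobis units in standardized
    PC score space); each candidate neighbourhood is clamped to between
    ``min_neighbors`` and ``max_neighbors`` nearest calibration samples.
    """

    thresholds: np.ndarray = field(
        default_factory=lambda: np.round(np.arange(0.4, 5.0 + 1e-9, 0.2), 10)
    )
    min_neighbors: int = 100
    max_neighbors: int = 200
    dissimilarity: str = "mahalanobis_pc"
    variance_target: float = 0.99
    max_pc: int = 40
    factor_range: tuple[int, int] = (5, 20)
    cv_folds: int = 10

    def __post_init__(self) -> None:
        t = np.asarray(self.thresholds, dtype=float)
        if t.size == 0 or not np.all(np.diff(t) > 0):
            raise ValueError("thresholds must be non-empty and strictly increasing")
        if t[0] <= 0:
            raise ValueError("thresholds must be positive")
        self.thresholds = t
        if self.min_neighbors > self.max_neighbors:
            raise ValueError("min_neighbors must be <= max_neighbors")
        if self.dissimilarity != "mahalanobis_pc":
            raise ValueError(f"unknown dissimilarity {self.dissimilarity!r}")


@dataclass
class MBLResults:
    """Per-target MBL predictions with the selected neighbourhoods."""

    predictions: np.ndarray
    chosen_threshold: np.ndarray
    neighborhood_size: np.ndarray
    config: MBLConfig

    def summary(self) -> str:
        lines = [
            "Memory-based learning (local weighted-average PLSR)",
            "=" * 52,
            f"targets predicted:     {self.predictions.size}",
            f"neighbourhood sizes:   {self.neighborhood_size.min()}"
            f"–{self.neighborhood_size.max()}"
            f" (median {int(np.median(self.neighborhood_size))})",
            f"threshold grid:        {self.config.thresholds[0]:g}"
            f"–{self.config.thresholds[-1]:g}",
        ]
        return "\n".join(lines)


def _dual_wapls_predict(Kc, y_train, Kn_c, factor_range):
    """Weighted-average PLS1 in kernel (dual) form.

    Mathematically identical to :func:`weighted_average_pls` but works
    entirely on the centered train Gram matrix ``Kc`` and the centered
    test-train cross products ``Kn_c`` — the natural formulation when a
    small neighbourhood (n of order 100) meets thousands of channels,
    and the reason one Gram matrix per neighbourhood can serve every
    cross-validation fold.
    """
    y_train = np.asarray(y_train, dtype=float).ravel()
    y_mean = y_train.mean()
    f = y_train - y_mean
    s = f.size
    cap = s - 1
    min_f = max(1, min(factor_range[0], cap))
    max_f = max(min_f, min(factor_range[1], cap))
    K = Kc.copy()
    Kn = Kn_c.copy()
    tol = max(np.finfo(float).eps * s * abs(np.trace(K)), 1e-30)
    fit_steps, pred_steps = [], []
    for _ in range(max_f):
        Kf = K @ f
        s2 = float(f @ Kf)
        if s2 <= tol:
            break
        s_a = np.sqrt(s2)
        t = Kf / s_a
        tt = float(t @ t)
        if tt <= tol:
            break
        tn = Kn @ f / s_a
        q = float(f @ t) / tt
        fit_steps.append(q * t)
        pred_steps.append(q * tn)
        f = f - q * t
        Kt = K @ t
        tKt = float(t @ Kt)
        K -= (np.outer(Kt, t) + np.outer(t, Kt)) / tt - (tKt / tt**2) * np.outer(t, t)
        Kn -= np.outer(Kn @ t, t) / tt + np.outer(tn, Kt) / tt - (
            tKt / tt**2
        ) * np.outer(tn, t)
    if not fit_steps:
        return np.full(Kn_c.shape[0], y_mean)
    fitted = np.cumsum(np.array(fit_steps), axis=0)  # (A, n_train)
    preds = np.cumsum(np.array(pred_steps), axis=0)  # (A, n_new)
    avail = fitted.shape[0]
    factors = np.arange(min(min_f, avail), avail + 1)
    norms = np.sqrt(np.sum((fitted[factors - 1] - (y_train - y_mean)) ** 2, axis=1))
    floor = max(1e-12, 1e-10 * np.abs(y_train).max())
    w = 1.0 / np.maximum(norms, floor)
    w /= w.sum()
    return y_mean + w @ preds[factors - 1]


def _center_gram(G_tt, G_vt):
    """Double-center a train Gram block and a val-train cross block."""
    r = G_tt.mean(axis=1)
    m = G_tt.mean()
    Kc = G_tt - r[None, :] - r[:, None] + m
    Kn = G_vt - G_vt.mean(axis=1, keepdims=True) - r[None, :] + m
    return Kc, Kn


class MemoryBasedLearner:
    """Local weighted-average PLSR with distance-thresholded neighbourhoods."""

    def __init__(self, X_cal: np.ndarray, y_cal: np.ndarray, config: MBLConfig | None = None):
        self.X_cal = np.asarray(X_cal, dtype=float)
        self.y_cal = np.asarray(y_cal, dtype=float).ravel()
        self.config = config if config is not None else MBLConfig()
        if self.X_cal.shape[0] < self.config.min_neighbors:
            raise ValueError(
                f"need at least min_neighbors={self.config.min_neighbors} "
                f"calibration samples, got {self.X_cal.shape[0]}"
            )
        n_pc = _n_pc_for_variance(
            self.X_cal, self.config.variance_target, self.config.max_pc
        )
        self._pca = pca_fit(self.X_cal, n_pc)
        scores = pca_scores(self._pca, self.X_cal)
        self._score_scale = scores.std(axis=0, ddof=1)
        self._score_scale[self._score_scale == 0] = 1.0
        self._cal_scores = scores / self._score_scale

    def _distances(self, X_new: np.ndarray) -> np.ndarray:
        s = pca_scores(self._pca, X_new) / self._score_scale
        d2 = (
            np.sum(s**2, axis=1)[:, None]
            + np.sum(self._cal_scores**2, axis=1)[None, :]
            - 2.0 * s @ self._cal_scores.T
        )
        return np.sqrt(np.maximum(d2, 0.0))

    def _local_cv_rmse(
        self, G: np.ndarray, y: np.ndarray, s: int, rng: np.random.Generator
    ) -> float:
        """K-fold CV RMSE of the local model on the ``s`` nearest neighbours.

        ``G`` is the Gram matrix of the largest neighbourhood; nested
        neighbourhoods reuse its leading block, so the spectra are
        touched once per target.
        """
        cfg = self.config
        folds = rng.permutation(s) % min(cfg.cv_folds, s)
        n_folds = folds.max() + 1
        sq_err, count = 0.0, 0
        for f in range(n_folds):
            val = np.flatnonzero(folds == f)
            trn = np.flatnonzero(folds != f)
            if val.size == s or trn.size < 2:
                continue
            Kc, Kn = _center_gram(G[np.ix_(trn, trn)], G[np.ix_(val, trn)])
            pred = _dual_wapls_predict(Kc, y[trn], Kn, cfg.factor_range)
            sq_err += float(np.sum((pred - y[val]) ** 2))
            count += val.size
        return np.sqrt(sq_err / count) if count else np.inf

    def predict(
        self, X_new: np.ndarray, seed: int = 0, exclude_self: bool = False
    ) -> MBLResults:
        """Predict each target from its own locally selected model.

        With ``exclude_self=True`` a calibration sample at zero distance
        from the target is dropped from every neighbourhood
        (leave-one-out usage on the calibration set itself).
        """
        cfg = self.config
        X_new = np.atleast_2d(np.asarray(X_new, dtype=float))
        dists = self._distances(X_new)
        preds = np.empty(X_new.shape[0])
        chosen_t = np.empty(X_new.shape[0])
        nb_size = np.empty(X_new.shape[0], dtype=int)
        master = np.random.default_rng(seed)
        for i in range(X_new.shape[0]):
            d = dists[i]
            order = np.argsort(d, kind="stable")
            if exclude_self:
                order = order[d[order] > 1e-12]
            avail = order.size
            lo = min(cfg.min_neighbors, avail)
            hi = min(cfg.max_neighbors, avail)
            counts = np.searchsorted(d[order], cfg.thresholds, side="right")
            counts = np.clip(counts, lo, hi)
            sizes, first_pos = np.unique(counts, return_index=True)
            s_max = int(sizes[-1])
            nb = order[:s_max]
            Xn = self.X_cal[nb]
            G = Xn @ Xn.T
            g_t = Xn @ X_new[i]
            y_nb = self.y_cal[nb]
            rng = np.random.default_rng(master.integers(2**31))
            best_rmse, best_j = np.inf, 0
            for j, s in enumerate(sizes):
                rmse = self._local_cv_rmse(G[:s, :s], y_nb[:s], int(s), rng)
                if rmse < best_rmse - 1e-15:
                    best_rmse, best_j = rmse, j
            s = int(sizes[best_j])
            Kc, Kn = _center_gram(G[:s, :s], g_t[:s][None, :])
            preds[i] = _dual_wapls_predict(Kc, y_nb[:s], Kn, cfg.factor_range)[0]
            chosen_t[i] = cfg.thresholds[first_pos[best_j]]
            nb_size[i] = s
        return MBLResults(
            predictions=preds,
            chosen_threshold=chosen_t,
            neighborhood_size=nb_size,
            config=cfg,
        )


def mbl_predict(
    X_cal: np.ndarray,
    y_cal: np.ndarray,
    X_new: np.ndarray,
    config: MBLConfig | None = None,
    seed: int = 0,
    exclude_self: bool = False,
) -> MBLResults:
    """Memory-based-learning prediction (functional alias)."""
    return MemoryBasedLearner(X_cal, y_cal, config).predict(
        X_new, seed=seed, exclude_self=exclude_self
    )


# ---------------------------------------------------------------------------
# Plugin model slot (rule-based model-tree family)
# ---------------------------------------------------------------------------


@dataclass
class ModelSpec:
    """Declarative model request used by the experiment pipeline."""

    family: str  # "plsr" | "mbl" | "plugin"
    pretreatment: str = "baseline_offset"
    plugin_name: str = "cubist"
    hyperparameters: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.family not in ("plsr", "mbl", "plugin"):
            raise ValueError(f"unknown model family {self.family!r}")
        if self.family == "plugin":
            self.hyperparameters.setdefault("committees", 1)
            self.hyperparameters.setdefault("max_rules", 100)


_PLUGINS: dict = {}


def register_plugin(name: str, fitter) -> None:
    """Register a plugin fitter: ``fitter(X, y, spec) -> model`` with ``.predict``."""
    _PLUGINS[name] = fitter


def registered_plugins() -> list[str]:
    return sorted(_PLUGINS)


def fit_plugin_model(X: np.ndarray, y: np.ndarray, spec: ModelSpec):
    """Fit the registered plugin named by ``spec.plugin_name``."""
    if spec.plugin_name not in _PLUGINS:
        raise LookupError(f"no plugin registered under {spec.plugin_name!r}")
    return _PLUGINS[spec.plugin_name](X, y, spec)


class ModelTreeRegressor:
    """Rule-based model tree: CART partition with per-leaf ridge models.

    A stand-in for the Cubist family: a single tree (committees = 1)
    with at most ``max_rules`` leaves partitions PCA score space, and a
    small ridge regression on the scores is fitted within each leaf.
    """

    def __init__(self, committees: int = 1, max_rules: int = 100, n_pc: int = 20):
        if committees != 1:
            raise ValueError("only committees=1 is supported")
        self.max_rules = int(max_rules)
        self.n_pc = n_pc

    def fit(self, X: np.ndarray, y: np.ndarray) -> "ModelTreeRegressor":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float).ravel()
        n_pc = int(min(self.n_pc, X.shape[0] - 1, X.shape[1]))
        self._pca = pca_fit(X, n_pc)
        Z = pca_scores(self._pca, X)
        self._tree = DecisionTreeRegressor(
            max_leaf_nodes=max(2, self.max_rules),
            min_samples_leaf=max(5, X.shape[0] // 200),
            random_state=0,
        ).fit(Z, y)
        leaves = self._tree.apply(Z)
        self._models = {}
        for leaf in np.unique(leaves):
            m = leaves == leaf
            if np.ptp(y[m]) == 0 or m.sum() < n_pc + 2:
                self._models[int(leaf)] = float(y[m].mean())
            else:
                self._models[int(leaf)] = Ridge(alpha=1e-6).fit(Z[m], y[m])
        return self

    def predict(self, X_new: np.ndarray) -> np.ndarray:
        Z = pca_scores(self._pca, np.atleast_2d(np.asarray(X_new, dtype=float)))
        leaves = self._tree.apply(Z)
        out = np.empty(Z.shape[0])
        for i, leaf in enumerate(leaves):
            model = self._models[int(leaf)]
            out[i] = model if isinstance(model, float) else model.predict(Z[i : i + 1])[0]
        return out


def _model_tree_fitter(X, y, spec: ModelSpec) -> ModelTreeRegressor:
    hp = spec.hyperparameters
    return ModelTreeRegressor(
        committees=hp.get("committees", 1), max_rules=hp.get("max_rules", 100)
    ).fit(X, y)


register_plugin("model_tree", _model_tree_fitter)
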