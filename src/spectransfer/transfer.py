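"""Calibration transfer between spectrometers.

A library of spectra scanned on one instrument (the *primary*) rarely
applies directly to spectra of the same material scanned on another (the
*secondary*): baseline shifts, detector gain differences and small
wavelength-registration offsets move the secondary spectra away from the
calibration space.  Piecewise direct standardization (PDS) corrects this
with a banded linear operator estimated from a *transfer set* — samples
scanned on both instruments: the primary absorbance at each channel is
regressed (via principal-component regression) on a small window of
neighbouring secondary channels, so the operator can absorb local
intensity and sub-channel wavelength distortions without the overfitting
risk of a full-spectrum transfer matrix.

The transfer set itself is chosen with the Kennard–Stone algorithm in
principal-component score space, which greedily picks the most mutually
distant — hence most representative — samples.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy.spatial.distance import cdist
from sklearn.decomposition import PCA as _SKPCA

from .spectra import PreprocessingState, SpectralLibrary, WavenumberGrid

__all__ = [
    "PCAModel",
    "pca_fit",
    "pca_scores",
    "kennard_stone",
    "select_transfer_indices",
    "PiecewiseDirectStandardization",
    "PDSTransferResults",
    "fit_pds",
    "apply_pds",
]


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------


@dataclass
class PCAModel:
    """Centered PCA of a spectral matrix.

    ``loadings`` has shape (n_channels, n_pc) with orthonormal columns;
    score column j of the training data has variance equal to
    eigenvalue j.
    """

    center: np.ndarray
    loadings: np.ndarray
    explained_variance: np.ndarray
    explained_variance_ratio: np.ndarray

    @property
    def n_pc(self) -> int:
        return self.loadings.shape[1]


def pca_fit(X: np.ndarray | SpectralLibrary, n_pc: int) -> PCAModel:
    """Fit a centered PCA with ``n_pc`` components."""
    if isinstance(X, SpectralLibrary):
        X = X.absorbance
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    max_pc = min(n - 1, p)
    if not 1 <= n_pc <= max_pc:
        raise ValueError(f"n_pc must be in [1, {max_pc}] for a {n}x{p} matrix")
    pca = _SKPCA(n_components=n_pc, svd_solver="full")
    pca.fit(X)
    return PCAModel(
        center=pca.mean_,
        loadings=pca.components_.T.copy(),
        explained_variance=pca.explained_variance_.copy(),
        explained_variance_ratio=pca.explained_variance_ratio_.copy(),
    )


def pca_scores(model: PCAModel, X: np.ndarray | SpectralLibrary) -> np.ndarray:
    """Project (centered) spectra onto the loadings."""
    if isinstance(X, SpectralLibrary):
        X = X.absorbance
    X = np.asarray(X, dtype=float)
    return (X - model.center) @ model.loadings


def _n_pc_for_variance(
    X: np.ndarray, target: float, cap: int
) -> int:
    """Smallest component count explaining >= ``target`` variance, capped."""
    n, p = X.shape
    limit = min(n - 1, p, cap)
    pca = _SKPCA(n_components=limit, svd_solver="full")
    pca.fit(X)
    cum = np.cumsum(pca.explained_variance_ratio_)
    hit = np.flatnonzero(cum >= target)
    return int(hit[0]) + 1 if hit.size else limit


# ---------------------------------------------------------------------------
# Kennard-Stone
# ---------------------------------------------------------------------------


def kennard_stone(scores: np.ndarray, n_select: int) -> np.ndarray:
    """Greedy max–min (Kennard–Stone) selection in score space.

    The first two picks are the globally most distant pair; every later
    pick maximizes its minimum Euclidean distance to the points already
    selected.  Deterministic: all ties break toward the lowest index.

    Returns the selected row indices in selection order.
    """
    scores = np.asarray(scores, dtype=float)
    if scores.ndim == 1:
        scores = scores.reshape(-1, 1)
    n = scores.shape[0]
    if not 2 <= n_select <= n:
        raise ValueError(f"n_select must be in [2, {n}]")
    d = cdist(scores, scores)
    # lexicographically first pair among those at maximal distance
    flat = np.argmax(d)
    best = d.flat[flat]
    ii, jj = np.where(np.isclose(d, best, rtol=0.0, atol=0.0))
    pairs = [(i, j) for i, j in zip(ii, jj) if i < j]
    first, second = min(pairs) if pairs else (0, 1)
    selected = [int(first), int(second)]
    min_d = np.minimum(d[first], d[second])
    mask = np.ones(n, dtype=bool)
    mask[selected] = False
    while len(selected) < n_select:
        cand = np.where(mask, min_d, -np.inf)
        nxt = int(np.argmax(cand))  # argmax returns the lowest tied index
        selected.append(nxt)
        mask[nxt] = False
        min_d = np.minimum(min_d, d[nxt])
    return np.asarray(selected, dtype=int)


def select_transfer_indices(
    lib: SpectralLibrary,
    n_select: int,
    variance_target: float = 0.99,
    max_pc: int = 50,
) -> np.ndarray:
    """Pick a representative transfer set from a library.

    PCA scores are computed with the smallest number of components
    explaining >= ``variance_target`` of the variance (capped at
    ``max_pc``), then Kennard–Stone runs in that score space.
    """
    n_pc = _n_pc_for_variance(lib.absorbance, variance_target, max_pc)
    model = pca_fit(lib, n_pc)
    return kennard_stone(pca_scores(model, lib), n_select)


# ---------------------------------------------------------------------------
# Piecewise direct standardization
# ---------------------------------------------------------------------------


class PiecewiseDirectStandardization:
    """PDS transfer model between a primary and a secondary spectrometer.

    Parameters
    ----------
    primary, secondary : SpectralLibrary
        Transfer-set spectra of the same samples, same grid, same sample
        order and same pretreatment state, scanned on the two
        instruments.
    half_window : int, default 1
        Half-width k of the moving window; the window covers ``2k + 1``
        channels (the default is the 3-point window).  Channels within k
        of either grid edge cannot form a complete window and are
        dropped from the output.
    n_pc : int, default 1
        Number of principal components of the windowed secondary block
        used in the per-channel principal-component regression.

    Notes
    -----
    Window columns are centered on the transfer-set means and the
    regression includes an intercept, so a pure baseline offset between
    instruments is absorbed exactly.  A zero-variance window yields a
    zero coefficient vector with the primary channel mean as intercept.
    """

    def __init__(
        self,
        primary: SpectralLibrary,
        secondary: SpectralLibrary,
        half_window: int = 1,
        n_pc: int = 1,
    ):
        if primary.grid != secondary.grid:
            raise ValueError("primary and secondary grids do not match")
        if primary.sample_ids != secondary.sample_ids:
            raise ValueError("primary and secondary sample orders do not match")
        if primary.state is not secondary.state:
            raise ValueError(
                "primary and secondary pretreatment states do not match "
                f"({primary.state.value!r} vs {secondary.state.value!r})"
            )
        if half_window < 0:
            raise ValueError("half_window must be >= 0")
        w = 2 * half_window + 1
        if primary.n_samples < w + 1:
            raise ValueError(
                f"need at least {w + 1} transfer samples for half_window={half_window}"
            )
        if not 1 <= n_pc <= w:
            raise ValueError(f"n_pc must be in [1, {w}]")
        self.primary = primary
        self.secondary = secondary
        self.half_window = half_window
        self.n_pc = n_pc

    def fit(self) -> "PDSTransferResults":
        k, w = self.half_window, 2 * self.half_window + 1
        P = self.primary.absorbance
        S = self.secondary.absorbance
        n, N = P.shape
        m = N - 2 * k
        # (m, n, w) stack of windowed secondary blocks, one per output channel
        blocks = np.ascontiguousarray(
            sliding_window_view(S, w, axis=1).transpose(1, 0, 2)
        )
        y = P[:, k : N - k].T  # (m, n)
        col_means = blocks.mean(axis=1)  # (m, w)
        y_means = y.mean(axis=1)  # (m,)
        Bc = blocks - col_means[:, None, :]
        yc = y - y_means[:, None]
        U, sv, Vt = np.linalg.svd(Bc, full_matrices=False)  # (m,n,w),(m,w),(m,w,w)
        tol = np.finfo(float).eps * max(n, w) * sv[:, :1]
        keep = (sv > np.maximum(tol, 1e-12)) & (
            np.arange(w)[None, :] < self.n_pc
        )  # (m, w)
        proj = np.einsum("mnj,mn->mj", U, yc)  # U^T yc per block
        gamma = np.where(keep, proj / np.where(sv > 0, sv, 1.0), 0.0)
        coeffs = np.einsum("mj,mjw->mw", gamma, Vt)  # (m, w)
        intercepts = y_means - np.einsum("mw,mw->m", col_means, coeffs)
        retained = WavenumberGrid(self.primary.grid.values[k : N - k])
        return PDSTransferResults(
            half_window=k,
            n_pc=self.n_pc,
            coeffs=coeffs,
            intercepts=intercepts,
            retained_grid=retained,
            fit_grid=self.primary.grid,
            input_state=self.primary.state,
            n_transfer=n,
        )


@dataclass
class PDSTransferResults:
    """Fitted PDS operator: one window coefficient vector per channel."""

    half_window: int
    n_pc: int
    coeffs: np.ndarray  # (n_retained, 2k+1)
    intercepts: np.ndarray  # (n_retained,)
    retained_grid: WavenumberGrid
    fit_grid: WavenumberGrid
    input_state: PreprocessingState
    n_transfer: int

    def __post_init__(self) -> None:
        if len(self.retained_grid) != len(self.fit_grid) - 2 * self.half_window:
            raise ValueError("retained grid inconsistent with half_window")
        if not (
            np.all(np.isfinite(self.coeffs)) and np.all(np.isfinite(self.intercepts))
        ):
            raise ValueError("PDS coefficients must be finite")

    def transform(self, secondary: SpectralLibrary) -> SpectralLibrary:
        """Apply the banded operator to secondary-instrument spectra."""
        if secondary.grid != self.fit_grid:
            raise ValueError("secondary grid does not match the PDS fitting grid")
        if secondary.state is not self.input_state:
            raise ValueError(
                f"PDS was fitted on {self.input_state.value!r} spectra, "
                f"got {secondary.state.value!r}"
            )
        w = 2 * self.half_window + 1
        blocks = sliding_window_view(secondary.absorbance, w, axis=1)  # (n, m, w)
        out = np.einsum("nmw,mw->nm", blocks, self.coeffs) + self.intercepts
        return secondary.with_absorbance(
            out, grid=self.retained_grid, instrument="secondary_pds"
        )

    def summary(self) -> str:
        lines = [
            "Piecewise Direct Standardization",
            "=" * 40,
            f"window size:        {2 * self.half_window + 1} channels (k={self.half_window})",
            f"PCs per window:     {self.n_pc}",
            f"transfer samples:   {self.n_transfer}",
            f"input pretreatment: {self.input_state.value}",
            f"channels retained:  {len(self.retained_grid)} of {len(self.fit_grid)}",
            f"coefficient range:  [{self.coeffs.min():.4g}, {self.coeffs.max():.4g}]",
            f"intercept range:    [{self.intercepts.min():.4g}, {self.intercepts.max():.4g}]",
        ]
        return "\n".join(lines)

    # -- portable JSON container -------------------------------------------

    def save(self, path) -> None:
        payload = {
            "half_window": self.half_window,
            "n_pc": self.n_pc,
            "input_state": self.input_state.value,
            "n_transfer": self.n_transfer,
            "fit_grid": self.fit_grid.values.tolist(),
            "coeffs": self.coeffs.tolist(),
            "intercepts": self.intercepts.tolist(),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def load(cls, path) -> "PDSTransferResults":
        with open(path) as fh:
            payload = json.load(fh)
        fit_grid = WavenumberGrid(np.asarray(payload["fit_grid"], dtype=float))
        k = int(payload["half_window"])
        retained = WavenumberGrid(fit_grid.values[k : len(fit_grid) - k])
        return cls(
            half_window=k,
            n_pc=int(payload["n_pc"]),
            coeffs=np.asarray(payload["coeffs"], dtype=float),
            intercepts=np.asarray(payload["intercepts"], dtype=float),
            retained_grid=retained,
            fit_grid=fit_grid,
            input_state=PreprocessingState(payload["input_state"]),
            n_transfer=int(payload["n_transfer"]),
        )


def fit_pds(
    primary: SpectralLibrary,
    secondary: SpectralLibrary,
    half_window: int = 1,
    n_pc: int = 1,
) -> PDSTransferResults:
    """Fit a PDS operator (functional alias)."""
    return PiecewiseDirectStandardization(
        primary, secondary, half_window=half_window, n_pc=n_pc
    ).fit()


def apply_pds(
    model: PDSTransferResults, secondary: SpectralLibrary
) -> SpectralLibrary:
    """Apply a fitted PDS operator (functional alias)."""
    return model.transform(secondary)
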