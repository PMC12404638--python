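"""Temporal receptive field (TRF) estimation with cross-validated ridge.

A TRF is a lagged linear map from a feature matrix (a network layer or a
cochleagram) to one unit's binned spike counts: the prediction at bin t
depends on the features at bins t-n_lags+1 .. t, a causal window of 250
ms by default.  Weights minimize L2-penalized squared error; the penalty
is chosen on a log-spaced grid spanning 1e-5..1e15 by k-fold
cross-validation over contiguous temporal blocks, then the model is
refit on all training data at the selected penalty.

Follows the statsmodels convention: ``TemporalReceptiveField`` holds the
data and design, ``fit()`` returns a :class:`TRFResults` with estimates,
the CV curve, and ``summary()``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import linalg

from .containers import FeatureMatrix

__all__ = [
    "LagSpec",
    "default_lambda_grid",
    "build_lagged_design",
    "TemporalReceptiveField",
    "TRFResults",
]


@dataclass(frozen=True)
class LagSpec:
    """Causal lag window: ``n_lags = round(window * rate)``, half-up."""

    window: float = 0.25
    rate: float = 20.0

    @property
    def n_lags(self) -> int:
        n = int(math.floor(self.window * self.rate + 0.5))
        if n < 1:
            raise ValueError("lag window shorter than one bin")
        return n


def default_lambda_grid(n_points: int = 21) -> np.ndarray:
    """Log-spaced ridge penalties from 1e-5 to 1e15."""
    return np.logspace(-5, 15, n_points)


def build_lagged_design(fm: FeatureMatrix, spec: LagSpec) -> np.ndarray:
    """Lagged design matrix for one stimulus.

    Row t concatenates the ``n_lags`` most recent frames, oldest first,
    zero-padded before stimulus onset — so lags never cross a stimulus
    boundary when stimuli are lagged separately and then concatenated.
    """
    if abs(fm.sampling_rate - spec.rate) > 1e-9 * max(fm.sampling_rate, spec.rate):
        raise ValueError(
            f"feature rate {fm.sampling_rate} != lag-spec rate {spec.rate}"
        )
    n_lags = spec.n_lags
    T, D = fm.values.shape
    padded = np.vstack([np.zeros((n_lags - 1, D)), fm.values])
    windows = np.lib.stride_tricks.sliding_window_view(padded, n_lags, axis=0)
    # windows: (T, D, n_lags) with lag axis oldest->newest; flatten lag-major
    return windows.transpose(0, 2, 1).reshape(T, n_lags * D)


def _as_lists(
    features: FeatureMatrix | list[FeatureMatrix],
    counts: np.ndarray | list[np.ndarray],
) -> tuple[list[FeatureMatrix], list[np.ndarray]]:
    if isinstance(features, FeatureMatrix):
        features = [features]
    counts = [np.asarray(c, dtype=float).ravel() for c in (
        [counts] if isinstance(counts, np.ndarray) else counts
    )]
    if len(features) != len(counts):
        raise ValueError("one count sequence per feature matrix required")
    return list(features), counts


class TemporalReceptiveField:
    """Ridge TRF model from feature matrices to one unit's spike counts.

    Parameters
    ----------
    counts
        Per-stimulus binned spike counts (one 1-D array per stimulus), at
        the same rate as the features.
    features
        Per-stimulus feature matrices, all at one sampling rate.
    window
        Causal lag window in seconds (default 0.25).
    lambda_grid
        Ridge penalties to cross-validate over; defaults to 21 log-spaced
        points across 1e-5..1e15.
    standardize
        Z-score design columns on the training folds before penalizing.
        The intercept is never penalized.
    """

    def __init__(
        self,
        counts: np.ndarray | list[np.ndarray],
        features: FeatureMatrix | list[FeatureMatrix],
        window: float = 0.25,
        lambda_grid: np.ndarray | None = None,
        standardize: bool = True,
    ) -> None:
        features, counts = _as_lists(features, counts)
        rate = features[0].sampling_rate
        self.spec = LagSpec(window=window, rate=rate)
        self.n_dims = features[0].n_dims
        designs, ys = [], []
        for fm, y in zip(features, counts):
            if fm.n_dims != self.n_dims:
                raise ValueError("inconsistent feature dimensionality across stimuli")
            n = min(fm.n_frames, y.size)
            designs.append(build_lagged_design(
                FeatureMatrix(fm.values[:n], rate), self.spec))
            ys.append(y[:n])
        self.exog = np.vstack(designs)
        self.endog = np.concatenate(ys)
        self.lambda_grid = (
            default_lambda_grid() if lambda_grid is None else np.asarray(lambda_grid)
        )
        self.standardize = standardize

    @classmethod
    def from_session(
        cls, unit_counts: dict[str, np.ndarray],
        features: dict[str, FeatureMatrix], **kwargs
    ) -> "TemporalReceptiveField":
        sids = sorted(unit_counts)
        return cls([unit_counts[s] for s in sids], [features[s] for s in sids], **kwargs)

    # -- fitting ---------------------------------------------------------

    def _fold_slices(self, n: int, k: int) -> list[slice]:
        """Contiguous temporal blocks, sizes differing by at most one."""
        edges = np.linspace(0, n, k + 1).astype(int)
        return [slice(a, b) for a, b in zip(edges[:-1], edges[1:])]

    @staticmethod
    def _ridge_path(
        X: np.ndarray, y: np.ndarray, lambdas: np.ndarray
    ) -> np.ndarray:
        """Ridge solutions for every penalty via one eigendecomposition.

        Returns (n_lambda, n_features).  X and y are assumed centered (and
        X scaled) already; the Gram eigenbasis is shared across penalties.
        """
        G = X.T @ X
        b = X.T @ y
        evals, evecs = linalg.eigh(G)
        evals = np.maximum(evals, 0.0)
        bt = evecs.T @ b
        return np.stack([evecs @ (bt / (evals + lam)) for lam in lambdas])

    def fit(self, k_folds: int = 3, seed: int = 0) -> "TRFResults":
        """Cross-validate the penalty, refit at the winner, return results.

        ``seed`` is recorded for provenance; fold assignment itself is the
        deterministic contiguous-block split, identical for every penalty.
        """
        X, y = self.exog, self.endog
        n = X.shape[0]
        if n < 2 * k_folds:
            raise ValueError("need at least 2 samples per fold")
        col_scale_all = X.std(axis=0)
        degenerate = not np.any(col_scale_all > 0)
        if degenerate:
            w = np.zeros(X.shape[1])
            return TRFResults(
                self, w, float(y.mean()), float(self.lambda_grid[0]),
                np.full(self.lambda_grid.size, np.nan),
                np.zeros(X.shape[1]), np.ones(X.shape[1]), seed, flagged=True,
            )
        folds = self._fold_slices(n, k_folds)
        cv_err = np.zeros((k_folds, self.lambda_grid.size))
        for f, val in enumerate(folds):
            mask = np.ones(n, dtype=bool)
            mask[val] = False
            Xt, yt = X[mask], y[mask]
            mu, sd = self._moments(Xt)
            Xs = (Xt - mu) / sd
            ym = yt.mean()
            W = self._ridge_path(Xs, yt - ym, self.lambda_grid)
            Xv = (X[val] - mu) / sd
            preds = Xv @ W.T + ym
            cv_err[f] = np.mean((preds - y[val][:, None]) ** 2, axis=0)
        cv_curve = cv_err.mean(axis=0)
        best = int(np.argmin(cv_curve))
        lam = float(self.lambda_grid[best])
        mu, sd = self._moments(X)
        Xs = (X - mu) / sd
        ym = y.mean()
        w_s = self._ridge_path(Xs, y - ym, np.array([lam]))[0]
        return TRFResults(self, w_s, float(ym), lam, cv_curve, mu, sd, seed)

    def _moments(self, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        if not self.standardize:
            return np.zeros(X.shape[1]), np.ones(X.shape[1])
        mu = X.mean(axis=0)
        sd = X.std(axis=0)
        sd[sd == 0] = 1.0
        return mu, sd


class TRFResults:
    """Fitted TRF: weights, intercept, selected penalty, CV curve.

    ``weights`` is (dimensions x n_lags) on the original feature scale;
    ``predict`` applies the model to new feature matrices.
    """

    def __init__(
        self,
        model: TemporalReceptiveField,
        weights_std: np.ndarray,
        intercept_centered: float,
        lambda_: float,
        cv_curve: np.ndarray,
        col_mean: np.ndarray,
        col_scale: np.ndarray,
        seed: int,
        flagged: bool = False,
    ) -> None:
        self.model = model
        self.lambda_ = lambda_
        self.cv_curve = cv_curve
        self.seed = seed
        self.flagged = flagged
        # fold standardization into raw-scale coefficients
        w_raw = weights_std / col_scale
        self.coef_ = w_raw
        self.intercept = intercept_centered - float(col_mean @ w_raw)
        n_lags, D = model.spec.n_lags, model.n_dims
        self.weights = w_raw.reshape(n_lags, D).T  # (dims x lags), oldest first

    def predict(
        self, features: FeatureMatrix | list[FeatureMatrix] | dict[str, FeatureMatrix]
    ) -> np.ndarray | list[np.ndarray] | dict[str, np.ndarray]:
        """Real-valued predicted counts, one value per feature frame."""
        if isinstance(features, dict):
            return {s: self.predict(fm) for s, fm in features.items()}
        if isinstance(features, list):
            return [self.predict(fm) for fm in features]
        if features.n_dims != self.model.n_dims:
            raise ValueError(
                f"feature dims {features.n_dims} != model dims {self.model.n_dims}"
            )
        design = build_lagged_design(features, self.model.spec)
        return design @ self.coef_ + self.intercept

    def training_correlation(self) -> float:
        pred = self.model.exog @ self.coef_ + self.intercept
        return float(np.corrcoef(pred, self.model.endog)[0, 1])

    def summary(self) -> str:
        lines = [
            "Temporal receptive field (ridge, CV-selected penalty)",
            "=" * 54,
            f"samples:          {self.model.exog.shape[0]}",
            f"feature dims:     {self.model.n_dims}",
            f"lags (window):    {self.model.spec.n_lags} "
            f"({self.model.spec.window * 1000:.0f} ms @ {self.model.spec.rate:g} Hz)",
            f"lambda*:          {self.lambda_:.3g}",
            f"cv curve min/max: {np.nanmin(self.cv_curve):.4g} / "
            f"{np.nanmax(self.cv_curve):.4g}",
            f"|weights|:        {np.linalg.norm(self.weights):.4g}",
            f"intercept:        {self.intercept:.4g}",
        ]
        if self.flagged:
            lines.append("flagged:          degenerate (all-zero) design")
        return "\n".join(lines)
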