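"""LNC regression: stage-specific VI models, PLSR and GPR, splits and metrics.

Models follow the scikit-learn estimator protocol (``fit``/``predict``,
``get_params``/``set_params``, fitted attributes with a trailing underscore)
so they compose with sklearn model selection:

* :class:`StageVIRegressor` — ordinary least squares of LNC on a single
  vegetation index, fitted per growth stage (or stage group).
* :class:`PLSNitrogenRegressor` — mean-centered partial least squares on full
  spectra; the latent count is chosen by leave-one-out cross-validation on
  the calibration set (smallest count within 0.1% of the minimum LOO RMSE).
* :class:`GPNitrogenRegressor` — Gaussian process regression with an
  anisotropic (ARD) squared-exponential kernel: one lengthscale sigma_b per
  band plus a noise term, hyperparameters by marginal-likelihood maximization
  from a fixed-seed multi-start.  Small sigma_b marks an informative band.

Calibration/validation splitting is by replicate block (blocks 1-2 calibrate,
block 3 validates), never random, so sibling plots of one treatment never
straddle the split.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, RegressorMixin, clone
from sklearn.cross_decomposition import PLSRegression
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process.kernels import RBF, ConstantKernel, WhiteKernel
from sklearn.utils.validation import check_is_fitted

__all__ = [
    "DataSplit",
    "Metrics",
    "split_by_replicate",
    "spearman_rho2",
    "evaluate",
    "StageVIRegressor",
    "PLSNitrogenRegressor",
    "GPNitrogenRegressor",
    "fit_stage_vi_model",
]

VEGETATIVE_STAGES = ("ET", "LT", "JT")


@dataclass
class DataSplit:
    """Replicate-based calibration/validation split of a sample table."""

    calibration: pd.DataFrame
    validation: pd.DataFrame
    scope: str

    def __post_init__(self) -> None:
        overlap = set(self.calibration.index) & set(self.validation.index)
        if overlap:
            raise ValueError("calibration and validation sets overlap")


@dataclass
class Metrics:
    """Validation metrics on the LNC scale (% dry mass)."""

    r2: float        # 1 - SS_res / SS_tot
    rmse: float
    spearman_rho2: float | None = None


def split_by_replicate(samples: pd.DataFrame, scope: str = "global",
                       validation_replicate: int = 3) -> DataSplit:
    """Split samples into calibration (2 replicates) and validation (1).

    ``scope`` is ``"global"`` (all acquisitions), ``"reproductive"`` (stage
    dates from booting onward) or a single pre-booting stage-date given as
    ``"<stage>:<year>"`` (e.g. ``"ET:2014"``) or as a bare vegetative stage
    label applied within each year separately is not allowed — the 36-sample
    stage scope is year-specific by design.
    """
    df = samples
    if scope == "global":
        sub = df
    elif scope == "reproductive":
        sub = df[~df["stage"].isin(VEGETATIVE_STAGES)]
    else:
        if ":" not in scope:
            raise ValueError(
                f"stage scope must be '<stage>:<year>' (e.g. 'ET:2014'), got {scope!r}"
            )
        stage, year = scope.split(":")
        sub = df[(df["stage"] == stage) & (df["year"] == int(year))]
    if sub.empty:
        raise ValueError(f"scope {scope!r} selects no samples")
    val = sub[sub["replicate"] == validation_replicate]
    cal = sub[sub["replicate"] != validation_replicate]
    return DataSplit(cal, val, scope)


def spearman_rho2(x: np.ndarray, y: np.ndarray) -> float:
    """Squared Spearman rank correlation (average ranks on ties).

    Returns NaN for constant input (the correlation is undefined there).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 pairs")
    if np.all(x == x[0]) or np.all(y == y[0]):
        warnings.warn("constant input: Spearman correlation undefined")
        return float("nan")
    rho = stats.spearmanr(x, y).statistic
    return float(rho ** 2)


def evaluate(model, X_val, y_val) -> Metrics:
    """Predictive R^2 (1 - SS_res/SS_tot), RMSE and Spearman rho^2."""
    y_val = np.asarray(y_val, dtype=float)
    if y_val.size == 0:
        raise ValueError("empty validation set")
    pred = np.asarray(model.predict(X_val), dtype=float).ravel()
    ss_res = float(np.sum((y_val - pred) ** 2))
    ss_tot = float(np.sum((y_val - y_val.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else float("nan")
    rmse = float(np.sqrt(np.mean((y_val - pred) ** 2)))
    rho2 = spearman_rho2(pred, y_val) if y_val.size >= 3 and np.ptp(pred) > 0 else None
    return Metrics(r2, rmse, rho2)


# ---------------------------------------------------------------------------
# Estimators
# ---------------------------------------------------------------------------

class StageVIRegressor(BaseEstimator, RegressorMixin):
    """Simple linear LNC ~ VI model for one stage scope.

    Fitted attributes: ``slope_``, ``intercept_``, ``vi_name_``.
    """

    def __init__(self, vi_name: str | None = None):
        self.vi_name = vi_name

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        if X.ndim == 2:
            if X.shape[1] != 1:
                raise ValueError("StageVIRegressor expects a single VI column")
            X = X[:, 0]
        y = np.asarray(y, dtype=float)
        if X.size < 3:
            raise ValueError("need at least 3 calibration samples")
        if np.ptp(X) == 0:
            raise ValueError("VI has zero variance on the calibration set")
        slope, intercept = np.polyfit(X, y, 1)
        self.slope_ = float(slope)
        self.intercept_ = float(intercept)
        self.vi_name_ = self.vi_name
        self.n_features_in_ = 1
        return self

    def predict(self, X):
        check_is_fitted(self, "slope_")
        X = np.asarray(X, dtype=float)
        if X.ndim == 2:
            X = X[:, 0]
        return self.slope_ * X + self.intercept_


def fit_stage_vi_model(split: DataSplit, vi_name: str
                       ) -> tuple[StageVIRegressor, Metrics]:
    """OLS of LNC on one VI on the calibration replicates; metrics on the
    held-out replicate."""
    model = StageVIRegressor(vi_name)
    model.fit(split.calibration[vi_name].to_numpy(),
              split.calibration["lnc"].to_numpy())
    metrics = evaluate(model, split.validation[vi_name].to_numpy(),
                       split.validation["lnc"].to_numpy())
    return model, metrics


class PLSNitrogenRegressor(BaseEstimator, RegressorMixin):
    """PLS regression of LNC on spectra with LOO-CV latent selection.

    The latent count minimizing leave-one-out RMSE on the training set is
    chosen, preferring the smallest count within ``cv_rtol`` (relative) of
    the minimum — a parsimony tie-break that also makes the selection
    invariant to duplicating every training sample.

    Fitted attributes: ``n_components_``, ``coef_`` (per-band regression
    coefficients on the original spectral scale), ``cv_rmse_``.
    """

    def __init__(self, max_components: int = 15, cv_rtol: float = 1e-3):
        self.max_components = max_components
        self.cv_rtol = cv_rtol

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float).ravel()
        n, d = X.shape
        if n < 5:
            raise ValueError("need at least 5 calibration samples for PLSR")
        kmax = min(self.max_components, n - 2, d)  # n-2: LOO leaves n-1 training rows
        cv_rmse = np.empty(kmax)
        for k in range(1, kmax + 1):
            press = 0.0
            for i in range(n):
                mask = np.ones(n, dtype=bool)
                mask[i] = False
                pls = PLSRegression(n_components=k, scale=False)
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    pls.fit(X[mask], y[mask])
                press += float(pls.predict(X[None, i]).ravel()[0] - y[i]) ** 2
            cv_rmse[k - 1] = np.sqrt(press / n)
        best = float(cv_rmse.min())
        self.n_components_ = int(np.argmax(cv_rmse <= best * (1 + self.cv_rtol))) + 1
        self.cv_rmse_ = cv_rmse
        self._pls = PLSRegression(n_components=self.n_components_, scale=False)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            self._pls.fit(X, y)
        self.coef_ = np.asarray(self._pls.coef_).reshape(-1)
        self.n_features_in_ = d
        return self

    def predict(self, X):
        check_is_fitted(self, "n_components_")
        return self._pls.predict(np.asarray(X, dtype=float)).ravel()


class GPNitrogenRegressor(BaseEstimator, RegressorMixin):
    """GP regression of LNC on spectra with one ARD lengthscale per band.

    Bands are standardized with calibration statistics before fitting (the
    kernel lengthscales are then comparable across bands); the target is
    centered.  Kernel: constant x RBF(ARD) + white noise; hyperparameters by
    L-BFGS marginal-likelihood maximization restarted ``n_restarts`` times
    from seeded draws.

    Fitted attributes: ``band_lengthscales_`` (sigma_b; small = relevant),
    ``relevance_rank_`` (band indices, most relevant first), ``noise_level_``.
    """

    def __init__(self, n_restarts: int = 1, random_state: int = 0,
                 length_scale_bounds: tuple = (1e-2, 1e4)):
        self.n_restarts = n_restarts
        self.random_state = random_state
        self.length_scale_bounds = length_scale_bounds

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float).ravel()
        n, d = X.shape
        if n < 5:
            raise ValueError("need at least 5 calibration samples for GPR")
        self.x_mean_ = X.mean(axis=0)
        self.x_std_ = X.std(axis=0)
        self.x_std_[self.x_std_ == 0] = 1.0
        self.y_mean_ = float(y.mean())
        Xs = (X - self.x_mean_) / self.x_std_
        kernel = (ConstantKernel(1.0, (1e-3, 1e3))
                  * RBF(np.full(d, 10.0), self.length_scale_bounds)
                  + WhiteKernel(1e-2, (1e-10, 1e1)))
        gp = GaussianProcessRegressor(
            kernel=kernel, normalize_y=False, optimizer="fmin_l_bfgs_b",
            n_restarts_optimizer=self.n_restarts,
            random_state=self.random_state, alpha=1e-10)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            gp.fit(Xs, y - self.y_mean_)
        self._gp = gp
        k = gp.kernel_
        self.band_lengthscales_ = np.asarray(k.k1.k2.length_scale, dtype=float)
        self.noise_level_ = float(k.k2.noise_level)
        self.relevance_rank_ = np.argsort(self.band_lengthscales_)
        self.n_features_in_ = d
        return self

    def predict(self, X):
        check_is_fitted(self, "band_lengthscales_")
        Xs = (np.asarray(X, dtype=float) - self.x_mean_) / self.x_std_
        return self._gp.predict(Xs) + self.y_mean_
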