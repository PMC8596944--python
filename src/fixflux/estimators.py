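"""Scikit-learn style estimators.

Two pieces of the pipeline are estimator-shaped and are exposed with the
sklearn fit/predict/transform contract so they compose with sklearn model
selection and pipelines:

* :class:`EPGT2Mapper` — voxelwise relaxometry: ``fit(X)`` on an
  (n_voxels, n_echoes) matrix of TSE magnitudes estimates per-voxel
  ``t2_``, ``b1_`` and amplitude ``s0_`` under the EPG signal model.
* :class:`ConcentrationConfoundRegressor` — the global linear confound
  T2 = t2_zero + beta * c: ``fit(x, y, sample_weight)`` is a weighted
  least-squares line, ``transform(x, y)`` removes the fitted slope.

The volume-level functions in :mod:`fixflux.epg` and
:mod:`fixflux.regression` are thin wrappers over these.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

__all__ = ["EPGT2Mapper", "ConcentrationConfoundRegressor"]


class EPGT2Mapper(BaseEstimator):
    """Voxelwise EPG T2/B1 estimation on multi-echo TSE magnitudes.

    Parameters
    ----------
    echo_times_ms : sequence of float
        Echo times of the train, strictly increasing.
    assumed_t1_ms : float
        Fixed longitudinal relaxation time; the protocol cannot separate T1.
    nominal_refocus_deg : float
        Nominal refocusing angle; the realised angle is ``b1 * nominal``.
    b1_fixed : None, scalar or array
        If given, b1 is frozen (stage-2 behaviour) and only (S0, T2) are fit.
    lambda_reg : float
        Weight of the quadratic penalty pulling T2 toward ``t2_reference``
        (passed to :meth:`fit`); 0 disables regularisation.

    Attributes
    ----------
    t2_ : ndarray (n_voxels,)
        Estimated T2 in ms (NaN for unusable voxels).
    b1_ : ndarray (n_voxels,)
        Estimated (or frozen) relative flip-angle scale in (0, 1].
    s0_ : ndarray (n_voxels,)
        Signal amplitude in input units.
    converged_ : ndarray of bool
    """

    def __init__(
        self,
        echo_times_ms=(13.0, 25.0, 38.0, 50.0, 63.0, 76.0),
        repetition_time_ms: float = 1000.0,
        assumed_t1_ms: float = 500.0,
        nominal_refocus_deg: float = 180.0,
        b1_fixed=None,
        lambda_reg: float = 0.0,
        t2_grid=None,
        b1_grid=None,
        n_iter: int = 40,
    ):
        self.echo_times_ms = echo_times_ms
        self.repetition_time_ms = repetition_time_ms
        self.assumed_t1_ms = assumed_t1_ms
        self.nominal_refocus_deg = nominal_refocus_deg
        self.b1_fixed = b1_fixed
        self.lambda_reg = lambda_reg
        self.t2_grid = t2_grid
        self.b1_grid = b1_grid
        self.n_iter = n_iter

    def protocol(self):
        from .epg import TSEProtocol

        return TSEProtocol(
            echo_times_ms=tuple(self.echo_times_ms),
            repetition_time_ms=self.repetition_time_ms,
            assumed_t1_ms=self.assumed_t1_ms,
            nominal_refocus_deg=self.nominal_refocus_deg,
        )

    def fit(self, X, y=None, t2_reference=None):
        from .epg import fit_epg_voxels

        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("X must be (n_voxels, n_echoes)")
        s0, t2, b1, conv = fit_epg_voxels(
            X,
            self.protocol(),
            b1_fixed=self.b1_fixed,
            t2_grid=None if self.t2_grid is None else np.asarray(self.t2_grid, float),
            b1_grid=None if self.b1_grid is None else np.asarray(self.b1_grid, float),
            lambda_reg=self.lambda_reg,
            t2_reference=t2_reference,
            n_iter=self.n_iter,
        )
        self.s0_, self.t2_, self.b1_, self.converged_ = s0, t2, b1, conv
        self.n_features_in_ = X.shape[1]
        return self

    def predict(self, X=None) -> np.ndarray:
        """Model-predicted echo magnitudes for the fitted voxels."""
        from .epg import epg_cpmg_signal

        check_is_fitted(self, "t2_")
        ok = np.isfinite(self.t2_)
        out = np.full((self.t2_.size, self.n_features_in_), np.nan)
        if ok.any():
            out[ok] = self.s0_[ok, None] * epg_cpmg_signal(
                self.t2_[ok], self.assumed_t1_ms, self.b1_[ok], self.protocol()
            )
        return out


class ConcentrationConfoundRegressor(RegressorMixin, BaseEstimator):
    """Weighted least-squares line T2 = intercept + coef * regressor.

    ``fit`` expects 1-D ``x`` (regressor values, e.g. bin centres of the
    fixative-concentration binning) and ``y`` (T2, ms), with optional
    ``sample_weight`` (voxel counts per bin).  ``transform`` removes the
    fitted slope — the voxelwise confound correction — leaving the intercept
    untouched so corrected values stay on the T2 scale.
    """

    def __init__(self):
        pass

    def fit(self, x, y, sample_weight=None):
        x = np.asarray(x, dtype=float).ravel()
        y = np.asarray(y, dtype=float).ravel()
        if x.size != y.size:
            raise ValueError("x and y must have the same length")
        if x.size < 2:
            raise ValueError("need at least two points")
        w = np.ones_like(x) if sample_weight is None else np.asarray(sample_weight, float).ravel()
        if (w < 0).any() or w.sum() == 0:
            raise ValueError("weights must be non-negative with positive sum")
        sw = w.sum()
        xbar = (w * x).sum() / sw
        ybar = (w * y).sum() / sw
        sxx = (w * (x - xbar) ** 2).sum()
        if sxx == 0:
            raise ValueError("all weight concentrated at a single regressor value")
        sxy = (w * (x - xbar) * (y - ybar)).sum()
        self.coef_ = sxy / sxx
        self.intercept_ = ybar - self.coef_ * xbar
        self.n_features_in_ = 1
        return self

    def predict(self, x) -> np.ndarray:
        check_is_fitted(self, "coef_")
        return self.intercept_ + self.coef_ * np.asarray(x, dtype=float)

    def transform(self, x, y) -> np.ndarray:
        """Remove the fitted confound: y - coef * x."""
        check_is_fitted(self, "coef_")
        return np.asarray(y, dtype=float) - self.coef_ * np.asarray(x, dtype=float)

    def score(self, x, y, sample_weight=None) -> float:
        """Weighted R^2 of the line on (x, y)."""
        y = np.asarray(y, dtype=float).ravel()
        pred = self.predict(np.asarray(x, dtype=float).ravel())
        w = np.ones_like(y) if sample_weight is None else np.asarray(sample_weight, float).ravel()
        ybar = (w * y).sum() / w.sum()
        ss_res = (w * (y - pred) ** 2).sum()
        ss_tot = (w * (y - ybar) ** 2).sum()
        return 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
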