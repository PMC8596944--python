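"""Fixative-concentration confound regression on T2 maps.

The presence of formalin in tissue shortens T2 approximately linearly in its
concentration, so a simulated concentration map c(r) predicts a spatial T2
confound

    T2(r) = T2_0 + beta * c(r),

with T2_0 the fixative-free value and beta (ms per unit concentration,
negative for formalin) the global sensitivity.  Both are estimated per brain
from white matter only — white matter is the training tissue; an improvement
in grey matter, which the fit never saw, validates the model.  The fit is a
weighted least squares on binned data: white-matter voxels are binned by the
regressor (100 bins by default), bin-mean T2 is regressed on bin centre with
the voxel count per bin as weight.  Using the estimated beta alone, the
confound is then removed voxelwise over the whole brain:

    T2_corrected(r) = T2(r) - beta * c(r).

The same machinery accepts any scalar regressor — concentration (KT/KI
models, range 0-1), distance to surface (D2S, mm), or a B1 map — so the
model comparison is purely a change of regressor.

Filtering conventions, applied identically when fitting and when reporting:
voxels within ``surface_exclusion_mm`` of the brain surface are dropped
(boundary voxels carry large T2 errors), and T2 outliers outside
median +/- k * MAD are dropped, with MAD the raw (unscaled) median absolute
deviation and k = 3 by default.  Inhomogeneity is summarised as the sample
standard deviation (ddof=1) of T2 over the surviving voxels of one tissue
type; groups of per-brain summaries are compared with Welch's unequal
variance t-test and Cohen's D (pooled-SD form).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .estimators import ConcentrationConfoundRegressor
from .volumes import Mask, ScalarVolume, check_grid_compatibility

__all__ = [
    "BinnedCurve",
    "RegressionFit",
    "HomogeneityReport",
    "bin_t2_by_regressor",
    "fit_confound",
    "apply_correction",
    "tissue_inhomogeneity",
    "compare_groups",
    "selection_mask",
]

DEFAULT_N_BINS = 100
DEFAULT_SURFACE_EXCLUSION_MM = 2.0
DEFAULT_OUTLIER_K = 3.0
#: default regressor ranges: unitless concentration and D2S distance in mm
CONCENTRATION_RANGE = (0.0, 1.0)
DISTANCE_RANGE = (0.0, 23.0)


@dataclass
class BinnedCurve:
    """Bin-mean T2 versus regressor value.

    ``centres`` are the centres of equal-width bins partitioning ``range``;
    bins with zero count carry NaN means and are dropped by the fit.
    """

    centres: np.ndarray
    mean_t2: np.ndarray
    counts: np.ndarray
    kind: str = "concentration"

    def __post_init__(self) -> None:
        self.centres = np.asarray(self.centres, dtype=float)
        self.mean_t2 = np.asarray(self.mean_t2, dtype=float)
        self.counts = np.asarray(self.counts, dtype=int)
        if not (len(self.centres) == len(self.mean_t2) == len(self.counts)):
            raise ValueError("centres, mean_t2 and counts must have equal length")
        if (self.counts < 0).any():
            raise ValueError("bin counts must be non-negative")

    @property
    def nonempty(self) -> np.ndarray:
        return self.counts > 0

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {"centre": self.centres, "mean_t2_ms": self.mean_t2, "count": self.counts}
        )


@dataclass
class RegressionFit:
    """Global linear confound fit: T2 = t2_zero + beta * regressor."""

    t2_zero: float
    beta: float
    r_squared: float
    n_bins: int

    def predict(self, x) -> np.ndarray:
        return self.t2_zero + self.beta * np.asarray(x, dtype=float)


@dataclass
class HomogeneityReport:
    """Welch's t-test and Cohen's D between two groups of per-brain scalars."""

    t_statistic: float
    p_value: float
    cohens_d: float
    df: float
    mean_a: float
    mean_b: float
    sd_a: float
    sd_b: float


def selection_mask(
    t2: ScalarVolume,
    fit_mask: Mask,
    d2s: ScalarVolume | None,
    surface_exclusion_mm: float = DEFAULT_SURFACE_EXCLUSION_MM,
    outlier_k: float = DEFAULT_OUTLIER_K,
) -> np.ndarray:
    """Boolean array of voxels surviving the shared exclusion rules.

    Starts from ``fit_mask``, removes non-finite T2, voxels within
    ``surface_exclusion_mm`` of the surface (using the distance-to-surface
    map ``d2s``), and T2 outliers outside median +/- outlier_k * MAD computed
    over the masked voxels (MAD unscaled).
    """
    sel = fit_mask.values & np.isfinite(t2.values)
    if d2s is not None and surface_exclusion_mm > 0:
        sel &= d2s.values > surface_exclusion_mm
    if outlier_k is not None and np.isfinite(outlier_k) and sel.any():
        vals = t2.values[sel]
        med = np.median(vals)
        mad = np.median(np.abs(vals - med))
        sel &= np.abs(t2.values - med) <= outlier_k * mad
    return sel


def bin_t2_by_regressor(
    t2: ScalarVolume,
    regressor: ScalarVolume,
    fit_mask: Mask,
    d2s: ScalarVolume | None = None,
    n_bins: int = DEFAULT_N_BINS,
    value_range: tuple[float, float] = CONCENTRATION_RANGE,
    surface_exclusion_mm: float = DEFAULT_SURFACE_EXCLUSION_MM,
    outlier_k: float = DEFAULT_OUTLIER_K,
    kind: str = "concentration",
) -> BinnedCurve:
    """Bin masked T2 values by regressor value into equal-width bins.

    Defaults follow the standard protocol: 100 bins over (0, 1) for
    concentration regressors (use (0, 23) mm for distance to surface),
    2 mm surface exclusion, outliers beyond median +/- 3 * MAD removed.
    """
    vols = [t2, regressor, fit_mask] + ([d2s] if d2s is not None else [])
    check_grid_compatibility(vols)
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    lo, hi = float(value_range[0]), float(value_range[1])
    if not hi > lo:
        raise ValueError(f"degenerate range {value_range}")

    sel = selection_mask(t2, fit_mask, d2s, surface_exclusion_mm, outlier_k)
    if not sel.any():
        raise ValueError("no voxels survive masking and exclusion rules")

    x = regressor.values[sel]
    y = t2.values[sel]
    edges = np.linspace(lo, hi, n_bins + 1)
    idx = np.digitize(x, edges) - 1
    idx = np.clip(idx, 0, n_bins - 1)
    inside = (x >= lo) & (x <= hi)
    counts = np.bincount(idx[inside], minlength=n_bins)
    sums = np.bincount(idx[inside], weights=y[inside], minlength=n_bins)
    with np.errstate(invalid="ignore", divide="ignore"):
        means = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    centres = 0.5 * (edges[:-1] + edges[1:])
    return BinnedCurve(centres, means, counts, kind=kind)


def fit_confound(curve: BinnedCurve) -> RegressionFit:
    """Weighted least squares of bin-mean T2 on bin centre, weights = counts.

    Returns the fixative-free intercept ``t2_zero`` (ms) and the slope
    ``beta`` (ms per regressor unit).  Requires at least two non-empty bins
    with distinct centres.
    """
    ok = curve.nonempty & np.isfinite(curve.mean_t2)
    x = curve.centres[ok]
    y = curve.mean_t2[ok]
    w = curve.counts[ok].astype(float)
    if len(x) < 2 or np.ptp(x) == 0:
        raise ValueError("need >= 2 non-empty bins with distinct centres")
    reg = ConcentrationConfoundRegressor().fit(x, y, sample_weight=w)
    return RegressionFit(
        t2_zero=float(reg.intercept_),
        beta=float(reg.coef_),
        r_squared=float(reg.score(x, y, sample_weight=w)),
        n_bins=int(ok.sum()),
    )


def apply_correction(t2: ScalarVolume, regressor: ScalarVolume, beta: float) -> ScalarVolume:
    """Remove the fitted confound voxelwise: T2_corrected = T2 - beta * regressor.

    Applied over the whole brain (all tissue types), including voxels that
    were excluded from the fit.
    """
    check_grid_compatibility([t2, regressor])
    return ScalarVolume(t2.grid, t2.values - beta * regressor.values, units=t2.units)


def tissue_inhomogeneity(
    t2: ScalarVolume,
    tissue_mask: Mask,
    d2s: ScalarVolume | None = None,
    surface_exclusion_mm: float = DEFAULT_SURFACE_EXCLUSION_MM,
    outlier_k: float = DEFAULT_OUTLIER_K,
) -> float:
    """Inhomogeneity of a T2 map within one tissue type: the sample SD (ms,
    ddof=1) over voxels surviving the same exclusions as the fit."""
    sel = selection_mask(t2, tissue_mask, d2s, surface_exclusion_mm, outlier_k)
    vals = t2.values[sel]
    if vals.size < 2:
        raise ValueError("fewer than 2 voxels survive the exclusion rules")
    return float(np.std(vals, ddof=1))


def compare_groups(a, b) -> HomogeneityReport:
    """Welch's two-sided unequal-variance t-test plus Cohen's D (pooled SD).

    ``a`` and ``b`` are per-brain summary scalars (e.g. mean T2 or
    inhomogeneity per brain), at least two each.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least two values")
    va, vb = np.var(a, ddof=1), np.var(b, ddof=1)
    if va == 0.0 and vb == 0.0:
        if np.mean(a) == np.mean(b):
            # degenerate null: identical constant groups
            return HomogeneityReport(0.0, 1.0, 0.0, float(a.size + b.size - 2),
                                     float(np.mean(a)), float(np.mean(b)), 0.0, 0.0)
        raise ValueError("zero variance in both groups with distinct means")
    t, p = stats.ttest_ind(a, b, equal_var=False)
    # Welch-Satterthwaite degrees of freedom
    na, nb = a.size, b.size
    num = (va / na + vb / nb) ** 2
    den = (va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1)
    df = num / den if den > 0 else float(na + nb - 2)
    pooled = np.sqrt(((na - 1) * va + (nb - 1) * vb) / (na + nb - 2))
    d = (np.mean(a) - np.mean(b)) / pooled if pooled > 0 else 0.0
    return HomogeneityReport(
        t_statistic=float(t),
        p_value=float(p),
        cohens_d=float(d),
        df=float(df),
        mean_a=float(np.mean(a)),
        mean_b=float(np.mean(b)),
        sd_a=float(np.sqrt(va)),
        sd_b=float(np.sqrt(vb)),
    )
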