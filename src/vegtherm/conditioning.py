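"""Spatial-conditioning regressions of the morning warming rate on FVC.

Pixels with near-identical long-term mean soil moisture (+-0.0025 m3/m3)
and shortwave radiation (+-1.25 W/m2) are binned so that across-pixel FVC
differences stand in for temporal vegetation change (space-for-time
substitution).  Within each bin an OLS fit

    E[dLST/dt] = b0 + b_FVC * E[FVC] + eps

estimates vegetation cover's net effect on the diurnal warming rate; a
statistically significant negative (positive) b_FVC is a cooling (warming)
effect, insignificant fits are neutral.  The seasonal variant adds seasonal
mean soil moisture and radiation as controls.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .config import AnalysisConfig, THETA_BIN_WIDTH, RS_BIN_WIDTH

__all__ = [
    "ConditioningBin", "EffectEstimate", "EffectClassMap", "SeasonalSplit",
    "build_bins", "fit_eq1", "classify_effect", "area_fractions",
    "gradient_summary", "seasonal_split", "fit_eq2",
    "env_percent_difference", "interannual_fvc_regression",
    "run_assessment", "bin_table",
]

CLASS_CODES = {"neutral": 0, "cooling": 1, "warming": 2}


@dataclass
class ConditioningBin:
    """Pixels sharing one (soil moisture, radiation) tile."""

    bin_id: Tuple[int, int]
    theta_center: float     # m3 m-3
    rs_center: float        # W m-2
    pixel_ids: np.ndarray


@dataclass
class EffectEstimate:
    """Fitted within-bin linear effect of FVC on the response."""

    beta0: float
    beta_fvc: float
    p_fvc: float
    ci_fvc: Tuple[float, float]
    n: int
    beta_theta: Optional[float] = None
    beta_rs: Optional[float] = None
    residuals: Optional[np.ndarray] = None
    flag: Optional[str] = None       # set when the fit is degraded (e.g. collinear)


@dataclass
class EffectClassMap:
    """Per-pixel effect class and per-0.1-FVC effect size, inherited from
    the pixel's conditioning bin.  Code -1 marks pixels whose bin could not
    be fitted."""

    class_code: np.ndarray           # {-1, 0, 1, 2}
    beta_per_step: np.ndarray        # K/h per fvc_report_step; NaN if unfitted
    estimates: Dict[Tuple[int, int], EffectEstimate] = field(default_factory=dict)

    def class_labels(self) -> np.ndarray:
        inv = {v: k for k, v in CLASS_CODES.items()}
        inv[-1] = "unclassified"
        return np.asarray([inv[c] for c in self.class_code])


def build_bins(
    theta_mean: np.ndarray,
    rs_mean: np.ndarray,
    cfg: Optional[AnalysisConfig] = None,
    mask: Optional[np.ndarray] = None,
) -> List[ConditioningBin]:
    """Deterministic tiling into conditioning bins.

    Bin index = (floor(theta/0.005), floor(RS/2.5)); centers at the tile
    midpoints, so every member lies within the half-width tolerances of its
    center.  Returns bins sorted by index; under-sized bins are kept here
    and flagged at fit time.
    """
    cfg = cfg or AnalysisConfig()
    theta = np.asarray(theta_mean, dtype=float)
    rs = np.asarray(rs_mean, dtype=float)
    if mask is None:
        mask = np.ones(theta.shape, dtype=bool)
    idx_t = np.floor(theta / cfg.theta_bin_width).astype(int)
    idx_r = np.floor(rs / cfg.rs_bin_width).astype(int)
    bins: List[ConditioningBin] = []
    keys = {}
    for pid in np.flatnonzero(mask):
        keys.setdefault((idx_t[pid], idx_r[pid]), []).append(pid)
    for key in sorted(keys):
        it, ir = key
        bins.append(ConditioningBin(
            bin_id=key,
            theta_center=(it + 0.5) * cfg.theta_bin_width,
            rs_center=(ir + 0.5) * cfg.rs_bin_width,
            pixel_ids=np.asarray(keys[key]),
        ))
    return bins


def _ols_effect(y: np.ndarray, X: np.ndarray, alpha: float) -> EffectEstimate:
    """OLS with the FVC regressor in column 0 of X (after the constant)."""
    model = sm.OLS(y, sm.add_constant(X, has_constant="add"))
    res = model.fit()
    ci = res.conf_int(alpha=alpha)
    est = EffectEstimate(
        beta0=float(res.params[0]),
        beta_fvc=float(res.params[1]),
        p_fvc=float(res.pvalues[1]),
        ci_fvc=(float(ci[1][0]), float(ci[1][1])),
        n=int(res.nobs),
        residuals=np.asarray(res.resid),
    )
    if X.shape[1] >= 3:
        est.beta_theta = float(res.params[2])
        est.beta_rs = float(res.params[3])
        if np.linalg.cond(model.exog) > 1e8:
            est.flag = "collinear"
    return est


def fit_eq1(
    bin_: ConditioningBin,
    fvc_mean: np.ndarray,
    rate_annual_mean: np.ndarray,
    cfg: Optional[AnalysisConfig] = None,
) -> EffectEstimate:
    """Within-bin OLS of the annual-mean morning rate on annual-mean FVC."""
    cfg = cfg or AnalysisConfig()
    ids = bin_.pixel_ids
    fvc = np.asarray(fvc_mean, dtype=float)[ids]
    y = np.asarray(rate_annual_mean, dtype=float)[ids]
    ok = np.isfinite(fvc) & np.isfinite(y)
    fvc, y = fvc[ok], y[ok]
    if fvc.size < 2 * cfg.min_pixels_per_regressor:
        raise ValueError(f"insufficient pixels in bin {bin_.bin_id} (n={fvc.size})")
    if np.ptp(fvc) == 0:
        raise ValueError(f"degenerate regressor: zero FVC variance in bin {bin_.bin_id}")
    return _ols_effect(y, fvc[:, None], cfg.alpha_level)


def classify_effect(est: EffectEstimate, alpha: float = 0.05,
                    report_step: float = 0.1) -> Tuple[str, float]:
    """Effect class plus the effect size re-expressed per `report_step`
    (0.1 by default) absolute FVC increase."""
    if est.p_fvc < alpha:
        label = "cooling" if est.beta_fvc < 0 else "warming"
    else:
        label = "neutral"
    return label, est.beta_fvc * report_step


def run_assessment(
    bins: Sequence[ConditioningBin],
    fvc_mean: np.ndarray,
    response: np.ndarray,
    n_pixels: int,
    cfg: Optional[AnalysisConfig] = None,
) -> EffectClassMap:
    """Fit every adequately sized bin and paint each member pixel with its
    bin's class and per-0.1-FVC effect size.  Pixels of unfittable bins get
    code -1 / NaN (flagged, still counted in coverage accounting)."""
    cfg = cfg or AnalysisConfig()
    codes = np.full(n_pixels, -1, dtype=int)
    beta = np.full(n_pixels, np.nan)
    estimates: Dict[Tuple[int, int], EffectEstimate] = {}
    for b in bins:
        try:
            est = fit_eq1(b, fvc_mean, response, cfg)
        except ValueError:
            continue
        label, per_step = classify_effect(est, cfg.alpha_level, cfg.fvc_report_step)
        estimates[b.bin_id] = est
        codes[b.pixel_ids] = CLASS_CODES[label]
        beta[b.pixel_ids] = per_step
    return EffectClassMap(class_code=codes, beta_per_step=beta, estimates=estimates)


def area_fractions(
    class_map: EffectClassMap,
    weights: Optional[np.ndarray] = None,
) -> Dict[str, float]:
    """Percent of classified (vegetated, fitted) surface in each effect
    class; area-weighted when weights are given.  Sums to 100."""
    codes = class_map.class_code
    ok = codes >= 0
    if weights is None:
        weights = np.ones(codes.shape)
    w = np.asarray(weights, dtype=float)[ok]
    total = w.sum()
    if total == 0:
        return {"cooling": np.nan, "neutral": np.nan, "warming": np.nan}
    out = {}
    for label, code in CLASS_CODES.items():
        out[label] = float(100.0 * w[codes[ok] == code].sum() / total)
    return {"cooling": out["cooling"], "neutral": out["neutral"],
            "warming": out["warming"]}


def gradient_summary(
    class_map: EffectClassMap,
    by: np.ndarray,
    kind: str = "precip",
    n_bins: int = 10,
) -> pd.DataFrame:
    """Effect size and class fractions along an environmental gradient:
    deciles of annual precipitation (kind="precip") or land-cover classes
    (kind="landcover")."""
    codes = class_map.class_code
    beta = class_map.beta_per_step
    ok = codes >= 0
    by = np.asarray(by)
    if kind == "precip":
        edges = np.quantile(by[ok], np.linspace(0, 1, n_bins + 1))
        group = np.clip(np.searchsorted(edges, by, side="right") - 1, 0, n_bins - 1)
        labels = [f"{edges[i]:.0f}-{edges[i+1]:.0f}" for i in range(n_bins)]
    elif kind == "landcover":
        cats = np.unique(by[ok])
        lut = {c: i for i, c in enumerate(cats)}
        group = np.asarray([lut.get(v, -1) for v in by])
        labels = [str(c) for c in cats]
    else:
        raise ValueError(f"unknown gradient kind {kind!r}")
    rows = []
    for g, lab in enumerate(labels):
        sel = ok & (group == g)
        if not sel.any():
            rows.append({"bin": lab, "n": 0, "beta_mean": np.nan,
                         "beta_median": np.nan, "cooling_pct": np.nan,
                         "neutral_pct": np.nan, "warming_pct": np.nan})
            continue
        c = codes[sel]
        rows.append({
            "bin": lab, "n": int(sel.sum()),
            "beta_mean": float(np.nanmean(beta[sel])),
            "beta_median": float(np.nanmedian(beta[sel])),
            "cooling_pct": 100.0 * np.mean(c == CLASS_CODES["cooling"]),
            "neutral_pct": 100.0 * np.mean(c == CLASS_CODES["neutral"]),
            "warming_pct": 100.0 * np.mean(c == CLASS_CODES["warming"]),
        })
    return pd.DataFrame(rows)


@dataclass
class SeasonalSplit:
    """Day labels splitting each pixel's year into low- and high-FVC halves
    by that pixel's own FVC median; tie days (FVC exactly at the median)
    fall in the high half."""

    low_days: np.ndarray   # boolean (day,) per call; see seasonal_split
    high_days: np.ndarray


def seasonal_split(fvc_series: np.ndarray) -> SeasonalSplit:
    """Partition one pixel's days into below-median (low_fvc) and
    at-or-above-median (high_fvc) vegetation halves."""
    fvc = np.asarray(fvc_series, dtype=float)
    if np.unique(fvc[np.isfinite(fvc)]).size < 2:
        raise ValueError("constant FVC series: pixel excluded from seasonal analysis")
    med = np.nanmedian(fvc)
    low = fvc < med
    high = ~low & np.isfinite(fvc)
    return SeasonalSplit(low_days=low, high_days=high)


def fit_eq2(
    bin_: ConditioningBin,
    fvc_seasonal: np.ndarray,
    theta_seasonal: np.ndarray,
    rs_seasonal: np.ndarray,
    rate_seasonal: np.ndarray,
    cfg: Optional[AnalysisConfig] = None,
) -> EffectEstimate:
    """Seasonal controlled regression: within-bin OLS of the seasonal mean
    rate on seasonal mean FVC with seasonal mean soil moisture and
    radiation as controls (to absorb direct environmental effects on LST
    not mediated by vegetation)."""
    cfg = cfg or AnalysisConfig()
    ids = bin_.pixel_ids
    X = np.column_stack([
        np.asarray(fvc_seasonal, dtype=float)[ids],
        np.asarray(theta_seasonal, dtype=float)[ids],
        np.asarray(rs_seasonal, dtype=float)[ids],
    ])
    y = np.asarray(rate_seasonal, dtype=float)[ids]
    ok = np.isfinite(y) & np.all(np.isfinite(X), axis=1)
    X, y = X[ok], y[ok]
    if y.size < 4 * cfg.min_pixels_per_regressor:
        raise ValueError(f"insufficient pixels in bin {bin_.bin_id} (n={y.size})")
    if np.ptp(X[:, 0]) == 0:
        raise ValueError(f"degenerate regressor: zero FVC variance in bin {bin_.bin_id}")
    return _ols_effect(y, X, cfg.alpha_level)


def env_percent_difference(seasonal_mean: float, annual_mean: float) -> float:
    """Percent difference of a seasonal environmental mean from the annual
    mean: 100 * (seasonal - annual) / annual."""
    if annual_mean == 0:
        raise ValueError("undefined percent difference: zero annual mean")
    return 100.0 * (seasonal_mean - annual_mean) / annual_mean


def interannual_fvc_regression(
    dtr_annual: np.ndarray,
    fvc_annual: np.ndarray,
    precip_annual: Optional[np.ndarray] = None,
    alpha: float = 0.05,
    min_years: int = 8,
) -> Optional[EffectEstimate]:
    """Per-pixel interannual robustness check: OLS of the annual DTR on
    annual FVC (with annual precipitation as an optional control), testing
    whether the spatial FVC-warming-rate relationship also holds in time.
    Returns None when too few complete years or a constant regressor."""
    dtr = np.asarray(dtr_annual, dtype=float)
    fvc = np.asarray(fvc_annual, dtype=float)
    cols = [fvc]
    if precip_annual is not None:
        cols.append(np.asarray(precip_annual, dtype=float))
    X = np.column_stack(cols)
    ok = np.isfinite(dtr) & np.all(np.isfinite(X), axis=1)
    if ok.sum() < min_years:
        return None
    X, y = X[ok], dtr[ok]
    if np.ptp(X[:, 0]) == 0:
        return None
    return _ols_effect(y, X, alpha)


def bin_table(
    bins: Sequence[ConditioningBin],
    class_map: EffectClassMap,
) -> pd.DataFrame:
    """Per-bin fit summary (CSV-ready): bin index, centers, n, effect,
    p-value and CI."""
    rows = []
    for b in bins:
        est = class_map.estimates.get(b.bin_id)
        rows.append({
            "theta_idx": b.bin_id[0], "rs_idx": b.bin_id[1],
            "theta_center": b.theta_center, "rs_center": b.rs_center,
            "n_pixels": b.pixel_ids.size,
            "beta_fvc": est.beta_fvc if est else np.nan,
            "p_fvc": est.p_fvc if est else np.nan,
            "ci_low": est.ci_fvc[0] if est else np.nan,
            "ci_high": est.ci_fvc[1] if est else np.nan,
        })
    return pd.DataFrame(rows)
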