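"""Interannual attribution of LST to greenness across the tropics.

Per pixel, annual mean LST is regressed on annual mean NDVI with annual
precipitation and shortwave radiation as controls,

    E[LST] = b0 + b_NDVI * E[NDVI] + b_P * E[P] + b_RS * E[RS] + eps,

after removing statistically significant linear trends from LST and NDVI
(to avoid LST-on-NDVI feedback confounding).  The headline quantity is
dLST = b_NDVI x 1% of the pixel's mean annual NDVI — the LST change a 1%
relative greening would cause — and the accounting of how much drylands
reduce the tropics-wide mean cooling.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional, Tuple

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .synthetic import AnnualPanel

__all__ = [
    "InterannualFit", "DeltaLSTMap", "CoolingReductionSummary",
    "detrend_if_significant", "fit_eq5", "fit_panel", "delta_lst",
    "delta_lst_map", "coverage_by_precip", "dryland_cooling_reduction",
    "regional_breakdown",
]


@dataclass
class InterannualFit:
    """Per-pixel interannual regression coefficients."""

    beta0: float
    beta_ndvi: float     # K per NDVI unit
    beta_p: float        # K per mm yr-1
    beta_rs: float       # K per W m-2
    p_ndvi: float
    ci_ndvi: Tuple[float, float]
    n_years: int
    detrended_lst: bool
    detrended_ndvi: bool
    reason: Optional[str] = None


@dataclass
class DeltaLSTMap:
    """Estimated LST change per 1% relative increase in mean annual NDVI."""

    delta_lst: np.ndarray    # K, per pixel; NaN where unfitted
    significant: np.ndarray  # boolean, p_ndvi < alpha
    beta_ndvi: np.ndarray    # K per NDVI unit
    p_ndvi: np.ndarray


@dataclass
class CoolingReductionSummary:
    """How much drylands reduce the tropics-wide vegetal cooling."""

    mean_delta_all: float
    mean_delta_humid: float
    mean_delta_dryland: float
    reduction_mean: float     # %
    reduction_median: float   # %
    ttest_p: float            # Welch test, all vs humid-only distributions
    dryland_area_fraction: float  # %


def detrend_if_significant(series: np.ndarray, alpha: float = 0.05,
                           ) -> Tuple[np.ndarray, bool]:
    """Remove a linear trend in year only when it is statistically
    significant (two-sided p < alpha); otherwise return the series
    unchanged.  Detrended output keeps the series mean.  Constant series
    (undefined trend p) are treated as trendless."""
    y = np.asarray(series, dtype=float)
    ok = np.isfinite(y)
    if ok.sum() < 3 or np.ptp(y[ok]) == 0:
        return y, False
    t = np.arange(y.size, dtype=float)
    res = stats.linregress(t[ok], y[ok])
    if not np.isfinite(res.pvalue) or res.pvalue >= alpha:
        return y, False
    out = y - (res.intercept + res.slope * t) + np.nanmean(y)
    return out, True


def fit_eq5(
    ndvi: np.ndarray, lst: np.ndarray, p: np.ndarray, rs: np.ndarray,
    alpha: float = 0.05, min_years: int = 10,
) -> InterannualFit:
    """One pixel's interannual multiple regression with trend screening."""
    ndvi = np.asarray(ndvi, dtype=float)
    lst = np.asarray(lst, dtype=float)
    p = np.asarray(p, dtype=float)
    rs = np.asarray(rs, dtype=float)
    ok = np.isfinite(ndvi) & np.isfinite(lst) & np.isfinite(p) & np.isfinite(rs)
    if ok.sum() < min_years:
        return _missing_fit("insufficient complete years", ok.sum())
    lst_d, f_lst = detrend_if_significant(np.where(ok, lst, np.nan), alpha)
    ndvi_d, f_ndvi = detrend_if_significant(np.where(ok, ndvi, np.nan), alpha)
    X = np.column_stack([ndvi_d[ok], p[ok], rs[ok]])
    if np.any(np.ptp(X, axis=0) == 0):
        return _missing_fit("constant regressor", ok.sum())
    exog = sm.add_constant(X, has_constant="add")
    if np.linalg.matrix_rank(exog) < exog.shape[1]:
        return _missing_fit("rank-deficient design", ok.sum())
    res = sm.OLS(lst_d[ok], exog).fit()
    ci = res.conf_int(alpha=alpha)
    return InterannualFit(
        beta0=float(res.params[0]), beta_ndvi=float(res.params[1]),
        beta_p=float(res.params[2]), beta_rs=float(res.params[3]),
        p_ndvi=float(res.pvalues[1]),
        ci_ndvi=(float(ci[1][0]), float(ci[1][1])),
        n_years=int(ok.sum()), detrended_lst=f_lst, detrended_ndvi=f_ndvi,
    )


def _missing_fit(reason: str, n: int) -> InterannualFit:
    nan = float("nan")
    return InterannualFit(nan, nan, nan, nan, nan, (nan, nan), int(n),
                          False, False, reason=reason)


def delta_lst(fit: InterannualFit, mean_ndvi: float) -> float:
    """LST change for a 1% *relative* increase in the pixel's mean annual
    NDVI: beta_NDVI x 0.01 x mean NDVI (K)."""
    return fit.beta_ndvi * 0.01 * mean_ndvi


def fit_panel(panel: AnnualPanel, alpha: float = 0.05,
              min_years: int = 10) -> DeltaLSTMap:
    """Fit every pixel of an annual panel and map dLST per 1% greening."""
    npx = panel.ndvi.shape[0]
    delta = np.full(npx, np.nan)
    beta = np.full(npx, np.nan)
    pval = np.full(npx, np.nan)
    sig = np.zeros(npx, dtype=bool)
    for i in range(npx):
        fit = fit_eq5(panel.ndvi[i], panel.lst[i], panel.p[i], panel.rs[i],
                      alpha, min_years)
        if fit.reason is not None:
            continue
        beta[i] = fit.beta_ndvi
        pval[i] = fit.p_ndvi
        sig[i] = fit.p_ndvi < alpha
        delta[i] = delta_lst(fit, float(np.nanmean(panel.ndvi[i])))
    return DeltaLSTMap(delta_lst=delta, significant=sig, beta_ndvi=beta,
                       p_ndvi=pval)


def delta_lst_map(panel: AnnualPanel, alpha: float = 0.05,
                  min_years: int = 10) -> DeltaLSTMap:
    """Alias of fit_panel (kept for discoverability)."""
    return fit_panel(panel, alpha, min_years)


def coverage_by_precip(
    delta_map: DeltaLSTMap,
    precip_annual: np.ndarray,
    edges: Optional[np.ndarray] = None,
    n_bins: int = 8,
) -> pd.DataFrame:
    """Areal coverage of significant warming / neutral / significant
    cooling effects, binned by mean annual precipitation.  Rows sum to 100
    where the bin is populated."""
    precip = np.asarray(precip_annual, dtype=float)
    ok = np.isfinite(delta_map.beta_ndvi)
    if edges is None:
        edges = np.quantile(precip[ok], np.linspace(0, 1, n_bins + 1))
    group = np.clip(np.searchsorted(edges, precip, side="right") - 1,
                    0, len(edges) - 2)
    rows = []
    for g in range(len(edges) - 1):
        sel = ok & (group == g)
        row = {"precip_low": float(edges[g]), "precip_high": float(edges[g + 1]),
               "n": int(sel.sum())}
        if not sel.any():
            row.update(warming_pct=np.nan, neutral_pct=np.nan, cooling_pct=np.nan)
        else:
            sig = delta_map.significant[sel]
            b = delta_map.beta_ndvi[sel]
            row.update(
                warming_pct=100.0 * np.mean(sig & (b > 0)),
                neutral_pct=100.0 * np.mean(~sig),
                cooling_pct=100.0 * np.mean(sig & (b < 0)),
            )
        rows.append(row)
    return pd.DataFrame(rows)


def dryland_cooling_reduction(
    delta: np.ndarray,
    dryland: np.ndarray,
    ttest: str = "all_vs_humid",
) -> CoolingReductionSummary:
    """Percent by which drylands reduce the tropics-wide mean (and median)
    vegetal cooling.

    reduction_mean = 100 * (mean(dLST | humid) - mean(dLST | all))
                          / mean(dLST | humid),
    and analogously with medians; the significance test is a Welch
    (unequal-variance) t-test between the full dLST distribution and the
    humid-only distribution (the "with and without drylands included"
    comparison; ttest="dry_vs_humid" compares the two disjoint groups
    instead, which keeps the nominal level since the samples are then
    independent).  An empty dryland (or humid-identical) set gives 0% by
    convention.
    """
    delta = np.asarray(delta, dtype=float)
    dryland = np.asarray(dryland, dtype=bool)
    ok = np.isfinite(delta)
    d_all = delta[ok]
    d_hum = delta[ok & ~dryland]
    d_dry = delta[ok & dryland]
    frac_dry = 100.0 * d_dry.size / d_all.size if d_all.size else np.nan
    if d_dry.size == 0 or d_hum.size == 0:
        m_h = float(np.mean(d_hum)) if d_hum.size else np.nan
        return CoolingReductionSummary(
            mean_delta_all=float(np.mean(d_all)) if d_all.size else np.nan,
            mean_delta_humid=m_h,
            mean_delta_dryland=float(np.mean(d_dry)) if d_dry.size else np.nan,
            reduction_mean=0.0, reduction_median=0.0, ttest_p=np.nan,
            dryland_area_fraction=frac_dry,
        )
    mean_h, mean_all = float(np.mean(d_hum)), float(np.mean(d_all))
    med_h, med_all = float(np.median(d_hum)), float(np.median(d_all))
    if mean_h == 0:
        raise ValueError("undefined reduction: zero humid mean dLST")
    red_mean = 100.0 * (mean_h - mean_all) / mean_h
    red_median = 0.0 if med_h == 0 else 100.0 * (med_h - med_all) / med_h
    if ttest == "all_vs_humid":
        tt = stats.ttest_ind(d_all, d_hum, equal_var=False)
    elif ttest == "dry_vs_humid":
        tt = stats.ttest_ind(d_dry, d_hum, equal_var=False)
    else:
        raise ValueError(f"unknown ttest variant {ttest!r}")
    return CoolingReductionSummary(
        mean_delta_all=mean_all, mean_delta_humid=mean_h,
        mean_delta_dryland=float(np.mean(d_dry)),
        reduction_mean=red_mean, reduction_median=red_median,
        ttest_p=float(tt.pvalue), dryland_area_fraction=frac_dry,
    )


def regional_breakdown(
    delta: np.ndarray,
    regions: np.ndarray,
    dryland: np.ndarray,
) -> pd.DataFrame:
    """Per-region cooling-reduction accounting (regions partition the
    domain): reduction mean/median, dryland area % and the Welch p."""
    regions = np.asarray(regions)
    rows = []
    for r in pd.unique(regions):
        sel = regions == r
        try:
            s = dryland_cooling_reduction(np.asarray(delta)[sel],
                                          np.asarray(dryland)[sel])
            rows.append({"region": r, "reduction_mean": s.reduction_mean,
                         "reduction_median": s.reduction_median,
                         "dryland_area_pct": s.dryland_area_fraction,
                         "ttest_p": s.ttest_p})
        except ValueError:
            rows.append({"region": r, "reduction_mean": np.nan,
                         "reduction_median": np.nan,
                         "dryland_area_pct": np.nan, "ttest_p": np.nan})
    return pd.DataFrame(rows)
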