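"""Technical-validation computations.

Vegetation indices, accuracy metrics (NSE / RMSE / R^2), pseudo-invariant
site diagnostics (detrended normalized anomalies, inter-epoch
discontinuities), OLS and Theil-Sen trend estimation with the Hamed-Rao
modified Mann-Kendall significance test, growing-season and low-signal
masking with area-weighted aggregation, and the site-level GPP comparison.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import xarray as xr
from scipy import stats

from .grids import biweekly_index_of

__all__ = [
    "vegetation_indices",
    "nse", "rmse", "r2",
    "PicsDiagnostics", "pics_diagnostics",
    "TrendResult", "trend_ols", "trend_theil_sen_mk",
    "growing_season_mask", "area_weighted_mean", "low_signal_mask",
    "aggregate_site_daily", "site_gpp_comparison",
]


# ---------------------------------------------------------------------------
# vegetation indices
# ---------------------------------------------------------------------------

def vegetation_indices(
    red: np.ndarray,
    nir: np.ndarray,
    rad: np.ndarray | None = None,
    kndvi_sigma: np.ndarray | float | None = None,
) -> dict[str, np.ndarray]:
    """NDVI, kNDVI, NIRv and (given radiation) NIRvP.

    NDVI = (NIR - red)/(NIR + red); kNDVI = tanh(((NIR - red)/(2 sigma))^2)
    with sigma defaulting to 0.5 (NIR + red), which reduces kNDVI to
    tanh(NDVI^2); NIRv = NDVI * NIR; NIRvP = NIRv * rad.
    Cells with NIR + red == 0 are undefined (NaN).
    """
    red = np.asarray(red, dtype=float)
    nir = np.asarray(nir, dtype=float)
    denom = nir + red
    bad = denom == 0
    safe = np.where(bad, 1.0, denom)
    ndvi = np.where(bad, np.nan, (nir - red) / safe)
    sigma = 0.5 * denom if kndvi_sigma is None else np.asarray(kndvi_sigma, dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        kndvi = np.tanh(((nir - red) / (2.0 * sigma)) ** 2)
    kndvi = np.where(bad, np.nan, kndvi)
    nirv = ndvi * nir
    out = {"ndvi": ndvi, "kndvi": kndvi, "nirv": nirv}
    if rad is not None:
        out["nirvp"] = nirv * np.asarray(rad, dtype=float)
    return out


# ---------------------------------------------------------------------------
# accuracy metrics
# ---------------------------------------------------------------------------

def _paired(pred, obs):
    pred = np.asarray(pred, dtype=float).ravel()
    obs = np.asarray(obs, dtype=float).ravel()
    if pred.size != obs.size:
        raise ValueError("pred and obs must have equal lengths")
    ok = np.isfinite(pred) & np.isfinite(obs)
    pred, obs = pred[ok], obs[ok]
    if pred.size < 2:
        raise ValueError("need at least 2 valid pairs")
    return pred, obs


def nse(pred, obs) -> float:
    """Nash-Sutcliffe efficiency: 1 - SSE / SS_obs."""
    pred, obs = _paired(pred, obs)
    denom = np.sum((obs - obs.mean()) ** 2)
    if denom == 0:
        raise ValueError("NSE undefined: observations have zero variance")
    return float(1.0 - np.sum((pred - obs) ** 2) / denom)


def rmse(pred, obs) -> float:
    pred, obs = _paired(pred, obs)
    return float(np.sqrt(np.mean((pred - obs) ** 2)))


def r2(x, y) -> float:
    """Squared Pearson correlation."""
    x, y = _paired(x, y)
    return float(np.corrcoef(x, y)[0, 1] ** 2)


# ---------------------------------------------------------------------------
# PICS diagnostics
# ---------------------------------------------------------------------------

@dataclass
class PicsDiagnostics:
    """Per-band PICS stability summary, all in percent of the series mean."""

    annual_years: np.ndarray
    anomalies_pct: dict[str, np.ndarray]          # detrended normalized, %
    discontinuities_pct: dict[str, dict[str, float]]  # band -> switch label -> %
    global_correlation: dict[str, tuple[float, float]] | None = None  # (r, p)

    def max_abs_anomaly_pct(self, band: str) -> float:
        return float(np.nanmax(np.abs(self.anomalies_pct[band])))


def _detrended_normalized_pct(years: np.ndarray, series: np.ndarray) -> np.ndarray:
    slope, intercept = np.polyfit(years, series, 1)
    resid = series - (slope * years + intercept)
    return 100.0 * resid / series.mean()


def pics_diagnostics(
    cube: xr.Dataset,
    pics_pixels: list[tuple[int, int]],
    switch_times: list | None = None,
    global_anomalies: dict[str, np.ndarray] | None = None,
    bands=("red", "nir"),
) -> PicsDiagnostics:
    """Stability diagnostics at (held-out) pseudo-invariant pixels.

    (a) annual PICS-mean reflectance, linearly detrended and normalized by
    the series mean, in percent; (b) for each sensor switch, the absolute
    difference of the 12-month means before vs after, as percent of the
    series mean; (c) optionally, Pearson r and p between the annual
    anomalies and a global product anomaly series.
    """
    rows = np.array([p[0] for p in pics_pixels])
    cols = np.array([p[1] for p in pics_pixels])
    years = cube["year"].values
    uyears = np.unique(years)
    times = cube["time"].values

    anomalies, discos, gcorr = {}, {}, {}
    for band in bands:
        series = np.nanmean(cube[band].values[:, rows, cols], axis=1)  # (nt,)
        annual = np.array([np.nanmean(series[years == y]) for y in uyears])
        if uyears.size >= 2:
            anomalies[band] = _detrended_normalized_pct(uyears.astype(float), annual)
        else:
            anomalies[band] = np.zeros_like(annual)

        d = {}
        for sw in switch_times or []:
            sw64 = np.datetime64(sw)
            before = (times < sw64) & (times >= sw64 - np.timedelta64(365, "D"))
            after = (times >= sw64) & (times < sw64 + np.timedelta64(365, "D"))
            if before.sum() < 2 or after.sum() < 2:
                continue
            step = abs(np.nanmean(series[after]) - np.nanmean(series[before]))
            d[str(sw)] = 100.0 * step / np.nanmean(series)
        discos[band] = d

        if global_anomalies is not None and band in global_anomalies:
            g = np.asarray(global_anomalies[band], dtype=float)
            r_val, p_val = stats.pearsonr(anomalies[band], g)
            gcorr[band] = (float(r_val), float(p_val))

    return PicsDiagnostics(uyears, anomalies, discos, gcorr or None)


# ---------------------------------------------------------------------------
# trends
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TrendResult:
    slope_per_decade: float
    intercept: float
    p_value: float
    method: str
    n_years: int


def trend_ols(years, values) -> TrendResult:
    """Least-squares linear trend of an annual series, slope per decade."""
    years = np.asarray(years, dtype=float)
    values = np.asarray(values, dtype=float)
    ok = np.isfinite(values)
    years, values = years[ok], values[ok]
    if years.size < 4:
        raise ValueError("need at least 4 annual values for an OLS trend")
    res = stats.linregress(years, values)
    return TrendResult(res.slope * 10.0, res.intercept, float(res.pvalue),
                       "ols", years.size)


def _mk_s_and_var(x: np.ndarray) -> tuple[float, float]:
    n = x.size
    s = 0.0
    for k in range(n - 1):
        s += np.sign(x[k + 1:] - x[k]).sum()
    # tie-corrected variance
    _, counts = np.unique(x, return_counts=True)
    tie_term = (counts * (counts - 1) * (2 * counts + 5)).sum()
    var = (n * (n - 1) * (2 * n + 5) - tie_term) / 18.0
    return s, var


def _hamed_rao_correction(x: np.ndarray, alpha: float = 0.05,
                          detrend: bool = False) -> float:
    """Variance inflation n/n* from significant rank autocorrelations.

    Only lags whose rank autocorrelation is individually significant at
    ``alpha`` enter the correction, and the factor is clamped at 1 (serial
    correlation can only inflate the Mann-Kendall variance).  The
    autocorrelation is estimated on the raw ranks by default: removing a
    Sen-slope trend first systematically absorbs the low-frequency power of
    strongly autocorrelated series and under-corrects the variance; the
    raw-rank estimate instead errs conservative for series with a genuine
    strong trend.
    """
    n = x.size
    if detrend:
        slope = stats.theilslopes(x, np.arange(n)).slope
        x = x - slope * np.arange(n)
    ranks = stats.rankdata(x)
    rc = ranks - ranks.mean()
    denom = (rc ** 2).sum()
    z_crit = stats.norm.ppf(1 - alpha / 2)
    factor = 0.0
    for lag in range(1, n):
        if n - lag < 3:
            break
        rho = (rc[:-lag] * rc[lag:]).sum() / denom
        if abs(rho) > z_crit / np.sqrt(n):
            factor += (n - lag) * (n - lag - 1) * (n - lag - 2) * rho
    return max(1.0 + 2.0 / (n * (n - 1) * (n - 2)) * factor, 1.0)


def trend_theil_sen_mk(years, values, hamed_rao: bool = True) -> TrendResult:
    """Theil-Sen slope with the (Hamed-Rao modified) Mann-Kendall test.

    The Theil-Sen slope is the median of pairwise slopes; the MK variance is
    inflated by the Hamed-Rao factor computed from significant lag
    autocorrelations of the ranks of the Sen-detrended series, guarding the
    test against serial correlation.  Ties-only series give S = 0, p = 1.
    """
    years = np.asarray(years, dtype=float)
    values = np.asarray(values, dtype=float)
    ok = np.isfinite(values)
    years, values = years[ok], values[ok]
    n = years.size
    if n < 8:
        raise ValueError("need at least 8 annual values for the modified MK test")
    order = np.argsort(years)
    years, values = years[order], values[order]

    sen = stats.theilslopes(values, years)
    s, var = _mk_s_and_var(values)
    if var <= 0:
        return TrendResult(sen.slope * 10.0, sen.intercept, 1.0, "theil_sen_mk", n)
    if hamed_rao:
        var *= _hamed_rao_correction(values)
    if s > 0:
        z = (s - 1) / np.sqrt(var)
    elif s < 0:
        z = (s + 1) / np.sqrt(var)
    else:
        z = 0.0
    p = 2.0 * (1.0 - stats.norm.cdf(abs(z)))
    return TrendResult(sen.slope * 10.0, sen.intercept, float(p), "theil_sen_mk", n)


# ---------------------------------------------------------------------------
# masking and aggregation
# ---------------------------------------------------------------------------

def growing_season_mask(ta_climatology: np.ndarray, threshold: float = 5.0) -> np.ndarray:
    """month x lat x lon boolean mask: in season iff climatological Ta >
    threshold (strict)."""
    return np.asarray(ta_climatology, dtype=float) > threshold


def area_weighted_mean(
    field: np.ndarray,
    lat: np.ndarray,
    mask: np.ndarray | None = None,
) -> np.ndarray:
    """cos(latitude)-weighted spatial mean of (..., nlat, nlon) fields."""
    field = np.asarray(field, dtype=float)
    w = np.cos(np.deg2rad(np.asarray(lat, dtype=float)))[:, None]
    w = np.broadcast_to(w, field.shape[-2:]).copy()
    ok = np.isfinite(field)
    if mask is not None:
        ok = ok & np.broadcast_to(mask, field.shape)
    wfull = np.where(ok, w, 0.0)
    num = np.nansum(np.where(ok, field, 0.0) * wfull, axis=(-2, -1))
    den = wfull.sum(axis=(-2, -1))
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(den > 0, num / den, np.nan)


def low_signal_mask(climatology: np.ndarray, threshold: float = 0.03) -> np.ndarray:
    """True where the multi-year mean is at or above threshold (pixels below
    are excluded from trend/correlation maps)."""
    return np.asarray(climatology, dtype=float) >= threshold


# ---------------------------------------------------------------------------
# site-level GPP comparison
# ---------------------------------------------------------------------------

def aggregate_site_daily(daily: pd.DataFrame, value_cols: list[str]) -> pd.DataFrame:
    """Aggregate per-site daily series to biweekly means with the mean QC."""
    df = daily.copy()
    keys = [biweekly_index_of(d) for d in df["date"]]
    df["year"] = [k.year for k in keys]
    df["poy"] = [k.ordinal for k in keys]
    group_cols = ["site", "year", "poy"]
    keep_meta = [c for c in ("landcover", "row", "col") if c in df.columns]
    agg = {c: "mean" for c in value_cols}
    if "qc" in df.columns:
        agg["qc"] = "mean"
    for c in keep_meta:
        agg[c] = "first"
    return df.groupby(group_cols, as_index=False).agg(agg)


def site_gpp_comparison(
    biweekly: pd.DataFrame,
    proxy_cols: list[str],
    gpp_col: str = "gpp",
    qc_col: str = "qc",
    qc_threshold: float = 0.7,
    alpha: float = 0.05,
    era_split_year: int | None = None,
    min_years_per_era: int = 3,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-site R^2 of each proxy against GPP, plus paired tests.

    Biweekly periods qualify only when their mean QC exceeds the threshold
    (strictly).  With ``era_split_year``, sites are restricted to those with
    at least ``min_years_per_era`` years of qualifying data on each side,
    and R^2 is computed separately per era.  Paired t-tests compare proxies
    across sites within each land-cover class (one-tailed "A beats B" and
    two-tailed difference).
    """
    df = biweekly[biweekly[qc_col] > qc_threshold].copy()
    if era_split_year is not None:
        df["era"] = np.where(df["year"] < era_split_year, "pre", "post")
        years_per = df.groupby(["site", "era"])["year"].nunique().unstack(fill_value=0)
        keep = years_per[(years_per >= min_years_per_era).all(axis=1)].index
        df = df[df["site"].isin(keep)]
        eras = ["pre", "post"]
    else:
        df["era"] = "all"
        eras = ["all"]

    rows = []
    for (site, era), sub in df.groupby(["site", "era"]):
        if len(sub) < 2 or sub[gpp_col].nunique() < 2:
            continue
        row = {"site": site, "era": era, "n_periods": len(sub)}
        if "landcover" in sub.columns:
            row["landcover"] = sub["landcover"].iloc[0]
        for pcol in proxy_cols:
            try:
                row[f"r2_{pcol}"] = r2(sub[pcol], sub[gpp_col])
            except ValueError:
                row[f"r2_{pcol}"] = np.nan
        rows.append(row)
    comparisons = pd.DataFrame(rows)

    tests = []
    if not comparisons.empty and "landcover" in comparisons.columns:
        for (lc, era), sub in comparisons.groupby(["landcover", "era"]):
            for i, a in enumerate(proxy_cols):
                for b in proxy_cols[i + 1:]:
                    paired = sub[[f"r2_{a}", f"r2_{b}"]].dropna()
                    if len(paired) < 2:
                        continue
                    diff = paired[f"r2_{a}"] - paired[f"r2_{b}"]
                    if np.allclose(diff, 0.0):
                        t_stat, p_two, p_one = 0.0, 1.0, 0.5
                    else:
                        t_stat, p_two = stats.ttest_rel(paired[f"r2_{a}"], paired[f"r2_{b}"])
                        p_one = p_two / 2 if t_stat > 0 else 1 - p_two / 2
                    tests.append({
                        "landcover": lc, "era": era, "proxy_a": a, "proxy_b": b,
                        "n_sites": len(paired), "t": float(t_stat),
                        "p_two_tailed": float(p_two),
                        "p_one_tailed_a_beats_b": float(p_one),
                        "significant": bool(p_two < alpha),
                    })
    return comparisons, pd.DataFrame(tests)
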