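"""Cross-calibration of the harmonized drifting record against the
reference sensor, and gap-filling.

The "double calibration" has two stages fitted on the sensor-overlap era:

1. a pixel-wise linear map fitted from all co-located (drifting, reference)
   pairs pooled over the 5x5 spatial neighborhood of each pixel, fitted per
   period-of-year where samples allow (pooled-across-periods fallback), and
   separately per sensor group (early NOAA-era epochs vs the late stable
   epoch);
2. a residual model: a small neural network mapping environmental
   covariates (AOD, snow depth, cloud cover, elevation, aridity) plus the
   linearly corrected red/NIR to the remaining residual
   gamma = reference - linear_corrected.  Geographic coordinates are
   deliberately not predictors.

Both stages are then applied over the whole record, including the era with
no reference data.  Remaining gaps are filled with the adjacent-year
seasonal mean and then with HANTS (iterative harmonic least squares with
low-side outlier rejection).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import xarray as xr
from scipy.ndimage import uniform_filter
from sklearn.neural_network import MLPRegressor
from sklearn.preprocessing import StandardScaler

from .grids import PERIODS_PER_YEAR

logger = logging.getLogger(__name__)

__all__ = [
    "WindowedLinearModel",
    "ResidualModel",
    "HantsConfig",
    "fit_windowed_linear",
    "apply_windowed_linear",
    "compute_residual",
    "train_residual_model",
    "apply_double_calibration",
    "seasonal_mean_fill",
    "hants_series",
    "hants_gapfill",
]

BANDS = ("red", "nir")
RESIDUAL_FEATURES = ("aod", "sd", "cc", "ele", "ai", "lin_red", "lin_nir")

# fill-provenance codes
FILL_OBSERVED, FILL_SEASONAL, FILL_HANTS, FILL_MISSING = 0, 1, 2, 3


def _box_sum(arr: np.ndarray, size: int) -> np.ndarray:
    """Sum over the size x size window clipped at the grid edge."""
    return uniform_filter(arr, size=size, mode="constant", cval=0.0) * size * size


@dataclass
class WindowedLinearModel:
    """Per-pixel affine maps drifting -> reference.

    slope/intercept: band -> group -> (24, nlat, nlon); flag 0 = per-period
    fit, 1 = pooled fallback, 2 = unfitted.
    """

    slope: dict[str, dict[str, np.ndarray]]
    intercept: dict[str, dict[str, np.ndarray]]
    flag: dict[str, dict[str, np.ndarray]]
    n_pairs: dict[str, dict[str, np.ndarray]]
    window: int
    groups: dict[int, str]  # epoch index -> group name


def fit_windowed_linear(
    drifting: xr.Dataset,
    reference: xr.Dataset,
    groups: dict[int, str],
    window: int = 5,
    min_pairs: int = 6,
    per_period: bool = True,
    aggregate_years: bool = True,
    center_anchor: bool = True,
    min_center: int = 8,
) -> WindowedLinearModel:
    """OLS slope/intercept per center pixel from neighborhood overlap pairs.

    For each band, sensor group, and (by default) period-of-year, all valid
    co-located pairs within the window around each pixel are pooled and a
    simple regression reference ~ drifting is fitted.  Windows are clipped
    at the grid edge.  Cells with fewer than ``min_pairs`` pairs or zero
    predictor variance fall back to the all-period pooled fit; if that is
    also degenerate they are left unfitted.

    With ``aggregate_years`` (the default) each pixel contributes its
    per-period-of-year mean over the overlap years rather than raw
    composite pairs.  Averaging the co-located pairs before the regression
    suppresses the errors-in-variables attenuation of the slope caused by
    observation noise in the predictor, which would otherwise differ
    between sensor groups (their records carry different upstream
    correction noise) and imprint a spurious level step at group
    boundaries on bright stable targets.

    With ``center_anchor`` (the default) the slope comes from the pooled
    window fit but the intercept is re-anchored on the center pixel's own
    co-located means (``c = mean(y_c) - m * mean(x_c)``) whenever the
    center has at least ``min_center`` pairs.  The neighborhood then only
    stabilizes the gain, while the level is pixel-faithful — important for
    pixels (bright calibration targets, water edges) whose radiometric
    behavior differs from their neighborhood.
    """
    if window % 2 != 1:
        raise ValueError("window must be odd")
    # align reference onto the drifting time axis
    common = np.intersect1d(drifting["time"].values, reference["time"].values)
    d = drifting.sel(time=common)
    r = reference.sel(time=common)
    sensor = d["sensor"].values
    poy = d["poy"].values

    group_names = sorted(set(groups.values()))
    slope = {b: {} for b in BANDS}
    intercept = {b: {} for b in BANDS}
    flag = {b: {} for b in BANDS}
    n_pairs = {b: {} for b in BANDS}

    for band in BANDS:
        x_all = d[band].values.astype(float)
        y_all = r[band].values.astype(float)
        ok_all = np.isfinite(x_all) & np.isfinite(y_all)
        for g in group_names:
            tsel_g = np.array([groups.get(int(s), None) == g for s in sensor])
            if not tsel_g.any():
                raise ValueError(f"sensor group {g!r} has no overlap with the reference")

            def pair_values(tmask):
                """Stacked (x, y, weight) samples over the selected times;
                one year-averaged sample per pixel-and-period if aggregating."""
                if not aggregate_years:
                    ok = ok_all[tmask]
                    return (np.where(ok, x_all[tmask], 0.0),
                            np.where(ok, y_all[tmask], 0.0),
                            ok.astype(float))
                xs, ys, ws = [], [], []
                for p in np.unique(poy[tmask]):
                    sub = tmask & (poy == p)
                    ok = ok_all[sub]
                    cnt = ok.sum(axis=0)
                    has = cnt > 0
                    denom = np.maximum(cnt, 1).astype(float)
                    xs.append(np.where(ok, x_all[sub], 0.0).sum(axis=0) / denom)
                    ys.append(np.where(ok, y_all[sub], 0.0).sum(axis=0) / denom)
                    ws.append(has.astype(float))
                return np.stack(xs), np.stack(ys), np.stack(ws)

            def sums(tmask):
                x, y, w = pair_values(tmask)  # x, y are 0 wherever w is 0
                center = {
                    "n": w.sum(axis=0),
                    "sx": x.sum(axis=0),
                    "sy": y.sum(axis=0),
                }
                boxed = {
                    "n": _box_sum(center["n"], window),
                    "sx": _box_sum(center["sx"], window),
                    "sy": _box_sum(center["sy"], window),
                    "sxx": _box_sum((x * x).sum(axis=0), window),
                    "sxy": _box_sum((x * y).sum(axis=0), window),
                }
                boxed["center"] = center
                return boxed

            def solve(s):
                n = s["n"]
                with np.errstate(invalid="ignore", divide="ignore"):
                    var = n * s["sxx"] - s["sx"] ** 2
                    m = (n * s["sxy"] - s["sx"] * s["sy"]) / var
                    c = (s["sy"] - m * s["sx"]) / n
                    if center_anchor:
                        cen = s["center"]
                        c_anchor = (cen["sy"] - m * cen["sx"]) / cen["n"]
                        use = cen["n"] >= min_center
                        c = np.where(use, c_anchor, c)
                good = (n >= min_pairs) & (var > 1e-12 * np.maximum(n, 1) ** 2)
                return np.where(good, m, np.nan), np.where(good, c, np.nan), good

            pooled = solve(sums(tsel_g))
            shape = (PERIODS_PER_YEAR,) + x_all.shape[1:]
            m_out = np.full(shape, np.nan)
            c_out = np.full(shape, np.nan)
            f_out = np.full(shape, 2, dtype=np.int8)
            n_out = np.zeros(shape)
            for p in range(1, PERIODS_PER_YEAR + 1):
                if per_period:
                    s = sums(tsel_g & (poy == p))
                    m, c, good = solve(s)
                    n_out[p - 1] = s["n"]
                else:
                    m, c, good = np.nan, np.nan, np.zeros(x_all.shape[1:], bool)
                mp, cp, gp = pooled
                m_out[p - 1] = np.where(good, m, np.where(gp, mp, np.nan))
                c_out[p - 1] = np.where(good, c, np.where(gp, cp, np.nan))
                f_out[p - 1] = np.where(good, 0, np.where(gp, 1, 2))
            slope[band][g] = m_out
            intercept[band][g] = c_out
            flag[band][g] = f_out
            n_pairs[band][g] = n_out

    return WindowedLinearModel(slope, intercept, flag, n_pairs, window, dict(groups))


def apply_windowed_linear(
    cube: xr.Dataset,
    model: WindowedLinearModel,
) -> xr.Dataset:
    """Apply the per-group affine maps over the whole record.

    Unfitted pixels pass through the raw value, flagged in
    ``<band>_lin_flag`` (0 per-period fit, 1 pooled, 2 pass-through).
    """
    sensor = cube["sensor"].values
    poy = cube["poy"].values
    out = cube.copy(deep=True)
    for band in BANDS:
        x = cube[band].values.astype(float)
        res = np.full_like(x, np.nan)
        fl = np.full(x.shape, 2, dtype=np.int8)
        for t in range(x.shape[0]):
            g = model.groups.get(int(sensor[t]))
            if g is None:
                res[t] = x[t]
                continue
            m = model.slope[band][g][poy[t] - 1]
            c = model.intercept[band][g][poy[t] - 1]
            fitted = np.isfinite(m)
            res[t] = np.where(fitted, m * x[t] + c, x[t])
            fl[t] = np.where(fitted, model.flag[band][g][poy[t] - 1], 2)
        out[band] = (("time", "lat", "lon"), res.astype(np.float32))
        out[f"{band}_lin_flag"] = (("time", "lat", "lon"), fl)
    return out


def compute_residual(linear_corrected: xr.Dataset, reference: xr.Dataset) -> xr.Dataset:
    """gamma = reference - linearly corrected drifting, on the overlap times."""
    common = np.intersect1d(linear_corrected["time"].values, reference["time"].values)
    lc = linear_corrected.sel(time=common)
    r = reference.sel(time=common)
    out = lc[[]].copy()
    for band in BANDS:
        out[f"gamma_{band}"] = r[band] - lc[band]
    out["sensor"] = lc["sensor"]
    return out


@dataclass
class ResidualModel:
    """Standardized-feature MLP for the post-linear residual, per band.

    Targets are standardized during training (residuals are a few 1e-3 in
    reflectance units, far below the unit scale the optimizer expects) and
    predictions are mapped back to reflectance units.
    """

    scaler: StandardScaler
    models: dict[str, MLPRegressor]
    target_mean: dict[str, float]
    target_sd: dict[str, float]
    validation_rmse: dict[str, float]
    n_train: int
    features: tuple[str, ...] = RESIDUAL_FEATURES

    def predict(self, features: np.ndarray) -> dict[str, np.ndarray]:
        z = self.scaler.transform(features)
        return {
            b: self.models[b].predict(z) * self.target_sd[b] + self.target_mean[b]
            for b in BANDS
        }


def _residual_feature_table(
    lin: xr.Dataset, met: xr.Dataset, times: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Feature matrix (n, 7) and validity mask over (time, lat, lon)."""
    m = met.sel(time=times)
    lc = lin.sel(time=times)
    nt = times.size
    stat = {v: np.broadcast_to(m[v].values, (nt,) + m[v].shape) for v in ("ele", "ai")}
    cols = [
        m["aod"].values, m["sd"].values, m["cc"].values,
        stat["ele"], stat["ai"],
        lc["red"].values, lc["nir"].values,
    ]
    feats = np.stack([c.reshape(nt, -1) for c in cols], axis=-1)  # (nt, npix, 7)
    ok = np.isfinite(feats).all(axis=-1)
    return feats, ok


def train_residual_model(
    gamma: xr.Dataset,
    met: xr.Dataset,
    linear_corrected: xr.Dataset,
    hidden: tuple[int, ...] = (32,),
    max_epochs: int = 120,
    val_block: int = 5,
    max_samples: int = 80_000,
    seed: int = 0,
) -> ResidualModel:
    """Train the covariate -> residual network on the overlap era.

    The train/validation split is by period blocks (every ``val_block``-th
    time step is validation) to respect temporal autocorrelation.  Rows with
    non-finite features or targets are dropped (counted in the log).
    """
    times = gamma["time"].values
    feats, ok = _residual_feature_table(linear_corrected, met, times)
    targets = {b: gamma[f"gamma_{b}"].values.reshape(times.size, -1) for b in BANDS}
    for b in BANDS:
        ok &= np.isfinite(targets[b])

    is_val = (np.arange(times.size) % val_block) == (val_block - 1)
    rng = np.random.default_rng(seed)

    def gather(tmask):
        rows_t, rows_p = np.nonzero(ok & tmask[:, None])
        X = feats[rows_t, rows_p]
        ys = {b: targets[b][rows_t, rows_p] for b in BANDS}
        return X, ys

    X_tr, y_tr = gather(~is_val)
    X_va, y_va = gather(is_val)
    n_dropped = int((~ok).sum())
    if n_dropped:
        logger.info("residual model: dropped %d rows with non-finite values", n_dropped)
    if X_tr.shape[0] > max_samples:
        keep = rng.choice(X_tr.shape[0], max_samples, replace=False)
        X_tr = X_tr[keep]
        y_tr = {b: y_tr[b][keep] for b in BANDS}

    scaler = StandardScaler().fit(X_tr)
    Z_tr = scaler.transform(X_tr)
    Z_va = scaler.transform(X_va)
    models, val_rmse, t_mean, t_sd = {}, {}, {}, {}
    for i, b in enumerate(BANDS):
        mu = float(np.mean(y_tr[b]))
        sd = float(np.std(y_tr[b])) or 1.0
        t_mean[b], t_sd[b] = mu, sd
        mlp = MLPRegressor(
            hidden_layer_sizes=hidden, solver="adam", batch_size=512,
            learning_rate_init=1e-3, max_iter=max_epochs, tol=1e-7,
            random_state=int(rng.integers(2**31)),
        )
        mlp.fit(Z_tr, (y_tr[b] - mu) / sd)
        models[b] = mlp
        pred = mlp.predict(Z_va) * sd + mu
        val_rmse[b] = float(np.sqrt(np.mean((pred - y_va[b]) ** 2)))
    logger.info("residual model validation RMSE: %s", val_rmse)
    return ResidualModel(scaler, models, t_mean, t_sd, val_rmse, X_tr.shape[0])


def apply_double_calibration(
    drifting_harmonized: xr.Dataset,
    lin: WindowedLinearModel,
    res: ResidualModel | None,
    met: xr.Dataset,
) -> xr.Dataset:
    """calibrated = linear_map(drifting) + residual_model(covariates).

    Applied over the whole record, including periods with no reference
    data.  If ``res`` is None, only the linear stage is applied.
    """
    out = apply_windowed_linear(drifting_harmonized, lin)
    if res is None:
        return out
    times = out["time"].values
    feats, ok = _residual_feature_table(out, met, times)
    nlat, nlon = out.sizes["lat"], out.sizes["lon"]
    rows_t, rows_p = np.nonzero(ok)
    preds = res.predict(feats[rows_t, rows_p])
    for band in BANDS:
        corr = np.zeros((times.size, nlat * nlon))
        corr[rows_t, rows_p] = preds[band]
        vals = out[band].values + corr.reshape(times.size, nlat, nlon).astype(np.float32)
        out[band] = (("time", "lat", "lon"), vals)
    return out


# ---------------------------------------------------------------------------
# gap filling
# ---------------------------------------------------------------------------

def seasonal_mean_fill(cube: xr.Dataset, bands=BANDS) -> xr.Dataset:
    """Fill each missing period with the mean of the same period-of-year in
    the adjacent years (one-sided at record edges).  Fill provenance is
    recorded in ``<band>_fill`` (0 observed, 1 seasonal, 3 still missing)."""
    out = cube.copy(deep=True)
    years = cube["year"].values
    poy = cube["poy"].values
    for band in bands:
        v = cube[band].values.astype(float)
        filled = v.copy()
        prov = np.where(np.isfinite(v), FILL_OBSERVED, FILL_MISSING).astype(np.int8)
        for t in range(v.shape[0]):
            if np.isfinite(v[t]).all():
                continue
            y, p = years[t], poy[t]
            neigh = []
            for dy in (-1, 1):
                sel = np.nonzero((years == y + dy) & (poy == p))[0]
                if sel.size:
                    neigh.append(v[sel[0]])
            if not neigh:
                continue
            with np.errstate(invalid="ignore"):
                cand = np.nanmean(np.stack(neigh), axis=0)
            gap = ~np.isfinite(v[t]) & np.isfinite(cand)
            filled[t][gap] = cand[gap]
            prov[t][gap] = FILL_SEASONAL
        out[band] = (("time", "lat", "lon"), filled.astype(np.float32))
        out[f"{band}_fill"] = (("time", "lat", "lon"), prov)
    return out


@dataclass(frozen=True)
class HantsConfig:
    n_harmonics: int = 3
    base_period: int = PERIODS_PER_YEAR
    reject_threshold: float = 2.5   # in residual-sd units, low side only
    max_iterations: int = 10
    min_points: int | None = None   # default 2*n_harmonics + 1

    def __post_init__(self) -> None:
        if self.n_harmonics < 1:
            raise ValueError("need at least one harmonic")
        if self.reject_threshold <= 0:
            raise ValueError("reject threshold must be positive")

    @property
    def minimum_points(self) -> int:
        return self.min_points if self.min_points is not None else 2 * self.n_harmonics + 1


def hants_series(
    values: np.ndarray,
    config: HantsConfig = HantsConfig(),
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Harmonic analysis of one series on the biweekly time index.

    Iteratively least-squares fits mean + annual-cycle harmonics, rejecting
    points whose residual is below -threshold*sd (low-biased outliers, i.e.
    residual cloud/shadow contamination in reflectance-type series), and
    returns (filled series, harmonic fit, kept-point mask).  Valid retained
    observations are never altered in the filled series.
    """
    y = np.asarray(values, dtype=float)
    t = np.arange(y.size)
    w = 2.0 * np.pi * t / config.base_period
    cols = [np.ones_like(t, dtype=float)]
    for k in range(1, config.n_harmonics + 1):
        cols += [np.cos(k * w), np.sin(k * w)]
    X = np.stack(cols, axis=-1)

    keep = np.isfinite(y)
    if keep.sum() < config.minimum_points:
        return y.copy(), np.full_like(y, np.nan), keep
    fit = np.full_like(y, np.nan)
    for _ in range(config.max_iterations):
        beta, *_ = np.linalg.lstsq(X[keep], y[keep], rcond=None)
        fit = X @ beta
        resid = y - fit
        sd = np.std(resid[keep])
        # an (essentially) exact fit: nothing left to reject
        if sd <= 1e-10 * max(float(np.max(np.abs(y[keep]))), 1.0):
            break
        reject = keep & (resid < -config.reject_threshold * sd)
        if not reject.any():
            break
        if (keep & ~reject).sum() < config.minimum_points:
            break
        keep = keep & ~reject
    filled = np.where(np.isfinite(y) & keep, y, fit)
    # rejected observations are replaced by the fit as well
    filled = np.where(np.isfinite(y) & ~keep, fit, filled)
    return filled, fit, keep


def hants_gapfill(
    cube: xr.Dataset,
    config: HantsConfig = HantsConfig(),
    bands=BANDS,
) -> xr.Dataset:
    """Apply HANTS per pixel to fill the gaps remaining after the seasonal
    fill; updates the ``<band>_fill`` provenance (2 = hants-filled)."""
    out = cube.copy(deep=True)
    nt = cube.sizes["time"]
    for band in bands:
        v = cube[band].values.astype(float)
        prov = (
            cube[f"{band}_fill"].values.copy()
            if f"{band}_fill" in cube
            else np.where(np.isfinite(v), FILL_OBSERVED, FILL_MISSING).astype(np.int8)
        )
        flat = v.reshape(nt, -1)
        prov_flat = prov.reshape(nt, -1)
        for j in range(flat.shape[1]):
            col = flat[:, j]
            gaps = ~np.isfinite(col)
            if not gaps.any():
                continue
            filled, fit, _ = hants_series(col, config)
            newly = gaps & np.isfinite(filled)
            col[newly] = filled[newly]
            prov_flat[newly, j] = FILL_HANTS
        out[band] = (("time", "lat", "lon"), flat.reshape(v.shape).astype(np.float32))
        out[f"{band}_fill"] = (("time", "lat", "lon"), prov_flat.reshape(v.shape))
    return out
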