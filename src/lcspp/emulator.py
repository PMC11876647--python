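"""SIF emulation: sounding gridding, splits, and the reflectance -> SIF
feedforward network.

Individual SIF soundings are screened (best quality, clear sky, nadir
mode), aggregated to daily grid-cell means — which shrinks the retrieval
noise by 1/sqrt(n) — and cells with fewer than five soundings are dropped.
A small feedforward network maps (red, NIR, cos SZA) to SIF; the
hyperparameter grid spans learning rates {1e-3, 5e-4}, 1-3 hidden layers
and widths {8, 32, 64}, each trained for 40 epochs with standardized
inputs.  The combination with the best validation Nash-Sutcliffe
efficiency is retrained on train+validation combined.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.neural_network import MLPRegressor

from .grids import GridSpec

logger = logging.getLogger(__name__)

__all__ = [
    "grid_soundings",
    "split_samples",
    "HyperGrid",
    "EmulatorModel",
    "train_emulator",
    "predict_sif",
]

FEATURES = ("red", "nir", "cos_sza")


def grid_soundings(
    table: pd.DataFrame,
    grid: GridSpec,
    min_soundings: int = 5,
) -> pd.DataFrame:
    """Aggregate screened soundings to daily grid-cell means.

    Keeps best-quality, clear-sky, nadir soundings; returns one row per
    (row, col, date) with the mean SIF, mean cos(SZA), matched mean
    red/NIR, and the sounding count n; cells with n < ``min_soundings``
    are dropped (counts logged).
    """
    screened = table[
        (table["quality_flag"] == "best")
        & (table["mode_flag"] == "nadir")
        & (table["cloud_flag"] == "clear")
    ].copy()
    screened["cos_sza"] = np.cos(np.deg2rad(screened["sza"]))
    agg_cols = {"sif_757": "mean", "cos_sza": "mean"}
    for extra in ("red", "nir", "sif_true"):
        if extra in screened.columns:
            agg_cols[extra] = "mean"
    cells = (
        screened.groupby(["row", "col", "date"], as_index=False)
        .agg(n=("sif_757", "size"), **{k: (k, v) for k, v in agg_cols.items()})
    )
    kept = cells[cells["n"] >= min_soundings].reset_index(drop=True)
    logger.info(
        "grid_soundings: %d cells kept, %d dropped with n < %d",
        len(kept), len(cells) - len(kept), min_soundings,
    )
    kept["lat"] = grid.lat_centers[kept["row"].to_numpy()]
    kept["lon"] = grid.lon_centers[kept["col"].to_numpy()]
    kept["year"] = [d.year for d in kept["date"]]
    return kept


def split_samples(
    samples: pd.DataFrame,
    train_years: set[int],
    test_years: set[int],
    val_fraction: float = 0.2,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """(train, val, test): test = all samples in test_years; val = an exact
    seeded ``val_fraction`` draw of the train-year samples."""
    if train_years & test_years:
        raise ValueError("train and test years must be disjoint")
    years = samples["year"].to_numpy()
    test = samples[np.isin(years, list(test_years))]
    pool = samples[np.isin(years, list(train_years))]
    if len(pool) == 0 or len(test) == 0:
        raise ValueError("empty train or test split")
    rng = np.random.default_rng(seed)
    n_val = int(round(val_fraction * len(pool)))
    val_idx = rng.choice(len(pool), size=n_val, replace=False)
    mask = np.zeros(len(pool), dtype=bool)
    mask[val_idx] = True
    return (
        pool[~mask].reset_index(drop=True),
        pool[mask].reset_index(drop=True),
        test.reset_index(drop=True),
    )


@dataclass(frozen=True)
class HyperGrid:
    learning_rates: tuple[float, ...] = (1e-3, 5e-4)
    n_layers: tuple[int, ...] = (1, 2, 3)
    widths: tuple[int, ...] = (8, 32, 64)

    def combinations(self):
        for lr in self.learning_rates:
            for d in self.n_layers:
                for w in self.widths:
                    yield lr, d, w


@dataclass
class EmulatorModel:
    """Trained emulator: frozen standardization + MLP weights."""

    feature_mean: np.ndarray
    feature_sd: np.ndarray
    mlp: MLPRegressor
    grid_scores: list[dict] = field(default_factory=list)
    best: dict | None = None
    feature_order: tuple[str, ...] = FEATURES

    def forward(self, X: np.ndarray) -> np.ndarray:
        z = (X - self.feature_mean) / self.feature_sd
        return self.mlp.predict(z)

    def save(self, path: str | Path) -> None:
        """Portable JSON container: standardization, architecture, weights."""

        def plain(obj):
            if isinstance(obj, dict):
                return {k: plain(v) for k, v in obj.items()}
            if isinstance(obj, (list, tuple)):
                return [plain(v) for v in obj]
            if isinstance(obj, np.generic):
                return obj.item()
            return obj

        payload = {
            "feature_order": list(self.feature_order),
            "feature_mean": self.feature_mean.tolist(),
            "feature_sd": self.feature_sd.tolist(),
            "hidden_layer_sizes": [int(h) for h in
                                   np.atleast_1d(self.mlp.hidden_layer_sizes)],
            "coefs": [w.tolist() for w in self.mlp.coefs_],
            "intercepts": [b.tolist() for b in self.mlp.intercepts_],
            "grid_scores": plain(self.grid_scores),
            "best": plain(self.best),
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def load(cls, path: str | Path) -> "EmulatorModel":
        payload = json.loads(Path(path).read_text())
        mlp = MLPRegressor(hidden_layer_sizes=tuple(payload["hidden_layer_sizes"]))
        coefs = [np.asarray(w) for w in payload["coefs"]]
        intercepts = [np.asarray(b) for b in payload["intercepts"]]
        # rebuild a predict-ready estimator without refitting
        mlp.coefs_ = coefs
        mlp.intercepts_ = intercepts
        mlp.n_layers_ = len(coefs) + 1
        mlp.n_outputs_ = 1
        mlp.out_activation_ = "identity"
        mlp.activation = "relu"
        mlp.n_features_in_ = coefs[0].shape[0]
        model = cls(
            np.asarray(payload["feature_mean"]),
            np.asarray(payload["feature_sd"]),
            mlp,
            payload.get("grid_scores", []),
            payload.get("best"),
            tuple(payload["feature_order"]),
        )
        return model


def _nse(pred: np.ndarray, obs: np.ndarray) -> float:
    obs_var = np.sum((obs - obs.mean()) ** 2)
    return float(1.0 - np.sum((pred - obs) ** 2) / obs_var)


def _feature_matrix(df: pd.DataFrame) -> np.ndarray:
    return df[list(FEATURES)].to_numpy(dtype=float)


def _fit_mlp(X, y, lr, depth, width, epochs, seed) -> MLPRegressor:
    mlp = MLPRegressor(
        hidden_layer_sizes=(width,) * depth,
        learning_rate_init=lr,
        solver="adam",
        batch_size=min(256, len(y)),
        max_iter=epochs,
        early_stopping=False,
        tol=0.0,  # always run the full epoch budget
        n_iter_no_change=epochs,
        random_state=seed,
    )
    import warnings
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        mlp.fit(X, y)
    return mlp


def train_emulator(
    train: pd.DataFrame,
    val: pd.DataFrame,
    grid: HyperGrid = HyperGrid(),
    epochs: int = 40,
    target: str = "sif_757",
    seed: int = 0,
) -> EmulatorModel:
    """Grid search, NSE-based selection, and retrain on train+val.

    Every grid combination is trained for the full epoch budget without
    early stopping; combinations whose loss diverges are marked failed and
    excluded from selection.
    """
    if len(train) == 0 or len(val) == 0:
        raise ValueError("empty train or validation split")
    X_tr, y_tr = _feature_matrix(train), train[target].to_numpy(dtype=float)
    X_va, y_va = _feature_matrix(val), val[target].to_numpy(dtype=float)
    mean = X_tr.mean(axis=0)
    sd = X_tr.std(axis=0)
    sd[sd == 0] = 1.0
    Z_tr, Z_va = (X_tr - mean) / sd, (X_va - mean) / sd

    scores = []
    rng = np.random.default_rng(seed)
    for lr, depth, width in grid.combinations():
        sub_seed = int(rng.integers(2**31))
        mlp = _fit_mlp(Z_tr, y_tr, lr, depth, width, epochs, sub_seed)
        entry = {"lr": lr, "depth": depth, "width": width, "seed": sub_seed}
        if not np.isfinite(mlp.loss_):
            entry.update(status="failed", val_nse=-np.inf)
        else:
            entry.update(status="ok", val_nse=_nse(mlp.predict(Z_va), y_va),
                         train_loss=float(mlp.loss_))
        scores.append(entry)
        logger.info("emulator grid: %s", entry)

    ok = [s for s in scores if s["status"] == "ok"]
    if not ok:
        raise RuntimeError("all hyperparameter combinations diverged")
    best = max(ok, key=lambda s: s["val_nse"])

    # retrain on train + validation combined with the winning combination
    X_all = np.vstack([X_tr, X_va])
    y_all = np.concatenate([y_tr, y_va])
    mean = X_all.mean(axis=0)
    sd = X_all.std(axis=0)
    sd[sd == 0] = 1.0
    final = _fit_mlp((X_all - mean) / sd, y_all, best["lr"], best["depth"],
                     best["width"], epochs, best["seed"])
    return EmulatorModel(mean, sd, final, scores, best)


def predict_sif(
    model: EmulatorModel,
    red: np.ndarray,
    nir: np.ndarray,
    cos_sza: np.ndarray,
) -> np.ndarray:
    """Emulated SIF (mW m-2 nm-1 sr-1) for arrays of any common shape.

    Reflectance outside [0, 1] is clipped with a warning; cells with
    cos(SZA) <= 0 (polar winter) are set to 0; non-finite inputs give NaN.
    """
    red = np.asarray(red, dtype=float)
    nir = np.asarray(nir, dtype=float)
    mu = np.asarray(cos_sza, dtype=float)
    shape = np.broadcast_shapes(red.shape, nir.shape, mu.shape)
    red, nir, mu = (np.broadcast_to(a, shape).copy() for a in (red, nir, mu))
    out_of_range = ((red < 0) | (red > 1) | (nir < 0) | (nir > 1)) & np.isfinite(red) & np.isfinite(nir)
    if out_of_range.any():
        logger.warning("predict_sif: clipped %d reflectance values outside [0, 1]",
                       int(out_of_range.sum()))
        red = np.clip(red, 0.0, 1.0)
        nir = np.clip(nir, 0.0, 1.0)
    ok = np.isfinite(red) & np.isfinite(nir) & np.isfinite(mu)
    out = np.full(shape, np.nan)
    day = ok & (mu > 0)
    if day.any():
        X = np.stack([red[day], nir[day], mu[day]], axis=-1)
        out[day] = model.forward(X)
    out[ok & (mu <= 0)] = 0.0
    return out
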