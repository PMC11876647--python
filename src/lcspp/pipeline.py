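"""End-to-end calibration chain over a synthetic scene.

Order of operations (mirroring the reflectance-processing flowchart):
daily streams -> exclusion windows -> biweekly NDVI maximum-value
composites -> PICS bias proxy -> SZA / inter-sensor OLS correction ->
5x5 windowed linear map to the reference sensor -> covariate residual
network -> (optional) seasonal-mean + HANTS gap-filling.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import xarray as xr

from . import crosscal, harmonize, preprocess
from .synthetic import Scene
from .validate import PicsDiagnostics, pics_diagnostics

__all__ = ["CalibrationResult", "run_calibration", "held_out_pics_diagnostics"]


@dataclass
class CalibrationResult:
    scene: Scene
    drifting_raw: xr.Dataset        # biweekly composites, uncorrected
    reference: xr.Dataset           # reference-stream composites
    delta: harmonize.PicsBiasSeries
    sza_model: harmonize.SzaBiasModel
    harmonized: xr.Dataset          # after SZA + inter-sensor correction
    linear_model: crosscal.WindowedLinearModel
    linear_only: xr.Dataset         # after the windowed linear map
    residual_model: crosscal.ResidualModel | None
    calibrated: xr.Dataset          # after the full double calibration

    @property
    def switch_dates(self):
        return self.scene.daily.epochs.switch_dates()


def run_calibration(
    scene: Scene,
    per_period_linear: bool = False,
    residual: bool = True,
    gapfill: bool = False,
    residual_max_epochs: int = 120,
    sza_min_n: int = 8,
    seed: int = 0,
) -> CalibrationResult:
    """Run the full harmonize + cross-calibration chain on a scene."""
    daily = scene.daily
    grid = scene.grid

    valid_d = preprocess.apply_exclusion_windows(
        daily.drifting.valid, daily.drifting.dates,
        daily.injection.exclusion_windows,
    )
    drifting_raw = preprocess.composite_mvc(daily.drifting, grid, valid=valid_d)
    reference = preprocess.composite_mvc(daily.reference, grid)

    reference_epoch = len(daily.epochs.epochs) - 1
    delta = harmonize.compute_pics_bias(drifting_raw, scene.pics_cal, reference_epoch)
    sza_model = harmonize.fit_sza_bias_model(drifting_raw, delta, daily.met,
                                             min_n=sza_min_n)
    harmonized = harmonize.remove_sza_bias(drifting_raw, sza_model, delta)

    # sensor groups: all drifting epochs together (NOAA-era analogue) vs the
    # stable last epoch (MetOp analogue)
    groups = {k: ("metop" if e.reference else "noaa")
              for k, e in enumerate(daily.epochs.epochs)}
    linear_model = crosscal.fit_windowed_linear(
        harmonized, reference, groups, per_period=per_period_linear)
    linear_only = crosscal.apply_windowed_linear(harmonized, linear_model)

    residual_model = None
    calibrated = linear_only
    if residual:
        gamma = crosscal.compute_residual(linear_only, reference)
        residual_model = crosscal.train_residual_model(
            gamma, daily.met, linear_only,
            max_epochs=residual_max_epochs, seed=seed)
        calibrated = crosscal.apply_double_calibration(
            harmonized, linear_model, residual_model, daily.met)

    if gapfill:
        calibrated = crosscal.seasonal_mean_fill(calibrated)
        calibrated = crosscal.hants_gapfill(calibrated)

    return CalibrationResult(
        scene, drifting_raw, reference, delta, sza_model, harmonized,
        linear_model, linear_only, residual_model, calibrated,
    )


def held_out_pics_diagnostics(result: CalibrationResult,
                              cube: xr.Dataset | None = None) -> PicsDiagnostics:
    """PICS stability diagnostics at the validation (held-out) PICS pixels."""
    cube = result.calibrated if cube is None else cube
    return pics_diagnostics(
        cube, result.scene.pics_val, switch_times=result.switch_dates)
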