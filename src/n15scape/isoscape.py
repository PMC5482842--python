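"""Continuous predicted d15N rasters and scenario decomposition maps.

Predictions are fixed-effects only (group intercepts are not defined on
the raster) and are masked beyond the maximum canopy distance observed in
the training table.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .gamm import FittedGAMM
from .predictors import PredictorStack
from .raster import RasterGrid

_CONTINUOUS = ("dist_ac", "log_area_ac", "elev_ac", "log_cover", "twi")


@dataclass
class ScenarioSpec:
    """Predictors kept at their original spatial variation; all others are
    held at the training mean (continuous) or modal class (landform)."""

    vary: tuple = ()

    def __post_init__(self) -> None:
        self.vary = tuple(self.vary)


def training_constants(table: pd.DataFrame) -> dict:
    """Mean of continuous predictors, most frequent landform class."""
    consts = {t: float(table[t].mean()) for t in _CONTINUOUS if t in table}
    if "landform" in table:
        consts["landform"] = table["landform"].astype(str).mode().iloc[0]
    return consts


def _cell_table(fit: FittedGAMM, stack: PredictorStack, scenario: ScenarioSpec,
                consts: dict, rows: np.ndarray, cols: np.ndarray) -> pd.DataFrame:
    layers = {
        "dist_ac": stack.dist_ac.values,
        "log_area_ac": np.log(stack.area_ac.values),
        "elev_ac": stack.elev_ac.values,
        "log_cover": np.log(stack.cover.values + 1.0),
        "twi": stack.twi.values,
    }
    data = {}
    terms = list(fit.spec.smooth_terms) + (["landform"] if fit.spec.landform else [])
    for term in terms:
        if term == "landform":
            if term in scenario.vary:
                codes = stack.landform.grid.values[rows, cols]
                names = np.full(codes.shape, "", dtype=object)
                for code, name in stack.landform.legend.items():
                    names[codes == code] = name
                data[term] = names
            else:
                data[term] = np.full(rows.shape, consts["landform"], dtype=object)
        else:
            if term not in layers:
                raise ValueError(f"predictor stack is missing layer {term!r}")
            if term in scenario.vary:
                data[term] = layers[term][rows, cols]
            else:
                data[term] = np.full(rows.shape, consts[term])
    return pd.DataFrame(data)


def scenario_isoscape(fit: FittedGAMM, stack: PredictorStack,
                      table: pd.DataFrame, scenario: ScenarioSpec, *,
                      chunk: int = 50_000) -> RasterGrid:
    """Predict a d15N raster with a subset of predictors varying spatially.

    Predictors in ``scenario.vary`` keep their raster values; the rest are
    replaced by training constants.  Cells farther from a canopy than any
    training plant, or with nodata in any needed varied layer, are nodata.
    """
    template = stack.template
    dist_max = float(table["dist_ac"].max())
    valid = np.isfinite(stack.dist_ac.values) & (stack.dist_ac.values <= dist_max)
    rows_all, cols_all = np.nonzero(valid)
    consts = training_constants(table)
    out = np.full(template.shape, np.nan)
    for start in range(0, rows_all.size, chunk):
        rows = rows_all[start:start + chunk]
        cols = cols_all[start:start + chunk]
        cells = _cell_table(fit, stack, scenario, consts, rows, cols)
        numeric = cells.select_dtypes(include=[float])
        ok = np.ones(len(cells), dtype=bool)
        if not numeric.empty:
            ok &= np.isfinite(numeric.to_numpy()).all(axis=1)
        if "landform" in cells:
            ok &= cells["landform"].to_numpy() != ""
        pred = np.full(len(cells), np.nan)
        if ok.any():
            pred[ok] = fit.predict(cells.loc[ok], include_random=False)
        out[rows, cols] = pred
    return template.like(out)


def predict_isoscape(fit: FittedGAMM, stack: PredictorStack,
                     table: pd.DataFrame) -> RasterGrid:
    """Full fixed-effects isoscape: every model predictor varies spatially."""
    terms = tuple(fit.spec.smooth_terms) + (("landform",) if fit.spec.landform else ())
    return scenario_isoscape(fit, stack, table, ScenarioSpec(vary=terms))
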