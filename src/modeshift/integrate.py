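"""Data integration: transfer accelerometer T-MVPA to the travel survey.

A random-forest regressor is fitted on the donor cohort (trips with
observed per-trip T-MVPA minutes) over the full predictor set — trip
duration, speed, mode, timing, distance, person attributes and the
accessibility/context blocks at departure, arrival and residence — and
used to predict per-trip T-MVPA for the survey.  Validation is the
forest's built-in out-of-bag R².  Two physical constraints are imposed
on predictions: they are clipped to [0, duration], and bicycle trips
bypass the model entirely (every biking minute counts as MVPA, so
predicted T-MVPA equals the trip duration).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor

from ._oob import oob_regression_predictions
from .features import MODES, FeatureSchema, SchemaError, tmvpa_schema


class IntegrationError(ValueError):
    pass


@dataclass
class TmvpaModel:
    forest: RandomForestRegressor
    schema: FeatureSchema
    oob_r2: float
    oob_predictions: np.ndarray
    n_oob_trees: np.ndarray


def fit_tmvpa_model(donor_trips: pd.DataFrame, *,
                    n_estimators: int = 500,
                    max_features: float | str = 0.3333,
                    min_samples_leaf: int = 1,
                    max_depth: int | None = None,
                    random_state: int = 0) -> TmvpaModel:
    """Fit the T-MVPA regression forest on donor trips.

    Requires at least 100 trips with an observed ``tmvpa_min`` column
    and a complete predictor schema.  ``max_features`` defaults to one
    third of the predictors, the usual regression-forest choice.
    """
    if len(donor_trips) < 100:
        raise IntegrationError(
            f"donor has {len(donor_trips)} trips; at least 100 required")
    if "tmvpa_min" not in donor_trips.columns:
        raise SchemaError("missing outcome column: 'tmvpa_min'")
    y = donor_trips["tmvpa_min"].to_numpy(dtype=float)
    if not np.isfinite(y).all():
        raise SchemaError("non-finite values in outcome column 'tmvpa_min'")
    schema = tmvpa_schema()
    X = schema.encode(donor_trips)
    forest = RandomForestRegressor(
        n_estimators=n_estimators, max_features=max_features,
        min_samples_leaf=min_samples_leaf, max_depth=max_depth,
        bootstrap=True, random_state=random_state, n_jobs=1)
    forest.fit(X, y)
    oob_pred, counts = oob_regression_predictions(forest, X)
    has = counts > 0
    ss_res = float(np.sum((y[has] - oob_pred[has]) ** 2))
    ss_tot = float(np.sum((y[has] - y[has].mean()) ** 2))
    oob_r2 = 1.0 - ss_res / ss_tot
    return TmvpaModel(forest, schema, oob_r2, oob_pred, counts)


def predict_tmvpa(model: TmvpaModel, trips: pd.DataFrame) -> np.ndarray:
    """Predict per-trip T-MVPA minutes, clipped to [0, duration].

    Bicycle trips return the trip duration regardless of the model.
    """
    X = model.schema.encode(trips)
    pred = model.forest.predict(X)
    dur = trips["duration_min"].to_numpy(dtype=float)
    pred = np.clip(pred, 0.0, dur)
    bike = (trips["mode"] == "bicycle").to_numpy()
    pred[bike] = dur[bike]
    return pred


def daily_tmvpa(trips: pd.DataFrame,
                person_ids=None) -> pd.DataFrame:
    """Per person-day T-MVPA, decomposed by transportation mode.

    Returns a frame indexed by (person_id, day_index) with one column
    per mode plus ``total`` (the exact sum of the mode columns).  If
    ``person_ids`` is given, persons without any trip are included with
    zeros (one row for day 1).
    """
    for col in ("person_id", "tmvpa_min", "mode"):
        if col not in trips.columns:
            raise SchemaError(f"missing column: {col!r}")
    day = trips["day_index"] if "day_index" in trips.columns else 1
    wide = (trips.assign(day_index=day)
            .pivot_table(index=["person_id", "day_index"], columns="mode",
                         values="tmvpa_min", aggfunc="sum", fill_value=0.0))
    for m in MODES:
        if m not in wide.columns:
            wide[m] = 0.0
    wide = wide[MODES]
    wide.columns.name = None
    if person_ids is not None:
        missing = pd.Index(person_ids).difference(
            wide.index.get_level_values("person_id"))
        if len(missing):
            zeros = pd.DataFrame(
                0.0, columns=MODES,
                index=pd.MultiIndex.from_product(
                    [missing, [1]], names=["person_id", "day_index"]))
            wide = pd.concat([wide, zeros]).sort_index()
    wide["total"] = wide[MODES].sum(axis=1)
    return wide
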