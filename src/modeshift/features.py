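"""Shared column schema and feature encoding for the three random forests.

The trip table carries, per trip: trip/timing characteristics, the
straight-line distance and derived speed, and — for departure, arrival
and residence — a block of five network distances to the nearest
public-transport/train/metro/tram/bus stations, a block of five
contextual measures (area education, destinations, intersections, park
surface, population density), and a three-level zone (Paris / adjacent
counties / non-adjacent counties).  Person attributes (age, gender,
education, work situation, income) are merged onto every trip.

Three predictor sets are derived from this table:

* mode model      — everything except duration, speed, T-MVPA (outcome: mode)
* duration model  — mode included, duration/speed/T-MVPA excluded
* T-MVPA model    — duration, speed and mode included (45 raw variables)
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MODES = ["walking", "bicycle", "public_transport", "private_motorized"]

#: short column suffix used in likelihood tables, ordered as MODES
MODE_SHORT = {"walking": "walk", "bicycle": "bike",
              "public_transport": "pt", "private_motorized": "pm"}

STATION_TYPES = ["pt", "train", "metro", "tram", "bus"]
CONTEXT_TYPES = ["education", "destinations", "intersections", "parks", "popdensity"]
ZONES = ["paris", "adjacent", "non_adjacent"]
EDUCATION_LEVELS = ["E1", "E2", "E3"]
WORK_SITUATIONS = ["employed", "unemployed", "retired", "other"]
GENDERS = ["female", "male"]
DAYS_OF_WEEK = ["mon", "tue", "wed", "thu", "fri", "sat", "sun"]


def access_cols(prefix: str) -> list[str]:
    return [f"{prefix}_dist_{s}" for s in STATION_TYPES]


def context_cols(prefix: str) -> list[str]:
    return [f"{prefix}_ctx_{c}" for c in CONTEXT_TYPES]


class SchemaError(ValueError):
    """A required predictor column is missing or malformed."""


@dataclass(frozen=True)
class FeatureSchema:
    """Frozen predictor list with fixed categorical encodings.

    ``numeric`` columns are used as-is (booleans cast to float);
    ``categorical`` maps a column to its frozen category order, encoded
    one-hot.  Freezing the order here guarantees that donor and survey
    tables are encoded identically.
    """

    numeric: tuple[str, ...]
    categorical: dict[str, tuple[str, ...]] = field(default_factory=dict)

    @property
    def columns(self) -> list[str]:
        return list(self.numeric) + list(self.categorical)

    @property
    def feature_names(self) -> list[str]:
        names = list(self.numeric)
        for col, cats in self.categorical.items():
            names.extend(f"{col}={c}" for c in cats)
        return names

    def validate(self, df: pd.DataFrame) -> None:
        for col in self.columns:
            if col not in df.columns:
                raise SchemaError(f"missing predictor column: {col!r}")
        num = df[list(self.numeric)].apply(pd.to_numeric, errors="coerce")
        if not np.isfinite(num.to_numpy(dtype=float)).all():
            bad = [c for c in self.numeric
                   if not np.isfinite(num[c].to_numpy(dtype=float)).all()]
            raise SchemaError(f"non-finite values in predictor columns: {bad}")
        for col, cats in self.categorical.items():
            unseen = set(df[col].astype(str)) - set(cats)
            if unseen:
                raise SchemaError(
                    f"column {col!r} has categories outside the frozen "
                    f"encoding: {sorted(unseen)}")

    def encode(self, df: pd.DataFrame) -> np.ndarray:
        """Encode trips to the model matrix (n_trips x n_features)."""
        self.validate(df)
        blocks = [df[list(self.numeric)].to_numpy(dtype=float)]
        for col, cats in self.categorical.items():
            codes = pd.Categorical(df[col].astype(str), categories=cats).codes
            onehot = np.eye(len(cats))[codes]
            blocks.append(onehot)
        return np.ascontiguousarray(np.hstack(blocks))


def _common_blocks() -> tuple[list[str], dict[str, tuple[str, ...]]]:
    numeric = [
        "departure_hour", "rush_hour", "straight_line_distance_m",
        "age", "income",
    ]
    for prefix in ("departure", "arrival", "residence"):
        numeric += access_cols(prefix)
        numeric += context_cols(prefix)
    categorical: dict[str, tuple[str, ...]] = {
        "day_of_week": tuple(DAYS_OF_WEEK),
        "gender": tuple(GENDERS),
        "work_situation": tuple(WORK_SITUATIONS),
        "education": tuple(EDUCATION_LEVELS),
        "departure_zone": tuple(ZONES),
        "arrival_zone": tuple(ZONES),
        "residence_zone": tuple(ZONES),
    }
    return numeric, categorical


def mode_schema() -> FeatureSchema:
    """Predictors of transportation mode (mode is the outcome)."""
    numeric, categorical = _common_blocks()
    return FeatureSchema(tuple(numeric), categorical)


def duration_schema() -> FeatureSchema:
    """Predictors of trip duration (mode included, duration excluded)."""
    numeric, categorical = _common_blocks()
    categorical = {"mode": tuple(MODES), **categorical}
    return FeatureSchema(tuple(numeric), categorical)


def tmvpa_schema() -> FeatureSchema:
    """Predictors of per-trip T-MVPA: duration, speed, mode and the rest."""
    numeric, categorical = _common_blocks()
    numeric = ["duration_min", "speed_m_min"] + numeric
    categorical = {"mode": tuple(MODES), **categorical}
    return FeatureSchema(tuple(numeric), categorical)
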