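"""Scenario execution: stochastic trip selection and mode reassignment.

For each scenario repetition, candidate trips are selected via their
rescaled mode likelihoods and reassigned a destination mode; the trip
duration is then re-predicted by a forest fitted on the original
(pre-shift) survey with mode as a predictor, the speed covariate is
recomputed from the new duration, and per-trip T-MVPA is re-predicted
with the data-integration model (biking override included).  The whole
procedure is repeated (default 100 times) to average out sampling
error.

Because the duration and T-MVPA re-predictions for a given (trip,
destination mode) pair are deterministic once the forests are fitted,
they are precomputed for every candidate and destination, and each
repetition only redraws the random selection — expectation-identical
to re-predicting inside the loop, and far cheaper.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor

from ._oob import oob_regression_predictions
from .features import MODES, FeatureSchema, duration_schema
from .integrate import TmvpaModel, daily_tmvpa, predict_tmvpa
from .likelihood import SHARE_COLS, MODE_SHORT
from .rescale import rescale_to_mean
from .scenario import Scenario, ShiftPlan, ScenarioError, build_shift_plan

#: a single rescaled-probability row summing above this is treated as
#: pathological rather than renormalizable
MAX_PROB_ROW_SUM = 1.5

MIN_DURATION_MIN = 1.0


class SimulationError(ValueError):
    pass


# ---------------------------------------------------------------------------
# duration model


@dataclass
class DurationModel:
    forest: RandomForestRegressor
    schema: FeatureSchema
    oob_r2: float


def fit_duration_model(trips: pd.DataFrame, *,
                       n_estimators: int = 500,
                       max_features: float | str = 0.3333,
                       min_samples_leaf: int = 1,
                       max_depth: int | None = None,
                       train_subsample: int | None = None,
                       random_state: int = 0) -> DurationModel:
    """Fit the trip-duration forest on the original survey.

    Mode is a predictor (so the model can be queried with a
    counterfactual mode); duration and speed are excluded.
    ``train_subsample`` optionally fits on a random subset of the
    trips, which barely moves the fit on large surveys.
    """
    schema = duration_schema()
    if train_subsample is not None and train_subsample < len(trips):
        rng = np.random.default_rng(random_state)
        keep = rng.choice(len(trips), size=train_subsample, replace=False)
        trips = trips.iloc[np.sort(keep)]
    X = schema.encode(trips)
    y = trips["duration_min"].to_numpy(dtype=float)
    forest = RandomForestRegressor(
        n_estimators=n_estimators, max_features=max_features,
        min_samples_leaf=min_samples_leaf, max_depth=max_depth,
        bootstrap=True, random_state=random_state, n_jobs=1)
    forest.fit(X, y)
    oob_pred, counts = oob_regression_predictions(forest, X)
    has = counts > 0
    ss_res = float(np.sum((y[has] - oob_pred[has]) ** 2))
    ss_tot = float(np.sum((y[has] - y[has].mean()) ** 2))
    return DurationModel(forest, schema, 1.0 - ss_res / ss_tot)


def predict_duration(model: DurationModel, trips: pd.DataFrame) -> np.ndarray:
    """Predicted trip duration in minutes, floored at 1."""
    pred = model.forest.predict(model.schema.encode(trips))
    return np.maximum(pred, MIN_DURATION_MIN)


# ---------------------------------------------------------------------------
# conversion


def convert_trips(trips: pd.DataFrame, new_mode: str,
                  duration_model: DurationModel,
                  tmvpa_model: TmvpaModel) -> pd.DataFrame:
    """Counterfactual copies of ``trips`` reassigned to ``new_mode``.

    Duration is re-predicted with the new mode (floored at 1 minute),
    speed recomputed as distance / new duration, and T-MVPA re-predicted
    on the updated trip (bicycle override: T-MVPA = new duration).
    """
    out = trips.copy()
    out["mode"] = new_mode
    out["duration_min"] = predict_duration(duration_model, out)
    out["speed_m_min"] = (out["straight_line_distance_m"]
                          / out["duration_min"])
    out["tmvpa_min"] = predict_tmvpa(tmvpa_model, out)
    return out


def apply_conversion(trip: pd.Series, new_mode: str,
                     duration_model: DurationModel,
                     tmvpa_model: TmvpaModel) -> pd.Series:
    """Convert a single trip to ``new_mode`` (see `convert_trips`)."""
    if trip["mode"] == new_mode:
        raise SimulationError(
            f"trip already has mode {new_mode!r}; nothing to convert")
    return convert_trips(pd.DataFrame([trip]), new_mode,
                         duration_model, tmvpa_model).iloc[0]


# ---------------------------------------------------------------------------
# selection


def rescaled_probability_matrix(likelihoods: pd.DataFrame,
                                plan: ShiftPlan) -> tuple[np.ndarray, list[str]]:
    """Per-candidate selection probabilities, one column per destination.

    Each destination mode's likelihood column is independently rescaled
    on the logit scale so its mean equals that mode's selection
    fraction.  Rows whose rescaled probabilities sum above 1 are
    renormalized; a row sum above ``MAX_PROB_ROW_SUM`` raises.
    """
    dests = [m for m in MODES if plan.conversions.get(m, 0) > 0]
    n = len(likelihoods)
    P = np.zeros((n, len(dests)))
    for j, mode in enumerate(dests):
        col = f"p_{MODE_SHORT[mode]}"
        P[:, j] = rescale_to_mean(
            likelihoods[col].to_numpy(dtype=float),
            plan.selection_fraction[mode]).shifted
    row_sum = P.sum(axis=1)
    if np.any(row_sum > MAX_PROB_ROW_SUM):
        raise SimulationError(
            f"rescaled selection probabilities sum to "
            f"{row_sum.max():.3f} > {MAX_PROB_ROW_SUM} for some trip")
    over = row_sum > 1.0
    if over.any():
        P[over] /= row_sum[over, None]
    return P, dests


def select_and_assign(candidates: pd.DataFrame, likelihoods: pd.DataFrame,
                      plan: ShiftPlan, rng: np.random.Generator) -> pd.Series:
    """Draw one destination mode (or none) per candidate trip.

    A single categorical draw per candidate over the destination modes
    plus "no change", with the rescaled likelihoods as probabilities —
    so expected per-mode conversion counts equal the plan's while no
    trip can be assigned two destinations.

    Returns a Series indexed like ``candidates`` with the new mode or
    ``None``.
    """
    lk = likelihoods.set_index("trip_id").reindex(
        candidates["trip_id"].to_numpy())
    if lk[SHARE_COLS].isna().any().any():
        raise SimulationError("some candidate trips have no likelihoods")
    P, dests = rescaled_probability_matrix(lk.reset_index(), plan)
    assigned = _categorical_draw(P, rng)
    labels = np.array(dests + [None], dtype=object)
    return pd.Series(labels[assigned], index=candidates.index,
                     name="new_mode")


def _categorical_draw(P: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Index of the drawn column of ``P`` per row; ``P.shape[1]`` = none."""
    if P.shape[1] == 0:
        return np.full(P.shape[0], 0, dtype=int)
    thresholds = np.cumsum(P, axis=1)
    u = rng.random(P.shape[0])
    return (thresholds < u[:, None]).sum(axis=1)


# ---------------------------------------------------------------------------
# scenario runs


@dataclass
class RepetitionResult:
    """Converted trips of one scenario repetition.

    ``converted`` has one row per reassigned trip: ids, old/new mode,
    old/new duration and old/new T-MVPA.  Unconverted trips are by
    construction bit-identical to the baseline survey.
    """

    index: int
    converted: pd.DataFrame

    def counts_by_destination(self) -> dict[str, int]:
        c = self.converted["new_mode"].value_counts().to_dict()
        return {m: int(c.get(m, 0)) for m in MODES}


@dataclass
class SimulationRun:
    scenario: Scenario
    plan: ShiftPlan
    baseline_decomp: pd.DataFrame
    repetitions: list[RepetitionResult] = field(default_factory=list)

    def rep_decomposition(self, i: int) -> pd.DataFrame:
        """Per-person daily T-MVPA decomposition after repetition ``i``."""
        decomp = self.baseline_decomp.copy()
        conv = self.repetitions[i].converted
        for mode in MODES:
            minus = conv.loc[conv["old_mode"] == mode].groupby(
                "person_id")["old_tmvpa"].sum()
            plus = conv.loc[conv["new_mode"] == mode].groupby(
                "person_id")["new_tmvpa"].sum()
            delta = plus.sub(minus, fill_value=0.0)
            if len(delta):
                decomp.loc[delta.index, mode] += delta.to_numpy()
        decomp["total"] = decomp[MODES].sum(axis=1)
        return decomp


def apply_repetition(survey: pd.DataFrame,
                     rep: RepetitionResult) -> pd.DataFrame:
    """Materialize the post-shift trip table of one repetition.

    Returns a copy of ``survey`` where the converted trips carry their
    new mode, duration, speed and T-MVPA; all other trips are
    bit-identical to the input.
    """
    out = survey.copy()
    conv = rep.converted
    if not len(conv):
        return out
    # predicted durations are fractional minutes
    out["duration_min"] = out["duration_min"].astype(float)
    pos = out.index[out["trip_id"].isin(conv["trip_id"])]
    aligned = conv.set_index("trip_id").loc[
        out.loc[pos, "trip_id"].to_numpy()]
    out.loc[pos, "mode"] = aligned["new_mode"].to_numpy()
    out.loc[pos, "duration_min"] = aligned["new_duration"].to_numpy()
    out.loc[pos, "speed_m_min"] = (
        out.loc[pos, "straight_line_distance_m"].to_numpy()
        / aligned["new_duration"].to_numpy())
    out.loc[pos, "tmvpa_min"] = aligned["new_tmvpa"].to_numpy()
    return out


def _person_decomp(trips: pd.DataFrame, person_ids=None) -> pd.DataFrame:
    d = daily_tmvpa(trips, person_ids=person_ids)
    return d.groupby(level="person_id").sum()


def run_scenario(survey: pd.DataFrame, likelihoods: pd.DataFrame,
                 duration_model: DurationModel, tmvpa_model: TmvpaModel,
                 scenario: Scenario,
                 person_ids=None) -> SimulationRun:
    """Run all repetitions of a mode-shift scenario on the survey.

    ``survey`` must carry the integrated ``tmvpa_min`` column.  The
    master seed spawns one independent stream per repetition, so the
    run is reproducible and repetitions are independent; trips never
    selected are untouched in every repetition.
    """
    scenario.validate()
    if "tmvpa_min" not in survey.columns:
        raise SimulationError(
            "survey must carry integrated 'tmvpa_min' predictions")
    counts = survey["mode"].value_counts().to_dict()
    plan = build_shift_plan(counts, scenario)
    baseline = _person_decomp(survey, person_ids)

    if scenario.origin_policy == "private_motorized_only":
        candidates = survey.loc[survey["mode"] == "private_motorized"]
    else:
        dests = [m for m, c in plan.conversions.items() if c > 0]
        if len(dests) > 1:
            raise ScenarioError(
                "any_origin scenarios support a single destination mode "
                "(candidate sets differ per destination)")
        candidates = survey.loc[survey["mode"] != dests[0]] if dests \
            else survey.iloc[:0]

    run = SimulationRun(scenario, plan, baseline)
    dests = [m for m in MODES if plan.conversions.get(m, 0) > 0]
    if not dests or len(candidates) == 0:
        empty = _empty_converted()
        run.repetitions = [RepetitionResult(i, empty.copy())
                           for i in range(scenario.n_repetitions)]
        return run

    lk = likelihoods.set_index("trip_id").reindex(
        candidates["trip_id"].to_numpy())
    if lk[SHARE_COLS].isna().any().any():
        raise SimulationError("some candidate trips have no likelihoods")
    P, dests = rescaled_probability_matrix(lk.reset_index(), plan)

    # deterministic re-predictions per destination, computed once
    conv_tables = {d: convert_trips(candidates, d, duration_model,
                                    tmvpa_model) for d in dests}

    streams = np.random.SeedSequence(scenario.seed).spawn(
        scenario.n_repetitions)
    for i, ss in enumerate(streams):
        rng = np.random.default_rng(ss)
        assigned = _categorical_draw(P, rng)
        run.repetitions.append(RepetitionResult(
            i, _build_converted(candidates, conv_tables, dests, assigned)))
    return run


def _empty_converted() -> pd.DataFrame:
    return pd.DataFrame({c: pd.Series(dtype=t) for c, t in [
        ("trip_id", "int64"), ("person_id", "int64"),
        ("old_mode", "object"), ("new_mode", "object"),
        ("old_duration", "float64"), ("new_duration", "float64"),
        ("old_tmvpa", "float64"), ("new_tmvpa", "float64")]})


def _build_converted(candidates: pd.DataFrame, conv_tables: dict,
                     dests: list[str], assigned: np.ndarray) -> pd.DataFrame:
    rows = []
    for j, mode in enumerate(dests):
        sel = assigned == j
        if not sel.any():
            continue
        base = candidates.loc[sel]
        conv = conv_tables[mode].loc[sel]
        rows.append(pd.DataFrame({
            "trip_id": base["trip_id"].to_numpy(),
            "person_id": base["person_id"].to_numpy(),
            "old_mode": base["mode"].to_numpy(),
            "new_mode": mode,
            "old_duration": base["duration_min"].to_numpy(dtype=float),
            "new_duration": conv["duration_min"].to_numpy(dtype=float),
            "old_tmvpa": base["tmvpa_min"].to_numpy(dtype=float),
            "new_tmvpa": conv["tmvpa_min"].to_numpy(dtype=float),
        }))
    if not rows:
        return _empty_converted()
    return pd.concat(rows, ignore_index=True)


def run_complementary(survey: pd.DataFrame, likelihoods: pd.DataFrame,
                      duration_model: DurationModel,
                      tmvpa_model: TmvpaModel,
                      destination_mode: str, increase: float, *,
                      n_repetitions: int = 100, seed: int = 0,
                      person_ids=None) -> SimulationRun:
    """Promote a single mode with unconstrained origin modes.

    Candidates are all trips not already of ``destination_mode``; the
    expected number of conversions is ``round(increase × current count
    of the destination mode)``.  Reverse effects (active trips
    cannibalized by the promoted mode) show up as negative per-mode
    components in the reported gains.
    """
    if destination_mode not in MODES:
        raise ScenarioError(f"unknown destination mode {destination_mode!r}")
    if increase < 0:
        raise ScenarioError("increase must be >= 0")
    sc = Scenario(name=f"complementary_{destination_mode}",
                  destination_increases={destination_mode: increase},
                  multiplier=1, origin_policy="any_origin",
                  n_repetitions=n_repetitions, seed=seed)
    return run_scenario(survey, likelihoods, duration_model, tmvpa_model,
                        sc, person_ids=person_ids)
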