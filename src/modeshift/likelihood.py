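"""Mode-choice forest and out-of-bag likelihood extraction.

A classification forest is fitted on the survey with the transportation
mode as the outcome (duration, speed and T-MVPA excluded from the
predictors).  For each trip, the fraction of its out-of-bag trees
voting for each mode is read off as the likelihood that the trip could
be performed by that mode — e.g. a trip observed by public transport
might be predicted as public transport by 60% of its OOB trees, private
motorized by 20%, biking by 15% and walking by 5%.  These vote shares
(not calibrated probabilities) feed the mode-shift selection.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier

from ._oob import oob_vote_counts
from .features import MODE_SHORT, MODES, FeatureSchema, mode_schema

#: likelihood-table column per mode, in MODES order
SHARE_COLS = [f"p_{MODE_SHORT[m]}" for m in MODES]


class LikelihoodError(ValueError):
    pass


@dataclass
class ModeModel:
    forest: RandomForestClassifier
    schema: FeatureSchema
    n_fit: int
    trip_ids: np.ndarray
    oob_accuracy: float


def fit_mode_model(trips: pd.DataFrame, *,
                   n_estimators: int = 500,
                   max_features: str | float = "sqrt",
                   min_samples_leaf: int = 1,
                   max_depth: int | None = None,
                   random_state: int = 0) -> ModeModel:
    """Fit the transportation-mode forest with per-tree in-bag records.

    The fitted forest retains, for every training trip, which trees it
    was out-of-bag for (via the per-tree bootstrap indices), which is
    what `extract_oob_likelihoods` consumes.
    """
    modes_present = trips["mode"].nunique()
    if modes_present < 2:
        raise LikelihoodError(
            f"need at least 2 transportation modes, found {modes_present}")
    schema = mode_schema()
    X = schema.encode(trips)
    y = trips["mode"].to_numpy()
    forest = RandomForestClassifier(
        n_estimators=n_estimators, max_features=max_features,
        min_samples_leaf=min_samples_leaf, max_depth=max_depth,
        bootstrap=True, random_state=random_state, n_jobs=1)
    forest.fit(X, y)
    votes, counts = oob_vote_counts(forest, X)
    has = counts > 0
    oob_pred = np.asarray(forest.classes_)[votes[has].argmax(axis=1)]
    acc = float(np.mean(oob_pred == y[has]))
    return ModeModel(forest, schema, len(trips),
                     trips["trip_id"].to_numpy(), acc)


def shares_from_votes(votes: dict[str, float]) -> dict[str, float]:
    """Normalize a per-mode vote tally into likelihood-table columns.

    ``{'public_transport': 60, 'private_motorized': 20, 'bicycle': 15,
    'walking': 5}`` becomes ``p_walk=0.05, p_bike=0.15, p_pt=0.60,
    p_pm=0.20`` (column order: walking, bicycle, public transport,
    private motorized).
    """
    total = float(sum(votes.values()))
    if total <= 0:
        raise LikelihoodError("vote tally is empty")
    return {f"p_{MODE_SHORT[m]}": votes.get(m, 0.0) / total for m in MODES}


def extract_oob_likelihoods(model: ModeModel, trips: pd.DataFrame, *,
                            min_oob_trees: int = 30) -> pd.DataFrame:
    """Per-trip OOB vote shares for every mode.

    Only defined for the trips the model was fitted on (out-of-bag
    status is a property of the training bootstrap).  Raises if any
    trip was out-of-bag for fewer than ``min_oob_trees`` trees — such a
    share would be too noisy to use as a probability.
    """
    if len(trips) != model.n_fit or not np.array_equal(
            trips["trip_id"].to_numpy(), model.trip_ids):
        raise LikelihoodError(
            "likelihoods are only defined for the trips the mode model "
            "was fitted on (trip ids or order differ)")
    X = model.schema.encode(trips)
    votes, counts = oob_vote_counts(model.forest, X)
    low = counts < min_oob_trees
    if low.any():
        ids = trips["trip_id"].to_numpy()[low][:10]
        raise LikelihoodError(
            f"{int(low.sum())} trip(s) have fewer than {min_oob_trees} "
            f"out-of-bag trees (e.g. trip_id {ids.tolist()}); "
            f"increase n_estimators")
    shares = votes / counts[:, None]
    classes = list(model.forest.classes_)
    out = pd.DataFrame({
        "trip_id": trips["trip_id"].to_numpy(),
        "observed_mode": trips["mode"].to_numpy(),
    })
    for m, col in zip(MODES, SHARE_COLS):
        out[col] = shares[:, classes.index(m)] if m in classes else 0.0
    out["n_oob_trees"] = counts
    return out
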