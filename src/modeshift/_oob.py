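"""Out-of-bag bookkeeping for bagged forests.

scikit-learn's bootstrap draws n samples with replacement per tree, so
each observation is out-of-bag for about 36.8% of the trees.  These
helpers recover, per observation, the aggregate of predictions from
exactly those trees — hard class votes for classifiers, mean
predictions for regressors — which is what both the built-in validation
(OOB accuracy / R²) and the mode-shift likelihoods are based on.
"""

from __future__ import annotations

import numpy as np


def oob_masks(forest, n_samples: int):
    """Yield (estimator, boolean OOB mask) per tree of a fitted forest."""
    for est, samples in zip(forest.estimators_, forest.estimators_samples_):
        mask = np.ones(n_samples, dtype=bool)
        mask[samples] = False
        yield est, mask


def oob_vote_counts(forest, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Hard per-tree class votes over each observation's OOB trees.

    Returns ``(votes, n_oob_trees)`` with ``votes`` of shape
    (n_samples, n_classes) in ``forest.classes_`` order.
    """
    n = X.shape[0]
    votes = np.zeros((n, len(forest.classes_)), dtype=np.int64)
    counts = np.zeros(n, dtype=np.int64)
    for est, mask in oob_masks(forest, n):
        idx = np.flatnonzero(mask)
        if idx.size == 0:
            continue
        # trees inside a fitted forest predict class indices into
        # forest.classes_ (sklearn encodes y before dispatching to trees)
        cols = est.predict(X[idx]).astype(np.int64)
        np.add.at(votes, (idx, cols), 1)
        counts[idx] += 1
    return votes, counts


def oob_regression_predictions(forest, X: np.ndarray
                               ) -> tuple[np.ndarray, np.ndarray]:
    """Mean per-tree prediction over each observation's OOB trees.

    Returns ``(oob_pred, n_oob_trees)``; observations that were in-bag
    for every tree get NaN.
    """
    n = X.shape[0]
    sums = np.zeros(n)
    counts = np.zeros(n, dtype=np.int64)
    for est, mask in oob_masks(forest, n):
        idx = np.flatnonzero(mask)
        if idx.size == 0:
            continue
        sums[idx] += est.predict(X[idx])
        counts[idx] += 1
    pred = np.full(n, np.nan)
    has = counts > 0
    pred[has] = sums[has] / counts[has]
    return pred, counts
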