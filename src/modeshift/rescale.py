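"""Logit-shift rescaling of a probability vector to a target mean.

Selection likelihoods extracted from the mode forest have an arbitrary
mean (e.g. 0.11 for private-motorized trips predicted as walking), while
the policy scenario prescribes a much smaller selection fraction (e.g.
0.033).  Rescaling is done by mapping the probabilities to the logit
scale, adding a constant, and mapping back — which keeps every value
inside (0, 1) and preserves the rank order exactly.  The shift constant
is found by bisection: the mean of the back-transformed vector is
strictly increasing in the shift, so the root is unique and bisection is
globally convergent.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import expit, logit

#: probabilities are clipped to [EPS, 1-EPS] before the logit transform;
#: tree-vote shares can be exactly 0 or 1.
EPS = 1e-6


class RescaleError(ValueError):
    pass


@dataclass(frozen=True)
class RescaleResult:
    shifted: np.ndarray
    shift_constant: float
    achieved_mean: float
    iterations: int
    target_mean: float


def rescale_to_mean(
    p,
    target_mean: float,
    tolerance: float = 1e-8,
    max_iter: int = 200,
) -> RescaleResult:
    """Shift ``p`` on the logit scale until its mean equals ``target_mean``.

    Parameters
    ----------
    p:
        Probability vector; values are clipped to ``[EPS, 1-EPS]``.
    target_mean:
        Required mean of the output, strictly inside (0, 1).
    tolerance:
        Convergence tolerance on ``|mean(output) - target_mean|``.
    max_iter:
        Bisection iteration cap; exceeding it raises ``RescaleError``
        reporting the final bracket.

    Returns
    -------
    RescaleResult
        With the shifted vector, the logit-scale shift constant, the
        achieved mean and the iteration count.  The output is an
        elementwise strictly monotone transform of the input, so ranks
        (and strict inequalities between clipped values) are preserved.
    """
    p = np.asarray(p, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise RescaleError("probability vector must be non-empty and 1-D")
    if not np.isfinite(p).all() or p.min() < 0 or p.max() > 1:
        raise RescaleError("probabilities must be finite and within [0, 1]")
    if not (0.0 < target_mean < 1.0):
        raise RescaleError(f"target_mean must be in (0, 1), got {target_mean}")

    lo_p = np.clip(p, EPS, 1.0 - EPS)
    lgt = logit(lo_p)

    def mean_at(c: float) -> float:
        return float(np.mean(expit(lgt + c)))

    # Shift 0 first: the identity case (target == mean after clipping)
    # must return an exact zero shift.
    if abs(mean_at(0.0) - target_mean) <= tolerance:
        return RescaleResult(expit(lgt), 0.0, mean_at(0.0), 0, target_mean)

    # Auto-expanding bracket around 0.
    lo, hi = -1.0, 1.0
    for _ in range(80):
        if mean_at(lo) <= target_mean:
            break
        lo *= 2.0
    for _ in range(80):
        if mean_at(hi) >= target_mean:
            break
        hi *= 2.0
    if mean_at(lo) > target_mean or mean_at(hi) < target_mean:
        raise RescaleError(
            f"could not bracket the shift constant in [{lo}, {hi}]")

    iterations = 0
    mid = 0.0
    for iterations in range(1, max_iter + 1):
        mid = 0.5 * (lo + hi)
        m = mean_at(mid)
        if abs(m - target_mean) <= tolerance:
            return RescaleResult(expit(lgt + mid), mid, m, iterations,
                                 target_mean)
        if m < target_mean:
            lo = mid
        else:
            hi = mid
    raise RescaleError(
        f"bisection did not converge within {max_iter} iterations; "
        f"bracket [{lo}, {hi}], last mean {mean_at(mid)}")
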