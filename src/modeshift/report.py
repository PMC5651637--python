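"""Summary tables: daily T-MVPA by education and mode, gains, inequality.

Aggregates the per-person daily decompositions into the analysis's
output tables: the baseline table (mean daily T-MVPA per stratum and
mode, with 95% CIs across persons), the gains table per scenario (mean
gain per stratum and mode with percentile intervals across
repetitions), and an inequality summary comparing the highest and
lowest education strata before and after the shift.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .features import EDUCATION_LEVELS, MODES
from .simulate import SimulationRun

STRATA = ["total"] + EDUCATION_LEVELS
SEGMENTS = ["all_modes"] + MODES


class ReportError(ValueError):
    pass


@dataclass
class SummaryTable:
    """Strata x segments table of means with interval bounds.

    Rows: total population and the three education strata; columns:
    all modes plus each mode.  The all-modes column always equals the
    sum of the mode columns (additivity of the decomposition).
    """

    mean: pd.DataFrame
    lo: pd.DataFrame
    hi: pd.DataFrame

    def rounded(self, decimals: int = 1) -> pd.DataFrame:
        return self.mean.round(decimals)

    def to_csv(self, path) -> None:
        out = self.mean.copy()
        for seg in SEGMENTS:
            out[f"{seg}_lo"] = self.lo[seg]
            out[f"{seg}_hi"] = self.hi[seg]
        out.to_csv(path)


def _education_map(persons: pd.DataFrame) -> pd.Series:
    edu = persons.set_index("person_id")["education"]
    if edu.isna().any() or not set(edu.dropna()).issubset(EDUCATION_LEVELS):
        bad = persons.loc[~persons["education"].isin(EDUCATION_LEVELS),
                          "person_id"].tolist()[:5]
        raise ReportError(f"persons with missing/unknown education: {bad}")
    return edu


def _strata_masks(edu: pd.Series, index: pd.Index) -> dict[str, np.ndarray]:
    aligned = edu.reindex(index)
    if aligned.isna().any():
        raise ReportError("decomposition contains persons without "
                          "education information")
    masks = {"total": np.ones(len(index), dtype=bool)}
    for e in EDUCATION_LEVELS:
        masks[e] = (aligned == e).to_numpy()
    return masks


def summarize_baseline(decomp: pd.DataFrame,
                       persons: pd.DataFrame) -> SummaryTable:
    """Mean daily T-MVPA per stratum and mode for observed behavior.

    ``decomp`` is the per-person decomposition (index person_id, one
    column per mode plus total).  Intervals are normal-approximation
    95% CIs across persons.
    """
    edu = _education_map(persons)
    masks = _strata_masks(edu, decomp.index)
    cols = {"all_modes": "total", **{m: m for m in MODES}}
    mean = pd.DataFrame(index=STRATA, columns=list(cols), dtype=float)
    lo = mean.copy()
    hi = mean.copy()
    for stratum, mask in masks.items():
        sub = decomp.loc[mask]
        n = len(sub)
        if n == 0:
            raise ReportError(f"stratum {stratum} has no persons")
        for seg, col in cols.items():
            v = sub[col].to_numpy(dtype=float)
            m = v.mean()
            se = v.std(ddof=1) / np.sqrt(n) if n > 1 else 0.0
            mean.loc[stratum, seg] = m
            lo.loc[stratum, seg] = m - 1.96 * se
            hi.loc[stratum, seg] = m + 1.96 * se
    return SummaryTable(mean, lo, hi)


def _stratum_means_of_run(run: SimulationRun,
                          masks: dict[str, np.ndarray]) -> np.ndarray:
    """(n_reps, n_strata, n_segments) stratum means per repetition.

    Computed incrementally: each repetition only shifts the converted
    trips, so stratum sums are the baseline sums plus the converted
    trips' deltas grouped by stratum.
    """
    base = run.baseline_decomp
    seg_cols = ["total"] + MODES
    base_sums = np.stack([
        base.loc[mask, seg_cols].sum(axis=0).to_numpy(dtype=float)
        for mask in masks.values()])                      # strata x segs
    counts = np.array([int(m.sum()) for m in masks.values()])

    person_stratum = np.zeros(len(base), dtype=int)       # 0 = E1 ...
    for k, e in enumerate(EDUCATION_LEVELS):
        person_stratum[masks[e]] = k
    stratum_of = pd.Series(person_stratum, index=base.index)

    mode_codes = {m: j for j, m in enumerate(MODES, start=1)}
    out = np.empty((len(run.repetitions), len(masks), len(seg_cols)))
    for i, rep in enumerate(run.repetitions):
        sums = base_sums.copy()
        conv = rep.converted
        if len(conv):
            strat = stratum_of.reindex(conv["person_id"]).to_numpy() + 1
            row0 = np.zeros(len(conv), dtype=int)
            for which, tm, sign in (("old_mode", "old_tmvpa", -1.0),
                                    ("new_mode", "new_tmvpa", +1.0)):
                col = conv[which].map(mode_codes).to_numpy(dtype=int)
                vals = sign * conv[tm].to_numpy(dtype=float)
                np.add.at(sums, (strat, col), vals)   # stratum rows
                np.add.at(sums, (row0, col), vals)    # total row
                np.add.at(sums, (strat, row0), vals)  # total column
                np.add.at(sums, (row0, row0), vals)
        out[i] = sums / counts[:, None]
    return out


def summarize_gains(run: SimulationRun, persons: pd.DataFrame) -> SummaryTable:
    """Mean gain in daily T-MVPA per stratum and mode across repetitions.

    Gain = (scenario stratum mean − baseline stratum mean), averaged
    over repetitions; intervals are the 2.5/97.5 percentiles of the
    per-repetition gains.
    """
    edu = _education_map(persons)
    base = run.baseline_decomp
    if not base.index.isin(edu.index).all():
        raise ReportError("scenario and persons cover different person sets")
    masks = _strata_masks(edu, base.index)
    per_rep = _stratum_means_of_run(run, masks)           # reps x strata x segs
    seg_cols = ["total"] + MODES
    base_means = np.stack([
        base.loc[mask, seg_cols].mean(axis=0).to_numpy(dtype=float)
        for mask in masks.values()])
    gains = per_rep - base_means[None]
    mean = pd.DataFrame(gains.mean(axis=0), index=list(masks),
                        columns=["all_modes"] + MODES)
    lo = pd.DataFrame(np.percentile(gains, 2.5, axis=0), index=list(masks),
                      columns=["all_modes"] + MODES)
    hi = pd.DataFrame(np.percentile(gains, 97.5, axis=0), index=list(masks),
                      columns=["all_modes"] + MODES)
    return SummaryTable(mean, lo, hi)


@dataclass
class InequalityDelta:
    baseline_gap: float      #: E3 − E1 mean daily T-MVPA before the shift
    gain_gap: float          #: E3 − E1 mean gain under the scenario
    amplified: bool          #: True when the shift widens the gap

    def as_dict(self) -> dict:
        return {"baseline_gap_E3_minus_E1": self.baseline_gap,
                "gain_gap_E3_minus_E1": self.gain_gap,
                "amplified": self.amplified}


def inequality_delta(baseline: SummaryTable,
                     gains: SummaryTable) -> InequalityDelta:
    """Education inequality before the shift and its change under it."""
    b = float(baseline.mean.loc["E3", "all_modes"]
              - baseline.mean.loc["E1", "all_modes"])
    g = float(gains.mean.loc["E3", "all_modes"]
              - gains.mean.loc["E1", "all_modes"])
    return InequalityDelta(b, g, g > 0)
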