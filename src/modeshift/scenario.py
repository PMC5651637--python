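"""Policy scenarios: translate mode-shift goals into selection fractions.

The main scenario mirrors a regional urban mobility plan: +11.8% public
transport trips and +2.5% walking and biking trips, all drawn from the
private motorized trips; more ambitious variants double or triple the
shifts.  Complementary scenarios promote a single mode and allow any
origin mode.  `build_shift_plan` turns the relative increases into
expected conversion counts and per-destination selection fractions
among the candidate trips.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import yaml

from .features import MODES

#: default relative increases from the mobility-plan goals
DEFAULT_INCREASES = {
    "public_transport": 0.118,
    "walking": 0.025,
    "bicycle": 0.025,
}

ORIGIN_POLICIES = ("private_motorized_only", "any_origin")


class ScenarioError(ValueError):
    pass


class InfeasibleScenarioError(ScenarioError):
    pass


@dataclass(frozen=True)
class Scenario:
    name: str = "mobility_plan"
    destination_increases: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_INCREASES))
    multiplier: int = 1
    origin_policy: str = "private_motorized_only"
    n_repetitions: int = 100
    seed: int = 0

    def validate(self) -> None:
        for mode, inc in self.destination_increases.items():
            if mode not in MODES:
                raise ScenarioError(f"unknown destination mode {mode!r}")
            if inc < 0:
                raise ScenarioError(
                    f"increase for {mode} must be >= 0, got {inc}")
        if self.multiplier < 1:
            raise ScenarioError("multiplier must be a positive integer")
        if self.origin_policy not in ORIGIN_POLICIES:
            raise ScenarioError(
                f"origin_policy must be one of {ORIGIN_POLICIES}")
        if self.n_repetitions < 1:
            raise ScenarioError("n_repetitions must be >= 1")

    @classmethod
    def from_yaml(cls, path) -> "Scenario":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        sc = cls(**data)
        sc.validate()
        return sc


@dataclass(frozen=True)
class ShiftPlan:
    """Expected conversions and selection fractions per destination mode."""

    conversions: dict[str, int]
    selection_fraction: dict[str, float]
    candidate_count: dict[str, int]
    total: int

    def as_dict(self) -> dict:
        return {
            "conversions": dict(self.conversions),
            "selection_fraction": dict(self.selection_fraction),
            "candidate_count": dict(self.candidate_count),
            "total": self.total,
        }


def _round_half_away(x: float) -> int:
    """Round half away from zero (keeps small counts like 30 stable)."""
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def build_shift_plan(mode_counts: dict[str, int],
                     scenario: Scenario) -> ShiftPlan:
    """Expected trip conversions for ``scenario`` given observed counts.

    Per destination mode d: ``conversions_d = round(increase_d *
    multiplier * count_d)``.  Candidates are the private motorized trips
    (``private_motorized_only``) or all trips not already of mode d
    (``any_origin``); the selection fraction is conversions over
    candidates.  Raises `InfeasibleScenarioError` when a fraction would
    exceed 1 or the candidates cannot absorb the total.
    """
    scenario.validate()
    total_trips = int(sum(mode_counts.get(m, 0) for m in MODES))
    conversions: dict[str, int] = {}
    fractions: dict[str, float] = {}
    candidates: dict[str, int] = {}
    for mode, inc in scenario.destination_increases.items():
        if inc == 0:
            continue
        count = int(mode_counts.get(mode, 0))
        if count <= 0:
            raise ScenarioError(
                f"no observed {mode} trips to scale the +{inc:.1%} goal from")
        conv = _round_half_away(inc * scenario.multiplier * count)
        if scenario.origin_policy == "private_motorized_only":
            cand = int(mode_counts.get("private_motorized", 0))
        else:
            cand = total_trips - count
        if cand <= 0 or conv > cand:
            raise InfeasibleScenarioError(
                f"{conv} conversions to {mode} exceed the {cand} "
                f"candidate trips")
        conversions[mode] = conv
        fractions[mode] = conv / cand
        candidates[mode] = cand
    total = sum(conversions.values())
    if (scenario.origin_policy == "private_motorized_only"
            and total > mode_counts.get("private_motorized", 0)):
        raise InfeasibleScenarioError(
            f"total conversions {total} exceed the "
            f"{mode_counts.get('private_motorized', 0)} private motorized "
            f"trips")
    return ShiftPlan(conversions, fractions, candidates, total)
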