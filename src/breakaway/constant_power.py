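"""Closed-form analysis of a constant-power breakaway on a flat stage.

The special rider lurks at position ``i`` spending the lurking power
``Pl = Cd,i`` (the cost of unit speed there), attacks at ``xa`` with constant
power ``Pa``, and rides solo against drag ``Cd,1`` to the line. Everything —
earliest feasible attack, budget-exhausting power, winning margin — is
closed-form in the dimensionless variables.
"""

from __future__ import annotations

from dataclasses import dataclass

from .crash import breakaway_crash_measure, lurking_crash_measure
from .scenario import RaceScenario

#: Attack positions this close to the line are rejected: the energy constraint
#: forces unbounded power as xa -> 1.
XA_SINGULARITY_GUARD = 1e-6


class InfeasibleEscapeError(ValueError):
    """The requested attack cannot outpace the peloton (Pa <= Cd,1)."""


class InfeasibleBudgetError(ValueError):
    """The energy budget cannot fund the requested plan."""


@dataclass(frozen=True)
class ConstantPlan:
    """A breakaway strategy: attack at ``xa`` with constant power ``pa``."""

    xa: float
    pa: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.xa <= 1.0:
            raise ValueError(f"attack position must lie in [0, 1], got {self.xa}")
        if not self.pa > 0:
            raise ValueError(f"attack power must be positive, got {self.pa}")


@dataclass(frozen=True)
class Outcome:
    """Race result of one strategy under one scenario."""

    finish_time: float     # tf, dimensionless (peloton finishes at 1)
    margin: float          # dt = 1 - tf; 0 when the escape fails
    crash_measure: float   # expected crash involvements P
    objective: float       # M = -beta*dt + (1-beta)*P
    energy_spent: float
    escaped: bool
    feasible: bool         # energy_spent within budget


def earliest_attack_position(pa: float, energy_budget: float, scenario: RaceScenario) -> float:
    """Earliest ``xa`` from which attacking at power ``pa`` exhausts the budget at the line.

    ``xa = max{(Cd1^(1/3) Pa^(2/3) - E*) / (Cd1^(1/3) Pa^(2/3) - Cdi), 0}``.
    """
    if pa <= scenario.cd1:
        raise InfeasibleEscapeError(
            f"attack power {pa} does not exceed the solo drag {scenario.cd1}; "
            "the rider cannot pull clear of the peloton"
        )
    attack_cost = scenario.cd1 ** (1.0 / 3.0) * pa ** (2.0 / 3.0)  # Pa / va
    return max((attack_cost - energy_budget) / (attack_cost - scenario.cd_lurk), 0.0)


def min_attack_envelope(energy_budget: float, scenario: RaceScenario) -> tuple[float, float, bool]:
    """Minimum escape power ``Cd,1``, its earliest attack position, and winnability.

    Returns ``(pa_min, xa_min, can_win)``; ``can_win`` is False when the
    budget is at or below the lurking cost ``Cd,i`` (xa_min >= 1).
    """
    if energy_budget <= 0:
        raise ValueError(f"energy budget must be positive, got {energy_budget}")
    pa_min = scenario.cd1
    xa_min = max((scenario.cd1 - energy_budget) / (scenario.cd1 - scenario.cd_lurk), 0.0)
    return pa_min, xa_min, xa_min < 1.0


def required_attack_power(xa: float, energy_budget: float, scenario: RaceScenario) -> float:
    """Constant power spending exactly ``E*`` by the line when attacking at ``xa``.

    ``Pa = ((E* - Cdi*xa) / (Cd1^(1/3) (1-xa)))^(3/2)``; singular as xa -> 1.
    """
    if xa > 1.0 - XA_SINGULARITY_GUARD:
        raise ValueError(
            f"attack position {xa} too close to the finish line; the energy "
            "constraint forces unbounded power there"
        )
    surplus = energy_budget - scenario.cd_lurk * xa
    if surplus <= 0:
        raise InfeasibleBudgetError(
            f"budget {energy_budget} is exhausted by lurking up to xa = {xa}"
        )
    return (surplus / (scenario.cd1 ** (1.0 / 3.0) * (1.0 - xa))) ** 1.5


def time_gap(xa: float, energy_budget: float, scenario: RaceScenario) -> float:
    """Winning margin ``dt = 1 - tf`` for a budget-exhausting attack at ``xa``.

    ``dt = 1 - xa - (1-xa)^(3/2) Cd1^(1/2) / (E* - Cdi*xa)^(1/2)``.
    Returns 0 for failed escapes (attacks before the minimum attack position
    lack the power to pull clear) and at ``xa = 1``.
    """
    if not 0.0 <= xa <= 1.0:
        raise ValueError(f"attack position must lie in [0, 1], got {xa}")
    if xa == 1.0:
        return 0.0
    _, xa_min, can_win = min_attack_envelope(energy_budget, scenario)
    if not can_win or xa < xa_min:
        return 0.0
    surplus = energy_budget - scenario.cd_lurk * xa
    return 1.0 - xa - (1.0 - xa) ** 1.5 * scenario.cd1**0.5 / surplus**0.5


def time_gap_from_power(pa: float, energy_budget: float, scenario: RaceScenario) -> float:
    """Margin in terms of attack power: ``dt = (Cdi - E*)/(Cd1^(1/3)Pa^(2/3) - Cdi) * ((Cd1/Pa)^(1/3) - 1)``."""
    if pa <= scenario.cd1:
        return 0.0
    attack_cost = scenario.cd1 ** (1.0 / 3.0) * pa ** (2.0 / 3.0)
    return (
        (scenario.cd_lurk - energy_budget)
        / (attack_cost - scenario.cd_lurk)
        * ((scenario.cd1 / pa) ** (1.0 / 3.0) - 1.0)
    )


def evaluate_constant_plan(plan: ConstantPlan, scenario: RaceScenario) -> Outcome:
    """Full outcome (finish time, margin, crash measure, objective, energy) of a plan.

    A failed escape (``pa <= Cd,1``) means the rider drifts back and finishes
    with the peloton: zero margin and full-race lurking exposure. Plans that
    overdraw the budget are evaluated but flagged infeasible, never clipped.
    """
    beta = scenario.beta
    if plan.pa <= scenario.cd1:
        crash = lurking_crash_measure(scenario)
        energy = scenario.cd_lurk  # lurks the entire unit race
        objective = beta * 0.0 + (1.0 - beta) * crash
        return Outcome(
            finish_time=1.0, margin=0.0, crash_measure=crash, objective=objective,
            energy_spent=energy, escaped=False,
            feasible=energy <= scenario.energy_budget + 1e-9,
        )
    va = (plan.pa / scenario.cd1) ** (1.0 / 3.0)
    tf = plan.xa + (1.0 - plan.xa) / va
    margin = 1.0 - tf
    energy = scenario.cd_lurk * plan.xa + plan.pa * (tf - plan.xa)
    crash = breakaway_crash_measure(plan.xa, scenario)
    objective = -beta * margin + (1.0 - beta) * crash
    return Outcome(
        finish_time=tf, margin=margin, crash_measure=crash, objective=objective,
        energy_spent=energy, escaped=True,
        feasible=energy <= scenario.energy_budget + 1e-9,
    )
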