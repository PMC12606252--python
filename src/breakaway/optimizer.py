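"""Risk-penalized strategy optimization for the constant-power breakaway.

The rider minimizes ``M = -beta*dt + (1-beta)*P`` over the attack position,
where ``dt`` is the winning margin and ``P`` the crash measure. Interior
stationary points come from a depressed cubic in the auxiliary variable
``eta = sqrt((1-xa)/(E* - Cdi*xa))``; the global optimum compares the interior
candidate against the discontinuity at the minimum attack position (and the
start line when the budget allows attacking from the gun).
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass

import numpy as np

from .constant_power import (
    XA_SINGULARITY_GUARD,
    min_attack_envelope,
    required_attack_power,
    time_gap,
)
from .crash import breakaway_crash_measure, lurking_crash_measure
from .scenario import RaceScenario


class NoWinningStrategyError(ValueError):
    """The budget is below the lurking cost: no attack position can win."""


class Branch(enum.Enum):
    INTERIOR = "interior"
    BOUNDARY_MIN_ATTACK = "boundary_min_attack"
    START_LINE = "start_line"
    NO_ESCAPE = "no_escape"


@dataclass(frozen=True)
class InteriorSolution:
    """Interior stationary point of the objective, in auxiliary coordinates."""

    eta: float
    xa_dagger: float
    pa_dagger: float


@dataclass(frozen=True)
class Optimum:
    """Argmin of the objective with its branch label."""

    xa_star: float | None
    power_star: float | None
    margin: float
    objective: float
    branch: Branch
    interior: InteriorSolution | None = None


def _geom_factor(scenario: RaceScenario) -> float:
    """``(1 - e^{-omega*i}) / (1 - e^{-omega})`` = N * H(i; omega)."""
    w = scenario.omega
    return -math.expm1(-w * scenario.lurk_position) / (-math.expm1(-w))


def objective(xa: float, scenario: RaceScenario) -> float:
    """``M(xa)`` for a budget-exhausting attack at ``xa``.

    Attacks before the minimum attack position fail: the rider finishes with
    the peloton (zero margin) and carries full-race lurking exposure.
    """
    if not 0.0 <= xa <= 1.0:
        raise ValueError(f"attack position must lie in [0, 1], got {xa}")
    beta = scenario.beta
    _, xa_min, can_win = min_attack_envelope(scenario.energy_budget, scenario)
    if not can_win or xa < xa_min:
        return (1.0 - beta) * lurking_crash_measure(scenario)
    dt = time_gap(xa, scenario.energy_budget, scenario)
    return -beta * dt + (1.0 - beta) * breakaway_crash_measure(xa, scenario)


def objective_grid(xs: np.ndarray, scenario: RaceScenario) -> np.ndarray:
    """Vectorized ``M`` over an array of attack positions (grid-oracle workhorse)."""
    xs = np.asarray(xs, dtype=float)
    beta = scenario.beta
    e_star, cdi, cd1 = scenario.energy_budget, scenario.cd_lurk, scenario.cd1
    _, xa_min, can_win = min_attack_envelope(e_star, scenario)
    out = np.full(xs.shape, (1.0 - beta) * lurking_crash_measure(scenario))
    if not can_win:
        return out
    ok = xs >= xa_min
    x = xs[ok]
    surplus = e_star - cdi * x
    with np.errstate(divide="ignore", invalid="ignore"):
        dt = np.where(
            x >= 1.0, 0.0, 1.0 - x - (1.0 - x) ** 1.5 * cd1**0.5 / np.sqrt(surplus)
        )
    geom = _geom_factor(scenario)
    crash = scenario.crash_rate / scenario.n_riders * (x * geom + 1.0 - x)
    out[ok] = -beta * dt + (1.0 - beta) * crash
    return out


def _depressed_cubic_real_roots(p: float, q: float) -> list[float]:
    """All real roots of ``t^3 + p*t + q = 0`` (trigonometric/Cardano closed form)."""
    if p == 0.0:
        return [float(np.cbrt(-q))]
    if q == 0.0:
        roots = [0.0]
        if p < 0:
            roots += [math.sqrt(-p), -math.sqrt(-p)]
        return roots
    if p < 0:
        m = 2.0 * math.sqrt(-p / 3.0)
        arg = 3.0 * q / (p * m)
        if abs(arg) <= 1.0:
            theta = math.acos(arg) / 3.0
            return [m * math.cos(theta - 2.0 * math.pi * k / 3.0) for k in range(3)]
        # One real root: hyperbolic analogue of the trig formula.
        t = -math.copysign(1.0, q) * m * math.cosh(math.acosh(3.0 * abs(q) / (-p * m)) / 3.0)
        return [t]
    m = 2.0 * math.sqrt(p / 3.0)
    t = -m * math.sinh(math.asinh(3.0 * q / (p * m)) / 3.0)
    return [t]


def interior_optimum(scenario: RaceScenario) -> InteriorSolution | None:
    """Interior stationary point of ``M``, if one lies in the admissible range.

    Setting ``dM/dxa = 0`` yields the depressed cubic (in ``eta``)
    ``(1-beta)(N*H - 1)P(C)/N + beta + beta*sqrt(Cd1)*((Cdi/2)*eta^3 - (3/2)*eta) = 0``;
    admissible roots are positive with ``xa in [xa_min, 1)``. A fully
    risk-averse rider (beta = 0) has no interior stationary point. The root
    ``eta`` does not involve the budget, so the optimal attack power is
    budget-independent and the attack position is affine in ``E*``.
    """
    beta = scenario.beta
    if beta == 0.0:
        return None
    cd1, cdi, e_star = scenario.cd1, scenario.cd_lurk, scenario.energy_budget
    const = (
        (1.0 - beta) * (_geom_factor(scenario) - 1.0) * scenario.crash_rate / scenario.n_riders
        + beta
    )
    scale = beta * math.sqrt(cd1)
    # A*eta^3 + B*eta + C = 0 with A = scale*cdi/2, B = -1.5*scale, C = const.
    p = -3.0 / cdi
    q = 2.0 * const / (scale * cdi)
    _, xa_min, can_win = min_attack_envelope(e_star, scenario)
    if not can_win:
        return None

    best: InteriorSolution | None = None
    for eta in _depressed_cubic_real_roots(p, q):
        if eta <= 0:
            continue
        denom = 1.0 - cdi * eta * eta
        if abs(denom) < 1e-14:
            continue
        xa = (1.0 - e_star * eta * eta) / denom
        if not (xa_min <= xa < 1.0 - XA_SINGULARITY_GUARD):
            continue
        # Confirm a local minimum by centered second difference.
        h = 1e-5
        lo = max(xa - h, xa_min)
        hi = min(xa + h, 1.0 - XA_SINGULARITY_GUARD)
        if objective(lo, scenario) + objective(hi, scenario) - 2.0 * objective(xa, scenario) < 0:
            continue
        pa = 1.0 / (math.sqrt(cd1) * eta**3)
        cand = InteriorSolution(eta=eta, xa_dagger=xa, pa_dagger=pa)
        if best is None or objective(xa, scenario) < objective(best.xa_dagger, scenario):
            best = cand
    return best


def _make_optimum(xa: float, scenario: RaceScenario, branch: Branch,
                  interior: InteriorSolution | None = None) -> Optimum:
    margin = time_gap(xa, scenario.energy_budget, scenario)
    try:
        power = required_attack_power(xa, scenario.energy_budget, scenario)
    except ValueError:
        power = None
    return Optimum(
        xa_star=xa, power_star=power, margin=margin,
        objective=objective(xa, scenario), branch=branch, interior=interior,
    )


def global_optimum(scenario: RaceScenario) -> Optimum:
    """Global minimizer of ``M`` over the attack position.

    Compares the interior stationary point (when admissible) with the
    discontinuity at the minimum attack position; when the budget allows
    attacking from the gun the boundary candidate is the start line itself.
    Ties break toward the smaller attack position (earlier escape, lower
    exposure). A budget at or below the lurking cost cannot escape at all.
    """
    _, xa_min, can_win = min_attack_envelope(scenario.energy_budget, scenario)
    beta = scenario.beta
    if not can_win:
        return Optimum(
            xa_star=None, power_star=None, margin=0.0,
            objective=(1.0 - beta) * lurking_crash_measure(scenario),
            branch=Branch.NO_ESCAPE,
        )
    boundary_branch = Branch.START_LINE if xa_min == 0.0 else Branch.BOUNDARY_MIN_ATTACK
    candidates = [_make_optimum(xa_min, scenario, boundary_branch)]
    interior = interior_optimum(scenario)
    if interior is not None:
        candidates.append(
            _make_optimum(interior.xa_dagger, scenario, Branch.INTERIOR, interior)
        )
    # argmin on M; ties toward smaller xa.
    return min(candidates, key=lambda o: (o.objective, o.xa_star))


def grid_oracle(scenario: RaceScenario, resolution: float = 1e-4) -> Optimum:
    """Brute-force argmin of ``M`` on a uniform grid (validation oracle).

    Evaluates the objective on a uniform grid over ``[0, 1)`` plus the exact
    candidate points ``{0, xa_min}`` and returns the grid argmin.
    """
    if not 0.0 < resolution <= 0.1:
        raise ValueError(f"resolution must lie in (0, 0.1], got {resolution}")
    _, xa_min, can_win = min_attack_envelope(scenario.energy_budget, scenario)
    xs = np.arange(0.0, 1.0 - XA_SINGULARITY_GUARD, resolution)
    extras = [0.0, 1.0 - XA_SINGULARITY_GUARD]
    if can_win and xa_min < 1.0:
        extras.append(xa_min)
    xs = np.unique(np.concatenate([xs, np.asarray(extras)]))
    ms = objective_grid(xs, scenario)
    k = int(np.argmin(ms))
    xa = float(xs[k])
    if not can_win:
        return Optimum(xa_star=None, power_star=None, margin=0.0,
                       objective=float(ms[k]), branch=Branch.NO_ESCAPE)
    if xa == xa_min:
        branch = Branch.START_LINE if xa_min == 0.0 else Branch.BOUNDARY_MIN_ATTACK
    else:
        branch = Branch.INTERIOR
    return _make_optimum(xa, scenario, branch)


def critical_risk(scenario: RaceScenario) -> float:
    """Risk index at which the winning strategy switches branch.

    Below it, winning requires attacking from the start line (budget
    ``>= Cd,1``); above it, a mid-race attack wins on a budget as low as the
    lurking cost ``Cd,i``. Closed form ``a/(a+b)`` with
    ``a = (P(C)/N)(N*H(i) - 1)`` and ``b = (1/2)(1 - Cdi/Cd1)``.
    """
    if scenario.cd_lurk >= scenario.cd1:
        raise ValueError("critical risk requires cd_lurk < cd1")
    a = scenario.crash_rate / scenario.n_riders * (_geom_factor(scenario) - 1.0)
    b = 0.5 * (1.0 - scenario.cd_lurk / scenario.cd1)
    return a / (a + b)


def min_energy_to_win(beta: float, scenario: RaceScenario) -> float:
    """Smallest budget that can win at risk index ``beta`` (piecewise constant).

    ``Cd,1`` below the critical risk (start-line escape), ``Cd,i`` above it
    (mid-race attack). At exactly the critical risk the right-continuous value
    ``Cd,i`` is returned.
    """
    if not 0.0 <= beta <= 1.0:
        raise ValueError(f"beta must lie in [0, 1], got {beta}")
    return scenario.cd1 if beta < critical_risk(scenario) else scenario.cd_lurk


def min_risk_to_win(energy_budget: float, scenario: RaceScenario) -> float:
    """Smallest risk index that can win on budget ``E*`` (inverse of the above).

    Zero above the critical energy ``Cd,1`` (very fit riders need no risk);
    the critical risk between the lurking cost and the critical energy;
    undefined at or below the lurking cost, where no strategy wins.
    """
    if energy_budget <= 0:
        raise ValueError(f"energy budget must be positive, got {energy_budget}")
    if energy_budget <= scenario.cd_lurk:
        raise NoWinningStrategyError(
            f"budget {energy_budget} is at or below the lurking cost "
            f"{scenario.cd_lurk}; no attack position wins"
        )
    if energy_budget > scenario.cd1:
        return 0.0
    return critical_risk(scenario)
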