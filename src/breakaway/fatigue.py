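"""Breakaway with fatigue: attack power decaying exponentially toward a sustainable level.

After attacking at ``ta = xa`` the rider's power is
``Pa(t) = (Pmax - Ps) * exp(-mu*(t - ta)) + Ps``: an anaerobic burst ``Pmax``
relaxing at rate ``mu`` toward the sustainable power ``Ps``. Small ``mu``
describes endurance riders (the burst barely decays, recovering the
constant-power model); large ``mu`` describes explosive sprinters. The finish
time is no longer closed-form, so the optimum over (attack position, finish
time, peak power) is found numerically under the energy-budget equality and
the finish-line condition.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from scipy.integrate import quad
from scipy.optimize import brentq, minimize

from .constant_power import InfeasibleBudgetError
from .crash import breakaway_crash_measure, lurking_crash_measure
from .optimizer import Branch, Optimum, global_optimum
from .scenario import RaceScenario

#: Below this decay rate the burst is treated as exactly constant
#: (analytic mu -> 0 limits; no 1/mu is ever evaluated).
_MU_FLOOR = 1e-12


@dataclass(frozen=True)
class FatiguePlan:
    """Attack at ``xa`` with peak power ``pmax`` decaying at rate ``mu`` to ``ps``."""

    xa: float
    pmax: float
    ps: float
    mu: float
    pl: float | None = None  # lurking power; defaults to ps

    def __post_init__(self) -> None:
        if not 0.0 <= self.xa < 1.0:
            raise ValueError(f"attack position must lie in [0, 1), got {self.xa}")
        if not self.ps > 0:
            raise ValueError(f"sustainable power must be positive, got {self.ps}")
        if self.pmax < self.ps:
            raise ValueError(f"peak power {self.pmax} below sustainable power {self.ps}")
        if self.mu < 0:
            raise ValueError(f"fatigue rate must be >= 0, got {self.mu}")
        if self.pl is None:
            object.__setattr__(self, "pl", self.ps)


def attack_power_profile(t: float, plan: FatiguePlan) -> float:
    """Rider power at time ``t``: lurking before the attack, decaying burst after."""
    if t < 0:
        raise ValueError(f"time must be >= 0, got {t}")
    if t < plan.xa:
        return plan.pl
    return (plan.pmax - plan.ps) * math.exp(-plan.mu * (t - plan.xa)) + plan.ps


def total_energy_fatigue(plan: FatiguePlan, tf: float) -> float:
    """Closed-form energy spent by the fatigue profile up to the finish time ``tf``.

    ``Pl*ta + Ps*(tf-ta) + (1/mu)(1 - e^{-mu(tf-ta)})(Pmax - Ps)``, with the
    analytic ``mu -> 0`` limit ``Pl*ta + Pmax*(tf-ta)``.
    """
    if tf < plan.xa:
        raise ValueError(f"finish time {tf} precedes the attack at {plan.xa}")
    dt = tf - plan.xa
    base = plan.pl * plan.xa + plan.ps * dt
    if plan.mu < _MU_FLOOR:
        return base + (plan.pmax - plan.ps) * dt
    return base + (-math.expm1(-plan.mu * dt)) / plan.mu * (plan.pmax - plan.ps)


def pmax_from_budget(
    xa: float, tf: float, mu: float, ps: float, energy_budget: float
) -> float:
    """Peak power that spends exactly the budget by ``tf`` (lurking power = ``Ps``).

    ``Pmax = Ps + mu*e^{mu*tf}(E* - Ps*tf)/(e^{mu*tf} - e^{mu*xa})``; the
    ``mu -> 0`` limit is the constant-power budget split
    ``Ps + (E* - Ps*tf)/(tf - xa)``.
    """
    if tf <= xa:
        raise ValueError(f"finish time {tf} must exceed the attack position {xa}")
    surplus = energy_budget - ps * tf
    if surplus < 0:
        raise InfeasibleBudgetError(
            f"budget {energy_budget} cannot even sustain Ps = {ps} until tf = {tf}"
        )
    if mu < _MU_FLOOR:
        return ps + surplus / (tf - xa)
    # e^{mu tf}/(e^{mu tf} - e^{mu xa}) = 1/(1 - e^{-mu(tf-xa)}), stable for large mu*tf.
    return ps + mu * surplus / (-math.expm1(-mu * (tf - xa)))


def position_after_attack(t: float, plan: FatiguePlan, scenario: RaceScenario) -> float:
    """Rider position at ``t >= ta``: quasi-steady speed integrated over the burst."""
    if t < plan.xa:
        raise ValueError(f"time {t} precedes the attack at {plan.xa}")
    cd1_cbrt = scenario.cd1 ** (1.0 / 3.0)
    if plan.mu < _MU_FLOOR:
        return plan.xa + (plan.pmax / scenario.cd1) ** (1.0 / 3.0) * (t - plan.xa)

    def speed(s: float) -> float:
        p = plan.ps + (plan.pmax - plan.ps) * math.exp(-plan.mu * (s - plan.xa))
        return p ** (1.0 / 3.0) / cd1_cbrt

    val, _ = quad(speed, plan.xa, t, epsrel=1e-9, epsabs=1e-12, limit=200)
    return plan.xa + float(val)


def finish_time_fatigue(plan: FatiguePlan, scenario: RaceScenario) -> float | None:
    """Time at which the escaping rider crosses the line, or None if never separated.

    Solves ``x_i(tf) = 1`` by bracketed root finding; the bracket is grown
    from the no-fatigue finish time until the residual changes sign. Returns
    None when the attack cannot reach the line ahead of sustained-power pace
    (the rider is effectively reabsorbed).
    """

    def residual(t: float) -> float:
        return position_after_attack(t, plan, scenario) - 1.0

    lo = plan.xa
    hi = plan.xa + 2.0 * (1.0 - plan.xa)
    # The speed is bounded below by (Ps/Cd1)^(1/3) > 0, so the line is always
    # reached in finite time; grow the bracket until the residual is positive.
    for _ in range(200):
        if residual(hi) >= 0:
            break
        hi = plan.xa + 2.0 * (hi - plan.xa)
    else:
        return None
    if residual(lo) >= 0:  # attack at the line itself
        return lo
    tf = brentq(residual, lo, hi, xtol=1e-12, rtol=8.881784197001252e-16, maxiter=200)
    return float(tf)


def _solve_plan_at_xa(
    xa: float, mu: float, ps: float, scenario: RaceScenario
) -> tuple[FatiguePlan, float] | None:
    """Solve the two constraints at fixed ``xa``: budget-exact ``Pmax`` and ``tf``.

    Eliminates (tf, Pmax): find tf with x_i(tf) = 1 where Pmax is the
    budget-exact peak for that tf. Returns (plan, tf) or None when no
    separating, budget-feasible solution exists at this ``xa``.
    """
    e_star = scenario.energy_budget

    def residual(tf: float) -> float:
        pmax = pmax_from_budget(xa, tf, mu, ps, e_star)
        if pmax < ps:
            return math.inf
        plan = FatiguePlan(xa=xa, pmax=pmax, ps=ps, mu=mu)
        return position_after_attack(tf, plan, scenario) - 1.0

    # tf must satisfy Ps*tf <= E* (budget) and tf > xa.
    tf_hi = min(e_star / ps, 10.0) - 1e-12
    tf_lo = xa + 1e-10
    if tf_hi <= tf_lo:
        return None
    try:
        r_lo, r_hi = residual(tf_lo), residual(tf_hi)
    except (ValueError, InfeasibleBudgetError):
        return None
    # residual is decreasing in tf near the root? Not necessarily monotone;
    # scan a coarse grid for a sign change from + to -.
    if r_lo <= 0 < r_hi:
        bracket = (tf_lo, tf_hi)
    elif r_hi <= 0 < r_lo:
        bracket = (tf_lo, tf_hi)
    else:
        grid = np.linspace(tf_lo, tf_hi, 40)
        vals = []
        for t in grid:
            try:
                vals.append(residual(float(t)))
            except (ValueError, InfeasibleBudgetError):
                vals.append(math.nan)
        bracket = None
        for a, b, va, vb in zip(grid[:-1], grid[1:], vals[:-1], vals[1:]):
            if np.isfinite(va) and np.isfinite(vb) and va * vb <= 0:
                bracket = (float(a), float(b))
                break
        if bracket is None:
            return None
    tf = brentq(lambda t: residual(t), *bracket, xtol=1e-12, maxiter=200)
    pmax = pmax_from_budget(xa, tf, mu, ps, e_star)
    if pmax < ps or (pmax / scenario.cd1) ** (1.0 / 3.0) <= 1.0:
        return None
    return FatiguePlan(xa=xa, pmax=pmax, ps=ps, mu=mu), float(tf)


def _objective_of_outcome(xa: float, tf: float, scenario: RaceScenario) -> float:
    beta = scenario.beta
    margin = 1.0 - tf
    if margin < 0:
        # Caught before the line: finishes with the peloton.
        return (1.0 - beta) * lurking_crash_measure(scenario)
    return -beta * margin + (1.0 - beta) * breakaway_crash_measure(xa, scenario)


def scan_fatigue(
    scenario: RaceScenario,
    mu: float,
    ps: float | None = None,
    n_grid: int = 200,
) -> Optimum:
    """Exhaustive 1-D scan over the attack position (constraints eliminated).

    At each grid point the budget and finish-line constraints pin down
    (Pmax, tf); the objective is then compared across the grid, against the
    never-attack baseline, and refined by golden-section around the best grid
    point. Serves as the oracle for the constrained optimizer.
    """
    if ps is None:
        ps = scenario.cd_lurk
    no_attack_m = (1.0 - scenario.beta) * lurking_crash_measure(scenario)
    best_xa, best_tf, best_plan, best_m = None, None, None, no_attack_m
    xs = np.linspace(0.0, 1.0 - 1e-4, n_grid)
    for xa in xs:
        sol = _solve_plan_at_xa(float(xa), mu, ps, scenario)
        if sol is None:
            continue
        plan, tf = sol
        m = _objective_of_outcome(float(xa), tf, scenario)
        if m < best_m - 1e-15:
            best_xa, best_tf, best_plan, best_m = float(xa), tf, plan, m
    if best_xa is None:
        return Optimum(xa_star=None, power_star=None, margin=0.0,
                       objective=no_attack_m, branch=Branch.NO_ESCAPE)
    # Local golden-section refinement around the best grid point.
    step = float(xs[1] - xs[0])
    lo, hi = max(best_xa - step, 0.0), min(best_xa + step, 1.0 - 1e-4)

    def m_of(xa: float) -> float:
        sol = _solve_plan_at_xa(xa, mu, ps, scenario)
        if sol is None:
            return no_attack_m
        return _objective_of_outcome(xa, sol[1], scenario)

    phi = (math.sqrt(5.0) - 1.0) / 2.0
    a, b = lo, hi
    c, d = b - phi * (b - a), a + phi * (b - a)
    fc, fd = m_of(c), m_of(d)
    for _ in range(60):
        if fc < fd:
            b, d, fd = d, c, fc
            c = b - phi * (b - a)
            fc = m_of(c)
        else:
            a, c, fc = c, d, fd
            d = a + phi * (b - a)
            fd = m_of(d)
        if b - a < 1e-10:
            break
    xa = 0.5 * (a + b)
    sol = _solve_plan_at_xa(xa, mu, ps, scenario)
    if sol is not None and _objective_of_outcome(xa, sol[1], scenario) < best_m:
        best_xa, best_tf, best_plan = xa, sol[1], sol[0]
        best_m = _objective_of_outcome(xa, sol[1], scenario)
    branch = Branch.START_LINE if best_xa < 1e-9 else Branch.INTERIOR
    if best_tf is not None and 1.0 - best_tf <= 1e-12 and best_xa > 1e-9:
        branch = Branch.BOUNDARY_MIN_ATTACK
    return Optimum(
        xa_star=best_xa, power_star=best_plan.pmax, margin=max(1.0 - best_tf, 0.0),
        objective=best_m, branch=branch,
    )


def optimize_fatigue(
    scenario: RaceScenario,
    mu: float,
    ps: float | None = None,
    n_starts: int = 16,
    pmax_cap: float | None = None,
) -> Optimum:
    """Constrained minimization of ``M`` over (attack position, finish time, peak power).

    Gradient-based (SLSQP) with the energy-budget equality and the finish-line
    condition as constraints, multi-started from a fixed grid of attack
    positions with (tf, Pmax) repaired to feasibility at each start.
    Deterministic: no randomness anywhere. Compared against the never-attack
    baseline; an optional ``pmax_cap`` rejects physiologically absurd bursts.
    """
    if mu < 0:
        raise ValueError(f"fatigue rate must be >= 0, got {mu}")
    if ps is None:
        ps = scenario.cd_lurk
    beta = scenario.beta
    e_star = scenario.energy_budget
    no_attack_m = (1.0 - beta) * lurking_crash_measure(scenario)

    def neg_margin_objective(z: np.ndarray) -> float:
        xa, tf, _ = z
        return _objective_of_outcome(float(xa), float(tf), scenario)

    def energy_constraint(z: np.ndarray) -> float:
        xa, tf, pmax = z
        plan = FatiguePlan(xa=min(max(xa, 0.0), 1 - 1e-9), pmax=max(pmax, ps), ps=ps, mu=mu)
        return total_energy_fatigue(plan, max(tf, xa)) - e_star

    def finish_constraint(z: np.ndarray) -> float:
        xa, tf, pmax = z
        xa = min(max(xa, 0.0), 1 - 1e-9)
        plan = FatiguePlan(xa=xa, pmax=max(pmax, ps), ps=ps, mu=mu)
        return position_after_attack(max(tf, xa), plan, scenario) - 1.0

    best: tuple[float, float, float, float] | None = None  # (M, xa, tf, pmax)
    for xa0 in np.linspace(0.0, 0.95, n_starts):
        repaired = _solve_plan_at_xa(float(xa0), mu, ps, scenario)
        if repaired is None:
            continue
        plan0, tf0 = repaired
        z0 = np.array([xa0, tf0, plan0.pmax])
        res = minimize(
            neg_margin_objective,
            z0,
            method="SLSQP",
            constraints=[
                {"type": "eq", "fun": energy_constraint},
                {"type": "eq", "fun": finish_constraint},
            ],
            bounds=[(0.0, 1.0 - 1e-6), (0.0, 10.0), (ps, None)],
            options={"maxiter": 200, "ftol": 1e-12},
        )
        for z in (res.x, z0):
            xa, tf, pmax = float(z[0]), float(z[1]), float(z[2])
            if tf <= xa or pmax < ps:
                continue
            plan = FatiguePlan(xa=xa, pmax=pmax, ps=ps, mu=mu)
            if abs(total_energy_fatigue(plan, tf) - e_star) > 1e-7:
                continue
            if abs(position_after_attack(tf, plan, scenario) - 1.0) > 1e-7:
                continue
            if pmax_cap is not None and pmax > pmax_cap:
                continue
            m = _objective_of_outcome(xa, tf, scenario)
            if best is None or m < best[0]:
                best = (m, xa, tf, pmax)
    if best is None or best[0] >= no_attack_m:
        return Optimum(xa_star=None, power_star=None, margin=0.0,
                       objective=no_attack_m, branch=Branch.NO_ESCAPE)
    m, xa, tf, pmax = best
    margin = max(1.0 - tf, 0.0)
    if xa < 1e-9:
        branch = Branch.START_LINE
    elif margin <= 1e-9:
        branch = Branch.BOUNDARY_MIN_ATTACK
    else:
        branch = Branch.INTERIOR
    return Optimum(xa_star=xa, power_star=pmax, margin=margin, objective=m, branch=branch)
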