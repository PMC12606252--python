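"""Rider dynamics: the quasi-steady speed law and its inertial validation.

A rider exerting power ``P`` against drag ``Cd`` obeys
``eps * x'' = P/x' - Cd * x'^2`` in dimensionless form, where the inertia
``eps`` is tiny for realistic stages. In the quasi-steady limit ``eps = 0``
speed responds instantly to power, ``v = (P/Cd)**(1/3)``; the inertial
integrator here exists to validate that limit, not to race.
"""

from __future__ import annotations

from typing import Callable

import numpy as np
from scipy.integrate import quad, solve_ivp


class IntegrationError(RuntimeError):
    """The inertial integrator failed to reach the target distance."""


def quasi_steady_speed(power: float, cd: float) -> float:
    """Speed balancing propulsive power against cubic drag: ``(P/Cd)**(1/3)``."""
    if power <= 0:
        raise ValueError(f"power must be positive, got {power}")
    if cd <= 0:
        raise ValueError(f"drag coefficient must be positive, got {cd}")
    return (power / cd) ** (1.0 / 3.0)


def integrate_inertial(
    power_profile: Callable[[float], float],
    cd: float,
    epsilon: float,
    x_target: float,
    v0: float | None = None,
    *,
    rtol: float = 1e-8,
    atol: float = 1e-10,
    t_max: float | None = None,
) -> float:
    """Finish time of the inertial equation of motion over ``[0, x_target]``.

    Integrates ``eps v' = P(t)/v - cd v**2``, ``x' = v`` with an event on the
    finish-line crossing. ``v0`` defaults to the quasi-steady speed of the
    initial power, matching a race that starts already rolling at equilibrium.
    Small ``eps`` makes the system stiff near power jumps, hence Radau.
    """
    if epsilon <= 0:
        raise ValueError(f"epsilon must be positive, got {epsilon}")
    if cd <= 0:
        raise ValueError(f"drag coefficient must be positive, got {cd}")
    if v0 is None:
        v0 = quasi_steady_speed(power_profile(0.0), cd)
    if v0 <= 0:
        raise ValueError(f"initial speed must be positive, got {v0}")

    def rhs(t: float, y: np.ndarray) -> list[float]:
        x, v = y
        v = max(v, 1e-12)
        return [v, (power_profile(t) / v - cd * v * v) / epsilon]

    def crossed(t: float, y: np.ndarray) -> float:
        return y[0] - x_target

    crossed.terminal = True
    crossed.direction = 1.0

    # Generous horizon: slowest plausible average speed is bounded below by
    # the quasi-steady speed floor; 10x the nominal time is ample.
    if t_max is None:
        t_max = 10.0 * max(x_target / v0, 1.0)
    sol = solve_ivp(
        rhs,
        (0.0, t_max),
        [0.0, v0],
        method="Radau",
        events=crossed,
        rtol=rtol,
        atol=atol,
        dense_output=False,
    )
    if not sol.success or len(sol.t_events[0]) == 0:
        raise IntegrationError(
            f"rider did not reach x = {x_target} within t = {t_max} "
            f"(solver status: {sol.message})"
        )
    return float(sol.t_events[0][0])


def quasi_steady_finish_time(power: float, cd: float, distance: float = 1.0) -> float:
    """Time to cover ``distance`` at the constant quasi-steady speed."""
    return distance / quasi_steady_speed(power, cd)


def energy_of_profile(
    power_profile: Callable[[float], float],
    t_end: float,
    *,
    rtol: float = 1e-8,
) -> float:
    """Energy spent by a power profile up to ``t_end``, by adaptive quadrature."""
    if t_end < 0:
        raise ValueError(f"t_end must be >= 0, got {t_end}")
    if t_end == 0:
        return 0.0
    value, _ = quad(power_profile, 0.0, t_end, epsrel=rtol, epsabs=1e-12, limit=200)
    return float(value)
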