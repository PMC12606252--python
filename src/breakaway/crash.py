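"""Crash propagation model and race-integrated crash exposure.

A crash starts at some peloton position and propagates backwards: riders ahead
of the first faller are spared, riders behind are swept up with probability
decaying exponentially in the number of positions behind. Combining the
propagation kernel with a start-position distribution and a per-race crash
rate yields, for any exposure history ``i(x)`` along the course, the expected
number of crash involvements ``P`` — the "crash measure" penalized by the
objective. ``P`` is an expectation, not a probability, so it may exceed one
for high crash rates.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np


@dataclass(frozen=True)
class CrashKernel:
    """Conditional involvement probabilities ``P(C_i | S_k)``.

    Either ``omega`` (exponential kernel ``exp(-omega*(i-k))`` for ``i >= k``,
    zero ahead of the crash) or an explicit ``involvement_matrix`` of shape
    ``(N, N)``. ``start_distribution`` is ``P(S_k | C)``; uniform by default.
    """

    omega: float | None = 0.5
    involvement_matrix: np.ndarray | None = None
    start_distribution: np.ndarray | None = None

    def __post_init__(self) -> None:
        if (self.omega is None) == (self.involvement_matrix is None):
            raise ValueError("specify exactly one of omega or involvement_matrix")
        if self.omega is not None and not self.omega > 0:
            raise ValueError(f"omega must be positive, got {self.omega}")
        if self.involvement_matrix is not None:
            m = np.asarray(self.involvement_matrix, dtype=float)
            if m.ndim != 2 or m.shape[0] != m.shape[1]:
                raise ValueError("involvement_matrix must be square")
            if np.any(m < 0) or np.any(m > 1):
                raise ValueError("involvement entries must lie in [0, 1]")
            if not np.allclose(np.diag(m), 1.0):
                raise ValueError("P(C_i|S_i) must equal 1 on the diagonal")
            if np.any(np.triu(m, 1) != 0):
                raise ValueError("riders ahead of the crash cannot be involved (i < k)")
            object.__setattr__(self, "involvement_matrix", m)
        if self.start_distribution is not None:
            p = np.asarray(self.start_distribution, dtype=float)
            if np.any(p < 0) or not np.isclose(p.sum(), 1.0):
                raise ValueError("start_distribution must be nonnegative and sum to 1")
            object.__setattr__(self, "start_distribution", p)

    def size(self, n_riders: int) -> int:
        if self.involvement_matrix is not None:
            return self.involvement_matrix.shape[0]
        return n_riders


@dataclass(frozen=True)
class ExposurePath:
    """Piecewise-constant drafting position ``i(x)`` over the unit course."""

    breakpoints: Sequence[float]   # len m+1, strictly increasing, [0, ..., 1]
    positions: Sequence[int]       # len m, drafting position on each segment

    def __post_init__(self) -> None:
        bp = np.asarray(self.breakpoints, dtype=float)
        pos = np.asarray(self.positions, dtype=int)
        if bp.ndim != 1 or len(bp) != len(pos) + 1:
            raise ValueError("need len(breakpoints) == len(positions) + 1")
        if not (np.all(np.diff(bp) > 0) and np.isclose(bp[0], 0.0) and np.isclose(bp[-1], 1.0)):
            raise ValueError("breakpoints must increase strictly from 0 to 1")
        if np.any(pos < 1):
            raise ValueError("drafting positions must be >= 1")
        object.__setattr__(self, "breakpoints", tuple(float(b) for b in bp))
        object.__setattr__(self, "positions", tuple(int(p) for p in pos))


def involvement_given_start(i: int, k: int, kernel: CrashKernel, n_riders: int = 10**9) -> float:
    """Probability that rider ``i`` is swept up given the crash started at ``k``."""
    n = kernel.size(n_riders)
    if not (1 <= i <= n and 1 <= k <= n):
        raise IndexError(f"positions ({i}, {k}) out of range [1, {n}]")
    if kernel.involvement_matrix is not None:
        return float(kernel.involvement_matrix[i - 1, k - 1])
    if i < k:
        return 0.0
    return float(np.exp(-kernel.omega * (i - k)))


def crash_prob_given_crash(i: int, kernel: CrashKernel, n_riders: int) -> float:
    """``H(i; omega)``: involvement probability of position ``i`` given a crash.

    Law of total probability over the crash start position. The exponential
    kernel with a uniform start distribution has the closed form
    ``(1/N) (1 - exp(-omega i)) / (1 - exp(-omega))``.
    """
    n = kernel.size(n_riders)
    if not 1 <= i <= n:
        raise IndexError(f"position {i} out of range [1, {n}]")
    if kernel.involvement_matrix is None and kernel.start_distribution is None:
        w = kernel.omega
        return float(-np.expm1(-w * i) / (-np.expm1(-w)) / n)
    start = kernel.start_distribution
    if start is None:
        start = np.full(n, 1.0 / n)
    return float(
        sum(involvement_given_start(i, k, kernel, n) * start[k - 1] for k in range(1, n + 1))
    )


def race_crash_measure(
    path: ExposurePath, kernel: CrashKernel, crash_rate: float, n_riders: int
) -> float:
    """Expected crash involvements over the race for an exposure history.

    ``P = P(C) * sum_segments (length) * H(i_segment)``; exact for
    piecewise-constant paths, and linear in the crash rate.
    """
    bp = np.asarray(path.breakpoints)
    lengths = np.diff(bp)
    hs = np.array([crash_prob_given_crash(i, kernel, n_riders) for i in path.positions])
    return float(crash_rate * np.dot(lengths, hs))


def breakaway_crash_measure(xa: float, scenario) -> float:
    """Crash measure for lurking at position ``i`` until ``xa``, then riding solo.

    A solo rider off the front carries the same exposure as the front of the
    peloton (position 1), giving the closed form
    ``(P(C)/N) * (xa * (1-e^{-omega i})/(1-e^{-omega}) + 1 - xa)``.
    """
    if not 0.0 <= xa <= 1.0:
        raise ValueError(f"attack position must lie in [0, 1], got {xa}")
    w = scenario.omega
    geom = -np.expm1(-w * scenario.lurk_position) / (-np.expm1(-w))
    return float(scenario.crash_rate / scenario.n_riders * (xa * geom + 1.0 - xa))


def lurking_crash_measure(scenario) -> float:
    """Crash measure for spending the whole race at the lurking position."""
    kernel = CrashKernel(omega=scenario.omega)
    h = crash_prob_given_crash(scenario.lurk_position, kernel, scenario.n_riders)
    return float(scenario.crash_rate * h)


def mc_crash_oracle(
    path: ExposurePath,
    kernel: CrashKernel,
    crash_rate: float,
    n_riders: int,
    trials: int,
    seed: int,
) -> tuple[float, float]:
    """Monte-Carlo estimate of the crash measure, with its standard error.

    Each trial draws a Poisson number of crashes (mean ``crash_rate``) at
    uniform locations; each crash draws a first faller from the start
    distribution and sweeps the rider up with the kernel probability at the
    rider's position for that stretch of road. Validation oracle only.
    """
    if trials < 1:
        raise ValueError(f"trials must be >= 1, got {trials}")
    rng = np.random.default_rng(seed)
    n = kernel.size(n_riders)
    start = kernel.start_distribution
    if start is None:
        start = np.full(n, 1.0 / n)
    bp = np.asarray(path.breakpoints)
    pos = np.asarray(path.positions)

    n_crashes = rng.poisson(crash_rate, size=trials)
    total = int(n_crashes.sum())
    if total == 0:
        return 0.0, 0.0
    locs = rng.uniform(0.0, 1.0, size=total)
    starters = rng.choice(np.arange(1, n + 1), size=total, p=start)
    # Rider's drafting position on the segment containing each crash location.
    seg = np.clip(np.searchsorted(bp, locs, side="right") - 1, 0, len(pos) - 1)
    rider_pos = pos[seg]
    probs = np.array(
        [involvement_given_start(int(i), int(k), kernel, n) for i, k in zip(rider_pos, starters)]
    )
    involved = rng.uniform(size=total) < probs
    per_trial = np.zeros(trials)
    np.add.at(per_trial, np.repeat(np.arange(trials), n_crashes), involved.astype(float))
    mean = float(per_trial.mean())
    sem = float(per_trial.std(ddof=1) / np.sqrt(trials)) if trials > 1 else 0.0
    return mean, sem
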