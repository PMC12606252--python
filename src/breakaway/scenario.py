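"""Scenario types: physical parameters, drag profile, scales and the dimensionless race.

The model describes a flat road stage ridden by a peloton of ``N`` riders, one
of whom ("the special rider") may attack. Aerodynamic drag decays exponentially
with depth into the peloton; all other quantities are nondimensionalized so that
the peloton covers a unit course in unit time with unit average power.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field, asdict


class ConfigurationError(ValueError):
    """Raised when a scenario or profile violates its invariants."""


class OffsetConvention(enum.Enum):
    """How drafting position ``i`` maps to exponential drafting depth.

    The geometric definition ``i = 1 + zeta/d`` puts the front rider at depth 0
    (``EXPONENT_I_MINUS_1``); the published dimensionless pair
    ``(Cd,1, Cd,5) = (1.43, 0.46)`` is instead consistent with depth ``i``
    (``EXPONENT_I``), which is therefore the default.
    """

    EXPONENT_I = "exponent_i"
    EXPONENT_I_MINUS_1 = "exponent_i_minus_1"


@dataclass(frozen=True)
class PhysicalParameters:
    """Dimensional rider/course parameters (SI units)."""

    rider_mass: float = 70.0          # kg
    mean_mass: float = 70.0           # kg, peloton average
    air_density: float = 1.225        # kg m^-3
    frontal_area: float = 0.5         # m^2
    course_length: float = 100_000.0  # m
    axle_spacing: float = 4.0         # m, axle-to-axle distance in the pack
    mean_initial_power: float = 150.0  # W, peloton average at the start

    def __post_init__(self) -> None:
        for name, value in asdict(self).items():
            if not value > 0:
                raise ConfigurationError(f"{name} must be strictly positive, got {value!r}")
        if self.axle_spacing / self.course_length >= 1e-2:
            raise ConfigurationError(
                "axle spacing must be much smaller than the course "
                f"(d/L = {self.axle_spacing / self.course_length:.3g} >= 1e-2)"
            )


@dataclass(frozen=True)
class DragProfile:
    """Exponential decay of the drag coefficient with drafting depth.

    ``peloton_mean_cd`` may be supplied directly (the usual route, since the
    published dimensionless drags fix it) or computed from a rectangular
    ``n_rows x n_cols`` layout via :meth:`from_row_layout`.
    """

    cd_max: float = 0.9
    cd_min: float = 0.05
    decay: float = 0.25               # per drafting position
    peloton_mean_cd: float | None = None
    offset_convention: OffsetConvention = OffsetConvention.EXPONENT_I

    def __post_init__(self) -> None:
        if not 0 < self.cd_min < self.cd_max:
            raise ConfigurationError(
                f"require 0 < cd_min < cd_max, got ({self.cd_min}, {self.cd_max})"
            )
        if not self.decay > 0:
            raise ConfigurationError(f"decay must be positive, got {self.decay}")
        if self.peloton_mean_cd is not None and not (
            self.cd_min <= self.peloton_mean_cd <= self.cd_max
        ):
            raise ConfigurationError(
                f"peloton_mean_cd {self.peloton_mean_cd} outside [cd_min, cd_max]"
            )

    @classmethod
    def from_row_layout(
        cls,
        n_rows: int,
        n_cols: int,
        *,
        cd_max: float = 0.9,
        cd_min: float = 0.05,
        decay: float = 0.25,
        offset_convention: OffsetConvention = OffsetConvention.EXPONENT_I,
    ) -> "DragProfile":
        """Build a profile whose peloton mean is the discrete row average.

        Riders sit on a rectangular grid; every rider in row ``r`` (1-based)
        drafts at depth ``r - 1`` axle spacings, so the peloton mean is the
        equal-weight average of the row drag coefficients.
        """
        if n_rows < 1 or n_cols < 1:
            raise ConfigurationError("row layout requires n_rows >= 1 and n_cols >= 1")
        base = cls(cd_max=cd_max, cd_min=cd_min, decay=decay,
                   offset_convention=offset_convention)
        mean = sum(base.drag_coefficient(float(r)) for r in range(n_rows)) / n_rows
        return cls(cd_max=cd_max, cd_min=cd_min, decay=decay,
                   peloton_mean_cd=mean, offset_convention=offset_convention)

    def drag_coefficient(self, zeta_over_d: float) -> float:
        """Dimensional drag coefficient at drafting depth ``zeta/d``.

        Equals ``cd_max`` at or ahead of the front of the peloton and decays
        exponentially toward ``cd_min`` with depth.
        """
        if zeta_over_d <= 0:
            return self.cd_max
        return self.cd_min + (self.cd_max - self.cd_min) * math.exp(-self.decay * zeta_over_d)

    def rescaled_drag(self, position: int) -> float:
        """Dimensionless drag ``Cd,i`` at drafting position ``i`` (1-based)."""
        if position < 1:
            raise ConfigurationError(f"drafting position must be >= 1, got {position}")
        if self.peloton_mean_cd is None:
            raise ConfigurationError(
                "peloton_mean_cd is not set; supply it or use from_row_layout"
            )
        if self.offset_convention is OffsetConvention.EXPONENT_I:
            depth = float(position)
        else:
            depth = float(position - 1)
        return self.drag_coefficient(depth) / self.peloton_mean_cd


#: Peloton-mean drag implied by the published pair Cd,1 = 0.9/<Cd> = 1.43.
DEFAULT_PELOTON_MEAN_CD = 0.9 / 1.43


@dataclass(frozen=True)
class DimensionlessScales:
    """Conversion factors between dimensional and dimensionless variables."""

    epsilon: float       # dimensionless inertia, 2<m>/(L <Cd> rho A)
    delta: float         # axle spacing / course length
    time_scale: float    # seconds per dimensionless time unit
    energy_scale: float  # joules per dimensionless energy unit

    def __post_init__(self) -> None:
        for name in ("epsilon", "delta", "time_scale", "energy_scale"):
            if not getattr(self, name) > 0:
                raise ConfigurationError(f"{name} must be positive")


def nondimensionalize(phys: PhysicalParameters, profile: DragProfile) -> DimensionlessScales:
    """Derive the dimensionless scales from dimensional parameters.

    The time scale is chosen so the peloton finishes the unit course at unit
    time under unit average power; the energy scale makes the peloton's mean
    race expenditure equal to one.
    """
    mean_cd = profile.peloton_mean_cd
    if mean_cd is None:
        raise ConfigurationError("peloton_mean_cd required to nondimensionalize")
    rho, area, length = phys.air_density, phys.frontal_area, phys.course_length
    p0 = phys.mean_initial_power
    time_scale = (mean_cd * rho * area * length**3 / (2.0 * p0)) ** (1.0 / 3.0)
    energy_scale = (mean_cd * rho * area * p0**2 * length**3 / 2.0) ** (1.0 / 3.0)
    epsilon = 2.0 * phys.mean_mass / (length * mean_cd * rho * area)
    delta = phys.axle_spacing / length
    return DimensionlessScales(
        epsilon=epsilon, delta=delta, time_scale=time_scale, energy_scale=energy_scale
    )


@dataclass(frozen=True)
class RaceScenario:
    """Dimensionless parameter bundle defining one race.

    Parameters
    ----------
    cd1 : solo (front-of-peloton) rescaled drag; the power needed to hold unit
        speed alone.
    cd_lurk : rescaled drag — equivalently the lurking power — at the special
        rider's peloton position.
    lurk_position : drafting position ``i`` of the special rider.
    n_riders : peloton size ``N``.
    omega : crash-propagation decay per rider; smaller means bigger pile-ups.
    crash_rate : expected crashes per race, ``P(C)``.
    energy_budget : dimensionless energy ``E*`` the rider may spend (peloton
        average = 1).
    beta : risk index in [0, 1]; 0 = fully risk-averse, 1 = risk-blind.
    """

    cd1: float = 1.43
    cd_lurk: float = 0.46
    lurk_position: int = 5
    n_riders: int = 75
    omega: float = 0.5
    crash_rate: float = 2.0
    energy_budget: float = 1.2
    beta: float = 0.5

    def __post_init__(self) -> None:
        if not 0 < self.cd_lurk <= self.cd1:
            raise ConfigurationError(
                f"require 0 < cd_lurk <= cd1, got ({self.cd_lurk}, {self.cd1})"
            )
        if self.cd_lurk == self.cd1 and self.lurk_position != 1:
            raise ConfigurationError("cd_lurk may equal cd1 only for the front rider (i=1)")
        if self.lurk_position < 1:
            raise ConfigurationError(f"lurk_position must be >= 1, got {self.lurk_position}")
        if not 0 <= self.beta <= 1:
            raise ConfigurationError(f"beta must lie in [0, 1], got {self.beta}")
        if self.energy_budget < 0:
            raise ConfigurationError(f"energy_budget must be >= 0, got {self.energy_budget}")
        if not self.omega > 0:
            raise ConfigurationError(f"omega must be positive, got {self.omega}")
        if self.n_riders < 1:
            raise ConfigurationError(f"n_riders must be >= 1, got {self.n_riders}")
        if self.crash_rate < 0:
            raise ConfigurationError(f"crash_rate must be >= 0, got {self.crash_rate}")

    def replace(self, **changes) -> "RaceScenario":
        """Return a copy with the given fields replaced (re-validated)."""
        params = asdict(self)
        params.update(changes)
        return RaceScenario(**params)


def default_scenario() -> RaceScenario:
    """Canonical flat-stage scenario (the worked default throughout)."""
    return RaceScenario()
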