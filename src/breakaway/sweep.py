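"""Parameter sweeps over optimal strategies, and the scenario fixture generator."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .fatigue import optimize_fatigue
from .optimizer import Optimum, global_optimum, objective as m_of
from .scenario import RaceScenario, default_scenario

log = logging.getLogger(__name__)

_SWEEPABLE = {"beta", "energy_budget", "omega", "mu", "xa"}


@dataclass(frozen=True)
class SweepSpec:
    """One-parameter sweep of the optimizer over a uniform grid."""

    parameter: str
    lo: float
    hi: float
    n: int
    scenario: RaceScenario = field(default_factory=default_scenario)
    mode: str = "constant"      # "constant" or "fatigue"
    mu: float = 1.0             # used when mode == "fatigue" and parameter != "mu"
    ps: float | None = None

    def __post_init__(self) -> None:
        if self.parameter not in _SWEEPABLE:
            raise ValueError(
                f"unknown sweep parameter {self.parameter!r}; choose from {sorted(_SWEEPABLE)}"
            )
        if self.n < 2:
            raise ValueError(f"sweep needs n >= 2 grid points, got {self.n}")
        if not self.lo < self.hi:
            raise ValueError(f"sweep needs lo < hi, got [{self.lo}, {self.hi}]")
        if self.mode not in {"constant", "fatigue"}:
            raise ValueError(f"mode must be 'constant' or 'fatigue', got {self.mode!r}")


def _optimum_row(value: float, opt: Optimum) -> dict:
    return {
        "sweep_value": value,
        "xa_star": opt.xa_star if opt.xa_star is not None else np.nan,
        "dt_star": opt.margin,
        "power_star": opt.power_star if opt.power_star is not None else np.nan,
        "M_star": opt.objective,
        "branch": opt.branch.value,
        "error": "",
    }


def run_sweep(spec: SweepSpec) -> pd.DataFrame:
    """Optimize at each grid point; failures land in the ``error`` column."""
    values = np.linspace(spec.lo, spec.hi, spec.n)
    rows = []
    for value in values:
        value = float(value)
        try:
            if spec.parameter == "mu":
                opt = optimize_fatigue(spec.scenario, mu=value, ps=spec.ps)
            elif spec.parameter == "xa":
                rows.append({
                    "sweep_value": value, "xa_star": value, "dt_star": np.nan,
                    "power_star": np.nan, "M_star": m_of(value, spec.scenario),
                    "branch": "", "error": "",
                })
                continue
            else:
                scenario = spec.scenario.replace(**{spec.parameter: value})
                if spec.mode == "fatigue":
                    opt = optimize_fatigue(scenario, mu=spec.mu, ps=spec.ps)
                else:
                    opt = global_optimum(scenario)
            rows.append(_optimum_row(value, opt))
            log.info("sweep %s=%.6g -> xa*=%s branch=%s",
                     spec.parameter, value, rows[-1]["xa_star"], rows[-1]["branch"])
        except Exception as exc:  # record and continue
            log.warning("sweep %s=%.6g failed: %s", spec.parameter, value, exc)
            rows.append({
                "sweep_value": value, "xa_star": np.nan, "dt_star": np.nan,
                "power_star": np.nan, "M_star": np.nan, "branch": "",
                "error": str(exc),
            })
    return pd.DataFrame(rows)


def write_sweep_csv(frame: pd.DataFrame, path: str | Path) -> None:
    """Fixed CSV dialect: comma, dot decimal, header, UTF-8, LF."""
    Path(path).write_text(frame.to_csv(index=False, lineterminator="\n"), encoding="utf-8")


def generate_fixtures(seed: int, count: int) -> dict[str, RaceScenario]:
    """Named scenario fixtures: the canonical default, edge cases, random variants.

    Random variants are drawn from ranges spanning plausible flat-stage
    conditions (solo drag 1.1-2, lurking drag below it, omega 0.1-1, full
    risk range, budgets 0.5-2); reproducible per seed.
    """
    if count < 0:
        raise ValueError(f"count must be >= 0, got {count}")
    base = default_scenario()
    fixtures: dict[str, RaceScenario] = {"default": base}
    if count:
        fixtures.update({
            "edge_risk_averse": base.replace(beta=0.0),
            "edge_risk_blind": base.replace(beta=1.0),
            "edge_budget_lurk": base.replace(energy_budget=base.cd_lurk),
            "edge_budget_solo": base.replace(energy_budget=base.cd1),
        })
    rng = np.random.default_rng(seed)
    for j in range(count):
        cd1 = rng.uniform(1.1, 2.0)
        cd_lurk = rng.uniform(0.2, cd1 * 0.999)
        fixtures[f"random_{j:03d}"] = RaceScenario(
            cd1=float(cd1),
            cd_lurk=float(cd_lurk),
            lurk_position=int(rng.integers(2, 16)),
            n_riders=int(rng.integers(20, 200)),
            omega=float(rng.uniform(0.1, 1.0)),
            crash_rate=float(rng.uniform(0.0, 4.0)),
            energy_budget=float(rng.uniform(0.5, 2.0)),
            beta=float(rng.uniform(0.0, 1.0)),
        )
    return fixtures
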