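"""One-at-a-time ten-fold sensitivity analysis of the equilibrium constants.

Each of Ki, Kc, Ka, Kp, Kx is perturbed ten-fold up and down by scaling its
off-rate (on-rates, and hence the bimolecular timescales, stay fixed); the
steady state is recomputed from identical all-free initial conditions and
the percent change of the two reported observables — the fully occupied
single divalent receptor Cd and the saturated aggregate pair Add — is
tabulated alongside the raw baseline/perturbed concentrations so the
arithmetic is independently checkable.
"""

from __future__ import annotations

import dataclasses
import logging
import math
from typing import Sequence

import pandas as pd

from .errors import ConfigurationError
from .kinetics import Microrates, Scenario, solve_steady_state, _CD, _ADD

logger = logging.getLogger("ecmbind.sensitivity")

#: Off-rate scaled when the named dissociation constant is perturbed.
CONSTANT_OFF_RATE = {"Ki": "k2", "Kc": "k4", "Ka": "k6", "Kp": "k10", "Kx": "k8"}
EQUILIBRIUM_CONSTANTS = tuple(CONSTANT_OFF_RATE)
#: Extra perturbation axis: total surface receptor concentration.
RECEPTOR_TOTAL = "receptor_total"

OBSERVABLES = {"Cd": _CD, "Add": _ADD}


@dataclasses.dataclass(frozen=True)
class SensitivityResult:
    """Outcome of one constant × direction × observable cell."""

    constant_id: str
    direction: str  # up10 | down10 (or xF for other factors)
    observable: str  # Cd | Add
    baseline: float  # nM
    perturbed: float  # nM
    percent_change: float  # %
    converged: bool = True


def perturb(
    rates: Microrates,
    constant_id: str,
    factor: float,
    maintain_kc_relation: bool = True,
) -> Microrates:
    """Multiply one equilibrium constant by ``factor`` via its off-rate.

    With ``maintain_kc_relation`` (default), perturbing Ki co-scales k4 so
    the Kc = ratio·Ki relation is preserved; otherwise Kc is treated as an
    independently fixed constant and only k2 moves.
    """
    if not factor > 0:
        raise ConfigurationError(f"perturbation factor must be > 0, got {factor}")
    if constant_id not in CONSTANT_OFF_RATE:
        raise ConfigurationError(
            f"unknown constant {constant_id!r}; expected one of {EQUILIBRIUM_CONSTANTS}"
        )
    off = CONSTANT_OFF_RATE[constant_id]
    updates = {off: getattr(rates, off) * factor}
    if constant_id == "Ki" and maintain_kc_relation:
        updates["k4"] = rates.k4 * factor
    return rates.replace(**updates)


def percent_change(baseline: float, perturbed: float) -> float:
    """(perturbed − baseline) / baseline × 100; NaN when baseline <= 0."""
    if not baseline > 0:
        return math.nan
    return (perturbed - baseline) / baseline * 100.0


def _direction(factor: float) -> str:
    if factor == 10:
        return "up10"
    if factor == 0.1:
        return "down10"
    return f"x{factor:g}"


def sensitivity_table(
    scenario: Scenario,
    constants: Sequence[str] = EQUILIBRIUM_CONSTANTS,
    factors: Sequence[float] = (10.0, 0.1),
    maintain_kc_relation: bool = True,
    observables: Sequence[str] = ("Add", "Cd"),
) -> pd.DataFrame:
    """Full one-at-a-time sensitivity table for one scenario.

    Every cell reruns the simulation to steady state with the perturbed
    rates from the same all-free initial conditions.  ``receptor_total`` may
    be included among ``constants`` to sweep surface receptor expression
    instead of a rate constant.  Non-convergent cells are flagged, not
    fatal.  Deterministic: fixed integrator settings, no randomness.
    """
    rates = scenario.microrates()
    base_state, base_conv = solve_steady_state(scenario, microrates=rates)
    if not base_conv:
        logger.warning(
            "baseline steady state not converged for %s:%s",
            scenario.ligand, scenario.receptor,
        )
    rows: list[SensitivityResult] = []
    for cid in constants:
        for factor in factors:
            if cid == RECEPTOR_TOTAL:
                sc = dataclasses.replace(
                    scenario, receptor_total_nM=scenario.receptor_total_nM * factor
                )
                state, conv = solve_steady_state(sc, microrates=rates)
            elif cid in CONSTANT_OFF_RATE:
                pr = perturb(rates, cid, factor, maintain_kc_relation)
                state, conv = solve_steady_state(scenario, microrates=pr)
            else:
                raise ConfigurationError(f"unknown constant {cid!r}")
            for obs in observables:
                base = float(base_state[OBSERVABLES[obs]])
                pert = float(state[OBSERVABLES[obs]])
                rows.append(
                    SensitivityResult(
                        constant_id=cid,
                        direction=_direction(factor),
                        observable=obs,
                        baseline=base,
                        perturbed=pert,
                        percent_change=percent_change(base, pert),
                        converged=conv,
                    )
                )
    return pd.DataFrame([dataclasses.asdict(r) for r in rows])
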