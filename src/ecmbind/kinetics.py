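"""Mass-action models of divalent integrin binding and receptor aggregation.

Two closed, deterministic reaction schemes over nine species (nM):

* **Divalent model** — sequential two-site binding of an ECM ligand E to a
  heterodimeric receptor I:  ``I + E <-> Cm`` (stepwise dissociation
  constant Ki = k2/k1) followed by ``Cm + E <-> Cd`` (Kc = k4/k3).  Setting
  Kc below Ki implements the low-to-high affinity conformational switch and
  yields positive cooperativity of the fully occupied fraction.

* **Aggregation model** — adds receptor pairing: a singly or doubly bound
  receptor may pair with an *unbound* receptor (Ka = k6/k5), producing the
  aggregate ladder Aim, Aid, Amm, Amd, Add.  Ligand binds the empty half of
  a pair with Kp = k10/k9 and fills the second site of a singly bound half
  with Kx = k8/k7.  Aggregation emulates the clustering of integrins into
  focal adhesions and is the second driver of cooperativity.

All equilibrium constants are dissociation-type (off-rate / on-rate, nM).
Trajectories conserve total receptor ``I + Cm + Cd + 2*sum(A)`` and total
ligand ``E + Cm + 2 Cd + Aim + 2 Aid + 2 Amm + 3 Amd + 4 Add`` exactly in
the scheme and to integrator precision numerically.

The module provides rate assembly from a measured (k_on, k_off) pair plus
ratio relations, stiff-capable trajectory integration (LSODA with analytic
Jacobian), steady-state extraction with an optional Newton polish under the
conservation constraints, a closed-form equilibrium solver for the divalent
model, ligand-titration occupancy curves and a logit-slope Hill estimator.
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp
from scipy.optimize import brentq

from .errors import ConfigurationError, IntegrationError, ValidationError

logger = logging.getLogger("ecmbind.kinetics")

SPECIES = ("I", "E", "Cm", "Cd", "Aim", "Aid", "Amm", "Amd", "Add")
_I, _E, _CM, _CD, _AIM, _AID, _AMM, _AMD, _ADD = range(9)

#: Receptors carried by each species (aggregate pairs hold two).
RECEPTOR_WEIGHTS = np.array([1, 0, 1, 1, 2, 2, 2, 2, 2], dtype=float)
#: Ligands carried by each species.
LIGAND_WEIGHTS = np.array([0, 1, 1, 2, 1, 2, 2, 3, 4], dtype=float)

DIVALENT = "divalent"
AGGREGATION = "aggregation"

#: s^-1 M^-1  ->  nM^-1 s^-1
PER_M_TO_PER_NM = 1e-9
#: µM -> nM
UM_TO_NM = 1e3


@dataclasses.dataclass(frozen=True)
class RatePair:
    """A measured association/dissociation rate pair for one ligand:receptor
    interaction.  ``k_on_per_M_s`` is in s⁻¹M⁻¹ as published; internal
    computations use nM⁻¹s⁻¹."""

    k_on_per_M_s: float
    k_off_per_s: float

    def __post_init__(self) -> None:
        if not self.k_on_per_M_s > 0:
            raise ValidationError(f"k_on must be > 0, got {self.k_on_per_M_s}")
        if not self.k_off_per_s >= 0:
            raise ValidationError(f"k_off must be >= 0, got {self.k_off_per_s}")

    @property
    def k_on_per_nM_s(self) -> float:
        return self.k_on_per_M_s * PER_M_TO_PER_NM


def rate_pair_to_kd(pair: RatePair) -> float:
    """Equilibrium dissociation constant Kd = k_off/k_on, in nM."""
    return pair.k_off_per_s / pair.k_on_per_nM_s


@dataclasses.dataclass(frozen=True)
class EquilibriumRelations:
    """Ratio relations tying the derived equilibrium constants to Ki.

    Kc = kc_over_ki * Ki   (second-site constant; 0.01 gives the affinity
                            switch after the first binding event)
    Ka = ka_over_ki * Ki   (aggregation constant; ten times Ki)
    Kp = kp_over_ki * Ki   (ligand binding the empty half of a pair; only
                            the inequality Kp > Ki is fixed by the scheme,
                            so the multiple is configurable)
    Kx = Kp / kp_over_kx   (second ligand on a paired receptor; Kp = 100 Kx)
    """

    kc_over_ki: float = 0.01
    ka_over_ki: float = 10.0
    kp_over_ki: float = 10.0
    kp_over_kx: float = 100.0

    def __post_init__(self) -> None:
        for name in ("kc_over_ki", "ka_over_ki", "kp_over_ki", "kp_over_kx"):
            if not getattr(self, name) > 0:
                raise ValidationError(f"{name} must be > 0")


@dataclasses.dataclass(frozen=True)
class Microrates:
    """The ten microscopic rate constants of the aggregation scheme.

    Bimolecular constants (k1, k3, k5, k7, k9) are in nM⁻¹s⁻¹, unimolecular
    ones (k2, k4, k6, k8, k10) in s⁻¹.  The derived dissociation constants
    are properties: Ki = k2/k1, Kc = k4/k3, Ka = k6/k5, Kx = k8/k7,
    Kp = k10/k9 (all nM).
    """

    k1: float
    k2: float
    k3: float
    k4: float
    k5: float
    k6: float
    k7: float
    k8: float
    k9: float
    k10: float

    def __post_init__(self) -> None:
        for name in ("k1", "k2", "k3", "k4", "k5", "k6", "k7", "k8", "k9", "k10"):
            if not getattr(self, name) >= 0:
                raise ValidationError(f"{name} must be >= 0")

    @property
    def ki(self) -> float:
        return self.k2 / self.k1

    @property
    def kc(self) -> float:
        return self.k4 / self.k3

    @property
    def ka(self) -> float:
        return self.k6 / self.k5

    @property
    def kx(self) -> float:
        return self.k8 / self.k7

    @property
    def kp(self) -> float:
        return self.k10 / self.k9

    def as_array(self) -> np.ndarray:
        return np.array(
            [self.k1, self.k2, self.k3, self.k4, self.k5,
             self.k6, self.k7, self.k8, self.k9, self.k10]
        )

    @classmethod
    def from_array(cls, k: Sequence[float]) -> "Microrates":
        return cls(*[float(v) for v in k])

    def replace(self, **kwargs) -> "Microrates":
        return dataclasses.replace(self, **kwargs)


def assemble_microrates(
    pair: RatePair, rel: EquilibriumRelations = EquilibriumRelations()
) -> Microrates:
    """Derive all ten microrates from a measured rate pair and the ratio
    relations.

    Only the equilibrium-constant *ratios* are fixed by the scheme; the
    kinetic anchoring chosen here pins every bimolecular on-rate to the
    ligand's published k_on and derives the off-rates so each ratio holds
    exactly (to 1e-12 relative), leaving the timescales physically anchored.
    """
    k1 = pair.k_on_per_nM_s
    k2 = pair.k_off_per_s
    ki = k2 / k1
    kc = rel.kc_over_ki * ki
    ka = rel.ka_over_ki * ki
    kp = rel.kp_over_ki * ki
    kx = kp / rel.kp_over_kx
    return Microrates(
        k1=k1, k2=k2,
        k3=k1, k4=kc * k1,
        k5=k1, k6=ka * k1,
        k7=k1, k8=kx * k1,
        k9=k1, k10=kp * k1,
    )


@dataclasses.dataclass
class Scenario:
    """One ligand:receptor simulation setup.

    ``receptor_total_nM`` is the surface receptor pool; ``ligand_total_nM``
    comes from the proteomic quantification (µM × 1000).  The initial state
    places all receptor in I and all ligand in E with no pre-formed
    complexes.
    """

    ligand: str
    receptor: str
    receptor_total_nM: float
    ligand_total_nM: float
    rates: RatePair
    relations: EquilibriumRelations = EquilibriumRelations()
    model: str = AGGREGATION
    t_end_s: float = 1e6
    rel_tol: float = 1e-9
    group: str | None = None

    def __post_init__(self) -> None:
        if not self.receptor_total_nM > 0:
            raise ValidationError("receptor_total_nM must be > 0")
        if not self.ligand_total_nM >= 0:
            raise ValidationError("ligand_total_nM must be >= 0")
        if self.model not in (DIVALENT, AGGREGATION):
            raise ConfigurationError(f"unknown model {self.model!r}")

    def microrates(self) -> Microrates:
        return assemble_microrates(self.rates, self.relations)

    def initial_state(self) -> np.ndarray:
        y0 = np.zeros(9)
        y0[_I] = self.receptor_total_nM
        y0[_E] = self.ligand_total_nM
        return y0


# ----------------------------------------------------------------------
# Right-hand sides and Jacobians
# ----------------------------------------------------------------------

def divalent_rhs(state: np.ndarray, rates: Microrates) -> np.ndarray:
    """Time derivatives of the divalent model (aggregate species inert)."""
    k = rates if isinstance(rates, np.ndarray) else rates.as_array()
    k1, k2, k3, k4 = k[0], k[1], k[2], k[3]
    I, E, Cm, Cd = state[_I], state[_E], state[_CM], state[_CD]
    d = np.zeros(9)
    d[_I] = k2 * Cm - k1 * I * E
    d[_E] = k2 * Cm - k1 * I * E + k4 * Cd - k3 * Cm * E
    d[_CM] = k1 * I * E - k2 * Cm + k4 * Cd - k3 * Cm * E
    d[_CD] = k3 * Cm * E - k4 * Cd
    return d


def _divalent_jac(y: np.ndarray, k: np.ndarray) -> np.ndarray:
    k1, k2, k3, k4 = k[0], k[1], k[2], k[3]
    I, E, Cm = y[_I], y[_E], y[_CM]
    J = np.zeros((9, 9))
    J[_I, _I] = -k1 * E
    J[_I, _E] = -k1 * I
    J[_I, _CM] = k2
    J[_E, _I] = -k1 * E
    J[_E, _E] = -k1 * I - k3 * Cm
    J[_E, _CM] = k2 - k3 * E
    J[_E, _CD] = k4
    J[_CM, _I] = k1 * E
    J[_CM, _E] = k1 * I - k3 * Cm
    J[_CM, _CM] = -k2 - k3 * E
    J[_CM, _CD] = k4
    J[_CD, _E] = k3 * Cm
    J[_CD, _CM] = k3 * E
    J[_CD, _CD] = -k4
    return J


def aggregation_rhs(
    state: np.ndarray, rates: Microrates, printed_amd_form: bool = False
) -> np.ndarray:
    """Time derivatives of the receptor-aggregation model.

    The Amd balance is implemented in the conservation-consistent mass-action
    form ``+ k8 (Add - Amd) + k7 E (Amm - Amd)``: every k7/k8 flux appearing
    here has its exact counterpart in the E and Amm/Add balances, making the
    receptor- and ligand-weighted derivative sums identically zero.
    ``printed_amd_form=True`` switches the k8 terms to carry an extra factor
    E (a published variant retained for comparison only); that variant
    demonstrably breaks receptor conservation.
    """
    k = rates if isinstance(rates, np.ndarray) else rates.as_array()
    k1, k2, k3, k4, k5, k6, k7, k8, k9, k10 = k
    I, E, Cm, Cd, Aim, Aid, Amm, Amd, Add = state[:9]
    d = np.zeros(9)
    d[_I] = k2 * Cm - k1 * I * E + k6 * (Aim + Aid) - k5 * I * (Cm + Cd)
    d[_E] = (
        k2 * Cm - k1 * I * E + k4 * Cd - k3 * Cm * E
        + k10 * (Amm + Amd) - k9 * E * (Aim + Aid)
        + k8 * (Aid + Amd + Add) - k7 * E * (Aim + Amm + Amd)
    )
    d[_CM] = k1 * I * E - k2 * Cm + k4 * Cd - k3 * Cm * E + k6 * Aim - k5 * I * Cm
    d[_CD] = k3 * Cm * E - k4 * Cd + k6 * Aid - k5 * I * Cd
    d[_AIM] = k5 * I * Cm - k6 * Aim + k10 * Amm - k9 * E * Aim + k8 * Aid - k7 * E * Aim
    d[_AID] = k5 * I * Cd - k6 * Aid + k10 * Amd - k9 * E * Aid + k7 * E * Aim - k8 * Aid
    d[_AMM] = k9 * E * Aim - k10 * Amm + k8 * Amd - k7 * E * Amm
    if printed_amd_form:
        d[_AMD] = k9 * E * Aid - k10 * Amd + k8 * E * (Add - Amd) + k7 * E * (Amm - Amd)
    else:
        d[_AMD] = k9 * E * Aid - k10 * Amd + k8 * (Add - Amd) + k7 * E * (Amm - Amd)
    d[_ADD] = k7 * E * Amd - k8 * Add
    return d


def _aggregation_jac(
    y: np.ndarray, k: np.ndarray, printed_amd_form: bool = False
) -> np.ndarray:
    k1, k2, k3, k4, k5, k6, k7, k8, k9, k10 = k
    I, E, Cm, Cd, Aim, Aid, Amm, Amd, Add = y[:9]
    J = np.zeros((9, 9))
    J[_I] = [
        -k1 * E - k5 * (Cm + Cd), -k1 * I, k2 - k5 * I, -k5 * I,
        k6, k6, 0.0, 0.0, 0.0,
    ]
    J[_E] = [
        -k1 * E,
        -k1 * I - k3 * Cm - k9 * (Aim + Aid) - k7 * (Aim + Amm + Amd),
        k2 - k3 * E, k4,
        -(k9 + k7) * E, -k9 * E + k8, k10 - k7 * E, k10 + k8 - k7 * E, k8,
    ]
    J[_CM] = [
        k1 * E - k5 * Cm, k1 * I - k3 * Cm, -k2 - k3 * E - k5 * I, k4,
        k6, 0.0, 0.0, 0.0, 0.0,
    ]
    J[_CD] = [
        -k5 * Cd, k3 * Cm, k3 * E, -k4 - k5 * I, 0.0, k6, 0.0, 0.0, 0.0,
    ]
    J[_AIM] = [
        k5 * Cm, -(k9 + k7) * Aim, k5 * I, 0.0,
        -k6 - (k9 + k7) * E, k8, k10, 0.0, 0.0,
    ]
    J[_AID] = [
        k5 * Cd, -k9 * Aid + k7 * Aim, 0.0, k5 * I,
        k7 * E, -k6 - k9 * E - k8, 0.0, k10, 0.0,
    ]
    J[_AMM] = [
        0.0, k9 * Aim - k7 * Amm, 0.0, 0.0,
        k9 * E, 0.0, -k10 - k7 * E, k8, 0.0,
    ]
    if printed_amd_form:
        J[_AMD] = [
            0.0, k9 * Aid + k8 * (Add - Amd) + k7 * (Amm - Amd), 0.0, 0.0,
            0.0, k9 * E, k7 * E, -k10 - (k8 + k7) * E, k8 * E,
        ]
    else:
        J[_AMD] = [
            0.0, k9 * Aid + k7 * (Amm - Amd), 0.0, 0.0,
            0.0, k9 * E, k7 * E, -k10 - k8 - k7 * E, k8,
        ]
    J[_ADD] = [0.0, k7 * Amd, 0.0, 0.0, 0.0, 0.0, 0.0, k7 * E, -k8]
    return J


def _rhs_for(model: str, printed_amd_form: bool = False):
    if model == DIVALENT:
        return (lambda t, y, k: divalent_rhs(y, k)), (lambda t, y, k: _divalent_jac(y, k))
    return (
        lambda t, y, k: aggregation_rhs(y, k, printed_amd_form),
        lambda t, y, k: _aggregation_jac(y, k, printed_amd_form),
    )


# ----------------------------------------------------------------------
# Trajectories
# ----------------------------------------------------------------------

@dataclasses.dataclass
class Trajectory:
    """Integrated time course: times (s), states (n_times × 9, nM) and
    solver diagnostics; carries the microrates and model used."""

    t: np.ndarray
    states: np.ndarray
    microrates: Microrates
    model: str
    scenario: Scenario | None = None
    printed_amd_form: bool = False
    diagnostics: dict = dataclasses.field(default_factory=dict)

    @property
    def final_state(self) -> np.ndarray:
        return self.states[-1]

    def receptor_total(self) -> np.ndarray:
        return self.states @ RECEPTOR_WEIGHTS

    def ligand_total(self) -> np.ndarray:
        return self.states @ LIGAND_WEIGHTS

    def conservation_error(self) -> dict[str, float]:
        """Maximum relative drift of the two conserved totals."""
        out = {}
        for name, totals in (
            ("receptor", self.receptor_total()),
            ("ligand", self.ligand_total()),
        ):
            scale = max(abs(totals[0]), 1e-300)
            out[name] = float(np.max(np.abs(totals - totals[0])) / scale)
        return out

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.states, columns=list(SPECIES))
        df.insert(0, "t_s", self.t)
        return df


def simulate(
    scenario: Scenario,
    model: str | None = None,
    t_end: float | None = None,
    microrates: Microrates | None = None,
    rtol: float = 1e-10,
    atol: float | None = None,
    t_eval: np.ndarray | None = None,
    printed_amd_form: bool = False,
    check: bool = True,
) -> Trajectory:
    """Integrate a scenario from its all-free initial state.

    Uses LSODA (adaptive, stiff-capable) with the analytic Jacobian.  The
    default absolute tolerance scales with the receptor pool so that trace
    aggregate species remain resolved.  Raises :class:`IntegrationError` on
    solver failure, negative excursions beyond tolerance, or conservation
    drift above 1e-6 relative (disable with ``check=False`` for the printed
    non-conservative Amd variant).
    """
    model = model or scenario.model
    rates = microrates if microrates is not None else scenario.microrates()
    k = rates.as_array()
    t_end = float(t_end if t_end is not None else scenario.t_end_s)
    if not t_end > 0:
        raise ConfigurationError(f"t_end must be > 0, got {t_end}")
    if atol is None:
        atol = max(scenario.receptor_total_nM * 1e-12, 1e-30)
    y0 = scenario.initial_state()
    fun, jac = _rhs_for(model, printed_amd_form)
    sol = solve_ivp(
        fun, (0.0, t_end), y0, args=(k,), method="LSODA",
        jac=jac, rtol=rtol, atol=atol, t_eval=t_eval,
    )
    if not sol.success:
        raise IntegrationError(
            f"integrator failed for {scenario.ligand}:{scenario.receptor}: {sol.message}"
        )
    states = sol.y.T
    diagnostics = {
        "n_steps": int(sol.t.size),
        "nfev": int(sol.nfev),
        "njev": int(sol.njev),
        "rtol": rtol,
        "atol": atol,
        "t_end_s": t_end,
        "method": "LSODA",
    }
    traj = Trajectory(
        t=sol.t, states=states, microrates=rates, model=model,
        scenario=scenario, printed_amd_form=printed_amd_form,
        diagnostics=diagnostics,
    )
    if check:
        neg_tol = max(1e-12, 1e-9 * atol)
        if states.min() < -neg_tol:
            raise IntegrationError(
                f"negative excursion {states.min():.3e} nM beyond tolerance"
            )
        cons = traj.conservation_error()
        diagnostics["conservation"] = cons
        if max(cons.values()) > 1e-6:
            raise IntegrationError(
                f"conservation violated along trajectory: {cons}"
            )
    else:
        diagnostics["conservation"] = traj.conservation_error()
    return traj


def steady_state(
    trajectory: Trajectory,
    rates: Microrates | None = None,
    rel_tol: float = 1e-9,
) -> tuple[np.ndarray, bool]:
    """Final state of a trajectory plus a convergence flag.

    Converged means ``max |dy/dt| / (|y| + floor) < rel_tol`` at the last
    stored point, with a floor at the integration atol so that empty species
    do not dominate the criterion.
    """
    if trajectory.t.size == 0:
        raise ValidationError("trajectory is empty")
    rates = rates or trajectory.microrates
    fun, _ = _rhs_for(trajectory.model, trajectory.printed_amd_form)
    y = trajectory.final_state
    d = fun(0.0, y, rates.as_array())
    floor = trajectory.diagnostics.get("atol", 1e-30)
    converged = bool(np.max(np.abs(d) / (np.abs(y) + floor)) < rel_tol)
    return y, converged


def solve_steady_state(
    scenario: Scenario,
    model: str | None = None,
    microrates: Microrates | None = None,
    polish: bool = True,
    t_end: float | None = None,
    max_extensions: int = 3,
) -> tuple[np.ndarray, bool]:
    """Steady state of a scenario: integrate, then polish algebraically.

    The polish solves ``rhs(y) = 0`` with the two conservation laws
    substituted for the I and E balances (Newton/hybr seeded by the ODE
    endpoint), which removes the slow terminal relaxation of trace aggregate
    species from the error budget.  If the polish fails to produce a
    non-negative machine-precision root, the integration horizon is extended
    (×100, up to ``max_extensions`` times) and the endpoint is used.
    """
    model = model or scenario.model
    rates = microrates if microrates is not None else scenario.microrates()
    t_end = float(t_end if t_end is not None else scenario.t_end_s)
    traj = simulate(scenario, model=model, t_end=t_end, microrates=rates)
    y, converged = steady_state(traj, rates, scenario.rel_tol)
    if polish:
        polished = _polish_steady_state(scenario, model, rates, y)
        if polished is not None:
            return polished, True
    for _ in range(max_extensions):
        if converged:
            break
        t_end *= 100.0
        traj = simulate(scenario, model=model, t_end=t_end, microrates=rates)
        y, converged = steady_state(traj, rates, scenario.rel_tol)
    return y, converged


def _polish_steady_state(
    scenario: Scenario, model: str, rates: Microrates, guess: np.ndarray
) -> np.ndarray | None:
    """Damped Newton on the conservation-constrained steady-state system.

    Works on the model's active species (the divalent model leaves the
    aggregate rows identically zero, which would make the full Jacobian
    singular).  Convergence is judged on the relative Newton *step*, which
    stays sensitive even when trace species sit on a slow mode whose
    absolute time derivative is already below machine noise.
    """
    k = rates.as_array()
    fun, jac = _rhs_for(model)
    R, L = scenario.receptor_total_nM, scenario.ligand_total_nM
    active = np.arange(4) if model == DIVALENT else np.arange(9)
    floor = 1e-14 * max(R, 1e-30)

    y = guess.copy()
    converged = False
    for _ in range(60):
        F = fun(0.0, y, k)
        F[_I] = RECEPTOR_WEIGHTS @ y - R
        F[_E] = LIGAND_WEIGHTS @ y - L
        J = jac(0.0, y, k)
        J[_I] = RECEPTOR_WEIGHTS
        J[_E] = LIGAND_WEIGHTS
        try:
            step = np.linalg.solve(J[np.ix_(active, active)], -F[active])
        except np.linalg.LinAlgError:
            return None
        delta = np.zeros(9)
        delta[active] = step
        # damp so no species overshoots far below zero
        lam = 1.0
        while lam > 1e-6 and np.min(y + lam * delta) < -10.0 * floor:
            lam *= 0.5
        y = y + lam * delta
        if np.max(np.abs(delta[active]) / (np.abs(y[active]) + floor)) < 1e-11:
            converged = True
            break
    if not converged or not np.isfinite(y).all() or y.min() < -10.0 * floor:
        logger.debug("steady-state polish rejected (converged=%s)", converged)
        return None
    return np.maximum(y, 0.0)


# ----------------------------------------------------------------------
# Closed-form divalent equilibrium (independent oracle)
# ----------------------------------------------------------------------

def equilibrium_divalent(
    receptor_total: float, ligand_total: float, ki: float, kc: float
) -> np.ndarray:
    """Closed-form equilibrium of the divalent model.

    Solves the detailed-balance relations ``Cm = I*E/Ki``, ``Cd = Cm*E/Kc``
    together with the receptor and ligand conservation laws by monotone
    bracketing root finding on free ligand E in [0, ligand_total].
    """
    if not (receptor_total >= 0 and ligand_total >= 0):
        raise ValidationError("totals must be >= 0")
    if not (ki > 0 and kc > 0):
        raise ValidationError("Ki and Kc must be > 0")
    y = np.zeros(9)
    if ligand_total == 0 or receptor_total == 0:
        y[_I], y[_E] = receptor_total, ligand_total
        return y

    def bound_ligand(E: float) -> tuple[float, float, float]:
        I = receptor_total / (1.0 + E / ki + E * E / (ki * kc))
        Cm = I * E / ki
        Cd = Cm * E / kc
        return I, Cm, Cd

    def f(E: float) -> float:
        _, Cm, Cd = bound_ligand(E)
        return E + Cm + 2.0 * Cd - ligand_total

    # f is strictly increasing in E, f(0) = -L < 0, f(L) >= 0
    E = brentq(f, 0.0, ligand_total, xtol=1e-300, rtol=8.9e-16, maxiter=300)
    I, Cm, Cd = bound_ligand(E)
    y[_I], y[_E], y[_CM], y[_CD] = I, E, Cm, Cd
    return y


# ----------------------------------------------------------------------
# Occupancy curves and Hill analysis
# ----------------------------------------------------------------------

def occupancy_curve(
    scenario: Scenario,
    ligand_grid: Sequence[float],
    model: str | None = None,
    method: str | None = None,
) -> pd.DataFrame:
    """Steady-state receptor occupancy across a ligand titration.

    For each grid value the scenario's total ligand is replaced and the
    steady state recomputed; reported are the fully occupied single-receptor
    fraction ``Cd / receptor_total`` and the saturated aggregate-pair
    fraction ``2*Add / receptor_total``.  ``method='analytic'`` (default for
    the divalent model) uses the closed-form equilibrium; ``'ode'`` (default
    for aggregation) integrates and polishes.
    """
    model = model or scenario.model
    if method is None:
        method = "analytic" if model == DIVALENT else "ode"
    grid = np.asarray(ligand_grid, dtype=float)
    if np.any(grid < 0):
        raise ValidationError("ligand grid values must be >= 0")
    rates = scenario.microrates()
    rows = []
    for L in grid:
        sc = dataclasses.replace(scenario, ligand_total_nM=float(L))
        if method == "analytic":
            if model != DIVALENT:
                raise ConfigurationError("analytic occupancy requires the divalent model")
            y = equilibrium_divalent(
                sc.receptor_total_nM, sc.ligand_total_nM, rates.ki, rates.kc
            )
            converged = True
        else:
            y, converged = solve_steady_state(sc, model=model, microrates=rates)
        R = sc.receptor_total_nM
        rows.append(
            {
                "ligand_nM": float(L),
                "frac_cd": float(y[_CD] / R),
                "frac_add": float(2.0 * y[_ADD] / R),
                "converged": converged,
            }
        )
    return pd.DataFrame(rows)


def hill_coefficient(
    ligand: Sequence[float],
    occupancy: Sequence[float],
    band: tuple[float, float] = (0.05, 0.95),
) -> float:
    """Hill coefficient of a binding curve by logit-slope least squares.

    Fits ``log(y/(1-y))`` against ``log(ligand)`` over the points whose
    occupancy lies strictly inside ``band``.  A value of 1 is the
    non-cooperative 1:1 reference; > 1 indicates positive cooperativity.
    """
    L = np.asarray(ligand, dtype=float)
    y = np.asarray(occupancy, dtype=float)
    mask = (y > band[0]) & (y < band[1]) & (L > 0)
    if mask.sum() < 5:
        raise ValidationError(
            f"need >= 5 points with occupancy in {band}, found {int(mask.sum())}"
        )
    x = np.log(L[mask])
    z = np.log(y[mask] / (1.0 - y[mask]))
    slope = np.polyfit(x, z, 1)[0]
    return float(slope)
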