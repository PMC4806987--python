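"""Core bioenergetic model of respiration in *Halobacterium salinarum*.

The model tracks five dependent variables — intracellular proton, ATP,
potassium and sodium concentrations, and the membrane potential ΔΨ — in a
1 mL cell suspension at OD 1. Five power-law fluxes couple them:

* ``J_ATPS``  — ATP synthase, driven by the proton motive force (pmf),
  synthesis-only (the pmf stays above the reversal point of the enzyme in
  all scenarios of interest);
* ``J_ETCP`` — proton pumping by the electron transport chain, inhibited
  exponentially by the pmf it builds;
* ``J_NaH``  — sodium–proton antiport, either electroneutral (1:1, driven
  by the difference of the Na⁺ and H⁺ gradients) or electrogenic
  (``n_NaH`` protons per sodium, driven by the free-energy imbalance);
* ``J_K``    — potassium uniport, proportional to Δμ_K⁺;
* ``J_ATPuse`` — non-vectorial ATP consumption, first order in ATP.

Sign convention: membrane fluxes are positive outward, except ``J_ATPS``
(positive = proton influx / ATP synthesis) and ``J_NaH`` (positive =
proton in, sodium out). Units are mol/L and seconds throughout; ΔΨ is in
volts and free energies Δμ in J/mol.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Callable

import numpy as np

LN10 = math.log(10.0)

EN_PARAM_NAMES = (
    "beta_ATPS",
    "gamma_ATPS_ADP",
    "beta_ETCP",
    "gamma_ETCP_pmf",
    "alpha_NaH",
    "alpha_K",
    "alpha_ATPuse",
    "beta_mempot",
)
EG_PARAM_NAMES = EN_PARAM_NAMES + ("n_NaH",)

STATE_NAMES = ("Hi", "ATP", "Ki", "Nai", "dPsi")


class DomainError(ValueError):
    """A state or parameter combination outside the model's domain."""


class ForwardOnlyWarning(UserWarning):
    """The pmf dropped below zero; the ATP synthase flux is held at zero
    instead of reversing into hydrolysis."""


@dataclass(frozen=True)
class Environment:
    """Constants of the suspension: physical constants, fixed pools and
    compartment volumes.

    ``Htot``, ``Ktot``, ``Natot`` are total ion contents of the suspension
    expressed per litre of suspension; ``a1`` is the summed cytoplasmic
    volume of all cells, ``a2`` the extracellular volume, and
    ``V_susp = a1 + a2`` the suspension volume (litres).
    """

    R: float = 8.314462          # J/mol/K
    T: float = 298.0             # K
    F: float = 96485.0           # C/mol
    Pi: float = 0.035            # mol/L
    O2: float = 0.108            # mol/L
    Atot: float = 0.0023         # mol/L, ATP + ADP
    XH: float = 5.8824e-3        # mol/L, electron donor
    ATPS_conc: float = 4.9816e-5  # mol/L
    ETCP_conc: float = 6.6422e-5  # mol/L
    Htot: float = 3.1593e-7      # mol / L suspension
    Ktot: float = 0.0251
    Natot: float = 3.7974
    a1: float = 1.36e-6          # L, total cell volume
    a2: float = 1.0e-3 - 1.36e-6  # L, extracellular volume
    V_susp: float = 1.0e-3       # L

    def __post_init__(self) -> None:
        for name in self.__dataclass_fields__:
            if getattr(self, name) <= 0:
                raise DomainError(f"Environment field {name!r} must be > 0")
        if abs(self.a1 + self.a2 - self.V_susp) > 1e-9:
            raise DomainError("a1 + a2 must equal V_susp to within 1e-9 L")

    @property
    def nernst_factor(self) -> float:
        """RT·ln(10)/F in volts (~59.1 mV per unit of pH gradient at 298 K)."""
        return self.R * self.T * LN10 / self.F


@dataclass(frozen=True)
class StateVector:
    """The five dependent variables at one instant."""

    Hi: float    # mol/L
    ATP: float   # mol/L
    Ki: float    # mol/L
    Nai: float   # mol/L
    dPsi: float  # V

    def validate(self, env: Environment) -> None:
        for name in ("Hi", "ATP", "Ki", "Nai"):
            if getattr(self, name) < 0:
                raise DomainError(f"state component {name!r} is negative")
        if self.ATP > env.Atot:
            raise DomainError("ATP exceeds the fixed ATP+ADP pool Atot")

    def as_array(self) -> np.ndarray:
        return np.array([self.Hi, self.ATP, self.Ki, self.Nai, self.dPsi])

    @classmethod
    def from_array(cls, y: np.ndarray) -> "StateVector":
        return cls(*(float(v) for v in y))


@dataclass(frozen=True)
class ModelParams:
    """Free parameters of one model variant plus fixed stoichiometries.

    ``variant`` selects the electroneutral ("EN") or electrogenic ("EG")
    antiport; only the EG variant carries the proton-per-sodium ratio
    ``n_NaH``. ``n_syn`` is the H⁺/ATP stoichiometry of the synthase and
    ``h_per_O2`` the bulk H⁺/O₂ ratio used for oxygen reconstruction.
    """

    variant: str
    beta_ATPS: float
    gamma_ATPS_ADP: float
    beta_ETCP: float
    gamma_ETCP_pmf: float
    alpha_NaH: float
    alpha_K: float
    alpha_ATPuse: float
    beta_mempot: float
    n_NaH: float | None = None
    n_syn: int = 4
    h_per_O2: float = 10.0

    def __post_init__(self) -> None:
        if self.variant not in ("EN", "EG"):
            raise DomainError(f"unknown variant {self.variant!r}")
        if self.variant == "EG" and self.n_NaH is None:
            raise DomainError("electrogenic variant requires n_NaH")
        if self.variant == "EN" and self.n_NaH is not None:
            raise DomainError("electroneutral variant carries no n_NaH")
        for name in EN_PARAM_NAMES:
            if getattr(self, name) < 0:
                raise DomainError(f"parameter {name!r} must be >= 0")
        if self.h_per_O2 <= 0:
            raise DomainError("h_per_O2 must be > 0")

    @property
    def free_names(self) -> tuple[str, ...]:
        return EG_PARAM_NAMES if self.variant == "EG" else EN_PARAM_NAMES

    @property
    def n_free(self) -> int:
        return len(self.free_names)

    def to_vector(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in self.free_names], dtype=float)

    @classmethod
    def from_vector(cls, p: np.ndarray, variant: str, n_syn: int = 4,
                    h_per_O2: float = 10.0) -> "ModelParams":
        names = EG_PARAM_NAMES if variant == "EG" else EN_PARAM_NAMES
        if len(p) != len(names):
            raise DomainError(
                f"variant {variant} expects {len(names)} parameters, got {len(p)}")
        kw = {n: float(v) for n, v in zip(names, p)}
        return cls(variant=variant, n_syn=n_syn, h_per_O2=h_per_O2, **kw)

    def with_values(self, **kw) -> "ModelParams":
        return replace(self, **kw)


@dataclass(frozen=True)
class AlgebraicState:
    """Quantities derived algebraically from a state and an environment."""

    Ho: float
    Ko: float
    Nao: float
    ADP: float
    pmf: float    # V
    dpH: float
    dpNa: float
    dpK: float
    dmuH: float   # J/mol
    dmuNa: float
    dmuK: float


@dataclass(frozen=True)
class FluxVector:
    """The five reaction fluxes, mol/(L·s)."""

    J_ATPS: float
    J_ETCP: float
    J_NaH: float
    J_K: float
    J_ATPuse: float

    def as_array(self) -> np.ndarray:
        return np.array([self.J_ATPS, self.J_ETCP, self.J_NaH,
                         self.J_K, self.J_ATPuse])


def compute_algebraic(state: StateVector, env: Environment) -> AlgebraicState:
    """Extracellular concentrations, gradients, pmf and free energies.

    Extracellular concentrations follow from conservation of each ion over
    the two compartments:  ``Xo = (Xtot·V_susp − Xi·a1)/a2``.  Gradients are
    outside-minus-inside: ``ΔpX = −log10(Xo/Xi)``, and free energies use
    ``Δμ_X = F·ΔΨ − RT·ln(10)·ΔpX`` so that moving a positive ion outward
    against a positive ΔΨ costs energy. The pmf is ``Δμ_H/F``.

    Raises :class:`DomainError`, naming the offending species, when any
    intracellular or computed extracellular concentration is non-positive
    (ion totals inconsistent with the state).
    """
    pools = {"H": (state.Hi, env.Htot), "K": (state.Ki, env.Ktot),
             "Na": (state.Nai, env.Natot)}
    outside = {}
    for species, (inside, total) in pools.items():
        if inside <= 0:
            raise DomainError(f"intracellular {species}+ concentration is non-positive")
        out = (total * env.V_susp - inside * env.a1) / env.a2
        if out <= 0:
            raise DomainError(f"extracellular {species}+ concentration is non-positive")
        outside[species] = out

    dpH = -math.log10(outside["H"] / state.Hi)
    dpK = -math.log10(outside["K"] / state.Ki)
    dpNa = -math.log10(outside["Na"] / state.Nai)
    RTln10 = env.R * env.T * LN10
    dmuH = env.F * state.dPsi - RTln10 * dpH
    dmuK = env.F * state.dPsi - RTln10 * dpK
    dmuNa = env.F * state.dPsi - RTln10 * dpNa
    return AlgebraicState(
        Ho=outside["H"], Ko=outside["K"], Nao=outside["Na"],
        ADP=env.Atot - state.ATP,
        pmf=dmuH / env.F,
        dpH=dpH, dpNa=dpNa, dpK=dpK,
        dmuH=dmuH, dmuNa=dmuNa, dmuK=dmuK,
    )


def compute_fluxes(state: StateVector, alg: AlgebraicState,
                   params: ModelParams, env: Environment) -> FluxVector:
    """Evaluate the five flux laws at one state.

    The synthase is synthesis-only: a negative pmf yields a warning and a
    zero flux rather than a reversed (hydrolysis) flux.
    """
    if alg.ADP < 0 and not float(params.gamma_ATPS_ADP).is_integer():
        raise DomainError(
            "ADP is negative with a fractional kinetic order "
            "(ATP exceeds Atot)")
    if alg.pmf < 0:
        warnings.warn("pmf < 0: holding the ATP synthase flux at zero",
                      ForwardOnlyWarning, stacklevel=2)
        J_ATPS = 0.0
    else:
        J_ATPS = params.beta_ATPS * alg.ADP ** params.gamma_ATPS_ADP * alg.pmf
    J_ETCP = params.beta_ETCP * math.exp(
        -env.F * params.gamma_ETCP_pmf * alg.pmf / (env.R * env.T))
    if params.variant == "EG":
        # Driving force: free energy released by importing n_NaH protons
        # minus the cost of exporting one sodium. At n_NaH = 1 this equals
        # RT·ln10 times the electroneutral driver (ΔpNa − ΔpH), so the two
        # variants agree on the direction of transport.
        J_NaH = params.alpha_NaH * (params.n_NaH * alg.dmuH - alg.dmuNa)
    else:
        J_NaH = params.alpha_NaH * (alg.dpNa - alg.dpH)
    J_K = params.alpha_K * alg.dmuK
    J_ATPuse = params.alpha_ATPuse * state.ATP
    return FluxVector(J_ATPS=J_ATPS, J_ETCP=J_ETCP, J_NaH=J_NaH,
                      J_K=J_K, J_ATPuse=J_ATPuse)


def rhs(t: float, state: StateVector, params: ModelParams,
        env: Environment) -> np.ndarray:
    """Right-hand side of the ODE system (autonomous; ``t`` is unused).

    Electroneutral:
        dHi/dt  = n_syn·J_ATPS + J_NaH − J_ETCP
        dΔΨ/dt  = β_mempot·(J_ETCP − n_syn·J_ATPS − J_K)
    Electrogenic:
        dHi/dt  = n_syn·J_ATPS + n_NaH·J_NaH − J_ETCP
        dΔΨ/dt  = β_mempot·(J_ETCP − n_syn·J_ATPS − J_K − (n_NaH−1)·J_NaH)
    Shared:
        dATP/dt = J_ATPS − J_ATPuse;  dKi/dt = J_K;  dNai/dt = −J_NaH.
    """
    alg = compute_algebraic(state, env)
    J = compute_fluxes(state, alg, params, env)
    n_syn = params.n_syn
    if params.variant == "EG":
        n = params.n_NaH
        dHi = n_syn * J.J_ATPS + n * J.J_NaH - J.J_ETCP
        dPsi = params.beta_mempot * (
            J.J_ETCP - n_syn * J.J_ATPS - J.J_K - (n - 1.0) * J.J_NaH)
    else:
        dHi = n_syn * J.J_ATPS + J.J_NaH - J.J_ETCP
        dPsi = params.beta_mempot * (J.J_ETCP - n_syn * J.J_ATPS - J.J_K)
    return np.array([dHi, J.J_ATPS - J.J_ATPuse, J.J_K, -J.J_NaH, dPsi])


def make_ode(params: ModelParams, env: Environment,
             guard_floor: float = 1e-300) -> Callable[[float, np.ndarray], np.ndarray]:
    """Compile a fast ``f(t, y)`` closure for the stiff solver.

    Identical mathematics to :func:`rhs` (a property test asserts this),
    but works on raw arrays, pre-binds all constants, and is exception-free
    so that wild solver trial steps can recover: concentrations (in- and
    extracellular) are floored at ``guard_floor``, ADP at zero, gradients
    are computed as differences of logarithms (no underflowing ratios) and
    the ETC exponent is capped below overflow. A negative pmf silently
    zeroes the synthase flux here; the dataclass path warns.
    """
    F, RT = env.F, env.R * env.T
    RTln10 = RT * LN10
    a1, a2 = env.a1, env.a2
    HtotV = env.Htot * env.V_susp
    KtotV = env.Ktot * env.V_susp
    NatotV = env.Natot * env.V_susp
    Atot = env.Atot
    b_ATPS, g_ADP = params.beta_ATPS, params.gamma_ATPS_ADP
    b_ETCP, g_pmf = params.beta_ETCP, params.gamma_ETCP_pmf
    a_NaH, a_K, a_use = params.alpha_NaH, params.alpha_K, params.alpha_ATPuse
    b_mem, n_syn = params.beta_mempot, float(params.n_syn)
    electrogenic = params.variant == "EG"
    n_NaH = params.n_NaH if electrogenic else 1.0

    def f(t: float, y: np.ndarray) -> np.ndarray:
        Hi = y[0] if y[0] > guard_floor else guard_floor
        ATP = min(max(y[1], 0.0), Atot)
        Ki = y[2] if y[2] > guard_floor else guard_floor
        Nai = y[3] if y[3] > guard_floor else guard_floor
        dPsi = y[4]
        Ho = max((HtotV - Hi * a1) / a2, guard_floor)
        Ko = max((KtotV - Ki * a1) / a2, guard_floor)
        Nao = max((NatotV - Nai * a1) / a2, guard_floor)
        dpH = (math.log(Hi) - math.log(Ho)) / LN10
        dpK = (math.log(Ki) - math.log(Ko)) / LN10
        dpNa = (math.log(Nai) - math.log(Nao)) / LN10
        dmuH = F * dPsi - RTln10 * dpH
        dmuK = F * dPsi - RTln10 * dpK
        dmuNa = F * dPsi - RTln10 * dpNa
        pmf = dmuH / F
        ADP_ = Atot - ATP
        J_ATPS = b_ATPS * ADP_ ** g_ADP * pmf if pmf > 0.0 else 0.0
        ex = -F * g_pmf * pmf / RT
        J_ETCP = b_ETCP * math.exp(ex if ex < 700.0 else 700.0)
        if electrogenic:
            J_NaH = a_NaH * (n_NaH * dmuH - dmuNa)
        else:
            J_NaH = a_NaH * (dpNa - dpH)
        J_K = a_K * dmuK
        dHi = n_syn * J_ATPS + n_NaH * J_NaH - J_ETCP
        dPsi_dot = b_mem * (J_ETCP - n_syn * J_ATPS - J_K
                            - (n_NaH - 1.0) * J_NaH)
        return np.array([dHi, J_ATPS - a_use * ATP, J_K, -J_NaH, dPsi_dot])

    return f


# ---------------------------------------------------------------------------
# Versioned fixtures shipped with the package
# ---------------------------------------------------------------------------

def _load_json(name: str) -> dict:
    with resources.files("haloresp.data").joinpath(name).open() as fh:
        return json.load(fh)


def load_parameter_set(name: str, n_syn: int = 4,
                       h_per_O2: float = 10.0) -> ModelParams:
    """Load a named fitted parameter set (EN1–EN5, EG1–EG5)."""
    payload = _load_json("parameter_sets.json")
    try:
        raw = dict(payload["sets"][name])
    except KeyError:
        known = ", ".join(sorted(payload["sets"]))
        raise KeyError(f"unknown parameter set {name!r}; known sets: {known}")
    raw.pop("reported_cost", None)
    variant = raw.pop("variant")
    for key, val in raw.items():
        if key not in EG_PARAM_NAMES:
            raise DomainError(f"unexpected field {key!r} in parameter fixture")
        if val < 0:
            raise DomainError(f"fixture parameter {key!r} is negative")
    return ModelParams(variant=variant, n_syn=n_syn, h_per_O2=h_per_O2, **raw)


def reported_cost(name: str) -> float:
    """Published cost-function value of a named parameter set."""
    return float(_load_json("parameter_sets.json")["sets"][name]["reported_cost"])


def parameter_set_names(variant: str | None = None) -> list[str]:
    sets = _load_json("parameter_sets.json")["sets"]
    return [n for n, s in sets.items()
            if variant is None or s["variant"] == variant]


def default_environment() -> Environment:
    env = _load_json("defaults.json")["environment"]
    return Environment(**env)


def default_initial_state() -> StateVector:
    state = _load_json("defaults.json")["initial_state"]
    return StateVector(**state)


def reference_algebraic() -> dict[str, float]:
    """Published algebraic-variable values at the default initial state."""
    return dict(_load_json("defaults.json")["reference_algebraic"])
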