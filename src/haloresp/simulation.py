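"""Stiff integration of the respiration ODEs and trajectory summaries.

The dynamics span ten decades of time: the membrane potential equilibrates
against the K⁺ Nernst potential within microseconds, the pH gradient within
~0.1 ms, ATP within seconds, and the ion pools over the hour. Trajectories
are therefore sampled on a logarithmic grid by default and a dense
interpolant is kept for arbitrary evaluation times.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import cumulative_trapezoid, solve_ivp

from .model_core import (
    Environment,
    ModelParams,
    StateVector,
    make_ode,
)
from .units_conversion import CellGeometry, convert

ALGEBRAIC_KEYS = ("Ho", "Ko", "Nao", "ADP", "pmf", "dpH", "dpNa", "dpK",
                  "dmuH", "dmuNa", "dmuK")
FLUX_KEYS = ("J_ATPS", "J_ETCP", "J_NaH", "J_K", "J_ATPuse")


class IntegrationError(RuntimeError):
    """The stiff solver failed before reaching the end of the time span."""


class IntegrityError(RuntimeError):
    """The computed trajectory violates a model invariant beyond tolerance."""


def default_time_grid(t_start: float, t_end: float, n: int = 400,
                      t_min: float = 1e-8,
                      extra: np.ndarray | None = None) -> np.ndarray:
    """Log-spaced output grid from ``max(t_start, t_min)`` to ``t_end``,
    prepended with ``t_start`` and merged with any user times."""
    lo = max(t_start, t_min)
    grid = np.geomspace(lo, t_end, n)
    pts = [np.array([t_start]), grid]
    if extra is not None:
        pts.append(np.asarray(extra, dtype=float))
    out = np.unique(np.concatenate(pts))
    out = out[(out >= t_start) & (out <= t_end)]
    # geomspace end point can overshoot t_end by one ulp
    out[-1] = min(out[-1], t_end)
    return out


def algebraics_from_arrays(Y: np.ndarray, env: Environment) -> dict[str, np.ndarray]:
    """Vectorized algebraic variables for a (5, N) state array."""
    Hi, ATP, Ki, Nai, dPsi = Y
    Ho = (env.Htot * env.V_susp - Hi * env.a1) / env.a2
    Ko = (env.Ktot * env.V_susp - Ki * env.a1) / env.a2
    Nao = (env.Natot * env.V_susp - Nai * env.a1) / env.a2
    with np.errstate(divide="ignore", invalid="ignore"):
        dpH = (np.log(Hi) - np.log(Ho)) / math.log(10.0)
        dpK = (np.log(Ki) - np.log(Ko)) / math.log(10.0)
        dpNa = (np.log(Nai) - np.log(Nao)) / math.log(10.0)
    RTln10 = env.R * env.T * math.log(10.0)
    dmuH = env.F * dPsi - RTln10 * dpH
    dmuK = env.F * dPsi - RTln10 * dpK
    dmuNa = env.F * dPsi - RTln10 * dpNa
    return {"Ho": Ho, "Ko": Ko, "Nao": Nao, "ADP": env.Atot - ATP,
            "pmf": dmuH / env.F, "dpH": dpH, "dpNa": dpNa, "dpK": dpK,
            "dmuH": dmuH, "dmuNa": dmuNa, "dmuK": dmuK}


def fluxes_from_arrays(Y: np.ndarray, alg: dict[str, np.ndarray],
                       params: ModelParams, env: Environment) -> dict[str, np.ndarray]:
    """Vectorized flux laws for a (5, N) state array."""
    pmf = alg["pmf"]
    ADP = np.maximum(alg["ADP"], 0.0)
    J_ATPS = np.where(pmf > 0,
                      params.beta_ATPS * ADP ** params.gamma_ATPS_ADP * pmf,
                      0.0)
    J_ETCP = params.beta_ETCP * np.exp(
        -env.F * params.gamma_ETCP_pmf * pmf / (env.R * env.T))
    if params.variant == "EG":
        J_NaH = params.alpha_NaH * (params.n_NaH * alg["dmuH"] - alg["dmuNa"])
    else:
        J_NaH = params.alpha_NaH * (alg["dpNa"] - alg["dpH"])
    return {"J_ATPS": J_ATPS, "J_ETCP": J_ETCP, "J_NaH": J_NaH,
            "J_K": params.alpha_K * alg["dmuK"],
            "J_ATPuse": params.alpha_ATPuse * Y[1]}


@dataclass
class TimeCourse:
    """A solved trajectory: states, algebraic variables and fluxes on the
    output grid, plus the dense interpolant for arbitrary times."""

    times: np.ndarray                 # (N,), s
    states: np.ndarray                # (5, N)
    algebraics: dict[str, np.ndarray]
    fluxes: dict[str, np.ndarray]
    params: ModelParams
    env: Environment
    rtol: float
    atol: float
    sol: object = field(default=None, repr=False)  # scipy OdeSolution or None

    def state_at(self, t: float) -> np.ndarray:
        """Dense-output state (5,) at time ``t``; clamps tiny negatives."""
        if self.sol is None:
            idx = int(np.searchsorted(self.times, t))
            if not np.isclose(self.times[min(idx, len(self.times) - 1)], t):
                raise ValueError("no dense output; t must be a grid point")
            return self.states[:, min(idx, len(self.times) - 1)]
        y = np.asarray(self.sol(t), dtype=float)
        return _clamp_states(y.reshape(5, -1), self.atol).ravel()

    def pmf_at(self, t: float) -> float:
        y = self.state_at(t).reshape(5, 1)
        return float(algebraics_from_arrays(y, self.env)["pmf"][0])

    def to_frame(self):
        """Long-form table (one row per sample) with states, extracellular
        concentrations, pmf and fluxes — the CSV schema of the CLI."""
        import pandas as pd

        data = {"t_s": self.times}
        for i, name in enumerate(("Hi", "ATP", "Ki", "Nai", "dPsi")):
            data[name] = self.states[i]
        for key in ("Ho", "Ko", "Nao", "pmf", "dpH"):
            data[key] = self.algebraics[key]
        for key in FLUX_KEYS:
            data[key] = self.fluxes[key]
        data["O2_cum"] = oxygen_consumed(self).O2_molar
        return pd.DataFrame(data)


@dataclass(frozen=True)
class TrajectorySummary:
    """Headline numbers of one trajectory (see :func:`summarize`)."""

    ATP_max: float            # mol/L
    t_ATP_max: float          # s
    pmf_max: float            # V
    dPsi_max: float           # V
    steady_state: dict        # state + algebraics at the steady horizon
    fraction_of_steady: dict  # {"pmf","dPsi","dpH58"} -> value(short)/value(steady)


def _clamp_states(Y: np.ndarray, atol: float) -> np.ndarray:
    """Abort on concentrations below −atol; clamp (−atol, 0) to +0."""
    conc = Y[:4]
    if np.any(conc < -atol):
        worst = float(conc.min())
        raise IntegrityError(
            f"solver produced a concentration of {worst:.3e} (< -atol)")
    Y = Y.copy()
    Y[:4] = np.maximum(conc, 0.0)
    return Y


class _BudgetExceeded(Exception):
    pass


def simulate(params: ModelParams, env: Environment, initial: StateVector,
             t_span: tuple[float, float] = (0.0, 3600.0),
             t_eval: np.ndarray | None = None,
             rtol: float = 1e-6, atol: float = 1e-8,
             dense_output: bool = True,
             invariant_check: bool = True,
             max_nfev: int = 200_000) -> TimeCourse:
    """Integrate one model variant with a stiff implicit solver.

    Defaults follow the reference numerical setup: relative tolerance 1e-6,
    absolute tolerance 1e-8, and a 400-point logarithmic output grid from
    1e-8 s. LSODA is tried first; on failure the integration is retried
    with Radau and BDF before an :class:`IntegrationError` is raised.
    ``max_nfev`` caps right-hand-side evaluations per solver attempt so
    that a pathological parameter vector (during fitting) fails fast
    instead of stalling.
    """
    t0, t1 = float(t_span[0]), float(t_span[1])
    if not t0 < t1:
        raise ValueError("t_span must satisfy t_span[0] < t_span[1]")
    if rtol <= 0 or atol <= 0:
        raise ValueError("rtol and atol must be positive")
    initial.validate(env)
    if t_eval is None:
        t_eval = default_time_grid(t0, t1)
    else:
        t_eval = np.asarray(t_eval, dtype=float)

    f_raw = make_ode(params, env)
    last_message = ""
    for method in ("LSODA", "Radau", "BDF"):
        calls = 0

        def f(t, y):
            nonlocal calls
            calls += 1
            if calls > max_nfev:
                raise _BudgetExceeded
            return f_raw(t, y)

        try:
            res = solve_ivp(f, (t0, t1), initial.as_array(), method=method,
                            rtol=rtol, atol=atol, t_eval=t_eval,
                            dense_output=dense_output)
        except _BudgetExceeded:
            last_message = f"{method}: exceeded {max_nfev} rhs evaluations"
            continue
        if res.status == 0 and np.all(np.isfinite(res.y)):
            break
        last_message = (f"{method}: {res.message or 'non-finite output'} "
                        f"(last t = {res.t[-1] if len(res.t) else t0:.6g})")
    else:
        raise IntegrationError(f"stiff solvers failed; {last_message}")

    Y = _clamp_states(res.y, atol)
    alg = algebraics_from_arrays(Y, env)
    if invariant_check:
        _check_invariants(Y, alg, env, rtol)
    fluxes = fluxes_from_arrays(Y, alg, params, env)
    return TimeCourse(times=res.t, states=Y, algebraics=alg, fluxes=fluxes,
                      params=params, env=env, rtol=rtol, atol=atol,
                      sol=res.sol if dense_output else None)


def _check_invariants(Y: np.ndarray, alg: dict, env: Environment,
                      rtol: float) -> None:
    tol = 100.0 * rtol
    if np.any(Y[1] > env.Atot * (1.0 + tol)):
        raise IntegrityError("ATP exceeded the fixed nucleotide pool Atot")
    # compartment conservation is structural (Xo computed from Xi), so the
    # meaningful check is that no pool over-drained its suspension total
    for i, (key, total) in enumerate((("Ho", env.Htot), ("Ko", env.Ktot),
                                      ("Nao", env.Natot)), start=0):
        if np.any(alg[key] < -tol * total):
            raise IntegrityError(f"{key} dropped below zero beyond tolerance")


def summarize(tc: TimeCourse, short_horizon: float = 1e-4,
              steady_horizon: float = 18000.0,
              n_fine: int = 4000) -> TrajectorySummary:
    """Trajectory summary: ATP maximum and its attainment time, maxima of
    pmf and ΔΨ, the state at the steady horizon, and the fraction of the
    steady value reached at ``short_horizon`` for pmf, ΔΨ and the pH
    gradient expressed in volts (the "58ΔpH" curve, computed with the
    exact RT·ln10/F factor).

    Attainment time of the ATP maximum: the argmax when the trajectory has
    an interior maximum; for a monotone rise, the first time ATP reaches
    99.9 % of its quasi-steady plateau J_ATPS/α_ATPuse (the level at which
    synthesis balances consumption). The end-of-horizon value is not used
    as the plateau because ATP keeps creeping by a few per-mille as the
    ion gradients relax over hours, which would push the crossing time
    into that slow phase.
    """
    t_lo, t_hi = float(tc.times[0]), float(tc.times[-1])
    if not (t_lo <= short_horizon <= t_hi and t_lo <= steady_horizon <= t_hi):
        raise ValueError("horizons must lie within the trajectory time range")
    if tc.sol is not None:
        tt = default_time_grid(t_lo, t_hi, n=n_fine)
        Y = _clamp_states(np.asarray(tc.sol(tt)), tc.atol)
    else:
        tt, Y = tc.times, tc.states
    alg = algebraics_from_arrays(Y, tc.env)
    fl = fluxes_from_arrays(Y, alg, tc.params, tc.env)

    ATP = Y[1]
    i_max = int(ATP.argmax())
    ATP_max = float(ATP[i_max])
    interior = i_max < len(tt) - 1 and ATP_max > ATP[-1] * (1.0 + 1e-6)
    if interior:
        t_ATP_max = float(tt[i_max])
    elif tc.params.alpha_ATPuse > 0:
        plateau = fl["J_ATPS"] / tc.params.alpha_ATPuse
        reached = np.nonzero(ATP >= 0.999 * plateau)[0]
        # skip t = t_start where both sides start at their initial ratio
        reached = reached[tt[reached] > t_lo]
        t_ATP_max = float(tt[reached[0]]) if len(reached) else float(tt[-1])
    else:
        t_ATP_max = t_lo

    def at(t: float, series: np.ndarray) -> float:
        return float(np.interp(t, tt, series))

    pmf = alg["pmf"]
    dpH58 = -tc.env.nernst_factor * alg["dpH"]  # pH-gradient term in volts
    fractions = {}
    for key, series in (("pmf", pmf), ("dPsi", Y[4]), ("dpH58", dpH58)):
        steady = at(steady_horizon, series)
        fractions[key] = at(short_horizon, series) / steady if steady != 0 else math.nan

    j = int(np.searchsorted(tt, steady_horizon))
    j = min(j, len(tt) - 1)
    steady_state = {name: float(Y[i, j]) for i, name in
                    enumerate(("Hi", "ATP", "Ki", "Nai", "dPsi"))}
    steady_state.update({k: float(v[j]) for k, v in alg.items()})

    return TrajectorySummary(
        ATP_max=ATP_max, t_ATP_max=t_ATP_max,
        pmf_max=float(pmf.max()), dPsi_max=float(Y[4].max()),
        steady_state=steady_state, fraction_of_steady=fractions)


@dataclass(frozen=True)
class OxygenSeries:
    """Cumulative consumed oxygen reconstructed from the ETC proton flux."""

    times: np.ndarray
    O2_molar: np.ndarray                    # mol O2 / L, cumulative
    O2_nmol_per_mg: np.ndarray | None = None


def oxygen_consumed(tc: TimeCourse, h_per_O2: float | None = None,
                    geometry: CellGeometry | None = None) -> OxygenSeries:
    """Cumulative O₂ consumption: ∫ J_ETCP dt divided by the H⁺/O₂ ratio.

    The integral is trapezoidal on the trajectory grid, starts at zero and
    is nondecreasing (J_ETCP > 0). With a :class:`CellGeometry` the series
    is also expressed as nmol O₂ per mg protein via the cell-water pivot.
    """
    if h_per_O2 is None:
        h_per_O2 = tc.params.h_per_O2
    if h_per_O2 <= 0:
        raise ValueError("h_per_O2 must be > 0")
    cum = cumulative_trapezoid(tc.fluxes["J_ETCP"], tc.times, initial=0.0)
    O2 = cum / h_per_O2
    per_mg = None
    if geometry is not None:
        per_mg = np.array([
            convert(v, "mol/L_cell_water", "nmol/mg_protein", geometry)
            for v in O2])
    return OxygenSeries(times=tc.times, O2_molar=O2, O2_nmol_per_mg=per_mg)
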