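"""Parameter estimation against the built-in ion time-course dataset.

The observation set mirrors the published experiments: sparse K⁺ and Na⁺
time courses over one hour, plus two steady-state scalars (ATP and pmf)
compared at ``t_final``. The cost is a normalized sum of squares for the
time courses plus weighted absolute relative errors for the scalars:

    J(p) = (1/N_K)·Σ(K_d−K_m)²/ΣK_d² + (1/N_Na)·Σ(Na_d−Na_m)²/ΣNa_d²
         + w_ATP·|ATP_d−ATP_m(t_f)|/ATP_d + w_pmf·|pmf_d−pmf_m(t_f)|/pmf_d

subject to the ODE model. Unit harmonization happens at the I/O boundary:
ion values in mmol/L become mol/L, the pmf datum mV → V, and the ATP datum
(mmol per kg cell water) is mapped to the model's mol/L-of-cell-volume
scale through the cell-water/cell-volume ratio (0.80/1.36 per OD·mL).

Two derivative-free optimizers are provided: Nelder–Mead simplex and a
seeded simulated-annealing scheme with geometric cooling, matching the
published staged strategy (anneal from a vector of ones; refine a manual
guess by simplex and by annealing; final annealing pass on the simplex
result).
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field, replace
from importlib import resources

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .model_core import (
    DomainError,
    Environment,
    ModelParams,
    StateVector,
    default_environment,
    default_initial_state,
    load_parameter_set,
)
from .simulation import IntegrationError, IntegrityError, simulate
from .units_conversion import CellGeometry, default_geometry

ATP_DATA_UNIT = "mmol/kg_cell_water"


def atp_datum_to_model_units(value_mmol_per_kg: float,
                             geometry: CellGeometry | None = None) -> float:
    """Map an ATP measurement in mmol per kg cell water onto the model's
    mol/L-of-cell-volume scale (water density 1 kg/L)."""
    if geometry is None:
        geometry = default_geometry()
    ratio = geometry.cell_water_per_ODmL / geometry.cell_volume_per_ODmL
    return value_mmol_per_kg * 1e-3 * ratio


@dataclass(frozen=True)
class FitDataset:
    """Observation set: ion time courses plus steady-state ATP and pmf.

    Times in seconds, concentrations in mol/L (model units), pmf in volts.
    """

    K_times: np.ndarray
    K_values: np.ndarray
    Na_times: np.ndarray
    Na_values: np.ndarray
    ss_ATP: float
    ss_pmf: float
    t_final: float = 3600.0

    def __post_init__(self) -> None:
        for name in ("K", "Na"):
            t = np.asarray(getattr(self, f"{name}_times"), dtype=float)
            v = np.asarray(getattr(self, f"{name}_values"), dtype=float)
            object.__setattr__(self, f"{name}_times", t)
            object.__setattr__(self, f"{name}_values", v)
            if len(t) != len(v) or len(t) < 1:
                raise ValueError(f"{name} series must have >= 1 matching points")
            if np.any(t < 0) or np.any(np.diff(t) <= 0):
                raise ValueError(f"{name} times must be nonnegative and increasing")
        if self.ss_ATP <= 0 or self.ss_pmf <= 0 or self.t_final <= 0:
            raise ValueError("steady-state values and t_final must be > 0")

    @property
    def N_K(self) -> int:
        return len(self.K_times)

    @property
    def N_Na(self) -> int:
        return len(self.Na_times)

    def to_csv(self, path) -> None:
        """Write the dataset in the fixture CSV schema (minutes / mmol/L,
        steady-state scalars in comment headers)."""
        lines = [
            "# haloresp dataset, version 1.0",
            f"# steady_state_ATP_mmol_per_kg_cell_water: "
            f"{self.ss_ATP / atp_datum_to_model_units(1.0):.10g}",
            f"# steady_state_pmf_mV: {self.ss_pmf * 1e3:.10g}",
            f"# t_final_s: {self.t_final:.10g}",
            "time_min,K_mmol_per_L,Na_mmol_per_L",
        ]
        na_map = dict(zip(self.Na_times, self.Na_values))
        for t, k in zip(self.K_times, self.K_values):
            na = na_map.get(t)
            na_s = f"{na * 1e3:.10g}" if na is not None else "NA"
            lines.append(f"{t / 60.0:.10g},{k * 1e3:.10g},{na_s}")
        for t in self.Na_times:  # Na-only times, if any
            if t not in set(self.K_times):
                lines.append(f"{t / 60.0:.10g},NA,{na_map[t] * 1e3:.10g}")
        with open(path, "w") as fh:
            fh.write("\n".join(lines) + "\n")

    @classmethod
    def from_csv(cls, source) -> "FitDataset":
        """Read a dataset CSV in the fixture schema."""
        if hasattr(source, "read"):
            text = source.read()
        else:
            with open(source) as fh:
                text = fh.read()
        meta = {}
        for line in text.splitlines():
            if line.startswith("#") and ":" in line:
                key, _, val = line.lstrip("# ").partition(":")
                try:
                    meta[key.strip()] = float(val)
                except ValueError:
                    pass
        df = pd.read_csv(io.StringIO(text), comment="#",
                         na_values=["NA"], skip_blank_lines=True)
        required = {"time_min", "K_mmol_per_L", "Na_mmol_per_L"}
        if not required.issubset(df.columns):
            raise ValueError(f"dataset CSV must have columns {sorted(required)}")
        t = df["time_min"].to_numpy() * 60.0
        k_mask = df["K_mmol_per_L"].notna().to_numpy()
        na_mask = df["Na_mmol_per_L"].notna().to_numpy()
        return cls(
            K_times=t[k_mask], K_values=df["K_mmol_per_L"].to_numpy()[k_mask] * 1e-3,
            Na_times=t[na_mask], Na_values=df["Na_mmol_per_L"].to_numpy()[na_mask] * 1e-3,
            ss_ATP=atp_datum_to_model_units(
                meta["steady_state_ATP_mmol_per_kg_cell_water"]),
            ss_pmf=meta["steady_state_pmf_mV"] * 1e-3,
            t_final=meta.get("t_final_s", 3600.0),
        )


def load_ion_dataset() -> FitDataset:
    """The built-in K⁺/Na⁺ time-course fixture (one missing Na value at
    40 min is dropped, so N_Na = 5)."""
    with resources.files("haloresp.data").joinpath("ion_timecourse.csv").open() as fh:
        return FitDataset.from_csv(fh)


@dataclass
class FitConfig:
    """Optimization settings (weights, solver/optimizer tolerances, seed)."""

    variant: str = "EN"
    w_ATP: float = 10.0
    w_pmf: float = 0.5
    rtol: float = 1e-6
    atol: float = 1e-8
    optimizer: str = "nelder_mead"     # or "simulated_annealing"
    opt_tol: float = 1e-6
    max_iter: int | None = None        # optimizer-specific cap
    seed: int | None = None
    p0: np.ndarray | None = None
    penalty: float = 1e6
    # rhs-evaluation budget per solver attempt inside one cost evaluation;
    # legitimate parameter sets need a few thousand, so this only truncates
    # pathological corners of parameter space (which score the penalty)
    max_nfev: int = 20_000
    # simulated-annealing schedule
    sa_T0: float = 1.0
    sa_cooling: float = 0.95
    sa_n_per_temp: int = 50
    sa_stop_T: float = 1e-6
    sa_proposal_scale: float = 0.1

    def __post_init__(self) -> None:
        if self.w_ATP <= 0 or self.w_pmf <= 0:
            raise ValueError("weights must be > 0")
        if self.variant not in ("EN", "EG"):
            raise ValueError("variant must be 'EN' or 'EG'")

    @property
    def n_params(self) -> int:
        return 9 if self.variant == "EG" else 8


def cost_terms(K_model: np.ndarray, Na_model: np.ndarray, ATP_model: float,
               pmf_model: float, dataset: FitDataset,
               config: FitConfig) -> dict[str, float]:
    """The four cost terms from model values at the data times."""
    K_d, Na_d = dataset.K_values, dataset.Na_values
    terms = {
        "K": float(np.sum((K_d - K_model) ** 2) / np.sum(K_d ** 2) / dataset.N_K),
        "Na": float(np.sum((Na_d - Na_model) ** 2) / np.sum(Na_d ** 2) / dataset.N_Na),
        "ATP": config.w_ATP * abs(dataset.ss_ATP - ATP_model) / dataset.ss_ATP,
        "pmf": config.w_pmf * abs(dataset.ss_pmf - pmf_model) / dataset.ss_pmf,
    }
    terms["total"] = sum(terms.values())
    return terms


def evaluate_model(params: ModelParams, dataset: FitDataset,
                   config: FitConfig, env: Environment,
                   initial: StateVector):
    """Simulate and extract (K_model, Na_model, ATP(t_f), pmf(t_f))."""
    t_eval = np.unique(np.concatenate(
        [[0.0], dataset.K_times, dataset.Na_times, [dataset.t_final]]))
    tc = simulate(params, env, initial,
                  t_span=(0.0, float(t_eval[-1])), t_eval=t_eval,
                  rtol=config.rtol, atol=config.atol, dense_output=False,
                  max_nfev=config.max_nfev)
    idx = {t: i for i, t in enumerate(tc.times)}
    K_m = tc.states[2, [idx[t] for t in dataset.K_times]]
    Na_m = tc.states[3, [idx[t] for t in dataset.Na_times]]
    j = idx[dataset.t_final]
    return K_m, Na_m, float(tc.states[1, j]), float(tc.algebraics["pmf"][j])


def cost(p: np.ndarray, dataset: FitDataset, config: FitConfig,
         env: Environment | None = None,
         initial: StateVector | None = None) -> float:
    """Eq-style cost of a free-parameter vector; infeasible vectors
    (solver failure, domain error, non-finite output) return the finite
    penalty so simplex methods can retreat."""
    p = np.asarray(p, dtype=float)
    if len(p) != config.n_params:
        raise ValueError(
            f"variant {config.variant} expects {config.n_params} parameters, "
            f"got {len(p)}")
    if not np.all(np.isfinite(p)):
        return config.penalty
    env = env or default_environment()
    initial = initial or default_initial_state()
    try:
        params = ModelParams.from_vector(np.abs(p), config.variant)
        K_m, Na_m, ATP_m, pmf_m = evaluate_model(
            params, dataset, config, env, initial)
    except (DomainError, IntegrationError, IntegrityError, ValueError,
            FloatingPointError, OverflowError):
        return config.penalty
    values = np.concatenate([K_m, Na_m, [ATP_m, pmf_m]])
    if not np.all(np.isfinite(values)):
        return config.penalty
    return cost_terms(K_m, Na_m, ATP_m, pmf_m, dataset, config)["total"]


@dataclass
class FitResult:
    p: np.ndarray
    cost: float
    trace: np.ndarray          # best-so-far cost after each evaluation
    n_evaluations: int
    optimizer: str
    seed: int | None = None
    stages: dict = field(default_factory=dict)


def _nelder_mead(fun, p0, config: FitConfig) -> FitResult:
    history = []

    def wrapped(p):
        val = fun(p)
        history.append(val)
        return val

    maxiter = config.max_iter
    res = minimize(wrapped, p0, method="Nelder-Mead",
                   options={"xatol": config.opt_tol, "fatol": config.opt_tol,
                            **({"maxiter": maxiter, "maxfev": maxiter}
                               if maxiter else {})})
    trace = np.minimum.accumulate(history)
    return FitResult(p=np.abs(res.x), cost=float(res.fun), trace=trace,
                     n_evaluations=len(history), optimizer="nelder_mead")


def _simulated_annealing(fun, p0, config: FitConfig) -> FitResult:
    if config.seed is None:
        raise ValueError("simulated annealing requires a seed")
    rng = np.random.default_rng(config.seed)
    p_cur = np.asarray(p0, dtype=float).copy()
    J_cur = fun(p_cur)
    if not math.isfinite(J_cur):
        raise ValueError("cost at the initial guess is not finite")
    p_best, J_best = p_cur.copy(), J_cur
    trace = [J_best]
    n_eval = 1
    T = config.sa_T0
    max_eval = config.max_iter or math.inf
    while T > config.sa_stop_T and n_eval < max_eval:
        for _ in range(config.sa_n_per_temp):
            # step size annealed with temperature so late proposals refine
            step = rng.standard_normal(len(p_cur)) * (
                config.sa_proposal_scale * np.abs(p_cur) * math.sqrt(T)
                + 1e-8)
            p_prop = p_cur + step
            J_prop = fun(p_prop)
            n_eval += 1
            if J_prop < J_cur or rng.random() < math.exp(
                    -min((J_prop - J_cur) / T, 700.0)):
                p_cur, J_cur = p_prop, J_prop
                if J_cur < J_best:
                    p_best, J_best = p_cur.copy(), J_cur
            trace.append(J_best)
            if n_eval >= max_eval:
                break
        T *= config.sa_cooling
    return FitResult(p=np.abs(p_best), cost=float(J_best),
                     trace=np.asarray(trace), n_evaluations=n_eval,
                     optimizer="simulated_annealing", seed=config.seed)


def optimize(fun, config: FitConfig, p0: np.ndarray | None = None) -> FitResult:
    """Minimize an arbitrary cost callable from ``p0`` with the configured
    optimizer. The returned trace is the best-so-far cost, nonincreasing
    by construction."""
    p0 = np.asarray(p0 if p0 is not None else config.p0, dtype=float)
    if p0 is None or p0.ndim != 1:
        raise ValueError("an initial parameter vector p0 is required")
    val0 = fun(p0)
    if not math.isfinite(val0):
        raise ValueError("cost at the initial guess is not finite")
    if config.optimizer == "nelder_mead":
        return _nelder_mead(fun, p0, config)
    if config.optimizer == "simulated_annealing":
        return _simulated_annealing(fun, p0, config)
    raise ValueError(f"unknown optimizer {config.optimizer!r}")


def fit(dataset: FitDataset, config: FitConfig,
        env: Environment | None = None,
        initial: StateVector | None = None,
        p0: np.ndarray | None = None) -> FitResult:
    """Fit one model variant to a dataset (thin wrapper binding
    :func:`cost` to :func:`optimize`)."""
    env = env or default_environment()
    initial = initial or default_initial_state()

    def fun(p):
        return cost(p, dataset, config, env, initial)

    return optimize(fun, config, p0=p0)


def staged_fit(variant: str, dataset: FitDataset, config: FitConfig,
               env: Environment | None = None,
               initial: StateVector | None = None,
               stage2_guess: np.ndarray | None = None,
               select: str = "by_cost") -> dict:
    """The published five-stage estimation pipeline.

    Stage 1: simulated annealing from a vector of ones.
    Stage 2: an externally supplied guess (the published manual search
             result EN2/EG2 by default).
    Stage 3: Nelder–Mead refinement of stage 2.
    Stage 4: simulated annealing from stage 2.
    Stage 5: simulated annealing from the stage-3 result.

    Returns every stage's parameter vector and cost. ``select`` picks the
    reported set: "by_cost" (lowest cost) or "final" (the stage-5 result,
    mirroring the published qualitative choice of the last refinement).
    """
    env = env or default_environment()
    initial = initial or default_initial_state()
    config = replace(config, variant=variant)
    if stage2_guess is None:
        stage2_guess = load_parameter_set(
            "EG2" if variant == "EG" else "EN2").to_vector()

    def fun(p):
        return cost(p, dataset, config, env, initial)

    sa = replace(config, optimizer="simulated_annealing")
    nm = replace(config, optimizer="nelder_mead")

    stages: dict[str, FitResult] = {}
    ones = np.ones(config.n_params)
    stages["stage1_anneal_from_ones"] = optimize(fun, sa, p0=ones)
    stages["stage2_manual_guess"] = FitResult(
        p=np.asarray(stage2_guess, float), cost=fun(stage2_guess),
        trace=np.array([fun(stage2_guess)]), n_evaluations=1,
        optimizer="fixture")
    stages["stage3_simplex_refinement"] = optimize(fun, nm, p0=stage2_guess)
    stages["stage4_anneal_refinement"] = optimize(fun, sa, p0=stage2_guess)
    stages["stage5_final_anneal"] = optimize(
        fun, sa, p0=stages["stage3_simplex_refinement"].p)

    if select == "final":
        best_name = "stage5_final_anneal"
    else:
        best_name = min(stages, key=lambda k: stages[k].cost)
    return {"stages": stages, "selected": best_name,
            "selected_result": stages[best_name]}
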