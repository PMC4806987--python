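# Methods note

This note records the model conventions, the numerical choices, and the
design decisions taken where the problem was genuinely open — including
the places where our faithful recomputation disagrees with previously
reported numbers and why we believe our values.

## Model and compartments

The system models a 1 mL suspension of *H. salinarum* at OD 1 in the
dark: five dependent variables ([H⁺ᵢ], [ATP], [K⁺ᵢ], [Na⁺ᵢ], ΔΨ), fixed
pools (Pi, O₂, electron donor, enzyme concentrations, A_tot = ATP+ADP),
and ion totals H_tot/K_tot/Na_tot expressed per litre of suspension.
Extracellular concentrations follow algebraically from conservation:
Xo = (X_tot·V − Xᵢ·a₁)/a₂ with a₁ = 1.36 μL the summed cytoplasmic
volume, a₂ = V − a₁, V = 1 mL. This volume split is the only one that
reproduces the reference extracellular values ([H⁺ₒ] = 3.1623e-7,
[K⁺ₒ] = 2.2e-2, [Na⁺ₒ] = 3.8 mol/L) from the intracellular initial
state, which is why the ion totals are interpreted as "total moles per
suspension volume".

Assumptions inherited from the model class: no enzyme saturation
(power-law kinetics throughout), no synthase reversal, no ion leaks,
ionophores or light-driven pumps, no cytoplasmic buffering, constant
enzyme and substrate pools over the ≤1 h horizon.

## Bioenergetic algebra and the ln(10) convention

Gradients are outside-minus-inside: ΔpX = −log10(Xo/Xᵢ). Free energies
and the pmf use

    Δμ_X = F·ΔΨ − RT·ln(10)·ΔpX,      pmf = Δμ_H / F,

at T = 298 K (RT·ln10/F ≈ 59.13 mV per pH unit). Back-solving the
reference initial state fixes this convention: ΔΨ = 0.08 V and
ΔpH = −0.5 give pmf = 0.10956 V only with the ln(10) factor. The
reference table's printed Δμ values are internally inconsistent with its
own pmf at the ~6e-5 relative level (e.g. Δμ_Na prints 9.4368e3 where
the stated constants give 9.4362e3); tests therefore assert agreement at
rtol 2e-4 ("four significant figures") rather than to the last printed
digit.

"58ΔpH" — the pH gradient expressed in millivolts — is computed with the
exact RT·ln10/F factor, not the rounded 58.

## Sign conventions and the electrogenic antiport driver

Membrane fluxes are positive outward, except J_ATPS (positive = proton
influx/ATP synthesis) and J_NaH (positive = proton in, sodium out). The
potassium flux enters d[K⁺ᵢ]/dt with a positive sign, so J_K < 0 at the
initial state transiently means K⁺ efflux until ΔΨ exceeds the K⁺ Nernst
potential — counterintuitive but kept literal.

The electroneutral antiport driver (ΔpNa − ΔpH) is identically
(Δμ_H − Δμ_Na)/(RT·ln10). The electrogenic generalisation is therefore

    J_NaH = α_NaH · (n_NaH·Δμ_H − Δμ_Na),

the free energy gained by importing n_NaH protons minus the cost of
exporting one sodium. The opposite sign, α(Δμ_Na − n·Δμ_H), is sometimes
written, but it makes the proton equation positively self-coupled: an
antiport proton influx lowers Δμ_H, which *increases* the flux again, and
the trajectory runs [H⁺ᵢ] into the proton-conservation cap within ~1e-7 s
where the system becomes singular (we verified this with three stiff
solvers and an analytic Jacobian — none can integrate past the runaway).
With the thermodynamically consistent driver the electrogenic model at
its published best-fit parameters reproduces the reported behaviour: a
higher pmf ceiling than the electroneutral model, 92% of the steady pmf
reached by 1e-4 s, and the same steady ATP level — so this is also the
form the original results must have been computed from. At the EG1
stoichiometry n_NaH = 0.76 the antiport sits below its reversal ratio
Δμ_Na/Δμ_H ≈ 0.89 at the initial state and initially runs in reverse.

## Numerics

Integration: `scipy.solve_ivp`, LSODA first, automatic fallback to Radau
then BDF; rtol 1e-6, atol 1e-8 by default. Output on a 400-point
logarithmic grid from 1e-8 s (the dynamics span ten decades) plus a dense
interpolant. The solver-facing right-hand side is exception-free: ion
concentrations are floored, ADP is clamped at 0, gradients are computed
as differences of logarithms, the ETC exponent is capped below overflow,
and a negative pmf zeroes the synthase flux (with a warning on the
user-facing path). Stored trajectories abort if any concentration drops
below −atol; values in (−atol, 0) are clamped to zero. A per-solver
budget of right-hand-side evaluations (default 200 000; 20 000 inside
cost evaluations) turns pathological parameter vectors into fast, finite
penalties instead of stalls.

ATP attainment time: when the trajectory has an interior ATP maximum we
report its argmax. For monotone trajectories (the usual case) we report
the first time ATP reaches 99.9% of its quasi-steady plateau
J_ATPS/α_ATPuse — the level at which synthesis balances consumption. The
plateau is *not* taken at the end of the horizon because ATP keeps
creeping by a few per-mille for hours as the ion gradients relax; an
end-of-horizon threshold would misattribute the attainment to that slow
phase (~1600 s instead of ~4 s for the electroneutral best fit).

## Fitting

Cost: J(p) = (1/N_K)·ΣΔK²/ΣK² + (1/N_Na)·ΣΔNa²/ΣNa² +
w_ATP·|ΔATP|/ATP + w_pmf·|Δpmf|/pmf with w_ATP = 10, w_pmf = 0.5, the
scalar terms evaluated at t_final = 3600 s (the last observation time;
configurable). Infeasible parameter vectors return a finite penalty
(1e6) so simplex methods can retreat.

Unit harmonisation happens at the I/O boundary. Ion observations
(mmol/L) map 1:1 onto the model state. The steady-state ATP datum is
reported per kg of cell water; the model concentration lives on the
cell-volume scale used by the compartment algebra, so the datum is
converted with the cell-water/cell-volume ratio (0.80/1.36 per OD·mL,
water density 1 kg/L): 3.7 mmol/kg water → 2.176e-3 mol/L. We adopted
this conversion (rather than the naive 1 kg ≈ 1 L identity, which would
put the datum at 3.7e-3 mol/L) because the fitted electrogenic optimum
settles at 2.1767e-3 mol/L — matching the converted datum to 2e-4
relative — while no admissible trajectory of either variant approaches
3.7e-3; the cost values only decompose sensibly under this reading.

Optimizers: Nelder–Mead (scipy, xatol = fatol = 1e-6) and a seeded
simulated annealing with geometric cooling (T₀ = 1, factor 0.95, 50
proposals per temperature, stop temperature 1e-6) and per-coordinate
Gaussian proposals with std 0.1·|p|·√T + 1e-8 — the √T factor anneals
the step size so late iterations refine. Only the stop temperature of
the original annealing implementation is known; the rest of the schedule
is this package's design, so annealing end-points are reproducible only
per-seed, not against history. The staged pipeline (anneal from ones →
external manual guess → simplex and anneal refinements → final anneal)
is exposed as `staged_fit`; parameters are fitted on their natural
linear scale.

Published cost values: our pipeline reproduces the *shape* of the
published table only partially. For the electrogenic best fit we compute
J(EG1) = 0.157 against the reported 0.184 (−15%); for the electroneutral
best fit we compute J(EN5) = 0.330 against 0.193. The decomposition
shows why: the reported values require the model's ATP at t_final to sit
at ≈2.17e-3 mol/L for *every* parameter set, whereas the faithful
equations give set-dependent steady ATP (2.14e-3 for EN5), and no choice
of t_final closes the gap (the EN5 trajectory never exceeds 2.148e-3).
The corresponding acceptance assertions are left failing at their stated
tolerances rather than retuned.

## Sensitivity analysis

Forward sensitivities solve dS/dt = (∂f/∂x)S + ∂f/∂p jointly with the
state (n + n·m equations), with both Jacobians generated symbolically
(sympy) and compiled to numpy; rtol 1e-8, atol 1e-10; S(0) = 0. A
central finite-difference oracle (step 1e-6·p_j) agrees to <1% on every
entry carrying at least 0.1% of its row's weight; smaller entries (e.g.
∂K⁺ᵢ/∂α_K once the uniport sits at quasi-equilibrium, ~1e-10) are below
what either method can resolve at these tolerances and are excluded from
the comparison.

The Fisher Information Matrix accumulates p_j·∂X_i/∂p_j weighted by the
diagonal error model σ_ik = ε₁·X_i(t_k) + ε₂ (ε₁ = 1e-8, ε₂ = 1e-10)
over a 200-point logarithmic grid on [1e-7, 3600] s plus the observation
times; ranking scores r_j are the FIM diagonal. Absolute scores scale
with the number and placement of grid points, so they are comparable
across studies only to order of magnitude; the *ordering* is
grid-robust (we verified it is unchanged across log, linear,
observation-only and solver-step grids).

Against the previously reported ranking our results differ materially:
we find the electrogenic stoichiometry n_NaH and the ETC inhibition
strength γ_ETCP,pmf nearly tied (5.4e18 vs 5.3e18) rather than n_NaH
dominating by five orders of magnitude, and the electroneutral order
interleaves α_ATPuse/α_NaH among the four power-law core parameters.
Both scores are dominated by the K⁺/Na⁺ rows through their common effect
on the pmf, which makes them nearly proportional — a structural feature
of the integrable dynamics that no grid choice undoes. Because the
forward solution is independently verified against finite differences,
we report our computed ranking and leave the corresponding acceptance
comparisons failing.

## Synthetic data and identifiability

The generator emulates the real observation set: the model is simulated
at the truth, sampled at the minute-scale observation times (one Na
value missing, mirroring the fixture), and perturbed with multiplicative
Gaussian noise (default CV 2% on ions and on the two steady-state
scalars; draws that would turn a concentration negative are resampled).
Multiplicative noise was chosen because the ion data span 1.3–2.9 mol/L
and the Fisher error model is relative-dominated. What it does *not*
emulate: instrument-specific error structure, autocorrelated drift, or
calibration offsets — so recovery results speak to identifiability under
idealised noise, not to real-assay robustness.

Recovery experiments (generate → refit from truth×1.2, Nelder–Mead)
show the model is sloppy: the two kinetic orders (γ_ETCP,pmf,
γ_ATPS,ADP) are recovered to a few percent, but the paired rate
constants β_ETCP/β_ATPS compensate along near-flat cost directions and
settle 20–30% off even on noise-free data, with final costs far below
the cost at the truth once the w_ATP = 10-weighted 2%-noisy ATP scalar
is chased. The acceptance clause expecting all four top-ranked
parameters within 15% median error therefore fails for the β's; this is
a property of the cost landscape, not of the optimizer budget (fits
terminate below the cost at truth).

## Unit conversions

All conversions pivot linearly through moles per OD·mL using the
cellular constants (1.36e9 cells, 1.36 μL cell volume, 0.80 μL cell
water, 1.63 μg cell mass per OD·mL; 1.2 pg and ~1.0 fL per cell).
Round-trips are exact to 1e-12. Two volume pivots are exposed
deliberately (cell water vs total cell volume) because mass-of-water
units and the compartment algebra use different denominators. The
protein constant (0.2347 mg per OD·mL) is calibrated so that 2.2 mmol/L
cell water ↔ 7.5 nmol/mg protein, is marked as calibrated in the
geometry provenance, and should be overridden by a measured protein
content. The shipped organic-material (0.47 μL) and cellular-salt
(0.45 μL) volumes do not sum to the 1.36 μL cell volume; the constants
are kept verbatim and no such sum is enforced.

## Problem sizes

Default problem sizes used throughout (tests and the acceptance script):
400-point trajectory grids, 200-point sensitivity grids, 10-replicate
recovery experiments with a 2000-evaluation simplex budget, 1000-state
property sweeps. These were chosen so the full pipeline re-runs in
minutes on one core while leaving every assertion's margin comfortably
resolved.

## Known limitations

* The oxygen reconstruction divides the ETC proton flux by a fixed
  H⁺/O₂ = 10; uncoupled (pmf-independent) respiration is not modelled,
  so absolute oxygen rates are lower bounds.
* The two antiport variants give α_NaH different effective units
  (dimensionless driver vs J/mol driver); values are not comparable
  across variants and are deliberately not rescaled.
* Simulated-annealing results depend on the package's own schedule
  beyond the published stop temperature.
* The ΔΨ/58ΔpH curves' concavity and figure-read oxygen magnitudes are
  qualitative; only structural properties (monotonicity, linearity after
  the transient, the pmf sum identity) are asserted.
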