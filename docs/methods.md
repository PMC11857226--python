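# Methods

## The reaction system and the simplified network

Ethyl chrysanthemate (EC), the simplest pyrethroid ester, is made industrially
by cyclopropanating 2,5-dimethyl-2,4-hexadiene (DMH) with the carbene derived
from ethyl diazoacetate (EDA), catalysed by a copper stearate–phenylhydrazine
complex. The full mechanism is a thicket — free-carbene channels, polymeric
by-products, cis/trans isomers, several catalyst-bound intermediates. This
package implements the reduced network that is sufficient to reproduce the
apparent kinetics:

| step | reaction | constant |
|---|---|---|
| 0 | EDA + Cat → N₂ + MC | k₀ |
| 1 | MC + DMH → Cat + EC | k₁ |
| 2 | MC + EDA → Cat + DIM | k₂ |
| 3 | MC + DIM → Cat + trimer | k₃ |
| eq. | Cat + DMH ⇌ Cat·DMH | K |

MC is the copper carbene; DIM pools diethyl fumarate and maleate. All four
steps are second order; the coordination equilibrium is treated as
instantaneous, giving the algebraic catalyst balance

C_cat = (C_cat,0 − C_MC) / (1 + K·C_DMH).

The rate equations are integrated for the six species (EDA, DMH, MC, EC,
DIM, trimer). The trimer carries no chemistry of its own beyond being the
k₃ sink; it is tracked so that the diazo-unit balance
C_EDA + C_MC + C_EC + 2·C_DIM + 3·C_TRI closes exactly, which the test suite
uses as a conservation diagnostic.

**Which catalyst species reacts with EDA.** The rate equations multiply k₀
by the DMH-bound complex, while the step list writes "EDA + Catalyst". Both
readings are implemented (`active_species_mode`: `complex-active`, the
default, matches the equations; `free-active` the step list). The choice
matters enormously: in free-active mode the uncomplexed catalyst fraction is
~1/(1+K·C_DMH) ≈ 0.5 % and conversion stalls, which is inconsistent with the
observed complete conversion within a minute — additional evidence that the
complex-active form is the intended one.

## Parameters

| parameter | default | units | origin |
|---|---|---|---|
| A₀, E₀ | 1.9555×10¹⁵, 89.60 | L mol⁻¹ s⁻¹, kJ/mol | published Arrhenius law, carbene formation |
| A₁, E₁ | 1.4989×10¹³, 71.77 | 〃 | cyclopropanation |
| A₂, E₂ | 8.0898×10¹⁷, 104.07 | 〃 | dimerisation |
| A₃, E₃ | 5.3287×10¹⁴, 78.49 | 〃 | trimerisation |
| K | 1×10⁴ | L/mol | not measured; chosen deep in saturation |
| C_cat,0 | 2×10⁻⁵ | mol/L | standard loading |
| R | 8.314 | J mol⁻¹ K⁻¹ | fixed |

K was never determined independently. With the default, K·C_DMH ≈ 220 under
the standard DMH loading, so the active-complex fraction is ≥ 99.5 % and
every prediction is insensitive to K's exact value (see the identifiability
note below). Temperatures are accepted in °C and converted as K = °C +
273.15; activation energies are stored in kJ/mol and converted at
evaluation.

**Dimer-yield convention.** Yields are referenced to the initial EDA charge.
EC consumes one diazo unit, so Y_EC = C_EC/C_EDA,0. Each dimer consumes two,
and the measured dimer yields (~0.3 at the 130 °C plug-flow outlet) are only
consistent with the diazo-unit basis Y_DIM = 2·C_DIM/C_EDA,0, which is
therefore the default (`dim_basis="eda"`); the per-molecule basis is
selectable. On the default basis the yields and the conversion shortfall sum
to one minus three times the trimer yield's remainder, i.e. the balance
closes.

## Reactor models

*Batch*: `solve_ivp` with LSODA at rtol 10⁻⁸, atol 10⁻¹² mol/L. The carbene
lives on the 10⁻⁵ mol/L catalyst scale with millisecond turnover while the
bulk species evolve over seconds to hours, so the system is stiff. If LSODA
fails (it can, on extreme trial rate sets during optimisation), the fully
implicit Radau scheme is retried before an error is raised. Solver output is
kept raw for balance tests; clipping of round-off negatives happens only in
the CSV export.

*Plug flow*: the micro-flow tube operates in laminar flow with Peclet
numbers of 20–50, i.e. little back-mixing, so the reactor is treated as an
ideal PFR: outlet composition = batch state at the hydraulic residence time
V/Q. Axial dispersion and the laminar velocity profile are neglected.
Tube geometry (1 mm and 2 mm i.d. sections, 2 m each, plus accessory
volume) is configurable; the standard six configurations span ~1.7–19 mL.

*Semi-batch*: the industrial practice of dripping the EDA + catalyst stream
into the olefin bulk is modelled as a piecewise-constant, volume-referenced
source term at constant volume (feed volumes are not specified for the
validation runs, so volume change is ignored). The dosed catalyst enters
the coordination balance through an explicitly time-dependent catalyst
total. Instantaneous dosing reproduces the batch integrator to solver
tolerance. The 60/70 °C validation predictions are computed as plain batch
integrations at the standard loadings; with a 1 h uniform feed the 3 h EC
yield moves by less than 0.05, so the batch approximation is adequate at
the reported precision.

## Regression

Per-temperature estimation minimises the unweighted sum of squared
residuals of (X_EDA, Y_EC, Y_DIM) over all rows of all tables at that
temperature, with replicates entering individually (a switch selects
per-time averaging). Optimisation is on log₁₀ k, which enforces positivity
and equalises scales. Five seeded starts (the extra four log-uniform within
±2 decades of the guess) run a bounded trust-region solver; the best basin
is then polished with Levenberg–Marquardt at tight tolerances. Two numerical
points matter:

- the finite-difference Jacobian step is 10⁻⁶ in log space. The default
  (~10⁻⁸) produces yield changes below the ODE solver's rtol, the Jacobian
  becomes noise, and the fit stalls at ~0.5 % error.
- trial points outside a generous search box are rejected with a flat
  penalty before any integration, which keeps wild exploratory starts cheap.

Arrhenius parameters come from ordinary least squares of ln k on 1/T
(Ea = −slope·R, A = exp(intercept)), exact on points generated from any
single law.

**Identifiability.** Two flat directions dominate the loss surface:

1. *K*: in saturation the observables depend on K only through the factor
   K·C_DMH/(1+K·C_DMH). The loss plateaus as K grows — per decade of K the
   change is a few percent at K = 10⁴ and falls below 10⁻⁴ by K ≈ 10⁷ —
   so K is fixed by default; freeing it (bounded at 10⁶ L/mol) merely slides
   along the plateau.
2. *QSS scale of (k₁, k₂, k₃)*: with the carbene near quasi-steady state,
   conversions and yields see k₀ and the *ratios* k₁:k₂:k₃ strongly, but the
   common scale of the three only through the small catalyst fraction
   sequestered as MC (~10 % at 130 °C). Noiseless data still pin the scale
   (the two-stage fit recovers every kᵢ to ≪1 %), but at measurement noise
   of 0.01 the per-temperature scale drifts freely. For noisy data the
   two-stage route therefore yields corrupted Arrhenius slopes for
   k₁–k₃, and the global mode (`joint_fit(..., mode="global")`), which fits
   {Aᵢ, Eᵢ} directly to all temperatures at once and thus shares the flat
   direction, is the right tool: it recovers activation energies to a few
   kJ/mol at that noise level, leaving the residual uncertainty in the
   intercepts ln Aᵢ.

`bootstrap_ci` provides residual-resampling percentile intervals
(2.5/97.5 %) by refitting resampled tables from the fitted optimum. Its
statistical coverage has not been simulated at scale in the test suite
(that is ~10⁴ refits); the suite verifies interval collapse on noiseless
data and seed determinism.

## Synthetic experiments

The generator emulates the kinetic campaign's three series — DMH:EDA excess
ratios {1.1, 2, 5} at 130 °C; concentration multipliers {0.5, 1, 2} at the
1:1.1 ratio; temperatures {110, 120, 130, 140} °C at standard loadings —
each measured in triplicate on the six-point residence-time grid
(5.0–55.8 s) that the tube-section configurations produce at 20.4 mL/min.
Only the 1:1.1 excess level is documented; the higher ratios are this
package's choices. Measurement noise is additive Gaussian on each
observable with sd 0.01 absolute (typical GC internal-standard precision),
truncated to [0, 1]; truncation bias is negligible (<0.002) for observables
inside [0.05, 0.95].

What passing round-trip tests on these data do *not* show: robustness to
systematic errors absent from the generator — flow non-idealities, EDA feed
impurity (nominal concentrations are used), temperature gradients,
GC calibration drift, or heteroscedastic noise.

## Problem sizes and runtime choices

The test suite and the acceptance script run everything at the sizes the
science needs, not larger: single-temperature fits use 3–7 condition
tables × 4–6 times × ≤3 replicates; the full-design joint fit (10 tables,
540 residuals per evaluation) completes in ~30 s; the fixed-step Euler
cross-check uses dt = 10⁻⁴ s over a 10 s window. Yield maps default to
60–140 °C in 10 K steps × 40 log-spaced times from 1 s to 5 h.

## Known limitations

- The per-temperature fitted rate constants of the original regression are
  not available for direct comparison; correctness of the regression layer
  is established by round-trip recovery instead.
- The 60 °C/3 h EC-yield prediction computed here (0.577) sits 0.034 above
  the reference model calculation (0.543) — within the tolerance attributable
  to the unpublished K and per-temperature constants, but a reminder that
  the published Arrhenius laws alone do not reproduce the reference
  calculation exactly.
- No heat transfer, pressure drop, axial dispersion or two-phase flow;
  temperature is uniform and constant within a run.
- The semi-batch model ignores volume change from dosing.
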