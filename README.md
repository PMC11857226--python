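# chrysokin

Kinetic modelling of the copper-catalysed cyclopropanation of ethyl
diazoacetate (EDA) with 2,5-dimethyl-2,4-hexadiene (DMH) to ethyl
chrysanthemate (EC), the core pyrethroid-insecticide intermediate.

EDA is unstable — it dimerises to diethyl fumarate/maleate (DIM) and worse —
so industrial practice drips it slowly into the olefin at 20–80 °C over
hours, and still loses ~30 % of it. Micro-flow reactors lift the safety
constraint and make fast, hot operation possible, but deciding *where* to
operate needs a quantitative kinetic model. This package implements such a
model for the copper stearate/phenylhydrazine catalyst system: a simplified
four-step network plus a catalyst–olefin coordination equilibrium,

- EDA + Cat → N₂ + MC (k₀) — metal-carbene formation
- MC + DMH → Cat + EC (k₁) — cyclopropanation (main reaction)
- MC + EDA → Cat + DIM (k₂) — carbene dimerisation
- MC + DIM → Cat + trimer (k₃) — dimer consumption
- Cat + DMH ⇌ Cat·DMH (K),

with catalyst balance C_cat = (C_cat,0 − C_MC)/(1 + K·C_DMH) and
kᵢ(T) = Aᵢ·exp(−Eᵢ/RT). Because E₁ is the lowest activation energy of the
three carbene sinks, selectivity to EC *falls* as temperature rises — the
central design tradeoff the package quantifies.

It provides:

- `kinetic_core` — parameters, rate laws, the ODE right-hand side, balances;
- `reactor` — stiff batch integration, ideal plug-flow (residence-time)
  mapping for the micro-flow tube, semi-batch dosing;
- `regression` — per-temperature rate-constant least squares, ln k vs 1/T
  Arrhenius fits, a global Arrhenius-space fit, bootstrap intervals;
- `synthetic` — a generator of noisy triplicate micro-flow experiment
  tables for the three campaign series (olefin excess, concentration,
  temperature);
- `screening` + a `chrysokin` CLI — (temperature, time) yield maps and the
  low-temperature validation predictions.

## Worked example

```python
import chrysokin as ck

params = ck.ModelParams.default()

# rate constants at 130 degC
rs = ck.rate_constants_at(ck.celsius_to_kelvin(130.0), params)
print(f"k0={rs.k0:.0f} k1={rs.k1:.0f} k2={rs.k2:.0f} k3={rs.k3:.0f}  (L/mol/s)")

# micro-flow outlet, 60 s residence time
initial = ck.SpeciesState(C_EDA=0.02, C_DMH=0.022)
traj = ck.simulate_batch(initial, params, 403.15, 60.0)
obs = ck.to_observables(traj, 0.02, 60.0)
t99 = ck.time_to_conversion(traj, 0.99)
print(f"X_EDA={obs.X_EDA:.3f}  Y_EC={obs.Y_EC:.3f}  Y_DIM={obs.Y_DIM:.3f}  t99={t99:.1f} s")

# low-temperature screening prediction vs experiment
print(ck.validation_report(params).to_string(index=False))
```

prints

```
k0=4805 k1=7524 k2=26515 k3=36024  (L/mol/s)
X_EDA=0.998  Y_EC=0.227  Y_DIM=0.284  t99=41.4 s
 T_C     t_s  Y_EC_pred  Y_EC_exp  abs_gap
60.0 10800.0   0.577425     0.516 0.061425
70.0 10800.0   0.526059     0.494 0.032059
```

Reading: at 130 °C the micro-flow tube converts >99 % of the EDA in 41 s,
but only ~23 % of it becomes EC — about 28 % is lost to dimers (yields on
the initial-EDA basis; each dimer consumes two diazo units) and the rest to
the trimer. Cooling to 60–70 °C and stretching to 3 h roughly doubles the
EC yield, in line with the yields measured in semi-batch stirred validation
runs (`Y_EC_exp`).

The same from the shell:

```sh
chrysokin simulate -T 130 --t-end 60 --out traj.csv
chrysokin screen --out yieldmap.csv        # 60-140 degC x 1 s-5 h map
chrysokin generate --noise-sd 0.01 --seed 1 --out tables.csv
chrysokin fit --tables tables.csv --out fit.json
chrysokin validate
```

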