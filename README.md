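# aodkit

Estimation of anaerobic energy release by the **accumulated O₂ deficit
(AOD)** principle from cycle-ergometer data, and systematic comparison of the
computational short-cuts used to obtain it.

## The problem

Aerobic energy release during exercise is measured directly as O₂ uptake;
anaerobic energy release is not measurable non-invasively. The AOD principle
estimates it indirectly: the total rate of energy release (the *O₂ demand*,
in O₂-equivalent units) is assumed linear in mechanical power,

    Y = a + b·P,

with intercept *a* (mmol s⁻¹) and slope *b* (μmol J⁻¹) fitted on submaximal
steady-state measurements and extrapolated to supramaximal powers
P = (Y − a)/b. Over an exhaustive bout of duration *t* the accumulated
deficit is

    AOD = Y·t − ∫₀ᵗ V̇O₂ dt,

i.e. accumulated demand minus accumulated uptake. Everything therefore hinges
on how the linear relation is established. `aodkit` implements nine ways
(M0–M8) of doing so and quantifies how much the resulting AOD differs:

| id | relation built from |
|----|---------------------|
| M0 | steady-state V̇O₂ at 8–10 min of ≥8–10 constant-power bouts (reference) |
| M1 | the 3–4-min window of rested bouts |
| M2 | M1 data with a forced common intercept (cohort mean of M1 intercepts) |
| M3 | a 4-min stepwise-increasing-power protocol |
| M4 | all 10-min-bout data including low powers and loadless pedaling |
| M5 | common intercept + slope through the highest-power steady-state point |
| M6 | gross efficiency: intercept 0 |
| M7 | net efficiency: intercept = resting V̇O₂ |
| M8 | net efficiency: intercept = loadless-pedaling V̇O₂ |

The package is aimed at exercise physiologists evaluating MAOD-style testing
protocols and at methodologists studying estimator bias: it ships the demand
relations as scikit-learn-style estimators, an AOD engine with the five
canonical supramaximal exercise models (100–250 % of the V̇O₂max intensity,
10–217 s to exhaustion), matched-pair comparison statistics, and a
synthetic-cohort generator with known ground truth (slow-component drift,
low-power non-linearity, cubic frequency dependence of loadless V̇O₂,
lactate threshold at 4.0 mmol L⁻¹).

## Worked example

Feed the published cohort-mean coefficients through the engine (cohort-mean
V̇O₂max 2.9 mmol s⁻¹, mean body mass 80.15 kg reconstructed from the sex-group
means 74 kg (n=3) and 82 kg (n=10)):

```python
import aodkit as ak
from aodkit import studydata

rels   = studydata.method_relations()          # M0..M8 coefficients
models = ak.printed_exercise_models()          # 100%..250% intensity rows
mass   = studydata.reconstructed_mean_mass()   # 80.15 kg
table  = ak.aod_table(rels, models, mass, reference_id="M0")
print(table.round(2))
print("120% power:", round(rels["M0"].invert(1.2 * 2.9), 1), "W")
```

prints (AOD in mmol per kg body mass):

```
           217 s, 100%  120 s, 120%  60 s, 150%  30 s, 200%  10 s, 250%
method_id
M0                1.96         1.94        1.75        1.52        0.82
M1                1.68         1.75        1.57        1.43        0.77
M2                1.78         1.82        1.62        1.46        0.79
M3                2.01         1.99        1.74        1.55        0.83
M4                1.85         1.83        1.60        1.43        0.77
M5                1.87         1.89        1.67        1.49        0.80
M6                2.12         2.24        1.99        1.79        0.94
M7                1.98         2.05        1.81        1.63        0.87
M8                1.80         1.77        1.55        1.39        0.75
120% power: 342.1 W
```

Reading it: under the 10-s all-out model the gross-efficiency method (M6)
yields 0.94 mmol kg⁻¹ — 15 % above the reference 0.82 — because forcing the
intercept through zero inflates the slope; the loadless-pedaling net
efficiency (M8) underestimates (0.75) because loadless V̇O₂ is raised by
non-linear low-power effects. Early-window fitting (M1) underestimates
because V̇O₂ keeps drifting upward after 4 min of constant-power exercise.

The same pipeline runs from the shell on synthetic cohorts:

```sh
aodkit report --seed 7 --out runs/demo        # simulate -> fit -> aod tables
```

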