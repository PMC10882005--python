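# h2o2bcr

Simulation and single-cell analytics of hydrogen-peroxide-driven B-cell
receptor (BCR) signalling.

Reactive oxygen species such as H₂O₂ inactivate protein tyrosine
phosphatases by cysteine oxidation, de-repressing kinase signalling. In
diffuse large B-cell lymphoma (DLBCL) cells this drives phosphorylation of
the proximal BCR cascade CD79a → SYK → PLCγ2, measured per cell by
phospho-specific flow cytometry. The population responds *digitally*: at a
given dose some cells switch fully ON while the rest stay OFF, producing
bimodal phospho-distributions, and the ON fraction depends not only on the
concentration reached but on the *rate* at which it was reached — cells
exposed to shallow gradients respond at lower doses than cells hit with a
step. This package provides the complete computational stack for studying
that behaviour: a mechanistic population model, dynamic input patterns,
dose–response and bimodality statistics, a gating/threshold pipeline for
per-cell event tables, and a ground-truthed synthetic data generator.

## The model

Each protein is a phosphorylation–dephosphorylation cycle with
Michaelis–Menten kinetics; H₂O₂ (S) inhibits the phosphatases through a
decreasing Hill term P(S) = 1/(1 + (S/k_ros)^H):

```
dX/dt = k_f (X_T−X)/(K_M1+X_T−X) − k_r P X/(K_M2+X)
dY/dt = k_f X (Y_T−Y)/(K_M3+Y_T−Y) + k_cat (Y_T−Y)/(k_pos+Y_T−Y) − k_r P Y/(K_M4+Y)
dZ/dt = k_f Y (Z_T−Z)/(K_M5+Z_T−Z) − k_r P Z/(K_M6+Z)
```

with X = pCD79a, Y = pSYK (which carries a positive feedback term) and
Z = pPLCγ2; totals are scaled to 1 and concentrations are model units
numerically identified with mM. Cell-to-cell variability enters as
independent lognormal draws of the Michaelis constants and k_ros
(arithmetic mean m, variance m·s²ₓ₅₀). A cell is "ON" for a protein when
its phospho-level exceeds 30 % of maximum; experimentally, when its
fluorescence exceeds the 97.5th percentile of the matched unstimulated
control. Population readouts are summarised by the Hill dose–response
R(S) = R₀ + R_max·Sᴴ/(Sᴴ + EC₅₀ᴴ); a population can respond bimodally only
when H·σₓ₅₀ > √2, where σₓ₅₀ is the lognormal spread of the per-cell
response threshold. For gradients, EC₅₀% is the concentration reached when
50 % of cells are ON, and the rate sensitivity is
(dose₅₀^steep − dose₅₀^shallow)/(rate^steep − rate^shallow).

## Worked example

```python
import numpy as np
from h2o2bcr import analysis, model
from h2o2bcr.patterns import InputPattern

params = model.ModelParameters()          # reference kinetic constants

# 1000 heterogeneous cells under a 5 mM step; % cells ON over time
traj = model.simulate_population(params, InputPattern("step", c_max=5.0),
                                 n=1000, t_grid=np.linspace(0, 10, 11), seed=42)
print(model.percent_on(traj).iloc[[2, 5, 10]].round(1))
#           pCD79a  pSYK  pPLCg2
# time_min
# 2.0         58.5  83.3    67.1
# 5.0         67.8  84.8    77.6
# 10.0        68.7  84.9    78.8

# EC50% of a 20-min linear gradient to 10 mM (0.5 mM/min)
grad = model.simulate_population(params, InputPattern("linear", c_max=10, T=20),
                                 n=1000, t_grid=np.linspace(0, 20, 81), seed=42)
print({k: round(v, 2) for k, v in model.ec50_percent(grad).items()})
# {'pCD79a': 2.84, 'pSYK': 1.49, 'pPLCg2': 2.39}

# which proteins can respond bimodally, from fitted (H, sigma_x50)?
for prot, (h, s) in {"pCD79a": (1.1, 1.04), "pSYK": (2.7, 0.59),
                     "pPLCg2": (3.3, 0.71)}.items():
    print(prot, analysis.bimodality_condition(h, s))
# pCD79a False / pSYK True / pPLCg2 True

# rate sensitivity: EC50% shift per unit change in gradient rate
print(analysis.rate_sensitivity(8.0, 5.0, 0.5, 0.17))   # 9.09 mM per (mM/min)
```

A 5 mM step switches 60–85 % of cells ON within minutes; during a 0.5
mM/min gradient half the population activates by ~1.5–2.8 mM depending on
the protein; and the printed (H, σₓ₅₀) pairs mark pSYK and pPLCγ2 — but not
pCD79a — as capable of bimodal population responses.

The same functionality is exposed on the command line:

```bash
h2o2 pattern --kind exponential --cmax 10 --duration 60 --out profile.csv
h2o2 simulate --pattern linear:10:20 --cells 1000 --seed 1 --out traj.csv
h2o2 sweep --rates 0.05,0.17,0.5,5 --cells 1000 --seed 1 --out sweep.csv
h2o2 synth --preset static --seed 1 --out data/
h2o2 analyze --events data/events.csv --samples data/samplesheet.csv --out summaries/
```

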