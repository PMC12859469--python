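# dpnflow

Temporal **drug prescription network (DPN)** analysis for pharmacy
dispensing registries.

Pharmacoepidemiologists studying polypharmacy want to know which
medication classes sit at the centre of co-prescription patterns in a
population — for example, what is co-prescribed around antidepressants
and anxiolytics, and how that structure drifts over years. `dpnflow`
implements the full analysis chain on plain dispensing records
(patient, ATC code, date, days supplied, prescribed dose in DDD units):

1. **Exposure**: each dispensing covers the half-open interval
   `[dispense_date, dispense_date + days_supplied)`; overlapping refills
   of the same drug are merged (or stockpiled, configurable).
2. **Daily networks**: medications are grouped into 24 ATC therapeutic
   classes. For each patient and day, a binary symmetric adjacency
   `A_p(t)` links every pair of concurrently active classes; the
   population network is the element-wise sum `A(t) = Σ_p A_p(t)`, whose
   off-diagonal entries count co-prescribing patients.
3. **DDD weighting**: each medication receives a Gaussian-kernel weight
   `w(DDD) = (σ√2π)⁻¹ exp(−(DDD−1)²/2σ²)` centred at the baseline DDD
   ratio of 1 (default σ = 1/3); an edge combines its endpoints by their
   average, and by default the pair-average multiplies the
   co-prescription count.
4. **Centrality**: eigenvector centrality `c_i = λ⁻¹ Σ_{j≠i} W_ji c_j`
   of each daily weighted network, L1-normalised (`Σ c_i = 1`), computed
   by power iteration and aggregated to ISO weeks. A class is *high*
   centrality when its mean exceeds the uniform baseline `1/n = 1/24`.
5. **Co-prescription statistics**: same-class, multi-class and total
   polypharmacy in *prescription-days* (7 medications on one day = 7
   prescription-days), per calendar year; general-polypharmacy flags
   (≥5 medications for ≥30 consecutive days) and age subgroups
   (<65 / ≥65) with independently built subgroup networks.
6. **Time series**: weekday/yearly seasonal deconstruction with
   ACF/PACF correlograms, and two-stage singular spectrum analysis
   (trend at lag L = 52, then 25 oscillatory components at L = ⌊N/2⌋)
   with Mann–Kendall trend tests.

Real dispensing registries are rarely shareable, so the package ships a
seeded generator (`dpnflow.simulate`) that emulates the statistical
structure of a community-pharmacy cohort of antidepressant/anxiolytic
users: ~37:63 male:female split, Monday-peak/Saturday-trough weekday
cycle, yearly seasonality, slowly rising antidepressant and declining
anxiolytic volumes, latent-multimorbidity-driven co-prescription, and
per-record DDD ratios scattered below 1.

## Worked example

```python
import datetime as dt
import numpy as np

from dpnflow import SimulationConfig, simulate_registry, Window
from dpnflow.exposure import build_exposure, build_activity_cube
from dpnflow.networks import WeightParams, gaussian_weight, daily_networks_from_cube
from dpnflow.experiments import mean_centrality_by_class
from dpnflow.centrality import classify_centrality

cfg = SimulationConfig(n_patients=1000, window_start=dt.date(2018, 1, 1),
                       window_end=dt.date(2019, 12, 31), seed=42)
records = simulate_registry(cfg)          # ~75k dispensings, 1000 patients
window = Window(cfg.window_start, cfg.window_end)
params = WeightParams()                   # sigma=1/3, per-record, multiply
segments = build_exposure(records, window)
cube = build_activity_cube(segments, window,
                           patient_ids=np.unique(records["patient_id"]),
                           weight_fn=lambda d: gaussian_weight(d, params))
counts, weighted = daily_networks_from_cube(cube, params)
mean_c = mean_centrality_by_class(weighted, cube.class_labels)
for lab, v in mean_c.sort_values(ascending=False).head(7).items():
    print(f"{lab:<28} {v:.4f}  {classify_centrality(v, 24)}")
```

prints

```
Alimentary and metabolism    0.1505  high
Cardiovascular               0.1383  high
Respiratory                  0.1129  high
Antidepressants              0.1079  high
Blood                        0.0656  high
Dermatologicals              0.0558  high
Genitourinary                0.0550  high
```

The high-volume somatic classes and the antidepressants sit well above
the 1/24 ≈ 0.0417 baseline: they are co-prescribed with other highly
connected classes, which is exactly what eigenvector centrality
measures.  A Mann–Kendall test on the weekly antidepressant dispensing
series of the same run returns `S=-504, p=0.163, direction none`: the
default +2 %/year drift is not detectable over only two simulated years
(the validation experiments use the full five-year window, where it
is).

The same analysis runs from the shell:

```bash
dpnflow simulate --seed 42 --out registry.csv
dpnflow run --seed 42 --out results/          # simulates when no registry is given
dpnflow verify --out results/
```

`run` writes daily edge lists, daily/weekly centrality tables, yearly
co-prescription summaries, subgroup outputs, correlograms, SSA
components/shares and trend tests, plus a manifest; `verify` re-checks
cross-file invariants (centralities sum to 1, subgroup counts sum to
the population, SSA components add back to the input).

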