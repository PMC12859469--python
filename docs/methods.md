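# Methods

This note documents the models, conventions and open design choices
behind `dpnflow`, in the order the pipeline applies them.

## Registry and taxonomy

A registry row is one dispensing event:
`patient_id, sex, birth_year, atc_code, dispense_date, days_supplied,
ddd_ratio`.  `ddd_ratio` is the prescribed daily dose divided by the
WHO defined daily dose (DDD) of the drug; the field is record-level, so
it supports both per-prescription dose ratios and fixed per-drug
constants upstream.

Medications map to **24 therapeutic classes** by longest-prefix match
on the ATC code.  Each anatomical root (A, B, C, D, G, H, J, L, M, P,
R, S, V) forms one class; the nervous-system root N splits into
anesthetics (N01), analgesics (N02), antiepileptics (N03),
antiparkinson (N04), antipsychotics (N05A), anxiolytics (N05B),
hypnotics/sedatives (N05C), antidepressants (N06A), psychostimulants
(N06B), antidementia (N06D) and other nervous-system drugs (N07, also
the fallback for rarer N codes such as N06C).  The rule table is a
packaged CSV (`dpnflow/data/atc_classes.csv`) so users can audit or
replace the grouping.  Unmapped codes raise an error naming the code;
silent drops would bias network counts.

**Cohort**: patients with ≥1 antidepressant or anxiolytic dispensing in
the study window, aged 18–65 at their first qualifying dispensing.
Age is dispense-year − birth-year (registries rarely carry birth days).
The registry does not say whether eligibility age should be evaluated
at study start, first dispensing, or throughout; first qualifying
dispensing is our documented choice.  Subgroup age (<65 / ≥65) is
re-evaluated per calendar year, which is how a cohort capped at 65 at
entry acquires a ≥65 subgroup later in the window.

## Exposure

A dispensing covers the half-open day interval
`[dispense_date, dispense_date + days_supplied)`; day indices are
0-based from the window start, clipped to the window.  Half-open
intervals make length arithmetic exact (`end − start = days_supplied`).

Overlapping refills of the same ATC code have no canonical resolution
in dispensing data; two policies are implemented:

* `union` (default): day-level union, no stockpiling — the minimal
  assumption.  On overlap days the most recent dispensing's
  `ddd_ratio` applies (ties broken by record order), since the latest
  prescription reflects the current regimen.
* `shift`: leftover days are pushed after the overlap (stockpiling),
  preserving total supplied days.

The central in-memory object is the **activity cube**, a dense
`patients × days × classes` array of distinct-active-medication counts
(plus a parallel sum of per-medication kernel weights).  Networks,
prescription-day statistics and polypharmacy flags are all exact
functions of this cube, which is what makes the cross-checks against
brute-force day scans feasible.

## Networks and DDD weighting

Per patient-day, every pair of distinct active classes is an edge
(`k` classes → `k(k−1)/2` edges, zero diagonal).  Summing individual
adjacencies gives the daily population count matrix; its diagonal is
filled with per-class active-patient counts (descriptive only — the
weighting step forces it back to zero, excluding self-loops from all
network analysis).

Each medication receives a Gaussian-kernel weight
`w(DDD) = (σ√2π)⁻¹ exp(−(DDD−1)²/(2σ²))`, centred at the baseline
ratio ω_B = 1 with σ = 1/3 by default, so dosing far from one DDD per
day is down-weighted gradually.  Two conventions both appear in the
DPN literature and both are implemented:

* `multiply_counts` (default): edge weight = co-prescription count ×
  pair-average `½(w_i + w_j)`.  This keeps centrality data-driven —
  heavily co-prescribed classes score high.
* `literal_eq4`: edge weight = bare pair-average wherever a
  co-prescription exists.  This discards frequency entirely and makes
  centrality depend only on which class pairs ever co-occur; it is kept
  for comparability, not recommended.

The kernel density peaks at 1.197, not at ω_B = 1; `peak_normalized`
rescales the kernel to 1 at the baseline.  Defaults keep the raw
density form.  DDD weights come per record by default (each
dispensing's ratio, averaged within patient-day-class), since class
DDD ratios have substantial within-class spread; `class_mean` mode
uses one exposure-weighted mean weight per class.

## Eigenvector centrality

`c = λ⁻¹ W c` on the daily weighted adjacency, L1-normalised so
`Σ c_i = 1`; with that normalisation the complete unweighted graph
gives exactly `1/n` per node, which serves as the high/low threshold
(`n = 24`; ties at exactly 1/n classify low — "high" is strictly
greater).  Computation is power iteration from the uniform vector with
tolerance 1e−10 (max 10 000 iterations), applied to the shifted matrix
`W + σI` with `σ = max|W_ij|`: the shift leaves eigenvectors unchanged
but breaks the ±λ symmetry of bipartite graphs, where the unshifted
iteration oscillates.  Cross-checked against `numpy.linalg.eigh` (and
networkx) in the test suite to < 1e−8.

Degenerate cases: an all-zero day yields a missing (NaN) centrality
flagged not-converged — a fabricated uniform vector would silently
count as data.  On disconnected graphs the iteration converges to the
dominant component's eigenvector; other components' nodes go to ~0.

Daily metrics (dispensings, patients dispensed-to, their ratio) and
centralities aggregate to ISO-8601 weeks ("YYYY-Www"): counts are
summed, the ratio recomputed from weekly sums, and centrality averaged
over converged days (the daily→weekly centrality aggregator is not
prescribed anywhere; the mean is our documented choice).

## Co-prescription statistics

The unit is the **prescription-day**: one medication active on one day.
"Medications" are distinct ATC level-5 codes, not classes — same-class
polypharmacy requires within-class multiplicity that class-level
counting would erase.  Per year and focal class (antidepressants,
anxiolytics):

* same-class: focal prescription-days on patient-days with ≥2 distinct
  focal medications;
* multi-class: non-focal prescription-days on patient-days where a
  focal medication is co-active with another class;
* total: all prescription-days (whole cohort, identical for both focal
  rows).

Per-person means divide by the year's focal cohort size (patients with
≥1 focal dispensing that year); the denominators are not standardised
in the literature, so this choice is explicit.  General polypharmacy is
≥5 distinct medications on each day of a ≥30-consecutive-day run; runs
may span year boundaries (the criterion is about the run, not the
calendar).  Subgroup networks (<65 / ≥65, polypharmacy yes/no, and the
combined <65-non-poly vs ≥65-poly pair) are built independently with
identical weighting parameters; for true partitions the subgroup count
matrices sum exactly (integer equality) to the population matrix, which
`dpnflow verify` re-checks from the written files.

## Seasonality and SSA

Seasonal structure is explored on detrended series: a centred moving
average (window 29 days for daily, 13 weeks for weekly data; edges by
symmetrically shrinking windows) or, alternatively, an SSA trend.
Daily series are deconstructed by weekday within ISO week, weekly
series by week within year.  ACF uses the biased (1/N) autocovariance
estimator (positive semidefinite); PACF is the Durbin–Levinson
recursion; the significance band is ±1.96/√N.  Both are cross-checked
against statsmodels in the tests.

SSA embeds a length-N series into the L × K Hankel trajectory matrix
(trajectory[i,j] = x[i+j], K = N − L + 1), takes its SVD, and maps
eigentriple groups back to series by anti-diagonal averaging.  The
weekly series are decomposed in two stages: lag L = 52 (one year of
weeks) for the dominant trend — eigentriple {1} by default,
configurable to {1, 2} — then the residual at the maximal lag
L = ⌊N/2⌋, reporting the top 25 eigentriples F1…F25 by singular value.
The headline reconstruction is trend + F1 + F2.  Variance shares are
squared singular values within their stage; a reconstructed-variance
estimator is available because "share of variability" is ambiguous
between the two.  Minimum series length is 2·L1 = 104 weeks.

The Mann–Kendall statistic `S = Σ_{i<j} sign(x_j − x_i)` uses the
tie-corrected variance `[n(n−1)(2n+5) − Σ_t t(t−1)(2t+5)]/18`, a ±1
continuity correction, and a two-sided normal p-value.  Because it is
ambiguous whether the test should apply to the raw weekly series or to
the extracted trend, the pipeline emits both, labelled `raw` and
`trend`.

## Synthetic registry

Dispensing events are generated per patient × class from an
inhomogeneous Poisson process with intensity

    base_rate_c · weekday(d) · seasonal(d) · trend_c(d) · exp(z_p g_c − g_c²/2)

* `base_rate_c`: class shares follow the relative five-year dispensing
  volumes of the 24 classes in a Dutch antidepressant/anxiolytic
  population, scaled to 19.4 dispensings per patient-year (the yearly
  volume per cohort patient such registries report).
* `weekday(d)`: the empirical Monday-peak/Saturday-trough profile,
  normalised to mean 1.
* `seasonal(d)`: `1 + a·cos(2π(doy − 15)/365.25)` with a = 0.10 — a
  mild winter-peaked yearly cycle.
* `trend_c(d)`: `(1 + slope_c)^years`; defaults +2 %/yr for
  antidepressants and −2 %/yr for anxiolytics.
* `z_p ~ N(0,1)` is a latent multimorbidity factor with loading
  g_c = 0.3 for every class (the `−g²/2` term keeps population mean
  rates fixed).  A single shared factor is the simplest mechanism that
  produces the dense cross-class co-prescription structure chronic
  comorbidity creates in real cohorts.

Sexes are ~36.7:63.3 male:female; entry ages N(44, 13²) clipped to
18–65; days supplied are 7/14/30/90 with probabilities
0.15/0.20/0.50/0.15; DDD ratios are class-specific lognormals matched
to empirical class means/SDs (all means < 1), truncated to (0, 3].
Patients without an index-class event receive one, so every simulated
registry is a valid cohort.  An optional planted hub multiplies one
class's base rate (`hub_boost`), used by the parameter-recovery
experiments.

What the generator does **not** emulate: prescriber/pharmacy-level
clustering, adherence gaps and early refills, correlated class-specific
comorbidity profiles (one latent factor, not a factor structure),
policy discontinuities, or drug-level substitution within classes.
Passing tests therefore demonstrate that the pipeline recovers planted
population-level structure — cycles, trends, hub classes, subgroup
enrichment — not that it reproduces any particular real registry's
numbers.

## Validation experiments and problem sizes

`dpnflow.experiments` re-runs the chain end to end on simulated
registries: hub recovery uses 20 seeds × 2000 patients × 1 year
(the planted class must rank top-2 in mean centrality); trend recovery
uses 20 seeds × 500 patients × 5 years with a +5 %/yr planted slope
(Mann–Kendall must return positive S at p < 0.01); conservation uses a
500-patient year; the numerical cross-checks use 100 random 24×24
matrices, 100 random length-261 series, and 200/2000 Mann–Kendall
replicates.  These sizes were chosen as the smallest at which the
planted effects are unambiguous; `scripts/acceptance.py` recomputes all
of them from scratch under a single seed.

## Known limitations

* The 24-class grouping is a coarse lens; drug-level (ATC level-5)
  networks are out of scope by design.
* Eq.-style literal weighting (`literal_eq4`) and per-record weighting
  answer different questions; results are not comparable across modes.
* Eigenvector centrality on near-empty days is numerically valid but
  epidemiologically thin; weekly averages should be read alongside the
  dispensing counts.
* Prescription-day means depend on the chosen denominator; compare
  categories and years, not absolute levels, unless the denominator
  convention is fixed.
* Augmentation and adjunctive polypharmacy require diagnoses and are
  deliberately not computed from dispensing data alone.
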