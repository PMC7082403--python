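# yieldgap

Boundary-line yield-potential estimation and interpretable machine-learning
analysis of yield determinants for almond orchards (and structurally similar
perennial-crop plot datasets).

## What it does, and for whom

Agronomists analysing multi-orchard, multi-year plot records face two
questions: *what is the maximum yield a canopy of a given size can deliver*,
and *what keeps real plots below that maximum*?  This package implements the
standard decomposition:

1. **Yield potential (frontier).**  Plot-years are binned by canopy light
   interception (LI, the fraction of PAR intercepted, `fPAR = 1 −
   PAR_below/PAR_above`) in 5% bins; within each bin the top decile of
   yields proxies the attainable maximum; a line through the origin is
   fitted to the bin decile means:

   `y_p = s · LI%`,  with `s = Σ x·y / Σ x²` (lbs/acre per LI point).

2. **Yield gap.**  Each observation is normalized by its potential,
   `y_n = y_o / y_p ∈ (0, ~1]`, and `y_n` is modelled against orchard
   attributes (age, location, spacing, cultivar) and engineered climate
   features (monthly/seasonal means at current and previous-year lags,
   extreme-hot-day counts, long-term climatology) with a random forest.
   Interpretation uses out-of-bag permutation importance (%IncMSE), partial
   dependence curves, and a representative CART rule set; predictor sets
   are compared with sixfold cross-validated RMSE / R² / RPIQ.

Because the 10-year field datasets such analyses run on are typically
proprietary, the package includes a synthetic-data generator that emulates
their structure (33 orchards on a latitude gradient, ~7,900 plot-years,
saturating LI–age curves, a linear frontier, and threshold-shaped climate
stressors with known ground truth).  See `docs/methods.md` for the model
and every default.

## Worked example

Simulate a study, estimate the frontier and the gap statistic:

```bash
yieldgap simulate --out demo --seed 1
yieldgap frontier --plots demo/plots.csv --out demo_frontier
```

which prints

```
frontier slope 57.2 lbs/acre per %LI (R2=0.988, 15 bins)
```

The slope says each percentage point of light interception raises the
*attainable* yield by ~57 lbs/acre (the generator's true value is 57.9; the
binned-decile estimator recovers it within a few percent under default
noise).  The R² is the fit over the 15 bin decile means.
`demo_frontier/gaps.csv` then holds one row per plot-year with observed
yield `y_o`, potential `y_p` and normalized yield `y_n`; here 7.0% of
plot-years sit above the frontier (`y_n > 1`), i.e. "very few", as a
boundary-line analysis requires.

The same stages are available as a library:

```python
from yieldgap import SimConfig, simulate_all, estimate_frontier, compute_gaps

res = simulate_all(SimConfig(seed=1))
model = estimate_frontier(res.dataset)   # model.slope ≈ 57.2
gaps = compute_gaps(res.dataset, model)  # gaps.y_n is the gap statistic
```

A full pipeline run (simulate → features → frontier → screen → fit →
report) is driven by one YAML config (a complete default is checked in at
`tests/fixtures/run_default.yaml`):

```bash
yieldgap run --config tests/fixtures/run_default.yaml --out runs/demo
yieldgap report --run runs/demo
```

The run directory contains `features.csv` (+ a column manifest),
`frontier.json`, `gaps.csv`, `scenario_comparison.csv` (cross-validated
RMSE/R²/RPIQ for scenarios A–D), per-model importance and partial-dependence
tables, decision-rule JSON, and a manifest with input/output hashes.  Two
runs with the same master seed are byte-identical.

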