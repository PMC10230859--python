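# trialpool

Discrete-event simulation and cost-effectiveness analysis of a pooled
funding mechanism for late-stage clinical trials of poverty-related and
neglected disease products.

The package models three funding design options (vaccines for 4 diseases;
vaccines + therapeutics + diagnostics for 9 or for the full disease list).
For each option it:

1. **generates a synthetic candidate portfolio and disease-parameter
   table** (`trialpool.synthetic_data`) honouring the published marginal
   counts, with seeded multinomial allocation of the unpublished cells;
2. **simulates the R&D pipeline 2019–2030** (`trialpool.pipeline_des`):
   candidates advance through preclinical/phase I/II/III with per-archetype
   costs, durations and success probabilities, annual replenishment for the
   first five years, Monte Carlo aggregation, and scenario transforms
   (+100% phase III cost & durations; 50%/100% adaptive-trial efficiency);
3. **converts launches into health and economic benefits through 2035**
   (`trialpool.benefits_model`): vaccine incidence-reduction and
   treatment-coverage ramps, yearly cases/deaths/YLL/YLD/DALYs/treatment
   costs averted;
4. **assembles the cost side** (`trialpool.cost_model`): operating,
   start-up and health-system-strengthening costs, phase III spend, and
   vaccine procurement;
5. **discounts everything and reports the headline economics**
   (`trialpool.economics`): net cost, net benefit, BCR, cost per DALY and
   per death averted, and ICERs between options, under societal and
   altruistic-investor perspectives.

## Command line

```bash
# synthetic inputs for design option 1
trialpool generate --option 1 --seed 1 --out out/gen

# pipeline simulation (100 Monte Carlo runs)
trialpool simulate --portfolio out/gen/portfolio.csv --option 1 \
    --scenario main --n-runs 100 --seed 1 --out out/sim

# averted outcomes from the simulated launches
trialpool benefits --launches out/sim/launches.csv --epi out/gen/epi.csv \
    --out out/ben

# discounted summary for one perspective
trialpool economics --benefit-series out/ben/benefit_series.csv \
    --spend out/sim/spend.csv --option 1 --out out/summary1.json

# or everything in one step
trialpool run-all --option 1 --scenario main --n-runs 100 --seed 1 --out out/all

# cross-option comparison table with ICERs
trialpool report --summary out/summary1.json --summary out/summary2.json \
    --out out/report.csv
```

`run-all` also accepts `--config config.yaml` whose keys mirror
`trialpool.cli.RunConfig` (option_id, scenario, n_runs, seed,
perspectives, discount_rate, …); explicit flags override the file.
Scenarios: `main`, `sensitivity_100`, `adaptive_50`, `adaptive_100`.

All intermediate artifacts are plain CSV/JSON, so each stage can be run,
inspected and tested in isolation. Every stage is deterministic given its
seed.

## Notes

- Phase parameters ship with the package (`base_phase_params()`); phases
  marked absent for an archetype are skipped (e.g. simple repurposed
  drugs enter at phase II, diagnostic assays launch on completing
  phase II).
- Launches occur on successful exit from the final active phase; market
  entry follows one calendar year later. Only the first launch of each
  product class per disease triggers benefit ramps.
- Monte Carlo benefit aggregation is per run, then averaged; all
  downstream maps are linear in the yearly series, so means are exact.
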