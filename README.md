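# occdebt

Dynamic occupancy modelling and extinction-debt diagnostics for
stream-dwelling species.

## The problem

Long-lived, declining species often keep occupying degraded habitat for years
before local extirpations catch up — an *extinction debt*. Demographic data to
detect this directly are rarely available for rare aquatic species, but
detection/non-detection surveys are. `occdebt` evaluates extinction-debt risk
from multi-season presence/absence data alone, via the dynamic (multi-season)
occupancy model: sites are occupied or not each season (a latent two-state
Markov chain), occupancy changes through colonization and extinction, and
imperfect detection is handled explicitly.

The package targets the design of a winter trapping survey of a threatened
aquatic salamander: 176 stream sites in 13 management units
("subpopulations"), 5 consecutive seasons, up to 4 daily trap checks per
surveyed season, and a heavily unbalanced revisit pattern (most sites
surveyed in only 1–2 seasons). It is written for quantitative ecologists and
agency biologists who need the full workflow — data validation, model
fitting and AICc selection, derived dynamics, uncertainty, and risk labels —
as tested, scriptable Python.

## The model

For site *i*, season *t*, visit *j*:

- Z_{i1} ~ Bernoulli(ψ₁ᵢ)  (initial occupancy)
- Z_{i,t+1} | Z_{it}=1 ~ Bernoulli(φ_{it}), with persistence φ = 1 − ε
- Z_{i,t+1} | Z_{it}=0 ~ Bernoulli(γ_{it})  (colonization)
- y_{itj} | Z_{it}=1 ~ Bernoulli(p_{itj}); no detections when Z_{it}=0

All four parameter groups take covariates through a logit link (e.g. habitat
quality and developed land cover on ε, a categorical drought index on ε,
log-discharge on p). The site likelihood marginalises the latent chain with
a scaled forward pass; missing visits contribute a factor of 1. Candidate
models are ranked by AICc with ΔAICc ≤ 2 flagged as equally supported.

From a fitted model the package derives, per subpopulation:

- finite-sample ("smoothed") occupancy ψ^fs_{it} = Pr(Z_{it}=1 | detection
  record), computed by forward–backward smoothing (exactly 1 where the
  species was detected);
- turnover τ_t = γ(1−ψ) / (γ(1−ψ) + φψ), the probability an occupied site
  was unoccupied the season before;
- equilibrium occupancy ψ_eq = γ / (γ + ε), the fixed point of the occupancy
  recursion ψ' = ψ(1−ε) + (1−ψ)γ;
- the non-equilibrium index (mean ψ^fs − mean ψ_eq), with parametric
  bootstrap 95% CIs for the turnover and equilibrium summaries;
- an ordinal extinction-debt risk label (high turnover with occupancy below
  equilibrium = "debt being realized"; high turnover still at/above
  equilibrium = "debt accruing, not yet realized"; …).

A parametric-bootstrap goodness-of-fit test (Pearson chi-square over
within-season detection-history cohorts) checks for overdispersion, and a
synthetic-data generator reproduces the survey's statistical structure with
known ground truth so every stage is verifiable. Hydrology helpers cover
drainage-area-ratio discharge interpolation at ungaged sites, TQmean flow
flashiness, and drought-stage encoding.

## Worked example

```python
import occdebt as od

config = od.SimulationConfig(drought_site_specific=True, seed=42)
dataset, truth = od.generate_study(config)
print(od.summarize_design(dataset))

model = od.DynamicOccupancyModel(
    psi1=("habitat_score",),
    gamma=("lulc_developed",),
    epsilon=("habitat_score", "lulc_developed", "drought"),
    p=("discharge",),
).fit(dataset)
print(f"converged: {model.converged_}, NLL: {model.nll_:.2f}, AICc: {model.aicc_:.2f}")

summaries = od.subpopulation_summary(model, dataset)
report = od.debt_report(summaries)
print(report[["subpopulation", "turnover", "non_equilibrium", "label"]]
      .round(2).head(4).to_string(index=False))
```

Output:

```
{'n_sites': 176, 'n_seasons': 5, 'naive_occupancy': 0.56, 'n_presence_sites': 98,
 'revisit_counts': {1: 66, 2: 64, 3: 32, 4: 14}, 'trap_nights_per_survey': 40,
 'presence_highscore_fraction': 0.826530612244898}
converged: True, NLL: 599.20, AICc: 1224.32
subpopulation  turnover  non_equilibrium               label
  Upper Neuse      0.60            -0.18 debt being realized
 Middle Neuse      0.40            -0.08   elevated turnover
  Lower Neuse      0.49             0.08   elevated turnover
     Flat/Eno      0.17             0.05         near stable
```

`naive_occupancy` is the share of sites ever producing a detection (0.56
here, before correcting for imperfect detection); `revisit_counts` shows the
unbalanced design (66 sites surveyed in just one season). The fitted
coefficients (see `model.coefficients_table()`) recover the generating
effects — e.g. a negative habitat effect and positive developed-land-cover
effect on extinction. In the debt report, the "Upper Neuse" unit combines
high turnover (0.60) with occupancy 0.18 below its equilibrium level, so
losses are already observable; "Flat/Eno" is near a stable state.

The same workflow is available from the shell:

```sh
occdebt simulate --seed 42 --out data/
occdebt pipeline --data data/ --models models.yaml --seed 1 --out results/
```

which writes `ranking.csv`, `coefficients.csv`, `subpopulations.csv` (the
per-management-unit table with bootstrap CIs), `gof.csv` and
`debt_report.csv`.

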