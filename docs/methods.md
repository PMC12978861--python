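# Methods

## Model and likelihood

`occdebt` fits the standard multi-season (dynamic) occupancy model: a latent
two-state Markov chain per site (occupied/unoccupied) with initial occupancy
ψ₁, colonization γ, extinction ε (persistence φ = 1 − ε), and a Bernoulli
detection layer with per-visit probability p conditional on occupancy. False
positives are excluded by assumption: a detection forces the latent state to
"occupied" in that season.

All four parameter groups use a logit link. The site likelihood marginalises
the latent chain with a *scaled forward pass* over seasons (cost O(T) per
site, vectorised over sites), never by enumerating the 2^T latent sequences;
the per-season scaling constants accumulate into the log-likelihood, so
records with very small emission probabilities cannot underflow. Missing
visits contribute an emission factor of 1; a season with no visits is simply
an unobserved step of the chain. The test suite verifies the forward pass
against an independent brute-force enumeration oracle to 1e-10 on hundreds
of random instances, including random missingness.

Finite-sample ("smoothed") occupancy — Pr(Z_it = 1 | the site's full
detection record) — is computed by forward–backward smoothing and is set to
exactly 1 at any site-season with a detection. For a site with no observed
visits it reduces to the unconditional trajectory ψ_t.

## Design matrices and covariates

Covariates live at three levels: site (habitat score 0–100, effective LULC
proportions, TQmean, drainage area), site × season (ordinal drought index
0–3), and site × season × visit (daily mean discharge, bait age).
Continuous covariates are z-standardised — after a log transform where
tagged, which is the default for discharge given its range — using the rows
that enter the likelihood (sites for site-level columns, performed visits
for visit-level columns). The applied scalings are stored in the fitted
design so rates predicted on new data stay on the training scale.
Standardisation matters for optimizer conditioning: raw 0–100 scores would
put coefficients three orders of magnitude apart.

The drought index expands to baseline-coded dummies (level 0 = no drought
as baseline). For transition parameters, the index attached to transition
t → t+1 is by default that of season t+1 (the interval the transition spans
ends in), configurable to season t; nothing in the biology fixes this
alignment, so both are offered and the default documented. Interactions are
supported for ψ₁ only; with realistic survey effort the likelihood is too
flat to support interactions in γ, ε or p, and they are rejected there.

## Estimation, model selection, uncertainty

Coefficients minimise the NLL by L-BFGS-B from a deterministic all-zero
start (gradient tolerance 1e-8, max 500 iterations), with optional seeded
random multi-starts; a fit is flagged non-converged if the optimizer fails
or the final gradient norm is large. Standard errors come from the inverse
of a central-finite-difference Hessian at the optimum (via
`statsmodels.tools.numdiff`); a singular Hessian (e.g. a covariate level
absent from the data) yields NaN SEs and an explicit
`se_available_ = False` flag rather than a crash.

AICc = 2·NLL + 2K + 2K(K+1)/(n−K−1) with effective sample size n = number
of sites by default (sites are the independent units of the likelihood);
this convention is configurable since reasonable alternatives exist.
Candidate sets are ranked ascending by AICc; ΔAICc ≤ 2 marks equal support;
ties break by fewer parameters, then name. When n ≤ K+1 the correction is
undefined: the scalar `aicc()` helper raises, and `fit` records NaN with a
warning so tiny toy fits remain usable.

## Derived quantities and extinction debt

Per subpopulation (management unit) and season, the package averages the
fitted rates and the smoothed occupancy over the sites *surveyed that
season*, then plugs the averages into

- turnover τ_t = γ̄(1−ψ̄) / (γ̄(1−ψ̄) + φ̄ψ̄), using season t−1 averages
  (ψ̄ is the mean smoothed occupancy, the reported default; an alternative
  mode averages site-level turnovers instead — the two differ in general
  because the plug-in of averages is not the average of plug-ins);
- equilibrium occupancy ψ_eq,t = γ̄_t / (γ̄_t + ε̄_t), the unique fixed
  point of the occupancy recursion (verified to 1e-12 on a grid);
- the non-equilibrium index: mean smoothed occupancy minus mean equilibrium
  occupancy. Negative values mean current occupancy is below the level
  colonization can sustain.

Dynamics-derived quantities are never reported for the final season; the
last transition's parameters are not separately identified in this
frequentist framework, so turnover covers seasons 2..T−1 and equilibrium
seasons 1..T−1.

Uncertainty comes from a parametric bootstrap: simulate latent states and
detections from the fitted rates on the *observed* survey design, refit the
same model structure, recompute the summaries; 95% intervals are percentile
intervals (the minimal-assumption choice; the bootstrap replicates are not
guaranteed symmetric). Replicates that fail to converge are dropped and
counted; more than 20% failures aborts with a diagnostic. Everything is
reproducible from a seed.

Debt classification uses configurable turnover cut-points (defaults 0.25
and 0.50 for low/moderate/high) and a ±0.10 "near zero" band on the
non-equilibrium index: high turnover with negative non-equilibrium is
labelled "debt being realized", high turnover with non-negative
non-equilibrium "debt accruing, not yet realized", low turnover with a
small index "near stable". The continuous values are always reported next
to the labels; the tiers are a communication device, not a statistical
test.

## Goodness of fit

The GOF statistic is a Pearson chi-square over within-season
detection-history cohorts: sites surveyed in a season are grouped by their
visit-missingness pattern; within a pattern every possible detection string
is a cell; expected counts combine the fitted detection probabilities with
the smoothed occupancy state probabilities; cells with expected count < 2
(configurable) pool into a per-season remainder. The statistic's null
distribution, p-value (fraction of bootstrap statistics ≥ observed) and
overdispersion factor c-hat (observed / bootstrap mean) all come from a
parametric bootstrap, so constructional bias in the statistic is shared
between observed and bootstrap values and cancels.

Two properties of this construction are worth knowing. First, the number of
effective cells bounds how tightly c-hat can concentrate: with the sparse
field design (~55 surveyed sites/season, a single all-4-visit pattern) only
~30 cells survive pooling, giving c-hat a CV near 0.3 under the true model
— that is intrinsic dispersion, not lack of fit. The calibration
experiments in the test suite therefore use a denser design (600 sites,
full revisits, 40% random visit dropout, ~400 retained cells) where c-hat
concentrates to ±7%. Second, parametric-bootstrap p-values are only
asymptotically uniform: the observed data come from the true parameters
while bootstrap data come from the estimate, and this "double bootstrap"
non-pivotality slightly fattens both tails of the p-value distribution at
finite sample sizes. An exchangeability experiment (outer data generated at
the same parameters the bootstrap uses) confirms the machinery itself is
exact.

## Synthetic data generator

The generator emulates the survey the package targets: 176 sites allocated
to 13 named management units (9/16/7/17/15/18/19/8/13/15/19/7/13), 5
seasons, 4 daily visits, and a per-site number of surveyed seasons drawn
with mass 0.38/0.36/0.20/0.05/0.01 on 1..5 — the published revisit
imbalance. Covariates: habitat score from a clipped Normal(70.45, 12.32)
(the survey's reported mean ± SD) on [0, 100]; developed LULC from
Beta(2, 5) with the remaining proportion split Dirichlet among
herbaceous/pasture, crop, wetland and forest so proportions stay in [0, 1]
and sum to 1; TQmean decreasing in developed cover; drought as one
basin-wide index per season (site-specific optional — the region typically
sees at most one regional drought per year, but the schema supports spatial
variation); per-visit log-discharge as site mean + season effect + within-
season AR(1) (ρ = 0.7). Default true coefficients put the qualitative
effect structure of the motivating analysis on standardised scales
(habitat −, developed +, drought + on extinction; discharge + on
detection) at moderate magnitudes chosen so all rates stay well inside
(0, 1); they are a realistic test bed, not a reproduction of any fitted
values. An optional `visit_dropout` thins visits within surveyed seasons
(keeping at least one) to create within-season missingness patterns.

All randomness flows through `numpy.random.default_rng` (PCG64);
`generate_study` spawns child seeds for covariates, latent states and
detections, so a master seed reproduces the study exactly.

What the generator does *not* emulate — and hence what passing tests do not
show about field data: spatial autocorrelation in covariates or dynamics,
unmodelled site-level detection heterogeneity (except in the dedicated
misspecification test), observer effects, trap loss, and any real
hydrology; discharge series are synthetic AR(1) draws, not gauge records.

## Experiment scales

Verification experiments are sized for desk hardware: oracle comparisons on
200 random instances (≤ 10 sites, T ≤ 4); coefficient recovery on 20
replicates of 500 sites; bootstrap coverage on 100 replicates at 176 sites
with 50 bootstrap refits each; GOF calibration on 20 replicates with 60
bootstrap refits each. The bootstrap default for a real analysis is 500
simulations.

## Known limitations

No Bayesian estimation, random effects, spatial autocorrelation,
multi-state or false-positive extensions. Subpopulation summaries compare a
data-conditional quantity (smoothed occupancy) with an unconditional one
(equilibrium occupancy); averaging over sites and seasons smooths real
variation, which is the price of reporting at the management-unit scale.
The AICc effective-sample-size convention is a documented choice, not a
settled fact. Gage selection uses planar Euclidean distance supplied by the
user; no geodesic or GIS computation is performed.
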