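"""Synthetic multi-season occupancy studies with known ground truth.

The generator emulates the structure of a 5-season stream-salamander survey:
176 sites split over 13 subpopulations, up to 4 consecutive daily visits per
surveyed season, and a heavily unbalanced revisit design in which most sites
are surveyed in only 1-2 of the 5 seasons (default per-site mass 0.38 / 0.36
/ 0.20 / 0.05 / 0.01 on 1..5 surveyed seasons). Covariates mimic the field
quantities: a 0-100 habitat assessment score, effective land-use proportions,
a seasonal ordinal drought index, and per-visit log-discharge with an AR(1)
within-season structure.

True coefficients act on the same standardised design matrices that
:func:`occdebt.design.build_design` produces, so fitted coefficients are
directly comparable to the generating ones. Default effect structure and
magnitudes echo the kind of multiscale-threat pattern seen in real surveys
(habitat quality and developed land cover on extinction, drought dummies on
extinction, log-discharge on detection); they are a realistic test bed, not
a reproduction of any particular fitted values.

All randomness flows through ``numpy.random.default_rng`` (PCG64); a given
seed reproduces the study bit-for-bit.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import DetectionHistory, StudyDataset
from .design import ModelSpec, build_design
from .likelihood import simulate_detections_from_states, simulate_latent_states
from .model import RateSurfaces, rates_from_params

#: site allocation of the 13 management units (sums to 176)
DEFAULT_SUBPOPULATIONS = {
    "Upper Neuse": 9, "Middle Neuse": 16, "Lower Neuse": 7, "Flat/Eno": 17,
    "Swift/Middle": 15, "Little River": 18, "Contentnea": 19, "Trent": 8,
    "Upper Tar": 13, "Middle Tar": 15, "Lower Tar": 19, "Sandy/Swift": 7,
    "Fishing": 13,
}

DEFAULT_REVISIT_PROBS = {1: 0.38, 2: 0.36, 3: 0.20, 4: 0.05, 5: 0.01}

DEFAULT_COEFFICIENTS = {
    "psi1": {"(intercept)": -0.14, "habitat_score": 0.2},
    "gamma": {"(intercept)": -1.5, "lulc_developed": 0.5},
    "epsilon": {"(intercept)": -1.6, "habitat_score": -1.0,
                "lulc_developed": 0.9,
                "drought_1": 0.8, "drought_2": 1.2, "drought_3": 1.6},
    "p": {"(intercept)": -0.1, "discharge": 0.31},
}

DEFAULT_SPEC = ModelSpec(
    psi1=("habitat_score",),
    gamma=("lulc_developed",),
    epsilon=("habitat_score", "lulc_developed", "drought"),
    p=("discharge",),
    name="generator",
)


@dataclass
class SimulationConfig:
    """Generating parameters of one synthetic study.

    ``coefficients`` maps parameter group -> {design column -> value} on the
    logit scale of the standardised design; columns absent from the model
    spec are ignored, columns in the spec but absent here default to 0.
    """

    n_sites: int = 176
    n_seasons: int = 5
    n_visits: int = 4
    subpopulations: dict = field(default_factory=lambda: dict(DEFAULT_SUBPOPULATIONS))
    revisit_probs: dict = field(default_factory=lambda: dict(DEFAULT_REVISIT_PROBS))
    habitat_mean: float = 70.45
    habitat_sd: float = 12.32
    developed_beta: tuple = (2.0, 5.0)
    drought_probs: tuple = (0.40, 0.25, 0.20, 0.15)
    drought_site_specific: bool = False
    visit_dropout: float = 0.0
    log_discharge_mean: float = 0.7
    log_discharge_site_sd: float = 1.0
    log_discharge_season_sd: float = 0.5
    discharge_ar1_rho: float = 0.7
    discharge_ar1_sd: float = 0.25
    coefficients: dict = field(default_factory=lambda: copy.deepcopy(DEFAULT_COEFFICIENTS))
    spec: ModelSpec = field(default_factory=lambda: DEFAULT_SPEC)
    seed: int | None = None

    def __post_init__(self):
        if abs(sum(self.revisit_probs.values()) - 1.0) > 1e-9:
            raise ValueError("revisit_probs must sum to 1")
        if any(k < 1 or k > self.n_seasons for k in self.revisit_probs):
            raise ValueError("revisit_probs keys must lie in 1..n_seasons")
        if abs(sum(self.drought_probs) - 1.0) > 1e-9 or len(self.drought_probs) != 4:
            raise ValueError("drought_probs must be 4 probabilities summing to 1")
        a, b = self.developed_beta
        if a <= 0 or b <= 0:
            raise ValueError("developed_beta parameters must be positive")
        if sum(self.subpopulations.values()) != self.n_sites:
            raise ValueError("subpopulation allocation must sum to n_sites")
        if not 0 <= self.discharge_ar1_rho < 1:
            raise ValueError("discharge AR(1) rho must be in [0, 1)")
        if not 0 <= self.visit_dropout < 1:
            raise ValueError("visit_dropout must be in [0, 1)")


@dataclass
class Covariates:
    """Generated covariate tables plus the planned survey design."""

    sites: pd.DataFrame
    drought: np.ndarray      # (n, T)
    discharge: np.ndarray    # (n, T, J), NaN at unsurveyed seasons
    bait_age: np.ndarray     # (n, T, J)
    observed: np.ndarray     # (n, T, J) bool: visit planned
    revisit_counts: dict     # k surveyed seasons -> number of sites


@dataclass
class SimulationTruth:
    """Ground truth of one synthetic study, for recovery testing."""

    config: SimulationConfig
    spec: ModelSpec
    coef: np.ndarray          # generating coefficients, design order
    coef_names: dict          # group -> column names
    Z: np.ndarray             # (n, T) latent occupancy
    rates: RateSurfaces
    scalings: dict
    revisit_counts: dict


def simulate_covariates(config: SimulationConfig,
                        seed: int | None = None) -> Covariates:
    """Draw site/season/visit covariates and the revisit plan.

    Reproducible from ``seed`` (falls back to ``config.seed``).
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    n, T, J = config.n_sites, config.n_seasons, config.n_visits

    subpop = np.repeat(list(config.subpopulations.keys()),
                       list(config.subpopulations.values()))
    huc10 = {name: f"03020{200 + i}" for i, name in enumerate(config.subpopulations)}

    habitat = np.clip(rng.normal(config.habitat_mean, config.habitat_sd, n), 0, 100)
    substrate = np.clip(rng.normal(10.0, 3.0, n), 0, 15)
    cover = np.clip(rng.normal(12.0, 4.0, n), 0, 20)
    developed = rng.beta(*config.developed_beta, size=n)
    # split the non-developed remainder so proportions stay in [0,1] and sum to 1
    rest = rng.dirichlet([1.5, 1.0, 0.8, 4.7], size=n) * (1.0 - developed)[:, None]
    herb, crop, wetland = rest[:, 0], rest[:, 1], rest[:, 2]
    tq = np.clip(rng.normal(0.42 - 0.25 * developed, 0.05), 0.01, 0.99)
    area = np.exp(rng.normal(6.0, 0.8, n))

    sites = pd.DataFrame({
        "subpopulation": subpop,
        "huc10": [huc10[s] for s in subpop],
        "drainage_area_km2": area,
        "habitat_score": habitat,
        "substrate_score": substrate,
        "cover_score": cover,
        "lulc_developed": developed,
        "lulc_herbpasture": herb,
        "lulc_crop": crop,
        "lulc_wetland": wetland,
        "tqmean": tq,
    }, index=pd.Index([f"S{i + 1:03d}" for i in range(n)], name="site"))

    if config.drought_site_specific:
        drought = rng.choice(4, size=(n, T), p=config.drought_probs)
    else:
        path = rng.choice(4, size=T, p=config.drought_probs)
        drought = np.broadcast_to(path, (n, T)).copy()

    # revisit design: number of surveyed seasons per site, then which seasons
    ks = sorted(config.revisit_probs)
    k_per_site = rng.choice(ks, size=n, p=[config.revisit_probs[k] for k in ks])
    observed = np.zeros((n, T, J), dtype=bool)
    for i in range(n):
        seasons = rng.choice(T, size=k_per_site[i], replace=False)
        observed[i, seasons, :] = True
    if config.visit_dropout > 0:
        # skip individual visits within surveyed seasons, keeping at least one
        keep = rng.random((n, T, J)) >= config.visit_dropout
        forced = rng.integers(0, J, (n, T))
        keep[np.arange(n)[:, None], np.arange(T)[None, :], forced] = True
        observed &= keep
    revisit_counts = {int(k): int((k_per_site == k).sum()) for k in np.unique(k_per_site)}

    # log-discharge: site mean + season effect + within-season AR(1)
    mu = rng.normal(config.log_discharge_mean, config.log_discharge_site_sd, n)
    season_eff = rng.normal(0.0, config.log_discharge_season_sd, (n, T))
    rho, sd = config.discharge_ar1_rho, config.discharge_ar1_sd
    ar = np.zeros((n, T, J))
    ar[:, :, 0] = rng.normal(0.0, sd / np.sqrt(1.0 - rho ** 2), (n, T))
    for j in range(1, J):
        ar[:, :, j] = rho * ar[:, :, j - 1] + rng.normal(0.0, sd, (n, T))
    logq = mu[:, None, None] + season_eff[:, :, None] + ar
    discharge = np.where(observed, np.exp(logq), np.nan)
    bait_age = np.where(observed, np.arange(1, J + 1)[None, None, :], np.nan).astype(float)

    return Covariates(sites, drought, discharge, bait_age, observed, revisit_counts)


def _provisional_dataset(cov: Covariates) -> StudyDataset:
    """Dataset with placeholder zeros at planned visits (for design building)."""
    y = np.where(cov.observed, 0.0, np.nan)
    det = DetectionHistory(list(cov.sites.index), y)
    return StudyDataset(det, cov.sites, cov.drought, cov.discharge, cov.bait_age)


def true_rates(config: SimulationConfig, cov: Covariates):
    """Rate surfaces implied by the generating coefficients on this design.

    Returns ``(rates, coef_vector, coef_names, scalings)``; coefficients are
    laid out in the same standardised-design order a fit would use, so the
    vector is directly comparable to fitted ``coef_``.
    """
    design = build_design(config.spec, _provisional_dataset(cov))
    coef = []
    for group in ("psi1", "gamma", "epsilon", "p"):
        wanted = config.coefficients.get(group, {})
        for col in design.columns[group]:
            coef.append(float(wanted.get(col, 0.0)))
    coef = np.asarray(coef)
    rates = rates_from_params(coef, design)
    lo = np.concatenate([np.atleast_1d(rates.psi1), rates.gamma.ravel(),
                         rates.epsilon.ravel()])
    if np.any((lo <= 0) | (lo >= 1)):
        raise ValueError("generating coefficients imply degenerate occupancy rates")
    return rates, coef, dict(design.columns), dict(design.scalings)


def simulate_latent(config: SimulationConfig, cov: Covariates,
                    seed: int | None = None) -> np.ndarray:
    """Latent occupancy Z (n, T): Z_1 ~ Bern(psi1), then the Markov chain."""
    rng = np.random.default_rng(config.seed if seed is None else seed)
    rates, *_ = true_rates(config, cov)
    return simulate_latent_states(rates.psi1, rates.gamma, rates.epsilon, rng)


def simulate_detections(Z: np.ndarray, config: SimulationConfig, cov: Covariates,
                        seed: int | None = None) -> DetectionHistory:
    """Visit detections y ~ Bernoulli(Z * p) on the planned survey design."""
    rng = np.random.default_rng(config.seed if seed is None else seed)
    rates, *_ = true_rates(config, cov)
    y = simulate_detections_from_states(Z, rates.p, cov.observed, rng)
    return DetectionHistory(list(cov.sites.index), y)


def generate_study(config: SimulationConfig | None = None,
                   seed: int | None = None) -> tuple[StudyDataset, SimulationTruth]:
    """Generate a complete synthetic study plus its ground truth.

    Covariates, latent states and detections use independent child seeds
    spawned deterministically from the master seed.
    """
    config = config or SimulationConfig()
    master = np.random.default_rng(config.seed if seed is None else seed)
    s_cov, s_lat, s_det = master.integers(0, 2 ** 31 - 1, size=3)

    cov = simulate_covariates(config, int(s_cov))
    rates, coef, names, scalings = true_rates(config, cov)
    Z = simulate_latent_states(rates.psi1, rates.gamma, rates.epsilon,
                               np.random.default_rng(int(s_lat)))
    y = simulate_detections_from_states(Z, rates.p, cov.observed,
                                        np.random.default_rng(int(s_det)))
    det = DetectionHistory(list(cov.sites.index), y)
    dataset = StudyDataset(det, cov.sites, cov.drought, cov.discharge, cov.bait_age)
    truth = SimulationTruth(config, config.spec, coef, names, Z, rates,
                            scalings, cov.revisit_counts)
    return dataset, truth
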