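"""Parametric-bootstrap goodness-of-fit (overdispersion) test.

The observed statistic is a Pearson chi-square over within-season detection
history cohorts: for each season, the sites surveyed that season are grouped
by their visit-missingness pattern, and within each pattern every possible
detection string is a cell. Expected counts come from the fitted detection
probabilities and the smoothed (full-record-conditional) occupancy state
probabilities; cells with expected count below a pooling threshold are pooled
into a per-season remainder cell. Because the statistic's null distribution
is produced by the parametric bootstrap itself (simulate from the fitted
model, refit, recompute), any bias in the statistic's construction is shared
between the observed and bootstrap values and cancels in the p-value and
c-hat.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.base import clone

from .data import StudyDataset
from .errors import BootstrapError
from .likelihood import simulate_detections_from_states, simulate_latent_states
from .model import DynamicOccupancyModel


@dataclass
class GofResult:
    statistic: float
    boot_mean: float
    boot_sd: float
    p_value: float
    c_hat: float
    n_sim: int
    n_failed: int
    seed: int | None
    boot_statistics: np.ndarray


def pearson_chisq(observed, expected, pool_threshold: float = 2.0) -> float:
    """Pearson chi-square over cells, pooling cells with expected count below
    ``pool_threshold`` into a single remainder cell."""
    chi = 0.0
    pooled_obs = pooled_exp = 0.0
    for O, E in zip(np.asarray(observed, dtype=float), np.asarray(expected, dtype=float)):
        if E < pool_threshold:
            pooled_obs += O
            pooled_exp += E
        else:
            chi += (O - E) ** 2 / E
    if pooled_exp > 0:
        chi += (pooled_obs - pooled_exp) ** 2 / pooled_exp
    return float(chi)


def cohort_chisq(fit: DynamicOccupancyModel, dataset: StudyDataset | None = None,
                 pool_threshold: float = 2.0) -> float:
    """Pearson chi-square of observed vs expected detection-history cohorts.

    Seasons with fewer than two distinct observed histories contribute 0
    (with a warning). Invariant to site ordering.
    """
    if dataset is None:
        dataset = fit._train_dataset
    rates = fit.predict_rates(None if dataset is fit._train_dataset else dataset)
    smoothed = fit.predict_smoothed(None if dataset is fit._train_dataset else dataset)
    y = dataset.detections.y
    obs_mask = dataset.detections.observed
    n, T, J = y.shape

    total = 0.0
    for t in range(T):
        surveyed_t = obs_mask[:, t].any(axis=1)
        idx = np.flatnonzero(surveyed_t)
        if idx.size == 0:
            continue
        # distinct observed histories this season
        hist_keys = set()
        for i in idx:
            pat = tuple(np.flatnonzero(obs_mask[i, t]))
            string = tuple(int(v) for v in y[i, t, list(pat)])
            hist_keys.add((pat, string))
        if len(hist_keys) < 2:
            warnings.warn(f"season {t + 1}: fewer than 2 distinct histories; contributes 0")
            continue

        # group sites by visit pattern; cells = all strings over the pattern
        patterns: dict[tuple, list[int]] = {}
        for i in idx:
            patterns.setdefault(tuple(np.flatnonzero(obs_mask[i, t])), []).append(i)

        cells_obs: list[float] = []
        cells_exp: list[float] = []
        for pat, members in patterns.items():
            members = np.asarray(members)
            v = len(pat)
            pvis = rates.p[members][:, t, list(pat)]       # (m, v)
            psi_state = smoothed[members, t]               # (m,)
            observed_strings = {}
            for i in members:
                s = tuple(int(x) for x in y[i, t, list(pat)])
                observed_strings[s] = observed_strings.get(s, 0) + 1
            for string in itertools.product((0, 1), repeat=v):
                d = np.asarray(string, dtype=float)
                pr_given_occ = np.prod(np.where(d == 1, pvis, 1.0 - pvis), axis=1)
                pr = psi_state * pr_given_occ
                if not any(string):
                    pr = pr + (1.0 - psi_state)
                cells_obs.append(float(observed_strings.get(string, 0)))
                cells_exp.append(float(pr.sum()))
        total += pearson_chisq(cells_obs, cells_exp, pool_threshold)
    return float(total)


def parametric_bootstrap_gof(fit: DynamicOccupancyModel,
                             dataset: StudyDataset | None = None,
                             n_sim: int = 100, seed: int | None = None,
                             pool_threshold: float = 2.0,
                             max_failure_rate: float = 0.2) -> GofResult:
    """Bootstrap the cohort chi-square under the fitted model.

    p-value = fraction of bootstrap statistics >= observed;
    c-hat = observed / mean(bootstrap). Reproducible from ``seed``.
    """
    if n_sim < 2:
        raise ValueError("n_sim must be >= 2")
    if dataset is None:
        dataset = fit._train_dataset
    rng = np.random.default_rng(seed)
    observed_stat = cohort_chisq(fit, dataset, pool_threshold)
    rates = fit.predict_rates(None if dataset is fit._train_dataset else dataset)
    obs_mask = dataset.detections.observed

    stats = []
    n_failed = 0
    for _ in range(n_sim):
        Z = simulate_latent_states(rates.psi1, rates.gamma, rates.epsilon, rng)
        ysim = simulate_detections_from_states(Z, rates.p, obs_mask, rng)
        sim = dataset.replace_detections(ysim)
        try:
            refit = clone(fit).fit(sim, compute_se=False)
        except Exception:
            n_failed += 1
            continue
        if not refit.converged_:
            n_failed += 1
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            stats.append(cohort_chisq(refit, sim, pool_threshold))

    if n_failed > max_failure_rate * n_sim:
        raise BootstrapError(
            f"{n_failed}/{n_sim} GOF bootstrap replicates failed "
            f"(> {max_failure_rate:.0%} allowed)")

    stats = np.asarray(stats, dtype=float)
    boot_mean = float(stats.mean())
    return GofResult(
        statistic=observed_stat,
        boot_mean=boot_mean,
        boot_sd=float(stats.std()),
        p_value=float(np.mean(stats >= observed_stat)),
        c_hat=float(observed_stat / boot_mean) if boot_mean > 0 else float("inf"),
        n_sim=int(stats.size),
        n_failed=n_failed,
        seed=seed,
        boot_statistics=stats,
    )
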