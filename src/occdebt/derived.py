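"""Derived occurrence dynamics and extinction-debt diagnostics.

From a fitted model we derive, per subpopulation (management unit):

- mean finite-sample ("smoothed") occupancy: the probability each surveyed
  site was occupied given its full detection record;
- mean colonization, extinction and persistence probabilities;
- annual turnover tau_t = Pr(site unoccupied in t-1 | occupied in t),
  computed by plugging subpopulation averages into
  tau = gamma(1-psi) / (gamma(1-psi) + phi*psi);
- equilibrium occupancy psi_eq = gamma / (gamma + eps), the fixed point of
  the occupancy recursion;
- the non-equilibrium index: mean finite-sample occupancy minus mean
  equilibrium occupancy (negative = occupancy below the stable level);
- percentile bootstrap CIs for mean turnover and mean equilibrium occupancy
  via parametric bootstrap (simulate from the fitted model on the observed
  design, refit, resummarise).

Dynamics-derived quantities are never reported for the final season: the
last transition's rates are not separately identified in this framework, so
turnover covers seasons 2..T-1 and equilibrium seasons 1..T-1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import clone

from .data import StudyDataset
from .errors import BootstrapError
from .likelihood import simulate_detections_from_states, simulate_latent_states
from .model import DynamicOccupancyModel


# ---------------------------------------------------------------------------
# Scalar identities
# ---------------------------------------------------------------------------

def occupancy_recursion(psi_t, gamma_t, epsilon_t):
    """One step of the occupancy recursion: psi' = psi(1-eps) + (1-psi)gamma."""
    psi_t, gamma_t, epsilon_t = (np.asarray(v, dtype=float) for v in (psi_t, gamma_t, epsilon_t))
    for name, v in (("psi", psi_t), ("gamma", gamma_t), ("epsilon", epsilon_t)):
        if np.any((v < 0) | (v > 1)):
            raise ValueError(f"{name} must lie in [0, 1]")
    return psi_t * (1.0 - epsilon_t) + (1.0 - psi_t) * gamma_t


def turnover_probability(gamma_prev, psi_prev, phi_prev):
    """tau = gamma(1-psi) / (gamma(1-psi) + phi*psi).

    The probability that a site occupied in season t was unoccupied in season
    t-1, given rates of season t-1. Raises on a zero denominator (the state
    "occupied at t" would be impossible).
    """
    gamma_prev, psi_prev, phi_prev = (np.asarray(v, dtype=float)
                                      for v in (gamma_prev, psi_prev, phi_prev))
    for name, v in (("gamma", gamma_prev), ("psi", psi_prev), ("phi", phi_prev)):
        if np.any((v < 0) | (v > 1)):
            raise ValueError(f"{name} must lie in [0, 1]")
    num = gamma_prev * (1.0 - psi_prev)
    den = num + phi_prev * psi_prev
    if np.any(den <= 0):
        raise ValueError("turnover undefined: Pr(occupied at t) = 0")
    return num / den


def equilibrium_occupancy(gamma, epsilon):
    """psi_eq = gamma / (gamma + epsilon); fixed point of the recursion."""
    gamma, epsilon = np.asarray(gamma, dtype=float), np.asarray(epsilon, dtype=float)
    den = gamma + epsilon
    if np.any(den <= 0):
        raise ValueError("equilibrium occupancy undefined for gamma = epsilon = 0")
    return gamma / den


def non_equilibrium(mean_psi_fs, mean_psi_eq):
    """Non-equilibrium index: finite-sample occupancy minus equilibrium."""
    return np.asarray(mean_psi_fs, dtype=float) - np.asarray(mean_psi_eq, dtype=float)


# ---------------------------------------------------------------------------
# Subpopulation summaries
# ---------------------------------------------------------------------------

@dataclass
class SubpopulationSummary:
    """Per-subpopulation seasonal and mean derived quantities (a table row).

    Seasonal vectors: ``psi_fs_t`` has length T (NaN in unsurveyed seasons);
    ``gamma_t``/``epsilon_t``/``psi_eq_t`` have length T-1 (transitions);
    ``tau_t`` has length T-2 (seasons 2..T-1).
    """

    subpopulation: str
    n_sites: int
    psi_fs_t: np.ndarray
    gamma_t: np.ndarray
    epsilon_t: np.ndarray
    tau_t: np.ndarray
    psi_eq_t: np.ndarray

    mean_psi_fs: float = field(init=False)
    mean_gamma: float = field(init=False)
    mean_epsilon: float = field(init=False)
    mean_tau: float = field(init=False)
    mean_psi_eq: float = field(init=False)
    non_equilibrium: float = field(init=False)

    def __post_init__(self):
        def m(v):
            v = np.asarray(v, dtype=float)
            return float(np.nanmean(v)) if np.any(np.isfinite(v)) else float("nan")

        self.mean_psi_fs = m(self.psi_fs_t)
        self.mean_gamma = m(self.gamma_t)
        self.mean_epsilon = m(self.epsilon_t)
        self.mean_tau = m(self.tau_t)
        self.mean_psi_eq = m(self.psi_eq_t)
        self.non_equilibrium = self.mean_psi_fs - self.mean_psi_eq

    def _range(self, v) -> tuple[float, float]:
        v = np.asarray(v, dtype=float)
        if not np.any(np.isfinite(v)):
            return (float("nan"), float("nan"))
        return (float(np.nanmin(v)), float(np.nanmax(v)))

    def as_row(self) -> dict:
        r = self._range
        return {
            "subpopulation": self.subpopulation,
            "n_sites": self.n_sites,
            "occupancy_mean": self.mean_psi_fs,
            "occupancy_min": r(self.psi_fs_t)[0], "occupancy_max": r(self.psi_fs_t)[1],
            "colonization_mean": self.mean_gamma,
            "extinction_mean": self.mean_epsilon,
            "extinction_min": r(self.epsilon_t)[0], "extinction_max": r(self.epsilon_t)[1],
            "turnover_mean": self.mean_tau,
            "turnover_min": r(self.tau_t)[0], "turnover_max": r(self.tau_t)[1],
            "equilibrium_mean": self.mean_psi_eq,
            "equilibrium_min": r(self.psi_eq_t)[0], "equilibrium_max": r(self.psi_eq_t)[1],
            "non_equilibrium": self.non_equilibrium,
        }


def _seasonal_means(values: np.ndarray, surveyed: np.ndarray) -> np.ndarray:
    """Mean over surveyed sites per season; NaN where no site was surveyed.

    ``values`` (m, T') and ``surveyed`` (m, T') boolean on the same seasons.
    """
    w = surveyed.astype(float)
    tot = w.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(tot > 0, (values * w).sum(axis=0) / np.where(tot > 0, tot, 1), np.nan)
    return out


def subpopulation_summary(fit: DynamicOccupancyModel, dataset: StudyDataset,
                          smoothed: np.ndarray | None = None,
                          site_level_turnover: bool = False
                          ) -> list[SubpopulationSummary]:
    """Summarise derived dynamics per subpopulation.

    Seasonal averages run over the sites of the subpopulation surveyed in
    that season. Turnover for season t (t = 2..T-1) plugs the subpopulation
    averages of season t-1 into the turnover formula; with
    ``site_level_turnover=True`` the site-level turnovers are averaged
    instead (the two generally differ; the plug-in of averages is the
    default reported mode). Subpopulations with zero surveyed sites are
    omitted with a warning.
    """
    rates = fit.predict_rates(dataset if dataset is not fit._train_dataset else None)
    if smoothed is None:
        smoothed = fit.predict_smoothed(dataset if dataset is not fit._train_dataset else None)
    surveyed = dataset.detections.surveyed
    T = dataset.n_seasons
    labels = dataset.sites["subpopulation"].to_numpy()

    out = []
    for sub in pd.unique(labels):
        m = labels == sub
        surv = surveyed[m]
        if not surv.any():
            warnings.warn(f"subpopulation {sub!r} has no surveyed site-seasons; omitted")
            continue
        psi_fs_t = _seasonal_means(smoothed[m], surv)
        # transition rates averaged over sites surveyed in the transition's
        # starting season t (t = 1..T-1)
        gamma_t = _seasonal_means(rates.gamma[m], surv[:, :-1])
        eps_t = _seasonal_means(rates.epsilon[m], surv[:, :-1])

        tau = np.full(max(T - 2, 0), np.nan)
        for t in range(1, T - 1):  # report seasons 2..T-1 (0-based t)
            if site_level_turnover:
                msk = surv[:, t - 1]
                if msk.any():
                    site_tau = turnover_probability(
                        rates.gamma[m][msk, t - 1], smoothed[m][msk, t - 1],
                        rates.phi[m][msk, t - 1])
                    tau[t - 1] = float(site_tau.mean())
            else:
                g, ps, ph = gamma_t[t - 1], psi_fs_t[t - 1], 1.0 - eps_t[t - 1]
                if np.isfinite(g) and np.isfinite(ps) and np.isfinite(ph):
                    tau[t - 1] = float(turnover_probability(g, ps, ph))

        psi_eq = np.full(T - 1, np.nan)
        ok = np.isfinite(gamma_t) & np.isfinite(eps_t) & ((gamma_t + eps_t) > 0)
        psi_eq[ok] = equilibrium_occupancy(gamma_t[ok], eps_t[ok])

        out.append(SubpopulationSummary(str(sub), int(m.sum()), psi_fs_t,
                                        gamma_t, eps_t, tau, psi_eq))
    return out


def summary_table(summaries: list[SubpopulationSummary]) -> pd.DataFrame:
    """Stack subpopulation rows into the report table."""
    return pd.DataFrame([s.as_row() for s in summaries])


# ---------------------------------------------------------------------------
# Parametric bootstrap for the derived summaries
# ---------------------------------------------------------------------------

def bootstrap_summaries(fit: DynamicOccupancyModel, dataset: StudyDataset,
                        n_sim: int = 500, seed: int | None = None,
                        max_failure_rate: float = 0.2) -> pd.DataFrame:
    """Percentile 95% CIs for mean turnover and mean equilibrium occupancy.

    Each replicate simulates latent states and detections from the fitted
    rates on the observed survey design, refits the same model structure,
    and recomputes the subpopulation summaries. Replicates that fail to
    converge are dropped and counted; more than ``max_failure_rate`` of
    failures aborts with :class:`BootstrapError`. Fully reproducible from
    ``seed``.
    """
    if n_sim < 2:
        raise ValueError("n_sim must be >= 2")
    rng = np.random.default_rng(seed)
    rates = fit.predict_rates()
    observed = dataset.detections.observed

    base = subpopulation_summary(fit, dataset)
    subs = [s.subpopulation for s in base]
    draws_tau = {s: [] for s in subs}
    draws_eq = {s: [] for s in subs}
    n_failed = 0

    for _ in range(n_sim):
        Z = simulate_latent_states(rates.psi1, rates.gamma, rates.epsilon, rng)
        y = simulate_detections_from_states(Z, rates.p, observed, rng)
        sim = dataset.replace_detections(y)
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
            reps = {s.subpopulation: s for s in subpopulation_summary(refit, sim)}
        for s in subs:
            if s in reps:
                draws_tau[s].append(reps[s].mean_tau)
                draws_eq[s].append(reps[s].mean_psi_eq)

    if n_failed > max_failure_rate * n_sim:
        raise BootstrapError(
            f"{n_failed}/{n_sim} bootstrap replicates failed to refit "
            f"(> {max_failure_rate:.0%} allowed)")

    rows = []
    for s in base:
        t = np.asarray(draws_tau[s.subpopulation], dtype=float)
        e = np.asarray(draws_eq[s.subpopulation], dtype=float)
        t, e = t[np.isfinite(t)], e[np.isfinite(e)]
        rows.append({
            "subpopulation": s.subpopulation,
            "turnover_mean": s.mean_tau,
            "turnover_ci_lower": float(np.percentile(t, 2.5)) if t.size else np.nan,
            "turnover_ci_upper": float(np.percentile(t, 97.5)) if t.size else np.nan,
            "equilibrium_mean": s.mean_psi_eq,
            "equilibrium_ci_lower": float(np.percentile(e, 2.5)) if e.size else np.nan,
            "equilibrium_ci_upper": float(np.percentile(e, 97.5)) if e.size else np.nan,
            "n_replicates": int(t.size),
            "n_failed": n_failed,
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Debt classification
# ---------------------------------------------------------------------------

@dataclass
class DebtThresholds:
    """Cut-points for the ordinal debt-risk labels.

    Turnover below ``low`` is "low", above ``high`` is "high", between is
    "moderate". ``stable_band`` is the |non-equilibrium| width treated as
    "near zero" for low-turnover subpopulations.
    """

    low: float = 0.25
    high: float = 0.50
    stable_band: float = 0.10


@dataclass
class DebtAssessment:
    subpopulation: str
    turnover: float
    non_equilibrium: float
    turnover_tier: str
    label: str
    rule: str


def classify_debt(summary: SubpopulationSummary | dict,
                  thresholds: DebtThresholds | None = None) -> DebtAssessment:
    """Ordinal extinction-debt risk label from turnover and non-equilibrium.

    High turnover with occupancy below equilibrium means losses are already
    observable ("debt being realized"); high turnover with occupancy still at
    or above equilibrium means the debt has accrued but not yet been paid.
    Low turnover with a small non-equilibrium index is "near stable".
    """
    th = thresholds or DebtThresholds()
    if isinstance(summary, SubpopulationSummary):
        sub, tau, neq = summary.subpopulation, summary.mean_tau, summary.non_equilibrium
    else:
        sub = summary.get("subpopulation", "?")
        tau = summary["turnover_mean"] if "turnover_mean" in summary else summary["turnover"]
        neq = summary["non_equilibrium"]

    tier = "low" if tau < th.low else ("high" if tau >= th.high else "moderate")
    if tier == "high":
        if neq < 0:
            label = "debt being realized"
            rule = f"turnover {tau:.3f} >= {th.high} and non-equilibrium {neq:+.3f} < 0"
        else:
            label = "debt accruing, not yet realized"
            rule = f"turnover {tau:.3f} >= {th.high} and non-equilibrium {neq:+.3f} >= 0"
    elif tier == "moderate":
        if neq < -th.stable_band:
            label = "elevated turnover, below equilibrium"
        else:
            label = "elevated turnover"
        rule = f"{th.low} <= turnover {tau:.3f} < {th.high}"
    else:
        if neq < -th.stable_band:
            label = "below equilibrium, low turnover"
            rule = f"turnover {tau:.3f} < {th.low} and non-equilibrium {neq:+.3f} < -{th.stable_band}"
        else:
            label = "near stable"
            rule = f"turnover {tau:.3f} < {th.low} and |non-equilibrium {neq:+.3f}| small"
    return DebtAssessment(sub, float(tau), float(neq), tier, label, rule)


def debt_report(summaries: list[SubpopulationSummary],
                thresholds: DebtThresholds | None = None) -> pd.DataFrame:
    rows = []
    for s in summaries:
        a = classify_debt(s, thresholds)
        rows.append({"subpopulation": a.subpopulation, "turnover": a.turnover,
                     "non_equilibrium": a.non_equilibrium,
                     "turnover_tier": a.turnover_tier, "label": a.label,
                     "rule": a.rule})
    return pd.DataFrame(rows)
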