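"""Maximum-likelihood estimation of the dynamic occupancy model.

:class:`DynamicOccupancyModel` is a scikit-learn-style estimator: covariate
structure and optimizer settings are constructor parameters, ``fit`` takes a
:class:`~occdebt.data.StudyDataset` and exposes fitted attributes with a
trailing underscore (``coef_``, ``se_``, ``nll_``, ``aicc_``, ...). All four
parameter groups use the logit link.

Standard errors come from the inverse of a numerically differentiated Hessian
of the NLL at the optimum (central finite differences via statsmodels).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.optimize as spo
from scipy.special import expit
from sklearn.base import BaseEstimator
from statsmodels.tools.numdiff import approx_hess

from .data import StudyDataset
from .design import DesignMatrices, ModelSpec, build_design
from .errors import ConvergenceError
from .likelihood import forward_loglik, occupancy_trajectory, smoothed_occupancy_probs

_GROUPS = ("psi1", "gamma", "epsilon", "p")


@dataclass
class RateSurfaces:
    """Model probabilities on the natural scale.

    ``psi1`` (n,); ``gamma``/``epsilon`` (n, T-1); ``p`` (n, T, J).
    Persistence ``phi`` is defined as ``1 - epsilon`` exactly.
    """

    psi1: np.ndarray
    gamma: np.ndarray
    epsilon: np.ndarray
    p: np.ndarray

    @property
    def phi(self) -> np.ndarray:
        return 1.0 - self.epsilon

    def trajectory(self) -> np.ndarray:
        """Unconditional occupancy per site and season (n, T)."""
        return occupancy_trajectory(self.psi1, self.gamma, self.epsilon)


def _split(theta: np.ndarray, design: DesignMatrices) -> dict:
    sizes = design.block_sizes
    out, pos = {}, 0
    for g in _GROUPS:
        out[g] = theta[pos:pos + sizes[g]]
        pos += sizes[g]
    return out


def rates_from_params(theta: np.ndarray, design: DesignMatrices) -> RateSurfaces:
    """Inverse-logit of the four linear predictors."""
    b = _split(np.asarray(theta, dtype=float), design)
    psi1 = expit(design.X_psi1 @ b["psi1"])
    gamma = expit(design.X_gamma @ b["gamma"])
    epsilon = expit(design.X_epsilon @ b["epsilon"])
    p = expit(design.X_p @ b["p"])
    return RateSurfaces(psi1, gamma, epsilon, p)


def nll_function(design: DesignMatrices, y: np.ndarray):
    """Return theta -> total NLL for fixed design and detections."""

    def nll(theta: np.ndarray) -> float:
        r = rates_from_params(theta, design)
        val = -forward_loglik(r.psi1, r.gamma, r.epsilon, r.p, y).sum()
        if not np.isfinite(val):
            return 1e12
        return float(val)

    return nll


def aicc(nll: float, k: int, n_effective: int) -> float:
    """AICc = 2*NLL + 2K + 2K(K+1)/(n-K-1); requires n_effective > K+1."""
    if n_effective <= k + 1:
        raise ValueError(f"AICc undefined: n_effective={n_effective} <= K+1={k + 1}")
    return 2.0 * nll + 2.0 * k + 2.0 * k * (k + 1) / (n_effective - k - 1)


class DynamicOccupancyModel(BaseEstimator):
    """Multi-season occupancy model with covariate-linked psi1, gamma,
    epsilon and p, fitted by maximum likelihood.

    Parameters
    ----------
    psi1, gamma, epsilon, p : sequence of str
        Covariate names per parameter group (see :mod:`occdebt.design`);
        empty means intercept-only.
    transforms : dict, optional
        Per-covariate transform-tag overrides.
    drought_alignment : {"next", "current"}
        Season whose drought index covaries with transition t -> t+1.
    n_effective : {"sites"} or int
        Effective sample size for AICc; the default uses the number of sites
        (the independent units of the likelihood).
    n_starts : int
        1 = deterministic all-zero start; >1 adds seeded random restarts.
    gtol, maxiter : optimizer controls (L-BFGS-B).
    random_state : seed for the optional multi-start draws.

    Attributes (after fit)
    ----------------------
    coef_ : ndarray, concatenated coefficient blocks on the logit scale
    se_ : ndarray, standard errors (NaN where the Hessian was singular)
    cov_ : ndarray, covariance of the estimates
    nll_, n_params_, aicc_, converged_, design_, result_
    """

    def __init__(self, psi1=(), gamma=(), epsilon=(), p=(), transforms=None,
                 drought_alignment="next", n_effective="sites", n_starts=1,
                 gtol=1e-8, maxiter=500, random_state=None, name=None):
        self.psi1 = psi1
        self.gamma = gamma
        self.epsilon = epsilon
        self.p = p
        self.transforms = transforms
        self.drought_alignment = drought_alignment
        self.n_effective = n_effective
        self.n_starts = n_starts
        self.gtol = gtol
        self.maxiter = maxiter
        self.random_state = random_state
        self.name = name

    # ------------------------------------------------------------------
    def spec(self) -> ModelSpec:
        return ModelSpec(psi1=tuple(self.psi1), gamma=tuple(self.gamma),
                         epsilon=tuple(self.epsilon), p=tuple(self.p),
                         transforms=dict(self.transforms or {}),
                         drought_alignment=self.drought_alignment,
                         name=self.name or "model")

    def fit(self, X: StudyDataset, y=None, compute_se: bool = True):
        """Fit by quasi-Newton minimisation of the forward-pass NLL."""
        dataset = X
        if dataset.n_seasons < 2:
            raise ValueError("dynamics estimation requires at least 2 seasons")
        design = build_design(self.spec(), dataset)
        yarr = dataset.detections.y
        nll = nll_function(design, yarr)
        k = design.n_params

        starts = [np.zeros(k)]
        if self.n_starts > 1:
            rng = np.random.default_rng(self.random_state)
            starts += [rng.normal(0.0, 0.5, size=k) for _ in range(self.n_starts - 1)]

        best = None
        for x0 in starts:
            res = spo.minimize(nll, x0, method="L-BFGS-B",
                               options={"maxiter": self.maxiter, "gtol": self.gtol,
                                        "ftol": 1e-12})
            if best is None or res.fun < best.fun:
                best = res

        grad_norm = float(np.max(np.abs(best.jac))) if best.jac is not None else np.inf
        # L-BFGS-B's own success flag plus an explicit gradient check
        self.converged_ = bool(best.success) and grad_norm < max(self.gtol * 1e6, 1e-2)
        self.coef_ = np.asarray(best.x, dtype=float)
        self.nll_ = float(best.fun)
        self.n_params_ = k
        self.design_ = design
        self.result_ = {"n_iter": int(best.nit), "grad_norm": grad_norm,
                        "message": str(best.message), "n_starts": len(starts)}
        n_eff = dataset.n_sites if self.n_effective == "sites" else int(self.n_effective)
        self.n_effective_ = n_eff
        if n_eff > k + 1:
            self.aicc_ = aicc(self.nll_, k, n_eff)
        else:
            warnings.warn(f"AICc undefined at n_effective={n_eff} with K={k}; set to NaN")
            self.aicc_ = float("nan")
        self._train_dataset = dataset

        if compute_se:
            self._compute_se(nll)
        else:
            self.cov_ = np.full((k, k), np.nan)
            self.se_ = np.full(k, np.nan)
        return self

    def _compute_se(self, nll) -> None:
        k = self.n_params_
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                H = approx_hess(self.coef_, nll)
                cov = np.linalg.inv(H)
            d = np.diag(cov)
            if np.any(~np.isfinite(d)) or np.any(d <= 0):
                raise np.linalg.LinAlgError("non-positive variance estimates")
            self.cov_ = cov
            self.se_ = np.sqrt(d)
            self.se_available_ = True
        except np.linalg.LinAlgError:
            self.cov_ = np.full((k, k), np.nan)
            self.se_ = np.full(k, np.nan)
            self.se_available_ = False

    # ------------------------------------------------------------------
    def _design_for(self, X: StudyDataset | None) -> DesignMatrices:
        self._check_fitted()
        if X is None or X is self._train_dataset:
            return self.design_
        d = build_design(self.spec(), X, scalings=self.design_.scalings)
        self._warn_extrapolation(d)
        return d

    def _warn_extrapolation(self, design: DesignMatrices) -> None:
        for g in _GROUPS:
            Xg = getattr(design, f"X_{g}")
            if np.any(np.abs(Xg) > 10):
                warnings.warn("covariates far outside the training scaling; "
                              "predicted rates are extrapolations", stacklevel=3)
                return

    def predict_rates(self, X: StudyDataset | None = None) -> RateSurfaces:
        """Probability surfaces psi1/gamma/epsilon/p via the inverse link."""
        return rates_from_params(self.coef_, self._design_for(X))

    def predict_smoothed(self, X: StudyDataset | None = None) -> np.ndarray:
        """Finite-sample (smoothed) occupancy Pr(Z_it=1 | detections), (n, T)."""
        dataset = self._train_dataset if X is None else X
        r = self.predict_rates(X)
        return smoothed_occupancy_probs(r.psi1, r.gamma, r.epsilon, r.p,
                                        dataset.detections.y)

    def score(self, X: StudyDataset | None = None, y=None) -> float:
        """Mean per-site log-likelihood (higher is better)."""
        dataset = self._train_dataset if X is None else X
        r = self.predict_rates(X)
        return float(forward_loglik(r.psi1, r.gamma, r.epsilon, r.p,
                                    dataset.detections.y).mean())

    def coefficients_table(self) -> pd.DataFrame:
        """Coefficients with SEs, Wald 95% CIs and p-values, one row per term."""
        from scipy.stats import norm
        self._check_fitted()
        rows = []
        pos = 0
        for g in _GROUPS:
            for term in self.design_.columns[g]:
                est, se = self.coef_[pos], self.se_[pos]
                z = est / se if se > 0 else np.nan
                rows.append({
                    "group": g, "term": term, "estimate": est, "se": se,
                    "ci_lower": est - 1.96 * se, "ci_upper": est + 1.96 * se,
                    "p_value": 2 * norm.sf(abs(z)) if np.isfinite(z) else np.nan,
                })
                pos += 1
        return pd.DataFrame(rows)

    def _check_fitted(self) -> None:
        if not hasattr(self, "coef_"):
            raise RuntimeError("model is not fitted; call fit() first")


# ---------------------------------------------------------------------------
# Functional wrappers and model ranking
# ---------------------------------------------------------------------------

def fit_model(spec: ModelSpec | dict, dataset: StudyDataset,
              **options) -> DynamicOccupancyModel:
    """Fit one candidate model described by a :class:`ModelSpec` (or dict)."""
    if isinstance(spec, dict):
        spec = ModelSpec.from_dict(spec)
    est = DynamicOccupancyModel(
        psi1=spec.psi1, gamma=spec.gamma, epsilon=spec.epsilon, p=spec.p,
        transforms=spec.transforms, drought_alignment=spec.drought_alignment,
        name=spec.name, **options)
    return est.fit(dataset)


def rank_models(fits: list[DynamicOccupancyModel],
                delta_threshold: float = 2.0) -> pd.DataFrame:
    """Rank converged fits by AICc.

    Returns a DataFrame sorted ascending by AICc with ``delta_aicc`` relative
    to the best model and ``equally_supported`` flag (delta <= threshold).
    Ties break by fewer parameters, then model name. Non-converged fits are
    excluded with a warning; an empty converged set raises ConvergenceError.
    """
    rows = []
    for f in fits:
        name = f.name or "model"
        if not getattr(f, "converged_", False):
            warnings.warn(f"model {name!r} did not converge; excluded from ranking")
            continue
        rows.append({"model": name, "K": f.n_params_, "nll": f.nll_, "aicc": f.aicc_})
    if not rows:
        raise ConvergenceError("no converged fits to rank")
    tab = pd.DataFrame(rows).sort_values(["aicc", "K", "model"], kind="mergesort")
    tab = tab.reset_index(drop=True)
    tab["delta_aicc"] = tab["aicc"] - tab["aicc"].iloc[0]
    tab["equally_supported"] = tab["delta_aicc"] <= delta_threshold
    return tab
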