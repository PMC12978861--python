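"""Marginal likelihood of the two-state latent occupancy chain.

The model: site i is occupied (Z=1) or not (Z=0) each season. Initial state
Z_1 ~ Bernoulli(psi1_i); transitions Pr(Z_{t+1}=1 | Z_t=1) = phi_{it} =
1 - eps_{it} and Pr(Z_{t+1}=1 | Z_t=0) = gamma_{it}. Given Z_t=1, visit j
yields a detection with probability p_{itj}; given Z_t=0 detections are
impossible. Missing visits contribute a factor of 1.

The site likelihood marginalises the latent chain with a forward pass
(scaled to avoid underflow), never by enumerating the 2^T latent sequences.
All functions are vectorised over sites.
"""

from __future__ import annotations

import numpy as np

_EPS = 1e-300


def emission_probs(y: np.ndarray, p: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per site-season emission probabilities of the observed visit record.

    Returns ``(e1, e0)`` of shape (n, T): probability of the season's record
    given occupied / unoccupied. Missing visits contribute 1; a season with
    any detection has e0 = 0.
    """
    obs = ~np.isnan(y)
    y0 = np.where(obs, y, 0.0)
    # log-prob given occupied, summed over performed visits
    with np.errstate(divide="ignore"):
        lp = np.where(obs, y0 * np.log(np.maximum(p, _EPS))
                      + (1.0 - y0) * np.log(np.maximum(1.0 - p, _EPS)), 0.0)
    e1 = np.exp(lp.sum(axis=2))
    e0 = np.where((y0 * obs).sum(axis=2) > 0, 0.0, 1.0)
    return e1, e0


def forward_loglik(psi1: np.ndarray, gamma: np.ndarray, eps: np.ndarray,
                   p: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Per-site log-likelihood via the scaled forward recursion.

    Parameters
    ----------
    psi1 : (n,); gamma, eps : (n, T-1); p : (n, T, J); y : (n, T, J) with NaN.

    Returns the (n,) vector of site log-likelihoods.
    """
    n, T, _ = y.shape
    e1, e0 = emission_probs(y, p)

    a0 = (1.0 - psi1) * e0[:, 0]
    a1 = psi1 * e1[:, 0]
    ll = np.zeros(n)
    for t in range(T - 1):
        b0 = a0 * (1.0 - gamma[:, t]) + a1 * eps[:, t]
        b1 = a0 * gamma[:, t] + a1 * (1.0 - eps[:, t])
        a0 = b0 * e0[:, t + 1]
        a1 = b1 * e1[:, t + 1]
        c = a0 + a1
        # rescale to dodge underflow on long/odd records
        safe = np.maximum(c, _EPS)
        ll += np.log(safe)
        a0 = a0 / safe
        a1 = a1 / safe
    ll += np.log(np.maximum(a0 + a1, _EPS))
    return ll


def negative_log_likelihood(psi1, gamma, eps, p, y) -> float:
    """Total NLL = -sum over sites of the forward-pass log-likelihood."""
    return float(-forward_loglik(psi1, gamma, eps, p, y).sum())


def smoothed_occupancy_probs(psi1, gamma, eps, p, y) -> np.ndarray:
    """Pr(Z_{it} = 1 | site i's full detection record), shape (n, T).

    Forward-backward over the latent chain. Equals 1 exactly at any
    site-season with a detection, and the unconditional trajectory at sites
    with no observed visits at all.
    """
    n, T, _ = y.shape
    e1, e0 = emission_probs(y, p)

    alpha = np.zeros((n, T, 2))
    alpha[:, 0, 0] = (1.0 - psi1) * e0[:, 0]
    alpha[:, 0, 1] = psi1 * e1[:, 0]
    c = np.maximum(alpha[:, 0].sum(axis=1), _EPS)
    alpha[:, 0] /= c[:, None]
    for t in range(T - 1):
        a0, a1 = alpha[:, t, 0], alpha[:, t, 1]
        b0 = (a0 * (1.0 - gamma[:, t]) + a1 * eps[:, t]) * e0[:, t + 1]
        b1 = (a0 * gamma[:, t] + a1 * (1.0 - eps[:, t])) * e1[:, t + 1]
        c = np.maximum(b0 + b1, _EPS)
        alpha[:, t + 1, 0] = b0 / c
        alpha[:, t + 1, 1] = b1 / c

    beta = np.ones((n, T, 2))
    for t in range(T - 2, -1, -1):
        b0 = beta[:, t + 1, 0] * e0[:, t + 1]
        b1 = beta[:, t + 1, 1] * e1[:, t + 1]
        beta[:, t, 0] = (1.0 - gamma[:, t]) * b0 + gamma[:, t] * b1
        beta[:, t, 1] = eps[:, t] * b0 + (1.0 - eps[:, t]) * b1
        norm = np.maximum(beta[:, t].sum(axis=1), _EPS)
        beta[:, t] /= norm[:, None]

    num1 = alpha[:, :, 1] * beta[:, :, 1]
    num0 = alpha[:, :, 0] * beta[:, :, 0]
    psi_fs = num1 / np.maximum(num0 + num1, _EPS)
    # exact 1 where a detection was recorded that season
    detected = np.nansum(y, axis=2) > 0
    psi_fs[detected] = 1.0
    return psi_fs


def occupancy_trajectory(psi1, gamma, eps) -> np.ndarray:
    """Unconditional occupancy probabilities per site and season, (n, T)."""
    T = gamma.shape[1] + 1
    psi = np.empty((psi1.shape[0], T))
    psi[:, 0] = psi1
    for t in range(T - 1):
        psi[:, t + 1] = psi[:, t] * (1.0 - eps[:, t]) + (1.0 - psi[:, t]) * gamma[:, t]
    return psi


def simulate_latent_states(psi1, gamma, eps, rng: np.random.Generator) -> np.ndarray:
    """Draw latent occupancy Z (n, T) from the chain parameters."""
    n = psi1.shape[0]
    T = gamma.shape[1] + 1
    Z = np.zeros((n, T), dtype=int)
    Z[:, 0] = rng.random(n) < psi1
    for t in range(T - 1):
        pr = np.where(Z[:, t] == 1, 1.0 - eps[:, t], gamma[:, t])
        Z[:, t + 1] = rng.random(n) < pr
    return Z


def simulate_detections_from_states(Z: np.ndarray, p: np.ndarray,
                                    observed: np.ndarray,
                                    rng: np.random.Generator) -> np.ndarray:
    """Draw a detection array on the support of ``observed`` given states Z."""
    n, T, J = p.shape
    y = np.full((n, T, J), np.nan)
    u = rng.random((n, T, J))
    hits = (u < p) & (Z[:, :, None] == 1)
    y[observed] = hits[observed].astype(float)
    return y
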