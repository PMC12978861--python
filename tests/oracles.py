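"""Independent brute-force oracles for the latent occupancy chain.

These enumerate all 2^T latent state sequences per site and never share code
with the forward-pass implementation they are used to check.
"""

import itertools

import numpy as np


def _sequence_probability(zs, i, psi1, gamma, eps, p, y):
    pr = psi1[i] if zs[0] == 1 else 1.0 - psi1[i]
    T = len(zs)
    for t in range(T - 1):
        if zs[t] == 1:
            pr *= (1.0 - eps[i, t]) if zs[t + 1] == 1 else eps[i, t]
        else:
            pr *= gamma[i, t] if zs[t + 1] == 1 else 1.0 - gamma[i, t]
    for t in range(T):
        for j in range(y.shape[2]):
            v = y[i, t, j]
            if np.isnan(v):
                continue
            if zs[t] == 1:
                pr *= p[i, t, j] if v == 1 else 1.0 - p[i, t, j]
            elif v == 1:
                pr = 0.0
    return pr


def enumerate_nll(psi1, gamma, eps, p, y):
    """Total NLL by full enumeration of latent sequences."""
    n, T, _ = y.shape
    total = 0.0
    for i in range(n):
        L = sum(_sequence_probability(zs, i, psi1, gamma, eps, p, y)
                for zs in itertools.product([0, 1], repeat=T))
        total -= np.log(L)
    return total


def enumerate_smoothed(psi1, gamma, eps, p, y):
    """Pr(Z_it = 1 | site i's record) by enumeration, shape (n, T)."""
    n, T, _ = y.shape
    out = np.zeros((n, T))
    for i in range(n):
        joint = {zs: _sequence_probability(zs, i, psi1, gamma, eps, p, y)
                 for zs in itertools.product([0, 1], repeat=T)}
        Z = sum(joint.values())
        for t in range(T):
            out[i, t] = sum(v for zs, v in joint.items() if zs[t] == 1) / Z
    return out


def random_instance(rng, max_sites=10, max_seasons=4, max_visits=3):
    """A random small instance with random missingness; every site keeps at
    least one observed visit."""
    n = int(rng.integers(1, max_sites + 1))
    T = int(rng.integers(2, max_seasons + 1))
    J = int(rng.integers(1, max_visits + 1))
    psi1 = rng.uniform(0.05, 0.95, n)
    gamma = rng.uniform(0.05, 0.95, (n, T - 1))
    eps = rng.uniform(0.05, 0.95, (n, T - 1))
    p = rng.uniform(0.05, 0.95, (n, T, J))
    y = rng.choice([0.0, 1.0, np.nan], size=(n, T, J), p=[0.4, 0.3, 0.3])
    for i in range(n):
        if np.all(np.isnan(y[i])):
            y[i, 0, 0] = float(rng.integers(0, 2))
    return psi1, gamma, eps, p, y
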