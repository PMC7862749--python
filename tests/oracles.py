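"""Independent oracles for validating the samplers and estimators.

These deliberately avoid the package's own computational paths: the joint
probability P(w, z, delta) is evaluated in closed form from the
Dirichlet/stick-breaking-multinomial conjugacy, states are enumerated by
brute force, and posterior moments are obtained by numerical integration.
"""

from __future__ import annotations

import itertools

import numpy as np
from scipy.integrate import quad
from scipy.special import betaln, gammaln
from scipy.stats import beta as beta_dist


def log_joint(
    n: np.ndarray, m: np.ndarray, dmat: np.ndarray, alpha: float, pi: float, a: float, b: float
) -> float:
    """log P(w, z, delta) for fixed assignment counts and indicators.

    ``n`` is K x V taxon-in-community counts, ``m`` is D x K
    community-in-sample counts, ``dmat`` is K x (V-1) indicators for the
    stick positions.  Collapsed over theta (Dirichlet-multinomial) and over
    the stick variables (independent Beta updates: the trailing sum for
    position i runs over *all* later taxa).  Returns -inf for inconsistent
    states (a structural zero with positive count).
    """
    K, V = n.shape
    if np.any((dmat == 1) & (n[:, : V - 1] > 0)):
        return -np.inf
    lp = 0.0
    for d in range(m.shape[0]):
        lp += gammaln(K * alpha) - gammaln(m[d].sum() + K * alpha)
        lp += float(np.sum(gammaln(m[d] + alpha) - gammaln(alpha)))
    if pi > 0 and pi < 1:
        lp += float(dmat.sum()) * np.log(pi) + float(dmat.size - dmat.sum()) * np.log1p(-pi)
    elif pi == 0 and dmat.any():
        return -np.inf
    elif pi == 1 and not dmat.all():
        return -np.inf
    for j in range(K):
        for i in range(V - 1):
            if dmat[j, i] == 0:
                lp += betaln(a + n[j, i], b + n[j, i + 1 :].sum()) - betaln(a, b)
    return lp


def counts_from_assignment(
    z: np.ndarray, read_sample: np.ndarray, read_taxon: np.ndarray, D: int, V: int, K: int
) -> tuple[np.ndarray, np.ndarray]:
    n = np.zeros((K, V), dtype=int)
    m = np.zeros((D, K), dtype=int)
    for r in range(z.size):
        n[z[r], read_taxon[r]] += 1
        m[read_sample[r], z[r]] += 1
    return n, m


def enumerate_posterior(
    read_sample: np.ndarray,
    read_taxon: np.ndarray,
    D: int,
    V: int,
    K: int,
    alpha: float,
    pi: float,
    a: float,
    b: float,
) -> dict[tuple, float]:
    """Exact posterior P(z, delta | w) over all (per-read z, delta) states."""
    R = read_sample.size
    logps: dict[tuple, float] = {}
    for z in itertools.product(range(K), repeat=R):
        zv = np.array(z)
        n, m = counts_from_assignment(zv, read_sample, read_taxon, D, V, K)
        for delta in itertools.product((0, 1), repeat=K * (V - 1)):
            dmat = np.array(delta).reshape(K, V - 1)
            lp = log_joint(n, m, dmat, alpha, pi, a, b)
            if np.isfinite(lp):
                logps[(z, delta)] = lp
    arr = np.array(list(logps.values()))
    probs = np.exp(arr - arr.max())
    probs /= probs.sum()
    return dict(zip(logps.keys(), probs))


def total_variation(exact: dict[tuple, float], freq: dict[tuple, int], n_draws: int) -> float:
    keys = set(exact) | set(freq)
    return 0.5 * sum(abs(exact.get(k, 0.0) - freq.get(k, 0) / n_draws) for k in keys)


def gd_posterior_mean_numeric(n: np.ndarray, a: float, b: float) -> np.ndarray:
    """E[beta | counts] under a full-support stick-breaking prior, by
    numerical integration of each Beta posterior factor (the stick variables
    are independent a posteriori; the composition mean is the product of
    the per-position moments)."""
    n = np.asarray(n)
    V = n.size
    e_q = np.empty(V - 1)
    e_1mq = np.empty(V - 1)
    for i in range(V - 1):
        a_post = a + n[i]
        b_post = b + n[i + 1 :].sum()
        pdf = beta_dist(a_post, b_post).pdf
        e_q[i], _ = quad(lambda x: x * pdf(x), 0, 1, limit=200)
        e_1mq[i], _ = quad(lambda x: (1 - x) * pdf(x), 0, 1, limit=200)
    out = np.empty(V)
    prefix = 1.0
    for i in range(V - 1):
        out[i] = e_q[i] * prefix
        prefix *= e_1mq[i]
    out[V - 1] = prefix
    return out


def best_assignment_bruteforce(beta_ref: np.ndarray, beta_est: np.ndarray) -> np.ndarray:
    """Maximum total-Pearson assignment by exhaustive search over all K!
    permutations (small K only)."""
    K = beta_ref.shape[0]
    corr = np.corrcoef(beta_ref, beta_est)[:K, K:]
    best_perm, best_score = None, -np.inf
    for perm in itertools.permutations(range(K)):
        score = sum(corr[r, perm[r]] for r in range(K))
        if score > best_score:
            best_score, best_perm = score, perm
    return np.array(best_perm)
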