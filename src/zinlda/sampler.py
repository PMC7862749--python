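"""Collapsed Gibbs sampling for the zero-inflated LDA model.

The model replaces LDA's Dir(eta) prior on each subcommunity profile beta^(j)
with a ZIGD(pi, a, b): profiles may put *exactly* zero probability on taxa
(structural zeros, flagged by delta_ij = 1), separating taxa truly absent
from a subcommunity from taxa merely unobserved at finite depth.  Both the
ZIGD and the Dirichlet are conjugate to the multinomial, so beta and theta
are integrated out and the chain runs over the discrete latents only: the
per-read assignments z and the indicator matrix delta.

Sufficient statistics are n_j^(i) (reads of taxon i in subcommunity j, pooled
over samples) and m_j^(d) (reads of sample d in subcommunity j).  Writing
U_j for the ordered support of subcommunity j (taxa with delta_ij = 0; the
last taxon always belongs, since the residual stick is never zero-inflated),
and a_ij = a + n_j^(i), b_ij = b_i + sum of trailing counts n_j^(l) for l > i,
the full conditionals are

    P(z_dn = j | rest) ∝ E[beta_ij | counts, delta] * (m_j,-n^(d) + alpha)
                                                    / (m_.,-n^(d) + K alpha)

with E[beta_ij] the stick-breaking posterior mean over the support

    E[beta_ij] = a_ij / (a_ij + b_ij) * prod_{t in U_j, t < i} b_tj / (a_tj + b_tj)

(for the last support member the leading factor is dropped: it takes the
residual stick), zero off-support; and

    P(delta_ij = 1 | rest) = 0                                  if n_j^(i) > 0
                           = pi / (pi + (1 - pi) * B(a, b_ij) / B(a, b_i))
                                                                if n_j^(i) = 0.

One Gibbs iteration is a full systematic scan of all reads (decrement,
sample, increment) followed by a full (j, ascending i) scan of delta.  After
burn-in, each retained iteration records the per-draw estimates: beta by the
stick-breaking posterior mean above, theta_dj = (m_j^(d) + alpha) /
(m^(d) + K alpha), and the delta state.  Finalization averages draws,
dichotomizes the posterior mean of delta at 0.5 (inclusive), zeroes the
corresponding beta entries and renormalizes each row.

Two engines produce identical posteriors: a numba-compiled kernel (default)
and a pure-Python reference used for small-instance validation.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from numba import njit
from scipy.special import betaln

from .lda import LDAHyper, expand_reads, fit_lda
from .types import Cohort, Fit, PosteriorDraws, as_generator
from .zigd import _b_vector

logger = logging.getLogger(__name__)

__all__ = [
    "ZinHyper",
    "ChainState",
    "init_from_lda",
    "conditional_z",
    "conditional_delta",
    "gibbs_sweep",
    "run_chain",
    "estimate_beta_draw",
    "estimate_theta_draw",
    "finalize",
    "fit_zinlda",
]


@dataclass(frozen=True)
class ZinHyper:
    """Zero-inflated LDA hyperparameters (symmetric; shared by the cohort).

    ``alpha`` defaults to 50/K.  ``b`` may be a scalar or a per-stick-position
    vector (length V-1); the vector form exists for the GD->Dirichlet
    reduction (see :func:`zinlda.zigd.dirichlet_nesting_b`).
    """

    K: int
    pi: float
    a: float
    b: float | np.ndarray
    alpha: float | None = None

    def __post_init__(self) -> None:
        if not isinstance(self.K, (int, np.integer)) or self.K < 1:
            raise ValueError(f"K must be an integer >= 1, got {self.K}")
        if not 0.0 <= self.pi <= 1.0:
            raise ValueError(f"pi must be in [0, 1], got {self.pi}")
        if self.a <= 0:
            raise ValueError("a must be positive")
        if self.alpha is None:
            object.__setattr__(self, "alpha", 50.0 / self.K)
        if self.alpha <= 0:
            raise ValueError("alpha must be positive")

    def b_vector(self, V: int) -> np.ndarray:
        return _b_vector(self.b, V)


@dataclass
class ChainState:
    """Mutable Gibbs chain state.

    Holds per-read assignments plus the sufficient counts; ``n[j, i]`` and
    ``m[d, j]`` are always consistent with ``z``, and ``delta[j, i] = 1``
    implies ``n[j, i] = 0`` (a structural zero admits no reads).
    """

    read_sample: np.ndarray  # R, int32
    read_taxon: np.ndarray  # R, int32
    z: np.ndarray  # R, int32
    delta: np.ndarray  # K x V, int8; last column always 0
    n: np.ndarray  # K x V, int64
    m: np.ndarray  # D x K, int64
    n_total: np.ndarray  # K, int64 row sums of n

    @classmethod
    def from_assignments(
        cls, read_sample: np.ndarray, read_taxon: np.ndarray, z: np.ndarray, D: int, V: int, K: int
    ) -> "ChainState":
        n = np.zeros((K, V), dtype=np.int64)
        m = np.zeros((D, K), dtype=np.int64)
        np.add.at(n, (z, read_taxon), 1)
        np.add.at(m, (read_sample, z), 1)
        return cls(
            read_sample=read_sample,
            read_taxon=read_taxon,
            z=z,
            delta=np.zeros((K, V), dtype=np.int8),
            n=n,
            m=m,
            n_total=n.sum(axis=1),
        )

    def support(self, j: int) -> np.ndarray:
        """Ordered in-support taxon indices U_j for subcommunity j."""
        return np.flatnonzero(self.delta[j] == 0)

    def check_consistency(self) -> None:
        K, V = self.n.shape
        n = np.zeros((K, V), dtype=np.int64)
        m = np.zeros_like(self.m)
        np.add.at(n, (self.z, self.read_taxon), 1)
        np.add.at(m, (self.read_sample, self.z), 1)
        if not (np.array_equal(n, self.n) and np.array_equal(m, self.m)):
            raise AssertionError("chain counts inconsistent with assignments")
        if np.any(self.n[self.delta == 1] > 0):
            raise AssertionError("structural zero with positive count")


def init_from_lda(
    cohort: Cohort,
    lda_fit: Fit,
    hyper: ZinHyper,
    rng: int | np.random.Generator | None = None,
) -> ChainState:
    """Informative chain initialization from a standard LDA fit.

    Each read of taxon i draws its subcommunity with probability proportional
    to the LDA estimate beta_ij; delta starts at zero everywhere (full
    support) and counts are rebuilt from the sampled assignments.
    """
    if lda_fit.n_components != hyper.K:
        raise ValueError(f"K mismatch: LDA fit has {lda_fit.n_components}, hyper has {hyper.K}")
    if lda_fit.n_taxa != cohort.n_taxa:
        raise ValueError("taxon-dimension mismatch between cohort and LDA fit")
    rng = as_generator(rng)
    read_sample, read_taxon = expand_reads(cohort)
    col = lda_fit.beta / lda_fit.beta.sum(axis=0, keepdims=True)  # per-taxon over communities
    cdf = np.cumsum(col, axis=0)  # K x V
    u = rng.random(read_taxon.size)
    z = np.empty(read_taxon.size, dtype=np.int32)
    for i in np.unique(read_taxon):
        mask = read_taxon == i
        z[mask] = np.searchsorted(cdf[:, i], u[mask], side="right").astype(np.int32)
    np.clip(z, 0, hyper.K - 1, out=z)
    return ChainState.from_assignments(read_sample, read_taxon, z, cohort.n_samples, cohort.n_taxa, hyper.K)


def _stick_posterior_mean_at(
    n_row: np.ndarray, delta_row: np.ndarray, total: int, i: int, a: float, b_vec: np.ndarray
) -> float:
    """E[beta_i | counts, delta] for one subcommunity at one taxon."""
    V = n_row.size
    if i < V - 1 and delta_row[i] == 1:
        return 0.0
    cum = 0
    prefix = 1.0
    for t in range(i):
        nt = int(n_row[t])
        if delta_row[t] == 0:
            bt = b_vec[t] + (total - cum - nt)
            prefix *= bt / (a + nt + bt)
        cum += nt
    if i == V - 1:
        return prefix
    ni = int(n_row[i])
    bi = b_vec[i] + (total - cum - ni)
    return prefix * (a + ni) / (a + ni + bi)


def conditional_z(i: int, d: int, state: ChainState, hyper: ZinHyper) -> np.ndarray:
    """Full conditional over subcommunities for one read of taxon i in sample d.

    Precondition: the read being resampled has already been decremented from
    the counts.  Off-support subcommunities get exactly 0.  If every
    subcommunity currently excludes taxon i (reachable only transiently), the
    conditional falls back to the full-support (pi = 0) form rather than
    halting, and logs a warning.
    """
    K, V = state.n.shape
    b_vec = hyper.b_vector(V)
    probs = np.zeros(K)
    for j in range(K):
        e = _stick_posterior_mean_at(state.n[j], state.delta[j], int(state.n_total[j]), i, hyper.a, b_vec)
        probs[j] = e * (state.m[d, j] + hyper.alpha)
    tot = probs.sum()
    if tot <= 0.0:
        logger.warning("taxon %d excluded from every subcommunity; using full-support fallback", i)
        no_delta = np.zeros(V, dtype=np.int8)
        for j in range(K):
            e = _stick_posterior_mean_at(state.n[j], no_delta, int(state.n_total[j]), i, hyper.a, b_vec)
            probs[j] = e * (state.m[d, j] + hyper.alpha)
        tot = probs.sum()
    return probs / tot


def conditional_delta(i: int, j: int, state: ChainState, hyper: ZinHyper) -> float:
    """P(delta_ij = 1 | rest): zero if taxon i has reads in subcommunity j,
    else the prior odds pi damped by the Beta-function ratio B(a, b_ij)/B(a, b_i)
    (evaluated in log space).  The last taxon is never zero-inflated.
    """
    V = state.n.shape[1]
    if i >= V - 1:
        return 0.0
    if state.n[j, i] > 0:
        return 0.0
    if hyper.pi == 0.0:
        return 0.0
    if hyper.pi == 1.0:
        return 1.0
    b_vec = hyper.b_vector(V)
    trailing = int(state.n[j, i + 1 :].sum())
    log_ratio = betaln(hyper.a, b_vec[i] + trailing) - betaln(hyper.a, b_vec[i])
    return float(hyper.pi / (hyper.pi + (1.0 - hyper.pi) * math.exp(log_ratio)))


def gibbs_sweep(state: ChainState, hyper: ZinHyper, rng: int | np.random.Generator | None = None) -> ChainState:
    """One full systematic scan: every read via conditional_z, then every
    (j, ascending i) indicator via conditional_delta.  Pure-Python reference;
    the compiled kernel in :func:`run_chain` performs the identical scan.
    """
    rng = as_generator(rng)
    K, V = state.n.shape
    for r in range(state.read_sample.size):
        i = int(state.read_taxon[r])
        d = int(state.read_sample[r])
        jo = int(state.z[r])
        state.n[jo, i] -= 1
        state.n_total[jo] -= 1
        state.m[d, jo] -= 1
        probs = conditional_z(i, d, state, hyper)
        jn = int(np.searchsorted(np.cumsum(probs), rng.random(), side="right"))
        jn = min(jn, K - 1)
        state.z[r] = jn
        state.n[jn, i] += 1
        state.n_total[jn] += 1
        state.m[d, jn] += 1
    for j in range(K):
        for i in range(V - 1):
            p1 = conditional_delta(i, j, state, hyper)
            if p1 <= 0.0:
                state.delta[j, i] = 0
            elif p1 >= 1.0:
                state.delta[j, i] = 1
            else:
                state.delta[j, i] = 1 if rng.random() < p1 else 0
    return state


def estimate_beta_draw(state: ChainState, hyper: ZinHyper) -> np.ndarray:
    """Per-draw beta estimate: stick-breaking posterior mean over each
    subcommunity's support; entries off support are exactly 0 and each row
    sums to 1 (the last support member absorbs the residual stick)."""
    K, V = state.n.shape
    b_vec = hyper.b_vector(V)
    beta = np.zeros((K, V))
    for j in range(K):
        if np.all(state.delta[j, : V - 1] == 1) and state.delta[j, V - 1] == 1:
            raise ValueError(f"degenerate subcommunity {j}: empty support")
        remaining = 1.0
        cum = 0
        total = int(state.n_total[j])
        for i in range(V - 1):
            ni = int(state.n[j, i])
            if state.delta[j, i] == 0:
                bi = b_vec[i] + (total - cum - ni)
                q = (hyper.a + ni) / (hyper.a + ni + bi)
                beta[j, i] = q * remaining
                remaining *= 1.0 - q
            cum += ni
        beta[j, V - 1] = remaining
    return beta


def estimate_theta_draw(state: ChainState, hyper: ZinHyper) -> np.ndarray:
    """Per-draw theta estimate: theta_dj = (m_j^(d) + alpha)/(m^(d) + K alpha)."""
    depths = state.m.sum(axis=1, keepdims=True)
    return (state.m + hyper.alpha) / (depths + hyper.K * hyper.alpha)


@njit(cache=True)
def _zin_run(
    read_sample,
    read_taxon,
    z,
    delta,
    D,
    V,
    K,
    alpha,
    pi,
    a,
    b_vec,
    n_iter,
    burn_in,
    thin,
    seed,
    beta_draws,
    theta_draws,
    delta_draws,
    z_draws,
    counters,
):  # pragma: no cover - exercised through run_chain
    np.random.seed(seed)
    R = read_sample.size
    n = np.zeros((K, V), dtype=np.int64)
    njt = np.zeros(K, dtype=np.int64)
    m = np.zeros((D, K), dtype=np.int64)
    depths = np.zeros(D, dtype=np.int64)
    for r in range(R):
        n[z[r], read_taxon[r]] += 1
        njt[z[r]] += 1
        m[read_sample[r], z[r]] += 1
        depths[read_sample[r]] += 1

    probs = np.empty(K)
    # Per-community caches of exclusive prefix count sums and stick prefix
    # products, built lazily only up to the position a read needs (reads are
    # laid out taxon-ascending within a sample, so extensions amortize) and
    # reset whenever the community's counts or support change.
    cumcnt = np.zeros((K, V), dtype=np.int64)
    prefprod = np.ones((K, V))
    built = np.zeros(K, dtype=np.int64)
    crun = np.zeros(K, dtype=np.int64)
    prun = np.ones(K)
    keep = 0
    for it in range(n_iter):
        # --- z scan ---
        for r in range(R):
            i = read_taxon[r]
            d = read_sample[r]
            jo = z[r]
            n[jo, i] -= 1
            njt[jo] -= 1
            m[d, jo] -= 1
            built[jo] = 0
            tot = 0.0
            for j in range(K):
                if built[j] <= i:
                    if built[j] == 0:
                        crun[j] = 0
                        prun[j] = 1.0
                    t = built[j]
                    while t <= i:
                        cumcnt[j, t] = crun[j]
                        prefprod[j, t] = prun[j]
                        nt = n[j, t]
                        if t < V - 1 and delta[j, t] == 0:
                            bt = b_vec[t] + (njt[j] - crun[j] - nt)
                            prun[j] *= bt / (a + nt + bt)
                        crun[j] += nt
                        t += 1
                    built[j] = t
                if i < V - 1 and delta[j, i] == 1:
                    probs[j] = 0.0
                    continue
                if i == V - 1:
                    e = prefprod[j, i]
                else:
                    ni = n[j, i]
                    bi = b_vec[i] + (njt[j] - cumcnt[j, i] - ni)
                    e = prefprod[j, i] * (a + ni) / (a + ni + bi)
                p = e * (m[d, j] + alpha)
                probs[j] = p
                tot += p
            if tot <= 0.0:
                # taxon transiently excluded everywhere: full-support fallback
                counters[0] += 1
                tot = 0.0
                for j in range(K):
                    cum = 0
                    prefix = 1.0
                    for t in range(i):
                        nt = n[j, t]
                        bt = b_vec[t] + (njt[j] - cum - nt)
                        prefix *= bt / (a + nt + bt)
                        cum += nt
                    if i == V - 1:
                        e = prefix
                    else:
                        ni = n[j, i]
                        bi = b_vec[i] + (njt[j] - cum - ni)
                        e = prefix * (a + ni) / (a + ni + bi)
                    p = e * (m[d, j] + alpha)
                    probs[j] = p
                    tot += p
            u = np.random.random() * tot
            acc = 0.0
            jn = K - 1
            for j in range(K):
                acc += probs[j]
                if u < acc:
                    jn = j
                    break
            z[r] = jn
            n[jn, i] += 1
            njt[jn] += 1
            m[d, jn] += 1
            built[jn] = 0
        # --- delta scan (systematic, j then ascending i) ---
        for j in range(K):
            cum = 0
            for i in range(V - 1):
                ni = n[j, i]
                if ni > 0 or pi <= 0.0:
                    delta[j, i] = 0
                elif pi >= 1.0:
                    delta[j, i] = 1
                else:
                    S = njt[j] - cum  # trailing counts after i (ni == 0)
                    lr = (
                        math.lgamma(b_vec[i] + S)
                        - math.lgamma(a + b_vec[i] + S)
                        - math.lgamma(b_vec[i])
                        + math.lgamma(a + b_vec[i])
                    )
                    p1 = pi / (pi + (1.0 - pi) * math.exp(lr))
                    delta[j, i] = 1 if np.random.random() < p1 else 0
                cum += ni
            built[j] = 0  # support may have changed
        # invariant: delta_ij = 1 implies n_j^(i) = 0, hence the trailing sum
        # over all taxa equals the trailing sum over support members
        for j in range(K):
            for i in range(V):
                if delta[j, i] == 1 and n[j, i] > 0:
                    counters[1] += 1
        # --- record retained draw ---
        if it >= burn_in and (it - burn_in) % thin == 0:
            for j in range(K):
                remaining = 1.0
                cum = 0
                for i in range(V - 1):
                    ni = n[j, i]
                    if delta[j, i] == 0:
                        bi = b_vec[i] + (njt[j] - cum - ni)
                        q = (a + ni) / (a + ni + bi)
                        beta_draws[keep, j, i] = q * remaining
                        remaining *= 1.0 - q
                    else:
                        beta_draws[keep, j, i] = 0.0
                    cum += ni
                beta_draws[keep, j, V - 1] = remaining
                for i in range(V):
                    delta_draws[keep, j, i] = delta[j, i]
            for d in range(D):
                denom = depths[d] + K * alpha
                for j in range(K):
                    theta_draws[keep, d, j] = (m[d, j] + alpha) / denom
            if z_draws.shape[0] > 0:
                for r in range(R):
                    z_draws[keep, r] = z[r]
            keep += 1
    return keep


def run_chain(
    cohort: Cohort,
    hyper: ZinHyper,
    n_iter: int = 2000,
    burn_in: int = 1000,
    thin: int = 1,
    rng: int | np.random.Generator | None = None,
    init: Fit | None = None,
    engine: str = "numba",
    state_out: ChainState | None = None,
    record_z: bool = False,
) -> PosteriorDraws:
    """Run the collapsed Gibbs chain and collect retained draws.

    ``init`` is an LDA fit used for informative initialization (recommended);
    without it each read starts at a uniform-random subcommunity.  With
    ``engine="python"`` the pure-Python reference sweep is used instead of
    the compiled kernel (small instances only).  ``state_out``, if given, is
    ignored as input and receives the final chain state.
    """
    if not n_iter > burn_in >= 0:
        raise ValueError("need n_iter > burn_in >= 0")
    if thin < 1:
        raise ValueError("thin must be >= 1")
    rng = as_generator(rng)
    D, V, K = cohort.n_samples, cohort.n_taxa, hyper.K
    b_vec = hyper.b_vector(V)

    if init is not None:
        state = init_from_lda(cohort, init, hyper, rng)
    else:
        read_sample, read_taxon = expand_reads(cohort)
        z = rng.integers(0, K, size=read_sample.size).astype(np.int32)
        state = ChainState.from_assignments(read_sample, read_taxon, z, D, V, K)

    n_keep = (n_iter - burn_in + thin - 1) // thin
    meta = {
        "model": "zinlda",
        "K": K,
        "alpha": float(hyper.alpha),
        "pi": float(hyper.pi),
        "a": float(hyper.a),
        "b": hyper.b if np.isscalar(hyper.b) else list(np.asarray(hyper.b, float)),
        "n_iter": n_iter,
        "burn_in": burn_in,
        "thin": thin,
        "engine": engine,
        "init": "lda" if init is not None else "uniform",
        "taxon_ids": list(cohort.taxon_ids),
    }

    if engine == "python":
        betas, thetas, deltas, zs = [], [], [], []
        for it in range(n_iter):
            gibbs_sweep(state, hyper, rng)
            if it >= burn_in and (it - burn_in) % thin == 0:
                betas.append(estimate_beta_draw(state, hyper))
                thetas.append(estimate_theta_draw(state, hyper))
                deltas.append(state.delta.copy())
                if record_z:
                    zs.append(state.z.copy())
        if record_z:
            meta["z_draws"] = np.array(zs)
        draws = PosteriorDraws(
            beta=np.array(betas), theta=np.array(thetas), delta=np.array(deltas, dtype=np.int8), meta=meta
        )
    elif engine == "numba":
        kernel_seed = int(rng.integers(0, 2**31 - 1))
        meta["kernel_seed"] = kernel_seed
        beta_draws = np.empty((n_keep, K, V))
        theta_draws = np.empty((n_keep, D, K))
        delta_draws = np.empty((n_keep, K, V), dtype=np.int8)
        z_draws = np.empty((n_keep if record_z else 0, state.z.size), dtype=np.int32)
        counters = np.zeros(2, dtype=np.int64)
        kept = _zin_run(
            state.read_sample,
            state.read_taxon,
            state.z,
            state.delta,
            D,
            V,
            K,
            float(hyper.alpha),
            float(hyper.pi),
            float(hyper.a),
            b_vec,
            n_iter,
            burn_in,
            thin,
            kernel_seed,
            beta_draws,
            theta_draws,
            delta_draws,
            z_draws,
            counters,
        )
        if record_z:
            meta["z_draws"] = z_draws[:kept]
        if counters[0]:
            logger.warning("full-support fallback used for %d read updates", counters[0])
        if counters[1]:
            raise AssertionError("sampler invariant violated: structural zero with positive count")
        # counts were updated in place by the kernel; refresh the cached sums
        state.n = np.zeros((K, V), dtype=np.int64)
        state.m = np.zeros((D, K), dtype=np.int64)
        np.add.at(state.n, (state.z, state.read_taxon), 1)
        np.add.at(state.m, (state.read_sample, state.z), 1)
        state.n_total = state.n.sum(axis=1)
        draws = PosteriorDraws(
            beta=beta_draws[:kept], theta=theta_draws[:kept], delta=delta_draws[:kept], meta=meta
        )
    else:
        raise ValueError(f"unknown engine {engine!r}")

    if state_out is not None:
        state_out.__dict__.update(state.__dict__)
    logger.info("chain finished: %d retained draws", draws.n_draws)
    return draws


def finalize(draws: PosteriorDraws) -> Fit:
    """Assemble the final fit from retained draws.

    pi_hat is the posterior mean of delta; entries with pi_hat >= 0.5
    (inclusive at the tie) are declared structural zeros and their beta set
    to exactly 0; remaining beta entries take their posterior mean and each
    row is renormalized to sum to 1.  theta_hat is the posterior mean.
    """
    if draws.n_draws < 1:
        raise ValueError("need at least one retained draw")
    pi_hat = draws.delta.mean(axis=0)
    delta_hat = (pi_hat >= 0.5).astype(np.int8)
    beta = draws.beta.mean(axis=0)
    beta = np.where(delta_hat == 1, 0.0, beta)
    row_sums = beta.sum(axis=1)
    dead = np.flatnonzero(row_sums <= 0)
    if dead.size:
        raise ValueError(f"degenerate subcommunity(ies) {dead.tolist()}: every taxon zeroed")
    beta = beta / row_sums[:, None]
    theta = draws.theta.mean(axis=0)
    return Fit(beta=beta, theta=theta, pi_hat=pi_hat, delta_hat=delta_hat, provenance=dict(draws.meta))


def fit_zinlda(
    cohort: Cohort,
    hyper: ZinHyper,
    n_iter: int = 2000,
    burn_in: int = 1000,
    thin: int = 1,
    rng: int | np.random.Generator | None = None,
    lda_n_iter: int | None = None,
    lda_burn_in: int | None = None,
    eta: float = 0.1,
) -> tuple[Fit, PosteriorDraws]:
    """Convenience pipeline: LDA fit for initialization, zero-inflated chain,
    finalization.  Returns (Fit, PosteriorDraws)."""
    rng = as_generator(rng)
    lda_hyper = LDAHyper(K=hyper.K, alpha=hyper.alpha, eta=eta)
    lda_fit = fit_lda(
        cohort,
        lda_hyper,
        n_iter=lda_n_iter if lda_n_iter is not None else n_iter,
        burn_in=lda_burn_in if lda_burn_in is not None else burn_in,
        thin=thin,
        rng=rng,
    )
    draws = run_chain(cohort, hyper, n_iter=n_iter, burn_in=burn_in, thin=thin, rng=rng, init=lda_fit)
    return finalize(draws), draws
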