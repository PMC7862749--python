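"""Collapsed-Gibbs LDA baseline.

Standard latent Dirichlet allocation on taxon counts: symmetric Dir(eta) on
the subcommunity profiles beta and symmetric Dir(alpha) on the per-sample
mixtures theta, with beta and theta integrated out and the chain run over
per-read subcommunity assignments z (Griffiths-Steyvers collapsed sampler):

    P(z = j | rest) ∝ (n_j^(i) + eta) / (n_j + V*eta)
                    * (m_j^(d) + alpha) / (m^(d) + K*alpha)

Per retained draw the point estimates are the smoothed proportions
beta_ij = (n_j^(i) + eta) / (n_j + V*eta) and theta the same form with alpha;
the fit is the posterior mean over retained draws, so every beta entry is
strictly positive -- the Dirichlet over-smoothing the zero-inflated model is
designed to remove.  Used both as a comparison baseline and to initialize the
zero-inflated chain.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

from .types import Cohort, Fit, PosteriorDraws, as_generator

__all__ = ["LDAHyper", "fit_lda", "expand_reads"]


@dataclass(frozen=True)
class LDAHyper:
    """Symmetric LDA hyperparameters; defaults alpha = 50/K, eta = 0.1."""

    K: int
    alpha: float | None = None
    eta: float = 0.1

    def __post_init__(self) -> None:
        if not isinstance(self.K, (int, np.integer)) or self.K < 1:
            raise ValueError(f"K must be an integer >= 1, got {self.K}")
        if self.alpha is None:
            object.__setattr__(self, "alpha", 50.0 / self.K)
        if self.alpha <= 0 or self.eta <= 0:
            raise ValueError("alpha and eta must be positive")


def expand_reads(cohort: Cohort) -> tuple[np.ndarray, np.ndarray]:
    """Flatten a count matrix to per-read (sample, taxon) index arrays.

    Reads are laid out sample-major, taxa in column order within a sample;
    this fixed order makes chains reproducible.
    """
    counts = cohort.counts
    total = int(counts.sum())
    read_sample = np.empty(total, dtype=np.int32)
    read_taxon = np.empty(total, dtype=np.int32)
    pos = 0
    for d in range(counts.shape[0]):
        row = counts[d]
        nz = np.flatnonzero(row)
        n_d = int(row.sum())
        read_sample[pos : pos + n_d] = d
        read_taxon[pos : pos + n_d] = np.repeat(nz.astype(np.int32), row[nz])
        pos += n_d
    return read_sample, read_taxon


@njit(cache=True)
def _lda_run(
    read_sample,
    read_taxon,
    z,
    D,
    V,
    K,
    alpha,
    eta,
    n_iter,
    burn_in,
    thin,
    seed,
    beta_draws,
    theta_draws,
    z_draws,
):  # pragma: no cover - exercised through fit_lda
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
    keep = 0
    for it in range(n_iter):
        for r in range(R):
            i = read_taxon[r]
            d = read_sample[r]
            jo = z[r]
            n[jo, i] -= 1
            njt[jo] -= 1
            m[d, jo] -= 1
            tot = 0.0
            for j in range(K):
                p = (n[j, i] + eta) / (njt[j] + V * eta) * (m[d, j] + alpha)
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
        if it >= burn_in and (it - burn_in) % thin == 0:
            for j in range(K):
                denom = njt[j] + V * eta
                for i in range(V):
                    beta_draws[keep, j, i] = (n[j, i] + eta) / denom
            for d in range(D):
                denom = depths[d] + K * alpha
                for j in range(K):
                    theta_draws[keep, d, j] = (m[d, j] + alpha) / denom
            if z_draws.shape[0] > 0:
                for r in range(R):
                    z_draws[keep, r] = z[r]
            keep += 1
    return keep


def fit_lda(
    cohort: Cohort,
    hyper: LDAHyper,
    n_iter: int = 2000,
    burn_in: int = 1000,
    thin: int = 1,
    rng: int | np.random.Generator | None = None,
    return_draws: bool = False,
    record_z: bool = False,
) -> Fit | tuple[Fit, PosteriorDraws]:
    """Fit LDA by collapsed Gibbs; estimates are means over retained draws.

    Initialization is a uniform-random subcommunity per read.  Returns the
    Fit, or (Fit, PosteriorDraws) with ``return_draws=True`` (needed for
    posterior predictive checks).
    """
    if cohort.n_samples == 0 or cohort.n_taxa == 0:
        raise ValueError("empty cohort")
    if not n_iter > burn_in >= 0:
        raise ValueError("need n_iter > burn_in >= 0")
    if thin < 1:
        raise ValueError("thin must be >= 1")
    total_reads = int(cohort.counts.sum())
    if hyper.K > total_reads:
        raise ValueError(f"degenerate configuration: K={hyper.K} exceeds total reads {total_reads}")

    rng = as_generator(rng)
    read_sample, read_taxon = expand_reads(cohort)
    z = rng.integers(0, hyper.K, size=read_sample.size).astype(np.int32)
    kernel_seed = int(rng.integers(0, 2**31 - 1))

    n_keep = (n_iter - burn_in + thin - 1) // thin
    D, V, K = cohort.n_samples, cohort.n_taxa, hyper.K
    beta_draws = np.empty((n_keep, K, V))
    theta_draws = np.empty((n_keep, D, K))
    z_draws = np.empty((n_keep if record_z else 0, z.size), dtype=np.int32)
    kept = _lda_run(
        read_sample,
        read_taxon,
        z,
        D,
        V,
        K,
        float(hyper.alpha),
        float(hyper.eta),
        n_iter,
        burn_in,
        thin,
        kernel_seed,
        beta_draws,
        theta_draws,
        z_draws,
    )
    beta_draws = beta_draws[:kept]
    theta_draws = theta_draws[:kept]

    provenance = {
        "model": "lda",
        "K": K,
        "alpha": float(hyper.alpha),
        "eta": float(hyper.eta),
        "n_iter": n_iter,
        "burn_in": burn_in,
        "thin": thin,
        "kernel_seed": kernel_seed,
        "taxon_ids": list(cohort.taxon_ids),
    }
    fit = Fit(beta=beta_draws.mean(axis=0), theta=theta_draws.mean(axis=0), provenance=provenance)
    if not return_draws:
        return fit
    meta = dict(provenance)
    if record_z:
        meta["z_draws"] = z_draws[:kept]
    draws = PosteriorDraws(
        beta=beta_draws,
        theta=theta_draws,
        delta=np.zeros((kept, K, V), dtype=np.int8),
        meta=meta,
    )
    return fit, draws
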