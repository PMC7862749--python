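"""Generative simulators with retained ground truth, plus count-matrix filters.

The zero-inflated generative process for a cohort of D samples over V taxa
with K subcommunities:

    for each subcommunity j:      beta^(j) ~ ZIGD(pi, a, b)
    for each sample d:            theta^(d) ~ Dir(alpha)  (symmetric)
        depth N_d ~ DiscreteUniform[depth_low, depth_high]  (inclusive)
        for each read:            z ~ Multinomial(1, theta^(d));
                                  taxon ~ Multinomial(1, beta^(z))

Reads are exchangeable within a sample, so the per-read loop is implemented
as nested multinomials -- community counts Multinomial(N_d, theta^(d)), then
taxon counts per community -- which is distributionally exact and fast.

Setting pi = 0 gives the plain generalized-Dirichlet variant; using the
Dirichlet-nesting b vector additionally reduces it to standard LDA.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .types import Cohort, GroundTruth, as_generator
from .zigd import ZIGDParams, sample_zigd

__all__ = [
    "FilterMap",
    "simulate_profiles",
    "simulate_cohort",
    "drop_unobserved_taxa",
    "prevalence_filter",
]


@dataclass
class FilterMap:
    """Maps a filtered cohort back to original row/column positions.

    ``kept_taxa`` / ``kept_samples`` hold the retained original indices in
    order; ``dropped_taxa`` / ``dropped_samples`` the removed ones.
    """

    kept_taxa: np.ndarray
    kept_samples: np.ndarray
    dropped_taxa: np.ndarray
    dropped_samples: np.ndarray

    @property
    def identity(self) -> bool:
        return self.dropped_taxa.size == 0 and self.dropped_samples.size == 0


def simulate_profiles(
    K: int, params: ZIGDParams, rng: int | np.random.Generator | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Draw K independent ZIGD subcommunity profiles.

    Returns (beta, delta): K x V stacked compositions with exact zeros and
    the matching structural-zero indicators.
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    rng = as_generator(rng)
    beta = np.zeros((K, params.V))
    delta = np.zeros((K, params.V), dtype=np.int8)
    for j in range(K):
        comp = sample_zigd(params, rng)
        beta[j] = comp.beta
        delta[j] = comp.delta
    return beta, delta


def simulate_cohort(
    profiles: tuple[np.ndarray, np.ndarray] | np.ndarray,
    D: int,
    depth_low: int,
    depth_high: int,
    alpha: float,
    rng: int | np.random.Generator | None = None,
) -> tuple[Cohort, GroundTruth]:
    """Simulate a D-sample cohort from fixed subcommunity profiles.

    ``profiles`` is (beta, delta) from :func:`simulate_profiles`, or just a
    K x V beta matrix (delta then inferred from exact zeros).  Depths are
    inclusive-uniform on [depth_low, depth_high]; theta^(d) is symmetric
    Dirichlet(alpha).
    """
    if isinstance(profiles, tuple):
        beta, delta = profiles
    else:
        beta = np.asarray(profiles, dtype=float)
        delta = (beta == 0.0).astype(np.int8)
    beta = np.asarray(beta, dtype=float)
    K, V = beta.shape
    row_sums = beta.sum(axis=1)
    if np.any(row_sums <= 0):
        raise ValueError("invalid profile: a subcommunity row is entirely zero")
    if not np.allclose(row_sums, 1.0, atol=1e-8):
        raise ValueError("profile rows must sum to 1")
    if D < 1:
        raise ValueError("D must be >= 1")
    if depth_low > depth_high or depth_low < 1:
        raise ValueError("need 1 <= depth_low <= depth_high")
    if alpha <= 0:
        raise ValueError("alpha must be positive")

    rng = as_generator(rng)
    depths = rng.integers(depth_low, depth_high + 1, size=D)
    theta = rng.dirichlet(np.full(K, float(alpha)), size=D)
    z_counts = np.zeros((D, K, V), dtype=np.int64)
    for d in range(D):
        per_community = rng.multinomial(depths[d], theta[d])
        for j in range(K):
            if per_community[j] > 0:
                z_counts[d, j] = rng.multinomial(per_community[j], beta[j])
    counts = z_counts.sum(axis=1)

    cohort = Cohort(
        counts=counts,
        sample_ids=[f"S{d + 1:04d}" for d in range(D)],
        taxon_ids=[f"T{i + 1:04d}" for i in range(V)],
    )
    truth = GroundTruth(theta=theta, beta=beta, delta=np.asarray(delta, dtype=np.int8), z_counts=z_counts)
    return cohort, truth


def _subset(cohort: Cohort, kept_taxa: np.ndarray, kept_samples: np.ndarray) -> Cohort:
    return Cohort(
        counts=cohort.counts[np.ix_(kept_samples, kept_taxa)],
        sample_ids=[cohort.sample_ids[d] for d in kept_samples],
        taxon_ids=[cohort.taxon_ids[i] for i in kept_taxa],
    )


def drop_unobserved_taxa(
    cohort: Cohort, truth: GroundTruth | None = None
) -> tuple[Cohort, FilterMap, GroundTruth | None]:
    """Remove taxa with zero total count in every sample (prevalence 0%).

    Mirrors the removal a real study would impose: never-observed taxa cannot
    enter the analysis.  Ground truth, when given, is subset to the same
    columns but *not* renormalized -- truth stays on the original scale and
    the dropped columns are recorded in the returned map.
    """
    totals = cohort.counts.sum(axis=0)
    kept = np.flatnonzero(totals > 0)
    if kept.size == 0:
        raise ValueError("empty cohort: every taxon has zero total count")
    dropped = np.flatnonzero(totals == 0)
    all_samples = np.arange(cohort.n_samples)
    fmap = FilterMap(
        kept_taxa=kept,
        kept_samples=all_samples,
        dropped_taxa=dropped,
        dropped_samples=np.empty(0, dtype=int),
    )
    out = _subset(cohort, kept, all_samples) if dropped.size else cohort
    truth_out = truth.subset_taxa(kept) if truth is not None else None
    return out, fmap, truth_out


def prevalence_filter(cohort: Cohort, min_prevalence: float) -> tuple[Cohort, FilterMap]:
    """Remove rare taxa, then empty samples.

    A taxon's prevalence is the fraction of samples where it is nonzero; taxa
    with prevalence strictly below ``min_prevalence`` are removed (prevalence
    exactly at the threshold is retained).  Afterwards any sample whose total
    count dropped to zero is removed.  The taxa-then-samples order is fixed.
    """
    if not 0.0 <= min_prevalence <= 1.0:
        raise ValueError("min_prevalence must be in [0, 1]")
    prevalence = (cohort.counts > 0).mean(axis=0)
    kept_taxa = np.flatnonzero(prevalence >= min_prevalence)
    if kept_taxa.size == 0:
        raise ValueError("prevalence filter removed every taxon")
    sub_counts = cohort.counts[:, kept_taxa]
    kept_samples = np.flatnonzero(sub_counts.sum(axis=1) > 0)
    if kept_samples.size == 0:
        raise ValueError("prevalence filter removed every sample")
    fmap = FilterMap(
        kept_taxa=kept_taxa,
        kept_samples=kept_samples,
        dropped_taxa=np.flatnonzero(prevalence < min_prevalence),
        dropped_samples=np.flatnonzero(sub_counts.sum(axis=1) == 0),
    )
    return _subset(cohort, kept_taxa, kept_samples), fmap
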