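"""Shared containers: cohorts, simulation ground truth, fits, posterior draws."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np

__all__ = ["Cohort", "GroundTruth", "Fit", "PosteriorDraws", "as_generator"]


def as_generator(rng: int | np.random.Generator | None) -> np.random.Generator:
    """Coerce an integer seed (or None) to a numpy Generator."""
    if isinstance(rng, np.random.Generator):
        return rng
    return np.random.default_rng(rng)


@dataclass
class Cohort:
    """A sample-by-taxon count matrix.

    Rows are biological samples, columns are taxa (ASVs, genera, ...).
    Taxon column order is authoritative: the generalized-Dirichlet family used
    downstream is not exchangeable in taxon order, so the order counts are
    loaded in is the order the model sees and is recorded in fit provenance.
    """

    counts: np.ndarray
    sample_ids: list[str]
    taxon_ids: list[str]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise ValueError("counts must be a 2-d sample-by-taxon matrix")
        if np.any(self.counts < 0):
            raise ValueError("counts must be nonnegative")
        if not np.issubdtype(self.counts.dtype, np.integer):
            if not np.all(self.counts == np.floor(self.counts)):
                raise ValueError("counts must be integers")
            self.counts = self.counts.astype(np.int64)
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.taxon_ids = [str(t) for t in self.taxon_ids]
        if len(self.sample_ids) != self.counts.shape[0]:
            raise ValueError("sample_ids length does not match counts rows")
        if len(self.taxon_ids) != self.counts.shape[1]:
            raise ValueError("taxon_ids length does not match counts columns")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("duplicate sample IDs")
        if len(set(self.taxon_ids)) != len(self.taxon_ids):
            raise ValueError("duplicate taxon IDs")

    @property
    def n_samples(self) -> int:
        return self.counts.shape[0]

    @property
    def n_taxa(self) -> int:
        return self.counts.shape[1]

    @property
    def depths(self) -> np.ndarray:
        """Per-sample read depths (row sums)."""
        return self.counts.sum(axis=1)


@dataclass
class GroundTruth:
    """Latent state retained by the simulators.

    ``z_counts[d, j, i]`` is the number of reads in sample ``d`` assigned to
    subcommunity ``j`` and taxon ``i``; summing over ``j`` reproduces the
    cohort counts exactly.  ``beta`` keeps exact zeros where ``delta`` is 1.

    After taxon filtering, ``beta`` rows are *not* renormalized: truth is kept
    on the original scale with the dropped columns recorded by the caller.
    """

    theta: np.ndarray  # D x K
    beta: np.ndarray  # K x V, rows on the simplex with exact zeros
    delta: np.ndarray  # K x V binary, delta=1 <=> beta=0
    z_counts: np.ndarray  # D x K x V

    def subset_taxa(self, kept: np.ndarray) -> "GroundTruth":
        """Restrict to the taxon columns in ``kept`` (original order)."""
        return GroundTruth(
            theta=self.theta,
            beta=self.beta[:, kept],
            delta=self.delta[:, kept],
            z_counts=self.z_counts[:, :, kept],
        )


@dataclass
class Fit:
    """A fitted topic model.

    ``beta`` is K x V (taxa-over-subcommunity probabilities; the zero-inflated
    model produces exact zeros, the plain LDA fit is strictly positive),
    ``theta`` is D x K (subcommunity mixture per sample).  ``pi_hat`` and
    ``delta_hat`` are present only for zero-inflated fits: the posterior mean
    of the structural-zero indicators and its dichotomization at 0.5.
    """

    beta: np.ndarray
    theta: np.ndarray
    pi_hat: np.ndarray | None = None
    delta_hat: np.ndarray | None = None
    provenance: dict[str, Any] = field(default_factory=dict)

    @property
    def n_components(self) -> int:
        return self.beta.shape[0]

    @property
    def n_taxa(self) -> int:
        return self.beta.shape[1]


@dataclass
class PosteriorDraws:
    """Post-burn-in, thinned per-iteration estimates from a Gibbs chain.

    ``beta[t]``/``theta[t]`` are the posterior-predictive point estimates
    computed from the chain state at retained iteration ``t``; ``delta[t]``
    is the structural-zero indicator state (all zeros for plain LDA).
    """

    beta: np.ndarray  # T x K x V
    theta: np.ndarray  # T x D x K
    delta: np.ndarray  # T x K x V (binary)
    meta: dict[str, Any] = field(default_factory=dict)

    @property
    def n_draws(self) -> int:
        return self.beta.shape[0]
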