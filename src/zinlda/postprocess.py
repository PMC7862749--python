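"""Evaluation machinery: label matching, structural-zero diagnostics,
posterior predictive checks, stability, and a plug-in log-likelihood.

Mixture posteriors are invariant to permutations of the subcommunity labels
(label switching), so any comparison between two fits, or between a fit and
simulation ground truth, first matches labels: pairwise Pearson correlations
between profile rows, greedily taking the highest-correlation pair, then the
highest among the remainder, until all pairs are matched.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .types import Cohort, Fit, PosteriorDraws, as_generator

logger = logging.getLogger(__name__)

__all__ = [
    "ConfusionSummary",
    "match_labels",
    "structural_zero_metrics",
    "posterior_predictive_simulate",
    "ppc_summary",
    "plot_ppc",
    "stability_cosine",
    "point_loglik",
]


@dataclass(frozen=True)
class ConfusionSummary:
    """Entry-wise confusion over the K x V indicator cells.

    Positive = structural zero (delta = 1).  Ratios with an empty denominator
    are reported as nan (missing), never as 0.
    """

    tp: int
    fp: int
    tn: int
    fn: int

    @staticmethod
    def _ratio(num: int, den: int) -> float:
        return num / den if den > 0 else float("nan")

    @property
    def sensitivity(self) -> float:
        return self._ratio(self.tp, self.tp + self.fn)

    @property
    def specificity(self) -> float:
        return self._ratio(self.tn, self.tn + self.fp)

    @property
    def ppv(self) -> float:
        return self._ratio(self.tp, self.tp + self.fp)

    @property
    def npv(self) -> float:
        return self._ratio(self.tn, self.tn + self.fn)

    def as_dict(self) -> dict[str, float]:
        return {
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "ppv": self.ppv,
            "npv": self.npv,
            "tp": self.tp,
            "fp": self.fp,
            "tn": self.tn,
            "fn": self.fn,
        }


def match_labels(beta_ref: np.ndarray, beta_est: np.ndarray) -> np.ndarray:
    """Greedy maximum-Pearson-correlation matching of profile rows.

    Returns ``perm`` with ``perm[r]`` the estimated row matched to reference
    row ``r``; always a bijection on 0..K-1.  Ties break deterministically by
    lowest reference index, then lowest estimate index.  A zero-variance row
    has undefined correlation and is treated as -inf attraction (matched
    last), with a log notice.
    """
    beta_ref = np.asarray(beta_ref, float)
    beta_est = np.asarray(beta_est, float)
    if beta_ref.shape != beta_est.shape:
        raise ValueError("reference and estimate must have the same shape")
    K = beta_ref.shape[0]
    corr = np.full((K, K), -np.inf)
    ref_sd = beta_ref.std(axis=1)
    est_sd = beta_est.std(axis=1)
    if np.any(ref_sd == 0) or np.any(est_sd == 0):
        logger.warning("zero-variance profile row(s): correlation undefined, treated as -inf")
    for r in range(K):
        for e in range(K):
            if ref_sd[r] > 0 and est_sd[e] > 0:
                corr[r, e] = np.corrcoef(beta_ref[r], beta_est[e])[0, 1]
    perm = np.full(K, -1, dtype=int)
    used_ref: set[int] = set()
    used_est: set[int] = set()
    for _ in range(K):
        best = (-np.inf, K, K)
        for r in range(K):
            if r in used_ref:
                continue
            for e in range(K):
                if e in used_est:
                    continue
                c = corr[r, e]
                # ties: higher corr, then lower ref index, then lower est index
                if c > best[0] or (c == best[0] and (r, e) < (best[1], best[2])):
                    best = (c, r, e)
        _, r, e = best
        perm[r] = e
        used_ref.add(r)
        used_est.add(e)
    return perm


def structural_zero_metrics(
    delta_true: np.ndarray, delta_est: np.ndarray, match: np.ndarray
) -> ConfusionSummary:
    """Confusion summary over all indicator cells after label matching.

    ``match[r]`` gives the estimated row paired with true row ``r``.
    """
    delta_true = np.asarray(delta_true)
    delta_est = np.asarray(delta_est)
    aligned = delta_est[np.asarray(match, int)]
    if aligned.shape != delta_true.shape:
        raise ValueError("shape mismatch after permutation")
    t = delta_true.astype(bool)
    e = aligned.astype(bool)
    return ConfusionSummary(
        tp=int(np.sum(t & e)),
        fp=int(np.sum(~t & e)),
        tn=int(np.sum(~t & ~e)),
        fn=int(np.sum(t & ~e)),
    )


def posterior_predictive_simulate(
    draws: PosteriorDraws,
    depths: np.ndarray,
    n_datasets: int,
    rng: int | np.random.Generator | None = None,
    sample_ids: list[str] | None = None,
    taxon_ids: list[str] | None = None,
) -> list[Cohort]:
    """Simulate replicate cohorts from the posterior predictive distribution.

    Each replicate picks one retained draw uniformly at random and simulates
    counts at the original depths from its (beta, theta); marginally over the
    read-level assignments this is Multinomial(N_d, theta^(d) beta).
    """
    if draws.n_draws < 1:
        raise ValueError("need at least one retained draw")
    rng = as_generator(rng)
    depths = np.asarray(depths, dtype=np.int64)
    D = depths.size
    V = draws.beta.shape[2]
    if sample_ids is None:
        sample_ids = [f"S{d + 1:04d}" for d in range(D)]
    if taxon_ids is None:
        taxon_ids = list(draws.meta.get("taxon_ids", [f"T{i + 1:04d}" for i in range(V)]))
    out: list[Cohort] = []
    for _ in range(n_datasets):
        t = int(rng.integers(0, draws.n_draws))
        probs = draws.theta[t] @ draws.beta[t]  # D x V mixed multinomial
        probs = probs / probs.sum(axis=1, keepdims=True)
        counts = np.vstack([rng.multinomial(depths[d], probs[d]) for d in range(D)])
        out.append(Cohort(counts=counts, sample_ids=list(sample_ids), taxon_ids=list(taxon_ids)))
    return out


def ppc_summary(observed: Cohort, replicates: list[Cohort]) -> pd.DataFrame:
    """Posterior predictive check table on the per-taxon count statistic.

    For each sample, taxa are ordered by observed count ascending (ties by
    column order); the table reports, in that order, the observed count and
    the median/2.5%/97.5% quantiles of the replicate counts, both raw and on
    the asinh scale used for plotting.
    """
    for rep in replicates:
        if rep.counts.shape != observed.counts.shape:
            raise ValueError("replicate dimensions do not match observed cohort")
    rep_stack = np.stack([rep.counts for rep in replicates]) if replicates else np.empty((0,) + observed.counts.shape)
    rows = []
    for d, sid in enumerate(observed.sample_ids):
        order = np.argsort(observed.counts[d], kind="stable")
        for rank, i in enumerate(order):
            obs = int(observed.counts[d, i])
            if rep_stack.shape[0]:
                reps = rep_stack[:, d, i]
                med = float(np.median(reps))
                lo, hi = np.quantile(reps, [0.025, 0.975])
            else:
                med = lo = hi = float("nan")
            rows.append(
                {
                    "sample_id": sid,
                    "taxon_id": observed.taxon_ids[i],
                    "rank": rank,
                    "observed": obs,
                    "rep_median": med,
                    "rep_lo": float(lo),
                    "rep_hi": float(hi),
                    "observed_asinh": float(np.arcsinh(obs)),
                    "rep_median_asinh": float(np.arcsinh(med)),
                }
            )
    return pd.DataFrame(rows)


def plot_ppc(
    observed: Cohort,
    replicates_by_model: dict[str, list[Cohort]],
    path: str,
    samples: list[str] | None = None,
    n_plot: int = 50,
) -> None:
    """Panel-per-sample PPC plot: asinh counts, taxa ordered by observed
    abundance, observed as a black line, replicate points and medians per
    model.  ``n_plot`` caps the replicates drawn as points."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if samples is None:
        samples = observed.sample_ids[:6]
    idx = [observed.sample_ids.index(s) for s in samples]
    ncol = min(3, len(idx))
    nrow = (len(idx) + ncol - 1) // ncol
    fig, axes = plt.subplots(nrow, ncol, figsize=(4 * ncol, 3 * nrow), squeeze=False)
    colors = plt.rcParams["axes.prop_cycle"].by_key()["color"]
    for ax_i, d in enumerate(idx):
        ax = axes[ax_i // ncol][ax_i % ncol]
        order = np.argsort(observed.counts[d], kind="stable")
        x = np.arange(order.size)
        ax.plot(x, np.arcsinh(observed.counts[d, order]), color="black", lw=1.5, label="observed")
        for c, (name, reps) in enumerate(replicates_by_model.items()):
            stack = np.stack([r.counts[d, order] for r in reps[:n_plot]])
            for row in np.arcsinh(stack):
                ax.plot(x, row, ".", color=colors[c % len(colors)], alpha=0.08, ms=2)
            ax.plot(x, np.arcsinh(np.median(stack, axis=0)), color=colors[c % len(colors)], lw=1.2, label=name)
        ax.set_title(observed.sample_ids[d])
        ax.set_xlabel("taxa (ordered by observed count)")
        ax.set_ylabel("asinh(count)")
    axes[0][0].legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def stability_cosine(fit_a: Fit, fit_b: Fit) -> float:
    """Average cosine similarity of matched subcommunity profiles.

    Labels are matched greedily on Pearson correlation of the beta rows; the
    result is the mean cosine over the K matched pairs (nan-skipping if a row
    is entirely zero, which has undefined cosine).
    """
    if fit_a.beta.shape != fit_b.beta.shape:
        raise ValueError("fits must share the taxon set and K")
    perm = match_labels(fit_a.beta, fit_b.beta)
    sims = []
    for r, e in enumerate(perm):
        u, v = fit_a.beta[r], fit_b.beta[e]
        nu, nv = np.linalg.norm(u), np.linalg.norm(v)
        if nu == 0 or nv == 0:
            logger.warning("zero profile row in cosine comparison; reported as missing")
            sims.append(float("nan"))
        else:
            sims.append(float(u @ v / (nu * nv)))
    return float(np.nanmean(sims))


def point_loglik(cohort: Cohort, fit: Fit) -> float:
    """Plug-in log-likelihood of the counts under the mixed multinomial.

    sum_d sum_i counts[d, i] * log(sum_j theta_dj * beta_ji).  Returns -inf
    (with a diagnostic listing offending cells) if an observed taxon has zero
    probability under the fit, e.g. a count on a taxon structurally zeroed in
    every subcommunity.  Multinomial coefficients are omitted: they do not
    depend on the fit, so comparisons across fits are unaffected.
    """
    if fit.theta.shape[0] != cohort.n_samples or fit.beta.shape[1] != cohort.n_taxa:
        raise ValueError("fit dimensions do not match cohort")
    probs = fit.theta @ fit.beta  # D x V
    mask = cohort.counts > 0
    bad = np.argwhere(mask & (probs <= 0))
    if bad.size:
        cells = [(cohort.sample_ids[d], cohort.taxon_ids[i]) for d, i in bad[:20]]
        logger.warning("observed counts with zero fitted probability at %s%s", cells, "..." if len(bad) > 20 else "")
        return float("-inf")
    with np.errstate(divide="ignore"):
        logp = np.where(mask, np.log(np.where(probs > 0, probs, 1.0)), 0.0)
    return float(np.sum(cohort.counts * logp))
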