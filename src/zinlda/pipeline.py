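"""End-to-end simulation-study pipeline.

Simulate a cohort from the zero-inflated generative process, drop the taxa
never observed, fit the standard LDA baseline (which also initializes the
zero-inflated chain), fit the zero-inflated model, match labels to ground
truth by greedy Pearson correlation, and score recovery of the structural
zeros.  Used by the evaluation CLI and the reproduction scripts.

The canonical study design is V = 120 taxa, D = 150 samples, depths
DiscreteUniform(5000, 25000), K = 5, alpha = 50/K, (pi, a, b) = (0.4, 0.05,
10).  Full-depth chains are expensive; for desk-scale evaluation the same
design is run at depths DiscreteUniform(1000, 5000) with shorter chains,
which preserves the qualitative behaviour of the estimators.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np

from .lda import LDAHyper, fit_lda
from .postprocess import ConfusionSummary, match_labels, structural_zero_metrics
from .sampler import ZinHyper, finalize, run_chain
from .simulate import drop_unobserved_taxa, simulate_cohort, simulate_profiles
from .types import as_generator
from .zigd import ZIGDParams

__all__ = ["DESK_SCALE", "StudyResult", "structural_zero_study"]

#: Reduced problem size for routine evaluation runs: the canonical design
#: (D = 150 samples, K = 5, alpha = 50/K) at depths DiscreteUniform(1000,
#: 5000) instead of (5000, 25000), with 1200-iteration chains (600 burn-in)
#: initialized from a 250-iteration LDA fit.  At roughly one fifth of the
#: canonical sequencing depth the estimators keep their qualitative
#: behaviour, but sparsity-driven misclassification of rare taxa rises; see
#: the methods notes for what this does and does not preserve.
DESK_SCALE = {
    "depth_low": 1000,
    "depth_high": 5000,
    "n_iter": 1200,
    "burn_in": 600,
    "lda_n_iter": 250,
    "lda_burn_in": 125,
}


@dataclass
class StudyResult:
    """Everything a simulation study produces, for downstream inspection."""

    metrics: ConfusionSummary
    n_observed_taxa: int
    match: np.ndarray
    cohort: Any
    truth: Any
    zin_fit: Any
    lda_fit: Any
    draws: Any
    config: dict[str, Any] = field(default_factory=dict)


def structural_zero_study(
    V: int = 120,
    a: float = 0.05,
    *,
    D: int = 150,
    K: int = 5,
    pi: float = 0.4,
    b: float = 10.0,
    alpha: float | None = None,
    depth_low: int = 5000,
    depth_high: int = 25000,
    n_iter: int = 2000,
    burn_in: int = 1000,
    thin: int = 1,
    lda_n_iter: int | None = None,
    lda_burn_in: int | None = None,
    eta: float = 0.1,
    seed: int | np.random.Generator | None = None,
) -> StudyResult:
    """Run one simulate-fit-evaluate cycle and score structural-zero recovery.

    The fit uses the true hyperparameters (alpha, pi, a, b), as a recovery
    study does; alpha defaults to 50/K.  Returns a :class:`StudyResult`
    whose ``metrics`` is the confusion summary over all indicator cells of
    the observed taxa, positive = structural zero.
    """
    rng = as_generator(seed)
    if alpha is None:
        alpha = 50.0 / K
    params = ZIGDParams(pi=pi, a=a, b=b, V=V)
    profiles = simulate_profiles(K, params, rng)
    cohort, truth = simulate_cohort(profiles, D, depth_low, depth_high, alpha, rng)
    cohort, fmap, truth_obs = drop_unobserved_taxa(cohort, truth)

    lda_hyper = LDAHyper(K=K, alpha=alpha, eta=eta)
    lda_fit = fit_lda(
        cohort,
        lda_hyper,
        n_iter=lda_n_iter if lda_n_iter is not None else n_iter,
        burn_in=lda_burn_in if lda_burn_in is not None else burn_in,
        thin=thin,
        rng=rng,
    )
    hyper = ZinHyper(K=K, pi=pi, a=a, b=b, alpha=alpha)
    draws = run_chain(cohort, hyper, n_iter=n_iter, burn_in=burn_in, thin=thin, rng=rng, init=lda_fit)
    zin_fit = finalize(draws)

    match = match_labels(truth_obs.beta, zin_fit.beta)
    metrics = structural_zero_metrics(truth_obs.delta, zin_fit.delta_hat, match)
    return StudyResult(
        metrics=metrics,
        n_observed_taxa=cohort.n_taxa,
        match=match,
        cohort=cohort,
        truth=truth_obs,
        zin_fit=zin_fit,
        lda_fit=lda_fit,
        draws=draws,
        config={
            "V": V,
            "D": D,
            "K": K,
            "alpha": alpha,
            "pi": pi,
            "a": a,
            "b": b,
            "depth_low": depth_low,
            "depth_high": depth_high,
            "n_iter": n_iter,
            "burn_in": burn_in,
            "thin": thin,
        },
    )
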