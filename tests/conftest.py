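import numpy as np
import pytest

from zinlda.types import Cohort


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture
def tiny_cohort():
    """Two samples over three taxa, five reads total: small enough that the
    full posterior over (z, delta) can be enumerated."""
    return Cohort(
        counts=np.array([[2, 1, 0], [0, 1, 1]]),
        sample_ids=["s1", "s2"],
        taxon_ids=["tA", "tB", "tC"],
    )


@pytest.fixture(scope="session")
def small_fitted_cohort():
    """A modest simulated cohort with both models fitted; shared by the
    recovery, PPC and stability tests to keep the suite fast."""
    import zinlda

    rng = np.random.default_rng(42)
    params = zinlda.ZIGDParams(pi=0.4, a=0.05, b=10.0, V=60)
    profiles = zinlda.simulate_profiles(5, params, rng)
    cohort, truth = zinlda.simulate_cohort(profiles, 50, 500, 2000, 10.0, rng)
    cohort, fmap, truth = zinlda.drop_unobserved_taxa(cohort, truth)
    lda_fit, lda_draws = zinlda.fit_lda(
        cohort, zinlda.LDAHyper(K=5), n_iter=400, burn_in=200, rng=rng, return_draws=True
    )
    hyper = zinlda.ZinHyper(K=5, pi=0.4, a=0.05, b=10.0)
    draws = zinlda.run_chain(cohort, hyper, n_iter=600, burn_in=300, rng=rng, init=lda_fit)
    fit = zinlda.finalize(draws)
    return {
        "cohort": cohort,
        "truth": truth,
        "lda_fit": lda_fit,
        "lda_draws": lda_draws,
        "zin_fit": fit,
        "zin_draws": draws,
    }
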