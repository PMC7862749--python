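# Methods

## Model

`zinlda` fits a topic model to a sample-by-taxon count matrix
(D samples × V taxa).  Each of K latent *subcommunities* is a probability
distribution over taxa, β⁽ʲ⁾; each sample mixes subcommunities with
proportions θ⁽ᵈ⁾ ~ Dir(α); each sequencing read first draws a subcommunity
z ~ Multinomial(1, θ⁽ᵈ⁾) and then a taxon from β⁽ᶻ⁾.  With a Dirichlet
prior on β this is standard latent Dirichlet allocation (LDA), and every
taxon receives strictly positive probability in every subcommunity — the
over-smoothing that makes LDA a poor description of sparse microbiome
counts.

The zero-inflated model replaces Dir(η) on β with a zero-inflated
generalized Dirichlet, ZIGD(π, a, b), built by stick-breaking over V−1
independent zero-inflated beta variables: Qᵢ is exactly 0 with probability
π, otherwise Beta(a, b); then

    β₁ = Q₁,  βᵢ = Qᵢ ∏_{l<i}(1−Q_l),  β_V = ∏_{l<V}(1−Q_l).

A zeroed stick makes βᵢ exactly zero — a *structural zero*, a taxon truly
absent from the subcommunity, flagged by the indicator Δᵢ = I(βᵢ = 0) — as
opposed to a *sampling zero*, a taxon present at low probability but
unobserved at finite sequencing depth.  The last component is never
zero-inflated: it absorbs the residual stick, so every subcommunity has
nonempty support.  The family is **not exchangeable in taxon order**; the
column order of the input matrix is the stick order, fixed per run and
recorded in fit provenance.

Hyperparameters are symmetric scalars shared by the cohort: α (default
50/K), π, a, b.  `b` may also be given per stick position; with a = η and
bᵢ = η(V−i) the π = 0 case reduces exactly to the symmetric Dirichlet(η),
which is how the reduction tests pin the sampler against plain LDA.

## Inference

Both the Dirichlet and the ZIGD are conjugate to the multinomial, so β and
θ are integrated out and a collapsed Gibbs sampler runs over the discrete
latents only: per-read assignments z and the indicator matrix Δ.  With
n_j⁽ⁱ⁾ the count of taxon-i reads in subcommunity j (pooled over samples),
m_j⁽ᵈ⁾ the count of sample-d reads in subcommunity j, and
b_ij = bᵢ + Σ_{l>i} n_j⁽ˡ⁾ the trailing-count update, a read of taxon i in
sample d is reassigned with probability

    P(z = j | rest) ∝ E[β_ij | counts, Δ] · (m_{j,−n}⁽ᵈ⁾ + α),

where E[β_ij] is the stick-breaking posterior mean over subcommunity j's
support (zero off support), and the indicators are resampled as

    P(Δ_ij = 1 | rest) = 0                                     if n_j⁽ⁱ⁾ > 0,
                       = π / (π + (1−π)·B(a, b_ij)/B(a, bᵢ))   if n_j⁽ⁱ⁾ = 0,

evaluated in log space.  One iteration is a full systematic z scan
(decrement → sample → increment per read) followed by a full (j, ascending
i) Δ scan; this order guarantees the Δ conditional always sees counts it is
consistent with, and Δ_ij = 1 ⟹ n_j⁽ⁱ⁾ = 0 is asserted every sweep.  The
trailing sum in b_ij runs over *all* later taxa; because structural zeros
carry no reads this equals the sum over support members, and it is the only
version of the update consistent with Beta–multinomial conjugacy — the
sampler is validated against a brute-force enumeration of P(z, Δ | w) on
tiny instances (total-variation < 0.02 at 10⁵ sweeps).

The chain is initialized from a standard collapsed-Gibbs LDA fit: each read
of taxon i draws its starting subcommunity with probability ∝ the LDA
estimate β̂_ij, and Δ starts at zero everywhere.  Without an LDA fit the
initialization is uniform-random.  A taxon transiently excluded from every
subcommunity would zero the whole conditional; the sampler then falls back
to the full-support form for that read and logs a warning (the event is
posterior-null but a finite chain must not halt).

Per retained iteration (after burn-in, with optional thinning) the sampler
records point estimates: β by the stick posterior mean above, θ_dj =
(m_j⁽ᵈ⁾ + α)/(m⁽ᵈ⁾ + Kα), and the Δ state.  Finalization averages draws:
π̂_ij is the posterior mean of Δ_ij; entries with π̂_ij ≥ 0.5 (the tie is
inclusive) are declared structural zeros and their β̂ set to exactly 0;
remaining entries take their posterior mean and rows are renormalized.
Estimates are means of per-draw estimates, not pooled counts.

Two engines share this definition: a numba-compiled kernel (default) with
lazily-extended per-subcommunity prefix caches, and a pure-Python reference
used on small instances.  Both are checked against the enumeration oracle.
Chains are deterministic given (data, seed, settings).

## Defaults and parameters

| parameter | default | meaning |
|---|---|---|
| K | — | number of subcommunities (chosen by the user) |
| α | 50/K | symmetric Dirichlet on θ |
| η | 0.1 | symmetric Dirichlet on β (LDA baseline) |
| π | 0.4 | zero-inflation probability per stick position |
| a, b | 0.05, 10 | beta shape parameters of the sticks |
| n_iter / burn_in / thin | 2000 / 1000 / 1 | chain schedule |

The (π, a, b) defaults are the canonical simulation values; a controls how
small nonzero probabilities can be (small a ⇒ many near-zero taxa, hard to
tell from structural zeros), b controls stick decay.

## Simulation studies

The generator draws K ZIGD profiles, per-sample mixtures θ ~ Dir(α), depths
DiscreteUniform[5000, 25000] (inclusive), and reads by nested multinomials
(exactly equidistributed with the per-read process, orders of magnitude
faster).  The canonical design is V = 120 taxa, D = 150 samples, K = 5,
α = 10, (π, a, b) = (0.4, 0.05, 10); taxa never observed are dropped, as
they would be invisible in a real study, which typically leaves ~85–100
observed taxa (realizations vary; ground-truth β is *not* renormalized
after dropping — comparisons use the retained columns on the original
scale).  Recovery is scored after greedy Pearson label matching
(highest-correlation pair first, deterministic tie-breaks) by an entry-wise
confusion matrix over the K×V indicator cells, positive = structural zero.

Routine evaluation (the test suite and `scripts/acceptance.py`) runs this
design at a reduced problem size, `zinlda.pipeline.DESK_SCALE`: depths
DiscreteUniform(1000, 5000) and 1200-iteration chains (600 burn-in)
initialized from a 250-iteration LDA fit; the easy (V = 50, a = 0.5) design
uses 1800/900, since windowed-trajectory checks show its indicator
estimates keep improving to roughly iteration 1500 at this scale.  What the
reduced depth preserves: sampler exactness (checked by enumeration, not
simulation), sensitivity and NPV of structural-zero recovery in the easy
design, top-taxon recovery, and the posterior-predictive contrast with LDA
at zero counts.  What it does not preserve: at one fifth of the canonical
depth more taxa with genuinely small β go unseen in a subcommunity and are
rightly called structural zeros, so specificity and PPV sit below their
full-depth values; and in the a = 0.05 designs the empty-cell indicator
probability π/(π + (1−π)·B(a, b+S)/B(a, b)) sits almost exactly at the 0.5
dichotomization threshold (≈0.51 at desk-scale trailing counts vs ≈0.53 at
full depth), so structural-zero sensitivity there is dominated by depth,
not by the sampler, and collapses relative to full-depth runs.  Full-depth,
fully-converged fits recover both, but cost tens of minutes each.

The generator emulates multinomial sampling from fixed subcommunity
profiles.  It does not emulate sequencing error, compositional library-size
artifacts, overdispersion beyond the mixture, or phylogenetic correlation
between taxa — so passing recovery tests says the *method* works when the
model is true, not that real data satisfy the model.

## Evaluation machinery

* **Posterior predictive checks**: each replicate picks one retained draw
  uniformly and simulates counts at the observed depths from its (β, θ)
  (defaults: 100 simulated datasets, 50 drawn in plots).  The statistic is
  the per-taxon count, reported per sample with taxa ordered by observed
  abundance, on the asinh scale (asinh(0) = 0, ~log for large counts).
* **Stability**: mean cosine similarity of matched β̂ rows between fits of
  independent sample sets.
* **Plug-in log-likelihood**: Σ_d Σ_i counts·log(Σ_j θ̂_dj β̂_ji), for manual
  tabulation across K; multinomial coefficients are omitted (constant in
  the fit).  An observed count on a taxon zeroed everywhere gives −∞ with a
  diagnostic.  No automated K selection is provided.

## Numerical and design choices

* Structural zeros are exact 0.0 plus the Δ mask, never small floats; the
  stick-breaking map guards against underflow manufacturing spurious zeros.
* Stick prefix quantities are cached per subcommunity and rebuilt lazily up
  to the position a read needs; Beta-function ratios use log-gamma.
* Pearson correlations for label matching are computed on raw β rows
  (least-assumption default, recorded in output metadata); a zero-variance
  row has undefined correlation and is matched last.
* Confusion ratios with empty denominators are reported missing (NaN),
  never 0.
* Degenerate inputs fail loudly: empty cohorts, all-zero profiles, K
  exceeding total reads, a fully-zeroed subcommunity at finalization.
* Counts are stored samples-as-rows; any run directory contains a JSON
  manifest (resolved parameters, seed, input checksum, package version)
  sufficient to reproduce the run.

## Known limitations

* Hyperparameters are fixed, symmetric, and user-supplied; no empirical or
  hierarchical estimation.
* Single chain; no cross-chain convergence diagnostics (R-hat, ESS) beyond
  trace logging, and no variational alternative.
* Greedy correlation matching can differ from the optimal assignment in
  adversarial near-tie cases; fits with well-separated subcommunities are
  unaffected.
* Mixing can be slow on large cohorts: indicator estimates need on the
  order of a thousand sweeps to stabilize, and runtime per sweep scales
  with total reads × taxa.
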