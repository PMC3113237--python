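# Methods

## Model

Observed data are a catalog of synthetic-lethal genetic interactions
(SLGIs) between proteins and a protein→domain assignment table. The
latent variables are per-domain-pair Bernoulli indicators D_ij with
success probability θ_ij, assumed independent across pairs. Two proteins
interact iff at least one domain pair between them interacts, giving the
noisy-OR observation model

    Pr(P_mn = 1) = 1 − ∏_{(i,j) ∈ pairs(m,n)} (1 − θ_ij),

where pairs(m, n) is the set of *distinct* unordered domain pairs between
the two proteins' domain sets. A pair realizable in both orientations
(e.g. both proteins carry both domains) contributes a single factor:
D_ij is a property of the domain pair, not of a placement. Domain content
is a set — repeated domains in one protein count once — and all pair
relations (protein and domain) are unordered, stored canonically as
(min, max); domain self-pairs (d, d) are legal, protein self-pairs are
not.

Only *candidate* pairs — those contained in at least one SLGI — receive a
fitted θ; all others are fixed at 0. A pair never seen in a positive has
no evidence to lift it above the prior, and fixing it at zero keeps the
candidate set finite and interpretable.

## Estimation

For each candidate we precompute M0 (number of SLGIs containing the
pair) and K (number of *non*-SLGI protein pairs containing it, over a
configurable protein universe that defaults to all assigned proteins;
K is fixed for the whole run). The objective is the penalized
log-likelihood

    L = Σ_SLGI ln Pr(P_mn = 1) + Σ_pairs K_ij ln(1 − θ_ij)
        + Σ_pairs [a ln θ_ij + b ln(1 − θ_ij)],

with pseudocounts a = b = 1 by default (a Beta-style penalty keeping θ
off the boundary when a pair is rare). EM:

- init: θ⁰_ij = (M0 + a)/(M0 + K + a + b) (M set to the SLGI count, N to 0);
- E-step: for each SLGI (m, n) containing (i, j), the posterior
  probability that D_ij fired given the observed positive is θ_ij / P_mn,
  so E[M_ij] = Σ θ_ij/P_mn and E[N_ij] = Σ (1 − θ_ij/P_mn) = M0 − E[M_ij];
- M-step: θ_ij = (E[M_ij] + a)/(E[M_ij] + E[N_ij] + K_ij + a + b).

The M-step exactly maximizes the expected complete-data penalized
objective (negatives contribute posterior 0 to D_ij, hence the K term),
so L is non-decreasing along the iteration — the test suite checks this
across 100 random worlds with 1e-9 slack. Convergence is declared when
|ΔL| < tol (default 1e-6 absolute) or after max_iter (default 500)
iterations, in which case the result is returned flagged unconverged with
a logged warning. θ is clamped to [1e-12, 1 − 1e-12] before any log; with
a = b ≥ 1 the clamp is never active in exact arithmetic.

When every protein carries a single domain, P_mn = θ_ij for the unique
contained pair, E[M] = M0 identically, and EM terminates at the closed
form (M0 + a)/(M0 + K + a + b) in one iteration — a useful exactness
check.

## Evidence score and selection

The evidence score of pair (i, j) is a positives-only plug-in log-ratio:

    E_ij = Σ_{SLGI (m,n) ⊇ (i,j)} ln [ P_mn(θ) / max(P_mn(θ | θ_ij := 0), floor) ]

with all other θ held at their converged values (no refit — the score is
deliberately not a standard likelihood-ratio test). A pair that is the
sole candidate explaining an SLGI would otherwise score +∞; flooring the
exclusion probability (default 1e-8) makes such pairs large but finite.
Natural logs are used so E = 2 means an e² ≈ 7.4-fold drop in the modeled
probability of the pair's SLGIs when it is excluded. Significant pairs
are those with E ≥ 2.0 (inclusive) **or** θ > 0.5 (strict); no
multiple-testing correction is applied.

## Prediction

Every unordered protein pair in the chosen universe (default: all
assigned proteins) gets the noisy-OR probability under the fitted θ;
pairs with probability strictly above the threshold are emitted, flagged
novel when absent from the training catalog. Scoring is a generator so a
universe of P proteins — P(P−1)/2 evaluations — streams to disk rather
than being materialized; `predict_all` is a convenience wrapper that
sorts the materialized records for small universes.

## Network statistics

The significant pairs form an undirected graph on domains (self-loops
allowed; a self-loop adds 2 to its node's degree, and average
connectivity is 2·E/N). Average shortest path is taken over all connected
ordered node pairs within components — the standard convention for
disconnected graphs — with self-loops removed; mean local clustering
counts degree-<2 nodes as 0. The degree-distribution exponent is, by
default, the negated OLS slope of log10 P(k) on log10 k over the unbinned
points with k ≥ 1 and P(k) > 0, mirroring a straight-line fit on a
log-log plot; a discrete (zeta-normalized) maximum-likelihood estimate is
available via `method="mle"`. Graph storage and traversal use networkx;
the exponent fit is this package's own.

## Overlap analysis

Physical domain pairs are first restricted to the studied domain
universe. Independence of genetic and physical membership is tested at
two levels with Fisher's exact test (scipy; two-sided point-probability
rule, matching R's default): domains, over the universe of all assigned
domains, and pairs, over all unordered pairs — self-pairs included,
n(n+1)/2 — of the domains appearing in either list. The true universes
behind any particular published comparison are not recoverable, so both
are configuration knobs; tests validate the p-values against an
exhaustive fixed-margin table enumeration written independently of scipy.

## Synthetic worlds

The generator runs the observation model forward: `n_proteins` proteins
draw domain sets of size uniform on 1..3 from `n_domains` domains;
`n_planted_pairs` domain pairs are drawn uniformly from the pairs
actually realizable by some protein pair and given θ* uniform in
`theta_range`; every protein pair then enters the catalog with
probability 1 − (1 − background)·∏(1 − θ*). The background term is a
per-protein-pair false-positive rate — equivalent to one always-present
pseudo domain pair — so the generative law stays exactly noisy-OR plus
label noise. The default world (60 domains, 250 proteins, 12 planted
pairs with θ* ∈ [0.7, 0.95], background 0.01) yields roughly a thousand
SLGIs and ~1300 candidate pairs: planted pairs are strongly identified
while background noise exercises the estimator's ability to keep spurious
candidates low. Recovery is scored by (a) the probability that a random
(planted, non-planted) candidate pair is ordered correctly by fitted θ
(ties ½ — a pairwise AUC) and (b) the mean absolute θ error on planted
candidates.

What the generator does *not* emulate: the heavy-tailed domain-frequency
distribution of real proteomes, domain co-occurrence structure within
proteins, and ascertainment bias of real screens (which oversample
certain processes). Passing recovery benchmarks therefore demonstrates
correctness of the estimator under its own model assumptions, not
performance on real screens.

## Numerical choices and limitations

- All probability products run through log1p/expm1 to keep precision for
  θ near 0 or 1.
- Candidate iteration and catalog iteration are over sorted keys, so
  results are independent of input order (tested to 1e-12).
- Ties in output orderings break lexicographically by identifier.
- Degenerate inputs fail loudly: empty catalog, universe smaller than the
  catalog's proteins, boundary θ with positive pseudocounts, fewer than
  two usable degree points for the exponent fit.
- Independence of domain pairs is a modeling assumption; cooperative
  multi-domain effects are out of scope, as are live database retrieval
  and enrichment analyses downstream of prediction.
- The acceptance script simulates its physical-interaction list (half the
  planted pairs plus random domain pairs) purely to exercise the overlap
  analysis; it is labelled synthetic and carries no biological meaning.

## Problem sizes

The test suite and acceptance script run the benchmark world (above),
100 small random worlds (8–20 domains, 20–60 proteins) for the
monotonicity property, 1000 random noisy-OR oracle draws at up to 12
pairs, a 30 000-degree configuration-model sample for the exponent
recovery, and 40 random Fisher tables at n ≤ 40 — sizes chosen so every
statistical check is comfortably stable under its stated tolerance.
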