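# Methods

## Problem and data model

The package analyzes a multiple protein alignment containing orthologs of
two duplicate genes (paralog clusters 1 and 2). The question is which
alignment sites carry evidence of post-duplication functional divergence —
either a rate shift (type I) or a radical physicochemical property shift
with within-cluster conservation (type II) — and whether such sites are
over-represented in a list of drug-binding residues.

All estimation is count-based. For each usable site the pipeline derives:

* x₁(k), x₂(k): minimum substitution counts within each cluster, from a
  Fitch parsimony pass over the cluster subtrees;
* a₁(k), a₂(k): the amino acids inferred at the two cluster roots;
* c(k) ∈ {N, C, R}: the class of the a₁→a₂ change — identical, conserved
  (same physicochemical group) or radical (different group).

A site is usable when no member of either cluster carries a gap or an
unknown residue there (complete deletion over cluster members; gaps confined
to outgroup rows do not exclude a column). Count-based likelihoods assume
fully observed columns, which is why complete deletion rather than pairwise
deletion is used. Reported site indices are 1-based positions on a
user-named reference sequence, mapped through its ungapped coordinates.

## Tree handling

Unless the user supplies a Newick tree, one is built by neighbor joining on
Poisson-corrected distances d = −ln(1−p), with p the proportion of differing
residues over columns usable for the pair. Observed p ≥ 0.95 is capped at
0.95 with a warning (a saturated protein pair should not kill a batch run);
negative NJ branch lengths are set to zero. The tree is rooted on the edge
separating the two clusters; if the clusters are not reciprocally
monophyletic the tree is midpoint rooted, a warning is emitted, and the
induced subtrees are used anyway with the non-monophyly flagged in the
output. Because the estimators consume only per-cluster substitution counts
and root states, any reasonable topology gives equivalent results; this is
also why a user-supplied tree simply bypasses the NJ step.

## Ancestral states

The Fitch bottom-up pass gives, per site and cluster, the minimum change
count and the set of root states. When a root set has more than one element
the site is tie-flagged. The tie-broken letter is chosen jointly across the
duplication node: the two cluster-root sets are intersected (union if
disjoint), the joint state is picked by combined leaf frequency (then
alphabetically), and each cluster root takes the joint state when compatible
with its own set, falling back to its within-cluster majority letter
otherwise. This is the down-pass of the standard Fitch refinement, with the
sister cluster acting as the outgroup.

The joint resolution matters quantitatively. Breaking ties independently
within each cluster makes root-state errors on fast-evolving null sites look
like early changes: in simulation at the default conditions it produced ~7%
spurious radical classes, biased θ̂_II down by ≈0.03 and pushed 95% CI
coverage to 0.70. With joint resolution the spurious-radical rate drops by
an order of magnitude, the bias to ≈−0.006, and coverage to ≈1.0. Tie-flagged
sites are included in the fits by default (the flag is carried through so a
strict mode can exclude them).

## Likelihoods

Site rates λ ~ gamma(shape α, rate α), mean 1; cluster depths m₁, m₂ absorb
time and absolute rate (only their products with λ are identifiable). Sites
are independent. Each model is a two-component mixture with weight θ on the
divergent state F₁:

**Type I.** F₀: one λ shared by both clusters, xᵢ ~ Poisson(λmᵢ); integrating
λ gives the bivariate negative binomial
f₀(x₁,x₂) = Γ(α+x₁+x₂)/(x₁!x₂!Γ(α)) · q₁^{x₁} q₂^{x₂} q₀^α with
qᵢ = mᵢ/(m₁+m₂+α), q₀ = α/(m₁+m₂+α). F₁: independent per-cluster rates, so
f₁ is the product of two negative binomial marginals with the same shape.
Free parameters: (θ, α, m₁, m₂).

**Type II.** The early phase (duplication branch, expected length d_e at
relative rate 1) changes the residue with probability 1 − e^{−λd_e}; a
change is radical with probability π_R, fixed at the scheme's neutral value
137/190 rather than estimated (at realistic site counts a free π_R trades
off against d_e and destabilizes θ̂; it remains a config override, including
empirical estimation from the observed C/R ratio). Late-phase counts are
Poisson(λmᵢ) under F₀ and Poisson(λ·ε·mᵢ) under F₁, with conservation factor
ε = 0.1 fixed by default (the divergent state is defined by within-cluster
conservation; ε encodes how strong). Under F₁ the early change is radical
with probability one, so f₁ = 0 at any N or C site. λ is integrated by an
8-category equal-probability discrete gamma using exact category means
(mean-preserving for every α). Free parameters: (θ, α, m₁, m₂, d_e); d_e is
initialized at −ln(fraction of N sites).

Both likelihoods are normalized over their outcome spaces (verified to 1e−6
by truncated summation in the tests).

## Optimization, uncertainty, testing

Identical (class,) count triples are aggregated with weights, so likelihood
evaluation cost is independent of alignment length. Optimization is a coarse
seed grid over (θ, α) with moment starts for m₁, m₂, followed by bounded
L-BFGS-B from the three best seeds; boxes are θ ∈ [0, 0.999],
α ∈ [0.05, 99], mᵢ ∈ [1e−4, 100], d_e ∈ [1e−3, 20].

The SE of θ̂ is the square root of the [θ,θ] element of the inverse observed
information, computed by central-difference Hessian at the MLE. By the block
inversion identity this equals the inverse curvature of the profile
likelihood in θ; differencing the full Hessian is used because profile
re-optimization at steps of 1e−4 sits below optimizer tolerance noise. At an
active bound the differencing center is shifted one step inside the box and
the SE is flagged one-sided.

The null θ = 0 is refit (nuisance parameters free) and the LRT statistic
2ΔlogL is referred to ½χ²(0) + ½χ²(1), the standard asymptotics for a
parameter on its boundary. A profile with zero radical sites short-circuits
to θ̂_II = 0 with an explicit "no identifiable signal" note.

## Site calls, pattern check, enrichment

Sites with Q(k) strictly above the cutoff (default 0.67, equivalently
posterior ratio R > 2) are called divergent. Each call can be screened for
the canonical type-II pattern: modal residue fraction ≥ τ (default 0.8) in
both clusters and a radical modal-residue change. Enrichment of called sites
within a binding-site list over a scan of `total_length` residues (default:
the reference's ungapped length) uses the Pearson chi-square without
continuity correction on the 2×2 table, with a Fisher exact p-value always
computed alongside and a flag raised whenever an expected cell is below 5 —
binding-site tables are typically small-count, and the flag makes the caveat
explicit without changing the headline test. Binding-site entries whose
stated residue letter disagrees with the reference sequence are a hard
error, catching off-by-one and wrong-isoform coordinate mistakes.

## Simulator

`simulate_family` draws each site's state (F₀ / F₁-type-I / F₁-type-II) with
probabilities (1−θ₁−θ₂, θ₁, θ₂) and generates exactly the generative process
the likelihoods assume: shared vs independent gamma rates; an early change
with probability 1 − e^{−λd_e}, radical with probability π_R, target residue
uniform within the allowed group set (forced radical for type-II sites);
late-phase evolution along balanced cluster subtrees whose branches split
λmᵢ (× ε for type-II sites) into equal Poisson shares, each substitution
uniform over the 19 alternatives. The root residue is uniform over the 20
letters. Defaults are L = 500 sites, 8 + 8 leaves, α = 1, m₁ = m₂ = 1
(about one substitution per site per cluster, a deep-vertebrate ortholog
depth), d_e = 0.5 (about two thirds of null sites keep identical cluster
ancestors) and ε = 0.1. One master seed drives everything; each site has a
deterministic substream, so extending L leaves earlier sites bit-identical.

What the simulator does *not* emulate: indels (no gaps are generated),
empirical exchangeabilities (replacement is uniform, not JTT/WAG-like),
among-lineage rate variation, and non-balanced topologies (configurable via
a supplied tree but not defaulted). Passing recovery tests therefore shows
the estimators are correct for their own model class, not that real
alignments satisfy that class.

## Recovery experiments and known limitations

`recovery_experiment` repeats simulate-and-refit over a config grid and
tabulates mean/SD/bias/MAE of θ̂, 95% CI coverage and LRT rejection at 5%.
Two sources are exposed:

* `pipeline` — the estimators see sequences only (mask → tree → parsimony →
  classify → fit), including all reconstruction noise;
* `counts` — the estimators see the simulator's realized count table
  (exactly Poisson) and true ancestral letters, isolating estimator
  correctness.

At the reference scales (problem sizes chosen to mirror a two-receptor
ortholog analysis: θ_II = 0.236 at L = 1000, θ_I = 0.49 at L = 2000, 8 + 8
leaves, α = 1, 10–20 replicates), type-II recovery is accurate end to end
from sequences (MAE ≈ 0.015, coverage ≥ 0.85), and both estimators are
accurate at the count-table level. The null calibration at θ = 0 is
conservative for both models (empirical rejection ≲ 2% at nominal 5%),
as expected from the boundary-mixture reference distribution.

The known limitation: **sequence-level type-I recovery is attenuated.**
Fitch parsimony undercounts multiple hits, and the undercount grows with the
site rate, compressing exactly the count over-dispersion that separates
independent from shared rates; at 8 + 8 leaves and m = 1 this attenuates
θ̂_I from 0.49 to ≈0.34. More taxa per cluster reduce the attenuation (the
parsimony count approaches the true count); the count-table source removes
it entirely. θ̂_II is robust because its signal (a forced radical early
change plus near-zero late counts) survives parsimony reconstruction
essentially intact. The same attenuation affects count-based rate-shift
analyses generally and is documented here so that sequence-level θ_I values
are read as lower bounds.

## Numerical conventions

* Likelihood floors at 1e−300 before logs; mixture weights clipped away from
  the θ = 1 boundary by 1e−12.
* NJ tie behavior and all other stochastic-free steps are deterministic;
  every random step takes an explicit integer seed and uses numpy
  `SeedSequence` substreams (all derived seeds < 2³¹).
* Saturated distance pairs capped at p = 0.95 (warned); degenerate 2×2
  margins return χ² = 0, p = 1.
* Ancestral tie flags propagate into the early-change profile; the type-II
  fit records fixed π_R and ε in its output metadata.
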