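# paradiverge

Maximum-likelihood analysis of **functional divergence between paralogous
gene clusters**, aimed at finding residues that discriminate one paralog from
another — the "selectivity filters" that let a drug bind its intended
receptor but not the receptor's close duplicate.

Gene duplication produces paralogs (e.g., the glucagon receptor GCGR and the
glucagon-like peptide-1 receptor GLP-1R) whose sequences, structures and
binding pockets remain so similar that drugs often cross-react. Two
evolutionary signatures single out the residues that nevertheless differ:

* **Type-I divergence** — a post-duplication shift in a site's evolutionary
  rate: the residue is conserved across the orthologs of one duplicate but
  variable across the orthologs of the other.
* **Type-II divergence** — a radical shift in a site's physicochemical
  property on the branch between the duplicates, followed by strong
  conservation within each ortholog cluster (e.g., hydrophobic in one
  cluster, hydrophilic in the other).

## Model

The observable per alignment site *k* is the pair of minimum substitution
counts (x₁, x₂) within the two clusters (Fitch parsimony on the cluster
subtrees) and, for type II, the class *c* ∈ {N, C, R} of the change between
the two cluster-root residues: **N** identical, **C** conserved (same
physicochemical group) or **R** radical (different group). The four groups
are positively charged {K,R,H}, negatively charged {D,E}, hydrophilic
{S,T,N,Q,C,G,P} and hydrophobic {A,I,L,M,F,W,V,Y}; 137 of the 190 unordered
residue pairs are radical (π_R = 137/190).

Site rates λ are gamma distributed with shape α and mean 1. Each site belongs
to the divergent state F₁ with probability θ and to the null state F₀ with
probability 1 − θ, and the log-likelihood ∑ₖ log[(1−θ) f₀ₖ + θ f₁ₖ] is
maximized over (θ, α, m₁, m₂[, d_e]):

* **Type I** — F₀: one shared λ, xᵢ ~ Poisson(λmᵢ), so (x₁,x₂) is bivariate
  negative binomial; F₁: independent per-cluster rates, a product of
  negative binomial marginals. θ_I measures the fraction of rate-shifted
  sites.
* **Type II** — F₀: an early (post-duplication) change fires with
  probability 1 − e^{−λd_e} and is radical with probability π_R; late-phase
  counts are Poisson(λmᵢ), with λ integrated over an 8-category discrete
  gamma. F₁: the early change is radical with probability one and the late
  phase is conserved, Poisson(λ·ε·mᵢ) with ε = 0.1 by default. θ_II measures
  the fraction of property-shifted sites.

Per-site posteriors Q(k) = θf₁ₖ / [(1−θ)f₀ₖ + θf₁ₖ] and posterior ratios
R(k) = Q(k)/(1−Q(k)) rank sites; the conventional call threshold
Q(k) > 0.67 equals R(k) > 2. Standard errors come from the observed
information; the test of θ = 0 is a likelihood ratio referred to the
boundary null ½χ²(0) + ½χ²(1). Called sites can be screened for the
canonical type-II pattern (modal fraction ≥ 0.8 in both clusters plus a
radical modal change) and tested for enrichment within a drug-binding-site
list by a 2×2 chi-square (or Fisher exact) test.

A matching simulator generates duplicated families from exactly this
generative mixture with full per-site truth, so every estimator is testable
without downloads.

## Worked example

The numbered scripts under `analysis/` form a complete narrative:

```bash
python analysis/01_simulate_family.py   # 477-site family, theta_II = 0.236
python analysis/02_fit_divergence.py    # full pipeline fit
python analysis/03_sites_and_enrichment.py
python analysis/04_recovery_experiment.py
```

Step 02 prints, for the seeded example family:

```
theta_I  = 0.0000 +/- 0.1319 (LRT p = 1)
theta_II = 0.2081 +/- 0.0241 (LRT p = 1.55e-25)
100 sites called at Q_II > 0.67 (true type-II fraction was 0.236)
```

The family was simulated with no type-I divergence and θ_II = 0.236, and the
fit recovers exactly that: θ_I is estimated at its boundary of zero while
θ_II is close to the generative value and overwhelmingly significant. Step
03 then checks the calls against the simulator's truth and runs the
enrichment test, both for a synthetic pocket and at the published
GCGR/MK-0893 table margins (8 divergent residues among 477, 12 binding
sites, 2 shared):

```
100 called, 111 true type-II sites, precision 0.90
100/100 calls show the conservation+radical pattern
simulated pocket: table (6, 94, 6, 371), chi2 = 6.26, p = 0.0123 (fisher p = 0.0227)
published margins: table (2, 6, 10, 459), chi2 = 16.77, p = 4.21e-05
```

The same operations are available from the shell via the `paradiverge` CLI
(`simulate`, `type1`, `type2`, `call-sites`, `enrich`, `recovery`, and `run`
with a YAML config); see `paradiverge --help`.

## Layout

- `src/paradiverge/` — the library: `seqdata` (alignments, clusters, masks,
  bootstrap), `phylo` (Poisson distances, NJ, cluster subtrees), `ancestral`
  (Fitch counts and root states), `type1_model` / `type2_model` (the ML
  estimators), `sitescan` (site calls, conservation, enrichment),
  `simulate` (the generator), `pipeline` + `cli` (orchestration).
- `analysis/` — the numbered narrative drivers; outputs under `results/`.
- `docs/methods.md` — model details, parameter defaults, numerical choices
  and known limitations.
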