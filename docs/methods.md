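# Methods

This note documents the statistical models behind `dompop`, the choices made
where conventions diverge, and what the synthetic-data tests do and do not
demonstrate about real data.

## Dominant data and allele-frequency estimation

A dominant marker locus is biallelic with a visible (dominant) allele of
frequency p and a null allele of frequency q = 1 − p. Band absence means the
null homozygote, so under Hardy–Weinberg equilibrium the band-absence
frequency is q². Throughout the package the null-allele frequency is
estimated as **q = √(1 − band frequency)**. (A widely circulated corrupted
rendering of this estimator divides by two; the square root is the only
form consistent with the HWE premise, and with a PIC that can reach values
near 0.28 on real panels.) This estimator is biased for small samples and
undefined nuance near fixation; loci with band frequency 1 give q = 0
exactly.

Shannon's H′ per locus is the **two-state entropy** −p̂ ln p̂ −(1−p̂) ln(1−p̂)
of the band frequency p̂. The one-term form −p ln p maxes at 1/e ≈ 0.368 and
cannot produce the values near 0.39 seen in real primer tables; the
two-state form is bounded by ln 2 ≈ 0.693.

Percent-polymorphic values are **truncated** (not rounded) to one decimal,
matching the convention of the classic reporting software (21/22 → 95.4,
15/16 → 93.7, 176/180 → 97.7); the LD-screen percentage rounds to one
decimal (745/32,400 → 2.3). A locus is polymorphic when its pooled band
frequency is strictly inside (0, 1); 95%/99% criteria are available as
options.

## Diversity

Per locus, h = 1 − p² − q², Ne = 1/(p² + q²) = 1/(1 − h), I = −p ln p −
q ln q, all from the square-root allele-frequency estimates. Expected
heterozygosity Hₑ is computed on **band states** (haploid coding) with the
n/(n−1) small-sample correction — the convention of software that treats
dominant rows as haplotypes. Note the exact ratio Hₑ/h = (n/(n−1))·q(1+q):
band-based Hₑ exceeds the allele-based h only where the null allele is
common (q ≳ 0.618), which is the typical dominant-marker regime and the
reason published tables can show Hₑ ≈ 0.31 alongside h ≈ 0.17. It is not a
universal inequality. Per-population means are arithmetic over all loci,
monomorphic loci contributing zeros; the "Species" row pools all
individuals, and by the Wahlund effect its gene diversity is at least the
mean within-population diversity.

## AMOVA and pairwise Fst

The molecular distance between two individuals is the squared Euclidean
distance between their 0/1 band vectors, i.e. the count of differing
(mutually scored) calls. Sums of squared deviations follow the standard
molecular-variance identities (total and within-group SSD from pairwise
distances divided by group size); variance components come from the
expected mean squares with the unequal-sample-size coefficient
n₀ = (N − Σn_k²/N)/(P−1), and Φst = σ²ₐ/(σ²ₐ+σ²_w). Components are not
clipped at zero, so Φst can be slightly negative on undifferentiated data
(its null expectation). The permutation test shuffles individuals across
populations keeping sizes, with the observed statistic included in
numerator and denominator (p ≥ 1/(n_perm+1)); default 1,000 permutations,
seed mandatory in the API. Pairwise Fst is the two-population Φst.

Because the distance operates on band **phenotypes**, Φst measures
band-state differentiation: for mid-frequency loci it runs roughly
4θq/(1+q) over the band heterozygosity, i.e. ~1.2–1.4× the allele-level θ
of the generative model. This is a property of dominant data, not an
implementation artefact; pairwise and overall Φst agree with each other,
and the package's tests assert that internal consistency rather than
equality with the allele-level θ.

Gst uses per-locus Ht = 2p̄q̄ from unweighted mean allele frequencies and
Hs = mean within-population 2pq, combined across loci as a ratio of sums.
Gene flow is the equilibrium island-model inversion Nm = (1−Fst)/(4Fst),
defined for Fst strictly inside (0,1).

The LD screen applies a two-sided Fisher's exact test to the pooled 2×2
band-state table of every pair of polymorphic loci. The default denominator
is the C(L,2) unordered pairs; an "ordered" convention reports the L²
denominator some studies quote. Pooling across populations mirrors the
single genome-wide percentage such studies report; note pooling structured
populations inflates associations (a form of the two-locus Wahlund effect),
so the type-I calibration test simulates unstructured data.

## Distances, UPGMA, PCoA, Mantel

Nei's unbiased (1978) distance uses locus-averaged gene identities with the
small-sample correction (2nΣp² − 1)/(2n − 1) within populations. UPGMA
merges the pair of clusters with the smallest arithmetic mean of cross-pair
distances, recomputed from the original matrix each step; node height is
half the merge distance (ultrametric), Newick branch lengths are height
differences. **Exact ties break by the lexicographically smallest pair of
cluster representative labels** (representative = alphabetically first
leaf). The published *L. regale* distance table contains a near-tie
(0.03345 vs 0.0335 at the step that attaches XV), which makes the
tie-break policy worth pinning down even though that step is decided by
magnitude, not the tie rule.

PCoA double-centres −d²/2 (Gower), eigendecomposes, and reports percentages
relative to the sum of **positive** eigenvalues; negative eigenvalues of
non-Euclidean matrices are reported but excluded from coordinates and
percentages. Geographic distances are great circles (haversine, Earth
radius 6371.0088 km) on coordinates parsed from degrees-minutes-seconds at
the input boundary. The Mantel statistic is the Pearson correlation of
lower-triangle entries under joint row/column permutation of the second
matrix; all n! permutations are enumerated when n! ≤ 5,040 (n ≤ 7, which
covers 8-population studies' leave-one-out checks but not n = 8 itself,
where 9,999 seeded random permutations are the default), two-sided on |r|,
observed included. Pearson r is invariant to the linear part of any
monotone rescaling of distance, but differs in general from
implementations that log-transform geographic distance; published r values
from such programs are therefore comparison points, not exact targets.

## Hierarchical Bayesian model (θB, θI, f, h_s)

Per locus, the ancestral dominant-allele frequency is π_l ~ Uniform(0,1);
per population, p_kl ~ Beta(π_l(1−θ)/θ, (1−π_l)(1−θ)/θ), so θ is the
dispersion of population allele frequencies (Var p_kl = θπ_l(1−π_l)) — the
Bayesian analogue of Gst, reported as **θB**. The observed band-absent
count per population/locus is Binomial(n_kl, q_kl² + f·q_kl(1−q_kl)) with
f ~ Uniform(0,1). Four variants: full; f = 0; θ = 0 (all populations share
one frequency per locus); and f-free, where f is redrawn from its prior
every sweep so the data never update it (a sensitivity device for the
weakly identified f).

Sampling is Metropolis-within-Gibbs with reflective Gaussian random walks.
Every q_kl is conditionally independent given (π, θ, f), so the whole
population×locus grid is proposed and accepted element-wise in parallel;
likewise each π_l. Proposal widths adapt multiplicatively during burn-in
only and are frozen afterwards, keeping the retained chain a valid Markov
chain. **θI** is recorded at each retained sweep as the ratio of sums over
loci of the among-population sample variance of p_kl to p̄_l(1−p̄_l) — a
ratio-of-means form chosen over the mean of per-locus ratios because
near-fixed loci make the per-locus ratio numerically unstable. h_s(k) is
the mean over loci of 2p_kl q_kl. DIC = D̄ + p_D with p_D = D̄ − D(posterior
means), deviance including the binomial normalising constant.

Because θI averages over posterior draws of the frequencies, posterior
uncertainty in each q_kl adds to the among-population variance; with few
individuals per population this biases θI upward by roughly Var(q̂)/p̄q̄.
At the study's dimensions (8 × ~21 × 180) the effect is small relative to
the posterior spread and the 95% interval covers the generating θ in the
large majority of replicates (asserted at ≥ 8/10 in the tests); with much
smaller samples the bias would dominate.

Production defaults are burn-in 50,000, 250,000 sweeps, thinning 50; the
tests and examples use 2,000/10,000/10, which this model mixes well at
because of the fully parallel conditional updates.

## Admixture model and ΔK

Bands are coded as haploid biallelic loci. Cluster band frequencies have
independent Beta(1,1) priors — a deliberate simplification of the
correlated-frequency prior, which is weakly identified on dominant data;
ancestry vectors Q_i have a symmetric Dirichlet(1) prior, and a latent
cluster-of-origin Z_il per scored call. The Gibbs sweep samples Z | Q,P
(categorical), P | Z,X (Beta), Q | Z (Dirichlet). The run-level data
log-probability is estimated as mean(ln L) − var(ln L)/2 over retained
sweeps, the standard deviance-based estimate used for ΔK work.
ΔK(K) = |mean(L(K+1) − 2L(K) + L(K−1))|/sd(L(K)) over replicate runs; it is
undefined (omitted, not extrapolated) at the end-point K values, so a K
range of at least three consecutive values with ≥ 2 replicates each is
required. Cluster labels are identified only up to permutation; accuracy
checks match labels by maximising ancestry mass before comparing, and the
assignment rule is inclusive: an individual belongs to a cluster iff some
ancestry component ≥ 0.8, else it is "admixed".

## Synthetic data

The generator is the generative mirror of the hierarchical model: π per
locus (default Uniform(0.05, 0.95), bounded away from fixation so loci are
informative), Beta-dispersed population frequencies, inbreeding through
the null-homozygote probability. `paper_like_dataset` fixes the study
design — 8 populations of (20, 23, 20, 23, 23, 21, 19, 23) individuals
(172 total), 180 loci in 10 primer groups with the published band counts,
θ = 0.19 and f = 0.14 taken from the study's own estimates so recovery
tests run at realistic signal strength.

What the simulator does **not** emulate: linkage between loci (columns are
conditionally independent, so the LD screen is exercised on constructed
duplicated columns), clonal ramets, genotyping noise/missing bands,
non-equilibrium demography (bottlenecks, admixture history), or locus-wise
selection. Passing recovery tests therefore demonstrates estimator
correctness under the stated model, not robustness to those violations.

## Numerical and interface choices

- Missing calls use sentinel −9 on disk and are excluded per-locus from
  frequencies and pairwise distances; defaults assume complete matrices.
- Frequencies in the MCMC are clipped to [1e−9, 1−1e−9] before logs.
- Distance matrices must be symmetric within 1e−12 with zero diagonal and
  are stored exactly symmetrised.
- Pipeline outputs carry a provenance header (version, stage seed,
  parameters); a single global seed derives per-stage seeds by CRC-stable
  hashing so disabling one stage never changes another's numbers. Rounding
  happens only at presentation; machine-readable outputs keep full
  precision.
- AMOVA with zero total SSD reports Φst as undefined via an explicit flag
  rather than NaN arithmetic downstream.

## Known limitations

- Observed heterozygosity and Fis are not estimable from dominant
  phenotypes by any stated procedure; the Bayesian f is this package's
  inbreeding estimate.
- Per-locus Hardy–Weinberg exact tests are undefined for phenotype-only
  data and are not provided.
- The admixture sampler's independent-frequency prior makes its ln Pr(X|K)
  values not directly comparable to correlated-frequency implementations;
  ΔK mechanics and assignments are unaffected on well-separated data.
- θI's small upward bias at low per-population sample sizes (above).
- The Mantel exhaustive mode stops at n = 7 (5,040 permutations); larger
  label sets use seeded random permutations.
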