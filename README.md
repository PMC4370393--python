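# dompop

Population-genetic analysis of **dominant presence/absence marker data**
(ISSR, AFLP, RAPD). Dominant markers score each individual at each locus as
band present (1) or absent (0); a heterozygote is indistinguishable from a
dominant homozygote, so only the band frequency is observable and allele
frequencies must be inferred under Hardy–Weinberg assumptions
(q = √(1 − band frequency) for the null allele). `dompop` implements the
full analysis chain that conservation-genetics surveys of this kind run —
the package ships the complete workflow used to characterise eight wild
populations of the endemic lily *Lilium regale* from 180 ISSR bands,
together with a generative simulator so every estimator can be validated by
parameter recovery.

**Who it is for:** researchers analysing band matrices from dominant marker
systems, and method developers who need a testable, scriptable reference
implementation of the classic POPGENE/Arlequin/Hickory/STRUCTURE toolchain
in one Python package.

## What it computes

| stage | statistics |
|---|---|
| marker informativeness | PIC = 1 − p² − q² (= 2pq), marker index MI = mean PIC × polymorphic loci, two-state Shannon H′ |
| within-population diversity | observed/effective alleles Na, Ne = 1/(p²+q²), Nei's gene diversity h = 2pq, Shannon I, band-state Hₑ with n/(n−1) correction |
| differentiation | Gst = (Ht−Hs)/Ht, AMOVA variance components and Φst with permutation test, pairwise Fst, gene flow Nm = (1−Fst)/(4Fst), Fisher-exact LD screen |
| distance structure | Nei's (1978) unbiased distance Dₛ, UPGMA dendrogram (Newick), PCoA, Mantel isolation-by-distance, great-circle site distances |
| Bayesian inference | hierarchical Beta-binomial model for θB (dispersion), θI (variance-ratio Fst analogue), inbreeding f and panmictic heterozygosity h_s with DIC model comparison; admixture Gibbs sampler with Evanno ΔK and the ≥ 0.8 assignment rule |
| simulation | p_kl ~ Beta(π(1−θ)/θ, (1−π)(1−θ)/θ) per population/locus; band absent with probability q² + f·q(1−q) |

## Worked example

```python
from dompop import amova, gene_flow, fit_hickory, paper_like_dataset

matrix, truth = paper_like_dataset(seed=42)   # 172 x 180, theta=0.19, f=0.14
res = amova(matrix, n_perm=199, seed=7)
print(f"{res.percent_within:.2f}% within, {res.percent_among:.2f}% among, "
      f"Phi-st={res.phi_st:.4f}, p={res.p_value:.4f}")
fit = fit_hickory(matrix, "full", burn_in=2000, samples=10000, thin=10, seed=10)
s = fit.summaries["theta_i"]
print(f"theta_I = {s['mean']:.4f} [{s['q2.5']:.4f}, {s['q97.5']:.4f}]")
print(f"Nm = {gene_flow(res.phi_st).nm:.4f}")
```

prints

```
77.10% within, 22.90% among, Phi-st=0.2290, p=0.0050
theta_I = 0.1897 [0.1727, 0.2067]
Nm = 0.8417
```

Most molecular variance lies within populations; the AMOVA Φst (band-state
differentiation, p from 199 label permutations) sits a little above the
allele-level θ because dominance amplifies band-frequency differences; the
Bayesian 95% credible interval for θI covers the simulated truth of 0.19;
Nm converts Φst into an equilibrium island-model migrant count.

The `examples/` directory holds one short narrative script per capability
(simulation + marker stats, diversity + AMOVA, distance/UPGMA/PCoA/Mantel
on the packaged published distance table, Bayesian fits, admixture + ΔK).
Each prints the numbers it computes and one line on what they mean:

```sh
python examples/03_distance_tree_ordination.py
```

A thin CLI wraps the same functions for shell pipelines
(`dompop simulate | informativeness | diversity | amova | pairwise-fst |
geneflow | ld | nei-distance | upgma | pcoa | mantel | hickory | structure |
run`); `dompop run config.yaml` executes the whole workflow with one global
seed and per-stage provenance headers.

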