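"""Admixture clustering and choice of K by the Evanno second-order statistic.

Simulates two well-separated population clusters, runs the Gibbs sampler for
K = 1..4 with replicate chains, computes DeltaK from the replicate
ln-probabilities, and assigns individuals to clusters with the >= 0.8
ancestry rule.
"""

from dompop import assign_individuals, evanno_delta_k, fit_admixture, simulate

matrix, _ = simulate(2, 40, 80, theta=0.45, f=0.0, seed=11)
print("simulated 2 clusters x 40 individuals x 80 loci (theta = 0.45)\n")

ln_probs: dict[int, list[float]] = {}
seed = 0
for k in (1, 2, 3, 4):
    ln_probs[k] = []
    for _ in range(3):
        run = fit_admixture(matrix, k, burn_in=200, reps=600, seed=seed, thin=3)
        ln_probs[k].append(run.ln_prob)
        seed += 1

table, best_k = evanno_delta_k(ln_probs)
print(table.round(2).to_string(index=False))
print(f"\noptimal K by DeltaK: {best_k}")

best = fit_admixture(matrix, best_k, burn_in=300, reps=900, seed=99, thin=3)
assignments, summary = assign_individuals(best.q, threshold=0.8)
print(f"percent admixed (no ancestry >= 0.8): {summary['percent_admixed']:.1f}%")
print("per-cluster percent assigned:",
      {c: round(v, 1) for c, v in summary['percent_per_cluster'].items()})
print("\nDeltaK peaks at the simulated cluster count; most individuals are "
      "confidently assigned because the clusters are strongly diverged.")
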