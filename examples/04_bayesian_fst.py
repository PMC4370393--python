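"""Hierarchical Bayesian differentiation and inbreeding with DIC comparison.

Fits the Beta-binomial hierarchical model to a simulated study-shaped
dataset under three variants (full; f fixed to 0; no differentiation) and
ranks them by DIC. theta_I is the variance-based Fst analogue, theta_B the
Beta dispersion parameter, f the inbreeding coefficient entering the
band-absence probability q^2 + f q(1-q). Chains here are scaled down from
the production defaults (50,000 / 250,000 / 50) to run in seconds.
"""

from dompop import compare_models, fit_hickory, paper_like_dataset

matrix, truth = paper_like_dataset(seed=42)
print(f"simulated truth: theta = {truth.theta}, f = {truth.f}\n")

fits = []
for i, variant in enumerate(("full", "f=0", "theta=0")):
    fit = fit_hickory(matrix, variant, burn_in=2000, samples=10000, thin=10,
                      seed=10 + i)
    fits.append(fit)
    s = fit.summaries
    print(f"[{variant}] theta_I = {s['theta_i']['mean']:.4f} "
          f"[{s['theta_i']['q2.5']:.4f}, {s['theta_i']['q97.5']:.4f}]  "
          f"f = {s['f']['mean']:.4f}  DIC = {fit.dic:.1f}")

print("\nDIC ranking (smaller is better):")
for row in compare_models(fits):
    print(f"  {row['variant']:8s} DIC {row['dic']:.1f}  (+{row['delta_dic']:.1f})")
print("\nThe no-differentiation variant should rank last on structured data; "
      "the credible interval for theta_I should cover the simulated theta.")
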