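"""Model-based clustering of haploid-coded band data with admixture.

Each band is treated as one haploid biallelic locus (present/absent). The
model assigns every individual an ancestry vector Q_i over K clusters
(Dirichlet(1,...,1) prior), gives every cluster c a band frequency P_cl per
locus (Beta(1,1) prior — independent cluster frequencies, a deliberate
simplification of the correlated-frequency prior, which is weakly
identified on dominant data), and introduces a latent cluster-of-origin
Z_il for every scored individual-locus call. A collapsed-free Gibbs sampler
alternates Z | Q,P (categorical), P | Z,X (Beta) and Q | Z (Dirichlet).

The marginal data probability for a run is estimated the way STRUCTURE
reports it: with D_t = -2 ln L_t the deviance trace over retained sweeps,
ln Pr(X | K) ~= mean(ln L) - var(ln L)/2. Replicate runs per K feed the
Evanno second-order statistic DeltaK(K) = |mean(L(K+1) - 2L(K) + L(K-1))| /
sd(L(K)), whose interior maximum estimates the number of clusters.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import permutations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core import MISSING, BinaryMarkerMatrix

__all__ = [
    "AdmixtureResult",
    "fit_admixture",
    "evanno_delta_k",
    "assign_individuals",
    "match_cluster_labels",
]


@dataclass
class AdmixtureResult:
    """One admixture run: posterior-mean ancestry and data log-probability."""

    k: int
    individual_ids: list[str]
    q: np.ndarray                 # (n_individuals, K), rows sum to 1
    ln_prob: float                # estimated ln Pr(X | K)
    mean_ln_lik: float
    var_ln_lik: float
    settings: dict

    def __post_init__(self) -> None:
        if not np.allclose(self.q.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("ancestry rows must sum to 1")


def fit_admixture(
    m: BinaryMarkerMatrix,
    k: int,
    burn_in: int = 10_000,
    reps: int = 100_000,
    seed: int | None = None,
    thin: int = 10,
) -> AdmixtureResult:
    """Run the Gibbs sampler for one K and one seed.

    Defaults mirror common practice (burn-in 10,000 and 100,000 sweeps);
    tests use much shorter chains. ``K = 1`` returns all-ones ancestry with
    the exact single-cluster likelihood handled by the same machinery.
    """
    if seed is None:
        raise ValueError("seed is mandatory")
    if k < 1:
        raise ValueError("K must be >= 1")
    if k > m.n_individuals:
        raise ValueError("K exceeds the number of individuals")
    rng = np.random.default_rng(seed)
    x = m.calls
    scored = x != MISSING
    n, L = x.shape
    x1 = (x == 1) & scored

    p = rng.uniform(size=(k, L))                    # cluster band frequencies
    q = np.full((n, k), 1.0 / k)
    lnlik_trace: list[float] = []
    q_sum = np.zeros((n, k))
    kept = 0

    total = burn_in + reps
    for it in range(total):
        # emission probability of each scored call under each cluster
        b = np.where(x1[:, :, None], p.T[None, :, :], (1.0 - p).T[None, :, :])
        w = q[:, None, :] * b                        # (n, L, K)
        w_sum = w.sum(axis=2)
        # latent origins by inverse-CDF sampling
        u = rng.random((n, L)) * w_sum
        cdf = np.cumsum(w, axis=2)
        z = (u[:, :, None] > cdf).sum(axis=2)        # in 0..K-1
        z_oh = np.eye(k, dtype=bool)[z] & scored[:, :, None]

        ones = (z_oh & x1[:, :, None]).sum(axis=0)   # (L, K)
        tot = z_oh.sum(axis=0)                       # (L, K)
        p = rng.beta(1.0 + ones.T, 1.0 + (tot - ones).T)

        counts = z_oh.sum(axis=1)                    # (n, K)
        gam = rng.gamma(1.0 + counts)
        q = gam / gam.sum(axis=1, keepdims=True)

        if it >= burn_in and (it - burn_in) % thin == thin - 1:
            lnlik_trace.append(float(np.log(w_sum[scored]).sum()))
            q_sum += q
            kept += 1

    trace = np.asarray(lnlik_trace)
    mean_l = float(trace.mean())
    var_l = float(trace.var(ddof=1)) if trace.size > 1 else 0.0
    q_mean = q_sum / max(kept, 1)
    q_mean /= q_mean.sum(axis=1, keepdims=True)
    if k == 1:
        q_mean = np.ones((n, 1))
    return AdmixtureResult(
        k=k,
        individual_ids=list(m.individual_ids),
        q=q_mean,
        ln_prob=mean_l - var_l / 2.0,
        mean_ln_lik=mean_l,
        var_ln_lik=var_l,
        settings={"burn_in": burn_in, "reps": reps, "thin": thin, "seed": seed},
    )


def evanno_delta_k(
    ln_probs: Mapping[int, Sequence[float]]
) -> tuple[pd.DataFrame, int]:
    """Evanno second-order rate-of-change table and the optimal K.

    ``ln_probs`` maps each K to its replicate ln-probabilities; at least
    three consecutive K values with >= 2 replicates each are required. The
    end-point K values have no DeltaK (reported as NaN); the optimal K is
    the interior argmax of DeltaK.
    """
    ks = sorted(ln_probs)
    if len(ks) < 3 or any(b - a != 1 for a, b in zip(ks, ks[1:])):
        raise ValueError("need >= 3 consecutive K values")
    means = {k: float(np.mean(ln_probs[k])) for k in ks}
    sds = {k: float(np.std(ln_probs[k], ddof=1)) for k in ks}
    rows = []
    for k in ks:
        if k == ks[0] or k == ks[-1]:
            dk = np.nan
        else:
            if sds[k] == 0.0:
                raise ValueError(f"zero replicate sd at K={k}; DeltaK undefined")
            dk = abs(means[k + 1] - 2.0 * means[k] + means[k - 1]) / sds[k]
        rows.append(
            {
                "K": k,
                "n_replicates": len(ln_probs[k]),
                "mean_ln_prob": means[k],
                "sd_ln_prob": sds[k],
                "delta_k": dk,
            }
        )
    table = pd.DataFrame(rows)
    interior = table.dropna(subset=["delta_k"])
    optimal = int(interior.loc[interior["delta_k"].idxmax(), "K"])
    return table, optimal


def assign_individuals(
    q: np.ndarray, threshold: float = 0.8
) -> tuple[list[int | str], dict]:
    """Assign each individual to the cluster with ancestry >= threshold.

    Individuals with no component reaching the (inclusive) threshold are
    labelled ``"admixed"``. Returns the assignments and a summary with the
    percentage of individuals per cluster and percent admixed.
    """
    q = np.asarray(q, dtype=float)
    if not np.allclose(q.sum(axis=1), 1.0, atol=1e-6):
        raise ValueError("ancestry rows must sum to 1")
    out: list[int | str] = []
    for row in q:
        top = int(np.argmax(row))
        out.append(top if row[top] >= threshold else "admixed")
    n = len(out)
    summary = {
        "percent_admixed": 100.0 * sum(1 for a in out if a == "admixed") / n,
        "percent_per_cluster": {
            c: 100.0 * sum(1 for a in out if a == c) / n for c in range(q.shape[1])
        },
    }
    return out, summary


def match_cluster_labels(q: np.ndarray, truth: Sequence[int]) -> np.ndarray:
    """Relabel clusters to best match integer truth labels (0..K-1).

    Cluster labels are only identified up to permutation; this searches all
    K! relabelings for the one maximising the summed ancestry mass on the
    true labels and returns Q with columns permuted accordingly.
    """
    q = np.asarray(q, dtype=float)
    k = q.shape[1]
    truth = np.asarray(truth)
    best_perm, best_score = None, -np.inf
    for perm in permutations(range(k)):
        score = sum(q[i, perm[truth[i]]] for i in range(len(truth)))
        if score > best_score:
            best_perm, best_score = perm, score
    return q[:, list(best_perm)]
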