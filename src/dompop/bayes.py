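"""Hierarchical Bayesian inference of differentiation and inbreeding from
dominant band counts.

The model treats each locus l as biallelic with ancestral dominant-allele
frequency pi_l ~ Uniform(0,1). Each population k draws its own dominant
frequency p_kl from a Beta distribution with mean pi_l and dispersion
parameter theta_B: p_kl ~ Beta(pi_l (1-theta)/theta, (1-pi_l)(1-theta)/theta),
so Var(p_kl) = theta * pi_l (1-pi_l). The observable per population/locus is
the count of band-absent individuals, Binomial(n_kl, q_kl^2 + f q_kl (1-q_kl))
with q_kl = 1 - p_kl and f ~ Uniform(0,1) the within-population inbreeding
coefficient.

Four variants mirror the standard dominant-marker analysis:

* ``full``   — theta and f both estimated;
* ``f=0``    — f fixed at zero (no inbreeding);
* ``theta=0``— all populations share one allele frequency per locus;
* ``f-free`` — f drawn fresh from its Uniform prior at every sweep, so the
  data never update it (a sensitivity device for the weakly identified f).

Sampling is Metropolis-within-Gibbs with reflective random-walk proposals,
vectorised across the population-by-locus grid (each q_kl is conditionally
independent given pi, theta, f, so element-wise parallel accept/reject is a
valid update). Proposal widths adapt during burn-in only and are frozen
afterwards. Two derived quantities are recorded at every retained sweep:
theta_I, a variance-based Fst analogue (ratio of the among-population
variance of p_kl to pbar(1-pbar), summed over loci), and the panmictic
heterozygosity h_s(k) = mean over loci of 2 p_kl q_kl. Model fit is compared
by DIC = Dbar + pD with the deviance-at-posterior-mean decomposition.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from scipy.special import betaln, gammaln

from .core import MISSING, BinaryMarkerMatrix

__all__ = ["HickoryFit", "fit_hickory", "compare_models", "VARIANTS"]

VARIANTS = ("full", "f=0", "theta=0", "f-free")

_EPS = 1e-9


@dataclass
class HickoryFit:
    """Posterior summaries and chains for one model variant."""

    variant: str
    summaries: Mapping[str, dict]      # param -> mean/sd/q2.5/q97.5
    dic: float
    mean_deviance: float
    p_d: float
    chains: Mapping[str, np.ndarray]   # thinned chains: theta_i, theta_b, f, h_s
    settings: dict
    data_shape: tuple[int, int]
    pop_labels: list[str] = field(default_factory=list)


def _counts(m: BinaryMarkerMatrix) -> tuple[np.ndarray, np.ndarray, list[str]]:
    pops = m.population_labels
    absent = np.zeros((len(pops), m.n_loci))
    scored = np.zeros((len(pops), m.n_loci))
    for k, pop in enumerate(pops):
        sub = m.calls[m.population_rows(pop)]
        absent[k] = (sub == 0).sum(axis=0)
        scored[k] = (sub != MISSING).sum(axis=0)
    if (scored == 0).any():
        raise ValueError("a population/locus cell has no scored calls")
    return absent, scored, pops


def _loglik(q: np.ndarray, f: float, absent: np.ndarray, scored: np.ndarray) -> np.ndarray:
    """Element-wise binomial log-likelihood (without the constant term)."""
    p0 = np.clip(q**2 + f * q * (1.0 - q), _EPS, 1.0 - _EPS)
    return absent * np.log(p0) + (scored - absent) * np.log1p(-p0)


def _beta_logpdf(q: np.ndarray, pi: np.ndarray, theta: float) -> np.ndarray:
    """Log density of q_kl ~ Beta((1-pi_l) s, pi_l s), s = (1-theta)/theta."""
    s = (1.0 - theta) / theta
    a = np.clip((1.0 - pi) * s, _EPS, None)
    b = np.clip(pi * s, _EPS, None)
    return (a - 1.0) * np.log(q) + (b - 1.0) * np.log1p(-q) - betaln(a, b)


def _reflect(x: np.ndarray, lo: float = _EPS, hi: float = 1.0 - _EPS) -> np.ndarray:
    """Reflect a random-walk proposal back into (lo, hi)."""
    span = hi - lo
    y = np.mod(np.abs(x - lo), 2.0 * span)
    return lo + np.where(y > span, 2.0 * span - y, y)


def _theta_i(q: np.ndarray) -> float:
    """Variance-ratio Fst analogue from the sampled frequency grid."""
    p = 1.0 - q
    pbar = p.mean(axis=0)
    num = p.var(axis=0, ddof=1).sum()
    den = (pbar * (1.0 - pbar)).sum()
    return float(num / den) if den > 0 else 0.0


def fit_hickory(
    m: BinaryMarkerMatrix,
    variant: str = "full",
    burn_in: int = 50_000,
    samples: int = 250_000,
    thin: int = 50,
    seed: int | None = None,
) -> HickoryFit:
    """Fit one variant of the hierarchical Beta-binomial model by MCMC.

    Defaults follow common practice for this analysis (burn-in 50,000,
    250,000 retained-phase sweeps, thinning 50); tests and quick looks
    should scale these down (e.g. 2,000 / 10,000 / 10).
    """
    if variant not in VARIANTS:
        raise ValueError(f"variant must be one of {VARIANTS}")
    if seed is None:
        raise ValueError("seed is mandatory")
    absent, scored, pops = _counts(m)
    K, L = absent.shape
    if K < 2:
        raise ValueError("need >= 2 populations")
    rng = np.random.default_rng(seed)

    shared_q = variant == "theta=0"
    sample_f = variant == "full"
    prior_f = variant == "f-free"

    # initial state from moment estimates
    bf = 1.0 - absent / scored
    q = np.clip(np.sqrt(np.clip(1.0 - bf, _EPS, 1.0)), 0.02, 0.98)
    if shared_q:
        q = np.tile(
            np.clip(np.sqrt(np.clip(1.0 - bf.mean(axis=0), _EPS, 1.0)), 0.02, 0.98),
            (K, 1),
        )
    pi = np.clip(1.0 - q.mean(axis=0), 0.02, 0.98)
    theta = 0.1
    f = 0.0 if variant == "f=0" else (rng.uniform() if prior_f else 0.1)

    step_q = np.full((1, L) if shared_q else (K, L), 0.1)
    step_pi = np.full(L, 0.1)
    step_theta = 0.05
    step_f = 0.05

    n_keep = samples // thin
    chain_ti = np.empty(n_keep)
    chain_tb = np.empty(n_keep)
    chain_f = np.empty(n_keep)
    chain_hs = np.empty((n_keep, K))
    chain_dev = np.empty(n_keep)
    sum_q = np.zeros_like(q)
    sum_f = 0.0

    # binomial coefficient constant, once
    dev_const = -2.0 * float(
        (gammaln(scored + 1) - gammaln(absent + 1) - gammaln(scored - absent + 1)).sum()
    )

    ll = _loglik(q, f, absent, scored)

    def q_logpost(qv: np.ndarray, fv: float) -> np.ndarray:
        lp = _loglik(qv, fv, absent, scored)
        if not shared_q:
            lp = lp + _beta_logpdf(qv, pi, theta)
        return lp

    kept = 0
    total = burn_in + samples
    for it in range(total):
        adapting = it < burn_in

        # ---- q update (element-wise parallel) ----
        if shared_q:
            prop_row = _reflect(q[0] + step_q[0] * rng.standard_normal(L))
            prop = np.tile(prop_row, (K, 1))
            cur_lp = _loglik(q, f, absent, scored).sum(axis=0)
            new_lp = _loglik(prop, f, absent, scored).sum(axis=0)
            acc = np.log(rng.random(L)) < (new_lp - cur_lp)
            q[:, acc] = prop[:, acc]
            if adapting:
                step_q[0] *= np.where(acc, 1.02, 0.98)
                np.clip(step_q, 1e-3, 0.5, out=step_q)
        else:
            prop = _reflect(q + step_q * rng.standard_normal((K, L)))
            cur_lp = q_logpost(q, f)
            new_lp = q_logpost(prop, f)
            acc = np.log(rng.random((K, L))) < (new_lp - cur_lp)
            q[acc] = prop[acc]
            if adapting:
                step_q *= np.where(acc, 1.02, 0.98)
                np.clip(step_q, 1e-3, 0.5, out=step_q)

        # ---- pi update (per locus) ----
        if shared_q:
            # pi is the shared dominant frequency: deterministic from q
            pi = 1.0 - q[0]
        else:
            prop_pi = _reflect(pi + step_pi * rng.standard_normal(L))
            cur = _beta_logpdf(q, pi, theta).sum(axis=0)
            new = _beta_logpdf(q, prop_pi, theta).sum(axis=0)
            acc = np.log(rng.random(L)) < (new - cur)
            pi[acc] = prop_pi[acc]
            if adapting:
                step_pi *= np.where(acc, 1.02, 0.98)
                np.clip(step_pi, 1e-3, 0.5, out=step_pi)

            # ---- theta update (scalar) ----
            prop_theta = float(_reflect(np.array(theta + step_theta * rng.standard_normal())))
            cur_t = _beta_logpdf(q, pi, theta).sum()
            new_t = _beta_logpdf(q, pi, prop_theta).sum()
            if np.log(rng.random()) < (new_t - cur_t):
                theta = prop_theta
                if adapting:
                    step_theta = min(step_theta * 1.02, 0.5)
            elif adapting:
                step_theta = max(step_theta * 0.98, 1e-3)

        # ---- f update ----
        if sample_f:
            prop_f = float(_reflect(np.array(f + step_f * rng.standard_normal())))
            cur_f = _loglik(q, f, absent, scored).sum()
            new_f = _loglik(q, prop_f, absent, scored).sum()
            if np.log(rng.random()) < (new_f - cur_f):
                f = prop_f
                if adapting:
                    step_f = min(step_f * 1.02, 0.5)
            elif adapting:
                step_f = max(step_f * 0.98, 1e-3)
        elif prior_f:
            f = float(rng.uniform())

        # ---- record ----
        if not adapting and (it - burn_in) % thin == thin - 1 and kept < n_keep:
            p = 1.0 - q
            chain_ti[kept] = 0.0 if shared_q else _theta_i(q)
            chain_tb[kept] = 0.0 if shared_q else theta
            chain_f[kept] = f
            chain_hs[kept] = (2.0 * p * q).mean(axis=1)
            chain_dev[kept] = dev_const - 2.0 * _loglik(q, f, absent, scored).sum()
            sum_q += q
            sum_f += f
            kept += 1

    chains = {
        "theta_i": chain_ti[:kept],
        "theta_b": chain_tb[:kept],
        "f": chain_f[:kept],
        "h_s": chain_hs[:kept],
        "deviance": chain_dev[:kept],
    }

    def summarize(x: np.ndarray) -> dict:
        return {
            "mean": float(np.mean(x)),
            "sd": float(np.std(x, ddof=1)) if x.size > 1 else 0.0,
            "q2.5": float(np.quantile(x, 0.025)),
            "q97.5": float(np.quantile(x, 0.975)),
        }

    summaries = {
        "theta_i": summarize(chains["theta_i"]),
        "theta_b": summarize(chains["theta_b"]),
        "f": summarize(chains["f"]),
    }
    for k, pop in enumerate(pops):
        summaries[f"h_s[{pop}]"] = summarize(chains["h_s"][:, k])

    mean_dev = float(chains["deviance"].mean())
    q_bar = np.clip(sum_q / max(kept, 1), _EPS, 1 - _EPS)
    f_bar = sum_f / max(kept, 1)
    dev_at_mean = dev_const - 2.0 * float(_loglik(q_bar, f_bar, absent, scored).sum())
    p_d = mean_dev - dev_at_mean
    dic = mean_dev + p_d

    return HickoryFit(
        variant=variant,
        summaries=summaries,
        dic=dic,
        mean_deviance=mean_dev,
        p_d=p_d,
        chains=chains,
        settings={
            "burn_in": burn_in, "samples": samples, "thin": thin, "seed": seed,
        },
        data_shape=(K, L),
        pop_labels=pops,
    )


def compare_models(fits: list[HickoryFit]) -> list[dict]:
    """Rank fits of the same data by DIC (smaller is preferred).

    Ties are ordered by variant name for stability. Returns one record per
    fit with ``variant``, ``dic`` and ``delta_dic`` (difference to the best).
    """
    if not fits:
        raise ValueError("no fits to compare")
    shapes = {f.data_shape for f in fits}
    if len(shapes) > 1:
        raise ValueError("fits come from different datasets")
    ranked = sorted(fits, key=lambda f: (f.dic, f.variant))
    best = ranked[0].dic
    return [
        {"variant": f.variant, "dic": f.dic, "delta_dic": f.dic - best}
        for f in ranked
    ]
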