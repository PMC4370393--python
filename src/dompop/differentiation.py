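"""Among-population differentiation for dominant band data.

AMOVA follows the Excoffier molecular-variance framework on pairwise
squared Euclidean distances between band vectors (for 0/1 calls this is the
count of differing non-missing calls): total and within-group sums of
squared deviations are obtained from pairwise distances, variance components
from the expected mean squares with the standard unequal-sample-size
coefficient, and Phi-st is tested by permuting individuals across
populations. Pairwise Fst is the two-population Phi-st. Gst is the classic
allele-frequency based measure (Ht - Hs)/Ht computed from the square-root
allele-frequency estimates, and gene flow uses the island-model relation
Nm = (1 - Fst)/(4 Fst). The linkage-disequilibrium screen applies a
two-sided Fisher's exact test to every pair of polymorphic loci on the
pooled 2x2 band-state table.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy.stats import fisher_exact

from .core import MISSING, BinaryMarkerMatrix, DistanceMatrix
from .informativeness import null_allele_frequency

__all__ = [
    "gst",
    "gst_from_frequencies",
    "AmovaResult",
    "band_distance_matrix",
    "amova",
    "pairwise_fst",
    "GeneFlowEstimate",
    "gene_flow",
    "ld_screen",
    "ld_percent",
]


# ---------------------------------------------------------------------------
# Gst
# ---------------------------------------------------------------------------

def gst_from_frequencies(q_by_pop: np.ndarray) -> float:
    """Gst from per-population null-allele frequencies, shape (n_pops, n_loci).

    Per locus, Ht = 2 p_bar q_bar from the unweighted mean allele frequency
    and Hs = unweighted mean of within-population 2pq; loci are combined as
    the ratio of sums (sum Ht - sum Hs)/(sum Ht). Returns 0 when every locus
    has Ht = 0.
    """
    q = np.asarray(q_by_pop, dtype=float)
    if q.ndim != 2 or q.shape[0] < 2:
        raise ValueError("need >= 2 populations of per-locus frequencies")
    p = 1.0 - q
    qbar = q.mean(axis=0)
    ht = 2.0 * (1.0 - qbar) * qbar
    hs = (2.0 * p * q).mean(axis=0)
    total_ht = ht.sum()
    if total_ht == 0.0:
        return 0.0
    return float((total_ht - hs.sum()) / total_ht)


def gst(m: BinaryMarkerMatrix) -> float:
    """Gst of a marker matrix via square-root allele-frequency estimates."""
    q = np.vstack(
        [
            null_allele_frequency(m.band_frequencies(m.population_rows(pop)))
            for pop in m.population_labels
        ]
    )
    return gst_from_frequencies(q)


# ---------------------------------------------------------------------------
# AMOVA
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AmovaResult:
    """Two-level AMOVA table (among / within populations)."""

    ssd_among: float
    ssd_within: float
    df_among: int
    df_within: int
    sigma2_among: float
    sigma2_within: float
    percent_among: float
    percent_within: float
    phi_st: float
    p_value: float | None
    n_permutations: int
    seed: int | None
    defined: bool = True

    @property
    def ssd_total(self) -> float:
        return self.ssd_among + self.ssd_within


def band_distance_matrix(m: BinaryMarkerMatrix) -> np.ndarray:
    """Pairwise squared Euclidean distance between 0/1 band vectors.

    With missing calls, a locus contributes to a pair only when both
    individuals are scored.
    """
    x = m.calls.astype(float)
    if (m.calls == MISSING).any():
        n = m.n_individuals
        d = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                ok = (m.calls[i] != MISSING) & (m.calls[j] != MISSING)
                d[i, j] = d[j, i] = float(((x[i, ok] - x[j, ok]) ** 2).sum())
        return d
    g = x @ x.T
    sq = np.diag(g)
    d = sq[:, None] + sq[None, :] - 2.0 * g
    np.fill_diagonal(d, 0.0)
    return np.maximum(d, 0.0)


def _ssd_parts(d: np.ndarray, groups: np.ndarray) -> tuple[float, float]:
    n = d.shape[0]
    iu = np.triu_indices(n, k=1)
    ssd_total = float(d[iu].sum()) / n
    ssd_within = 0.0
    for g in np.unique(groups):
        rows = np.flatnonzero(groups == g)
        sub = d[np.ix_(rows, rows)]
        ssd_within += float(np.triu(sub, k=1).sum()) / rows.size
    return ssd_total, ssd_within


def _phi_from_ssd(
    ssd_total: float, ssd_within: float, sizes: np.ndarray
) -> tuple[float, float, float]:
    n = int(sizes.sum())
    n_pops = sizes.size
    df_among = n_pops - 1
    df_within = n - n_pops
    ssd_among = ssd_total - ssd_within
    sigma_w = ssd_within / df_within
    n0 = (n - float((sizes**2).sum()) / n) / df_among
    sigma_a = (ssd_among / df_among - sigma_w) / n0
    denom = sigma_a + sigma_w
    phi = sigma_a / denom if denom != 0 else np.nan
    return sigma_a, sigma_w, phi


def amova(
    m: BinaryMarkerMatrix,
    n_perm: int = 1000,
    seed: int | None = None,
) -> AmovaResult:
    """Two-level AMOVA with a permutation test of Phi-st.

    The permutation null shuffles individuals across populations keeping the
    sample sizes; the p-value includes the observed statistic in numerator
    and denominator. ``n_perm = 0`` skips the test (p reported as None).
    """
    pops = np.asarray(m.populations, dtype=object)
    labels, groups = np.unique(pops, return_inverse=True)
    if labels.size < 2:
        raise ValueError("AMOVA needs >= 2 populations")
    sizes = np.bincount(groups)
    if (sizes < 2).any():
        raise ValueError("AMOVA needs >= 2 individuals per population")

    d = band_distance_matrix(m)
    ssd_total, ssd_within = _ssd_parts(d, groups)
    n = m.n_individuals
    n_pops = labels.size
    df_among, df_within = n_pops - 1, n - n_pops
    ssd_among = ssd_total - ssd_within

    if ssd_total == 0.0:
        return AmovaResult(
            ssd_among=0.0, ssd_within=0.0, df_among=df_among, df_within=df_within,
            sigma2_among=0.0, sigma2_within=0.0, percent_among=np.nan,
            percent_within=np.nan, phi_st=np.nan, p_value=None,
            n_permutations=0, seed=seed, defined=False,
        )

    sigma_a, sigma_w, phi = _phi_from_ssd(ssd_total, ssd_within, sizes)
    total_var = sigma_a + sigma_w

    p_value: float | None = None
    if n_perm > 0:
        if seed is None:
            raise ValueError("seed is required when permuting")
        rng = np.random.default_rng(seed)
        hits = 1  # observed included
        perm = groups.copy()
        for _ in range(n_perm):
            rng.shuffle(perm)
            _, ssd_w = _ssd_parts(d, perm)
            _, _, phi_p = _phi_from_ssd(ssd_total, ssd_w, sizes)
            if phi_p >= phi:
                hits += 1
        p_value = hits / (n_perm + 1)

    return AmovaResult(
        ssd_among=ssd_among,
        ssd_within=ssd_within,
        df_among=df_among,
        df_within=df_within,
        sigma2_among=sigma_a,
        sigma2_within=sigma_w,
        percent_among=100.0 * sigma_a / total_var,
        percent_within=100.0 * sigma_w / total_var,
        phi_st=phi,
        p_value=p_value,
        n_permutations=n_perm,
        seed=seed,
    )


def pairwise_fst(
    m: BinaryMarkerMatrix,
    n_perm: int = 0,
    seed: int | None = None,
) -> tuple[DistanceMatrix, np.ndarray | None]:
    """Pairwise Fst matrix: two-population Phi-st for every population pair.

    Returns the symmetric Fst matrix and, when ``n_perm > 0``, an aligned
    matrix of permutation p-values (NaN on the diagonal).
    """
    pops = m.population_labels
    k = len(pops)
    fst = np.zeros((k, k))
    pvals = np.full((k, k), np.nan) if n_perm > 0 else None
    rng = np.random.default_rng(seed) if n_perm > 0 else None
    for a, b in combinations(range(k), 2):
        sub = m.subset_populations([pops[a], pops[b]])
        pair_seed = int(rng.integers(2**31 - 1)) if rng is not None else None
        res = amova(sub, n_perm=n_perm, seed=pair_seed)
        fst[a, b] = fst[b, a] = res.phi_st
        if pvals is not None:
            pvals[a, b] = pvals[b, a] = res.p_value
    return DistanceMatrix(list(pops), fst, units="fst"), pvals


# ---------------------------------------------------------------------------
# gene flow
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GeneFlowEstimate:
    fst: float
    nm: float


def gene_flow(fst: float) -> GeneFlowEstimate:
    """Island-model gene flow Nm = (1 - Fst)/(4 Fst), for Fst in (0, 1)."""
    if not 0.0 < fst < 1.0:
        raise ValueError("Fst must lie strictly in (0, 1)")
    return GeneFlowEstimate(fst=float(fst), nm=(1.0 - fst) / (4.0 * fst))


# ---------------------------------------------------------------------------
# linkage-disequilibrium screen
# ---------------------------------------------------------------------------

def ld_percent(n_significant: int, n_tested: int) -> float:
    """Percentage of significant locus pairs, rounded to one decimal."""
    if n_tested <= 0:
        raise ValueError("n_tested must be positive")
    return round(100.0 * n_significant / n_tested, 1)


def ld_screen(
    m: BinaryMarkerMatrix,
    alpha: float = 0.05,
    pair_convention: str = "unordered",
) -> dict[str, float | int]:
    """Genome-wide pairwise association screen on pooled band states.

    Each pair of polymorphic loci is tested with a two-sided Fisher's exact
    test on the 2x2 table of joint presence/absence across all individuals
    (populations pooled). ``pair_convention='unordered'`` tests C(L,2) pairs;
    ``'ordered'`` reports the L^2 denominator (each unordered pair counted
    twice; self-pairs enter the denominator only), matching reports that
    quote all ordered combinations.
    """
    if pair_convention not in ("unordered", "ordered"):
        raise ValueError("pair_convention must be 'unordered' or 'ordered'")
    bf = m.band_frequencies()
    poly = np.flatnonzero((bf > 0) & (bf < 1))
    if poly.size < 2:
        raise ValueError("need >= 2 polymorphic loci")
    n_monomorphic = m.n_loci - poly.size

    n_sig = 0
    n_unordered = 0
    calls = m.calls
    for a, b in combinations(poly.tolist(), 2):
        ok = (calls[:, a] != MISSING) & (calls[:, b] != MISSING)
        xa, xb = calls[ok, a], calls[ok, b]
        table = np.array(
            [
                [int(((xa == 1) & (xb == 1)).sum()), int(((xa == 1) & (xb == 0)).sum())],
                [int(((xa == 0) & (xb == 1)).sum()), int(((xa == 0) & (xb == 0)).sum())],
            ]
        )
        _, p = fisher_exact(table, alternative="two-sided")
        n_unordered += 1
        if p <= alpha:
            n_sig += 1

    if pair_convention == "ordered":
        n_tested = poly.size**2
        n_sig *= 2
    else:
        n_tested = n_unordered
    return {
        "n_pairs_tested": n_tested,
        "n_significant": n_sig,
        "percent": ld_percent(n_sig, n_tested),
        "n_monomorphic_excluded": n_monomorphic,
        "alpha": alpha,
    }
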