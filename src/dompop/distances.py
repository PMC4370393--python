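"""Genetic and geographic distances, UPGMA clustering, PCoA and Mantel test.

Nei's unbiased genetic distance (the 1978 small-sample version) is computed
from the dominant-marker allele-frequency estimates; UPGMA is agglomerative
clustering with cluster-to-cluster distance equal to the arithmetic mean of
all cross-pairs of original distances (heights = merge distance / 2, giving
an ultrametric tree); PCoA is classical metric scaling via Gower double
centering; the Mantel test correlates two distance matrices with a joint
row/column permutation null, enumerated exhaustively for small n.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations, permutations
from math import factorial

import numpy as np

from .core import BinaryMarkerMatrix, DistanceMatrix, PopulationSite
from .informativeness import null_allele_frequency

__all__ = [
    "nei_unbiased_distance",
    "nei_distance_matrix",
    "UpgmaNode",
    "UpgmaTree",
    "upgma",
    "OrdinationResult",
    "pcoa",
    "haversine_km",
    "geographic_distances",
    "mantel",
]

EARTH_RADIUS_KM = 6371.0088


# ---------------------------------------------------------------------------
# Nei's unbiased distance
# ---------------------------------------------------------------------------

def nei_unbiased_distance(
    q_x: np.ndarray, q_y: np.ndarray, n_x: int, n_y: int
) -> float:
    """Nei's (1978) unbiased genetic distance between two populations.

    ``q_x``/``q_y`` are per-locus null-allele frequencies and ``n_x``/``n_y``
    the numbers of diploid individuals sampled. Within-population gene
    identities use the small-sample-unbiased form (2n sum(p_i^2) - 1)/(2n - 1)
    per locus; the distance is -ln(Jxy / sqrt(Jx Jy)) on locus-averaged
    identities.
    """
    if n_x < 2 or n_y < 2:
        raise ValueError("both samples must have n >= 2")
    q_x = np.asarray(q_x, dtype=float)
    q_y = np.asarray(q_y, dtype=float)
    if q_x.shape != q_y.shape:
        raise ValueError("populations must share the same loci")
    p_x, p_y = 1.0 - q_x, 1.0 - q_y
    jxy = (p_x * p_y + q_x * q_y).mean()
    sum2_x = p_x**2 + q_x**2
    sum2_y = p_y**2 + q_y**2
    jx = ((2 * n_x * sum2_x - 1.0) / (2 * n_x - 1.0)).mean()
    jy = ((2 * n_y * sum2_y - 1.0) / (2 * n_y - 1.0)).mean()
    denom = np.sqrt(jx * jy)
    if jxy <= 0 or denom <= 0:
        raise ValueError("zero gene identity; distance undefined")
    return float(-np.log(jxy / denom))


def nei_distance_matrix(m: BinaryMarkerMatrix) -> DistanceMatrix:
    """Pairwise Nei unbiased distances among the matrix's populations."""
    pops = m.population_labels
    freqs = {}
    sizes = {}
    for pop in pops:
        rows = m.population_rows(pop)
        freqs[pop] = null_allele_frequency(m.band_frequencies(rows))
        sizes[pop] = rows.size
    n = len(pops)
    d = np.zeros((n, n))
    for a, b in combinations(range(n), 2):
        d[a, b] = d[b, a] = nei_unbiased_distance(
            freqs[pops[a]], freqs[pops[b]], sizes[pops[a]], sizes[pops[b]]
        )
    return DistanceMatrix(pops, d, units="nei-distance")


# ---------------------------------------------------------------------------
# UPGMA
# ---------------------------------------------------------------------------

@dataclass
class UpgmaNode:
    """A node of an ultrametric UPGMA tree."""

    label: str | None = None
    height: float = 0.0
    children: tuple["UpgmaNode", "UpgmaNode"] | None = None

    def leaves(self) -> list[str]:
        if self.children is None:
            return [self.label]  # type: ignore[list-item]
        return self.children[0].leaves() + self.children[1].leaves()

    def newick(self, parent_height: float | None = None) -> str:
        length = (
            "" if parent_height is None else f":{parent_height - self.height:.10g}"
        )
        if self.children is None:
            return f"{self.label}{length}"
        inner = ",".join(c.newick(self.height) for c in self.children)
        return f"({inner}){length}"


@dataclass
class UpgmaTree:
    """UPGMA result: rooted ultrametric tree plus the merge order."""

    root: UpgmaNode
    merge_order: list[tuple[str, str, float]] = field(default_factory=list)

    def newick(self) -> str:
        return self.root.newick() + ";"

    def cut(self, n_groups: int) -> list[frozenset[str]]:
        """Leaf-label groups obtained by undoing the last merges."""
        clusters = [self.root]
        while len(clusters) < n_groups:
            internal = [c for c in clusters if c.children is not None]
            if not internal:
                break
            top = max(internal, key=lambda c: c.height)
            clusters.remove(top)
            clusters.extend(top.children)  # type: ignore[arg-type]
        return sorted(
            (frozenset(c.leaves()) for c in clusters), key=lambda s: sorted(s)[0]
        )


def upgma(d: DistanceMatrix) -> UpgmaTree:
    """UPGMA clustering of a distance matrix.

    At each step the pair of clusters with the smallest mean cross-pair
    distance (computed from the original matrix) merges at height =
    distance/2. Exact ties are broken by the lexicographically smallest pair
    of cluster representative labels (a cluster is represented by its
    alphabetically first leaf).
    """
    labels = d.labels
    if len(labels) < 2:
        raise ValueError("UPGMA needs >= 2 taxa")
    base = d.values
    idx = {lab: i for i, lab in enumerate(labels)}
    clusters: list[UpgmaNode] = [UpgmaNode(label=lab) for lab in labels]
    members: list[list[int]] = [[idx[lab]] for lab in labels]
    merges: list[tuple[str, str, float]] = []

    def mean_cross(a: list[int], b: list[int]) -> float:
        return float(base[np.ix_(a, b)].mean())

    while len(clusters) > 1:
        best = None
        for i, j in combinations(range(len(clusters)), 2):
            dist = mean_cross(members[i], members[j])
            ri = min(clusters[i].leaves())
            rj = min(clusters[j].leaves())
            key = (dist, *sorted((ri, rj)))
            if best is None or key < best[0]:
                best = (key, i, j)
        (dist, ra, rb), i, j = best  # type: ignore[misc]
        node = UpgmaNode(
            height=dist / 2.0, children=(clusters[i], clusters[j])
        )
        merges.append((ra, rb, dist))
        new_members = members[i] + members[j]
        for k in sorted((i, j), reverse=True):
            clusters.pop(k)
            members.pop(k)
        clusters.append(node)
        members.append(new_members)
    return UpgmaTree(root=clusters[0], merge_order=merges)


# ---------------------------------------------------------------------------
# PCoA
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class OrdinationResult:
    """Principal-coordinate embedding of a distance matrix."""

    labels: list[str]
    coordinates: np.ndarray        # (n_items, n_axes), positive axes only
    percent_variance: np.ndarray   # per retained axis, sums to 100
    eigenvalues: np.ndarray        # all eigenvalues, descending


def pcoa(d: DistanceMatrix, n_axes: int | None = None) -> OrdinationResult:
    """Classical metric scaling (principal coordinates) of a distance matrix.

    Gower double centering of -d^2/2 followed by eigendecomposition; axes
    are ordered by eigenvalue, percentages are relative to the sum of
    positive eigenvalues, and negative-eigenvalue axes are reported in
    ``eigenvalues`` but excluded from coordinates and percentages.
    """
    vals = d.values
    if not np.any(vals > 0):
        raise ValueError("all distances are zero; ordination undefined")
    n = vals.shape[0]
    a = -0.5 * vals**2
    j = np.eye(n) - np.ones((n, n)) / n
    b = j @ a @ j
    eigval, eigvec = np.linalg.eigh((b + b.T) / 2.0)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    pos = eigval > max(1e-12, 1e-10 * abs(eigval[0]))
    lam = eigval[pos]
    coords = eigvec[:, pos] * np.sqrt(lam)
    pct = 100.0 * lam / lam.sum()
    if n_axes is not None:
        coords = coords[:, :n_axes]
        pct = pct[:n_axes]
    return OrdinationResult(
        labels=list(d.labels),
        coordinates=coords,
        percent_variance=pct,
        eigenvalues=eigval,
    )


# ---------------------------------------------------------------------------
# geographic distances
# ---------------------------------------------------------------------------

def haversine_km(lat1: float, lon1: float, lat2: float, lon2: float) -> float:
    """Great-circle distance in km between two points in decimal degrees."""
    phi1, phi2 = np.radians(lat1), np.radians(lat2)
    dphi = phi2 - phi1
    dlam = np.radians(lon2 - lon1)
    a = np.sin(dphi / 2) ** 2 + np.cos(phi1) * np.cos(phi2) * np.sin(dlam / 2) ** 2
    return float(2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(a)))


def geographic_distances(sites: list[PopulationSite]) -> DistanceMatrix:
    """Great-circle distance matrix (km) among sampling sites."""
    n = len(sites)
    d = np.zeros((n, n))
    for i, j in combinations(range(n), 2):
        d[i, j] = d[j, i] = haversine_km(
            sites[i].latitude, sites[i].longitude,
            sites[j].latitude, sites[j].longitude,
        )
    return DistanceMatrix([s.name for s in sites], d, units="km")


# ---------------------------------------------------------------------------
# Mantel test
# ---------------------------------------------------------------------------

_EXHAUSTIVE_LIMIT = 5040  # 7!


def mantel(
    d1: DistanceMatrix,
    d2: DistanceMatrix,
    n_perm: int = 9999,
    seed: int | None = None,
    exhaustive: bool | None = None,
    alternative: str = "two-sided",
) -> tuple[float, float]:
    """Mantel correlation between two distance matrices with permutation p.

    r is the Pearson correlation over lower-triangle entries; the null
    permutes rows and columns of ``d2`` jointly. With ``exhaustive=None``
    all n! permutations are enumerated when n! <= 5040, otherwise ``n_perm``
    random permutations are drawn (observed included in numerator and
    denominator). Two-sided by default: extreme means |r_perm| >= |r_obs|.
    """
    if d1.labels != d2.labels:
        d2 = d2.reorder(d1.labels)
    n = len(d1.labels)
    if n < 3:
        raise ValueError("Mantel test needs >= 3 items")
    tri = np.tril_indices(n, k=-1)
    x = d1.values[tri]

    def corr(mat: np.ndarray) -> float:
        y = mat[tri]
        sx, sy = x.std(), y.std()
        if sx == 0 or sy == 0:
            raise ValueError("zero variance in a distance triangle")
        return float(((x - x.mean()) * (y - y.mean())).mean() / (sx * sy))

    r_obs = corr(d2.values)

    def extreme(r: float) -> bool:
        if alternative == "two-sided":
            return abs(r) >= abs(r_obs) - 1e-12
        if alternative == "greater":
            return r >= r_obs - 1e-12
        if alternative == "less":
            return r <= r_obs + 1e-12
        raise ValueError(f"unknown alternative {alternative!r}")

    use_exhaustive = (
        exhaustive if exhaustive is not None else factorial(n) <= _EXHAUSTIVE_LIMIT
    )
    if use_exhaustive:
        hits = total = 0
        for perm in permutations(range(n)):
            p = np.array(perm)
            if extreme(corr(d2.values[np.ix_(p, p)])):
                hits += 1
            total += 1
        return r_obs, hits / total
    if seed is None:
        raise ValueError("seed is required for random permutations")
    rng = np.random.default_rng(seed)
    hits = 1
    perm = np.arange(n)
    for _ in range(n_perm):
        rng.shuffle(perm)
        if extreme(corr(d2.values[np.ix_(perm, perm)])):
            hits += 1
    return r_obs, hits / (n_perm + 1)
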