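"""Synthetic dominant-marker datasets with known truth.

The generative model mirrors the hierarchical model used for Bayesian
inference: each locus has an ancestral dominant-allele frequency pi_l; each
population draws its own dominant-allele frequency p_kl from a Beta
distribution centred on pi_l with among-population dispersion theta
(Var p_kl = theta * pi_l * (1 - pi_l)); within a population, an individual's
band is absent with the null-homozygote probability q^2 + f*q*(1-q) where
q = 1 - p and f is the within-population inbreeding coefficient. Band
presence therefore means "carries at least one dominant allele".

``paper_like_dataset`` reproduces the study design: 8 populations of 19-23
individuals (172 total) scored at 180 loci amplified by 10 primers, with
differentiation theta = 0.19 and inbreeding f = 0.14 set to the study's own
estimates so that estimator-recovery tests run under realistic conditions.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .core import BinaryMarkerMatrix

__all__ = ["SimulationTruth", "simulate", "paper_like_dataset", "PAPER_DESIGN"]

#: Study design constants: population labels/sizes and bands per primer.
PAPER_DESIGN = {
    "pop_sizes": {
        "YMF": 20, "FHB": 23, "SDG": 20, "SEG": 23,
        "XV": 23, "TF": 21, "WZT": 19, "SP": 23,
    },
    "primer_bands": {
        "3A01": 19, "3A21": 22, "3A42": 18, "3A54": 18, "3A62": 16,
        "3A07": 17, "3A39": 20, "3A53": 10, "3A56": 19, "UBC873": 21,
    },
    "theta": 0.19,
    "f": 0.14,
}


@dataclass(frozen=True)
class SimulationTruth:
    """Ground-truth parameters behind a simulated dataset."""

    pi: np.ndarray                  # ancestral dominant-allele frequency per locus
    theta: float                    # among-population differentiation
    f: float                        # within-population inbreeding coefficient
    pop_frequencies: np.ndarray     # realized p_kl, shape (n_pops, n_loci)
    seed: int

    def __post_init__(self) -> None:
        if np.any((self.pop_frequencies < 0) | (self.pop_frequencies > 1)):
            raise ValueError("realized frequencies outside [0,1]")


def simulate(
    n_pops: int,
    n_per_pop: int | Sequence[int],
    n_loci: int,
    pi: float | Sequence[float] | None = None,
    theta: float = 0.0,
    f: float = 0.0,
    seed: int = 0,
    pi_range: tuple[float, float] = (0.05, 0.95),
    pop_labels: Sequence[str] | None = None,
) -> tuple[BinaryMarkerMatrix, SimulationTruth]:
    """Simulate a band presence/absence matrix under the hierarchical model.

    Parameters
    ----------
    pi : scalar, vector or None
        Ancestral dominant-allele frequency per locus; ``None`` draws each
        from Uniform ``pi_range`` (bounded away from 0/1 so loci are
        informative).
    theta : float in [0, 1)
        Among-population dispersion of allele frequencies (Beta model);
        ``theta = 0`` copies ``pi`` to every population exactly.
    f : float in [0, 1]
        Inbreeding coefficient entering the null-homozygote probability.
    """
    if not 0.0 <= theta < 1.0:
        raise ValueError("theta must be in [0, 1); theta = 1 is degenerate")
    if not 0.0 <= f <= 1.0:
        raise ValueError("f must be in [0, 1]")
    if n_pops < 1 or n_loci < 1:
        raise ValueError("counts must be positive")
    sizes = (
        np.full(n_pops, int(n_per_pop))
        if np.isscalar(n_per_pop)
        else np.asarray(list(n_per_pop), dtype=int)
    )
    if len(sizes) != n_pops or (sizes < 1).any():
        raise ValueError("n_per_pop must give a positive size per population")

    rng = np.random.default_rng(seed)
    if pi is None:
        pi_vec = rng.uniform(*pi_range, size=n_loci)
    else:
        pi_vec = np.broadcast_to(np.asarray(pi, dtype=float), (n_loci,)).copy()
    if np.any((pi_vec <= 0) | (pi_vec > 1)) and not np.all((pi_vec >= 0) & (pi_vec <= 1)):
        raise ValueError("pi must lie in [0, 1]")

    if theta == 0.0:
        p = np.tile(pi_vec, (n_pops, 1))
    else:
        scale = (1.0 - theta) / theta
        a = np.clip(pi_vec * scale, 1e-12, None)
        b = np.clip((1.0 - pi_vec) * scale, 1e-12, None)
        p = rng.beta(a, b, size=(n_pops, n_loci))
        # degenerate pi at 0/1 stay fixed
        p[:, pi_vec <= 0.0] = 0.0
        p[:, pi_vec >= 1.0] = 1.0

    q = 1.0 - p
    absent_prob = q**2 + f * q * (1.0 - q)

    labels = (
        [str(x) for x in pop_labels]
        if pop_labels is not None
        else [f"P{k + 1}" for k in range(n_pops)]
    )
    calls = np.empty((int(sizes.sum()), n_loci), dtype=np.int8)
    pops: list[str] = []
    ids: list[str] = []
    row = 0
    for k, (label, nk) in enumerate(zip(labels, sizes)):
        block = rng.random((nk, n_loci)) >= absent_prob[k]
        calls[row : row + nk] = block.astype(np.int8)
        pops.extend([label] * nk)
        ids.extend(f"{label}_{i + 1:03d}" for i in range(nk))
        row += nk

    matrix = BinaryMarkerMatrix(
        calls=calls,
        individual_ids=ids,
        populations=pops,
        locus_ids=[f"L{j + 1:04d}" for j in range(n_loci)],
    )
    truth = SimulationTruth(
        pi=pi_vec, theta=float(theta), f=float(f), pop_frequencies=p, seed=int(seed)
    )
    return matrix, truth


def paper_like_dataset(seed: int = 0) -> tuple[BinaryMarkerMatrix, SimulationTruth]:
    """Simulate a dataset shaped exactly like the study's: 172 x 180.

    8 populations with the study's sample sizes, 180 loci split into the 10
    primer groups with the published band counts, theta = 0.19, f = 0.14.
    """
    sizes = PAPER_DESIGN["pop_sizes"]
    bands = PAPER_DESIGN["primer_bands"]
    matrix, truth = simulate(
        n_pops=len(sizes),
        n_per_pop=list(sizes.values()),
        n_loci=sum(bands.values()),
        theta=PAPER_DESIGN["theta"],
        f=PAPER_DESIGN["f"],
        seed=seed,
        pop_labels=list(sizes),
    )
    primer_of: dict[str, str] = {}
    j = 0
    for primer, count in bands.items():
        for _ in range(count):
            primer_of[matrix.locus_ids[j]] = primer
            j += 1
    matrix.primer_of = primer_of
    return matrix, truth
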